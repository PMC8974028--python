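"""Normality transforms and reference-referenced standardization.

Mahalanobis distances assume roughly elliptical data, so each biomarker is
first transformed (identity, log, or sqrt — whichever minimizes the absolute
bias-corrected sample skewness) and then standardized against the mean and
standard deviation of the *reference population*, never the scored cohort's
own statistics.  Transforms are selected once on training data and frozen
into the fitted reference; scoring never re-selects.

A non-negative offset is added before log/sqrt whenever the training minimum
is at or below zero, so the transform is defined on all training values.
Ties in |skewness| (within 1e-9) break toward the least aggressive
transform: identity, then sqrt, then log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, ValidationError

_EPS = 1e-6
_TIE_TOL = 1e-9
#: preference order when |skewness| ties: least aggressive wins
_TIE_ORDER = ("identity", "sqrt", "log")


@dataclass(frozen=True)
class MarkerTransform:
    """Transform for one biomarker: a label plus the shift offset for log/sqrt."""

    label: str
    offset: float = 0.0
    constant_input: bool = False  # degenerate training column flagged

    def __post_init__(self) -> None:
        if self.label not in ("identity", "log", "sqrt"):
            raise ValidationError(f"unknown transform label {self.label!r}")
        if self.label == "identity" and self.offset != 0.0:
            raise ValidationError("offset must be 0 for identity transform")
        if self.offset < 0:
            raise ValidationError("offset must be non-negative")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.label == "identity":
            return x
        shifted = x + self.offset
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.label == "log":
                out = np.where(shifted > 0, np.log(np.where(shifted > 0, shifted, 1.0)), np.nan)
            else:
                out = np.where(shifted >= 0, np.sqrt(np.where(shifted >= 0, shifted, 0.0)), np.nan)
        return out


@dataclass
class TransformSpec:
    """Per-biomarker transforms, frozen into a fitted reference population."""

    markers: Dict[str, MarkerTransform] = field(default_factory=dict)

    def __getitem__(self, name: str) -> MarkerTransform:
        return self.markers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.markers

    def to_dict(self) -> dict:
        return {
            n: {"label": t.label, "offset": t.offset, "constant_input": t.constant_input}
            for n, t in self.markers.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransformSpec":
        return cls({n: MarkerTransform(**v) for n, v in d.items()})

    @classmethod
    def identity(cls, names: Sequence[str]) -> "TransformSpec":
        return cls({n: MarkerTransform("identity") for n in names})


def _abs_skew(x: np.ndarray) -> float:
    return abs(float(stats.skew(x, bias=False)))


def select_transform(values: Iterable[float], min_n: int = 20) -> MarkerTransform:
    """Pick the transform in {identity, log, sqrt} minimizing |sample skewness|.

    log/sqrt candidates are evaluated after adding ``offset = max(0, 1e-6 -
    min(values))`` so the transform is defined on all training values.  A
    constant input returns identity with ``constant_input=True`` and a
    warning.  Deterministic and permutation-invariant.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise InsufficientDataError(
            f"select_transform needs >= {min_n} finite values, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        warnings.warn("constant input: falling back to identity transform", stacklevel=2)
        return MarkerTransform("identity", constant_input=True)

    offset = max(0.0, _EPS - float(np.min(x)))
    candidates = {
        "identity": MarkerTransform("identity"),
        "sqrt": MarkerTransform("sqrt", offset=offset),
        "log": MarkerTransform("log", offset=offset),
    }
    scores = {}
    for label, tr in candidates.items():
        tx = tr(x)
        tx = tx[np.isfinite(tx)]
        if tx.size < min_n or np.ptp(tx) == 0.0:
            scores[label] = np.inf
        else:
            scores[label] = _abs_skew(tx)
    best = min(scores.values())
    for label in _TIE_ORDER:  # least aggressive transform wins ties
        if scores[label] <= best + _TIE_TOL:
            return candidates[label]
    raise AssertionError("unreachable")


def fit_transform_spec(
    frames: Sequence[pd.DataFrame] | pd.DataFrame,
    names: Sequence[str],
    min_n: int = 20,
) -> TransformSpec:
    """Select one transform per biomarker on pooled training data.

    ``frames`` may be a single DataFrame or several (e.g. multiple training
    cohorts); values are pooled before selection so a single best transform
    is chosen across datasets.
    """
    if isinstance(frames, pd.DataFrame):
        frames = [frames]
    spec = {}
    for name in names:
        pooled = np.concatenate(
            [pd.to_numeric(f[name], errors="coerce").to_numpy(dtype=float) for f in frames]
        )
        spec[name] = select_transform(pooled[np.isfinite(pooled)], min_n=min_n)
    return TransformSpec(spec)


def apply_transform(
    df: pd.DataFrame, spec: TransformSpec, names: Sequence[str]
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Replace biomarker columns by their transformed values.

    Values whose shifted argument falls outside the transform's domain
    (e.g. ``value + offset <= 0`` under log) become missing; the returned
    report counts them per biomarker.
    """
    missing_spec = [n for n in names if n not in spec]
    if missing_spec:
        raise ConfigurationError(f"transform spec missing biomarkers: {missing_spec}")
    out = df.copy()
    report: Dict[str, int] = {}
    for name in names:
        raw = pd.to_numeric(out[name], errors="coerce").to_numpy(dtype=float)
        tx = spec[name](raw)
        newly_missing = int(np.sum(np.isfinite(raw) & ~np.isfinite(tx)))
        report[name] = newly_missing
        out[name] = tx
    return out, report


def standardize(
    df: pd.DataFrame,
    names: Sequence[str],
    means: Sequence[float],
    sds: Sequence[float],
) -> pd.DataFrame:
    """Map each biomarker column to (x - mean) / sd with the supplied statistics.

    The statistics must come from the reference population; standardizing a
    scored cohort by its own statistics would silently recalibrate the
    metric.
    """
    from .errors import CalibrationError

    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if len(names) != means.size or len(names) != sds.size:
        raise ConfigurationError("means/sds length must match biomarker list")
    bad = np.flatnonzero(~(sds > 0))
    if bad.size:
        raise CalibrationError(
            f"non-positive standardization SD for biomarker(s): {[names[i] for i in bad]}"
        )
    out = df.copy()
    for i, name in enumerate(names):
        x = pd.to_numeric(out[name], errors="coerce").to_numpy(dtype=float)
        out[name] = (x - means[i]) / sds[i]
    return out
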