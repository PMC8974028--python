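"""Quartile-count allostatic load (AL), the comparator metric.

AL counts how many of a subject's biomarkers fall in their *risk-direction*
quartile of a fitting population: strictly above the 75th percentile for
most components, strictly below the 25th percentile for HDL, IGF-1 and
DHEAS, where low values carry the risk.  The default component list covers
five systems: cardiovascular (systolic/diastolic/mean arterial pressure,
heart rate), immune (IL-6, CRP), metabolic (HDL, LDL, glucose, IGF-1),
anthropometric (BMI) and neuroendocrine (DHEAS).

Unlike the Mahalanobis score, AL is one-directional per component and
ignores correlations; it is included as the field's standard comparator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import InsufficientDataError, SchemaError, ValidationError
from .panel import AL_COMPONENTS


@dataclass
class ALSpecification:
    """Fitted allostatic-load cutoffs.

    ``components`` is an ordered list of ``(biomarker, direction)`` with
    direction ``upper`` (risk above Q3) or ``lower`` (risk below Q1);
    ``cutoffs`` holds the fitted quartile per component.  Percentiles use
    linear interpolation between order statistics.
    """

    components: List[Tuple[str, str]]
    cutoffs: List[float]
    n_fit: int
    degenerate: List[str] = field(default_factory=list)
    percentile_convention: str = "linear interpolation between order statistics"

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValidationError("AL specification needs at least one component")
        if len(self.cutoffs) != len(self.components):
            raise ValidationError("one cutoff per component required")
        for (name, direction) in self.components:
            if direction not in ("upper", "lower"):
                raise ValidationError(f"component {name!r}: direction must be upper/lower")
        if not np.all(np.isfinite(self.cutoffs)):
            raise ValidationError("cutoffs must be finite")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "components": [list(c) for c in self.components],
                    "cutoffs": list(map(float, self.cutoffs)),
                    "n_fit": self.n_fit,
                    "degenerate": self.degenerate,
                    "percentile_convention": self.percentile_convention,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ALSpecification":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            components=[tuple(c) for c in d["components"]],
            cutoffs=d["cutoffs"],
            n_fit=d["n_fit"],
            degenerate=d.get("degenerate", []),
        )


def fit_al(
    cohort: Cohort,
    components: Optional[Sequence[Tuple[str, str]]] = None,
    min_n: int = 8,
) -> ALSpecification:
    """Fit quartile cutoffs on a cohort: Q3 for upper-risk, Q1 for lower-risk."""
    components = [tuple(c) for c in (components or AL_COMPONENTS)]
    cutoffs = []
    degenerate = []
    n_fit = len(cohort)
    for name, direction in components:
        if name not in cohort.data.columns:
            raise SchemaError(f"AL component {name!r} absent from cohort")
        vals = pd.to_numeric(cohort.data[name], errors="coerce").to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < min_n:
            raise InsufficientDataError(
                f"AL component {name!r}: need >= {min_n} finite values, got {vals.size}"
            )
        q = 75 if direction == "upper" else 25
        cutoffs.append(float(np.percentile(vals, q)))  # linear interpolation
        if np.ptp(vals) == 0:
            degenerate.append(name)
    if degenerate:
        warnings.warn(f"degenerate (constant) AL components: {degenerate}", stacklevel=2)
    return ALSpecification(components=components, cutoffs=cutoffs, n_fit=n_fit,
                           degenerate=degenerate)


def compute_al(
    cohort: Cohort,
    spec: ALSpecification,
    boundary: str = "strict",
) -> pd.DataFrame:
    """Score a cohort: one point per non-missing component in its risk quartile.

    ``boundary="strict"`` (default) scores only values strictly beyond the
    cutoff; ties at the cutoff score zero.  ``boundary="inclusive"`` uses
    >= / <=.  Rows missing components are scored on what is present, with
    the missing count reported.

    Returns a DataFrame with subject_id, visit, ``al`` and
    ``n_missing_components``.
    """
    if boundary not in ("strict", "inclusive"):
        raise ValidationError("boundary must be 'strict' or 'inclusive'")
    absent = [name for name, _ in spec.components if name not in cohort.data.columns]
    if absent:
        raise SchemaError(f"AL components absent from cohort: {absent}")

    n = len(cohort)
    al = np.zeros(n, dtype=int)
    missing = np.zeros(n, dtype=int)
    for (name, direction), cutoff in zip(spec.components, spec.cutoffs):
        vals = pd.to_numeric(cohort.data[name], errors="coerce").to_numpy(dtype=float)
        miss = ~np.isfinite(vals)
        if boundary == "strict":
            hit = (vals > cutoff) if direction == "upper" else (vals < cutoff)
        else:
            hit = (vals >= cutoff) if direction == "upper" else (vals <= cutoff)
        al += np.where(~miss & hit, 1, 0)
        missing += miss.astype(int)
    return pd.DataFrame(
        {
            "subject_id": cohort.data["subject_id"].to_numpy(),
            "visit": cohort.data["visit"].to_numpy(),
            "al": al,
            "n_missing_components": missing,
        }
    )
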