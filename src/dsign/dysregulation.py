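"""Reference-population fitting and Mahalanobis dysregulation scores.

The dysregulation score of a subject with (transformed, standardized)
biomarker vector x' is the Mahalanobis distance to the reference centroid:

    DM(x') = sqrt((x' - mu)^T  Sigma^{-1}  (x' - mu))

where mu and Sigma are the mean vector and covariance matrix of the
reference population (RP) on the same scale.  Because DM is approximately
log-normal in practice, downstream analyses use log(DM).

Fitting an RP: select/accept per-marker transforms, apply them, compute the
standardization mean/SD on complete cases, standardize, then take mu as the
column means (zero by construction when the same sample standardizes
itself) and Sigma as the sample covariance (n-1 denominator).  Scoring a
cohort re-uses the frozen transforms and standardization — never the scored
cohort's own statistics — so scores are comparable across cohorts.

A composite RP pools an equal number of subjects sampled without
replacement from several source cohorts, giving each training population
equal weight in the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .cohort import Cohort
from .errors import (
    CalibrationError,
    ConfigurationError,
    InsufficientDataError,
    ScalingError,
    SizeError,
)
from .panel import BiomarkerPanel, default_panel
from .reference import ReferencePopulation
from .transforms import TransformSpec, apply_transform, fit_transform_spec, standardize

_MU_TOL = 1e-10


@dataclass
class DysregulationResult:
    """Per-subject DM and log-DM under a named biomarker set and RP."""

    set_label: str
    rp_id: str
    scores: pd.DataFrame  # columns: subject_id, visit, dm, log_dm, n_markers_used
    n_excluded: int = 0  # rows dropped for missing set-member values
    n_zero_dm: int = 0  # rows with dm == 0 (log_dm undefined, left missing)

    @property
    def dm(self) -> pd.Series:
        return self.scores["dm"]

    @property
    def log_dm(self) -> pd.Series:
        return self.scores["log_dm"]


@dataclass
class CompositeRPConfig:
    """Equal-allocation sampling plan for a composite reference population."""

    sources: Sequence[Cohort]
    n_per_source: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_per_source <= 0:
            raise ConfigurationError("n_per_source must be positive")
        if len(self.sources) < 1:
            raise ConfigurationError("at least one source cohort required")


def _resolve_names(markers, panel: Optional[BiomarkerPanel]):
    if isinstance(markers, str):
        if panel is None:
            panel = default_panel()
        return panel.resolve_set(markers)
    return list(markers)


def fit_reference(
    cohort: Cohort,
    markers: Union[str, Sequence[str]],
    panel: Optional[BiomarkerPanel] = None,
    transform_spec: Optional[TransformSpec] = None,
    rp_id: Optional[str] = None,
    shrinkage: float = 0.0,
) -> ReferencePopulation:
    """Fit a reference population on a cohort's complete cases.

    Parameters
    ----------
    markers:
        A set label resolved through ``panel`` (e.g. ``"DM17"``) or an
        explicit ordered list of biomarker names.
    transform_spec:
        Frozen transforms to accept as-is; when ``None``, one transform per
        marker is selected on this cohort's data.
    shrinkage:
        Convex shrinkage weight toward the identity for the covariance,
        ``(1-w)*S + w*I``.  Off (0.0) by default and non-standard; intended
        only for users fitting on small reference samples.
    """
    names = _resolve_names(markers, panel)
    set_label = markers if isinstance(markers, str) else ",".join(names)
    p = len(names)

    complete = cohort.complete_cases(names)
    if len(complete) < p + 2:
        raise InsufficientDataError(
            f"need >= {p + 2} complete cases to fit a {p}-marker RP, got {len(complete)}"
        )
    if transform_spec is None:
        transform_spec = fit_transform_spec(complete, names)

    txed, _ = apply_transform(complete, transform_spec, names)
    X = txed[names].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1)  # log/sqrt domain can introduce missingness
    X = X[keep]
    n = X.shape[0]
    if n < p + 2:
        raise InsufficientDataError(
            f"only {n} rows remain after transforms; need >= {p + 2}"
        )

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero_sd = np.flatnonzero(~(sds > 0))
    if zero_sd.size:
        raise CalibrationError(
            f"zero standard deviation for biomarker(s): {[names[i] for i in zero_sd]}"
        )
    Z = (X - means) / sds
    mu = Z.mean(axis=0)
    assert np.max(np.abs(mu)) < 1e-8, "self-standardized centroid must be ~0"
    sigma = np.cov(Z, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    if shrinkage:
        sigma = (1.0 - shrinkage) * sigma + shrinkage * np.eye(p)
    sigma = (sigma + sigma.T) / 2.0
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise CalibrationError(
            "reference covariance is singular or not positive definite; "
            "remove collinear biomarkers from the set"
        ) from exc

    return ReferencePopulation(
        set_label=set_label,
        biomarker_names=names,
        transform_spec=TransformSpec({n_: transform_spec[n_] for n_ in names}),
        standardize_mean=means,
        standardize_sd=sds,
        mu=mu,
        sigma=sigma,
        n_reference=n,
        rp_id=rp_id or cohort.dataset_label,
        provenance={"source": cohort.dataset_label, "n_input_rows": int(len(cohort))},
    )


def build_composite_rp(
    cfg: CompositeRPConfig,
    markers: Union[str, Sequence[str]],
    panel: Optional[BiomarkerPanel] = None,
    transform_spec: Optional[TransformSpec] = None,
):
    """Sample an equal number of complete cases from each source and fit an RP.

    Returns ``(composite_cohort, rp)``.  Sampling is uniform without
    replacement with a single integer seed; sources are visited in the
    order given, and the selected row indices are recorded in the RP
    provenance for reproducibility.
    """
    names = _resolve_names(markers, panel)
    rng = np.random.default_rng(cfg.seed)
    pieces = []
    picked: dict[str, list] = {}
    for src in cfg.sources:
        complete = src.complete_cases(names)
        if cfg.n_per_source > len(complete):
            raise SizeError(
                f"n_per_source={cfg.n_per_source} exceeds {len(complete)} complete "
                f"cases in source {src.dataset_label!r}"
            )
        idx = np.sort(rng.choice(len(complete), size=cfg.n_per_source, replace=False))
        rows = complete.iloc[idx].copy()
        picked[src.dataset_label] = rows["subject_id"].tolist()
        rows["dataset_label"] = src.dataset_label
        pieces.append(rows)
    combined = pd.concat(pieces, ignore_index=True)
    # composite rows keep their source subject ids; re-key to stay unique
    combined["subject_id"] = [
        f"{lab}:{sid}" for lab, sid in zip(combined["dataset_label"], combined["subject_id"])
    ]
    composite = Cohort("composite", combined, names)
    if transform_spec is None:
        transform_spec = fit_transform_spec(combined, names)
    rp = fit_reference(
        composite, markers if isinstance(markers, str) else names,
        panel=panel, transform_spec=transform_spec, rp_id="composite",
    )
    rp.provenance.update(
        {
            "kind": "composite",
            "seed": int(cfg.seed),
            "n_per_source": int(cfg.n_per_source),
            "sampled_subject_ids": picked,
        }
    )
    return composite, rp


def compute_dm(cohort: Cohort, rp: ReferencePopulation) -> DysregulationResult:
    """Score a cohort against a fitted reference population.

    Rows missing any set-member value (before or after the transform) are
    excluded and counted.  The quadratic form is evaluated through a
    Cholesky solve of Sigma rather than an explicit inverse.
    """
    names = list(rp.biomarker_names)
    raw = cohort.complete_cases(names)
    n_excluded = len(cohort) - len(raw)
    txed, _ = apply_transform(raw, rp.transform_spec, names)
    X = txed[names].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1)
    n_excluded += int((~keep).sum())
    X = X[keep]
    rows = raw.iloc[np.flatnonzero(keep)]

    Z = (X - rp.standardize_mean) / rp.standardize_sd
    D = Z - rp.mu
    factor = cho_factor(rp.sigma, lower=True)
    sol = cho_solve(factor, D.T)  # Sigma^{-1} (x' - mu)
    d2 = np.einsum("ij,ji->i", D, sol)
    d2 = np.clip(d2, 0.0, None)  # guard tiny negative round-off
    dm = np.sqrt(d2)
    with np.errstate(divide="ignore"):
        log_dm = np.where(dm > 0, np.log(np.where(dm > 0, dm, 1.0)), np.nan)
    n_zero = int((dm == 0).sum())

    scores = pd.DataFrame(
        {
            "subject_id": rows["subject_id"].to_numpy(),
            "visit": rows["visit"].to_numpy(),
            "dm": dm,
            "log_dm": log_dm,
            "n_markers_used": rp.p,
        },
        index=rows.index,
    )
    return DysregulationResult(
        set_label=rp.set_label,
        rp_id=rp.rp_id,
        scores=scores,
        n_excluded=n_excluded,
        n_zero_dm=n_zero,
    )


def score_per_sd(values) -> np.ndarray:
    """Divide a metric column by the sample SD (n-1) of its finite values.

    Applied to log-DM, allostatic load and self-assessed health before
    association modelling so effect sizes are per-SD and comparable across
    metrics.  Missing values pass through as NaN.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ScalingError("need >= 2 finite values to scale per SD")
    sd = float(np.std(finite, ddof=1))
    if sd <= 0:
        raise ScalingError("cannot scale a constant metric (zero SD)")
    return x / sd
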