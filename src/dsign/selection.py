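"""Biomarker-suite selection and reference-population stability analyses.

The selection procedure screens candidate biomarkers and subsets on two
empirical properties:

* **RP stability** — the correlation, within a study population, between
  log-DM calibrated on that population itself and log-DM calibrated on a
  different reference (another cohort, a pooled composite, or a demographic
  subset).  A good "standard" marker set should yield nearly the same
  ranking of subjects regardless of which reasonable reference calibrates
  it.
* **Signal** — the correlation of a subset-based log-DM with the log-DM of
  the full marker universe, a proxy for how much multivariate information
  the subset retains.

Pre-selection screens individual markers whose subgroup means (males,
females, age tertiles, ...) differ across datasets by more than a
standardized-difference threshold, or whose overall mean falls outside
clinical bounds.  Subset enumeration then evaluates all (or a seeded
sample of) k-marker combinations on stability and signal.  The final
promotion of a subset to a "standard" is deliberately left to the user:
this module ranks and reports, it does not pick.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cohort import Cohort
from .dysregulation import CompositeRPConfig, build_composite_rp, compute_dm, fit_reference
from .errors import ConfigurationError, DsignError, InsufficientDataError
from .panel import BiomarkerPanel, default_panel
from .transforms import TransformSpec, apply_transform, fit_transform_spec

ENUMERATION_BUDGET = 10**6


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------


@dataclass
class SubsetEvaluation:
    """Stability and signal correlations for one candidate biomarker subset."""

    biomarker_names: Tuple[str, ...]
    rp_stability_r: Dict[str, float] = field(default_factory=dict)
    signal_r: Dict[str, float] = field(default_factory=dict)
    mean_rp_stability: float = math.nan
    mean_signal: float = math.nan
    failed: bool = False
    error: Optional[str] = None

    def finalize(self) -> "SubsetEvaluation":
        if self.rp_stability_r:
            self.mean_rp_stability = float(np.mean(list(self.rp_stability_r.values())))
        if self.signal_r:
            self.mean_signal = float(np.mean(list(self.signal_r.values())))
        return self


@dataclass
class StabilityMatrix:
    """Cross-calibration Pearson correlations of log-DM.

    Entry ``(i, j)`` is the correlation, over the subjects of study
    population ``col_labels[j]``, between log-DM calibrated on population j
    itself and log-DM calibrated on reference ``row_labels[i]``.
    """

    row_labels: List[str]
    col_labels: List[str]
    r: np.ndarray
    mean_r: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.row_labels, columns=self.col_labels)


@dataclass
class RedundancyReport:
    correlations: pd.DataFrame
    flagged: List[Tuple[str, str, float]]
    threshold: float


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _pearson(a: pd.Series, b: pd.Series) -> float:
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        return math.nan
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def _tertile_labels(values: pd.Series) -> pd.Series:
    ranks = values.rank(method="first", pct=True)
    return pd.cut(ranks, bins=[0, 1 / 3, 2 / 3, 1.0], labels=["t1", "t2", "t3"], include_lowest=True)


def _default_subsets(cohorts: Sequence[Cohort]) -> List[Tuple[str, List[np.ndarray]]]:
    """Default demographic subsets: everyone, sex groups, age tertiles.

    Age tertile cut points come from the pooled age distribution so the
    same bins apply to every cohort.
    """
    subsets: List[Tuple[str, List[np.ndarray]]] = []
    n_all = [np.ones(len(c), dtype=bool) for c in cohorts]
    subsets.append(("all", n_all))
    if all("sex" in c.data.columns for c in cohorts):
        levels = sorted(set().union(*(set(c.data["sex"].dropna().unique()) for c in cohorts)))
        for lev in levels:
            subsets.append(
                (f"sex={lev}", [(c.data["sex"] == lev).to_numpy() for c in cohorts])
            )
    pooled_age = pd.concat([pd.to_numeric(c.data["age"], errors="coerce") for c in cohorts])
    cuts = pooled_age.quantile([1 / 3, 2 / 3]).to_numpy()
    edges = [-np.inf, cuts[0], cuts[1], np.inf]
    for k, name in enumerate(["age_t1", "age_t2", "age_t3"]):
        masks = []
        for c in cohorts:
            a = pd.to_numeric(c.data["age"], errors="coerce").to_numpy(dtype=float)
            masks.append((a > edges[k]) & (a <= edges[k + 1]) if k else (a <= edges[1]))
        subsets.append((name, masks))
    return subsets


def _var_subsets(cohorts: Sequence[Cohort], var: str) -> List[Tuple[str, List[np.ndarray]]]:
    for c in cohorts:
        if var not in c.data.columns:
            raise ConfigurationError(
                f"split variable {var!r} absent from cohort {c.dataset_label!r}"
            )
    pooled = pd.concat([c.data[var] for c in cohorts])
    numeric = pd.to_numeric(pooled, errors="coerce")
    if numeric.notna().all() and numeric.nunique() > 10:
        cuts = numeric.quantile([1 / 3, 2 / 3]).to_numpy()
        out = []
        for k, name in enumerate([f"{var}_t1", f"{var}_t2", f"{var}_t3"]):
            masks = []
            for c in cohorts:
                a = pd.to_numeric(c.data[var], errors="coerce").to_numpy(dtype=float)
                if k == 0:
                    masks.append(a <= cuts[0])
                elif k == 1:
                    masks.append((a > cuts[0]) & (a <= cuts[1]))
                else:
                    masks.append(a > cuts[1])
            out.append((name, masks))
        return out
    levels = sorted(pooled.dropna().unique(), key=str)
    return [
        (f"{var}={lev}", [(c.data[var] == lev).to_numpy() for c in cohorts])
        for lev in levels
    ]


# --------------------------------------------------------------------------
# step 1: pre-selection
# --------------------------------------------------------------------------


def pre_select(
    cohorts: Sequence[Cohort],
    panel: Optional[BiomarkerPanel] = None,
    markers: Optional[Sequence[str]] = None,
    subset_vars: Optional[Sequence[str]] = None,
    threshold_d: float = 0.5,
    use_clinical_bounds: bool = False,
) -> Tuple[List[str], pd.DataFrame]:
    """Screen biomarkers for cross-dataset consistency of subgroup means.

    For every biomarker and demographic subset, the subset mean is computed
    per cohort on the transformed scale; the marker is excluded when the
    largest pairwise standardized mean difference ``|m_i - m_j| /
    s_pooled`` across cohorts exceeds ``threshold_d`` for any subset, or
    (``use_clinical_bounds``) when any cohort's overall raw-scale mean
    falls outside the marker's clinical bounds.

    Returns ``(retained_names, report)`` where the report has one row per
    marker x subset with the statistic and any exclusion reason.
    """
    if len(cohorts) < 2:
        raise ConfigurationError("pre_select needs at least 2 cohorts")
    panel = panel or default_panel()
    if markers is None:
        # default to the cohorts' declared biomarker panels, not every
        # panel-matching column (AL components etc. are not DM candidates)
        markers = [
            n
            for n in panel.names
            if all(
                n in (c.biomarker_names if c.biomarker_names else c.data.columns)
                for c in cohorts
            )
        ]
    spec = fit_transform_spec([c.data for c in cohorts], markers)
    txed = [apply_transform(c.data, spec, markers)[0] for c in cohorts]

    subsets = _default_subsets(cohorts)
    for var in subset_vars or []:
        subsets.extend(_var_subsets(cohorts, var))

    records = []
    excluded: Dict[str, str] = {}
    for marker in markers:
        for sub_name, masks in subsets:
            stats = []
            for frame, mask in zip(txed, masks):
                vals = pd.to_numeric(frame[marker], errors="coerce").to_numpy(dtype=float)
                vals = vals[mask & np.isfinite(vals)]
                if vals.size >= 2:
                    stats.append((vals.mean(), vals.var(ddof=1), vals.size))
            max_d = 0.0
            for (m1, v1, n1), (m2, v2, n2) in combinations(stats, 2):
                s_pooled = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
                d = abs(m1 - m2) / s_pooled if s_pooled > 0 else math.inf
                max_d = max(max_d, d)
            over = max_d > threshold_d
            records.append(
                {
                    "biomarker": marker,
                    "subset": sub_name,
                    "max_std_diff": max_d,
                    "exceeds_threshold": over,
                }
            )
            if over and marker not in excluded:
                excluded[marker] = f"subset {sub_name!r}: standardized diff {max_d:.3f} > {threshold_d}"
        if use_clinical_bounds and marker not in excluded:
            bdef = panel[marker] if marker in panel else None
            if bdef and (bdef.clinical_low is not None or bdef.clinical_high is not None):
                for c in cohorts:
                    raw = pd.to_numeric(c.data[marker], errors="coerce")
                    m = float(raw.mean())
                    lo = bdef.clinical_low if bdef.clinical_low is not None else -math.inf
                    hi = bdef.clinical_high if bdef.clinical_high is not None else math.inf
                    if not lo <= m <= hi:
                        excluded[marker] = (
                            f"clinical bounds: mean {m:.3g} in {c.dataset_label!r} "
                            f"outside ({bdef.clinical_low}, {bdef.clinical_high})"
                        )
                        break

    report = pd.DataFrame.from_records(records)
    report["excluded"] = report["biomarker"].map(lambda m: m in excluded)
    report["reason"] = report["biomarker"].map(lambda m: excluded.get(m, ""))
    retained = [m for m in markers if m not in excluded]
    return retained, report


# --------------------------------------------------------------------------
# step 2: subset enumeration
# --------------------------------------------------------------------------


def _combination_from_rank(rank: int, n: int, k: int) -> Tuple[int, ...]:
    """Lexicographic unranking of a k-combination of range(n)."""
    out = []
    x = 0
    for i in range(k):
        while True:
            count = math.comb(n - x - 1, k - i - 1)
            if rank < count:
                out.append(x)
                x += 1
                break
            rank -= count
            x += 1
    return tuple(out)


def _sample_ranks(total: int, count: int, rng: np.random.Generator) -> List[int]:
    if count >= total:
        return list(range(total))
    seen: set = set()
    out: List[int] = []
    while len(out) < count:
        r = int(rng.integers(0, total))
        if r not in seen:
            seen.add(r)
            out.append(r)
    return sorted(out)


def enumerate_and_evaluate(
    cohorts: Sequence[Cohort],
    candidate_names: Sequence[str],
    k: int,
    composite_cfg: CompositeRPConfig,
    full_set_names: Sequence[str],
    sample: Optional[Tuple[int, int]] = None,
    panel: Optional[BiomarkerPanel] = None,
    budget: int = ENUMERATION_BUDGET,
) -> List[SubsetEvaluation]:
    """Evaluate all (or a seeded sample of) k-marker subsets of the candidates.

    For each subset and each cohort, log-DM is computed twice — with the
    cohort as its own RP and with the composite RP — giving the RP-stability
    correlation, and once against the full-set own-RP log-DM, giving the
    signal correlation.  Evaluations are returned in a deterministic total
    order: mean RP stability (desc), mean signal (desc), then names.

    ``sample=(count, seed)`` draws a uniform sample of subset ranks; it is
    mandatory when C(n, k) exceeds ``budget``.
    """
    candidate_names = list(candidate_names)
    full_set_names = list(full_set_names)
    if k > len(candidate_names):
        raise ConfigurationError(f"k={k} exceeds {len(candidate_names)} candidates")
    total = math.comb(len(candidate_names), k)
    if total > budget and sample is None:
        raise ConfigurationError(
            f"C({len(candidate_names)},{k})={total} exceeds the enumeration budget "
            f"({budget}); pass sample=(count, seed)"
        )

    all_names = sorted(set(candidate_names) | set(full_set_names))
    spec = fit_transform_spec([c.data for c in cohorts], all_names)
    composite, _ = build_composite_rp(composite_cfg, candidate_names, panel=panel,
                                      transform_spec=spec)

    full_logdm: Dict[str, pd.Series] = {}
    for c in cohorts:
        rp_full = fit_reference(c, full_set_names, transform_spec=spec)
        full_logdm[c.dataset_label] = compute_dm(c, rp_full).scores["log_dm"]

    if sample is None:
        subsets = [tuple(candidate_names[i] for i in idx)
                   for idx in combinations(range(len(candidate_names)), k)]
    else:
        count, seed = sample
        rng = np.random.default_rng(seed)
        ranks = _sample_ranks(total, count, rng)
        subsets = [
            tuple(candidate_names[i] for i in _combination_from_rank(r, len(candidate_names), k))
            for r in ranks
        ]

    evaluations: List[SubsetEvaluation] = []
    for names in subsets:
        ev = SubsetEvaluation(biomarker_names=names)
        try:
            rp_comp = fit_reference(composite, list(names), transform_spec=spec)
            for c in cohorts:
                rp_own = fit_reference(c, list(names), transform_spec=spec)
                own = compute_dm(c, rp_own).scores["log_dm"]
                comp = compute_dm(c, rp_comp).scores["log_dm"]
                ev.rp_stability_r[c.dataset_label] = _pearson(own, comp)
                ev.signal_r[c.dataset_label] = _pearson(own, full_logdm[c.dataset_label])
            ev.finalize()
        except DsignError as exc:
            ev.failed = True
            ev.error = str(exc)
        evaluations.append(ev)

    def _key(ev: SubsetEvaluation):
        rs = ev.mean_rp_stability if math.isfinite(ev.mean_rp_stability) else -math.inf
        sg = ev.mean_signal if math.isfinite(ev.mean_signal) else -math.inf
        return (ev.failed, -rs, -sg, ev.biomarker_names)

    evaluations.sort(key=_key)
    return evaluations


def evaluations_to_frame(evaluations: Sequence[SubsetEvaluation]) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        row = {
            "biomarkers": "+".join(ev.biomarker_names),
            "mean_rp_stability": ev.mean_rp_stability,
            "mean_signal": ev.mean_signal,
            "failed": ev.failed,
            "error": ev.error or "",
        }
        for lab, r in ev.rp_stability_r.items():
            row[f"rp_stability_{lab}"] = r
        for lab, r in ev.signal_r.items():
            row[f"signal_{lab}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stability matrices
# --------------------------------------------------------------------------


def cross_rp_stability(
    cohorts: Sequence[Cohort],
    markers: Union[str, Sequence[str]],
    panel: Optional[BiomarkerPanel] = None,
    include_pooled: bool = False,
    transform_spec: Optional[TransformSpec] = None,
) -> StabilityMatrix:
    """Correlate log-DM across reference-population choices.

    Each cohort serves once as the study population (columns) and once as
    an alternative RP (rows); entry (i, j) correlates, over cohort j's
    subjects, log-DM calibrated on cohort j with log-DM calibrated on
    cohort i.  ``include_pooled`` adds a pooled-RP row fitted on the
    concatenation of all cohorts.  ``mean_r`` averages all cells whose row
    and column labels differ.
    """
    if len(cohorts) < 2:
        raise ConfigurationError("cross_rp_stability needs at least 2 cohorts")
    names = panel.resolve_set(markers) if isinstance(markers, str) and panel else (
        default_panel().resolve_set(markers) if isinstance(markers, str) else list(markers)
    )
    if transform_spec is None:
        transform_spec = fit_transform_spec([c.data for c in cohorts], names)

    rps = []
    row_labels = []
    for c in cohorts:
        rps.append(fit_reference(c, names, transform_spec=transform_spec))
        row_labels.append(c.dataset_label)
    if include_pooled:
        pooled_df = pd.concat(
            [c.data.assign(subject_id=c.dataset_label + ":" + c.data["subject_id"].astype(str))
             for c in cohorts],
            ignore_index=True,
        )
        pooled = Cohort("pooled", pooled_df, names)
        rps.append(fit_reference(pooled, names, transform_spec=transform_spec, rp_id="pooled"))
        row_labels.append("pooled")

    col_labels = [c.dataset_label for c in cohorts]
    r = np.full((len(rps), len(cohorts)), np.nan)
    for j, c in enumerate(cohorts):
        own = compute_dm(c, rps[j]).scores["log_dm"]
        for i, rp in enumerate(rps):
            other = own if i == j else compute_dm(c, rp).scores["log_dm"]
            r[i, j] = 1.0 if i == j else _pearson(own, other)
    off = [r[i, j] for i in range(len(rps)) for j in range(len(cohorts))
           if row_labels[i] != col_labels[j]]
    return StabilityMatrix(row_labels, col_labels, r, float(np.nanmean(off)))


def subset_stability(
    cohort: Cohort,
    markers: Union[str, Sequence[str]],
    split_var: str,
    panel: Optional[BiomarkerPanel] = None,
) -> StabilityMatrix:
    """Within-population stability: demographic subsets act as alternative RPs.

    The cohort is split on ``split_var`` (levels of a categorical, or
    tertiles of a continuous variable); each usable group calibrates an RP
    and entry (i, j) correlates group-j members' log-DM under their own
    versus group i's calibration.  Groups too small to fit an RP are
    dropped with a warning.
    """
    names = panel.resolve_set(markers) if isinstance(markers, str) and panel else (
        default_panel().resolve_set(markers) if isinstance(markers, str) else list(markers)
    )
    groups = _var_subsets([cohort], split_var)
    spec = fit_transform_spec(cohort.data, names)
    p = len(names)
    sub_cohorts = []
    for gname, (mask,) in groups:
        sub = cohort.data.loc[np.asarray(mask, dtype=bool)]
        if len(sub) == 0:
            continue
        sc = Cohort(gname, sub.copy(), names)
        if len(sc.complete_cases(names)) < p + 2:
            warnings.warn(f"group {gname!r} too small to fit an RP; dropped", stacklevel=2)
            continue
        sub_cohorts.append(sc)
    if len(sub_cohorts) < 2:
        raise InsufficientDataError(
            f"split on {split_var!r} yields fewer than 2 usable groups"
        )
    return cross_rp_stability(sub_cohorts, names, transform_spec=spec)


# --------------------------------------------------------------------------
# step 4: redundancy
# --------------------------------------------------------------------------


def redundancy_report(
    cohort: Cohort,
    markers: Union[str, Sequence[str]],
    panel: Optional[BiomarkerPanel] = None,
    threshold: float = 0.8,
) -> RedundancyReport:
    """Pairwise Pearson correlations between set members (transformed scale).

    Pairs with |r| above the threshold are listed for inspection; nothing
    is excluded — within a Mahalanobis metric redundancy is handled by the
    covariance weighting, but heavily redundant suites carry less breadth
    of biological signal, so the table is worth reading.
    """
    names = panel.resolve_set(markers) if isinstance(markers, str) and panel else (
        default_panel().resolve_set(markers) if isinstance(markers, str) else list(markers)
    )
    complete = cohort.complete_cases(names)
    if len(complete) < 30:
        raise InsufficientDataError(
            f"redundancy_report needs >= 30 complete cases, got {len(complete)}"
        )
    spec = fit_transform_spec(complete, names)
    txed, _ = apply_transform(complete, spec, names)
    corr = txed[names].astype(float).corr(method="pearson")
    flagged = [
        (names[i], names[j], float(corr.iloc[i, j]))
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(corr.iloc[i, j]) > threshold
    ]
    return RedundancyReport(correlations=corr, flagged=flagged, threshold=threshold)
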