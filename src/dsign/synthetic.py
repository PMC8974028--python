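"""Synthetic multi-cohort generator.

Real multi-study biomarker panels share three structural features the
metric and the selection procedure lean on: (i) positive, roughly
log-normal biomarker marginals; (ii) a common correlation structure across
markers within a subject; and (iii) dataset-specific mean shifts on a few
markers (assay or population differences) — exactly what pre-selection is
designed to detect.  The generator draws a latent multivariate normal per
subject with a shared correlation matrix, maps each marker through its
marginal family (identity or exp), applies per-dataset shifts expressed in
latent-SD units, and attaches demographics and outcomes.

Outcomes are simulated from a unit-variance risk score (a fixed linear
combination of the standardized latent markers): exponential survival
times with hazard ``h0 * exp(beta_mort * risk)``, Poisson frailty and
comorbidity counts with log-rate linear in the risk, Bernoulli disease
indicators with log-odds linear in the risk, and an ordinal 1-5
self-assessed health derived from the risk plus noise.  The realized risk
score is kept as a ``risk_score`` column so parameter-recovery tests can
use the true linear predictor as a metric.

Everything is reproducible from one integer seed; per-dataset random
streams are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigurationError
from .panel import AL_COMPONENTS, DM17_NAMES

# (marginal family, latent mean, latent SD) — latent scale is log-scale for
# lognormal markers, raw scale for normal ones.  Values are plausible adult
# reference magnitudes.
_MARKER_DEFAULTS: Dict[str, Tuple[str, float, float]] = {
    "mch": ("normal", 30.0, 2.0),
    "rdw": ("normal", 13.5, 1.2),
    "platelets": ("lognormal", 5.52, 0.25),
    "rbc": ("normal", 4.7, 0.45),
    "hemoglobin": ("normal", 14.0, 1.3),
    "wbc": ("lognormal", 1.87, 0.30),
    "baso_pct": ("lognormal", -0.70, 0.50),
    "hdl": ("lognormal", 4.00, 0.25),
    "lym_pct": ("normal", 30.0, 8.0),
    "ggt": ("lognormal", 3.20, 0.60),
    "ast": ("lognormal", 3.18, 0.35),
    "alkp": ("lognormal", 4.25, 0.30),
    "albumin": ("normal", 4.3, 0.35),
    "total_proteins": ("normal", 7.2, 0.45),
    "calcium": ("normal", 9.5, 0.40),
    "potassium": ("normal", 4.2, 0.35),
    "vitamin_b12": ("lognormal", 6.10, 0.45),
}

# AL-component stand-ins (continuous, weakly risk-coupled); HDL reuses the
# marker column when both are generated.
_AL_DEFAULTS: Dict[str, Tuple[str, float, float]] = {
    "sbp": ("normal", 125.0, 15.0),
    "dbp": ("normal", 75.0, 10.0),
    "map": ("normal", 92.0, 11.0),
    "heart_rate": ("normal", 70.0, 10.0),
    "il6": ("lognormal", 0.7, 0.6),
    "crp": ("lognormal", 0.7, 0.9),
    "ldl": ("normal", 120.0, 30.0),
    "glucose": ("lognormal", 4.55, 0.20),
    "igf1": ("normal", 150.0, 50.0),
    "bmi": ("normal", 27.0, 5.0),
    "dheas": ("lognormal", 4.6, 0.5),
}


@dataclass
class SyntheticConfig:
    """Generating parameters for a family of synthetic cohorts."""

    n_per_dataset: Sequence[int] = (1000, 1000, 1000)
    dataset_labels: Optional[Sequence[str]] = None
    marker_names: Sequence[str] = tuple(DM17_NAMES)
    base_mean: Optional[Sequence[float]] = None
    base_sd: Optional[Sequence[float]] = None
    families: Optional[Sequence[str]] = None
    correlation: Optional[np.ndarray] = None  # full matrix; else exchangeable(rho)
    rho: float = 0.3
    dataset_shifts: Dict[str, Dict[str, float]] = field(default_factory=dict)  # SD units
    variance_multipliers: Dict[str, Dict[str, float]] = field(default_factory=dict)
    age_range: Tuple[float, float] = (20.0, 90.0)
    age_slopes: Optional[Dict[str, float]] = None  # latent-SD units per year
    missing_rate: float = 0.0
    include_al_components: bool = True
    simulate_outcomes: bool = True
    mortality_log_hr: float = 0.3  # per SD of the risk score
    frailty_log_rate: float = 0.2
    comorbidity_log_rate: float = 0.2
    disease_log_or: float = 0.4
    deviation_weight: float = 0.0  # weight of multivariate-deviation magnitude in the risk
    baseline_hazard: float = 0.04  # events per person-year at risk 0
    follow_up_years: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.marker_names = list(self.marker_names)
        p = len(self.marker_names)
        if self.dataset_labels is None:
            self.dataset_labels = [f"cohort_{i + 1}" for i in range(len(self.n_per_dataset))]
        if len(self.dataset_labels) != len(self.n_per_dataset):
            raise ConfigurationError("dataset_labels must match n_per_dataset in length")
        defaults = [_MARKER_DEFAULTS.get(m, ("lognormal", 3.0, 0.4)) for m in self.marker_names]
        if self.families is None:
            self.families = [d[0] for d in defaults]
        if self.base_mean is None:
            self.base_mean = [d[1] for d in defaults]
        if self.base_sd is None:
            self.base_sd = [d[2] for d in defaults]
        self.base_mean = np.asarray(self.base_mean, dtype=float)
        self.base_sd = np.asarray(self.base_sd, dtype=float)
        if not (len(self.families) == self.base_mean.size == self.base_sd.size == p):
            raise ConfigurationError("marker parameter vectors must all have length p")
        if self.correlation is None:
            self.correlation = np.full((p, p), self.rho)
            np.fill_diagonal(self.correlation, 1.0)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (p, p):
            raise ConfigurationError(f"correlation must be {p}x{p}")
        try:
            np.linalg.cholesky(self.correlation)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("correlation matrix is not positive definite") from exc
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        for shifts in self.dataset_shifts.values():
            for m, s in shifts.items():
                if m not in self.marker_names:
                    raise ConfigurationError(f"shift references unknown marker {m!r}")
                if not np.isfinite(s):
                    raise ConfigurationError("shifts must be finite")


def _risk_weights(cfg: SyntheticConfig) -> np.ndarray:
    """Equal weights scaled so the risk score has unit variance under R."""
    p = len(cfg.marker_names)
    w = np.ones(p)
    var = float(w @ cfg.correlation @ w)
    return w / np.sqrt(var)


def _simulate_dataset(cfg: SyntheticConfig, label: str, n: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    p = len(cfg.marker_names)
    L = np.linalg.cholesky(cfg.correlation)
    Z = rng.standard_normal((n, p)) @ L.T  # correlated, standard marginals

    age = rng.uniform(*cfg.age_range, size=n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    race = rng.choice(["groupA", "groupB"], size=n, p=[0.7, 0.3])
    education = rng.integers(6, 19, size=n)
    marital = rng.choice(["married", "single", "widowed"], size=n, p=[0.55, 0.25, 0.20])

    shifts = cfg.dataset_shifts.get(label, {})
    vmult = cfg.variance_multipliers.get(label, {})
    slopes = cfg.age_slopes or {}
    mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])

    values = np.empty((n, p))
    for j, name in enumerate(cfg.marker_names):
        z = Z[:, j] * vmult.get(name, 1.0) + shifts.get(name, 0.0)
        z = z + slopes.get(name, 0.0) * (age - mid_age)
        latent = cfg.base_mean[j] + cfg.base_sd[j] * z
        values[:, j] = np.exp(latent) if cfg.families[j] == "lognormal" else latent

    df = pd.DataFrame(
        {
            "subject_id": [f"{label}_{i:05d}" for i in range(n)],
            "visit": 1,
            "age": age,
            "sex": sex,
            "race": race,
            "education": education.astype(float),
            "marital_status": marital,
        }
    )
    for j, name in enumerate(cfg.marker_names):
        df[name] = values[:, j]

    if cfg.include_al_components:
        for name, (fam, m, s) in _AL_DEFAULTS.items():
            if name in df.columns:
                continue
            latent = m + s * (0.3 * (Z @ _risk_weights(cfg)) + np.sqrt(1 - 0.09) * rng.standard_normal(n))
            df[name] = np.exp(latent) if fam == "lognormal" else latent

    if cfg.simulate_outcomes:
        risk = Z @ _risk_weights(cfg)  # unit variance by construction
        if cfg.deviation_weight:
            # dysregulation-driven risk: standardized Mahalanobis deviation of
            # the latent markers; uncorrelated with the signed component, so
            # the combined score is renormalized back to unit variance
            q = np.einsum("ij,ij->i", Z @ np.linalg.inv(cfg.correlation), Z)
            dev = (q - p) / np.sqrt(2 * p)
            risk = (risk + cfg.deviation_weight * dev) / np.sqrt(
                1.0 + cfg.deviation_weight**2
            )
        df["risk_score"] = risk
        hazard = cfg.baseline_hazard * np.exp(cfg.mortality_log_hr * risk)
        t_death = rng.exponential(1.0 / hazard)
        event = t_death <= cfg.follow_up_years
        df["event"] = event.astype(int)
        df["event_age"] = age + np.minimum(t_death, cfg.follow_up_years)
        df["frailty"] = np.minimum(
            rng.poisson(np.exp(np.log(1.2) + cfg.frailty_log_rate * risk)), 5
        )
        df["comorbidity_count"] = rng.poisson(
            np.exp(np.log(2.0) + cfg.comorbidity_log_rate * risk)
        )
        base_logit = np.log(0.2 / 0.8)
        for disease in ("cvd", "diabetes"):
            pdis = 1.0 / (1.0 + np.exp(-(base_logit + cfg.disease_log_or * risk)))
            df[disease] = rng.binomial(1, pdis)
        df["sah"] = np.clip(np.rint(3.0 + 0.8 * risk + 0.8 * rng.standard_normal(n)), 1, 5).astype(int)
        df["walk_time"] = np.maximum(4.0 + 0.5 * risk + 0.8 * rng.standard_normal(n), 1.5)
        df["mmse"] = np.clip(np.rint(27.0 - risk - 1.5 * rng.standard_normal(n)), 0, 30)

    if cfg.missing_rate > 0:
        for name in cfg.marker_names:
            mask = rng.random(n) < cfg.missing_rate
            df.loc[mask, name] = np.nan
    return df


def generate_cohorts(cfg: SyntheticConfig) -> List[Cohort]:
    """Generate one cohort per dataset label, reproducibly from ``cfg.seed``."""
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cfg.n_per_dataset))
    cohorts = []
    for label, n, ss in zip(cfg.dataset_labels, cfg.n_per_dataset, streams):
        df = _simulate_dataset(cfg, label, int(n), np.random.default_rng(ss))
        cohorts.append(Cohort(label, df, list(cfg.marker_names)))
    return cohorts


def generate_rp_pair(
    cfg: SyntheticConfig,
    perturbation: Optional[Dict] = None,
) -> Tuple[Cohort, Cohort]:
    """Two cohorts from identical generating parameters, B optionally perturbed.

    ``perturbation`` keys: ``shift_sd`` (additive latent shift in SD units),
    ``markers`` (which markers it hits), ``var_multiplier`` (latent SD
    multiplier on the same markers).  Used by the stability analyses as a
    matched same-distribution / shifted-distribution fixture.
    """
    n = int(cfg.n_per_dataset[0])
    shifts = dict(cfg.dataset_shifts)
    vmults = dict(cfg.variance_multipliers)
    if perturbation:
        targets = perturbation.get("markers", list(cfg.marker_names))
        if "shift_sd" in perturbation:
            shifts = {**shifts, "B": {m: float(perturbation["shift_sd"]) for m in targets}}
        if "var_multiplier" in perturbation:
            vmults = {**vmults, "B": {m: float(perturbation["var_multiplier"]) for m in targets}}
    pair_cfg = replace(
        cfg,
        n_per_dataset=[n, n],
        dataset_labels=["A", "B"],
        dataset_shifts=shifts,
        variance_multipliers=vmults,
    )
    a, b = generate_cohorts(pair_cfg)
    return a, b
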