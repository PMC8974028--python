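"""Fitted reference-population (RP) calibration objects and their JSON I/O.

An RP freezes everything needed to score new subjects: the per-biomarker
transform spec, the standardization mean/SD (post-transform scale), the
centroid ``mu`` and covariance ``sigma`` on the standardized scale, and the
number of complete cases used.  Serialization is plain JSON with
full-precision floats so a "standard" calibration is human-auditable and
round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .transforms import TransformSpec

SCHEMA_VERSION = 1
_SYM_TOL = 1e-10
_MU_TOL = 1e-10


@dataclass
class ReferencePopulation:
    set_label: str
    biomarker_names: Sequence[str]
    transform_spec: TransformSpec
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    n_reference: int
    rp_id: str = "unnamed"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.biomarker_names = list(self.biomarker_names)
        for attr in ("standardize_mean", "standardize_sd", "mu"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    @property
    def p(self) -> int:
        return len(self.biomarker_names)

    def validate(self) -> None:
        p = self.p
        for attr in ("standardize_mean", "standardize_sd", "mu"):
            v = getattr(self, attr)
            if v.shape != (p,):
                raise ValidationError(f"{attr} must have length {p}, got {v.shape}")
        if self.sigma.shape != (p, p):
            raise ValidationError(f"sigma must be {p}x{p}, got {self.sigma.shape}")
        if not np.all(self.standardize_sd > 0):
            raise ValidationError("standardize_sd entries must be strictly positive")
        if np.max(np.abs(self.sigma - self.sigma.T)) > _SYM_TOL:
            raise ValidationError("sigma is not symmetric within 1e-10")
        try:
            np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "sigma is not positive definite; consider removing collinear biomarkers"
            ) from exc
        if self.n_reference <= p:
            raise ValidationError(
                f"n_reference ({self.n_reference}) must exceed the number of biomarkers ({p})"
            )

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "set_label": self.set_label,
            "rp_id": self.rp_id,
            "biomarker_names": list(self.biomarker_names),
            "transform_spec": self.transform_spec.to_dict(),
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "n_reference": int(self.n_reference),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferencePopulation":
        required = {
            "set_label",
            "biomarker_names",
            "transform_spec",
            "standardize_mean",
            "standardize_sd",
            "mu",
            "sigma",
            "n_reference",
        }
        missing = required - set(d)
        if missing:
            raise ValidationError(f"reference-population document missing fields: {sorted(missing)}")
        return cls(
            set_label=d["set_label"],
            biomarker_names=d["biomarker_names"],
            transform_spec=TransformSpec.from_dict(d["transform_spec"]),
            standardize_mean=d["standardize_mean"],
            standardize_sd=d["standardize_sd"],
            mu=d["mu"],
            sigma=d["sigma"],
            n_reference=d["n_reference"],
            rp_id=d.get("rp_id", "unnamed"),
            provenance=d.get("provenance", {}),
        )


def write_rp(rp: ReferencePopulation, path) -> None:
    """Serialize an RP to JSON (floats at full repr precision, >= 15 digits)."""
    rp.validate()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rp.to_dict(), fh, indent=2)


def read_rp(path) -> ReferencePopulation:
    """Load and validate an RP document; corrupted files raise ValidationError."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"corrupted reference-population file {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ValidationError("reference-population file must contain a JSON object")
    return ReferencePopulation.from_dict(d)
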