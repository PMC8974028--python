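"""Biomarker panel definitions.

A :class:`BiomarkerPanel` is a registry of biomarker definitions plus named
biomarker sets.  The built-in default panel covers the 31-marker universe of
routine clinical chemistry and complete-blood-count markers on which the
standard dysregulation suites are defined, together with the named sets:

``DM9``
    MCH, RDW, platelets, RBC, hemoglobin, WBC, BASO%, HDL, LYM%.
``DM17``
    DM9 plus GGT, AST, ALKP, albumin, total proteins, calcium, potassium,
    vitamin B12.
``DM31``
    the full universe.
``pre22``
    a provisional 22-marker pre-selected list; the normative path to a
    pre-selected list is :func:`dsign.selection.pre_select`, which screens
    markers for cross-dataset consistency.  The built-in constant exists so
    downstream sweeps have a default candidate pool.

Allostatic-load components (blood pressures, heart rate, inflammatory and
metabolic markers, BMI, DHEAS) are defined here as well because they carry a
risk direction used by :mod:`dsign.allostatic`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError

TRANSFORM_LABELS = ("identity", "log", "sqrt")
AL_DIRECTIONS = ("upper", "lower")


@dataclass(frozen=True)
class BiomarkerDef:
    """Definition of a single biomarker.

    Parameters
    ----------
    name:
        Unique identifier (column name in cohort tables).
    unit:
        Free-text measurement unit.
    transform:
        One of ``identity``/``log``/``sqrt``, or ``auto`` to let the
        calibration step pick the transform that best symmetrizes the data.
    clinical_low, clinical_high:
        Optional clinical reference bounds on the raw scale.
    al_risk_direction:
        ``upper`` or ``lower`` when the marker participates in allostatic
        load; ``None`` otherwise.
    """

    name: str
    unit: str = ""
    transform: str = "auto"
    clinical_low: Optional[float] = None
    clinical_high: Optional[float] = None
    al_risk_direction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORM_LABELS + ("auto",):
            raise ValidationError(
                f"biomarker {self.name!r}: transform must be one of "
                f"{TRANSFORM_LABELS + ('auto',)}, got {self.transform!r}"
            )
        if (
            self.clinical_low is not None
            and self.clinical_high is not None
            and not self.clinical_low < self.clinical_high
        ):
            raise ValidationError(
                f"biomarker {self.name!r}: clinical_low must be < clinical_high"
            )
        if self.al_risk_direction is not None and self.al_risk_direction not in AL_DIRECTIONS:
            raise ValidationError(
                f"biomarker {self.name!r}: al_risk_direction must be 'upper' or 'lower'"
            )


@dataclass
class BiomarkerPanel:
    """Ordered biomarker registry with named sets (e.g. ``DM9``, ``DM17``)."""

    biomarkers: Sequence[BiomarkerDef]
    named_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [b.name for b in self.biomarkers]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate biomarker names: {dupes}")
        self._by_name = {b.name: b for b in self.biomarkers}
        for label, members in self.named_sets.items():
            missing = [m for m in members if m not in self._by_name]
            if missing:
                raise ValidationError(
                    f"named set {label!r} references unknown biomarkers: {missing}"
                )
        if "DM9" in self.named_sets and len(self.named_sets["DM9"]) != 9:
            raise ValidationError("built-in set 'DM9' must have exactly 9 members")
        if "DM17" in self.named_sets:
            if len(self.named_sets["DM17"]) != 17:
                raise ValidationError("built-in set 'DM17' must have exactly 17 members")
            if "DM9" in self.named_sets and not set(self.named_sets["DM9"]) <= set(
                self.named_sets["DM17"]
            ):
                raise ValidationError("'DM17' must be a superset of 'DM9'")

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> BiomarkerDef:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.biomarkers]

    def resolve_set(self, set_or_names) -> list[str]:
        """Resolve a set label or an explicit name list to an ordered name list."""
        if isinstance(set_or_names, str):
            if set_or_names not in self.named_sets:
                raise KeyError(f"unknown biomarker set {set_or_names!r}")
            return list(self.named_sets[set_or_names])
        names = list(set_or_names)
        missing = [m for m in names if m not in self._by_name]
        if missing:
            raise ValidationError(f"unknown biomarkers: {missing}")
        return names

    # ---------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "biomarkers": [
                {
                    "name": b.name,
                    "unit": b.unit,
                    "transform": b.transform,
                    "clinical_low": b.clinical_low,
                    "clinical_high": b.clinical_high,
                    "al_risk_direction": b.al_risk_direction,
                }
                for b in self.biomarkers
            ],
            "named_sets": {k: list(v) for k, v in self.named_sets.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BiomarkerPanel":
        return cls(
            biomarkers=[BiomarkerDef(**b) for b in d["biomarkers"]],
            named_sets=dict(d.get("named_sets", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "BiomarkerPanel":
        """Read a panel definition from a JSON or YAML file."""
        text = open(path, "r", encoding="utf-8").read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            import yaml  # optional; only needed for YAML panels

            d = yaml.safe_load(text)
        return cls.from_dict(d)


# --------------------------------------------------------------------------
# Built-in default panel
# --------------------------------------------------------------------------

DM9_NAMES = [
    "mch",
    "rdw",
    "platelets",
    "rbc",
    "hemoglobin",
    "wbc",
    "baso_pct",
    "hdl",
    "lym_pct",
]

DM17_NAMES = DM9_NAMES + [
    "ggt",
    "ast",
    "alkp",
    "albumin",
    "total_proteins",
    "calcium",
    "potassium",
    "vitamin_b12",
]

DM31_NAMES = [
    "hemoglobin",
    "hematocrit",
    "rdw",
    "mch",
    "mchc",
    "rbc",
    "platelets",
    "wbc",
    "baso_pct",
    "lym_pct",
    "mono_pct",
    "neut_pct",
    "ferritin",
    "glucose",
    "calcium",
    "chloride",
    "sodium",
    "potassium",
    "vitamin_b12",
    "folate",
    "total_cholesterol",
    "triglycerides",
    "hdl",
    "albumin",
    "alkp",
    "total_proteins",
    "ggt",
    "ldh",
    "uric_acid",
    "alt",
    "ast",
]

# Provisional 22-marker pre-selected pool: DM17 plus five further markers
# whose population means are typically consistent across surveys.  Folate is
# deliberately absent (notoriously RP-dependent through fortification policy).
# The normative pre-selection path is dsign.selection.pre_select.
PRE22_NAMES = DM17_NAMES + [
    "hematocrit",
    "mchc",
    "mono_pct",
    "neut_pct",
    "total_cholesterol",
]

# Allostatic-load components: one point per marker in the upper risk quartile,
# except HDL, IGF-1 and DHEAS where low values carry the risk.
AL_COMPONENTS = [
    ("sbp", "upper"),
    ("dbp", "upper"),
    ("map", "upper"),
    ("heart_rate", "upper"),
    ("il6", "upper"),
    ("crp", "upper"),
    ("hdl", "lower"),
    ("ldl", "upper"),
    ("glucose", "upper"),
    ("igf1", "lower"),
    ("bmi", "upper"),
    ("dheas", "lower"),
]

_UNITS = {
    "hemoglobin": "g/dL",
    "hematocrit": "%",
    "rdw": "%",
    "mch": "pg",
    "mchc": "g/dL",
    "rbc": "10^6/uL",
    "platelets": "10^3/uL",
    "wbc": "10^3/uL",
    "baso_pct": "%",
    "lym_pct": "%",
    "mono_pct": "%",
    "neut_pct": "%",
    "ferritin": "ng/mL",
    "glucose": "mg/dL",
    "calcium": "mg/dL",
    "chloride": "mmol/L",
    "sodium": "mmol/L",
    "potassium": "mmol/L",
    "vitamin_b12": "pg/mL",
    "folate": "ng/mL",
    "total_cholesterol": "mg/dL",
    "triglycerides": "mg/dL",
    "hdl": "mg/dL",
    "albumin": "g/dL",
    "alkp": "U/L",
    "total_proteins": "g/dL",
    "ggt": "U/L",
    "ldh": "U/L",
    "uric_acid": "mg/dL",
    "alt": "U/L",
    "ast": "U/L",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "map": "mmHg",
    "heart_rate": "bpm",
    "il6": "pg/mL",
    "crp": "mg/L",
    "ldl": "mg/dL",
    "igf1": "ng/mL",
    "bmi": "kg/m^2",
    "dheas": "ug/dL",
}

_AL_DIRECTION = dict(AL_COMPONENTS)


def default_panel() -> BiomarkerPanel:
    """Build the bundled default panel (31-marker universe + AL components)."""
    extra = [name for name, _ in AL_COMPONENTS if name not in DM31_NAMES]
    defs = [
        BiomarkerDef(
            name=n,
            unit=_UNITS.get(n, ""),
            transform="auto",
            al_risk_direction=_AL_DIRECTION.get(n),
        )
        for n in DM31_NAMES + extra
    ]
    return BiomarkerPanel(
        biomarkers=defs,
        named_sets={
            "DM9": list(DM9_NAMES),
            "DM17": list(DM17_NAMES),
            "DM31": list(DM31_NAMES),
            "pre22": list(PRE22_NAMES),
        },
    )
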