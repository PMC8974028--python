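"""Cohort container and delimited-text I/O.

A :class:`Cohort` wraps a pandas DataFrame with one row per subject-visit and
a dataset label.  Columns fall into three groups: mandatory identifiers
(``subject_id``, ``age``), optional demographics (``sex``, ``race``,
``education``, ``marital_status``, ``visit``), biomarker columns (numeric,
missing allowed), and optional outcome columns (``event``/``event_age`` for
survival, ``frailty``, ``cvd``, ``diabetes``, ``comorbidity_count``,
``sah``).  Demographics are kept as the categorical strings found in the
file; no recoding happens at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .panel import BiomarkerPanel

MANDATORY_COLUMNS = ("subject_id", "age")

OUTCOME_COLUMNS = (
    "event",
    "event_age",
    "frailty",
    "cvd",
    "diabetes",
    "comorbidity_count",
    "sah",
)


@dataclass
class Cohort:
    """Subjects x (demographics + biomarkers + outcomes) with a dataset label."""

    dataset_label: str
    data: pd.DataFrame
    biomarker_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if "visit" not in self.data.columns:
            self.data = self.data.assign(visit=1)
        self.biomarker_names = [c for c in self.biomarker_names if c in self.data.columns]
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"cohort {self.dataset_label!r}: missing mandatory column {col!r}")
        ages = pd.to_numeric(df["age"], errors="coerce")
        if (ages <= 0).any():
            raise ValidationError(f"cohort {self.dataset_label!r}: ages must be strictly positive")
        key = df[["subject_id", "visit"]].astype(str).agg("|".join, axis=1)
        if key.duplicated().any():
            raise ValidationError(
                f"cohort {self.dataset_label!r}: duplicate (subject_id, visit) pairs"
            )
        if "frailty" in df.columns:
            fr = pd.to_numeric(df["frailty"], errors="coerce").dropna()
            if not fr.isin(range(6)).all():
                raise ValidationError("frailty count must be in 0..5")
        for col in ("event", "cvd", "diabetes"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce").dropna()
                if not vals.isin((0, 1)).all():
                    raise ValidationError(f"binary outcome {col!r} must be 0/1")

    def __len__(self) -> int:
        return len(self.data)

    def complete_cases(self, names: Sequence[str]) -> pd.DataFrame:
        """Rows with all of `names` observed (finite)."""
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            from .errors import SchemaError

            raise SchemaError(
                f"cohort {self.dataset_label!r}: biomarker columns absent: {missing}"
            )
        sub = self.data[list(names)].apply(pd.to_numeric, errors="coerce")
        mask = np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)
        return self.data.loc[mask]

    def subset(self, mask, label_suffix: str = "") -> "Cohort":
        lab = self.dataset_label + (f"/{label_suffix}" if label_suffix else "")
        return Cohort(lab, self.data.loc[mask].copy(), list(self.biomarker_names))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_cohort(
    path,
    panel: BiomarkerPanel,
    column_map: Optional[Mapping[str, str]] = None,
    dataset_label: Optional[str] = None,
) -> Cohort:
    """Read a cohort from a delimited text file.

    Parameters
    ----------
    path:
        CSV or TSV file with a header row (delimiter inferred from the
        extension, ``.tsv`` meaning tab).  Empty cells are missing values.
    panel:
        Biomarker panel; any file column matching a panel biomarker name
        (after ``column_map``) is parsed as a numeric biomarker.
    column_map:
        Optional ``{file column -> canonical name}`` renaming applied first.
    dataset_label:
        Defaults to the file stem.
    """
    import pathlib

    p = pathlib.Path(path)
    sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(p, sep=sep, dtype=str, keep_default_na=True, na_values=[""])
    if column_map:
        absent = [c for c in column_map if c not in df.columns]
        if absent:
            raise FormatError(f"column_map refers to absent columns: {absent}")
        df = df.rename(columns=dict(column_map))

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {p.name}")

    marker_cols = [c for c in df.columns if c in panel]
    numeric_cols = marker_cols + ["age"] + [c for c in OUTCOME_COLUMNS if c in df.columns]
    if "visit" in df.columns:
        numeric_cols.append("visit")
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
            raise ParseError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column {col!r} at row {row}"
            )
        df[col] = parsed
    return Cohort(dataset_label or p.stem, df, biomarker_names=marker_cols)
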