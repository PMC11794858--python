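"""Cohort table: group membership, demographics, clinical and cognitive scores.

One row per subject. Clinical severity is quantified by the 19 SIPS
items (5 positive, 6 negative, 4 disorganization, 4 general) plus two
GAF functioning scores; cognition by the eight MCCB tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

SIPS_ITEMS = (
    "P1", "P2", "P3", "P4", "P5",
    "N1", "N2", "N3", "N4", "N5", "N6",
    "D1", "D2", "D3", "D4",
    "G1", "G2", "G3", "G4",
)
SIPS_DOMAINS = ("sips_positive", "sips_negative", "sips_disorganization", "sips_general")
GAF_SCORES = ("gaf_before", "gaf_now")
#: The 21 clinical items entering edge-item correlation (19 SIPS + 2 GAF).
CLINICAL_ITEMS = SIPS_ITEMS + GAF_SCORES
MCCB_TESTS = (
    "TMT", "BACS_SC", "HVLT_R", "WMS_III_SS",
    "NAB_Mazes", "BVMT_R", "Fluency", "CPT_IP",
)
GROUPS = ("CHR", "HC")

REQUIRED_COLUMNS = (
    ("subject_id", "group", "age", "sex", "education")
    + CLINICAL_ITEMS
    + SIPS_DOMAINS
    + MCCB_TESTS
)


@dataclass
class CohortTable:
    """Wrapper around a per-subject DataFrame with schema validation."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"cohort table missing column(s): {missing}")
        if t["subject_id"].duplicated().any():
            dups = t.loc[t["subject_id"].duplicated(), "subject_id"].tolist()
            raise FormatError(f"duplicate subject id(s): {dups}")
        bad = sorted(set(t["group"]) - set(GROUPS))
        if bad:
            raise FormatError(f"unknown group label(s): {bad}")
        bad_sex = sorted(set(t["sex"]) - {"F", "M"})
        if bad_sex:
            raise FormatError(f"unknown sex label(s): {bad_sex}")
        self.table = t.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def group_mask(self, group: str) -> np.ndarray:
        return (self.table["group"] == group).to_numpy()

    def clinical_items(self, subjects: np.ndarray | None = None) -> pd.DataFrame:
        """The 21-item clinical matrix (19 SIPS + 2 GAF), optionally row-subset."""
        items = self.table[list(CLINICAL_ITEMS)]
        return items if subjects is None else items.iloc[subjects]

    def covariates(self, names=("sex", "age", "education")) -> pd.DataFrame:
        """Numeric covariate matrix; sex coded F=0, M=1."""
        cov = self.table[list(names)].copy()
        if "sex" in cov.columns:
            cov["sex"] = (cov["sex"] == "M").astype(float)
        return cov.astype(float)
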