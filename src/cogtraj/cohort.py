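"""Cohort data model, CSV I/O, APOE allele-group classification and summary tables.

A cohort is a cross-sectional table of kindred members: one row per
participant with age, sex, years of formal education, MMSE total score
(0-30, higher = better cognition), PSEN1 E280A mutation carrier status and
the two APOE alleles (each one of e2/e3/e4).

Participants are classified by the presence of at least one e4 allele
(e4+ vs e4-) and, separately, at least one e2 allele (e2+ vs e2-); an
e2/e4 heterozygote belongs to both the e4+ and the e2+ group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .stats import chi_square, mann_whitney_u

ALLELES = ("e2", "e3", "e4")
SEXES = ("M", "F")

#: Canonical unordered APOE genotype labels (alleles sorted, joined by "/").
GENOTYPES = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")

COHORT_COLUMNS = (
    "id",
    "age",
    "sex",
    "education_years",
    "mmse",
    "psen1_carrier",
    "apoe_allele_1",
    "apoe_allele_2",
)


class SchemaError(ValueError):
    """A cohort file does not have the documented column layout."""


class CohortValidationError(ValueError):
    """A row violates the participant invariants (range or enum)."""


@dataclass(frozen=True)
class ApoeGroups:
    """Dichotomous APOE classification: carries ≥1 e4 allele / ≥1 e2 allele."""

    e4_positive: bool
    e2_positive: bool


@dataclass(frozen=True)
class Participant:
    """One cross-sectional observation of a kindred member.

    ``mmse`` is the Mini Mental State Examination total (integer, 0-30),
    used as the global-cognition outcome. ``education_years`` is
    self-reported total years of formal education.
    """

    id: str
    age: float
    sex: str
    education_years: float
    mmse: int
    psen1_carrier: bool
    apoe_allele_1: str
    apoe_allele_2: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "age", float(self.age))
        object.__setattr__(self, "education_years", float(self.education_years))
        object.__setattr__(self, "mmse", int(self.mmse))
        if self.sex not in SEXES:
            raise CohortValidationError(
                f"participant {self.id!r}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.apoe_allele_1 not in ALLELES or self.apoe_allele_2 not in ALLELES:
            raise CohortValidationError(
                f"participant {self.id!r}: APOE alleles must be in {ALLELES}, "
                f"got ({self.apoe_allele_1!r}, {self.apoe_allele_2!r})"
            )
        if not (0 <= self.mmse <= 30):
            raise CohortValidationError(
                f"participant {self.id!r}: MMSE must lie in [0, 30], got {self.mmse}"
            )
        if self.age < 18:
            raise CohortValidationError(
                f"participant {self.id!r}: age must be ≥ 18 years, got {self.age}"
            )
        if self.education_years < 0:
            raise CohortValidationError(
                f"participant {self.id!r}: education_years must be ≥ 0, "
                f"got {self.education_years}"
            )

    @property
    def genotype(self) -> str:
        """Unordered genotype label, alleles sorted (e.g. always 'e2/e4')."""
        return genotype_label(self.apoe_allele_1, self.apoe_allele_2)

    @property
    def apoe_groups(self) -> ApoeGroups:
        return classify_apoe(self.apoe_allele_1, self.apoe_allele_2)


def classify_apoe(allele_1: str, allele_2: str) -> ApoeGroups:
    """Classify an APOE genotype into the dichotomous e4+/e2+ groups.

    Symmetric in allele order. An e2/e4 heterozygote is a member of both
    groups (both flags True).
    """
    for allele in (allele_1, allele_2):
        if allele not in ALLELES:
            raise CohortValidationError(f"unknown APOE allele {allele!r}")
    pair = (allele_1, allele_2)
    return ApoeGroups(e4_positive="e4" in pair, e2_positive="e2" in pair)


def genotype_label(allele_1: str, allele_2: str) -> str:
    a, b = sorted((allele_1, allele_2))
    return f"{a}/{b}"


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of participants with unique ids."""

    participants: tuple[Participant, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterator[Participant]:
        return iter(self.participants)

    @classmethod
    def from_iterable(cls, participants: Iterable[Participant]) -> "Cohort":
        return cls(tuple(participants))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with derived group columns appended.

        Derived columns: ``e4_positive``, ``e2_positive`` (booleans) and
        ``genotype`` (unordered label).
        """
        records = []
        for p in self.participants:
            groups = p.apoe_groups
            records.append(
                {
                    "id": p.id,
                    "age": p.age,
                    "sex": p.sex,
                    "education_years": p.education_years,
                    "mmse": p.mmse,
                    "psen1_carrier": p.psen1_carrier,
                    "apoe_allele_1": p.apoe_allele_1,
                    "apoe_allele_2": p.apoe_allele_2,
                    "e4_positive": groups.e4_positive,
                    "e2_positive": groups.e2_positive,
                    "genotype": p.genotype,
                }
            )
        return pd.DataFrame.from_records(
            records, columns=list(COHORT_COLUMNS) + ["e4_positive", "e2_positive", "genotype"]
        )


def _participant_from_row(row: pd.Series) -> Participant:
    rid = str(row["id"])
    mmse_raw = row["mmse"]
    try:
        mmse = int(mmse_raw)
    except (TypeError, ValueError):
        raise CohortValidationError(f"participant {rid!r}: MMSE {mmse_raw!r} is not an integer")
    if float(mmse_raw) != mmse:
        raise CohortValidationError(f"participant {rid!r}: MMSE {mmse_raw!r} is not an integer")
    carrier_raw = row["psen1_carrier"]
    if carrier_raw not in (0, 1, "0", "1", True, False):
        raise CohortValidationError(
            f"participant {rid!r}: psen1_carrier must be 0 or 1, got {carrier_raw!r}"
        )
    return Participant(
        id=rid,
        age=float(row["age"]),
        sex=str(row["sex"]),
        education_years=float(row["education_years"]),
        mmse=mmse,
        psen1_carrier=bool(int(carrier_raw)),
        apoe_allele_1=str(row["apoe_allele_1"]),
        apoe_allele_2=str(row["apoe_allele_2"]),
    )


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV (header ``id,age,sex,...``; see COHORT_COLUMNS).

    Rows with missing values are rejected: the v1 schema does not permit
    missingness.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing required column(s): {missing}")
    participants = []
    for _, row in df.iterrows():
        if row[list(COHORT_COLUMNS)].isna().any():
            blank = [c for c in COHORT_COLUMNS if pd.isna(row[c])]
            raise CohortValidationError(
                f"participant {row['id']!r}: missing value(s) in column(s) {blank}"
            )
        participants.append(_participant_from_row(row))
    return Cohort(tuple(participants))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort CSV (schema columns only, row order preserved)."""
    df = cohort.to_frame()[list(COHORT_COLUMNS)].copy()
    df["psen1_carrier"] = df["psen1_carrier"].astype(int)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

def _round2(x: float) -> float:
    # half-to-even, matching 2-decimal table display
    return round(float(x), 2)


def genotype_table(cohort: Cohort) -> pd.DataFrame:
    """Counts and percentages of the six unordered genotypes by carrier status.

    Returns a frame indexed by genotype with columns ``carrier_n``,
    ``carrier_pct``, ``noncarrier_n``, ``noncarrier_pct``. Percentages are
    within-stratum, rounded half-to-even to 2 decimals.
    """
    if len(cohort) == 0:
        raise CohortValidationError("genotype_table requires a non-empty cohort")
    df = cohort.to_frame()
    out = pd.DataFrame(index=list(GENOTYPES))
    for label, mask in (("carrier", df["psen1_carrier"]), ("noncarrier", ~df["psen1_carrier"])):
        sub = df[mask]
        counts = sub["genotype"].value_counts().reindex(GENOTYPES, fill_value=0)
        out[f"{label}_n"] = counts.to_numpy()
        n = len(sub)
        pct = counts / n * 100.0 if n else counts * np.nan
        out[f"{label}_pct"] = [_round2(v) if n else np.nan for v in pct]
    out.index.name = "genotype"
    return out


def apoe_group_counts(cohort: Cohort) -> pd.DataFrame:
    """e4+/e4- and e2+/e2- group sizes within each PSEN1 stratum."""
    df = cohort.to_frame()
    rows = {}
    for label, mask in (("carriers", df["psen1_carrier"]), ("noncarriers", ~df["psen1_carrier"])):
        sub = df[mask]
        rows[label] = {
            "n": len(sub),
            "e4_positive": int(sub["e4_positive"].sum()),
            "e4_negative": int((~sub["e4_positive"]).sum()),
            "e2_positive": int(sub["e2_positive"].sum()),
            "e2_negative": int((~sub["e2_positive"]).sum()),
            "e2e4": int((sub["genotype"] == "e2/e4").sum()),
        }
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class ContinuousRow:
    """Per-group mean ± SD (n−1 denominator) and Mann–Whitney p-value."""

    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    p_value: float


@dataclass(frozen=True)
class DemographicsTable:
    """The demographics comparison battery for one stratum and one allele split.

    Continuous variables (age, education, MMSE) are compared with two-sided
    Mann–Whitney U; sex with a Pearson chi-square on the 2x2 table.
    """

    label_pos: str
    label_neg: str
    n_pos: int
    n_neg: int
    age: ContinuousRow
    education_years: ContinuousRow
    mmse: ContinuousRow
    sex_counts_pos: tuple[int, int]  # (M, F)
    sex_counts_neg: tuple[int, int]
    sex_p_value: float

    def to_frame(self) -> pd.DataFrame:
        def fmt(row: ContinuousRow) -> list[str | float]:
            return [
                f"{row.mean_pos:.2f} ± {row.sd_pos:.2f}",
                f"{row.mean_neg:.2f} ± {row.sd_neg:.2f}",
                row.p_value,
            ]

        data = {
            "N": [self.n_pos, self.n_neg, np.nan],
            "Age": fmt(self.age),
            "Sex (M/F)": [
                f"{self.sex_counts_pos[0]}/{self.sex_counts_pos[1]}",
                f"{self.sex_counts_neg[0]}/{self.sex_counts_neg[1]}",
                self.sex_p_value,
            ],
            "Educational attainment (years)": fmt(self.education_years),
            "MMSE": fmt(self.mmse),
        }
        return pd.DataFrame(data, index=[self.label_pos, self.label_neg, "p"]).T


def demographics_table(
    cohort: Cohort, allele: str = "e4", stratum: str = "carriers"
) -> DemographicsTable:
    """Build the demographics table for one PSEN1 stratum split by an allele flag.

    ``allele`` is ``"e4"`` (e4+ vs e4-) or ``"e2"`` (e2+ vs e2-);
    ``stratum`` is ``"carriers"`` or ``"noncarriers"``.
    """
    if allele not in ("e4", "e2"):
        raise ValueError(f"allele must be 'e4' or 'e2', got {allele!r}")
    if stratum not in ("carriers", "noncarriers"):
        raise ValueError(f"stratum must be 'carriers' or 'noncarriers', got {stratum!r}")
    df = cohort.to_frame()
    df = df[df["psen1_carrier"]] if stratum == "carriers" else df[~df["psen1_carrier"]]
    flag = df[f"{allele}_positive"]
    pos, neg = df[flag], df[~flag]
    if len(pos) == 0 or len(neg) == 0:
        raise CohortValidationError(
            f"demographics_table: empty {allele}{'+' if len(pos) == 0 else '-'} "
            f"group in {stratum}"
        )

    def cont(col: str) -> ContinuousRow:
        x, y = pos[col].to_numpy(float), neg[col].to_numpy(float)
        return ContinuousRow(
            mean_pos=float(np.mean(x)),
            sd_pos=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            mean_neg=float(np.mean(y)),
            sd_neg=float(np.std(y, ddof=1)) if len(y) > 1 else 0.0,
            p_value=mann_whitney_u(x, y).p_value,
        )

    sex_pos = (int((pos["sex"] == "M").sum()), int((pos["sex"] == "F").sum()))
    sex_neg = (int((neg["sex"] == "M").sum()), int((neg["sex"] == "F").sum()))
    sex_table = np.array([sex_pos, sex_neg])
    try:
        sex_p = chi_square(sex_table).p_value
    except ValueError:
        sex_p = np.nan  # a sex absent from both groups: test undefined

    return DemographicsTable(
        label_pos=f"{allele}+",
        label_neg=f"{allele}-",
        n_pos=len(pos),
        n_neg=len(neg),
        age=cont("age"),
        education_years=cont("education_years"),
        mmse=cont("mmse"),
        sex_counts_pos=sex_pos,
        sex_counts_neg=sex_neg,
        sex_p_value=float(sex_p),
    )
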