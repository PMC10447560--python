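"""Synthetic kindred-cohort generator with known ground truth.

The registry data this pipeline targets are access-restricted, so every
downstream stage is exercised on simulated cohorts that reproduce the
statistical structure the analysis assumes: cross-sectional ages over
~18-75, APOE genotype frequencies typical of the Colombian PSEN1 E280A
kindred, a broad education distribution, near-ceiling MMSE in mutation
non-carriers, and an age-related MMSE decline in carriers that begins in
midlife, is accelerated by the e4 allele, delayed by the e2 allele, and
attenuated by educational attainment.

Decline model
-------------
The carrier mean trajectory is a logistic (sigmoid) plateau-then-decline:

    m(age) = floor + (ceiling − floor) / (1 + exp(rate · (age − onset)))

where ``onset`` is the inflection age (MMSE halfway between ceiling and
floor). Each carrier's latent onset is

    onset = base_onset + e4_shift·1[e4+] + e2_shift·1[e2+]
            + edu_shift·(education − education_mean)

so allele and education effects act as horizontal shifts of the same curve:
a single mechanism that yields both a main education effect and a
genotype×education interaction in the cross-sectional regression.
Non-carriers decline linearly and shallowly from the ceiling. Observed
MMSE adds Gaussian noise, clips to [floor, ceiling] and rounds to an
integer, matching the discrete 0-30 scale.

This is a stand-in functional form: the analysis model (a restricted cubic
spline) assumes no parametric shape, and the generator defaults are
simulation choices, not estimates of the kindred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import GENOTYPES, Cohort, Participant

#: APOE genotype counts observed among PSEN1 E280A mutation carriers of the
#: Colombian kindred (n = 675); the default genotype sampling distribution.
KINDRED_CARRIER_GENOTYPE_COUNTS: dict[str, int] = {
    "e2/e2": 4,
    "e2/e3": 85,
    "e2/e4": 13,
    "e3/e3": 445,
    "e3/e4": 117,
    "e4/e4": 11,
}

#: Counts for the mutation non-carrier relatives (n = 594).
KINDRED_NONCARRIER_GENOTYPE_COUNTS: dict[str, int] = {
    "e2/e2": 2,
    "e2/e3": 55,
    "e2/e4": 16,
    "e3/e3": 389,
    "e3/e4": 122,
    "e4/e4": 10,
}


def _proportions(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {g: counts[g] / total for g in GENOTYPES}


DEFAULT_GENOTYPE_PROBS = _proportions(KINDRED_CARRIER_GENOTYPE_COUNTS)


@dataclass(frozen=True)
class GeneratorParams:
    """Simulation conditions for one synthetic cohort.

    Defaults mirror the kindred sample: 675 carriers / 594 non-carrier
    relatives, ages truncated-normal 33.7 ± 10.9 on [18, 75] (a uniform
    mode is available), carrier genotype frequencies, education
    ≈ 7.4 ± 4.4 years truncated to [0, 20]. Decline-model defaults
    (base onset 49, e4 shift −5 y, e2 shift +5 y, +0.3 y per education
    year, rate 0.45, noise SD 2.5) place the e4+/e4− divergence in the
    mid-40s, near the kindred's median age of MCI onset.
    """

    n_carriers: int = 675
    n_noncarriers: int = 594
    age_range: tuple[float, float] = (18.0, 75.0)
    age_distribution: str = "truncnorm"  # or "uniform"
    age_mean: float = 33.7
    age_sd: float = 10.9
    apoe_genotype_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PROBS)
    )
    education_mean: float = 7.4
    education_sd: float = 4.4
    education_max: float = 20.0
    mmse_ceiling: float = 30.0
    mmse_floor: float = 0.0
    base_onset_age: float = 49.0
    decline_rate: float = 0.45
    e4_onset_shift: float = -5.0
    e2_onset_shift: float = 5.0
    education_onset_shift_per_year: float = 0.3
    noncarrier_slope: float = 0.02
    noise_sd: float = 2.5
    prob_female: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carriers <= 0 or self.n_noncarriers < 0:
            raise ValueError("n_carriers must be positive, n_noncarriers non-negative")
        if self.age_range[0] < 18 or self.age_range[1] <= self.age_range[0]:
            raise ValueError(f"invalid age_range {self.age_range}; min must be ≥ 18")
        probs = self.apoe_genotype_probs
        if set(probs) != set(GENOTYPES):
            raise ValueError(f"apoe_genotype_probs must cover exactly {GENOTYPES}")
        if abs(sum(probs.values()) - 1.0) > 1e-12:
            raise ValueError("apoe_genotype_probs must sum to 1 within 1e-12")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.mmse_floor >= self.mmse_ceiling:
            raise ValueError("mmse_floor must be below mmse_ceiling")
        if self.decline_rate <= 0:
            raise ValueError("decline_rate must be > 0")
        if self.age_distribution not in ("truncnorm", "uniform"):
            raise ValueError("age_distribution must be 'truncnorm' or 'uniform'")


def mean_mmse(age, onset_age, rate, ceiling=30.0, floor=0.0):
    """Noiseless sigmoid mean MMSE at ``age`` for inflection age ``onset_age``.

    floor + (ceiling − floor) / (1 + exp(rate·(age − onset_age))); monotone
    non-increasing in age, → ceiling far before onset, → floor far after.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if floor >= ceiling:
        raise ValueError("floor must be below ceiling")
    age = np.asarray(age, dtype=float)
    return floor + (ceiling - floor) * expit(-rate * (age - np.asarray(onset_age, dtype=float)))


@dataclass(frozen=True)
class GroundTruth:
    """Latent simulation state: per-participant onsets and true mean curves."""

    params: GeneratorParams
    ids: tuple[str, ...]
    carrier_mask: np.ndarray
    e4_mask: np.ndarray
    e2_mask: np.ndarray
    onset_ages: np.ndarray  # NaN for non-carriers

    def noncarrier_mean(self, ages) -> np.ndarray:
        p = self.params
        ages = np.asarray(ages, dtype=float)
        return np.clip(
            p.mmse_ceiling - p.noncarrier_slope * (ages - p.age_range[0]),
            p.mmse_floor,
            p.mmse_ceiling,
        )

    def group_mean_curve(self, group: str) -> Callable[[np.ndarray], np.ndarray]:
        """True mean MMSE curve of a group, averaged over its members' onsets.

        ``group`` ∈ {"carriers", "noncarriers", "carriers_e4+",
        "carriers_e4-", "carriers_e2+", "carriers_e2-"}.
        """
        if group == "noncarriers":
            return self.noncarrier_mean
        masks = {
            "carriers": self.carrier_mask,
            "carriers_e4+": self.carrier_mask & self.e4_mask,
            "carriers_e4-": self.carrier_mask & ~self.e4_mask,
            "carriers_e2+": self.carrier_mask & self.e2_mask,
            "carriers_e2-": self.carrier_mask & ~self.e2_mask,
        }
        if group not in masks:
            raise KeyError(f"unknown group {group!r}")
        onsets = self.onset_ages[masks[group]]
        if onsets.size == 0:
            raise ValueError(f"group {group!r} is empty in this cohort")
        p = self.params

        def curve(ages):
            ages = np.atleast_1d(np.asarray(ages, dtype=float))
            grid = mean_mmse(
                ages[:, None], onsets[None, :], p.decline_rate, p.mmse_ceiling, p.mmse_floor
            )
            return grid.mean(axis=1)

        return curve

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "psen1_carrier": self.carrier_mask.astype(int),
                "e4_positive": self.e4_mask.astype(int),
                "e2_positive": self.e2_mask.astype(int),
                "onset_age": self.onset_ages,
            }
        )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, index=False)


def generate_cohort(params: GeneratorParams | None = None) -> tuple[Cohort, GroundTruth]:
    """Draw one synthetic cohort. Identical params (incl. seed) ⇒ identical cohort.

    Independent RNG sub-streams per field (ages, genotypes, education, sex,
    noise), spawned deterministically from the seed, so changing cohort size
    does not reshuffle unrelated draws.
    """
    p = params if params is not None else GeneratorParams()
    n = p.n_carriers + p.n_noncarriers
    ss = np.random.SeedSequence(p.seed)
    rng_age, rng_geno, rng_edu, rng_sex, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    if p.age_distribution == "uniform":
        ages = rng_age.uniform(p.age_range[0], p.age_range[1], size=n)
    else:
        a = (p.age_range[0] - p.age_mean) / p.age_sd
        b = (p.age_range[1] - p.age_mean) / p.age_sd
        ages = truncnorm.rvs(
            a, b, loc=p.age_mean, scale=p.age_sd, size=n, random_state=rng_age
        )
    probs = np.array([p.apoe_genotype_probs[g] for g in GENOTYPES])
    genotypes = rng_geno.choice(len(GENOTYPES), size=n, p=probs)
    lo = (0.0 - p.education_mean) / p.education_sd
    hi = (p.education_max - p.education_mean) / p.education_sd
    education = truncnorm.rvs(
        lo, hi, loc=p.education_mean, scale=p.education_sd, size=n, random_state=rng_edu
    )
    sex = np.where(rng_sex.uniform(size=n) < p.prob_female, "F", "M")
    noise = rng_noise.normal(0.0, p.noise_sd, size=n)

    carrier = np.zeros(n, dtype=bool)
    carrier[: p.n_carriers] = True
    geno_labels = np.array(GENOTYPES)[genotypes]
    e4 = np.char.count(geno_labels.astype(str), "e4") > 0
    e2 = np.char.count(geno_labels.astype(str), "e2") > 0

    onset = (
        p.base_onset_age
        + p.e4_onset_shift * e4
        + p.e2_onset_shift * e2
        + p.education_onset_shift_per_year * (education - p.education_mean)
    )
    onset = np.where(carrier, onset, np.nan)

    mean = np.empty(n)
    mean[carrier] = mean_mmse(
        ages[carrier], onset[carrier], p.decline_rate, p.mmse_ceiling, p.mmse_floor
    )
    mean[~carrier] = np.clip(
        p.mmse_ceiling - p.noncarrier_slope * (ages[~carrier] - p.age_range[0]),
        p.mmse_floor,
        p.mmse_ceiling,
    )
    mmse = np.rint(np.clip(mean + noise, p.mmse_floor, p.mmse_ceiling)).astype(int)
    # observed scale is always the 0-30 instrument range
    mmse = np.clip(mmse, 0, 30)

    width = len(str(n))
    ids = tuple(f"P{i + 1:0{width}d}" for i in range(n))
    participants = []
    for i in range(n):
        a1, a2 = geno_labels[i].split("/")
        participants.append(
            Participant(
                id=ids[i],
                age=float(ages[i]),
                sex=str(sex[i]),
                education_years=float(education[i]),
                mmse=int(mmse[i]),
                psen1_carrier=bool(carrier[i]),
                apoe_allele_1=a1,
                apoe_allele_2=a2,
            )
        )
    cohort = Cohort(tuple(participants))
    truth = GroundTruth(
        params=p,
        ids=ids,
        carrier_mask=carrier,
        e4_mask=e4,
        e2_mask=e2,
        onset_ages=onset,
    )
    return cohort, truth


def cohort_from_genotype_counts(
    carrier_counts: Mapping[str, int] | None = None,
    noncarrier_counts: Mapping[str, int] | None = None,
) -> Cohort:
    """Build a bookkeeping cohort with exactly the given genotype counts.

    Ages/sex/education/MMSE are filled with fixed valid placeholders: the
    result is meant for genotype and group-size accounting only. Defaults
    are the kindred's published genotype distribution.
    """
    carrier_counts = dict(carrier_counts or KINDRED_CARRIER_GENOTYPE_COUNTS)
    noncarrier_counts = dict(noncarrier_counts or KINDRED_NONCARRIER_GENOTYPE_COUNTS)
    participants = []
    i = 0
    for counts, is_carrier in ((carrier_counts, True), (noncarrier_counts, False)):
        for geno in GENOTYPES:
            a1, a2 = geno.split("/")
            for _ in range(int(counts.get(geno, 0))):
                i += 1
                participants.append(
                    Participant(
                        id=f"G{i:05d}",
                        age=40.0,
                        sex="F",
                        education_years=8.0,
                        mmse=28,
                        psen1_carrier=is_carrier,
                        apoe_allele_1=a1,
                        apoe_allele_2=a2,
                    )
                )
    return Cohort(tuple(participants))


def params_from_mapping(d: Mapping) -> GeneratorParams:
    """Build GeneratorParams from a flat mapping (e.g. a parsed YAML config)."""
    d = dict(d)
    if "age_range" in d and not isinstance(d["age_range"], tuple):
        d["age_range"] = tuple(float(v) for v in d["age_range"])
    return replace(GeneratorParams(), **d)
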