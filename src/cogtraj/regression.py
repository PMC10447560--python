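"""Gene-environment interaction regressions: MMSE ~ genotype × education.

Ordinary least squares within one PSEN1 stratum, with MMSE total score as
the response and three predictors: a dichotomous APOE genotype indicator,
years of education (continuous, uncentered by default), and their product.
Risk-oriented genotype coding: for the e4 comparison the indicator is 1
for e4+ (the at-risk group); for the e2 comparison it is 1 for e2−
(absence of the protective allele), so a negative genotype coefficient
always reads "the at-risk group scores lower". Age and sex are not
adjusted for. Classical (non-robust) standard errors; two-sided t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort

COEF_NAMES = ("intercept", "genotype", "education_years", "genotype_x_education")


@dataclass(frozen=True)
class RegressionFit:
    names: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    n: int
    resid_sd: float
    r_squared: float

    def __post_init__(self) -> None:
        if not np.all((self.p_values >= 0) & (self.p_values <= 1)):
            raise ValueError("p-values out of [0, 1]")

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def p(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "estimate": self.estimates,
                "se": self.std_errors,
                "t": self.t_values,
                "p": self.p_values,
            }
        )


def _collinear_columns(design: np.ndarray, names) -> list[str]:
    # flag columns whose removal does not reduce rank
    full_rank = np.linalg.matrix_rank(design)
    bad = []
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(names[j] if names is not None else f"col{j}")
    return bad


def fit_ols(y, design, names=None) -> RegressionFit:
    """OLS via a numerically stable decomposition (statsmodels backend).

    SEs are σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n−p); p-values two-sided from the
    t distribution on n−p degrees of freedom. Rank-deficient designs raise
    an error naming the collinear columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("design/response dimensions inconsistent")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    if names is not None and len(names) != p:
        raise ValueError("names length must match column count")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            f"design is rank deficient; collinear column(s): {_collinear_columns(X, names)}"
        )
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return RegressionFit(
        names=tuple(names) if names is not None else tuple(f"x{j}" for j in range(p)),
        estimates=np.asarray(res.params, dtype=float),
        std_errors=np.asarray(res.bse, dtype=float),
        t_values=np.asarray(res.tvalues, dtype=float),
        p_values=np.clip(np.nan_to_num(np.asarray(res.pvalues, dtype=float), nan=1.0), 0.0, 1.0),
        n=n,
        resid_sd=resid_sd,
        r_squared=float(res.rsquared),
    )


def education_model(
    cohort: Cohort,
    stratum: str = "carriers",
    allele: str = "e4",
    center_education: bool = False,
) -> RegressionFit:
    """Fit MMSE ~ genotype + education + genotype:education in one stratum.

    ``allele="e4"``: genotype = 1 for e4+. ``allele="e2"``: genotype = 1
    for e2− (risk orientation). ``center_education`` subtracts the stratum
    mean education before building the design, which makes the genotype
    main effect interpretable at average education; off by default.
    """
    if allele not in ("e4", "e2"):
        raise ValueError(f"allele must be 'e4' or 'e2', got {allele!r}")
    if stratum not in ("carriers", "noncarriers"):
        raise ValueError(f"stratum must be 'carriers' or 'noncarriers', got {stratum!r}")
    df = cohort.to_frame()
    df = df[df["psen1_carrier"]] if stratum == "carriers" else df[~df["psen1_carrier"]]
    if len(df) == 0:
        raise ValueError(f"stratum {stratum!r} is empty")
    flag = df[f"{allele}_positive"].to_numpy()
    genotype = flag.astype(float) if allele == "e4" else (~flag).astype(float)
    if genotype.min() == genotype.max():
        raise ValueError(
            f"stratum {stratum!r} has a single {allele} genotype group; "
            "the comparison is undefined"
        )
    education = df["education_years"].to_numpy(float)
    if center_education:
        education = education - education.mean()
    design = np.column_stack(
        [np.ones(len(df)), genotype, education, genotype * education]
    )
    return fit_ols(df["mmse"].to_numpy(float), design, names=COEF_NAMES)
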