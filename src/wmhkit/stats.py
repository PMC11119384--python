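"""Association statistics for the case-control cohort layer.

Covers the univariable tests behind a two-phenotype baseline table
(Pearson chi-square without continuity correction, two-sided Fisher exact,
Mann–Whitney U, Welch t), the two multivariable logistic models with Wald
odds ratios and VIF collinearity screening, Cohen's kappa for rater
agreement, and the small derivations used for SVD marker scores (total
WMH score, perivascular-space severity bands).

The chi-square deliberately omits the Yates continuity correction: on
2-by-k count tables of this size the uncorrected Pearson statistic is the
one that matches routine epidemiological reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DegenerateInputError, InvalidSpecError

__all__ = [
    "AssociationResult",
    "LogisticModelResult",
    "pearson_chi_square",
    "fisher_exact",
    "choose_categorical_test",
    "mann_whitney",
    "welch_t",
    "logistic_fit",
    "build_model_designs",
    "vif",
    "cohens_kappa",
    "total_wmh_score",
    "categorize_pvs",
    "PVS_CATEGORIES",
    "derive_svd_columns",
    "univariable_table",
    "MODEL1_PREDICTORS",
    "VIF_THRESHOLD",
]

VIF_THRESHOLD = 5.0


@dataclass
class AssociationResult:
    test_name: str
    statistic: float
    df: int | float | None
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise InvalidSpecError("p-value outside [0, 1]")


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidSpecError("contingency table must be 2-dimensional")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise InvalidSpecError("counts must be non-negative integers")
    return arr


def pearson_chi_square(table) -> AssociationResult:
    """Pearson chi-square on a 2×k table, no continuity correction;
    df = (rows − 1)(cols − 1), p from the upper tail."""
    arr = _as_table(table)
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateInputError("zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return AssociationResult("chi_square", float(chi2), int(dof), float(p))


def fisher_p_by_margins(n: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every 2×2 table with margins (r1, n−r1) ×
    (c1, n−c1), indexed by the top-left cell.

    Returns (support, p): p[i] is the sum of hypergeometric probabilities
    of all tables with those margins whose probability does not exceed
    that of top-left cell support[i] (small relative tolerance for ties).
    """
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # for each a: total mass of outcomes no more probable than a
    idx = np.searchsorted(pmf[order], pmf * (1 + 1e-9), side="right")
    p = np.minimum(csum[np.maximum(idx - 1, 0)], 1.0)
    return support, p


def fisher_exact(table) -> AssociationResult:
    """Two-sided Fisher exact test on a 2×2 table.

    p = sum over all tables with the observed margins of the hypergeometric
    probabilities that do not exceed the observed table's probability.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise InvalidSpecError("Fisher exact requires a 2×2 table")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateInputError("zero row or column margin")
    a = int(arr[0, 0])
    r1, c1, n = int(arr[0].sum()), int(arr[:, 0].sum()), int(arr.sum())
    support, p_all = fisher_p_by_margins(n, r1, c1)
    p = float(p_all[support == a][0])
    odds = math.inf if arr[0, 1] * arr[1, 0] == 0 else (
        arr[0, 0] * arr[1, 1] / (arr[0, 1] * arr[1, 0])
    )
    return AssociationResult("fisher_exact", float(odds), None, min(p, 1.0))


def choose_categorical_test(table) -> str:
    """'fisher_exact' when any expected cell count is below 5 (and the
    table is 2×2), else 'chi_square'."""
    arr = _as_table(table)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected < 5).any() and arr.shape == (2, 2):
        return "fisher_exact"
    return "chi_square"


def mann_whitney(
    x, y, method: str = "asymptotic", use_continuity: bool = True
) -> AssociationResult:
    """Two-sided Mann–Whitney U.

    The default is the tie-corrected normal approximation with continuity
    correction; method='exact' enumerates (untied samples only, small n).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise InvalidSpecError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=use_continuity
    )
    return AssociationResult("mann_whitney_u", float(res.statistic), None,
                             float(min(res.pvalue, 1.0)))


def welch_t(x, y) -> AssociationResult:
    """Welch unequal-variance t test with Satterthwaite df."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise InvalidSpecError("need at least 2 observations per sample")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return AssociationResult("welch_t", 0.0, float(x.size + y.size - 2), 1.0)
        raise DegenerateInputError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return AssociationResult("welch_t", float(res.statistic), float(res.df),
                             float(res.pvalue))


# ----------------------------------------------------------------------------
# Logistic models
# ----------------------------------------------------------------------------

@dataclass
class LogisticModelResult:
    predictors: list[str]
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    converged: bool
    separation: bool
    vif: dict[str, float] = field(default_factory=dict)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def conf_int(self, z: float = 1.96) -> np.ndarray:
        with np.errstate(over="ignore"):  # separated fits have infinite CIs
            lo = np.exp(self.coef - z * self.se)
            hi = np.exp(self.coef + z * self.se)
        return np.column_stack([lo, hi])

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "coef": self.coef,
                "se": self.se,
                "or": self.odds_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.p_values,
                "vif": [self.vif.get(p, np.nan) for p in self.predictors],
            }
        )


def logistic_fit(outcome, design: pd.DataFrame, add_constant: bool = True,
                 compute_vif: bool = True) -> LogisticModelResult:
    """Maximum-likelihood logistic regression with Wald inference.

    Newton/IRLS fit (score tolerance 1e-8, at most 100 iterations) through
    statsmodels; quasi-perfect separation is detected and flagged rather
    than silently diverging. VIFs are computed on the non-constant columns.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = np.asarray(outcome, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome is constant")
    X = pd.DataFrame(design).astype(float)
    names = list(X.columns)
    if not np.all(np.isfinite(X.to_numpy())):
        raise InvalidSpecError("design matrix contains non-finite values")
    if add_constant:
        X = sm.add_constant(X, has_constant="add")
    separation = False
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            converged = bool(fit.mle_retvals.get("converged", False))
        except (PerfectSeparationError, PerfectSeparationWarning):
            # refit with a bounded-step optimizer just to report something
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=0)
    params = np.asarray(fit.params, dtype=np.float64)
    ses = np.asarray(fit.bse, dtype=np.float64)
    pvals = np.asarray(fit.pvalues, dtype=np.float64)
    if add_constant:
        params, ses, pvals = params[1:], ses[1:], pvals[1:]
    if np.any(np.abs(params) > 15):  # |log OR| > 15: effectively separated
        separation = True
    vifs = {}
    if compute_vif and len(names) >= 2:
        vifs = vif(design[names])
    return LogisticModelResult(names, params, ses, np.clip(pvals, 0, 1),
                               converged, separation, vifs)


MODEL1_PREDICTORS = [
    "age", "sex", "hypertension", "diabetes", "hyperlipidemia", "cad", "ckd",
    "prior_is", "prior_ich", "smoking", "alcohol", "antiplatelet",
    "lipid_lowering",
]


def derive_svd_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add derived SVD marker columns: any_lacune, total_wmh_score,
    bgpvs_modsev, csopvs_modsev, any_cmb (NaN where no susceptibility
    scan), log10 WMH %ICV."""
    out = cohort.copy()
    out["any_lacune"] = (out["lacune_n"] > 0).astype(int)
    out["total_wmh_score"] = [
        total_wmh_score(pv, dp)
        for pv, dp in zip(out["fazekas_pv"], out["fazekas_deep"])
    ]
    out["bgpvs_modsev"] = (out["bgpvs_cat"] >= 2).astype(int)
    out["csopvs_modsev"] = (out["csopvs_cat"] >= 2).astype(int)
    out["any_cmb"] = np.where(
        out["cmb_n"].isna(), np.nan, (out["cmb_n"] > 0).astype(float)
    )
    out["log10_wmh_pct_icv"] = np.log10(out["wmh_pct_icv"])
    return out


def build_model_designs(
    cohort: pd.DataFrame,
    selection_p: float = 0.05,
    include_cmb: bool = True,
    include_wmh_volume: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Design matrices of the two phenotype models.

    Model 1: age, sex, the vascular risk factors, and pre-stroke
    medications. Model 2: age, sex, the Model-1 predictors whose Wald p
    fell below selection_p, plus the individual SVD markers (lacune
    presence, total WMH score, moderate-to-severe BG-PVS, CMB presence);
    WMH %ICV enters log10-transformed when requested. The outcome codes
    dICH as 1, so OR > 1 reads "more associated with dICH". Returns
    (X1, X2, y1, y2, selected) with Model 2 restricted to complete cases.
    """
    missing = [c for c in MODEL1_PREDICTORS + ["phenotype"] if c not in cohort]
    if missing:
        raise InvalidSpecError(f"cohort table lacks columns: {missing}")
    df = derive_svd_columns(cohort)
    y = (df["phenotype"] == "dICH").astype(int)
    X1 = df[MODEL1_PREDICTORS].astype(float)

    fit1 = logistic_fit(y, X1, compute_vif=False)
    selected = [
        name
        for name, p in zip(fit1.predictors, fit1.p_values)
        if p < selection_p and name not in ("age", "sex")
    ]
    cols2 = ["age", "sex"] + selected + [
        "any_lacune", "total_wmh_score", "bgpvs_modsev"
    ]
    if include_cmb:
        cols2.append("any_cmb")
    if include_wmh_volume:
        cols2.append("log10_wmh_pct_icv")
    X2 = df[cols2].astype(float)
    keep = X2.notna().all(axis=1)
    return X1, X2[keep], y, y[keep], selected


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor 1/(1−R²_j) per predictor, from regressing
    each column on the others (with intercept). Exact collinearity yields
    inf. Values above VIF_THRESHOLD (5) signal problematic collinearity."""
    X = pd.DataFrame(design).astype(float)
    if X.shape[1] < 2:
        raise InvalidSpecError("VIF needs at least 2 predictors")
    if (X.std(ddof=0) == 0).any():
        raise InvalidSpecError("constant predictor column")
    out: dict[str, float] = {}
    arr = X.to_numpy()
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.column_stack(
            [np.ones(len(arr)), np.delete(arr, j, axis=1)]
        )
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa (p_o − p_e)/(1 − p_e) with chance agreement from the
    marginal products. When both raters are constant and identical, chance
    agreement is 1 and kappa is defined as 1 with a warning."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size != b.size or a.size == 0:
        raise InvalidSpecError("ratings must be non-empty and equal length")
    cats = np.unique(np.concatenate([a, b]))
    ia = np.searchsorted(cats, a)
    ib = np.searchsorted(cats, b)
    k = len(cats)
    conf = np.zeros((k, k))
    np.add.at(conf, (ia, ib), 1)
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e >= 1.0:
        warnings.warn("both raters constant and equal; kappa defined as 1",
                      stacklevel=2)
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def total_wmh_score(pv: int, deep: int) -> int:
    """Total WMH burden score: periventricular plus deep Fazekas grade."""
    pv, deep = int(pv), int(deep)
    if not (0 <= pv <= 3 and 0 <= deep <= 3):
        raise InvalidSpecError("Fazekas grades must lie in 0..3")
    return pv + deep


PVS_CATEGORIES = ("none", "mild", "moderate", "frequent", "severe")


def categorize_pvs(count: int) -> tuple[str, bool]:
    """Perivascular-space severity band for a PVS count: none (0),
    mild (1–10), moderate (11–20), frequent (21–40), severe (>40); the
    flag marks moderate-to-severe (count >= 11)."""
    count = int(count)
    if count < 0:
        raise InvalidSpecError("PVS count must be non-negative")
    if count == 0:
        cat = "none"
    elif count <= 10:
        cat = "mild"
    elif count <= 20:
        cat = "moderate"
    elif count <= 40:
        cat = "frequent"
    else:
        cat = "severe"
    return cat, count >= 11


# ----------------------------------------------------------------------------
# Univariable cohort summary
# ----------------------------------------------------------------------------

_BINARY_VARS = [
    "sex", "hypertension", "diabetes", "hyperlipidemia", "cad", "ckd",
    "prior_is", "prior_ich", "smoking", "alcohol", "antiplatelet",
    "lipid_lowering",
]
_RANK_VARS = ["fazekas_pv", "fazekas_deep", "bgpvs_cat", "csopvs_cat",
              "lacune_n", "wmh_pct_icv"]
_T_VARS = ["age"]


def univariable_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-variable univariable comparison between the two phenotypes.

    Binary factors get chi-square or Fisher (expected-count rule), ordinal
    scores and skewed volumes get Mann–Whitney, age gets Welch t. Returns
    a tidy frame: variable, test, statistic, df, p.
    """
    df = derive_svd_columns(cohort)
    g = df["phenotype"] == "dICH"
    rows = []
    for var in _BINARY_VARS + ["any_lacune", "bgpvs_modsev", "csopvs_modsev"]:
        tab = pd.crosstab(~g, df[var]).to_numpy()  # row 0 = LIS
        test = choose_categorical_test(tab)
        res = fisher_exact(tab) if test == "fisher_exact" else pearson_chi_square(tab)
        rows.append((var, res.test_name, res.statistic, res.df, res.p_value))
    cmb = df.dropna(subset=["any_cmb"])
    if not cmb.empty and cmb["any_cmb"].nunique() > 1:
        tab = pd.crosstab(cmb["phenotype"] != "dICH", cmb["any_cmb"]).to_numpy()
        test = choose_categorical_test(tab)
        res = fisher_exact(tab) if test == "fisher_exact" else pearson_chi_square(tab)
        rows.append(("any_cmb", res.test_name, res.statistic, res.df, res.p_value))
    for var in _RANK_VARS:
        res = mann_whitney(df.loc[~g, var], df.loc[g, var])
        rows.append((var, res.test_name, res.statistic, res.df, res.p_value))
    for var in _T_VARS:
        res = welch_t(df.loc[~g, var], df.loc[g, var])
        rows.append((var, res.test_name, res.statistic, res.df, res.p_value))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "df", "p"])
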