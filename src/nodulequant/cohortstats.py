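"""Invasiveness-prediction statistics for a tumor cohort.

Univariate screening (two-sample t tests for continuous covariates, Pearson
chi-square / Fisher's exact test for categorical ones), Spearman rank
correlation of the component proportions with the lepidic growth percentage,
multivariable logistic regression with Wald odds ratios, and ROC comparison
of predictors via the DeLong structural-components test, including the
Youden-optimal solid-proportion cutoff for calling a tumor invasive.

Standard tests are delegated to scipy/statsmodels; the DeLong covariance
estimator for correlated AUCs is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .thresholding import ROCCurve, ThresholdResult, roc_curve, youden_cutoff

__all__ = [
    "GroupSummary",
    "ContingencyTable",
    "TTestResult",
    "Chi2Result",
    "LogisticFit",
    "AUCComparison",
    "CohortReport",
    "SeparationError",
    "pooled_t",
    "welch_t",
    "pearson_chi2",
    "fisher_exact",
    "spearman_rho",
    "logistic_fit",
    "delong_auc",
    "delong_compare",
    "analyze_cohort",
]


class SeparationError(RuntimeError):
    """Raised when logistic MLE does not exist due to complete separation."""


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one continuous covariate in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class ContingencyTable:
    """Covariate levels (rows) by invasive / non-invasive (columns)."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ("invasive", "non-invasive")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError(f"need at least a 2x2 table, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        object.__setattr__(self, "counts", counts)


class TTestResult:
    """t statistic with df and two-sided p."""

    __slots__ = ("t", "df", "p")

    def __init__(self, t: float, df: float, p: float):
        self.t, self.df, self.p = t, df, p

    def __repr__(self) -> str:
        return f"TTestResult(t={self.t:.3f}, df={self.df:.1f}, p={self.p:.3g})"


class Chi2Result:
    __slots__ = ("chi2", "df", "p")

    def __init__(self, chi2: float, df: int, p: float):
        self.chi2, self.df, self.p = chi2, df, p

    def __repr__(self) -> str:
        return f"Chi2Result(chi2={self.chi2:.3f}, df={self.df}, p={self.p:.3g})"


def pooled_t(summary_a: GroupSummary, summary_b: GroupSummary) -> TTestResult:
    """Classical pooled-variance two-sample t test from summary statistics.

    The statistic is signed as (mean_b - mean_a), i.e. second group minus the
    first listed; df = n_a + n_b - 2.
    """
    t, p = stats.ttest_ind_from_stats(
        summary_b.mean, summary_b.sd, summary_b.n,
        summary_a.mean, summary_a.sd, summary_a.n,
        equal_var=True,
    )
    return TTestResult(float(t), summary_a.n + summary_b.n - 2, float(p))


def welch_t(summary_a: GroupSummary, summary_b: GroupSummary) -> TTestResult:
    """Welch's unequal-variance t test with Satterthwaite df, sign (b - a)."""
    t, p = stats.ttest_ind_from_stats(
        summary_b.mean, summary_b.sd, summary_b.n,
        summary_a.mean, summary_a.sd, summary_a.n,
        equal_var=False,
    )
    va = summary_a.sd**2 / summary_a.n
    vb = summary_b.sd**2 / summary_b.n
    if va + vb == 0:
        df = float(summary_a.n + summary_b.n - 2)
    else:
        df = (va + vb) ** 2 / (
            va**2 / (summary_a.n - 1) + vb**2 / (summary_b.n - 1)
        )
    return TTestResult(float(t), float(df), float(p))


def pearson_chi2(table: ContingencyTable) -> Chi2Result:
    """Pearson chi-square without continuity correction.

    All expected counts must be positive (a zero marginal is an error).
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return Chi2Result(float(chi2), int(df), float(p))


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric enumeration:
    the total probability of tables no more likely than the observed one)."""
    counts = table.counts
    if counts.shape != (2, 2):
        raise ValueError(f"Fisher exact requires a 2x2 table, got {counts.shape}")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("Fisher exact requires integer counts")
        counts = counts.astype(int)
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return float(p)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (tie-aware mid-ranks), p via t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``table`` has one row per predictor (plus intercept) with columns
    coef, se, odds_ratio, ci_low, ci_high, p. ``linear_predictor`` is the
    in-sample score X @ beta, usable directly as a ROC predictor.
    """

    table: pd.DataFrame
    converged: bool
    n: int
    llf: float
    linear_predictor: np.ndarray

    def odds_ratio(self, name: str) -> float:
        return float(self.table.loc[name, "odds_ratio"])


def logistic_fit(
    design: pd.DataFrame,
    outcome: Sequence[int],
    add_intercept: bool = True,
) -> LogisticFit:
    """Fit a binary logistic model by IRLS (Newton) with Wald CIs.

    Raises :class:`SeparationError` on complete separation (the MLE diverges)
    and ``ValueError`` on a rank-deficient design, naming the collinear
    columns. Odds-ratio CIs are exp(coef +/- 1.96 se).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = design.astype(float)
    y = np.asarray(outcome, dtype=float)
    if len(X) != len(y):
        raise ValueError("design and outcome lengths differ")
    if len(X) <= X.shape[1]:
        raise ValueError("need n > number of predictors")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        cols: list[str] = []
        for c in X.columns:
            trial = X[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(c)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise SeparationError(f"logistic MLE failed: {err}") from err
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not res.mle_retvals.get("converged", False) or not np.isfinite(bse).all():
        raise SeparationError(
            "logistic fit did not converge (possible complete separation)"
        )
    z = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p": np.asarray(res.pvalues, dtype=float),
        },
        index=X.columns,
    )
    return LogisticFit(
        table=table,
        converged=True,
        n=len(y),
        llf=float(res.llf),
        linear_predictor=np.asarray(X.to_numpy() @ params, dtype=float),
    )


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUCs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AUCComparison:
    """Paired comparison of two correlated AUCs (same subjects)."""

    auc_1: float
    auc_2: float
    var_1: float
    var_2: float
    cov: float
    z: float
    p: float


def _structural_components(pred: np.ndarray, labels: np.ndarray):
    """Per-subject placement values V10 (cases) and V01 (controls)."""
    x = pred[labels == 1][:, None]  # cases, shape (m, 1)
    y = pred[labels == 0][None, :]  # controls, shape (1, n)
    psi = (x > y).astype(float) + 0.5 * (x == y)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01


def delong_auc(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance for one predictor."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    v10, v01 = _structural_components(pred, labels)
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))
    return auc, var


def delong_compare(
    pred_1: np.ndarray,
    pred_2: np.ndarray,
    labels: np.ndarray,
) -> AUCComparison:
    """DeLong Z test for the difference of two correlated AUCs.

    Both predictors score the same subjects; the covariance of the AUC
    estimates is obtained from the per-subject structural components. Swapping
    the predictors flips the sign of Z; identical predictors give Z = 0, p = 1.
    """
    pred_1 = np.asarray(pred_1, dtype=float)
    pred_2 = np.asarray(pred_2, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(pred_1) == len(pred_2) == len(labels)):
        raise ValueError("predictors and labels must share length")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")

    v10_1, v01_1 = _structural_components(pred_1, labels)
    v10_2, v01_2 = _structural_components(pred_2, labels)
    m, n = len(v10_1), len(v01_1)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())

    def _cov(a, b):
        return float(np.cov(a, b, ddof=1)[0, 1])

    var1 = np.var(v10_1, ddof=1) / m + np.var(v01_1, ddof=1) / n
    var2 = np.var(v10_2, ddof=1) / m + np.var(v01_2, ddof=1) / n
    cov12 = _cov(v10_1, v10_2) / m + _cov(v01_1, v01_2) / n

    var_diff = var1 + var2 - 2 * cov12
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (auc1 - auc2) / np.sqrt(var_diff)
        p = 2 * stats.norm.sf(abs(z))
    return AUCComparison(
        auc_1=auc1, auc_2=auc2, var_1=float(var1), var_2=float(var2),
        cov=float(cov12), z=float(z), p=float(p),
    )


# ---------------------------------------------------------------------------
# full cohort analysis
# ---------------------------------------------------------------------------

_CONTINUOUS = ("size_cm", "ggoc_pct", "sc_pct", "suv_max")
_CATEGORICAL = {
    "location": ("centre", "periphery"),
    "contour": ("smooth", "lobular", "spiculated"),
    "necrosis": (1, 0),
    "vacuole_cyst": ("none", "vacuole", "cyst"),
}
_ORDINAL_CODES = {
    "contour": {"smooth": 0, "lobular": 1, "spiculated": 2},
    "vacuole_cyst": {"none": 0, "vacuole": 1, "cyst": 2},
}


@dataclass
class CohortReport:
    """Structured output of :func:`analyze_cohort`."""

    univariate_continuous: dict[str, dict] = field(default_factory=dict)
    univariate_categorical: dict[str, dict] = field(default_factory=dict)
    spearman: dict[str, tuple[float, float]] = field(default_factory=dict)
    logistic: LogisticFit | None = None
    logistic_error: str | None = None
    aucs: dict[str, float] = field(default_factory=dict)
    auc_comparisons: dict[str, AUCComparison] = field(default_factory=dict)
    sc_cutoff: ThresholdResult | None = None
    n_invasive: int = 0
    n_noninvasive: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Flat key/value view of every scalar in the report (for CSV export)."""
        rows: list[tuple[str, float]] = []
        for var, d in self.univariate_continuous.items():
            rows += [(f"t_{var}", d["t"]), (f"p_{var}", d["p"])]
        for var, d in self.univariate_categorical.items():
            rows += [(f"chi2_{var}", d["chi2"]), (f"p_{var}", d["p_chi2"])]
        for var, (rho, p) in self.spearman.items():
            rows += [(f"spearman_{var}", rho), (f"spearman_p_{var}", p)]
        for name, auc in self.aucs.items():
            rows.append((f"auc_{name}", auc))
        for name, cmp in self.auc_comparisons.items():
            rows += [(f"z_{name}", cmp.z), (f"p_{name}", cmp.p)]
        if self.sc_cutoff is not None:
            rows += [
                ("sc_cutoff_pct", self.sc_cutoff.cutoff),
                ("sc_cutoff_sensitivity", self.sc_cutoff.sensitivity),
                ("sc_cutoff_specificity", self.sc_cutoff.specificity),
            ]
        if self.logistic is not None:
            for name, r in self.logistic.table.iterrows():
                rows += [(f"or_{name}", r["odds_ratio"]), (f"or_p_{name}", r["p"])]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def analyze_cohort(
    cohort: pd.DataFrame,
    multivariable: Sequence[str] = (
        "size_cm", "contour", "necrosis", "vacuole_cyst", "ggoc_pct", "sc_pct",
    ),
    proportion_scale: float = 0.01,
) -> CohortReport:
    """Run the full invasiveness analysis on a cohort table.

    Steps: Welch t tests per continuous covariate (invasive vs non-invasive),
    Pearson chi-square per categorical covariate (plus Fisher's exact when the
    table is 2x2 or any expected count falls below 5), Spearman correlation of
    GGOc/Sc proportions with the lepidic percentage, multivariable logistic
    regression on the requested covariates (SUV_max is excluded: it is
    missing for tumors without PET/CT), ROC/AUC for the Sc proportion, tumor
    size and the combined size+Sc model score, pairwise DeLong comparisons,
    and the Youden-optimal Sc cutoff for predicting invasiveness.

    ``proportion_scale`` converts percentage covariates to the modeling scale
    (default 0.01: proportions enter the logistic model on 0-1, so the Sc odds
    ratio reads "0% versus 100%").
    """
    inv = cohort[cohort["invasive"] == 1]
    non = cohort[cohort["invasive"] == 0]
    if len(inv) == 0 or len(non) == 0:
        raise ValueError("cohort must contain both invasive and non-invasive tumors")
    report = CohortReport(n_invasive=len(inv), n_noninvasive=len(non))

    for var in _CONTINUOUS:
        if var not in cohort:
            continue
        a = inv[var].dropna()
        b = non[var].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        res = welch_t(
            GroupSummary(len(a), a.mean(), a.std(ddof=1)),
            GroupSummary(len(b), b.mean(), b.std(ddof=1)),
        )
        report.univariate_continuous[var] = {
            "t": res.t, "df": res.df, "p": res.p,
            "mean_invasive": float(a.mean()), "sd_invasive": float(a.std(ddof=1)),
            "mean_noninvasive": float(b.mean()), "sd_noninvasive": float(b.std(ddof=1)),
        }

    for var, levels in _CATEGORICAL.items():
        if var not in cohort:
            continue
        counts = np.array(
            [[(inv[var] == lv).sum(), (non[var] == lv).sum()] for lv in levels]
        )
        keep = counts.sum(axis=1) > 0
        counts = counts[keep]
        if counts.shape[0] < 2:
            continue
        table = ContingencyTable(counts)
        chi = pearson_chi2(table)
        entry = {"chi2": chi.chi2, "df": chi.df, "p_chi2": chi.p}
        expected = stats.contingency.expected_freq(counts)
        if counts.shape == (2, 2) or (expected < 5).any():
            if counts.shape == (2, 2):
                entry["p_fisher"] = fisher_exact(table)
        report.univariate_categorical[var] = entry

    if "lepidic_pct" in cohort and cohort["lepidic_pct"].nunique() > 1:
        for var in ("ggoc_pct", "sc_pct"):
            if var in cohort and cohort[var].nunique() > 1:
                report.spearman[var] = spearman_rho(
                    cohort[var].to_numpy(), cohort["lepidic_pct"].to_numpy()
                )

    design = pd.DataFrame(index=cohort.index)
    for var in multivariable:
        if var == "suv_max":
            raise ValueError(
                "SUV_max is excluded from the multivariable model (incomplete "
                "PET/CT coverage); drop it from `multivariable`"
            )
        col = cohort[var]
        if var in _ORDINAL_CODES:
            design[var] = col.map(_ORDINAL_CODES[var]).astype(float)
        elif var == "location":
            design[var] = (col == "periphery").astype(float)
        elif var.endswith("_pct"):
            design[var] = col.astype(float) * proportion_scale
        else:
            design[var] = col.astype(float)
    y = cohort["invasive"].to_numpy()
    try:
        report.logistic = logistic_fit(design, y)
    except SeparationError as err:
        # flagged, not fatal: small cohorts can separate on the full model
        report.logistic_error = str(err)

    labels = y
    sc = cohort["sc_pct"].to_numpy(dtype=float)
    size = cohort["size_cm"].to_numpy(dtype=float)
    try:
        combined_fit = logistic_fit(
            cohort[["size_cm"]].assign(sc=sc * proportion_scale), y
        )
        combined = combined_fit.linear_predictor
    except SeparationError:
        # MLE does not exist (tiny/separated cohort): fall back to the sum of
        # standardized predictors as the combined score
        combined = (sc - sc.mean()) / sc.std() + (size - size.mean()) / size.std()

    report.aucs["sc"], _ = delong_auc(sc, labels)
    report.aucs["size"], _ = delong_auc(size, labels)
    report.aucs["combined"], _ = delong_auc(combined, labels)
    report.auc_comparisons["sc_vs_size"] = delong_compare(sc, size, labels)
    report.auc_comparisons["combined_vs_size"] = delong_compare(combined, size, labels)
    report.auc_comparisons["combined_vs_sc"] = delong_compare(combined, sc, labels)

    report.sc_cutoff = youden_cutoff(roc_curve(sc, labels, direction="high"))
    return report
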