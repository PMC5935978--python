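"""Observer agreement for the GGOc/Sc measurements.

Two radiologists (or one radiologist on two occasions) measure the same
component proportion on the same tumors; agreement is summarized by the 95%
Bland-Altman limits of agreement (bias +/- 1.96 SD of the paired differences)
and the intraclass correlation coefficient ICC(2,1) — two-way random effects,
absolute agreement, single measures — with an F-based 95% confidence
interval. An ICC above 0.75 is conventionally read as good agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PairedMeasurements", "AgreementResult", "bland_altman",
           "icc_two_way", "agreement_result", "agreement_experiment"]


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-tumor values by two raters (or two reading occasions)."""

    rater_a: np.ndarray
    rater_b: np.ndarray
    tumor_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.rater_a, dtype=float)
        b = np.asarray(self.rater_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("rater columns must be equal-length 1D vectors")
        if len(a) < 3:
            raise ValueError(f"need n >= 3 paired measurements, got {len(a)}")
        object.__setattr__(self, "rater_a", a)
        object.__setattr__(self, "rater_b", b)
        if self.tumor_ids is None:
            object.__setattr__(self, "tumor_ids", np.arange(len(a)))

    @property
    def n(self) -> int:
        return len(self.rater_a)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman bias and limits plus ICC(2,1) with its 95% CI."""

    bias: float
    loa_low: float
    loa_high: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float


def bland_altman(pairs: PairedMeasurements) -> tuple[float, tuple[float, float]]:
    """Bias and 95% limits of agreement of the paired differences.

    Differences are rater_b - rater_a; limits are bias +/- 1.96 sample SD
    (n-1 denominator), the conventional normal-quantile form.
    """
    d = pairs.rater_b - pairs.rater_a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def icc_two_way(pairs: PairedMeasurements, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares (subjects x raters); the CI
    follows the F-distribution construction of McGraw & Wong. Returns
    ``(icc, (ci_low, ci_high))``. Perfectly identical columns give icc = 1.
    """
    if np.array_equal(pairs.rater_a, pairs.rater_b) and np.ptp(pairs.rater_a) > 0:
        return 1.0, (1.0, 1.0)  # exact agreement, bypassing ANOVA round-off
    data = np.column_stack([pairs.rater_a, pairs.rater_b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")

    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)       # between subjects
    msc = ss_cols / (k - 1)       # between raters
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 1.0

    if mse == 0 and msc == 0:
        # raters identical: agreement is exact and the CI degenerates
        return 1.0, (1.0, 1.0)

    # McGraw & Wong F-based interval for ICC(A,1)
    fj = msc / mse if mse > 0 else np.inf
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(fj) and np.isfinite(a):
        v = (a * fj + b) ** 2 / (
            a**2 * fj**2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
        )
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
    else:
        lower = upper = 1.0
    return float(icc), (float(lower), float(upper))


def agreement_result(pairs: PairedMeasurements) -> AgreementResult:
    """Combined Bland-Altman + ICC summary for one set of paired readings."""
    bias, (lo, hi) = bland_altman(pairs)
    icc, (cl, ch) = icc_two_way(pairs)
    return AgreementResult(bias=bias, loa_low=lo, loa_high=hi,
                           icc=icc, icc_ci_low=cl, icc_ci_high=ch)


def agreement_experiment(
    n_tumors: int = 50,
    seed: int = 0,
    rater_seeds: tuple[int, int] = (0, 0),
    edit_sd: float = 0.02,
) -> PairedMeasurements:
    """Replay a proportion measurement by two raters on the same tumors.

    Each tumor's true Sc proportion is drawn once (seed-controlled); each
    rater observes it through an independent zero-mean Gaussian editing
    perturbation whose RNG stream is that rater's seed. Equal rater seeds
    reproduce the measurement exactly, so the ICC is 1 — the reproducibility
    claim at its logical extreme.
    """
    rng = np.random.default_rng(seed)
    truth = rng.uniform(0.0, 1.0, n_tumors)

    def _read(rater_seed: int) -> np.ndarray:
        r = np.random.default_rng(rater_seed)
        return np.clip(truth + r.normal(0.0, edit_sd, n_tumors), 0.0, 1.0)

    return PairedMeasurements(_read(rater_seeds[0]), _read(rater_seeds[1]))
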