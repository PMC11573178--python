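"""Behavioral task measures and test-retest reliability statistics.

Behavioral measures per session: total accuracy (fraction of trials
choosing the pie-chart-favoured option), advice taking (overall and per
phase), win-stay and lose-switch probabilities. Reliability statistics
across paired sessions: ICC(A,1) — the two-way, single-measure,
absolute-agreement intraclass correlation — with its F-based 95% CI,
Pearson's r, paired t-tests with Cohen's d and the JZS Bayes factor for
the null (BF01), Tukey extreme-outlier screening, and Cook's-distance
influence diagnostics on the ICC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

__all__ = [
    "BehavioralMeasures",
    "ICCResult",
    "PairedComparison",
    "BEHAVIORAL_MEASURE_NAMES",
    "behavioral_measures",
    "icc_a1",
    "paired_comparison",
    "jzs_bf01_paired",
    "tukey_extreme_outliers",
    "icc_influence_diagnostics",
    "KOO_LI_LABELS",
]

BEHAVIORAL_MEASURE_NAMES = (
    "accuracy",
    "advice_taking_total",
    "advice_taking_stable",
    "advice_taking_volatile",
    "win_stay",
    "lose_switch",
)

#: conventional qualitative labels for ICC ranges
KOO_LI_LABELS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


def icc_label(icc: float) -> str:
    for upper, label in KOO_LI_LABELS:
        if icc < upper:
            return label
    return "excellent"


@dataclass(frozen=True)
class BehavioralMeasures:
    accuracy: float
    advice_taking_total: float
    advice_taking_stable: float
    advice_taking_volatile: float
    win_stay: float
    lose_switch: float

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in BEHAVIORAL_MEASURE_NAMES}


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: float
    df2: float
    n: int

    @property
    def label(self) -> str:
        return icc_label(self.icc)

    def to_dict(self) -> dict:
        return {"icc": self.icc, "ci": [self.ci_low, self.ci_high],
                "F": self.f_value, "df1": self.df1, "df2": self.df2,
                "n": self.n, "label": self.label}


@dataclass(frozen=True)
class PairedComparison:
    t: float
    p: float
    cohens_d: float
    bf01: float
    mean_diff: float
    n: int

    @property
    def bf10(self) -> float:
        return 1.0 / self.bf01

    def to_dict(self) -> dict:
        return {"t": self.t, "p": self.p, "d": self.cohens_d,
                "bf01": self.bf01, "mean_diff": self.mean_diff, "n": self.n}


def behavioral_measures(session, accuracy_rule: str = "cue") -> BehavioralMeasures:
    """Compute the six behavioral measures of one played session.

    accuracy: fraction of trials on which the chosen option was the one
    with the higher pie-chart win probability (``accuracy_rule="cue"``,
    the default) or the realised winning option (``"outcome"``).
    advice_taking_*: mean of y over all / stable / volatile trials.
    win_stay: P(y(k+1) = y(k) | win(k) = 1); lose_switch:
    P(y(k+1) != y(k) | win(k) = 0). Empty conditioning subsets (e.g. a
    session without losses) yield NaN.
    """
    if session.y is None or session.win is None:
        raise ValueError("session has no choices/outcomes")
    y = np.asarray(session.y)
    win = np.asarray(session.win)
    c = np.asarray(session.c, dtype=float)
    phase = np.asarray(session.phase)
    if not (len(y) == len(win) == len(c) == len(phase)):
        raise ValueError("session sequences have unequal lengths")
    if accuracy_rule == "cue":
        # following advice picks the advised option, whose cue prob is c
        chose_better = np.where(y == 1, c > 0.5, c < 0.5)
        accuracy = float(np.mean(chose_better))
    elif accuracy_rule == "outcome":
        accuracy = float(np.mean(win))
    else:
        raise ValueError(f"unknown accuracy_rule {accuracy_rule!r}")

    def _mean(mask):
        return float(np.mean(y[mask])) if mask.any() else float("nan")

    stay = y[1:] == y[:-1]
    after_win = win[:-1] == 1
    after_loss = win[:-1] == 0
    win_stay = float(np.mean(stay[after_win])) if after_win.any() else float("nan")
    lose_switch = float(np.mean(~stay[after_loss])) if after_loss.any() else float("nan")
    return BehavioralMeasures(
        accuracy=accuracy,
        advice_taking_total=float(np.mean(y)),
        advice_taking_stable=_mean(phase == "stable"),
        advice_taking_volatile=_mean(phase == "volatile"),
        win_stay=win_stay,
        lose_switch=lose_switch,
    )


def icc_a1(x, y, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way, single-measure, absolute-agreement ICC.

    Computed from the two-way ANOVA mean squares (rows = subjects,
    columns = the two sessions):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    with k = 2 sessions and the F-based confidence interval of the
    absolute-agreement case (Satterthwaite df for the denominator).
    Unlike Pearson's r, a systematic offset between sessions lowers the
    coefficient. NaN pairs are dropped listwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong absolute agreement, single measure)
    if icc < 1.0 and mse > 0:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
        fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
        f_value = msr / mse
        df2 = v
    else:  # perfect agreement: degenerate CI
        lo = hi = icc
        f_value, df2 = np.inf, float(n - 1)
        v = df2
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     f_value=float(f_value), df1=float(n - 1), df2=float(df2), n=n)


def jzs_bf01_paired(t: float, n: int, r: float = math.sqrt(2) / 2) -> float:
    """JZS Bayes factor for the null from a paired-sample t statistic.

    The alternative places a Cauchy(0, r) prior on the standardised
    effect; BF10 is the Rouder et al. one-sample integral evaluated by
    adaptive quadrature over the scale mixture, and BF01 = 1/BF10.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1

    def integrand(g):
        return (
            (1.0 + n * g * r * r) ** -0.5
            * (1.0 + t * t / ((1.0 + n * g * r * r) * df)) ** (-(df + 1) / 2.0)
            * (2.0 * math.pi) ** -0.5
            * g ** -1.5
            * math.exp(-1.0 / (2.0 * g))
        )

    marginal, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    null = (1.0 + t * t / df) ** (-(df + 1) / 2.0)
    bf10 = marginal / null
    return 1.0 / bf10


def paired_comparison(x, y, bf_scale: float = math.sqrt(2) / 2) -> PairedComparison:
    """Paired t-test of y vs x with Cohen's d and the JZS BF01.

    Differences are y - x (session 2 minus session 1); Cohen's d is
    mean(diff)/sd(diff). NaN pairs are dropped listwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    diff = y - x
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() != 0:
            raise ValueError("zero-variance non-zero differences: t undefined")
        # exact null sample (identical sessions): no evidence of change
        t, p, d = 0.0, 1.0, 0.0
    else:
        t = float(diff.mean() / (sd / math.sqrt(n)))
        p = float(2 * stats.t.sf(abs(t), n - 1))
        d = float(diff.mean() / sd)
    bf01 = jzs_bf01_paired(t, n, r=bf_scale)
    return PairedComparison(t=t, p=p, cohens_d=d, bf01=float(bf01),
                            mean_diff=float(diff.mean()), n=n)


def tukey_extreme_outliers(values) -> np.ndarray:
    """Boolean mask of extreme outliers by the Tukey 3-IQR rule.

    Flags values below Q1 - 3*IQR or above Q3 + 3*IQR, with quartiles by
    linear interpolation (NumPy's default convention). NaNs are never
    flagged.
    """
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 4:
        raise ValueError("need at least 4 finite values")
    q1, q3 = np.nanpercentile(v, [25, 75])
    iqr = q3 - q1
    with np.errstate(invalid="ignore"):
        return (v < q1 - 3 * iqr) | (v > q3 + 3 * iqr)


@dataclass
class InfluenceReport:
    cooks_distance: np.ndarray
    threshold: float
    removed: np.ndarray  # indices removed
    icc_full: ICCResult
    icc_after_removal: ICCResult

    def to_dict(self) -> dict:
        return {"cooks_distance": self.cooks_distance.tolist(),
                "threshold": self.threshold,
                "removed": self.removed.tolist(),
                "icc_full": self.icc_full.to_dict(),
                "icc_after_removal": self.icc_after_removal.to_dict()}


def icc_influence_diagnostics(x, y, threshold: float | None = None) -> InfluenceReport:
    """Cook's-distance screen of pairs with outsized effect on the ICC.

    Distances come from the simple OLS regression of session-2 on
    session-1 values; pairs above the threshold (default 4/n) are
    removed and the ICC(A,1) recomputed. Perfectly collinear data yield
    all-zero distances and no removals.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    icc_full = icc_a1(x, y)
    n = len(x)
    if threshold is None:
        threshold = 4.0 / n
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if model.mse_resid <= 1e-12 * max(float(np.var(y)), 1.0):
        cooks = np.zeros(n)  # perfect fit: influence ratios are numerical noise
    else:
        cooks = np.nan_to_num(model.get_influence().cooks_distance[0], nan=0.0)
    removed = np.flatnonzero(cooks > threshold)
    if len(removed) and n - len(removed) >= 3:
        keep = np.setdiff1d(np.arange(n), removed)
        icc_after = icc_a1(x[keep], y[keep])
    else:
        removed = np.array([], dtype=int)
        icc_after = icc_full
    return InfluenceReport(cooks_distance=cooks, threshold=float(threshold),
                           removed=removed, icc_full=icc_full,
                           icc_after_removal=icc_after)
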