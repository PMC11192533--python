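"""Flexibility estimation, bias, QC rules, and group-level statistics.

Flexibility is the ability of the internal oscillator to adapt to
trial-to-trial changes in stimulus rate (ΔIOI). It is estimated per
participant and per rate-change direction as the slope of performance on
the absolute rate change |ΔIOI|:

* duration discrimination — logistic regression of trial accuracy on
  |ΔIOI|, fitted separately for faster- and slower-than-previous trials;
  more negative slopes mean accuracy collapses faster under rate change,
  i.e. a less flexible oscillator;
* paced tapping — ordinary least squares of |TME| on |ΔIOI| per direction,
  with the raw slope sign-flipped so that, as in discrimination, more
  negative values indicate less flexibility.

The module also houses trial annotation (ΔIOI bookkeeping across block
boundaries), response bias, participant-level exclusion rules, 2AFC
psychometric thresholds, Benjamini-Hochberg FDR, the Brown-Forsythe
variance test, Tukey-fence outlier filtering, and the age-correlation
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FlexibilityEstimate",
    "QcReport",
    "annotate_delta",
    "fit_logistic",
    "flexibility_discrimination",
    "flexibility_tapping",
    "bias_summary",
    "qc_participant",
    "fit_threshold",
    "pooled_threshold",
    "bh_fdr",
    "brown_forsythe",
    "tukey_filter",
    "age_analysis",
]

#: |slope| * SD(x) beyond which a logistic fit is treated as separated.
_SEPARATION_CAP = 30.0


@dataclass(frozen=True)
class FlexibilityEstimate:
    """Per-participant, per-direction flexibility slope."""

    participant_id: str
    task: str  # "discrimination" | "paced_tapping"
    direction: str  # "faster" | "slower"
    beta: float
    intercept: float
    converged: bool
    n_trials: int
    low_n: bool = False


@dataclass
class QcReport:
    """Participant-level quality-control flags and per-task exclusions."""

    participant_id: str
    flags: set = field(default_factory=set)
    excluded_tasks: set = field(default_factory=set)


def annotate_delta(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ΔIOI fields computed over the full presentation sequence.

    ``delta_ioi_ms`` is the current minus the previous *presented* IOI, so
    a boundary-repeat trial serves as the predecessor of the trial after
    it (preserving between-trial histories across block breaks); the
    repeats themselves are then dropped. The session's first trial keeps an
    undefined ΔIOI. ``delta_sign`` is ``"faster"`` for negative ΔIOI,
    ``"slower"`` for positive, and NA for zero or undefined.
    """
    if "trial_index" in trials.columns:
        order = trials["trial_index"].to_numpy()
        if np.any(np.diff(order) <= 0):
            raise ValueError("trials must be in presentation order")
    df = trials.copy()
    df["delta_ioi_ms"] = df["ioi_ms"].diff()
    if "is_boundary_repeat" in df.columns:
        df = df[~df["is_boundary_repeat"].astype(bool)].copy()
    df["abs_delta"] = df["delta_ioi_ms"].abs()
    sign = pd.Series(pd.NA, index=df.index, dtype="object")
    sign[df["delta_ioi_ms"] < 0] = "faster"
    sign[df["delta_ioi_ms"] > 0] = "slower"
    df["delta_sign"] = sign
    return df


def fit_logistic(x, y, cap: float = _SEPARATION_CAP) -> tuple[float, float, bool]:
    """Maximum-likelihood logistic fit of binary ``y`` on ``x``.

    Returns ``(intercept, slope, converged)``. Degenerate inputs do not
    raise: constant ``y`` yields a capped intercept with zero slope, and
    (quasi-)complete separation yields a slope capped at
    ``±cap / SD(x)``; both are flagged ``converged=False``.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(x) != len(y):
        raise ValueError("x and y must be equal-length and non-empty")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct x values")
    sx = float(np.std(x))
    if np.all(y == y[0]):
        return float(np.copysign(cap, y[0] - 0.5)), 0.0, False
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        intercept, slope = float(res.params[0]), float(res.params[1])
        converged = bool(getattr(res, "converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        converged = False
        slope = np.nan
        intercept = np.nan
    if not np.isfinite(slope) or abs(slope) * sx > cap:
        direction = np.corrcoef(x, y)[0, 1] if np.isfinite(slope) is False else slope
        sgn = np.sign(direction) if np.isfinite(direction) and direction != 0 else 1.0
        slope = float(sgn * cap / sx)
        intercept = float(np.log(np.mean(y) / (1 - np.mean(y))) - slope * np.mean(x)) \
            if 0 < np.mean(y) < 1 else 0.0
        return intercept, slope, False
    return intercept, slope, converged


def _direction_fit(
    df: pd.DataFrame,
    xcol: str,
    ycol: str,
    fitter,
    participant_id: str,
    task: str,
    min_n: int = 10,
) -> list[FlexibilityEstimate]:
    out = []
    for direction in ("faster", "slower"):
        sub = df[(df["delta_sign"] == direction)
                 & df[xcol].notna() & df[ycol].notna()]
        if len(sub) < 2 or sub[xcol].nunique() < 2:
            continue
        intercept, beta, converged = fitter(sub[xcol].to_numpy(float),
                                            sub[ycol].to_numpy(float))
        out.append(FlexibilityEstimate(
            participant_id, task, direction, beta, intercept, converged,
            len(sub), low_n=len(sub) < min_n,
        ))
    return out


def flexibility_discrimination(
    trials: pd.DataFrame, participant_id: str = ""
) -> list[FlexibilityEstimate]:
    """Logistic accuracy ~ |ΔIOI| slopes, one per rate-change direction.

    ``trials`` must carry the :func:`annotate_delta` fields. The raw slope
    is reported (negative = accuracy falls with rate change = less
    flexible). Directions with fewer than 10 trials are flagged ``low_n``.
    """
    return _direction_fit(trials, "abs_delta", "accuracy", fit_logistic,
                          participant_id, "discrimination")


def flexibility_tapping(
    tap_trials: pd.DataFrame, participant_id: str = ""
) -> list[FlexibilityEstimate]:
    """Linear |TME| ~ |ΔIOI| slopes per direction, sign-flipped.

    A positive raw slope (tempo-matching error growing with rate change)
    maps to a negative flexibility beta, aligning the scale with the
    discrimination task. Requires ``tme`` and the ΔIOI annotation fields.
    """
    def ols(x, y):
        slope, intercept = np.polyfit(x, y, 1)
        return float(intercept), float(-slope), True

    df = tap_trials.assign(abs_tme=tap_trials["tme"].abs())
    return _direction_fit(df, "abs_delta", "abs_tme", ols,
                          participant_id, "paced_tapping")


def bias_summary(trials: pd.DataFrame) -> dict[str, float]:
    """Mean response bias per rate-change direction.

    Bias is -1 when a longer comparison was judged shorter, +1 for the
    opposite error, 0 when correct; hysteresis makes the mean negative on
    faster-than-previous trials and positive on slower-than-previous ones.
    """
    out = {}
    for direction in ("faster", "slower"):
        sub = trials[trials["delta_sign"] == direction]
        out[direction] = float(sub["bias"].mean()) if len(sub) else float("nan")
    return out


def qc_participant(
    disc_trials: pd.DataFrame | None = None,
    tap_trials: pd.DataFrame | None = None,
    participant_id: str = "",
    profile: str = "exp1",
    ceiling: float = 0.95,
    chance_alpha: float = 0.05,
    chance_eps: float = 0.05,
    tap_slope_min: float = 0.5,
    tap_count_min: float = 7.0,
) -> QcReport:
    """Participant-level exclusion screening.

    Discrimination flags: ``dev_slope_nonpositive`` (a per-DEV-direction
    logistic slope of accuracy on |DEV| is <= 0 — accuracy should rise with
    deviation size; needs multiple |DEV| levels, so Exp-1 profile only),
    ``chance_both_directions`` (per-direction accuracy not above 0.5 by a
    one-sample t-test *and* mean <= 0.5 + ``chance_eps``, in both
    directions), and — for the Exp-2 profile — ``ceiling`` (overall
    accuracy > 0.95). Tapping flags: ``tap_slope_low`` (OLS slope of
    per-trial median ITI on stimulus IOI < 0.5, i.e. tapping does not track
    the stimulus) and ``tap_count_low`` (mean cleaned ITIs per trial < 7).
    Exclusions are per task.
    """
    report = QcReport(participant_id)
    if disc_trials is not None and len(disc_trials):
        df = disc_trials
        if "is_boundary_repeat" in df.columns:
            df = df[~df["is_boundary_repeat"].astype(bool)]
        if profile == "exp1":
            for side in (df["dev"] < 0, df["dev"] > 0):
                sub = df[side]
                if sub["dev"].abs().nunique() >= 2:
                    _, slope, _ = fit_logistic(sub["dev"].abs().to_numpy(),
                                               sub["accuracy"].to_numpy())
                    if slope <= 0:
                        report.flags.add("dev_slope_nonpositive")
        chance = []
        for side in (df["dev"] < 0, df["dev"] > 0):
            acc = df.loc[side, "accuracy"].to_numpy(float)
            if len(acc) < 2:
                continue
            if np.std(acc) == 0:
                significant = acc.mean() > 0.5
            else:
                _, pval = stats.ttest_1samp(acc, 0.5, alternative="greater")
                significant = pval < chance_alpha
            chance.append((not significant)
                          and acc.mean() <= 0.5 + chance_eps)
        if len(chance) == 2 and all(chance):
            report.flags.add("chance_both_directions")
        if profile == "exp2" and df["accuracy"].mean() > ceiling:
            report.flags.add("ceiling")
    if tap_trials is not None and len(tap_trials):
        med = tap_trials["median_iti"].to_numpy(float)
        ioi = tap_trials["ioi_ms"].to_numpy(float)
        ok = np.isfinite(med)
        if ok.sum() >= 2 and np.std(ioi[ok]) > 0:
            slope = np.polyfit(ioi[ok], med[ok], 1)[0]
            if slope < tap_slope_min:
                report.flags.add("tap_slope_low")
        if float(np.nanmean(tap_trials["n_itis"])) < tap_count_min:
            report.flags.add("tap_count_low")
    if report.flags & {"dev_slope_nonpositive", "chance_both_directions",
                       "ceiling"}:
        report.excluded_tasks.add("discrimination")
    if report.flags & {"tap_slope_low", "tap_count_low"}:
        report.excluded_tasks.add("paced_tapping")
    return report


def fit_threshold(dev_levels, acc_means) -> float | None:
    """75 %-correct threshold from a 2AFC psychometric fit.

    Fits ``acc = 0.5 + 0.5 / (1 + exp(-(|DEV| - mu)/s))`` (floor 0.5,
    ceiling 1) to per-level mean accuracies by least squares; the deviation
    yielding 75 % predicted accuracy is ``mu``. Returns None when the fit
    cannot place the threshold inside the observed deviation range.
    """
    from scipy.optimize import curve_fit

    x = np.asarray(dev_levels, float)
    y = np.asarray(acc_means, float)
    if len(x) < 3:
        raise ValueError("need at least 3 deviation levels")

    def f(x, mu, s):
        return 0.5 + 0.5 / (1.0 + np.exp(-(x - mu) / s))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                f, x, y, p0=[np.median(x), np.ptp(x) / 4 or 0.05],
                bounds=([-np.max(x), 1e-6], [2 * np.max(x), 10 * np.ptp(x) + 1]),
                maxfev=5000,
            )
    except RuntimeError:
        return None
    mu = float(popt[0])
    if not (0 < mu <= np.max(x)):
        return None
    return mu


def pooled_threshold(thresholds) -> float:
    """Mean threshold after removing values beyond 3x the MAD of the pool."""
    t = np.asarray([v for v in thresholds if v is not None], float)
    if len(t) == 0:
        raise ValueError("no thresholds to pool")
    med = np.median(t)
    mad = np.median(np.abs(t - med))
    keep = t if mad == 0 else t[np.abs(t - med) <= 3.0 * mad]
    return float(np.mean(keep))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def brown_forsythe(a, b) -> tuple[float, float]:
    """Brown-Forsythe test of equal variability between two groups.

    One-way ANOVA on absolute deviations from each group's median;
    returns ``(F, p)`` with (1, n_a + n_b - 2) degrees of freedom.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    n_a, n_b = len(za), len(zb)
    grand = np.concatenate([za, zb]).mean()
    ss_between = n_a * (za.mean() - grand) ** 2 + n_b * (zb.mean() - grand) ** 2
    ss_within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    df1, df2 = 1, n_a + n_b - 2
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return float(F), p


def tukey_filter(values, mode: str = "fences") -> np.ndarray:
    """Outlier exclusion before group-level tests.

    ``mode="fences"`` (default) keeps values within
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR]; ``mode="literal"`` keeps only values
    inside [Q1, Q3] (discarding roughly half the data — provided because
    some analysis descriptions are ambiguous between the two readings).
    """
    x = np.asarray(values, float)
    if len(x) < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    if mode == "literal":
        return x[(x >= q1) & (x <= q3)]
    if mode != "fences":
        raise ValueError(f"unknown mode {mode!r}")
    iqr = q3 - q1
    return x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]


def _filtered_pearson(age, values, alternative) -> tuple[float, float, int]:
    """Pearson r after Tukey-fence filtering of the value distribution."""
    age = np.asarray(age, float)
    v = np.asarray(values, float)
    ok = np.isfinite(age) & np.isfinite(v)
    age, v = age[ok], v[ok]
    if len(v) >= 4:
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
        age, v = age[keep], v[keep]
    if len(v) < 5:
        raise ValueError("fewer than 5 participants after outlier filtering")
    r, p = stats.pearsonr(age, v, alternative=alternative)
    return float(r), float(p), len(v)


def age_analysis(
    table: pd.DataFrame,
    flexibility_cols=("beta_disc_faster", "beta_disc_slower",
                      "beta_tap_faster", "beta_tap_slower"),
    performance_cols=("mean_accuracy", "mean_abs_tme"),
    preferred_cols=(),
) -> pd.DataFrame:
    """Age correlations with per-family FDR control.

    ``table`` holds one row per participant with an ``age`` column.
    Flexibility estimates are tested with one-tailed (negative) Pearson
    correlations — the decline hypothesis — and BH-FDR-adjusted within that
    family; overall-performance measures are two-tailed with their own FDR
    family; preferred-rate columns are two-tailed and uncorrected. Each
    measure's distribution is Tukey-fence filtered (with its age pairing)
    first. Returns a tidy report with columns
    ``measure, family, r, p, p_adj, n``.
    """
    rows = []
    for family, cols, alternative in (
        ("flexibility", flexibility_cols, "less"),
        ("performance", performance_cols, "two-sided"),
        ("preferred_rate", preferred_cols, "two-sided"),
    ):
        for col in cols:
            if col not in table.columns:
                continue
            r, p, n = _filtered_pearson(table["age"], table[col], alternative)
            rows.append({"measure": col, "family": family, "r": r, "p": p, "n": n})
    report = pd.DataFrame(rows)
    report["p_adj"] = np.nan
    for family in ("flexibility", "performance"):
        idx = report.index[report["family"] == family]
        if len(idx):
            report.loc[idx, "p_adj"] = bh_fdr(report.loc[idx, "p"].to_numpy())
    mask = report["family"] == "preferred_rate"
    report.loc[mask, "p_adj"] = report.loc[mask, "p"]
    return report
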