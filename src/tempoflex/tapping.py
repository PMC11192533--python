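"""Tap-series cleaning and tapping outcome measures.

Implements the drift-aware inter-tap-interval (ITI) outlier removal used for
both paced and unpaced tapping, the paced-tapping stimulus-relative
prefilter, and the outcome measures: tapping rate (median ITI), coefficient
of variation, and tempo-matching error (TME).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CleanResult", "clean_itis", "paced_prefilter", "tme", "rate_and_cv"]


@dataclass
class CleanResult:
    """Outcome of cleaning one trial's ITI series.

    ``kept_mask`` indexes the *input* series (True = retained); ``flags``
    may contain ``"too_few"`` (fewer than 3 ITIs, cleaning skipped),
    ``"all_marked"`` (MAD stage marked everything; regression fell back to
    the full series) or ``"empty"`` (no ITI survived the prefilter).
    """

    kept: np.ndarray
    kept_mask: np.ndarray
    flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return "empty" not in self.flags and len(self.kept) > 0


def clean_itis(itis, apply_fences_to_marked: bool = True) -> CleanResult:
    """Three-stage drift-aware ITI cleaning.

    1. Mark ITIs whose deviation from the trial median exceeds 3x the raw
       median absolute deviation (MAD, unscaled) of all ITIs.
    2. Fit an ordinary least-squares regression of the unmarked ITIs on tap
       index (tracks within-trial drift). If everything was marked, fall
       back to regressing on the full series.
    3. Remove any ITI below half or above 1.5x the ITI the regression
       predicts at its index (inclusive fences). By default the fences are
       evaluated for every ITI — marked or not — so an ITI marked in stage 1
       but inside the fences is retained; set ``apply_fences_to_marked=False``
       to drop stage-1-marked ITIs outright.

    Series with fewer than 3 ITIs are returned unmodified with a
    ``"too_few"`` flag.
    """
    x = np.asarray(itis, dtype=float)
    if len(x) < 3:
        return CleanResult(x.copy(), np.ones(len(x), bool), ("too_few",))
    flags: list[str] = []
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    marked = np.abs(x - med) > 3.0 * mad
    idx = np.arange(len(x), dtype=float)
    fit_on = ~marked
    if fit_on.sum() < 2:
        flags.append("all_marked")
        fit_on = np.ones(len(x), bool)
    slope, intercept = np.polyfit(idx[fit_on], x[fit_on], 1)
    predicted = intercept + slope * idx
    eps = 1e-9 * np.abs(predicted)  # keep exact-boundary values inclusive
    within = (x >= 0.5 * predicted - eps) & (x <= 1.5 * predicted + eps)
    keep = within if apply_fences_to_marked else (within & ~marked)
    return CleanResult(x[keep], keep, tuple(flags))


def paced_prefilter(itis, ioi_ms: float, **clean_kwargs) -> CleanResult:
    """Stimulus-relative prefilter then drift-aware cleaning (paced tapping).

    ITIs outside [0.5, 1.8] x the stimulus IOI (inclusive) are excluded
    before :func:`clean_itis` runs on the survivors. The returned
    ``kept_mask`` indexes the original input. An empty survivor set yields
    an invalid result flagged ``"empty"``.
    """
    if ioi_ms <= 0:
        raise ValueError("ioi_ms must be positive")
    x = np.asarray(itis, dtype=float)
    pre = (x >= 0.5 * ioi_ms) & (x <= 1.8 * ioi_ms)
    if not pre.any():
        return CleanResult(np.array([]), np.zeros(len(x), bool), ("empty",))
    inner = clean_itis(x[pre], **clean_kwargs)
    mask = np.zeros(len(x), bool)
    mask[np.flatnonzero(pre)[inner.kept_mask]] = True
    return CleanResult(x[mask], mask, inner.flags)


def tme(kept_itis, ioi_ms: float) -> float:
    """Tempo-matching error: ``(median(ITI) - IOI) / IOI``.

    Positive TME means tapping slower than the stimulus.
    """
    x = np.asarray(kept_itis, dtype=float)
    if len(x) == 0:
        raise ValueError("TME undefined for an empty ITI series")
    if ioi_ms <= 0:
        raise ValueError("ioi_ms must be positive")
    return float((np.median(x) - ioi_ms) / ioi_ms)


def rate_and_cv(kept_itis, ddof: int = 1) -> tuple[float, float]:
    """Tapping rate (median ITI, ms) and coefficient of variation (SD/mean).

    Sample (n-1) SD by default; set ``ddof=0`` for the population convention.
    """
    x = np.asarray(kept_itis, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 ITIs for rate and CV")
    return float(np.median(x)), float(np.std(x, ddof=ddof) / np.mean(x))
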