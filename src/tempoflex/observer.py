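"""Adaptive-oscillator synthetic observer.

Generates discrimination responses, paced-tapping inter-tap-interval (ITI)
series, and unpaced (spontaneous motor tempo, SMT) tapping from a minimal
entrainment model:

* each observer has an intrinsic preferred period ``P`` (ms);
* an internal oscillator period ``p`` relaxes toward each newly presented
  stimulus IOI by a fraction ``adapt_rate`` per heard interval and is
  carried across trials, producing hysteresis (serial dependence) when
  adaptation is incomplete;
* duration judgments compare the comparison interval, corrupted by
  multiplicative Gaussian noise, against the current oscillator period;
  decision noise grows with the harmonic detuning of the stimulus rate from
  ``P`` (distance to the nearest 1:2 / 1:1 / 2:1 relation), which makes
  accuracy peak at the preferred period and its octave harmonics;
* motor tasks run at a slowed intrinsic period ``motor_factor * P``, with
  continuation tapping drifting back toward it.

The model is the generator used for parameter-recovery testing of the
estimation pipeline; it is not fitted to data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SessionPlan, continuation_allowance, exp2_matched_design

__all__ = [
    "ObserverParams",
    "CohortSpec",
    "period_update",
    "harmonic_detuning",
    "simulate_discrimination_session",
    "simulate_paced_tapping_session",
    "simulate_smt",
    "simulate_cohort",
]

#: Harmonic ratios the oscillator can lock to (octave below, unison, octave above).
HARMONICS = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic participant.

    Parameters
    ----------
    preferred_period_ms:
        Intrinsic oscillator period ``P`` (ms).
    adapt_rate:
        Entrainment strength in [0, 1]: the oscillator's period residual
        after one standard sequence (four heard intervals) is
        ``(1 - adapt_rate)**3``, realized as per-interval relaxation steps
        of rate ``1 - (1 - adapt_rate)**(3/4)`` so that short IOIs adapt
        by the same per-interval amount. The {0.2, 0.5, 0.9} span maps to
        carried-over period fractions of roughly 0.51 / 0.13 / 0.001 —
        strong, moderate and negligible serial dependence. This is the
        generative counterpart of "flexibility": 1 means full adaptation
        within a single trial (no hysteresis).
    oscillator_weight:
        Weight of the entrained oscillator period in the decision
        reference; the comparison is judged against
        ``w * p + (1 - w) * IOI`` (cue combination of the entrained period
        with an unbiased memory trace of the standard). 1 = pure
        oscillator, 0 = no serial dependence.
    base_noise:
        SD of the multiplicative duration noise at zero detuning.
    detuning_gain:
        Growth of decision noise per octave of harmonic detuning from ``P``.
    lapse:
        Probability that a response is replaced by a fair coin flip.
    motor_factor:
        Ratio of the motor preferred period to ``P`` (>= 1; tapping is slower
        than perception for most people).
    motor_cv:
        Coefficient of variation of produced inter-tap intervals.
    drift_rate:
        Fractional pull of the period toward ``motor_factor * P`` per
        continuation interval.
    outlier_rate:
        Probability that a produced interval is replaced by a contaminant
        (missed tap or double-trigger).
    adapt_rate_up / adapt_rate_down:
        Optional asymmetric adaptation rates for slowing (target > period)
        versus speeding; default None uses the symmetric ``adapt_rate``.
    """

    preferred_period_ms: float = 600.0
    adapt_rate: float = 0.25
    base_noise: float = 0.05
    detuning_gain: float = 3.0
    oscillator_weight: float = 0.4
    lapse: float = 0.02
    motor_factor: float = 1.15
    motor_cv: float = 0.05
    drift_rate: float = 0.05
    outlier_rate: float = 0.02
    age_years: float = 25.0
    adapt_rate_up: float | None = None
    adapt_rate_down: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.adapt_rate <= 1.0):
            raise ValueError("adapt_rate must be in [0, 1]")
        if self.preferred_period_ms <= 0:
            raise ValueError("preferred period must be positive")
        for name in ("base_noise", "detuning_gain", "lapse", "motor_cv",
                     "drift_rate", "outlier_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.motor_factor < 1.0:
            raise ValueError("motor_factor must be >= 1")
        if not (0.0 <= self.oscillator_weight <= 1.0):
            raise ValueError("oscillator_weight must be in [0, 1]")

    def _rate_toward(self, target: float, p: float,
                     n_intervals: int = 4) -> float:
        """Per-interval relaxation rate realizing the per-trial adapt_rate."""
        rate = self.adapt_rate
        if target > p and self.adapt_rate_up is not None:
            rate = self.adapt_rate_up
        elif target < p and self.adapt_rate_down is not None:
            rate = self.adapt_rate_down
        return 1.0 - (1.0 - rate) ** (3.0 / n_intervals)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of an age-structured synthetic cohort.

    ``adapt_rate`` for participant *i* is
    ``clip(alpha_intercept + alpha_age_slope * (age_i - mean_age)/10 + noise,
    0.02, 1)``, i.e. the slope is expressed per decade of age.
    Preferred periods are log-normal (median ``exp(P_mu)`` ms).
    """

    n: int = 30
    age_range: tuple[float, float] = (20.0, 76.0)
    P_mu: float = float(np.log(550.0))
    P_sigma: float = 0.22
    alpha_intercept: float = 0.5
    alpha_age_slope: float = -0.08
    alpha_noise_sd: float = 0.08
    motor_factor_mu: float = float(np.log(1.15))
    motor_factor_sigma: float = 0.06

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("degenerate age range")


def period_update(p: float, target: float, rate: float, n_steps: int = 1) -> float:
    """Oscillator period after ``n_steps`` relaxation steps toward ``target``.

    One step is ``p <- p + rate * (target - p)``; the closed form is
    ``target + (1 - rate)**n_steps * (p - target)``.
    """
    if p <= 0 or target <= 0:
        raise ValueError("periods must be positive")
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    return target + (1.0 - rate) ** n_steps * (p - target)


def harmonic_detuning(ioi_ms: float, preferred_ms: float) -> float:
    """Octave distance of a stimulus rate from the nearest harmonic of ``P``.

    ``min_h |log2(ioi / (h * P))|`` over h in {1/2, 1, 2}; zero at the
    preferred period and at its 2:1 and 1:2 harmonics.
    """
    if ioi_ms <= 0 or preferred_ms <= 0:
        raise ValueError("durations must be positive")
    return min(
        abs(np.log2(ioi_ms / (h * preferred_ms))) for h in HARMONICS
    )


def _adapt_over_standard(params: ObserverParams, p: float, ioi: float,
                         n_intervals: int = 4) -> float:
    """Apply per-interval adaptation over the standard sequence."""
    for _ in range(n_intervals):
        p = period_update(p, ioi, params._rate_toward(ioi, p), 1)
    return p


def simulate_discrimination_session(
    params: ObserverParams,
    plan: SessionPlan,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate responses to a discrimination session plan.

    Per trial the oscillator period adapts toward the stimulus IOI over the
    four standard intervals (closing ``adapt_rate`` of the gap in total);
    the observer responds "longer" iff the noisy comparison duration
    exceeds the decision reference — a cue combination of the entrained
    period with an unbiased memory trace of the standard:
    ``IOI * (1 + DEV) * (1 + eta) > w * p + (1 - w) * IOI`` with
    ``eta ~ N(0, base_noise * (1 + detuning_gain * detuning))``.
    With incomplete adaptation the carried period biases judgments toward
    the previous trial's rate (negative bias on faster-than-previous trials,
    positive on slower-than-previous), the serial-dependence signature the
    estimators quantify. Boundary-repeat trials update the oscillator state
    but stay flagged for downstream exclusion.

    Returns a trial table with columns ``trial_index, block, ioi_ms, dev,
    is_boundary_repeat, response, accuracy, bias``.
    """
    P = params.preferred_period_ms
    p = P
    rows = []
    for t in plan.trials:
        if t.dev is None:
            raise ValueError("plan contains tapping trials; expected discrimination")
        p = _adapt_over_standard(params, p, t.ioi_ms)
        sigma = params.base_noise * (
            1.0 + params.detuning_gain * harmonic_detuning(t.ioi_ms, P)
        )
        eta = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        reference = (params.oscillator_weight * p
                     + (1.0 - params.oscillator_weight) * t.ioi_ms)
        longer = t.ioi_ms * (1.0 + t.dev) * (1.0 + eta) > reference
        if params.lapse > 0 and rng.random() < params.lapse:
            longer = rng.random() < 0.5
        correct = longer == (t.dev > 0)
        if correct:
            bias = 0
        else:
            bias = -1 if t.dev > 0 else 1
        rows.append(
            (t.trial_index, t.block, t.ioi_ms, t.dev, t.is_boundary_repeat,
             "longer" if longer else "shorter", int(correct), bias)
        )
    return pd.DataFrame(
        rows,
        columns=["trial_index", "block", "ioi_ms", "dev",
                 "is_boundary_repeat", "response", "accuracy", "bias"],
    )


def simulate_paced_tapping_session(
    params: ObserverParams,
    plan: SessionPlan,
    rng: np.random.Generator,
    n_sync_intervals: int = 4,
) -> pd.DataFrame:
    """Simulate a synchronization–continuation paced-tapping session.

    During synchronization the period adapts toward the stimulus IOI per
    interval and each produced ITI is ``p * (1 + eps)`` with
    ``eps ~ N(0, motor_cv)``; during continuation the period drifts toward
    the motor preferred period ``motor_factor * P`` at ``drift_rate`` per
    interval. The number of continuation intervals honours the plan's
    continuation allowance. With probability ``outlier_rate`` an ITI is
    replaced by a uniform draw from [0.2, 3] x IOI (contaminant taps).
    The period carries across trials.

    Returns a trial table with columns ``trial_index, ioi_ms, itis``
    (``itis`` holds a numpy array per row).
    """
    P = params.preferred_period_ms
    motor_target = params.motor_factor * P
    p = motor_target
    rows = []
    for t in plan.trials:
        allowance = continuation_allowance(t.ioi_ms)
        n_cont = max(1, int(allowance // t.ioi_ms))
        itis = []
        for _ in range(n_sync_intervals):
            p = period_update(p, t.ioi_ms, params._rate_toward(t.ioi_ms, p), 1)
            itis.append(p * (1.0 + rng.normal(0.0, params.motor_cv)))
        for _ in range(n_cont):
            p = period_update(p, motor_target, params.drift_rate, 1)
            itis.append(p * (1.0 + rng.normal(0.0, params.motor_cv)))
        itis = np.array(itis)
        if params.outlier_rate > 0:
            hit = rng.random(len(itis)) < params.outlier_rate
            itis[hit] = rng.uniform(0.2, 3.0, hit.sum()) * t.ioi_ms
        rows.append((t.trial_index, t.ioi_ms, itis))
    return pd.DataFrame(rows, columns=["trial_index", "ioi_ms", "itis"])


def simulate_smt(
    params: ObserverParams,
    rng: np.random.Generator,
    n_taps: int = 40,
    return_mask: bool = False,
    drift_rho: float = 0.95,
    drift_innovation_sd: float = 0.006,
):
    """Simulate a spontaneous-motor-tempo (unpaced) tap series.

    Intervals fluctuate around ``motor_factor * P`` with a slow AR(1) drift
    of the local tempo plus white motor noise. Contaminants are injected at
    ``outlier_rate`` and modelled as the two typical tap-extraction failure
    modes: a missed tap (interval ~ uniform [1.6, 3] x base period) or a
    double-trigger (interval ~ uniform [0.1, 0.45] x base period).

    Returns the ITI array, or ``(itis, injected_mask)`` if ``return_mask``.
    """
    if n_taps < 2:
        raise ValueError("need at least 2 taps")
    base = params.motor_factor * params.preferred_period_ms
    n = n_taps - 1  # intervals between taps
    d = 0.0
    itis = np.empty(n)
    for k in range(n):
        d = drift_rho * d + rng.normal(0.0, drift_innovation_sd)
        itis[k] = base * (1.0 + d) * (1.0 + rng.normal(0.0, params.motor_cv))
    mask = np.zeros(n, dtype=bool)
    if params.outlier_rate > 0:
        mask = rng.random(n) < params.outlier_rate
        for i in np.flatnonzero(mask):
            if rng.random() < 0.5:
                itis[i] = rng.uniform(1.6, 3.0) * base  # missed tap
            else:
                itis[i] = rng.uniform(0.1, 0.45) * base  # double-trigger
    if return_mask:
        return itis, mask
    return itis


def _draw_params(spec: CohortSpec, age: float, mean_age: float,
                 rng: np.random.Generator) -> ObserverParams:
    P = float(np.exp(rng.normal(spec.P_mu, spec.P_sigma)))
    P = float(np.clip(P, 250.0, 950.0))
    alpha = (
        spec.alpha_intercept
        + spec.alpha_age_slope * (age - mean_age) / 10.0
        + rng.normal(0.0, spec.alpha_noise_sd)
    )
    alpha = float(np.clip(alpha, 0.02, 1.0))
    m = float(np.exp(rng.normal(spec.motor_factor_mu, spec.motor_factor_sigma)))
    return ObserverParams(
        preferred_period_ms=P,
        adapt_rate=alpha,
        motor_factor=max(1.0, m),
        age_years=float(age),
    )


def simulate_cohort(
    spec: CohortSpec, rng: np.random.Generator
) -> list[dict]:
    """Simulate an age-structured cohort through the matched Exp-2 battery.

    Each participant receives their own matched discrimination/tapping
    design, simulated responses for both tasks, and an SMT series. Returns a
    list of dicts with keys ``participant_id, params, disc_plan, tap_plan,
    disc, tap, smt``.
    """
    ages = rng.uniform(*spec.age_range, size=spec.n)
    mean_age = float(ages.mean())
    cohort = []
    for i, age in enumerate(ages):
        params = _draw_params(spec, float(age), mean_age, rng)
        disc_plan, tap_plan = exp2_matched_design(rng)
        disc = simulate_discrimination_session(params, disc_plan, rng)
        tap = simulate_paced_tapping_session(params, tap_plan, rng)
        smt = simulate_smt(params, rng)
        cohort.append(
            {"participant_id": f"S{i + 1:03d}", "params": params,
             "disc_plan": disc_plan, "tap_plan": tap_plan,
             "disc": disc, "tap": tap, "smt": smt}
        )
    return cohort
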