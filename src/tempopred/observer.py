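"""Parametric synthetic observer: accuracy, response times, rhythmicity
ratings and the adaptive SNR staircase.

The observer is the study's data-generating stand-in.  Its accuracy model is
linear in probability so the planted "percentage points per 25 ms of global
STD" slope is, by construction, exactly the average marginal effect the
logistic mixed model should recover; response times are gamma with a mean
linear in global (and optionally local) STD; per-block rhythmicity ratings
decline linearly with the condition STD.  Default effect sizes: accuracy
falls 0.6 percentage points and RT rises 5 ms per 25 ms of global STD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import history_stats
from .sequences import ALLOWED_STDS, Session, build_session

__all__ = [
    "ObserverParams",
    "Response",
    "PsychometricSpec",
    "StaircaseResult",
    "trial_success_probability",
    "simulate_session_responses",
    "simulate_ratings",
    "simulate_cohort",
    "run_staircase",
]

P_FLOOR, P_CEIL = 0.05, 0.95


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the synthetic listener.

    Slopes are per ms of STD; ``acc_slope_global`` of 0.006/25 means 0.6
    percentage points of accuracy lost per 25 ms of global STD, and
    ``rt_slope_global`` of 5/25 means RT grows 5 ms per 25 ms.  The local
    terms act on the sample STD / mean of the ``local_window`` SOAs
    preceding a target and default to zero.  ``mean_tuning_amp`` adds a
    zero-mean Gaussian tuning of accuracy around a 500 ms local mean SOA.
    """

    p0: float = 0.80
    acc_slope_global: float = 0.006 / 25.0
    acc_slope_local: float = 0.0
    mean_tuning_amp: float = 0.0
    mean_tuning_width: float = 50.0
    lapse: float = 0.02
    rt0: float = 500.0
    rt_slope_global: float = 5.0 / 25.0
    rt_slope_local: float = 0.0
    rt_gamma_shape: float = 20.0
    subj_acc_sd: float = 0.03
    subj_rt_sd: float = 30.0
    subj_rt_slope_sd: float = 1.5 / 25.0
    rating_intercept: float = 9.0
    rating_slope: float = -1.0 / 25.0
    rating_noise_sd: float = 1.0
    local_window: int = 4

    def __post_init__(self) -> None:
        for name in ("p0", "lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rt0 <= 0 or self.rt_gamma_shape <= 0:
            raise ValueError("rt0 and rt_gamma_shape must be positive")


@dataclass(frozen=True)
class Response:
    correct: int
    rt_ms: float

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


def _tuning_baseline(width: float, lo: float = 400.0, hi: float = 600.0,
                     center: float = 500.0) -> float:
    """Mean of the tuning kernel over the local-mean analysis range, so the
    tuning term is zero-mean over [400, 600] ms and does not shift baseline
    accuracy."""
    a = (lo - center) / width
    b = (hi - center) / width
    # integral of exp(-x^2/2) / (b - a) over [a, b]
    return math.sqrt(math.pi / 2.0) * (math.erf(b / math.sqrt(2)) - math.erf(a / math.sqrt(2))) / (b - a)


def trial_success_probability(
    params: ObserverParams,
    subject_offset: float,
    global_std_ms: float,
    local_mean_ms: float = 500.0,
    local_std_ms: float = 0.0,
) -> float:
    """Per-target probability of a correct discrimination.

    Linear in global and local STD, with an optional zero-mean Gaussian
    tuning of accuracy around a 500 ms local mean; mixed with a lapse rate
    (chance = 0.5) and clamped to [0.05, 0.95].
    """
    kern = math.exp(-((local_mean_ms - 500.0) ** 2) / (2.0 * params.mean_tuning_width**2))
    p = (
        params.p0
        + subject_offset
        - params.acc_slope_global * global_std_ms
        - params.acc_slope_local * local_std_ms
        + params.mean_tuning_amp * (kern - _tuning_baseline(params.mean_tuning_width))
    )
    p = (1.0 - params.lapse) * p + params.lapse * 0.5
    return float(np.clip(p, P_FLOOR, P_CEIL))


@dataclass(frozen=True)
class SubjectEffects:
    acc_offset: float = 0.0
    rt_offset: float = 0.0
    rt_slope_offset: float = 0.0


def draw_subject_effects(params: ObserverParams, rng: np.random.Generator) -> SubjectEffects:
    """Per-subject deviations: accuracy intercept, RT intercept and RT slope
    (the RT model carries both a random intercept and a random slope)."""
    return SubjectEffects(
        acc_offset=float(rng.normal(0.0, params.subj_acc_sd)),
        rt_offset=float(rng.normal(0.0, params.subj_rt_sd)),
        rt_slope_offset=float(rng.normal(0.0, params.subj_rt_slope_sd)),
    )


def _draw_rt(mean_ms: np.ndarray | float, shape: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma RT draws parameterized by (shape k, mean): scale = mean / k."""
    mean_ms = np.asarray(mean_ms, dtype=float)
    if np.any(mean_ms <= 0):
        raise ValueError("RT mean must be positive")
    return rng.gamma(shape, mean_ms / shape)


def simulate_session_responses(
    session: Session,
    params: ObserverParams,
    rng: np.random.Generator,
    effects: SubjectEffects | None = None,
) -> pd.DataFrame:
    """Simulate one subject's responses to every target of a session.

    Returns one row per target: block, trial_index, condition_std_ms,
    correct, rt_ms.  Accuracy and RT expectations depend on the block's
    global STD and on the local statistics of the ``params.local_window``
    preceding SOAs.
    """
    if effects is None:
        effects = draw_subject_effects(params, rng)
    n = params.local_window
    rows = []
    for b_i, block in enumerate(session.blocks, start=1):
        gstd = block.condition.std_soa
        feats = history_stats.compute_history_features(block, block_id=b_i)
        lmean = feats[f"mean_{n}"].to_numpy()
        lstd = feats[f"std_{n}"].to_numpy()
        probs = np.array(
            [
                trial_success_probability(params, effects.acc_offset, gstd, m, s)
                for m, s in zip(lmean, lstd)
            ]
        )
        correct = (rng.random(len(probs)) < probs).astype(int)
        rt_mean = (
            params.rt0
            + effects.rt_offset
            + (params.rt_slope_global + effects.rt_slope_offset) * gstd
            + params.rt_slope_local * lstd
        )
        rts = _draw_rt(rt_mean, params.rt_gamma_shape, rng)
        for idx, c, r in zip(feats["trial_index"], correct, rts):
            rows.append((b_i, int(idx), gstd, int(c), float(r)))
    return pd.DataFrame(
        rows, columns=["block", "trial_index", "condition_std_ms", "correct", "rt_ms"]
    )


def simulate_ratings(
    session: Session,
    params: ObserverParams,
    rng: np.random.Generator,
    rating_slope: float | None = None,
) -> pd.DataFrame:
    """Per-block rhythmicity rating: linear decline with condition STD plus
    Gaussian noise, clamped to the 0-10 scale."""
    slope = params.rating_slope if rating_slope is None else rating_slope
    rows = []
    for b_i, block in enumerate(session.blocks, start=1):
        std = block.condition.std_soa
        r = params.rating_intercept + slope * std + rng.normal(0.0, params.rating_noise_sd)
        rows.append((b_i, std, float(np.clip(r, 0.0, 10.0))))
    return pd.DataFrame(rows, columns=["block", "condition_std_ms", "rating"])


def simulate_cohort(
    n_subjects: int,
    params: ObserverParams,
    rng: np.random.Generator,
    conditions=ALLOWED_STDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: sessions, target responses and block ratings.

    Returns ``(trials, ratings)``: the long-format trial table with
    ``correct``/``rt_ms`` filled on target rows, and the per-block rating
    table.
    """
    from .io import session_to_frame

    trial_frames, rating_frames = [], []
    for s_i in range(1, n_subjects + 1):
        sid = f"S{s_i:02d}"
        session = build_session(sid, rng, conditions=conditions)
        frame = session_to_frame(session)
        resp = simulate_session_responses(session, params, rng)
        frame = frame.merge(
            resp[["block", "trial_index", "correct", "rt_ms"]],
            on=["block", "trial_index"],
            how="left",
        )
        ratings = simulate_ratings(session, params, rng)
        ratings.insert(0, "subject", sid)
        trial_frames.append(frame)
        rating_frames.append(ratings)
    return (
        pd.concat(trial_frames, ignore_index=True),
        pd.concat(rating_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Adaptive staircase


@dataclass(frozen=True)
class PsychometricSpec:
    """Cumulative-Gaussian psychometric function for the two-alternative
    standard/deviant discrimination: floor fixed at chance (0.5)."""

    threshold_db: float = -15.0
    slope_db: float = 3.0
    floor: float = 0.5
    lapse: float = 0.02

    def p_correct(self, snr_db: float) -> float:
        from scipy.stats import norm

        z = (snr_db - self.threshold_db) / self.slope_db
        return self.floor + (1.0 - self.floor - self.lapse) * float(norm.cdf(z))


@dataclass
class StaircaseResult:
    snr_db: float
    n_reversals: int
    n_target_trials: int
    track: list[float]
    converged: bool


def run_staircase(
    psychometric: PsychometricSpec,
    rng: np.random.Generator,
    n_tones: int = 75,
    start_snr_db: float = 0.0,
    step_db: float = 4.0,
    n_halvings: int = 2,
    min_step_db: float = 2.0,
) -> StaircaseResult:
    """Transformed 3-down-1-up staircase on SNR over a 75-tone periodic stream.

    Target trials occur every 2-3 tones (uniform), giving roughly 25-37
    discrimination trials.  To reach the tracking region quickly the
    staircase runs 1-down-1-up until the first error, then switches to
    3-down-1-up (convergence point 79.4% correct); the transition error
    resets direction tracking so the acceleration overshoot does not count
    as a reversal.  The step halves after each of the first ``n_halvings``
    reversals, floored at ``min_step_db`` (with ~30 trials a sub-2 dB step
    recovers too slowly from the initial descent and biases the track low).
    Returns the mean SNR of the final 4 reversals; with fewer than 4
    reversals a convergence-failure warning is issued and the last SNR is
    returned.
    """
    # target tone positions: gaps of 2-3 tones
    positions = []
    pos = 0
    while True:
        pos += int(rng.integers(2, 4))
        if pos > n_tones:
            break
        positions.append(pos)

    snr = float(start_snr_db)
    step = float(step_db)
    track = [snr]
    reversals: list[float] = []
    consecutive = 0
    last_dir = 0  # -1 down, +1 up
    accelerated = True
    for _ in positions:
        correct = rng.random() < psychometric.p_correct(snr)
        move = 0
        if correct:
            consecutive += 1
            if accelerated or consecutive >= 3:
                move = -1
                consecutive = 0
        else:
            if accelerated:
                accelerated = False
                last_dir = 0  # transition out of acceleration: no reversal
            move = +1
            consecutive = 0
        if move != 0:
            if last_dir != 0 and move != last_dir:
                reversals.append(snr)
                if len(reversals) <= n_halvings:
                    step = max(step / 2.0, min_step_db)
            last_dir = move
            snr += move * step
            track.append(snr)
    if len(reversals) >= 4:
        out = float(np.mean(reversals[-4:]))
        converged = True
    else:
        warnings.warn("staircase ended with fewer than 4 reversals")
        out = snr
        converged = False
    return StaircaseResult(out, len(reversals), len(positions), track, converged)
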