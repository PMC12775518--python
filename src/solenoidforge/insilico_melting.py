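"""In silico melting: sequence-masking robustness curves and Succ50.

A design's robustness to sequence perturbation is probed by masking an
increasing fraction of its sequence, repredicting each masked variant,
and recording the fraction of replicates whose global fold confidence
(pTM) stays above a threshold.  The resulting success-rate-vs-masking
curve is fitted with a decreasing four-parameter logistic; its
inflection point — the masking fraction at which half the dynamic range
is lost — is the in silico melting point, Succ50.  Higher Succ50 means
the predictor still recognises the fold under heavier corruption of the
sequence, an empirical proxy for a more robust design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidInputError, InvalidParameterError

MASK_TOKEN = "X"

#: Fit validity outcomes.
REASON_NONE = "none"
REASON_FIT_FAILED = "fit_failed"
REASON_OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class MeltingCurve:
    """Success rates over a masking schedule.

    Each rate is a fraction ``k / n_replicates`` of replicates whose
    pTM exceeded ``ptm_threshold`` at that masking level.
    """

    mask_levels: np.ndarray
    success_rates: np.ndarray
    n_replicates: int = 64
    ptm_threshold: float = 0.75

    def __post_init__(self) -> None:
        levels = np.asarray(self.mask_levels, dtype=float)
        rates = np.asarray(self.success_rates, dtype=float)
        if levels.ndim != 1 or rates.shape != levels.shape:
            raise InvalidInputError("levels and rates must be matching 1-D arrays")
        if np.any(np.diff(levels) <= 0):
            raise InvalidInputError("mask levels must be strictly increasing")
        if np.any((levels < 0) | (levels > 1)) or np.any((rates < 0) | (rates > 1)):
            raise InvalidInputError("levels and rates must be fractions in [0,1]")
        object.__setattr__(self, "mask_levels", levels)
        object.__setattr__(self, "success_rates", rates)


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted logistic parameters; ``succ50`` is the inflection point."""

    succ50: float
    slope: float
    upper_asymptote: float
    lower_asymptote: float
    valid: bool
    reason_invalid: str = REASON_NONE


def masking_schedule(
    start: float = 0.30, stop: float = 0.99, step: float = 0.05
) -> np.ndarray:
    """Masking levels: ``start, start+step, ...`` up to and including ``stop``.

    The terminal level is appended explicitly when the arithmetic grid
    does not land on it (0.05 steps from 0.30 reach 0.95, so the default
    schedule is 0.30 … 0.95 plus 0.99 — fifteen levels).
    """
    if not (0.0 <= start < stop <= 1.0):
        raise InvalidParameterError(f"need 0 <= start < stop <= 1, got ({start}, {stop})")
    if step <= 0:
        raise InvalidParameterError(f"step must be positive, got {step}")
    n_steps = int(np.floor((stop - start) / step + 1e-9))
    levels = start + step * np.arange(n_steps + 1)
    if stop - levels[-1] > 1e-9:
        levels = np.append(levels, stop)
    return levels


def _round_half_up(x: float) -> int:
    # Deterministic across platforms, unlike banker's rounding.
    return int(np.floor(x + 0.5))


def apply_mask(
    sequence: str, level: float, rng: np.random.Generator, mask_token: str = MASK_TOKEN
) -> str:
    """Mask ``round(level * n)`` distinct positions, uniformly at random."""
    if not 0.0 <= level <= 1.0:
        raise InvalidParameterError(f"mask level must be in [0,1], got {level}")
    n = len(sequence)
    k = _round_half_up(level * n)
    if k == 0:
        return sequence
    positions = rng.choice(n, size=k, replace=False)
    chars = list(sequence)
    for p in positions:
        chars[p] = mask_token
    return "".join(chars)


def melt(
    sequence: str,
    ptm_predictor: Callable[[str], float],
    schedule: Optional[np.ndarray] = None,
    n_replicates: int = 64,
    ptm_threshold: float = 0.75,
    rng: Optional[np.random.Generator] = None,
) -> MeltingCurve:
    """Run the masking experiment and return the melting curve.

    ``ptm_predictor`` maps a masked sequence to a pTM scalar.  At each
    masking level, ``n_replicates`` independent masking patterns are
    applied and the success rate is the fraction of replicates with
    pTM strictly greater than ``ptm_threshold``.
    """
    if rng is None:
        raise InvalidParameterError("melt requires a seeded Generator")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    levels = masking_schedule() if schedule is None else np.asarray(schedule, dtype=float)
    rates = np.empty_like(levels)
    for i, level in enumerate(levels):
        successes = 0
        for _ in range(n_replicates):
            masked = apply_mask(sequence, float(level), rng)
            try:
                ptm = ptm_predictor(masked)
            except Exception as err:
                raise type(err)(f"pTM prediction failed at mask level {level:.2f}: {err}") from err
            if ptm > ptm_threshold:
                successes += 1
        rates[i] = successes / n_replicates
    return MeltingCurve(levels, rates, n_replicates=n_replicates, ptm_threshold=ptm_threshold)


def _logistic(m, lower, upper, slope, m50):
    return lower + (upper - lower) / (1.0 + np.exp(slope * (m - m50)))


def fit_succ50(curve: MeltingCurve) -> SigmoidFit:
    """Fit the decreasing logistic and extract the inflection (Succ50).

    Model: ``s(m) = b + (t - b) / (1 + exp(k (m - m50)))`` with
    ``0 <= b <= t <= 1`` and ``k > 0``.  Initial guesses: asymptotes from
    the observed extreme rates, inflection at the level whose rate is
    closest to half-range, slope 20.  A fit is invalid when the
    optimiser fails or the curve carries no dynamic range
    (``fit_failed``), or when the recovered inflection falls outside
    [0, 1] (``out_of_range``) — such melting points are unphysical and
    the design is excluded from downstream analysis.
    """
    levels = curve.mask_levels
    rates = curve.success_rates
    if levels.size < 4:
        raise InvalidInputError(f"need >= 4 levels to fit a 4-parameter sigmoid, got {levels.size}")

    def invalid(reason: str) -> SigmoidFit:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, valid=False, reason_invalid=reason)

    if np.ptp(rates) < 1e-12:
        return invalid(REASON_FIT_FAILED)  # inflection unidentifiable

    t0, b0 = float(rates.max()), float(rates.min())
    half = b0 + 0.5 * (t0 - b0)
    m50_0 = float(levels[np.argmin(np.abs(rates - half))])
    try:
        popt, pcov = curve_fit(
            _logistic,
            levels,
            rates,
            p0=(b0, t0, 20.0, m50_0),
            bounds=([0.0, 0.0, 1e-6, -1.0], [1.0, 1.0, 500.0, 2.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return invalid(REASON_FIT_FAILED)
    lower, upper, slope, m50 = (float(v) for v in popt)
    if upper < lower or not np.all(np.isfinite(popt)):
        return invalid(REASON_FIT_FAILED)
    if not 0.0 <= m50 <= 1.0:
        return SigmoidFit(m50, slope, upper, lower, valid=False, reason_invalid=REASON_OUT_OF_RANGE)
    return SigmoidFit(m50, slope, upper, lower, valid=True)


class UnmaskedFractionPtm:
    """Surrogate pTM oracle: pTM equals the unmasked fraction of the input.

    With the default 0.75 success threshold this produces a clean step:
    success below 25% masking, failure above — handy for exercising the
    threshold algebra without any model in the loop.
    """

    def __init__(self, mask_token: str = MASK_TOKEN):
        self.mask_token = mask_token

    def __call__(self, sequence: str) -> float:
        if not sequence:
            raise InvalidInputError("empty sequence")
        return 1.0 - sequence.count(self.mask_token) / len(sequence)


class LogisticPtm:
    """Surrogate pTM oracle with a tunable melting point.

    pTM is drawn so that the success probability at masked fraction
    ``m`` follows a logistic with inflection ``m50``: each call returns
    a value just above or below the threshold according to a Bernoulli
    draw.  Gives realistic binomial noise on melting curves with a known
    ground-truth Succ50.
    """

    def __init__(
        self,
        m50: float,
        slope: float = 30.0,
        threshold: float = 0.75,
        rng: Optional[np.random.Generator] = None,
        mask_token: str = MASK_TOKEN,
    ):
        if rng is None:
            raise InvalidParameterError("LogisticPtm requires a seeded Generator")
        self.m50 = m50
        self.slope = slope
        self.threshold = threshold
        self.rng = rng
        self.mask_token = mask_token

    def __call__(self, sequence: str) -> float:
        m = sequence.count(self.mask_token) / len(sequence)
        p_success = 1.0 / (1.0 + np.exp(self.slope * (m - self.m50)))
        if self.rng.random() < p_success:
            return min(1.0, self.threshold + 0.1)
        return max(0.0, self.threshold - 0.1)
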