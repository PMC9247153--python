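"""Exact PWM score p-values by dynamic programming.

Under an i.i.d. background, the score of a random length-m window is
``S = sum_j W_j`` where position j contributes weight ``w[b, j]`` with
probability ``bg[b]``.  The full distribution of S is computed exactly by
discretising the weights to a grid of step ``epsilon`` (in bits) and
convolving the four-point per-position laws across positions — cost
O(m * 4 * span/epsilon), sub-millisecond at typical motif sizes.

Discretisation policy: weights are rounded *up* to the grid and the query
score rounded *down*, so the discretised score of every window dominates
its true score and the returned p-value P(S_eps >= floor_eps(s)) never
underestimates the true P(S >= s).  The over-estimate is bounded by the
probability mass of windows whose true score lies within m*epsilon below
the query — negligible at the default epsilon of 1e-4 bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ValidationError
from .motif_io import Background, PWM

__all__ = [
    "ScoreDistribution",
    "ScoreThreshold",
    "score_distribution",
    "score_to_pvalue",
    "pvalue_to_score",
]

# tolerance absorbing float noise when a weight or query already sits on the grid
_GRID_SLOP = 1e-9


@dataclass
class ScoreDistribution:
    """Discretised distribution of the background window score for one PWM.

    ``support`` holds the attainable grid scores (in bits, ascending) and
    ``pmf`` their probabilities; ``survival(s)`` gives
    P(S_eps >= floor_eps(s)).
    """

    pwm_id: str
    epsilon: float
    kmin: int  # grid index of the smallest attainable discretised score
    dense_pmf: np.ndarray  # pmf over consecutive grid indices kmin..kmin+len-1

    def __post_init__(self) -> None:
        total = float(self.dense_pmf.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise AssertionError(f"pmf mass {total} != 1")
        # survival from the top: _sf[i] = P(S >= kmin + i)
        self._sf = np.cumsum(self.dense_pmf[::-1])[::-1]

    @property
    def support(self) -> np.ndarray:
        nz = np.nonzero(self.dense_pmf)[0]
        return (self.kmin + nz) * self.epsilon

    @property
    def pmf(self) -> np.ndarray:
        return self.dense_pmf[np.nonzero(self.dense_pmf)[0]]

    def survival_at_index(self, k: int) -> float:
        i = k - self.kmin
        if i <= 0:
            return 1.0
        if i >= len(self.dense_pmf):
            return 0.0
        return float(self._sf[i])

    def survival(self, score: float) -> float:
        """P(S_eps >= score), with score rounded down to the grid."""
        k = math.floor(score / self.epsilon + _GRID_SLOP)
        return self.survival_at_index(k)

    def to_frame(self):
        """Two-column (score, pmf) table for inspection."""
        import pandas as pd

        return pd.DataFrame({"score": self.support, "pmf": self.pmf})


def _grid_weights(pwm: PWM, epsilon: float) -> np.ndarray:
    """Integer weights, rounded up to multiples of epsilon."""
    return np.ceil(pwm.weights / epsilon - _GRID_SLOP).astype(np.int64)


def score_distribution(
    pwm: PWM, background: Background | None = None, epsilon: float = 1e-4
) -> ScoreDistribution:
    """Exact distribution of the background window score on the epsilon-grid."""
    if epsilon <= 0:
        raise ValidationError(f"epsilon must be > 0, got {epsilon}")
    bg = (background or pwm.background).as_array()
    k = _grid_weights(pwm, epsilon)
    col_min = k.min(axis=0)
    col_max = k.max(axis=0)
    kmin = int(col_min.sum())
    span = int((col_max - col_min).sum())
    pmf = np.zeros(span + 1)
    pmf[0] = 1.0
    length = 1
    for j in range(pwm.m):
        new_len = length + int(col_max[j] - col_min[j])
        new = np.zeros(new_len)
        for b in range(4):
            off = int(k[b, j] - col_min[j])
            new[off : off + length] += bg[b] * pmf[:length]
        pmf[:new_len] = new
        length = new_len
    return ScoreDistribution(pwm_id=pwm.matrix_id, epsilon=epsilon, kmin=kmin,
                             dense_pmf=pmf[:length].copy())


def score_to_pvalue(
    pwm: PWM,
    score: float,
    background: Background | None = None,
    epsilon: float = 1e-4,
    dist: ScoreDistribution | None = None,
) -> float:
    """Conservative exact p-value P(background window score >= ``score``).

    A precomputed ``dist`` (from :func:`score_distribution`) may be passed
    to amortise the DP across many queries for the same PWM.
    """
    if dist is None:
        dist = score_distribution(pwm, background, epsilon)
    return dist.survival(score)


class ScoreThreshold(NamedTuple):
    """Score cutoff achieving a target p-value; ``attainable`` is False when
    no real window can reach it (alpha below the consensus probability)."""

    score: float
    attainable: bool


def pvalue_to_score(
    pwm: PWM,
    alpha: float,
    background: Background | None = None,
    epsilon: float = 1e-4,
    dist: ScoreDistribution | None = None,
) -> ScoreThreshold:
    """Smallest grid score s with P(S_eps >= s) <= alpha.

    Round-trip guarantee: ``score_to_pvalue(pvalue_to_score(alpha).score)
    <= alpha``.  When alpha is below the probability of the best attainable
    score, the returned score exceeds ``max_score`` and is flagged
    unattainable.
    """
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    if dist is None:
        dist = score_distribution(pwm, background, epsilon)
    sf = dist._sf
    # smallest index i with sf[i] <= alpha; sf is non-increasing
    idx = np.searchsorted(-sf, -alpha, side="left")
    if idx >= len(sf):
        # even excluding everything but the top bin leaves too much mass:
        # only a score above every attainable one satisfies alpha
        k = dist.kmin + len(sf)
        return ScoreThreshold(score=k * dist.epsilon, attainable=False)
    if idx == 0:
        # the whole support qualifies; report the true minimum score
        return ScoreThreshold(score=pwm.min_score, attainable=True)
    return ScoreThreshold(score=(dist.kmin + int(idx)) * dist.epsilon, attainable=True)
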