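"""Wallenius' noncentral hypergeometric distribution.

The law of the number of red cards obtained when ``n_draws`` cards are drawn
sequentially without replacement from a pile of ``n_red`` red and ``n_black``
black cards, where at every step each remaining red card's odds of being drawn
are multiplied by ``omega``.  For ``omega = 1`` this reduces to the central
hypergeometric distribution.

The pmf is computed by exact dynamic programming over the sequential draw
process rather than the classical integral representation: for the small pile
sizes used in the card game (at most 65 cards) the DP is exact to machine
precision and bit-reproducible, which makes it usable as an oracle for the
sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WalleniusParams:
    """Parameters of a biased draw without replacement.

    Attributes
    ----------
    n_draws : int
        Number of cards drawn (shown to the participant).
    n_red : int
        Number of red cards in the pile.
    n_black : int
        Number of black cards in the pile.
    omega : float
        Odds ratio in favour of red cards; each remaining red card is
        ``omega`` times as likely to be drawn next as each remaining black
        card.  Must be positive and finite.
    """

    n_draws: int
    n_red: int
    n_black: int
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.n_draws < 0:
            raise ValueError(f"n_draws must be >= 0, got {self.n_draws}")
        if self.n_red < 0:
            raise ValueError(f"n_red must be >= 0, got {self.n_red}")
        if self.n_black < 0:
            raise ValueError(f"n_black must be >= 0, got {self.n_black}")
        if self.n_draws > self.n_red + self.n_black:
            raise ValueError(
                f"n_draws ({self.n_draws}) exceeds pile size "
                f"({self.n_red + self.n_black})"
            )
        if not (self.omega > 0 and math.isfinite(self.omega)):
            raise ValueError(f"omega must be positive and finite, got {self.omega}")

    @property
    def k_min(self) -> int:
        """Smallest attainable red-draw count."""
        return max(0, self.n_draws - self.n_black)

    @property
    def k_max(self) -> int:
        """Largest attainable red-draw count."""
        return min(self.n_draws, self.n_red)


def wallenius_pmf(params: WalleniusParams) -> np.ndarray:
    """Exact pmf of the red-draw count, indexed ``0 .. k_max``.

    Dynamic programming over the state (reds drawn so far ``i``, draws so far
    ``t``): after ``t`` draws with ``i`` reds drawn, the probability that the
    next card is red is ``omega * R / (omega * R + B)`` with ``R = n_red - i``
    remaining reds and ``B = n_black - (t - i)`` remaining blacks.

    Returns a vector ``p`` of length ``k_max + 1`` with ``p[k] = P(K = k)``;
    entries below ``k_min`` are exactly zero.  The vector sums to 1 within
    1e-12.
    """
    n, w = params.n_draws, params.omega
    kmax = params.k_max
    # prob[i] = P(i reds drawn after t draws)
    prob = np.zeros(kmax + 1)
    prob[0] = 1.0
    for t in range(n):
        nxt = np.zeros(kmax + 1)
        imax = min(t, kmax)
        for i in range(imax + 1):
            p = prob[i]
            if p == 0.0:
                continue
            R = params.n_red - i
            B = params.n_black - (t - i)
            denom = w * R + B
            if R > 0 and i + 1 <= kmax:
                nxt[i + 1] += p * (w * R / denom)
            if B > 0:
                nxt[i] += p * (B / denom)
        prob = nxt
    return prob


def wallenius_sample(
    params: WalleniusParams, rng: np.random.Generator, size: int | None = None
):
    """Sample red-draw counts by simulating the sequential biased draw.

    This is the generative definition of the distribution (the physical story
    of the game dealing cards one by one), so the empirical distribution of
    samples converges to :func:`wallenius_pmf`.

    Parameters
    ----------
    params : WalleniusParams
    rng : numpy.random.Generator
        Seeded source of randomness; no global state is used.
    size : int, optional
        If given, return an array of ``size`` i.i.d. counts; otherwise a
        single ``int``.
    """
    if size is None:
        return _sample_one(params, rng)
    # vectorized over samples: one uniform per (sample, draw) step
    w = params.omega
    R = np.full(size, params.n_red, dtype=np.int64)
    B = np.full(size, params.n_black, dtype=np.int64)
    for _ in range(params.n_draws):
        u = rng.random(size)
        red = u * (w * R + B) < w * R
        R -= red
        B -= ~red
    return params.n_red - R


def _sample_one(params: WalleniusParams, rng: np.random.Generator) -> int:
    reds = 0
    R, B = params.n_red, params.n_black
    w = params.omega
    for _ in range(params.n_draws):
        if rng.random() * (w * R + B) < w * R:
            reds += 1
            R -= 1
        else:
            B -= 1
    return reds
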