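"""Game design: pile types, calibrated AI confidence, biased deals, batches.

A game pile is a pair (r, a): the true fraction r of red cards among the 65
cards in the pile, and the AI confidence a that the randomly picked card is
red.  The AI confidence grid is a = k/13 for k = 1..12, and each level a has
exactly two piles, r = a - var_a and r = a + var_a, so that the mean of r over
a level equals a exactly: the AI is calibrated *by design*,
P(C = red | A = a) = a.

The degree of alignment between the AI and the participants is steered by
biasing which 21 of the 65 cards are shown: the shown red count is drawn from
a Wallenius noncentral hypergeometric distribution whose odds ratio depends on
the experimental group (toward / away / unbiased; the realigned group replays
the toward group's deals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from .wallenius import WalleniusParams, wallenius_sample

GROUPS = ("toward", "away", "unbiased", "realigned")

#: timeline slots (0-based, within the 27-round sequence) of the three
#: attention checks; identical across groups
ATTENTION_POSITIONS = (5, 14, 23)


class ConfigError(ValueError):
    pass


class UndefinedBiasError(ValueError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    pile_size: int = 65
    n_shown: int = 21
    confidence_denominator: int = 13
    var_a: Fraction = Fraction(3, 65)
    n_rounds: int = 24
    n_batches: int = 20
    n_calibration_batches: int = 60
    attention_fractions: tuple = (Fraction(0), Fraction(3, 4), Fraction(1))
    bonus_per_point: float = 0.12  # GBP

    def __post_init__(self) -> None:
        va = Fraction(self.var_a)
        object.__setattr__(self, "var_a", va)
        if not (self.pile_size * va).denominator == 1 or self.pile_size * va <= 0:
            raise ConfigError(
                f"pile_size*var_a must be a positive integer, got {self.pile_size * va}"
            )
        if not self.n_shown < self.pile_size:
            raise ConfigError("n_shown must be smaller than pile_size")


@dataclass(frozen=True)
class PileType:
    """One design point: AI confidence a and true red fraction r (exact rationals)."""

    a: Fraction
    r: Fraction

    def __post_init__(self) -> None:
        if not (0 < self.r < 1):
            raise ConfigError(f"r must lie strictly in (0,1), got {self.r}")
        if self.r == Fraction(1, 2):
            raise ConfigError("r = 1/2 is excluded by design (no undefined optimum)")

    def red_count(self, cfg: DesignConfig) -> int:
        n = self.r * cfg.pile_size
        if n.denominator != 1:
            raise ConfigError(f"r*pile_size must be integral, got {n}")
        return int(n)


@dataclass(frozen=True)
class GameInstance:
    pile: PileType
    z_count: int  # red cards among the n_shown shown
    is_attention_check: bool = False
    picked_is_red: Optional[bool] = None  # drawn per participant at play time

    def z(self, cfg: DesignConfig) -> Fraction:
        return Fraction(self.z_count, cfg.n_shown)


@dataclass
class Batch:
    group: str
    batch_id: int
    games: list = field(default_factory=list)  # list[GameInstance], scored only


def enumerate_pile_types(cfg: DesignConfig = DesignConfig()) -> list[PileType]:
    """All pile types, ordered by (a, r): two per confidence level, r = a ± var_a."""
    piles = []
    for k in range(1, cfg.confidence_denominator):
        a = Fraction(k, cfg.confidence_denominator)
        for r in (a - cfg.var_a, a + cfg.var_a):
            piles.append(PileType(a=a, r=r))  # PileType validates r
    return piles


def odds_ratio(group: str, r: Fraction, a: Fraction) -> float:
    """Group-specific Wallenius odds ratio for the shown-card deal.

    toward: pull the shown fraction toward a (fewer reds shown when r > a);
    away: push it past r away from a; unbiased: 1.  The realigned group
    replays the toward group's deals, hence the toward rule.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if group == "unbiased":
        return 1.0
    if r == a:
        raise UndefinedBiasError("bias undefined at r == a")
    if group in ("toward", "realigned"):
        return 0.25 if r > a else 4.0
    return 4.0 if r > a else 0.25  # away


def sample_shown_fraction(
    pile: PileType, group: str, cfg: DesignConfig, rng: np.random.Generator
) -> int:
    """Draw the shown red count z·n_shown for one pile under the group's bias."""
    n_red = pile.red_count(cfg)
    params = WalleniusParams(
        n_draws=cfg.n_shown,
        n_red=n_red,
        n_black=cfg.pile_size - n_red,
        omega=odds_ratio(group, pile.r, pile.a),
    )
    return int(wallenius_sample(params, rng))


def pick_card(pile: PileType, rng: np.random.Generator) -> bool:
    """Pick one card uniformly from the full pile; True iff it is red.

    Drawing from all pile_size cards (not just the unshown remainder) is what
    makes P(C = red | A = a) = a hold exactly.
    """
    return bool(rng.random() < float(pile.r))


def display_confidence(a) -> int:
    """Re-scale a confidence in [0,1] to an integer 0..100, rounding half up."""
    a = float(a)
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"confidence must be in [0,1], got {a}")
    return int(np.floor(100.0 * a + 0.5))


def attention_checks(cfg: DesignConfig, rng: np.random.Generator) -> list[GameInstance]:
    """The three unbiased attention-check games (0%, 75%, 100% reds).

    The 75% pile uses the nearest integral red count (49 of 65 cards).  The
    same three instances, with the same shown cards, are reused in every
    group, so the caller generates them once per study.
    """
    checks = []
    for frac in cfg.attention_fractions:
        n_red = int(round(float(frac) * cfg.pile_size))
        if n_red == 0:
            z = 0
        elif n_red == cfg.pile_size:
            z = cfg.n_shown
        else:
            params = WalleniusParams(cfg.n_shown, n_red, cfg.pile_size - n_red, 1.0)
            z = int(wallenius_sample(params, rng))
        pile = object.__new__(PileType)  # bypass r∈(0,1) check for r=0,1 checks
        object.__setattr__(pile, "a", Fraction(n_red, cfg.pile_size))
        object.__setattr__(pile, "r", Fraction(n_red, cfg.pile_size))
        checks.append(GameInstance(pile=pile, z_count=z, is_attention_check=True))
    return checks


def build_batches(
    cfg: DesignConfig,
    group: str,
    n_batches: int,
    rng: np.random.Generator,
    source_batches: Optional[list] = None,
) -> list[Batch]:
    """Construct game batches: one dealt GameInstance per pile type per batch.

    For ``group="realigned"`` pass the toward group's batches as
    ``source_batches``; their shown-card deals (z values) are copied verbatim,
    pile by pile, since both groups play the same deals and differ only in the
    AI confidence displayed.
    """
    if group == "realigned":
        if source_batches is None:
            raise ValueError("realigned batches copy z from toward batches; "
                             "pass source_batches")
        return [
            Batch(group="realigned", batch_id=b.batch_id,
                  games=[GameInstance(g.pile, g.z_count) for g in b.games])
            for b in source_batches[:n_batches]
        ]
    piles = enumerate_pile_types(cfg)
    batches = []
    for b in range(n_batches):
        games = [
            GameInstance(pile=p, z_count=sample_shown_fraction(p, group, cfg, rng))
            for p in piles
        ]
        batches.append(Batch(group=group, batch_id=b, games=games))
    return batches


def design_calibration_check(piles: list[PileType]) -> dict:
    """Mean true red fraction per AI confidence level (exact rationals).

    For the standard design this equals a for every level — the calibration-
    by-design identity.  Raises if any level lacks its two piles.
    """
    by_a: dict = {}
    for p in piles:
        by_a.setdefault(p.a, []).append(p.r)
    out = {}
    for a, rs in sorted(by_a.items()):
        if len(rs) != 2:
            raise ConfigError(f"incomplete design: level a={a} has {len(rs)} pile(s)")
        out[a] = sum(rs, Fraction(0)) / len(rs)
    return out


def batches_to_json(batches: list[Batch], cfg: DesignConfig) -> list[dict]:
    """JSON-serializable form of a batch list."""
    out = []
    for b in batches:
        games = [
            {
                "a_num": g.pile.a.numerator, "a_den": g.pile.a.denominator,
                "r_num": g.pile.r.numerator, "r_den": g.pile.r.denominator,
                "z_count": g.z_count, "order_index": i,
                "is_attention": g.is_attention_check,
            }
            for i, g in enumerate(b.games)
        ]
        out.append({"group": b.group, "batch_id": b.batch_id, "games": games})
    return out


def batches_from_json(payload: list[dict]) -> list[Batch]:
    batches = []
    for rec in payload:
        games = []
        for g in sorted(rec["games"], key=lambda d: d["order_index"]):
            pile = object.__new__(PileType)
            object.__setattr__(pile, "a", Fraction(g["a_num"], g["a_den"]))
            object.__setattr__(pile, "r", Fraction(g["r_num"], g["r_den"]))
            games.append(GameInstance(pile=pile, z_count=g["z_count"],
                                      is_attention_check=g["is_attention"]))
        batches.append(Batch(group=rec["group"], batch_id=rec["batch_id"], games=games))
    return batches
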