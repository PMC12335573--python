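"""Synthetic participants: confidence formation and guessing behavior.

The generator emulates the behavioral structure the downstream analysis
assumes rather than any individual's psychology:

* initial confidence is approximately normal around the percentage of red
  cards shown (mean 100·z, SD ``sigma_initial``), clipped to [0, 100] and
  rounded to an integer;
* the initial guess is red exactly when confidence exceeds 50 (fair coin at
  exactly 50);
* the final guess is red with probability
  ``logistic(w_h·(conf-50) + w_a·(a_shown-50))``, mixed with a small lapse
  rate of uniformly random responses — monotone on average in both the
  participant's own confidence and the displayed AI confidence;
* a small fraction of simulated participants is inattentive and answers the
  attention checks with uniform confidence, which is what the attention-check
  exclusion rule is meant to catch.

A Bayes-observer benchmark is included: the posterior-optimal guess given the
shown fraction z, knowing the two candidate piles r = a ± var_a and the
group's dealing bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import design
from .alignment import discretize_confidence
from .design import ATTENTION_POSITIONS, Batch, DesignConfig, GameInstance, PileType
from .multical import RealignmentMap, apply_realignment
from .wallenius import WalleniusParams, wallenius_pmf

RESPONSE_COLUMNS = [
    "participant_id", "group", "batch_id", "round_index",
    "a_num", "a_den", "a_shown", "r_num", "r_den", "z_count",
    "initial_confidence", "initial_guess", "final_guess",
    "outcome_is_red", "is_attention_check",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Tunables of the synthetic decision maker.

    sigma_initial: SD of initial confidence around 100·z, on the 0-100 scale.
    w_h, w_a: logit weights (per confidence point) on own and AI confidence.
    lapse: probability that the final guess is a uniform coin flip.
    inattentive_rate: fraction of participants answering checks at random.
    """

    sigma_initial: float = 12.0
    w_h: float = 0.08
    w_a: float = 0.08
    lapse: float = 0.02
    inattentive_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_initial <= 0:
            raise ValueError("sigma_initial must be > 0")
        if self.w_h < 0 or self.w_a < 0:
            raise ValueError("w_h and w_a must be >= 0")
        if not (0 <= self.lapse < 1 and 0 <= self.inattentive_rate < 1):
            raise ValueError("lapse and inattentive_rate must lie in [0, 1)")


def draw_initial_confidence(
    z: float, params: BehaviorParams, rng: np.random.Generator
) -> int:
    """Integer confidence 0..100 ~ round(clip(Normal(100 z, sigma), 0, 100))."""
    if not (0.0 <= float(z) <= 1.0):
        raise ValueError(f"z must be in [0,1], got {z}")
    x = rng.normal(100.0 * float(z), params.sigma_initial)
    return int(round(float(np.clip(x, 0.0, 100.0))))


def initial_guess_from_confidence(conf: int, rng: np.random.Generator) -> str:
    if not (0 <= conf <= 100):
        raise ValueError(f"confidence must be in [0,100], got {conf}")
    if conf > 50:
        return "red"
    if conf < 50:
        return "black"
    return "red" if rng.random() < 0.5 else "black"


def final_decision_p_red(conf: float, a_shown: float, params: BehaviorParams) -> float:
    """P(final guess = red), including the lapse mixture."""
    p = expit(params.w_h * (conf - 50.0) + params.w_a * (a_shown - 50.0))
    return (1.0 - params.lapse) * float(p) + params.lapse / 2.0


def final_decision(
    conf: int, a_shown: int, params: BehaviorParams, rng: np.random.Generator
) -> str:
    if not (0 <= conf <= 100 and 0 <= a_shown <= 100):
        raise ValueError("conf and a_shown must be in [0,100]")
    return "red" if rng.random() < final_decision_p_red(conf, a_shown, params) else "black"


def bayes_observer_guess(
    z_count: int, a: Fraction, group: str, cfg: DesignConfig = DesignConfig()
) -> tuple[str, float]:
    """Posterior-optimal guess given the shown red count, and P(card is red).

    Uniform prior over the two admissible piles r = a ± var_a; likelihood of
    the observed shown red count under each pile uses the exact Wallenius pmf
    at that pile's group-specific dealing odds.  Returns ("red"/"black",
    posterior probability that the picked card is red).  A tie at exactly 0.5
    resolves toward the AI's side (red iff a > 1/2).
    """
    candidates = [a - cfg.var_a, a + cfg.var_a]
    liks = []
    for r in candidates:
        n_red = int(r * cfg.pile_size)
        omega = design.odds_ratio(group, r, a) if group != "unbiased" else 1.0
        pmf = wallenius_pmf(
            WalleniusParams(cfg.n_shown, n_red, cfg.pile_size - n_red, omega)
        )
        liks.append(pmf[z_count] if 0 <= z_count < len(pmf) else 0.0)
    total = sum(liks)
    if total == 0.0:
        raise ValueError(f"shown count {z_count} impossible under both piles of a={a}")
    post = [l / total for l in liks]
    p_red = sum(p * float(r) for p, r in zip(post, candidates))
    if p_red > 0.5:
        guess = "red"
    elif p_red < 0.5:
        guess = "black"
    else:
        guess = "red" if a > Fraction(1, 2) else "black"
    return guess, p_red


def _attention_response(
    game: GameInstance, inattentive: bool, params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[int, str, str]:
    """Confidence and guesses on an attention check.

    Attentive participants answer near the obvious truth (tight normal around
    100·z); inattentive ones state uniform confidence and guess accordingly.
    """
    if inattentive:
        conf = int(rng.integers(0, 101))
    else:
        # attentive: confidence tightly concentrated on the obvious pile fraction
        conf = int(round(float(np.clip(
            rng.normal(100.0 * float(game.pile.r), 5.0), 0.0, 100.0))))
    guess = initial_guess_from_confidence(conf, rng)
    return conf, guess, guess


def simulate_cohort(
    cfg: DesignConfig,
    group: str,
    n_participants: int,
    params: BehaviorParams,
    rng: np.random.Generator,
    batches: list[Batch],
    attention: list[GameInstance],
    realignment_map: Optional[RealignmentMap] = None,
    participants_per_batch: int = 5,
    id_offset: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort playing its group's batches; one row per round.

    Participants are assigned round-robin to batches (``participants_per_
    batch`` per batch before wrapping), play the 24 scored games of their
    batch in a seeded random order, with the three attention checks inserted
    at fixed timeline positions.  For the realigned group the displayed AI
    confidence is the realignment map's output for the participant's own
    initial-confidence bin, passed through display rounding.
    """
    if group == "realigned" and realignment_map is None:
        raise ValueError("realigned group requires a fitted RealignmentMap")
    n_batches = len(batches)
    rows = []
    for i in range(n_participants):
        pid = id_offset + i
        batch = batches[(i // participants_per_batch) % n_batches]
        inattentive = rng.random() < params.inattentive_rate
        order = rng.permutation(len(batch.games))
        timeline: list[tuple[GameInstance, bool]] = [
            (batch.games[k], False) for k in order
        ]
        for pos, chk in zip(ATTENTION_POSITIONS, attention):
            timeline.insert(pos, (chk, True))
        for round_index, (game, is_chk) in enumerate(timeline):
            pile = game.pile
            outcome = design.pick_card(pile, rng)
            if is_chk:
                conf, d0, d1 = _attention_response(game, inattentive, params, rng)
                a_shown = design.display_confidence(pile.a)
            else:
                z = game.z_count / cfg.n_shown
                conf = draw_initial_confidence(z, params, rng)
                d0 = initial_guess_from_confidence(conf, rng)
                if group == "realigned":
                    h = discretize_confidence(conf, d0)
                    v = apply_realignment(realignment_map, h, float(pile.a), rng)
                    a_shown = design.display_confidence(v)
                else:
                    a_shown = design.display_confidence(pile.a)
                d1 = final_decision(conf, a_shown, params, rng)
            rows.append((
                pid, group, batch.batch_id, round_index,
                pile.a.numerator, pile.a.denominator, a_shown,
                pile.r.numerator, pile.r.denominator, game.z_count,
                conf, d0, d1, int(outcome), int(is_chk),
            ))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def calibration_triples(records: pd.DataFrame) -> pd.DataFrame:
    """(h_bin, a, r) training triples for realignment, from scored records."""
    df = records[records["is_attention_check"] == 0].copy()
    df["h_bin"] = [
        discretize_confidence(int(c), g)
        for c, g in zip(df["initial_confidence"], df["initial_guess"])
    ]
    df["a"] = df["a_num"] / df["a_den"]
    df["r"] = df["r_num"] / df["r_den"]
    return df[["h_bin", "a", "r"]].reset_index(drop=True)
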