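"""Alignment-error metrics between AI confidence and human confidence.

Alignment means monotonicity of P(Y=1 | A=a, H=h) in the pair (a, h): among
comparable confidence pairs, higher joint confidence should never predict the
outcome worse.  The maximum alignment error (MAE) is the largest monotonicity
violation over comparable pairs,

    MAE = max_{h<=h', a<=a'}  P(Y=1|A=a,H=h) - P(Y=1|A=a',H=h'),

and the expected alignment error (EAE) is the mean positive-part violation
over all N comparable ordered pairs (identical pairs included, contributing
zero), so 0 <= EAE <= MAE <= 1 always.

Human confidence (an integer 0..100) is discretized into four ordered bins,
very_low < low < high < very_high, by quartering the range; a stated
confidence of exactly 50 is assigned high or low according to the initial
guess (red or black).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

H_BINS = ("very_low", "low", "high", "very_high")
_H_INDEX = {b: i for i, b in enumerate(H_BINS)}


@dataclass(frozen=True)
class AlignmentSummary:
    mae: float
    eae: float
    n_pairs: int
    n_cells: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "eae": self.eae,
                "n_pairs": self.n_pairs, "n_cells": self.n_cells}


def discretize_confidence(conf: int, guess: str) -> str:
    """Map a stated confidence 0..100 and initial guess to an ordered h-bin."""
    if not (0 <= conf <= 100):
        raise ValueError(f"confidence must be in [0, 100], got {conf}")
    if conf <= 25:
        return "very_low"
    if conf < 50:
        return "low"
    if conf == 50:
        return "high" if guess == "red" else "low"
    if conf <= 75:
        return "high"
    return "very_high"


def outcome_table(records: pd.DataFrame, min_count: int = 1) -> pd.DataFrame:
    """Estimate P(Y=1 | A=a, H=h) on the (a_level, h_bin) lattice.

    ``records`` must carry columns a_shown (displayed integer confidence,
    the a-level), initial_confidence, initial_guess, outcome_is_red, and must
    exclude attention checks.  Cells observed fewer than ``min_count`` times
    are omitted.  Returns a frame with columns a_level, h_bin, estimate,
    count.
    """
    if len(records) == 0:
        raise ValueError("cannot build an alignment table from zero records")
    if "is_attention_check" in records.columns and records["is_attention_check"].any():
        raise ValueError("records must exclude attention checks")
    df = records.copy()
    df["h_bin"] = [
        discretize_confidence(int(c), g)
        for c, g in zip(df["initial_confidence"], df["initial_guess"])
    ]
    grp = (
        df.groupby(["a_shown", "h_bin"], sort=False)["outcome_is_red"]
        .agg(estimate="mean", count="size")
        .reset_index()
        .rename(columns={"a_shown": "a_level"})
    )
    grp = grp[grp["count"] >= min_count].reset_index(drop=True)
    grp["estimate"] = grp["estimate"].astype(float)
    return grp.sort_values(["a_level", "h_bin"], key=_sort_key).reset_index(drop=True)


def _sort_key(col: pd.Series) -> pd.Series:
    if col.name == "h_bin":
        return col.map(_H_INDEX)
    return col


def _comparable_pairs(table: pd.DataFrame):
    """Yield (estimate_low, estimate_high) over ordered cell pairs (a,h) <= (a',h')."""
    a = np.asarray(table["a_level"], dtype=float)
    h = np.asarray([_H_INDEX[b] for b in table["h_bin"]])
    est = np.asarray(table["estimate"], dtype=float)
    le = (a[:, None] <= a[None, :]) & (h[:, None] <= h[None, :])
    i, j = np.nonzero(le)
    return est[i], est[j]


def max_alignment_error(table: pd.DataFrame) -> float:
    """MAE: largest violation estimate(a,h) - estimate(a',h') over comparable pairs."""
    if len(table) == 0:
        raise ValueError("empty alignment table")
    lo, hi = _comparable_pairs(table)
    return float(np.max(lo - hi))  # identical pair attains 0, so never negative


def expected_alignment_error(table: pd.DataFrame) -> tuple[float, int]:
    """EAE and the number N of comparable ordered pairs it averages over."""
    if len(table) == 0:
        raise ValueError("empty alignment table")
    lo, hi = _comparable_pairs(table)
    viol = np.clip(lo - hi, 0.0, None)
    return float(viol.mean()), int(len(viol))


def alignment_summary(records: pd.DataFrame, min_count: int = 10) -> AlignmentSummary:
    """Convenience: table + MAE + EAE in one call.

    Cells with fewer than ``min_count`` observations are excluded before the
    metrics are computed: a cell estimated from a handful of records takes
    extreme values 0/1 by chance and the max/positive-part statistics would
    then measure sampling noise rather than misalignment.  The default
    matches the ">10 data points" display convention used for the stratified
    heatmaps.
    """
    table = outcome_table(records, min_count=min_count)
    mae = max_alignment_error(table)
    eae, n_pairs = expected_alignment_error(table)
    return AlignmentSummary(mae=mae, eae=eae, n_pairs=n_pairs, n_cells=len(table))


def calibration_error(records: pd.DataFrame) -> float:
    """Expected calibration error of the displayed AI confidence.

    Sum over distinct displayed levels a of (n_a/n)·|mean(Y | a) - a/100|.
    """
    if len(records) == 0:
        raise ValueError("no records")
    n = len(records)
    err = 0.0
    for a, sub in records.groupby("a_shown"):
        err += len(sub) / n * abs(float(sub["outcome_is_red"].mean()) - a / 100.0)
    return err


def decision_heatmap(records: pd.DataFrame, min_count: int = 10) -> dict:
    """P(guess = red) by (h_bin, a_level), for initial and final guesses.

    Cells with ``min_count`` or fewer observations are omitted (strict
    inequality: a cell needs more than ``min_count`` records to be kept).
    Returns {"initial": frame, "final": frame} with columns h_bin, a_level,
    p_red, count.
    """
    if len(records) == 0:
        raise ValueError("no records")
    df = records.copy()
    df["h_bin"] = [
        discretize_confidence(int(c), g)
        for c, g in zip(df["initial_confidence"], df["initial_guess"])
    ]
    out = {}
    for name, col in (("initial", "initial_guess"), ("final", "final_guess")):
        df["_red"] = (df[col] == "red").astype(float)
        grp = (
            df.groupby(["h_bin", "a_shown"], sort=False)["_red"]
            .agg(p_red="mean", count="size")
            .reset_index()
            .rename(columns={"a_shown": "a_level"})
        )
        grp = grp[grp["count"] > min_count].reset_index(drop=True)
        out[name] = grp.sort_values(["h_bin", "a_level"], key=_sort_key).reset_index(
            drop=True
        )
    return out


def isotonic_violation_mass(heat: pd.DataFrame, value_col: str = "p_red") -> float:
    """Mean positive-part monotonicity violation of a heatmap over comparable pairs.

    Diagnostic used to check that decision probabilities are nondecreasing in
    both own confidence and AI confidence, up to sampling noise.
    """
    t = heat.rename(columns={value_col: "estimate"})
    eae, _ = expected_alignment_error(t)
    return eae
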