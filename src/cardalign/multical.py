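"""Realignment of AI confidence by multicalibration.

The human confidence bin h partitions the game instances into disjoint
subspaces.  Within each subspace the AI confidence is post-processed by
uniform-mass histogram binning: the subspace's training instances are split
into N equal-count bins of AI confidence, and each bin's output is the
empirical mean *true* red fraction r of the training instances it contains
(using r rather than the Bernoulli outcomes gives lower-variance estimates).
A new instance in the same subspace falling into the same bin receives that
bin's output as its realigned AI confidence.

Because the designed AI confidence takes only 12 discrete levels, a small
uniform noise (bounded by 1e-10/(1+1e-10)) is added to the confidence both
when fitting and when deploying, so that the uniform-mass quantile edges are
well defined (ties are broken almost surely).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import H_BINS

DEFAULT_NOISE_HIGH = 1e-10 / (1 + 1e-10)


@dataclass(frozen=True)
class RealignmentConfig:
    n_bins: int = 5
    noise_high: float = DEFAULT_NOISE_HIGH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not (0 < self.noise_high < 1e-9):
            raise ValueError("noise_high must lie in (0, 1e-9)")


@dataclass
class RealignmentMap:
    """Fitted uniform-mass binning per human-confidence subspace.

    For each h-bin: ``edges`` are the n_bins-1 interior quantile edges over
    the noised AI confidence (bins are left-closed, right-open; the extreme
    bins absorb out-of-range values), ``outputs`` the per-bin mean true red
    fraction, ``train_counts`` the per-bin training counts.
    """

    config: RealignmentConfig
    subspaces: dict = field(default_factory=dict)  # h_bin -> dict

    def to_json(self) -> str:
        payload = {
            "config": {"n_bins": self.config.n_bins,
                       "noise_high": self.config.noise_high,
                       "seed": self.config.seed},
            "subspaces": {
                h: {"edges": list(map(float, s["edges"])),
                    "outputs": list(map(float, s["outputs"])),
                    "train_counts": list(map(int, s["train_counts"]))}
                for h, s in self.subspaces.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RealignmentMap":
        payload = json.loads(text)
        cfg = RealignmentConfig(**payload["config"])
        m = cls(config=cfg)
        for h, s in payload["subspaces"].items():
            m.subspaces[h] = {
                "edges": np.asarray(s["edges"], dtype=float),
                "outputs": np.asarray(s["outputs"], dtype=float),
                "train_counts": np.asarray(s["train_counts"], dtype=int),
            }
        return m


def fit_realignment(
    calib_records: pd.DataFrame, cfg: RealignmentConfig = RealignmentConfig()
) -> RealignmentMap:
    """Fit the uniform-mass binning map from calibration triples (h_bin, a, r).

    ``calib_records`` needs columns ``h_bin`` (one of very_low/low/high/
    very_high), ``a`` (AI confidence in [0,1]) and ``r`` (true red fraction).
    Each subspace present must hold at least ``cfg.n_bins`` records.
    """
    rng = np.random.default_rng(cfg.seed)
    m = RealignmentMap(config=cfg)
    for h in H_BINS:
        sub = calib_records[calib_records["h_bin"] == h]
        if len(sub) == 0:
            continue
        if len(sub) < cfg.n_bins:
            raise ValueError(
                f"subspace {h!r} has {len(sub)} records, fewer than "
                f"n_bins={cfg.n_bins}"
            )
        a = np.asarray(sub["a"], dtype=float)
        r = np.asarray(sub["r"], dtype=float)
        x = a + rng.uniform(0.0, cfg.noise_high, size=len(a))
        qs = np.arange(1, cfg.n_bins) / cfg.n_bins
        edges = np.quantile(x, qs)
        idx = np.searchsorted(edges, x, side="right")
        outputs = np.empty(cfg.n_bins)
        counts = np.zeros(cfg.n_bins, dtype=int)
        for b in range(cfg.n_bins):
            mask = idx == b
            counts[b] = int(mask.sum())
            outputs[b] = float(r[mask].mean()) if counts[b] else float(r.mean())
        m.subspaces[h] = {"edges": edges, "outputs": outputs, "train_counts": counts}
    return m


def apply_realignment(
    m: RealignmentMap, h: str, a: float, rng: np.random.Generator
) -> float:
    """Realigned AI confidence for a new instance in subspace ``h``.

    Deployment noise (same bound as at training) is added to ``a`` before the
    bin lookup; values outside the training range clamp to the extreme bins.
    """
    if h not in m.subspaces:
        raise KeyError(f"no fitted subspace for h-bin {h!r}")
    s = m.subspaces[h]
    x = float(a) + rng.uniform(0.0, m.config.noise_high)
    b = int(np.searchsorted(s["edges"], x, side="right"))
    return float(s["outputs"][b])
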