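"""End-to-end synthetic study: design, simulate, realign, measure, test.

Replays the whole experimental pipeline on synthetic participants from one
master seed: build the calibrated game design and group-biased batches,
simulate a calibration cohort on the toward-bias distribution, fit the
realignment map on it, simulate the four study cohorts (toward / away /
unbiased / realigned), apply the attention-check exclusion rule, compute
per-group alignment errors and calibration error, and run the Bayesian A/B
tests on conditional matching rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignment, analysis, design, multical, participants


@dataclass
class StudyResult:
    records: dict            # group -> full response frame (incl. excluded, checks)
    kept: dict               # group -> list of kept participant ids
    excluded: dict           # group -> list of excluded participant ids
    summaries: dict          # group -> AlignmentSummary
    calibration_errors: dict  # group -> ECE of displayed AI confidence
    empirical_theta: dict    # (group, q) -> plug-in conditional matching rate
    posterior_3group: analysis.ABPosterior | None
    posterior_realign: analysis.ABPosterior | None
    tests: dict              # name -> HypothesisResult
    realignment_map: multical.RealignmentMap
    calibration_excluded: list = field(default_factory=list)


def scored(records: pd.DataFrame, keep_ids=None) -> pd.DataFrame:
    """Scored (non-attention) rows, optionally restricted to kept participants."""
    df = records[records["is_attention_check"] == 0]
    if keep_ids is not None:
        df = df[df["participant_id"].isin(keep_ids)]
    return df.reset_index(drop=True)


def simulate_study(
    seed: int,
    n_per_group: int = 100,
    n_calibration: int = 300,
    cfg: design.DesignConfig = design.DesignConfig(),
    behavior: participants.BehaviorParams = participants.BehaviorParams(),
    realign_cfg: multical.RealignmentConfig | None = None,
) -> dict:
    """Simulate calibration + four study cohorts; returns the raw materials.

    Returns a dict with keys ``records`` (group -> frame), ``calibration``
    (frame), ``realignment_map``, ``batches``, ``attention``.
    """
    ss = np.random.SeedSequence(seed)
    (s_att, s_batch, s_calib, s_map, s_cohort) = ss.spawn(5)
    att_rng = np.random.default_rng(s_att)
    attention = design.attention_checks(cfg, att_rng)

    batch_rng = np.random.default_rng(s_batch)
    batches = {
        "toward": design.build_batches(cfg, "toward", cfg.n_batches, batch_rng),
        "away": design.build_batches(cfg, "away", cfg.n_batches, batch_rng),
        "unbiased": design.build_batches(cfg, "unbiased", cfg.n_batches, batch_rng),
    }
    batches["realigned"] = design.build_batches(
        cfg, "realigned", cfg.n_batches, batch_rng, source_batches=batches["toward"]
    )
    calib_batches = design.build_batches(
        cfg, "toward", cfg.n_calibration_batches, batch_rng
    )

    # calibration cohort: toward-bias distribution, own filtering reference
    calib_rng = np.random.default_rng(s_calib)
    calib = participants.simulate_cohort(
        cfg, "toward", n_calibration, behavior, calib_rng, calib_batches,
        attention, id_offset=100_000,
    )
    kept_c, excl_c, _ = analysis.filter_participants(
        calib[calib["is_attention_check"] == 1]
    )
    if realign_cfg is None:
        map_seed = int(np.random.default_rng(s_map).integers(0, 2**31 - 1))
        realign_cfg = multical.RealignmentConfig(seed=map_seed)
    triples = participants.calibration_triples(scored(calib, kept_c))
    rmap = multical.fit_realignment(triples, realign_cfg)

    cohort_rngs = dict(zip(design.GROUPS, s_cohort.spawn(4)))
    records = {}
    for i, group in enumerate(design.GROUPS):
        rng = np.random.default_rng(cohort_rngs[group])
        records[group] = participants.simulate_cohort(
            cfg, group, n_per_group, behavior, rng, batches[group], attention,
            realignment_map=rmap if group == "realigned" else None,
            id_offset=1000 * (i + 1),
        )
    return {
        "records": records,
        "calibration": calib,
        "calibration_excluded": excl_c,
        "realignment_map": rmap,
        "batches": batches,
        "attention": attention,
    }


def run_study(
    seed: int,
    n_per_group: int = 100,
    n_calibration: int = 300,
    cfg: design.DesignConfig = design.DesignConfig(),
    behavior: participants.BehaviorParams = participants.BehaviorParams(),
    mcmc_steps: int = 800,
    mcmc_burn: int = 300,
    fit_models: bool = True,
) -> StudyResult:
    """The full analysis pipeline on a fresh synthetic study."""
    sim = simulate_study(seed, n_per_group, n_calibration, cfg, behavior)
    records = sim["records"]

    # attention filtering: reference population = all four groups pooled
    pooled_checks = pd.concat(
        [r[r["is_attention_check"] == 1] for r in records.values()]
    )
    kept_all, excluded_all, _ = analysis.filter_participants(pooled_checks)
    kept, excluded = {}, {}
    for group, recs in records.items():
        ids = set(recs["participant_id"].unique())
        kept[group] = sorted(ids.intersection(kept_all))
        excluded[group] = sorted(ids.intersection(excluded_all))

    summaries, cal_errors, emp_theta = {}, {}, {}
    counts_frames = {}
    for group, recs in records.items():
        sc = scored(recs, kept[group])
        summaries[group] = alignment.alignment_summary(sc)
        cal_errors[group] = alignment.calibration_error(sc)
        with_q = analysis.add_match_indicators(sc)
        for q in (0, 1):
            sub = with_q[with_q["Q"] == q]
            emp_theta[(group, q)] = float(sub["Qp"].mean()) if len(sub) else np.nan
        counts_frames[group] = analysis.aggregate_counts(sc)

    post3 = post_r = None
    tests = {}
    if fit_models:
        mcmc_seed = int(np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[5])
                        .integers(0, 2**31 - 1))
        def fit(counts, fit_seed):
            # retry once with longer chains if split-R-hat misses the bar
            try:
                return analysis.fit_ab_model(
                    counts, seed=fit_seed, n_steps=mcmc_steps, n_burn=mcmc_burn
                )
            except analysis.ConvergenceError:
                return analysis.fit_ab_model(
                    counts, seed=fit_seed, n_steps=2 * mcmc_steps,
                    n_burn=2 * mcmc_burn,
                )

        counts3 = pd.concat(
            [counts_frames[g] for g in ("toward", "away", "unbiased")]
        )
        post3 = fit(counts3, mcmc_seed)
        counts_r = pd.concat([counts_frames[g] for g in ("toward", "realigned")])
        post_r = fit(counts_r, mcmc_seed + 1)
        for q in (0, 1):
            for ga in ("away", "unbiased"):
                tests[f"theta{q}_{ga}_gt_toward"] = analysis.hypothesis_evidence(
                    post3, q, ga, "toward"
                )
            tests[f"theta{q}_realigned_gt_toward"] = analysis.hypothesis_evidence(
                post_r, q, "realigned", "toward"
            )

    return StudyResult(
        records=records,
        kept=kept,
        excluded=excluded,
        summaries=summaries,
        calibration_errors=cal_errors,
        empirical_theta=emp_theta,
        posterior_3group=post3,
        posterior_realign=post_r,
        tests=tests,
        realignment_map=sim["realignment_map"],
        calibration_excluded=sim["calibration_excluded"],
    )
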