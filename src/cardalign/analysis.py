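"""Utility analysis: matching rates, filtering, Bayesian A/B tests.

The utility of AI assistance is measured against the optimal guess
pi*(r) = red iff r > 1/2.  For every scored game, Q = 1[pi*(r) = d] indicates
whether the participant's initial guess was optimal and Q' = 1[pi*(r) = d']
whether the final guess (after seeing the AI confidence) was.  The
conditional matching rates theta_0 = E[Q' | Q=0] and theta_1 = E[Q' | Q=1]
summarize how often the AI corrected an initially sub-optimal guess and how
often it preserved an initially optimal one.

Group differences in theta are tested with a Bayesian binomial-logit mixed
model over per-participant aggregated counts,

    Q' | trials(Q')  ~  0 + g * Q + (1 | participant),

i.e. one fixed-effect cell coefficient beta[g, q] per (group, initial-match)
cell (no global intercept, so no fixed reference group) and a Gaussian random
intercept per participant.  Priors are standard normal on all fixed effects
and half-normal(1) on the random-intercept SD.  theta[g, q] =
logistic(beta[g, q]) is the rate for the population-median participant
(random intercept 0).  One-sided hypotheses theta[q, gA] > theta[q, gB] are
summarized by the posterior probability of the inequality and the evidence
ratio (posterior odds), reported as "> n_draws" when no draw violates it.

Inference: the random intercepts are marginalized out of the likelihood with
Gauss-Hermite quadrature, leaving a low-dimensional posterior over the cell
coefficients and the intercept SD, which is sampled with an affine-invariant
ensemble sampler (emcee); convergence is checked with split-R-hat over
walkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import boschloo_exact

from .alignment import H_BINS  # noqa: F401  (re-exported for convenience)


class UndefinedOptimumError(ValueError):
    pass


def optimal_guess(r: float) -> str:
    """pi*(r): red iff the pile's true red fraction exceeds 1/2."""
    r = float(r)
    if r == 0.5:
        raise UndefinedOptimumError("optimal guess undefined at r = 1/2")
    return "red" if r > 0.5 else "black"


def add_match_indicators(records: pd.DataFrame) -> pd.DataFrame:
    """Append Q (initial guess optimal) and Qp (final guess optimal) columns."""
    df = records.copy()
    r = df["r_num"] / df["r_den"]
    if (r == 0.5).any():
        raise UndefinedOptimumError("records contain games with r = 1/2")
    opt = np.where(r > 0.5, "red", "black")
    df["Q"] = (df["initial_guess"].to_numpy() == opt).astype(int)
    df["Qp"] = (df["final_guess"].to_numpy() == opt).astype(int)
    return df


def match_indicators(record) -> tuple[int, int]:
    """(Q, Q') for a single scored record (mapping-like with the CSV fields)."""
    opt = optimal_guess(record["r_num"] / record["r_den"])
    return int(record["initial_guess"] == opt), int(record["final_guess"] == opt)


def score_participant(records: pd.DataFrame, bonus_per_point: float = 0.12):
    """Points (+1 correct final guess, -1 incorrect) and bonus in GBP."""
    correct = (records["final_guess"] == "red") == (records["outcome_is_red"] == 1)
    points = int(correct.sum() - (~correct).sum())
    return points, round(max(points, 0) * bonus_per_point, 2)


def filter_participants(attention_records: pd.DataFrame):
    """Attention-check exclusion rule.

    Per check, the mean and SD of the stated confidence are computed over the
    supplied reference population (pass all groups pooled to filter the study
    cohorts, or the calibration cohort alone to filter it).  A participant is
    flagged on a check when their confidence deviates from the check's mean
    by more than one SD, and excluded when flagged on more than one check.

    Returns (kept ids, excluded ids, per-check stats frame).  Checks are
    identified by their round_index.  A check with zero SD is degenerate:
    any nonzero deviation then flags.
    """
    df = attention_records[attention_records["is_attention_check"] == 1]
    n_checks = df["round_index"].nunique()
    counts = df.groupby("participant_id")["round_index"].nunique()
    if (counts != n_checks).any():
        raise ValueError("every participant must have all attention checks")
    stats = (
        df.groupby("round_index")["initial_confidence"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=0))
        .reset_index()
    )
    merged = df.merge(stats, on="round_index")
    merged["flag"] = (
        np.abs(merged["initial_confidence"] - merged["mean"]) > merged["sd"]
    )
    flags = merged.groupby("participant_id")["flag"].sum()
    excluded = sorted(flags[flags > 1].index.tolist())
    kept = sorted(flags[flags <= 1].index.tolist())
    return kept, excluded, stats


def aggregate_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant binomial rows: successes = sum(Q'), trials, per Q level."""
    if len(records) == 0:
        return pd.DataFrame(
            columns=["participant_id", "group", "q", "successes", "trials"]
        )
    df = add_match_indicators(records[records["is_attention_check"] == 0])
    out = (
        df.groupby(["participant_id", "group", "Q"])["Qp"]
        .agg(successes="sum", trials="size")
        .reset_index()
        .rename(columns={"Q": "q"})
    )
    return out[out["trials"] > 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bayesian binomial-logit mixed model
# ---------------------------------------------------------------------------

@dataclass
class ABPosterior:
    """Posterior draws of the group x initial-match binomial-logit model.

    theta, beta have shape (n_draws, n_groups, 2); sigma (n_draws,).
    """

    groups: list
    beta: np.ndarray
    sigma: np.ndarray
    rhat: dict

    @property
    def theta(self) -> np.ndarray:
        return expit(self.beta)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def theta_draws(self, group: str, q: int) -> np.ndarray:
        return self.theta[:, self.groups.index(group), q]


@dataclass
class HypothesisResult:
    hypothesis: str
    estimate: float
    est_error: float
    post_prob: float
    evidence_ratio: float
    evidence_ratio_label: str


class ConvergenceError(RuntimeError):
    def __init__(self, rhat: dict):
        self.rhat = rhat
        super().__init__(f"MCMC did not converge: split-R-hat {rhat}")


def _gh_nodes(n: int = 21):
    # standard-normal quadrature: x = sqrt(2)*t, w normalized
    t, w = np.polynomial.hermite.hermgauss(n)
    return np.sqrt(2.0) * t, w / np.sqrt(np.pi)


def fit_ab_model(
    counts: pd.DataFrame,
    prior_sd: float = 1.0,
    n_chains: int = 4,
    n_walkers: int = 16,
    n_steps: int = 800,
    n_burn: int = 300,
    seed: int = 0,
    rhat_tol: float = 1.01,
    check_convergence: bool = True,
) -> ABPosterior:
    """Fit the mixed model on aggregated MatchCounts rows.

    ``counts`` columns: participant_id, group, q, successes, trials (rows for
    both q levels of a participant share that participant's random
    intercept).  Runs ``n_chains`` independent ensembles; split-R-hat is
    computed across them (each ensemble's draws, step-major, form one chain).
    Returns at least 4000 post-warmup draws.
    """
    groups = sorted(counts["group"].unique())
    if len(groups) < 2:
        raise ValueError("need counts from at least two groups")
    pids = counts["participant_id"].unique()
    pidx = {p: i for i, p in enumerate(pids)}
    P, G = len(pids), len(groups)
    # per participant: successes/trials for q=0 and q=1 (0 trials where absent)
    s = np.zeros((P, 2))
    n = np.zeros((P, 2))
    gidx = np.zeros(P, dtype=int)
    for row in counts.itertuples(index=False):
        i = pidx[row.participant_id]
        s[i, row.q] = row.successes
        n[i, row.q] = row.trials
        gidx[i] = groups.index(row.group)
    lchoose = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
    nodes, weights = _gh_nodes(21)
    K = len(nodes)

    def log_prob(theta_flat: np.ndarray) -> np.ndarray:
        # vectorized over walkers: theta_flat (W, G*2 + 1)
        th = np.atleast_2d(theta_flat)
        beta = th[:, : G * 2].reshape(-1, G, 2)
        sigma = th[:, -1]
        W = th.shape[0]
        lp = np.full(W, -np.inf)
        ok = sigma > 0
        if not ok.any():
            return lp if theta_flat.ndim > 1 else lp[0]
        b = beta[ok]          # (w, G, 2)
        sg = sigma[ok]        # (w,)
        eta = b[:, gidx, :]   # (w, P, 2)
        # (w, P, 2, K)
        full = eta[..., None] + sg[:, None, None, None] * nodes
        p = expit(full)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                s[None, :, :, None] * np.log(p)
                + (n - s)[None, :, :, None] * np.log1p(-p)
            )
        ll = np.where(n[None, :, :, None] > 0, ll, 0.0)
        per_pk = ll.sum(axis=2)  # (w, P, K) joint over the two q rows
        mx = per_pk.max(axis=2, keepdims=True)
        lik = np.log((weights * np.exp(per_pk - mx)).sum(axis=2)) + mx[..., 0]
        loglik = lik.sum(axis=1) + lchoose.sum()
        logprior = (
            -0.5 * (b.reshape(len(b), -1) ** 2).sum(axis=1) / prior_sd**2
            - 0.5 * sg**2
        )
        lp[ok] = loglik + logprior
        return lp if theta_flat.ndim > 1 else lp[0]

    import emcee

    ndim = G * 2 + 1
    # initialize near the empirical pooled logits
    emp = np.zeros((G, 2))
    for g in range(G):
        for q in range(2):
            mask = gidx == g
            tot_n, tot_s = n[mask, q].sum(), s[mask, q].sum()
            emp[g, q] = np.log((tot_s + 0.5) / (tot_n - tot_s + 0.5)) if tot_n else 0.0
    p0 = np.concatenate([emp.ravel(), [0.5]])
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng((seed, c))
        init = p0 + 0.05 * rng.standard_normal((n_walkers, ndim))
        init[:, -1] = np.abs(init[:, -1]) + 0.05
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_prob, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(
            rng.integers(0, 2**31 - 1)
        ).get_state()
        sampler.run_mcmc(init, n_steps, progress=False)
        kept = sampler.get_chain(discard=n_burn)  # (steps, walkers, ndim)
        chains.append(kept.reshape(-1, ndim))  # step-major flatten

    import arviz as az

    posterior = np.stack(chains)  # (chain, draw, ndim)
    rhat = {}
    names = [f"beta[{groups[g]},{q}]" for g in range(G) for q in range(2)] + ["sigma"]
    for d, name in enumerate(names):
        rhat[name] = float(az.rhat(az.convert_to_dataset(posterior[:, :, d]))["x"])
    if check_convergence and any(
        v > rhat_tol for k, v in rhat.items() if k.startswith("beta")
    ):
        raise ConvergenceError(rhat)
    flat = posterior.reshape(-1, ndim)
    return ABPosterior(
        groups=list(groups),
        beta=flat[:, : G * 2].reshape(-1, G, 2),
        sigma=flat[:, -1],
        rhat=rhat,
    )


def hypothesis_evidence(
    posterior: ABPosterior, q: int, group_a: str, group_b: str
) -> HypothesisResult:
    """One-sided test theta[q, group_a] > theta[q, group_b] from the draws."""
    da = posterior.theta_draws(group_a, q)
    db = posterior.theta_draws(group_b, q)
    diff = da - db
    post_prob = float((diff > 0).mean())
    nd = posterior.n_draws
    if post_prob >= 1.0:
        ratio, label = float(nd), f"> {nd}"
    elif post_prob <= 0.0:
        ratio, label = 1.0 / nd, f"< {1.0 / nd:.2g}"
    else:
        ratio = post_prob / (1.0 - post_prob)
        label = f"{ratio:.2f}"
    return HypothesisResult(
        hypothesis=f"theta[{q},{group_a}] > theta[{q},{group_b}]",
        estimate=float(diff.mean()),
        est_error=float(diff.std(ddof=1)),
        post_prob=post_prob,
        evidence_ratio=ratio,
        evidence_ratio_label=label,
    )


def stratified_matching(records: pd.DataFrame, min_count: int = 10) -> pd.DataFrame:
    """Empirical E[Q'] by game type, stratified by AI-agreement, vs E[Q].

    The agreement flag marks games where the initial guess coincides with the
    AI's implied guess (red iff a > 1/2, using the displayed/realigned
    confidence).  Per (game type, agreement) cell: x = mean Q, y = mean Q'.
    Cells with ``min_count`` or fewer records are omitted.
    """
    df = add_match_indicators(records[records["is_attention_check"] == 0])
    ai_guess = np.where(df["a_shown"] > 50, "red", "black")
    df["agrees_with_ai"] = (df["initial_guess"].to_numpy() == ai_guess).astype(int)
    grp = (
        df.groupby(["a_num", "a_den", "r_num", "r_den", "agrees_with_ai"])
        .agg(x=("Q", "mean"), y=("Qp", "mean"), count=("Q", "size"))
        .reset_index()
    )
    return grp[grp["count"] > min_count].reset_index(drop=True)


def boschloo_test(
    successes_a: int, trials_a: int, successes_b: int, trials_b: int,
    alternative: str = "greater",
) -> float:
    """Boschloo's exact unconditional p-value comparing two binomial rates.

    ``alternative="greater"`` tests rate_a > rate_b.
    """
    if trials_a <= 0 or trials_b <= 0:
        raise ValueError("both samples need at least one trial")
    if not (0 <= successes_a <= trials_a and 0 <= successes_b <= trials_b):
        raise ValueError("successes must lie in [0, trials]")
    # scipy's convention: each *column* is one binomial sample
    table = [[successes_a, successes_b],
             [trials_a - successes_a, trials_b - successes_b]]
    return float(boschloo_exact(table, alternative=alternative, n=64).pvalue)
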