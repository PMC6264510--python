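"""Bayesian admixture clustering of binary band profiles (haploid model).

Model (the admixture model of structured-population inference, applied to
dominant bands treated as haploid loci with independent frequencies):

* each individual x has ancestry proportions q_x ~ Dirichlet(alpha, ..., alpha);
* each locus l of x descends from cluster z_xl ~ Categorical(q_x);
* the band is x_l ~ Bernoulli(p_{k,l}) given z_xl = k, with p_{k,l} ~ Beta(1,1).

A Gibbs sampler alternates the conjugate updates z | p, q, then p | z, x,
then q | z, with alpha learned by random-walk Metropolis on log(alpha)
under a uniform prior on (0, alpha_max].  The data log-likelihood is
recorded every ``thin`` post-burn-in sweeps; the model-selection summary
is ln P(X|K) ~= mean(lnL) - var(lnL)/2, and the number of clusters is
chosen by the Evanno delta-K statistic over replicate runs:
delta_K = |L(K+1) - 2 L(K) + L(K-1)| / sd(K).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .marker_data import MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "gibbs_sample",
    "estimate_lnPK",
    "delta_k",
    "align_labels",
    "run_k_scan",
    "AdmixtureRun",
    "DeltaKTable",
]


@dataclass
class AdmixtureRun:
    """Posterior summaries of one MCMC run at a fixed K."""

    K: int
    Q: np.ndarray  # (n, K) posterior-mean ancestry, rows sum to 1
    P: np.ndarray  # (K, L) posterior-mean band frequencies, in (0, 1)
    lnL_trace: np.ndarray
    lnPK: float
    seed: int | None
    burn_in: int
    n_iter: int
    alpha_trace: np.ndarray | None = None


def _loglik(x: np.ndarray, q: np.ndarray, p: np.ndarray) -> float:
    # sum_{x,l} log sum_k q_xk p_kl^x (1-p_kl)^(1-x)
    like1 = q @ p  # (n, L): P(band present)
    lik = np.where(x == 1, like1, 1.0 - like1)
    return float(np.log(np.clip(lik, 1e-300, None)).sum())


def _dirichlet_loglik(q: np.ndarray, alpha: float) -> float:
    n, K = q.shape
    return n * (lgamma(K * alpha) - K * lgamma(alpha)) + (alpha - 1.0) * float(
        np.log(q).sum()
    )


def gibbs_sample(
    m: MarkerMatrix | np.ndarray,
    K: int,
    burn_in: int = 10_000,
    n_iter: int = 20_000,
    seed: int | None = None,
    *,
    alpha_init: float = 1.0,
    alpha_max: float = 10.0,
    alpha_step: float = 0.05,
    update_alpha: bool = True,
    thin: int = 10,
) -> AdmixtureRun:
    """Run the Gibbs sampler at a fixed cluster count K.

    Returns posterior means of Q and P plus the thinned log-likelihood
    trace.  Deterministic given ``seed``.  The reference program's
    million-sweep settings are supported; the binary-locus model mixes
    fast, so the defaults here are deliberately smaller.
    """
    x = (m.values if isinstance(m, MarkerMatrix) else np.asarray(m)).astype(np.int8)
    n, L = x.shape
    if not 1 <= K <= n:
        raise ValidationError(f"K must be in [1, {n}], got {K}")
    if burn_in < 1 or n_iter < 1:
        raise ValidationError("burn_in and n_iter must be >= 1")
    if x.std() == 0:
        logger.warning("all-identical band data: posterior is prior-dominated")
    rng = np.random.default_rng(seed)

    alpha = float(alpha_init)
    p = rng.beta(1.0, 1.0, size=(K, L))
    q = rng.dirichlet(np.full(K, alpha), size=n)
    x1 = x == 1

    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L))
    lnls: list[float] = []
    alphas: list[float] = []
    n_rec = 0

    total = burn_in + n_iter
    for sweep in range(total):
        # z | p, q  --- per-locus cluster origins
        pw = np.where(x1[:, :, None], p.T[None, :, :], (1.0 - p).T[None, :, :])
        w = q[:, None, :] * pw  # (n, L, K)
        cum = np.cumsum(w, axis=2)
        u = rng.random((n, L, 1)) * cum[:, :, -1:]
        z = (cum < u).sum(axis=2)  # (n, L) in 0..K-1

        # p | z, x  --- Beta(1,1) conjugate update
        onehot_eq = z[:, :, None] == np.arange(K)[None, None, :]  # (n, L, K)
        t = onehot_eq.sum(axis=0).T.astype(float)  # (K, L) assignments
        s = (x1[:, :, None] & onehot_eq).sum(axis=0).T.astype(float)  # presences
        p = rng.beta(1.0 + s, 1.0 + (t - s))
        np.clip(p, 1e-9, 1.0 - 1e-9, out=p)

        # q | z  --- Dirichlet conjugate update via gamma draws
        counts = onehot_eq.sum(axis=1).astype(float)  # (n, K)
        g = rng.gamma(alpha + counts)
        g = np.clip(g, 1e-300, None)
        q = g / g.sum(axis=1, keepdims=True)

        # alpha --- random-walk Metropolis on log alpha, uniform prior
        if update_alpha and K > 1:
            prop = alpha * np.exp(alpha_step * rng.standard_normal())
            if 0.0 < prop <= alpha_max:
                delta = (
                    _dirichlet_loglik(q, prop)
                    - _dirichlet_loglik(q, alpha)
                    + log(prop)
                    - log(alpha)  # Jacobian of the log transform
                )
                if log(rng.random()) < delta:
                    alpha = prop

        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            lnls.append(_loglik(x, q, p))
            alphas.append(alpha)
            q_sum += q
            p_sum += p
            n_rec += 1

    Q = q_sum / n_rec
    Q /= Q.sum(axis=1, keepdims=True)
    P = np.clip(p_sum / n_rec, 1e-9, 1.0 - 1e-9)
    trace = np.asarray(lnls)
    run = AdmixtureRun(
        K=K,
        Q=Q,
        P=P,
        lnL_trace=trace,
        lnPK=estimate_lnPK(trace),
        seed=seed,
        burn_in=burn_in,
        n_iter=n_iter,
        alpha_trace=np.asarray(alphas),
    )
    return run


def estimate_lnPK(trace: np.ndarray | AdmixtureRun) -> float:
    """ln P(X|K) ~= mean(lnL) - var(lnL)/2 over the recorded trace.

    Sample variance (ddof=1).  Needs at least two recorded values.
    """
    if isinstance(trace, AdmixtureRun):
        trace = trace.lnL_trace
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValidationError("trace too short for the variance-corrected estimator")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


@dataclass
class DeltaKTable:
    """Mean/sd of lnP(X|K) per K, the delta-K statistic, and its argmax."""

    table: pd.DataFrame
    optimal_k: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def delta_k(runs_by_k: dict[int, list[AdmixtureRun | float]]) -> DeltaKTable:
    """Evanno delta-K over replicate runs grouped by K.

    ``delta_K = |L(K+1) - 2 L(K) + L(K-1)| / sd(K)`` with L(K) the mean
    lnP(X|K) across replicates and sd over the replicates at K; defined
    only for interior K of a contiguous scan.  A zero sd leaves delta
    undefined at that K (flagged, excluded from the argmax).
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValidationError("need a contiguous K range of length >= 3")
    means, sds = {}, {}
    for k in ks:
        vals = [
            r.lnPK if isinstance(r, AdmixtureRun) else float(r) for r in runs_by_k[k]
        ]
        if len(vals) < 2:
            raise ValidationError(f"need >= 2 replicate runs at K={k}")
        means[k] = float(np.mean(vals))
        sds[k] = float(np.std(vals, ddof=1))
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            second_diff = abs(means[k + 1] - 2.0 * means[k] + means[k - 1])
            if sds[k] > 0:
                dk = second_diff / sds[k]
            else:
                logger.warning("sd of lnP(X|K) is 0 at K=%d: delta-K undefined", k)
        rows.append(
            {"K": k, "mean_lnPK": means[k], "sd_lnPK": sds[k], "delta_K": dk}
        )
    table = pd.DataFrame(rows)
    valid = table["delta_K"].dropna()
    if valid.empty:
        raise ValidationError("delta-K undefined at every interior K")
    optimal_k = int(table.loc[valid.idxmax(), "K"])
    return DeltaKTable(table=table, optimal_k=optimal_k)


def align_labels(runs: list[AdmixtureRun | np.ndarray]) -> list[np.ndarray]:
    """Permute cluster columns of replicate Q matrices to match the first.

    Greedy matching on column correlation; used for averaged ancestry bar
    plots (cluster labels are arbitrary across MCMC runs).
    """
    qs = [r.Q if isinstance(r, AdmixtureRun) else np.asarray(r) for r in runs]
    if len(qs) < 1:
        raise ValidationError("no runs to align")
    ref = qs[0]
    K = ref.shape[1]
    out = [ref]
    for q in qs[1:]:
        if q.shape != ref.shape:
            raise ValidationError("runs must share n and K")
        if K == 1:
            out.append(q)
            continue
        # correlation between every ref column and every candidate column
        a = ref - ref.mean(axis=0)
        b = q - q.mean(axis=0)
        denom = np.outer(np.linalg.norm(a, axis=0), np.linalg.norm(b, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, a.T @ b / denom, 0.0)
        perm = np.full(K, -1)
        used_r, used_c = set(), set()
        for _ in range(K):
            best, bi, bj = -np.inf, -1, -1
            for i in range(K):
                if i in used_r:
                    continue
                for j in range(K):
                    if j in used_c:
                        continue
                    if corr[i, j] > best:
                        best, bi, bj = corr[i, j], i, j
            perm[bi] = bj
            used_r.add(bi)
            used_c.add(bj)
        out.append(q[:, perm])
    return out


def run_k_scan(
    m: MarkerMatrix,
    k_min: int,
    k_max: int,
    replicates: int = 10,
    burn_in: int = 10_000,
    n_iter: int = 20_000,
    seed: int | None = None,
    **sampler_kwargs,
) -> tuple[DeltaKTable, dict[int, list[AdmixtureRun]]]:
    """Replicated runs over K = k_min..k_max plus the delta-K summary."""
    if k_max - k_min < 2:
        raise ValidationError("delta-K needs a K range of length >= 3")
    child_seeds = np.random.SeedSequence(seed).spawn((k_max - k_min + 1) * replicates)
    runs: dict[int, list[AdmixtureRun]] = {}
    i = 0
    for k in range(k_min, k_max + 1):
        runs[k] = []
        for _ in range(replicates):
            s = int(np.random.default_rng(child_seeds[i]).integers(2**31))
            runs[k].append(
                gibbs_sample(m, k, burn_in, n_iter, seed=s, **sampler_kwargs)
            )
            i += 1
    return delta_k(runs), runs
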