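"""Jaccard dissimilarity and nonmetric multidimensional scaling (NMDS).

The band-profile dissimilarity between two individuals is D = 2B/(1+B)
with B the binary Bray-Curtis index B = sum|x_j - x_k| / sum(x_j + x_k);
algebraically D equals the classical Jaccard distance,
mismatching bands / bands present in either individual.

NMDS embeds the dissimilarities in k dimensions (default 3) using only
their rank order: each iteration fits a monotone (isotonic) regression of
the configuration distances onto the dissimilarity ranks and then moves
the configuration by a Guttman (majorization) step, with a backtracking
safeguard so Kruskal stress-1,

    stress = sqrt( sum (d - dhat)^2 / sum d^2 ),

never increases within a start.  A start stops when the stress ratio
between consecutive iterations exceeds ``conv_ratio`` (default 0.999999),
when stress falls below 1e-4, or when it plateaus; the best of many
random starts (the first start is seeded from classical metric scaling)
is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .exceptions import ValidationError
from .marker_data import MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = ["jaccard_dissimilarity", "kruskal_stress", "nmds", "NMDSResult"]


def jaccard_dissimilarity(m: MarkerMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Jaccard dissimilarity matrix of binary band profiles.

    Requires every individual to carry at least one band (guaranteed after
    locus filtering); an all-zero profile makes the index undefined.
    """
    x = m.values if isinstance(m, MarkerMatrix) else np.asarray(m)
    if x.ndim != 2:
        raise ValidationError("expected a 2-D binary matrix")
    empty = x.sum(axis=1) == 0
    if empty.any():
        raise ValidationError(
            f"all-zero band profiles at rows {np.flatnonzero(empty).tolist()[:5]}; "
            "run filter_loci first"
        )
    d = squareform(pdist(x.astype(bool), metric="jaccard"))
    return d


def _monotone_disparities(diss: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Isotonic fit of configuration distances onto dissimilarity ranks.

    Primary treatment of ties: pairs with equal dissimilarity are ordered
    by their current configuration distance, so tied dissimilarities may
    receive different fitted values.
    """
    order = np.lexsort((d, diss))
    fit = isotonic_regression(d[order], increasing=True).x
    dhat = np.empty_like(d)
    dhat[order] = fit
    return dhat


def kruskal_stress(config: np.ndarray, diss: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    A degenerate configuration with all points coincident has stress 1 by
    convention (worst fit).
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[1] < 1:
        raise ValidationError("configuration must be n x k with k >= 1")
    diss_c = squareform(np.asarray(diss, dtype=float), checks=False)
    d = pdist(config)
    denom = float(np.sum(d**2))
    if denom == 0.0:
        logger.warning("degenerate all-coincident configuration: stress = 1")
        return 1.0
    dhat = _monotone_disparities(diss_c, d)
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


@dataclass
class NMDSResult:
    """Best configuration over random starts, with its Kruskal stress-1."""

    configuration: np.ndarray  # (n, k), column-centered
    stress: float
    n_starts_used: int
    best_start_index: int
    converged: bool
    stress_per_start: np.ndarray | None = None
    stress_trace: np.ndarray | None = None  # per-iteration stress of the best start


def _classical_mds(diss: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling: the deterministic first start."""
    n = diss.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (diss**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)


def _one_start(
    x0: np.ndarray,
    diss_c: np.ndarray,
    conv_ratio: float,
    max_iter: int,
    plateau: int,
    stress_floor: float,
) -> tuple[np.ndarray, float, bool, np.ndarray]:
    n = x0.shape[0]
    x = x0 - x0.mean(axis=0)
    d = pdist(x)
    if np.all(d == 0):
        return x, 1.0, False, np.array([1.0])
    stress = kruskal_stress(x, squareform(diss_c, checks=False))
    trace = [stress]
    converged = False
    stall = 0
    for _ in range(max_iter):
        dhat = _monotone_disparities(diss_c, d)
        # Guttman transform: majorization step for fixed disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        bmat = -squareform(ratio, checks=False)
        np.fill_diagonal(bmat, -bmat.sum(axis=1))
        x_new = bmat @ x / n
        d_new = pdist(x_new)
        denom = float(np.sum(d_new**2))
        if denom == 0.0:
            break
        s_new = kruskal_stress(x_new, squareform(diss_c, checks=False))
        if s_new > stress:  # safeguard: stress-1 must not increase
            x_half = 0.5 * (x + x_new)
            s_half = kruskal_stress(x_half, squareform(diss_c, checks=False))
            if s_half < stress:
                x_new, s_new = x_half, s_half
            else:
                converged = True
                break
        ratio_stress = s_new / stress if stress > 0 else 1.0
        improved = stress - s_new > 1e-10
        x, stress, d = x_new, s_new, pdist(x_new)
        trace.append(stress)
        if stress < stress_floor or ratio_stress > conv_ratio:
            converged = True
            break
        stall = 0 if improved else stall + 1
        if stall >= plateau:
            converged = True
            break
    return x - x.mean(axis=0), stress, converged, np.asarray(trace)


def nmds(
    diss: np.ndarray,
    k: int = 3,
    max_starts: int = 20,
    conv_ratio: float = 0.999999,
    seed: int | None = None,
    *,
    max_iter: int = 500,
    plateau: int = 50,
    stress_floor: float = 1e-4,
    stop_stress: float | None = None,
) -> NMDSResult:
    """Nonmetric MDS of a dissimilarity matrix.

    Runs up to ``max_starts`` starts (start 0 from classical metric
    scaling, the rest random Gaussian) and keeps the lowest-stress
    configuration.  ``stop_stress``, if given, ends the search early once
    a start beats that stress (mirrors restart schedules that stop on a
    convergent solution).  Reproducible under a fixed ``seed``.
    """
    diss = np.asarray(diss, dtype=float)
    n = diss.shape[0]
    if diss.shape != (n, n):
        raise ValidationError("dissimilarity matrix must be square")
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} points for a {k}-D embedding")
    if not 0.0 < conv_ratio < 1.0:
        raise ValidationError("conv_ratio must lie in (0, 1)")
    diss_c = squareform(diss, checks=False)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, int, bool, np.ndarray] | None = None
    stresses = []
    n_used = 0
    for s in range(max_starts):
        x0 = _classical_mds(diss, k) if s == 0 else rng.standard_normal((n, k))
        x, stress, conv, trace = _one_start(
            x0, diss_c, conv_ratio, max_iter, plateau, stress_floor
        )
        stresses.append(stress)
        n_used += 1
        if best is None or stress < best[0]:
            best = (stress, x, s, conv, trace)
        if stop_stress is not None and best[0] <= stop_stress:
            break
    assert best is not None
    stress, x, idx, conv, trace = best
    logger.info("nmds: best stress %.4f at start %d of %d", stress, idx, n_used)
    return NMDSResult(
        configuration=x,
        stress=stress,
        n_starts_used=n_used,
        best_start_index=idx,
        converged=conv,
        stress_per_start=np.array(stresses),
        stress_trace=trace,
    )
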