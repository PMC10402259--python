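"""Independent reference implementations used only to check riboclean.

Deliberately naive: direct formula transcriptions, exhaustive enumeration
and grid searches. Nothing here imports the code paths it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup(pvals: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        value = min(pvals[i] * m / rank, 1.0)
        running_min = min(running_min, value)
        adj[i] = running_min
    return adj


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """RLE size factors computed the slow, literal way."""
    eligible = [g for g in range(counts.shape[0]) if all(counts[g] > 0)]
    geomeans = {
        g: math.exp(sum(math.log(c) for c in counts[g]) / counts.shape[1])
        for g in eligible
    }
    factors = []
    for s in range(counts.shape[1]):
        ratios = sorted(counts[g, s] / geomeans[g] for g in eligible)
        n = len(ratios)
        mid = n // 2
        factors.append(ratios[mid] if n % 2 else 0.5 * (ratios[mid - 1] + ratios[mid]))
    return np.array(factors)


def hypergeom_upper_tail(N: int, n1: int, n2: int, k: int) -> float:
    """P[overlap >= k] by summing exact counts of draws, via math.comb."""
    total = math.comb(N, n2)
    acc = 0
    for j in range(k, min(n1, n2) + 1):
        acc += math.comb(n1, j) * math.comb(N - n1, n2 - j)
    return acc / total


def hypergeom_upper_tail_bruteforce(N: int, set_a: set, set_b_size: int, k: int) -> float:
    """P[overlap >= k] by literally enumerating every possible second set."""
    universe = list(range(N))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, set_b_size):
        total += 1
        if len(set_a & set(draw)) >= k:
            hits += 1
    return hits / total


def nb_negloglik_one_group(log_mu: float, y: np.ndarray, sf: np.ndarray,
                           alpha: float) -> float:
    """Exact NB negative log-likelihood of one constant-mean group with offsets."""
    ll = 0.0
    r = 1.0 / alpha
    for yi, si in zip(y, sf):
        mu = si * math.exp(log_mu)
        ll += (
            math.lgamma(yi + r) - math.lgamma(r) - math.lgamma(yi + 1)
            + r * math.log(r / (r + mu)) + yi * math.log(mu / (r + mu))
        )
    return -ll


def nb_mle_two_group_grid(
    y: np.ndarray, sf: np.ndarray, groups: np.ndarray, alpha: float,
    n_refine: int = 14,
) -> tuple[float, float]:
    """Brute-force grid search for the two group log-means (natural log).

    The two groups are variation-independent given the offsets, so each
    log-mean is located by its own 1-D coarse-to-fine grid (61 points per
    pass, bracket shrunk to 4 grid steps each refinement), reaching well
    past 1e-6 resolution.
    """
    out = []
    for g in (0, 1):
        sel = groups == g
        center = math.log(max(np.sum(y[sel]) / np.sum(sf[sel]), 1e-8))
        half = 3.0
        for _ in range(n_refine):
            grid = np.linspace(center - half, center + half, 61)
            vals = [nb_negloglik_one_group(c, y[sel], sf[sel], alpha) for c in grid]
            center = float(grid[int(np.argmin(vals))])
            half = 4 * (grid[1] - grid[0])
        out.append(center)
    return out[0], out[1]


def pca_eigh(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample-space PCA by eigen-decomposition of the Gram matrix.

    ``x`` is samples x features, already centered. Returns (variances,
    coordinates) sorted by decreasing variance.
    """
    gram = x @ x.T / (x.shape[0] - 1)
    w, v = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0, None)
    v = v[:, order]
    coords = v * np.sqrt(w * (x.shape[0] - 1))
    return w, coords
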