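"""Gene-set overlap statistics.

Two statistics used to interpret gene lists against reference sets:

* the exact hypergeometric overlap test with its representation factor
  (observed overlap divided by the chance expectation ``n1*n2/N``; 1 means
  the overlap is exactly what random sampling would give); and
* a resampling z-score for overlap with a reference ("operon") set: the
  observed overlap of a query list is compared to the mean/sd of overlaps
  of random same-size gene sets drawn from an expressed-gene background.
  A stringent specificity call uses z > 5.

The resampling default is K=1000 random sets; ``paper_mode=True`` uses
K=10, the minimal historical procedure, whose sd estimate is unstable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "OperonZResult",
    "hypergeom_overlap",
    "overlap_table",
    "operon_zscore",
    "operon_zscore_table",
]


@dataclass
class OverlapResult:
    """Hypergeometric overlap of two gene sets in a universe of size N."""

    universe_size: int
    n1: int
    n2: int
    overlap: int
    expected: float
    representation_factor: float   # NaN when the expectation is zero
    p: float                       # upper tail, P[K >= k]

    def as_dict(self) -> dict:
        return {
            "universe_size": self.universe_size, "n1": self.n1, "n2": self.n2,
            "overlap": self.overlap, "expected": self.expected,
            "representation_factor": self.representation_factor, "p": self.p,
        }


@dataclass
class OperonZResult:
    """Resampling z-score for the overlap of a query with one reference set."""

    name: str
    query_size: int
    set_size: int
    overlap: int
    null_mean: float
    null_sd: float
    z: float                       # NaN when null_sd == 0 (flagged undefined)
    n_resamples: int
    passes: bool

    def as_dict(self) -> dict:
        return {
            "name": self.name, "query_size": self.query_size,
            "set_size": self.set_size, "overlap": self.overlap,
            "null_mean": self.null_mean, "null_sd": self.null_sd,
            "z": self.z, "n_resamples": self.n_resamples, "passes": self.passes,
        }


def hypergeom_overlap(
    set_a: set[str], set_b: set[str], universe: set[str] | int
) -> OverlapResult:
    """Exact upper-tail hypergeometric test of the overlap of two gene sets.

    ``universe`` is either the explicit background gene set (members of
    ``set_a``/``set_b`` outside it are dropped with a logged count) or its
    size, in which case both sets are trusted to lie inside it.
    """
    set_a, set_b = set(set_a), set(set_b)
    if isinstance(universe, int):
        N = universe
        if N <= 0:
            raise ContractError("universe size must be positive")
        if max(len(set_a), len(set_b)) > N:
            raise ContractError("a set is larger than the stated universe size")
    else:
        universe = set(universe)
        if not universe:
            raise ContractError("empty universe")
        N = len(universe)
        dropped = len(set_a - universe) + len(set_b - universe)
        if dropped:
            logger.warning("dropped %d set members outside the universe", dropped)
        set_a &= universe
        set_b &= universe
    n1, n2 = len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = n1 * n2 / N
    if n1 == 0 or n2 == 0:
        return OverlapResult(N, n1, n2, 0, expected, math.nan, 1.0)
    rf = k / expected
    p = float(stats.hypergeom.sf(k - 1, N, n1, n2))
    p = min(max(p, 0.0), 1.0)
    if p == 0.0:  # guard against underflow: an exact tail is in (0, 1]
        p = float(np.nextafter(0.0, 1.0))
    return OverlapResult(N, n1, n2, k, expected, rf, p)


def overlap_table(
    query: set[str], sets: GeneSetCollection, universe: set[str] | int
) -> pd.DataFrame:
    """One hypergeometric overlap row per set in the collection."""
    rows = []
    for name in sets.names():
        res = hypergeom_overlap(query, sets[name], universe)
        rows.append({"set": name, **res.as_dict()})
    return pd.DataFrame(rows).set_index("set")


# ---------------------------------------------------------------------------
# resampling z-score
# ---------------------------------------------------------------------------

def _draw_subsets(
    n_items: int, subset_size: int, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of uniform random ``subset_size``-subsets of ``range(n_items)``.

    Drawn without replacement by ranking i.i.d. random keys, chunked to
    bound memory; returns an (n_resamples, subset_size) index array.
    """
    out = np.empty((n_resamples, subset_size), dtype=np.int64)
    chunk = max(1, min(n_resamples, int(2e7) // max(n_items, 1)))
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        keys = rng.random((b, n_items))
        out[done:done + b] = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
        done += b
    return out


def _null_overlaps(
    background: np.ndarray, query_size: int, member_mask: np.ndarray,
    n_resamples: int, rng: np.random.Generator,
) -> np.ndarray:
    """Overlap counts of random query-sized background subsets with a set."""
    idx = _draw_subsets(len(background), query_size, n_resamples, rng)
    return member_mask[idx].sum(axis=1)


def operon_zscore(
    query_set: set[str],
    operon_set: set[str],
    background_expressed: set[str] | list[str],
    n_resamples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    name: str = "operon",
    z_threshold: float = 5.0,
    paper_mode: bool = False,
) -> OperonZResult:
    """Resampling z-score of a query list's overlap with one reference set.

    Draws ``n_resamples`` uniform random subsets of ``background_expressed``
    of the query's size, computes their overlaps with ``operon_set``, and
    standardises the observed overlap by the sample mean and sd (K-1
    denominator) of those null overlaps. Deterministic given a seed.
    """
    if paper_mode:
        n_resamples = 10
    if n_resamples < 2:
        raise ContractError("n_resamples must be >= 2 for a defined sd")
    if not operon_set:
        raise ContractError("operon set is empty")
    background = np.asarray(sorted(set(background_expressed)))
    if len(set(query_set)) > len(background):
        raise ContractError("background is smaller than the query")
    query = set(query_set) & set(background)
    dropped = len(set(query_set)) - len(query)
    if dropped:
        logger.warning("dropped %d query genes outside the background", dropped)
    if not query:
        raise ContractError("query has no genes inside the background")
    if rng is None:
        if seed is None:
            raise ContractError("a seed (or rng) is required for resampling")
        rng = np.random.default_rng(seed)
    member_mask = np.isin(background, sorted(set(operon_set)))
    k_obs = len(query & set(operon_set))
    nulls = _null_overlaps(background, len(query), member_mask, n_resamples, rng)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    z = (k_obs - null_mean) / null_sd if null_sd > 0 else math.nan
    return OperonZResult(
        name=name, query_size=len(query), set_size=int(member_mask.sum()),
        overlap=k_obs, null_mean=null_mean, null_sd=null_sd, z=z,
        n_resamples=n_resamples, passes=bool(null_sd > 0 and z > z_threshold),
    )


def operon_zscore_table(
    query_set: set[str],
    sets: GeneSetCollection,
    background_expressed: set[str] | list[str],
    n_resamples: int = 1000,
    seed: int | None = None,
    z_threshold: float = 5.0,
    shared_draws: bool = True,
    paper_mode: bool = False,
) -> pd.DataFrame:
    """z-scores of one query against every set in a collection.

    With ``shared_draws=True`` (default) one list of random background
    subsets is drawn and reused for every set, so the per-set nulls are
    computed on identical resamples; otherwise each set gets fresh draws.
    """
    if paper_mode:
        n_resamples = 10
    if seed is None:
        raise ContractError("a seed is required for resampling")
    rows = []
    if shared_draws:
        background = np.asarray(sorted(set(background_expressed)))
        query = set(query_set) & set(background)
        if len(background) < len(query) or not query:
            raise ContractError("background must contain the (nonempty) query")
        rng = np.random.default_rng(seed)
        N, n = len(background), len(query)
        if n_resamples < 2:
            raise ContractError("n_resamples must be >= 2 for a defined sd")
        idx = _draw_subsets(N, n, n_resamples, rng)
        for name in sets.names():
            operon = sets[name]
            if not operon:
                raise ContractError(f"operon set {name!r} is empty")
            mask = np.isin(background, sorted(operon))
            nulls = mask[idx].sum(axis=1)
            k_obs = len(query & operon)
            m, s = float(nulls.mean()), float(nulls.std(ddof=1))
            z = (k_obs - m) / s if s > 0 else math.nan
            rows.append(OperonZResult(
                name=name, query_size=n, set_size=int(mask.sum()), overlap=k_obs,
                null_mean=m, null_sd=s, z=z, n_resamples=n_resamples,
                passes=bool(s > 0 and z > z_threshold),
            ).as_dict())
    else:
        rng = np.random.default_rng(seed)
        for name in sets.names():
            res = operon_zscore(
                query_set, sets[name], background_expressed,
                n_resamples=n_resamples, rng=rng, name=name, z_threshold=z_threshold,
            )
            rows.append(res.as_dict())
    return pd.DataFrame(rows).set_index("name")
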