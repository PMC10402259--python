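"""Library-size normalization and low-count filtering.

RLE (relative log expression, a.k.a. median-of-ratios) size factors: for
each sample, the median over genes of the ratio of its count to that gene's
geometric mean across samples. Only genes with a nonzero count in every
sample enter the median by default; the ``pseudo_reference`` fallback uses
the geometric mean over positive counts instead when no such gene exists.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .io import CountMatrix

logger = logging.getLogger(__name__)


def rle_size_factors(
    counts: CountMatrix | pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Factors are not rescaled further: multiplying every count by a constant
    multiplies every factor by that constant.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    if pseudo_reference:
        pos = arr > 0
        eligible = pos.any(axis=1)
        with np.errstate(divide="ignore"):
            logs = np.where(pos, np.log(np.where(pos, arr, 1.0)), 0.0)
        log_ref = logs.sum(axis=1) / np.maximum(pos.sum(axis=1), 1)
    else:
        eligible = (arr > 0).all(axis=1)
        if not eligible.any():
            raise NormalizationError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        log_ref = np.log(arr[eligible]).mean(axis=1)
        arr = arr[eligible]
        with np.errstate(divide="ignore"):
            ratios = np.exp(np.log(arr) - log_ref[:, None])
        return pd.Series(np.median(ratios, axis=0), index=df.columns, name="size_factor")
    arr = arr[eligible]
    log_ref = log_ref[eligible]
    pos = arr > 0
    log_ratios = np.where(pos, np.log(np.where(pos, arr, 1.0)), np.nan)
    log_ratios = log_ratios - log_ref[:, None]
    # median over the genes actually observed in each sample
    factors = np.exp(np.nanmedian(log_ratios, axis=0))
    if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
        raise NormalizationError("degenerate size factors; counts too sparse")
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalized_counts(
    counts: CountMatrix | pd.DataFrame, size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """Counts divided by their sample's RLE size factor."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if size_factors is None:
        size_factors = rle_size_factors(df)
    return df / size_factors


def filter_low_counts(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes with fewer than ``min_total`` counts summed over samples.

    Gene order is preserved; ``min_total=0`` is the identity.
    """
    keep = counts.counts.sum(axis=1) >= min_total
    if not keep.any():
        logger.warning("low-count filter removed every gene (min_total=%d)", min_total)
    return CountMatrix(counts.counts.loc[keep], counts.meta)
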