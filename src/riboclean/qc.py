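"""Experiment-level quality checks.

Three diagnostics that a paired IP/input experiment should pass before any
differential analysis is trusted:

* qPCR-style ddCT fold enrichment of marker transcripts (IP relative to its
  paired input, normalised to reference genes): ``fold = 2**(-ddCT)`` with
  ``ddCT = (Ct_target_IP - Ct_ref_IP) - (Ct_target_input - Ct_ref_input)``;
  multiple reference genes are combined by averaging their Ct values before
  differencing.
* count-based marker-panel enrichment: per IP/input pair, the ratio of
  RLE-normalised counts (+1 pseudo-count) for each marker, summarised per
  cell type by the median; the tagged cell type's markers should be
  enriched (median fold > 1) and other cell types depleted.
* a PCA summary of log2(normalised count + 1) profiles: variance explained
  per component and per-sample coordinates. In a clean experiment the
  IP/input axis dominates PC1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import CountMatrix, GeneSetCollection
from .norm import normalized_counts, rle_size_factors

__all__ = ["QCReport", "ddct_fold", "marker_enrichment", "pca_summary", "PCASummary"]


def ddct_fold(
    ct_target_ip: float,
    ct_ref_ip: float | np.ndarray | list[float],
    ct_target_input: float,
    ct_ref_input: float | np.ndarray | list[float],
) -> float:
    """ddCT fold change of a target transcript in IP relative to input."""
    ref_ip = float(np.mean(ct_ref_ip))
    ref_in = float(np.mean(ct_ref_input))
    if not all(np.isfinite([ct_target_ip, ref_ip, ct_target_input, ref_in])):
        raise ContractError("Ct values must be finite")
    ddct = (ct_target_ip - ref_ip) - (ct_target_input - ref_in)
    return float(2.0 ** (-ddct))


@dataclass
class QCReport:
    """Marker-panel enrichment summary.

    ``folds``: tidy table (pair, cell_type, gene, fold); ``median_folds``:
    per-cell-type median IP/input fold; ``verdicts``: "enriched" if the
    median fold is >= 1 else "depleted"; ``n_missing``: panel genes absent
    from the count matrix (dropped with a warning).
    """

    folds: pd.DataFrame
    median_folds: pd.Series
    verdicts: pd.Series
    n_missing: int


def marker_enrichment(
    cm: CountMatrix,
    panel: GeneSetCollection,
    size_factors: pd.Series | None = None,
    pseudo_count: float = 1.0,
) -> QCReport:
    """Count-based IP/input marker enrichment per cell type.

    For every IP sample with a paired input, each marker's fold is
    ``(norm_IP + pc) / (norm_input + pc)`` on RLE-normalised counts.
    """
    if size_factors is None:
        size_factors = rle_size_factors(cm)
    norm = normalized_counts(cm, size_factors)
    meta = cm.meta
    pairs = []
    for sample, row in meta[meta["fraction"] == "IP"].iterrows():
        partner = meta[
            (meta["pair_id"] == row["pair_id"]) & (meta["fraction"] == "input")
        ]
        if len(partner) == 1:
            pairs.append((row["pair_id"], sample, partner.index[0]))
    if not pairs:
        raise ContractError("no paired IP/input samples found")
    n_missing = 0
    rows = []
    for cell_type in panel.names():
        markers = sorted(panel[cell_type])
        present = [g for g in markers if g in norm.index]
        n_missing += len(markers) - len(present)
        for pair_id, ip, inp in pairs:
            fold = (norm.loc[present, ip] + pseudo_count) / (
                norm.loc[present, inp] + pseudo_count
            )
            for g, f in fold.items():
                rows.append({
                    "pair": pair_id, "cell_type": cell_type, "gene": g, "fold": f,
                })
    folds = pd.DataFrame(rows)
    median_folds = folds.groupby("cell_type")["fold"].median()
    verdicts = pd.Series(
        np.where(median_folds >= 1.0, "enriched", "depleted"),
        index=median_folds.index, name="verdict",
    )
    return QCReport(folds=folds, median_folds=median_folds,
                    verdicts=verdicts, n_missing=n_missing)


@dataclass
class PCASummary:
    """Variance explained and sample coordinates of an expression PCA."""

    variance_fraction: np.ndarray      # non-increasing, sums to <= 1
    coordinates: pd.DataFrame          # samples x components


def pca_summary(
    cm: CountMatrix,
    size_factors: pd.Series | None = None,
    n_components: int | None = None,
    scale: bool = False,
) -> PCASummary:
    """PCA of log2(normalised count + 1) sample profiles.

    Features (genes) are centered; with ``scale=True`` they are also divided
    by their standard deviation. A constant matrix yields an all-zero
    variance report rather than an error.
    """
    if cm.n_samples < 2:
        raise ContractError("PCA needs at least two samples")
    x = np.log2(normalized_counts(cm, size_factors).to_numpy().T + 1.0)  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    total_var = (x ** 2).sum() / (x.shape[0] - 1)
    k = n_components or min(x.shape[0] - 1, 10)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u * s
    var = s ** 2 / (x.shape[0] - 1)
    frac = var / total_var if total_var > 0 else np.zeros_like(var)
    k = min(k, len(s))
    return PCASummary(
        variance_fraction=frac[:k],
        coordinates=pd.DataFrame(
            coords[:, :k], index=cm.sample_ids,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
    )
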