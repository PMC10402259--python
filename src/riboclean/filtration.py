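"""Enrichment classification and two-arm contamination filtration.

A DE call made in the IP fraction can be driven by the ambient pool rather
than the tagged cell type (e.g. inflammatory transcripts surging after
injury co-purify with the beads). The two-arm filter keeps a DE gene only if

* arm 1: its IP/input enrichment itself changed after injury, in the same
  direction as the expression change (|delta| above threshold, significant), or
* arm 2: it is constantly highly enriched in the tagged cell type — at the
  reference condition AND at the injury condition under test (optionally at
  every timepoint) — so the tagged cells are its major expressors and the
  total-RNA change still reflects their response.

Thresholds follow the translatome-analysis convention: DE |log2FC| >= 1 at
q <= 0.05; enrichment classes at +/-0.5 and +2.0; arm-1 |delta| >= 1; arm-2
enrichment >= 1. Exact threshold ties pass (inclusive comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ContractError
from .de import InteractionResult
from .glm import DEResult

__all__ = [
    "Thresholds",
    "EnrichmentProfile",
    "FiltrationReport",
    "classify_enrichment",
    "two_arm_filter",
    "acute_specific_set",
]


@dataclass
class Thresholds:
    """All cutoffs applied by classification and filtration, in log2 units."""

    de_lfc: float = 1.0          # |Log2FC(reference)| for a DE call
    enrich_lfc: float = 0.5      # enriched / depleted boundary
    high_enrich_lfc: float = 2.0  # highly selective expression
    arm2_lfc: float = 1.0        # "preferential expression" for arm 2
    delta_lfc: float = 1.0       # |delta enrichment| for arm 1
    q: float = 0.05
    arm2_mode: str = "endpoints"  # or "all": enriched at every timepoint

    def __post_init__(self) -> None:
        for name in ("de_lfc", "enrich_lfc", "high_enrich_lfc", "arm2_lfc", "delta_lfc"):
            if getattr(self, name) <= 0:
                raise ContractError(f"threshold {name} must be positive")
        if not (0 < self.q < 1):
            raise ContractError("q threshold must lie in (0, 1)")
        if self.arm2_mode not in ("endpoints", "all"):
            raise ContractError("arm2_mode must be 'endpoints' or 'all'")

    def as_dict(self) -> dict:
        return asdict(self)


CLASSES = ("depleted", "neutral", "enriched", "highly_selective")


@dataclass
class EnrichmentProfile:
    """Per-gene, per-condition IP/input enrichment with significance and class.

    ``log2_enrich`` and ``q`` are genes x conditions; ``classification``
    holds one of ``depleted | neutral | enriched | highly_selective``:
    significance-gated (non-significant genes are neutral regardless of the
    estimate) and deterministic given the thresholds.
    """

    log2_enrich: pd.DataFrame
    q: pd.DataFrame
    classification: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def conditions(self) -> list[str]:
        return list(self.log2_enrich.columns)

    def class_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: self.classification[c].value_counts().reindex(CLASSES, fill_value=0)
             for c in self.conditions}
        )

    def table(self) -> pd.DataFrame:
        frames = []
        for c in self.conditions:
            frames.append(pd.DataFrame({
                "gene": self.log2_enrich.index,
                "condition": c,
                "log2_enrich": self.log2_enrich[c].to_numpy(),
                "q": self.q[c].to_numpy(),
                "classification": self.classification[c].to_numpy(),
            }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   thresholds: "Thresholds | None" = None) -> "EnrichmentProfile":
        """Rebuild a profile from its tidy :meth:`table` representation."""
        if "gene" not in table.columns:
            table = table.reset_index()
        lfc = table.pivot(index="gene", columns="condition", values="log2_enrich")
        q = table.pivot(index="gene", columns="condition", values="q")
        cond_order = list(dict.fromkeys(table["condition"]))
        lfc, q = lfc[cond_order], q[cond_order]
        cls_tab = table.pivot(index="gene", columns="condition",
                              values="classification")[cond_order]
        # preserve the writer's gene order
        gene_order = list(dict.fromkeys(table["gene"]))
        return cls(log2_enrich=lfc.loc[gene_order], q=q.loc[gene_order],
                   classification=cls_tab.loc[gene_order],
                   thresholds=thresholds or Thresholds())


def classify_enrichment(
    enrich_by_condition: dict[str, DEResult],
    thresholds: Thresholds | None = None,
) -> EnrichmentProfile:
    """Label each gene per condition from its IP-vs-input Wald results."""
    thresholds = thresholds or Thresholds()
    if not enrich_by_condition:
        raise ContractError("no per-condition enrichment results supplied")
    conditions = list(enrich_by_condition)
    genes = enrich_by_condition[conditions[0]].table.index
    for c, res in enrich_by_condition.items():
        if not res.table.index.equals(genes):
            raise ContractError(f"condition {c!r} covers a different gene universe")
    lfc = pd.DataFrame({c: enrich_by_condition[c].table["log2fc"] for c in conditions})
    q = pd.DataFrame({c: enrich_by_condition[c].table["q"] for c in conditions})
    sig = q.to_numpy() <= thresholds.q
    e = lfc.to_numpy()
    cls = np.full(e.shape, "neutral", dtype=object)
    cls[sig & (e <= -thresholds.enrich_lfc)] = "depleted"
    cls[sig & (e >= thresholds.enrich_lfc)] = "enriched"
    cls[sig & (e >= thresholds.high_enrich_lfc)] = "highly_selective"
    return EnrichmentProfile(
        log2_enrich=lfc, q=q,
        classification=pd.DataFrame(cls, index=genes, columns=conditions),
        thresholds=thresholds,
    )


@dataclass
class FiltrationReport:
    """Arm-by-arm flags and the final high-confidence call for one condition.

    ``table`` columns: gene index plus ``log2fc``, ``q_de``, ``delta``,
    ``q_delta``, ``log2_enrich_ref``, ``log2_enrich_cond``, ``de_pass``,
    ``direction`` (up/down/none), ``arm1``, ``arm2``, ``final``.
    ``final = de_pass AND (arm1 OR arm2)``.
    """

    condition: str
    reference: str
    table: pd.DataFrame
    thresholds: Thresholds

    def passing(self, direction: str | None = None) -> pd.Index:
        t = self.table
        mask = t["final"].to_numpy(copy=True)
        if direction is not None:
            mask &= (t["direction"] == direction).to_numpy()
        return t.index[mask]

    def summary(self) -> dict:
        t = self.table
        return {
            "condition": self.condition,
            "n_genes": len(t),
            "n_de": int(t["de_pass"].sum()),
            "n_de_up": int((t["de_pass"] & (t["direction"] == "up")).sum()),
            "n_de_down": int((t["de_pass"] & (t["direction"] == "down")).sum()),
            "n_arm1": int((t["de_pass"] & t["arm1"]).sum()),
            "n_arm2": int((t["de_pass"] & t["arm2"]).sum()),
            "n_final": int(t["final"].sum()),
            "n_final_up": int((t["final"] & (t["direction"] == "up")).sum()),
            "n_final_down": int((t["final"] & (t["direction"] == "down")).sum()),
        }


def two_arm_filter(
    de: DEResult,
    delta: InteractionResult,
    enrich: EnrichmentProfile,
    thresholds: Thresholds | None = None,
    reference: str = "naive",
) -> FiltrationReport:
    """Apply the two-arm filter for one injury condition.

    ``de`` is the IP-fraction condition-vs-reference result, ``delta`` the
    matching interaction result and ``enrich`` the per-condition enrichment
    profile (must include the reference and the tested condition). All three
    must share one gene universe.
    """
    thresholds = thresholds or Thresholds()
    condition = delta.condition
    genes = de.table.index
    offending = genes.symmetric_difference(delta.table.index)
    if len(offending) or not genes.equals(delta.table.index):
        raise ContractError(f"DE/delta gene universes differ: {list(offending)[:5]}")
    if not genes.equals(enrich.log2_enrich.index):
        off = genes.symmetric_difference(enrich.log2_enrich.index)
        raise ContractError(f"DE/enrichment gene universes differ: {list(off)[:5]}")
    for cond in (reference, condition):
        if cond not in enrich.conditions:
            raise ContractError(f"enrichment profile lacks condition {cond!r}")

    lfc = de.table["log2fc"].to_numpy()
    q_de = de.table["q"].to_numpy()
    d = delta.table["delta"].to_numpy()
    q_d = delta.table["q"].to_numpy()

    de_pass = (np.abs(lfc) >= thresholds.de_lfc) & (q_de <= thresholds.q)
    direction = np.where(de_pass, np.where(lfc > 0, "up", "down"), "none")

    arm1 = (
        (np.abs(d) >= thresholds.delta_lfc)
        & (q_d <= thresholds.q)
        & (np.sign(d) == np.sign(lfc))
    )
    if thresholds.arm2_mode == "all":
        arm2_conditions = enrich.conditions
    else:
        arm2_conditions = [reference, condition]
    arm2 = np.ones(len(genes), dtype=bool)
    for cond in arm2_conditions:
        arm2 &= (
            (enrich.log2_enrich[cond].to_numpy() >= thresholds.arm2_lfc)
            & (enrich.q[cond].to_numpy() <= thresholds.q)
        )
    final = de_pass & (arm1 | arm2)
    table = pd.DataFrame(
        {
            "condition": condition,
            "log2fc": lfc,
            "q_de": q_de,
            "delta": d,
            "q_delta": q_d,
            "log2_enrich_ref": enrich.log2_enrich[reference].to_numpy(),
            "log2_enrich_cond": enrich.log2_enrich[condition].to_numpy(),
            "de_pass": de_pass,
            "direction": direction,
            "arm1": arm1,
            "arm2": arm2,
            "final": final,
        },
        index=genes,
    )
    return FiltrationReport(
        condition=condition, reference=reference, table=table, thresholds=thresholds
    )


def acute_specific_set(
    filtered_acute: FiltrationReport,
    filtered_late: FiltrationReport,
    de_acute: DEResult,
    de_late: DEResult,
    q: float = 0.05,
    fold_drop: float = 1.0,
) -> list[str]:
    """Genes whose upregulation is acute-phase specific.

    Starting from genes passing the acute up-filter, keep those that at the
    late timepoint are either not significantly changed (q above threshold)
    or whose late log2FC is at least ``fold_drop`` log2 units (two-fold by
    default) below the acute log2FC.
    """
    up = filtered_acute.passing("up")
    q_late = de_late.table.loc[up, "q"]
    lfc_late = de_late.table.loc[up, "log2fc"]
    lfc_acute = de_acute.table.loc[up, "log2fc"]
    keep = (q_late > q) | (lfc_late <= lfc_acute - fold_drop)
    return list(up[keep.to_numpy()])
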