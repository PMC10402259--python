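"""Differential expression and differential enrichment contrasts.

Three analyses over a paired IP/input count matrix, all backed by the NB GLM
in :mod:`riboclean.glm`:

* ``de_between_conditions`` — injury vs reference within one fraction
  (Log2FC(naive) in the IP fraction is the translatome DE signal);
* ``enrichment_for_condition`` — IP vs input within one condition
  (Log2FC(Total), the cell-type enrichment of a transcript);
* ``differential_enrichment`` — the fraction x condition interaction
  coefficient, i.e. delta Log2FC(Total) = Log2FC(Total)_injury -
  Log2FC(Total)_reference, with positive values meaning enrichment
  increased after injury.

Size factors are normally estimated once on the full matrix and passed to
every contrast so all fold-changes share one normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .glm import DEResult, NBGLMFit, fit_nb_glm, lrt_full_vs_reduced, wald_contrast
from .io import CountMatrix
from .norm import rle_size_factors

__all__ = [
    "InteractionResult",
    "make_design",
    "de_between_conditions",
    "enrichment_for_condition",
    "differential_enrichment",
    "lrt_any_interaction",
]


@dataclass
class InteractionResult:
    """Per-gene change of IP/input enrichment between a condition and reference.

    ``table`` columns: ``delta`` (log2 enrichment change), ``se``, ``stat``,
    ``p``, ``q``, ``mean_norm_count``, ``flag``.
    """

    condition: str
    reference: str
    table: pd.DataFrame


def make_design(
    meta: pd.DataFrame,
    condition_ref: str | None = None,
    fraction: bool = False,
    interaction: bool = False,
    paired: bool = False,
) -> pd.DataFrame:
    """Build a numeric design matrix from sample metadata.

    Columns: intercept, condition dummies relative to ``condition_ref``,
    optionally ``fraction_IP``, optionally interaction columns
    ``fraction_IP:cond_<c>``. With ``paired=True``, pair-id dummies replace
    the condition main effects (pairs are nested within conditions), which
    turns the tissue pair into a blocking fixed effect.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    conditions = list(dict.fromkeys(meta["condition"]))
    if condition_ref is not None:
        if condition_ref not in conditions:
            raise DesignError(f"reference condition {condition_ref!r} absent from samples")
        others = [c for c in conditions if c != condition_ref]
    else:
        others = []
    if paired:
        pairs = list(dict.fromkeys(meta["pair_id"]))
        for pid in pairs[1:]:
            cols[f"pair_{pid}"] = (meta["pair_id"] == pid).to_numpy(float)
    else:
        for c in others:
            cols[f"cond_{c}"] = (meta["condition"] == c).to_numpy(float)
    if fraction:
        cols["fraction_IP"] = (meta["fraction"] == "IP").to_numpy(float)
    if interaction:
        if not fraction:
            raise DesignError("interaction requires the fraction main effect")
        for c in others:
            cols[f"fraction_IP:cond_{c}"] = (
                ((meta["fraction"] == "IP") & (meta["condition"] == c)).to_numpy(float)
            )
    return pd.DataFrame(cols, index=meta.index)


def _subset(
    cm: CountMatrix,
    conditions: list[str] | None = None,
    fraction: str | None = None,
) -> CountMatrix:
    mask = pd.Series(True, index=cm.sample_ids)
    if conditions is not None:
        mask &= cm.meta["condition"].isin(conditions)
    if fraction is not None:
        mask &= cm.meta["fraction"] == fraction
    if not mask.any():
        raise DesignError("no samples left after condition/fraction selection")
    return cm.subset_samples(mask)


def _sf(cm: CountMatrix, size_factors: pd.Series | None) -> pd.Series:
    if size_factors is None:
        return rle_size_factors(cm)
    return size_factors.loc[cm.sample_ids]


def de_between_conditions(
    cm: CountMatrix,
    condition: str,
    reference: str = "naive",
    fraction: str = "IP",
    size_factors: pd.Series | None = None,
    **fit_kwargs,
) -> DEResult:
    """Wald DE of ``condition`` vs ``reference`` within one fraction."""
    sub = _subset(cm, [reference, condition], fraction)
    if condition not in set(sub.meta["condition"]) or reference not in set(
        sub.meta["condition"]
    ):
        raise DesignError(f"both {condition!r} and {reference!r} must have samples")
    design = make_design(sub.meta, condition_ref=reference)
    fit = fit_nb_glm(sub, design, size_factors=_sf(sub, size_factors), **fit_kwargs)
    res = wald_contrast(fit, f"cond_{condition}", name=f"{fraction}:{condition}-vs-{reference}")
    return res


def enrichment_for_condition(
    cm: CountMatrix,
    condition: str,
    size_factors: pd.Series | None = None,
    **fit_kwargs,
) -> DEResult:
    """Wald IP-vs-input enrichment (Log2FC(Total)) within one condition."""
    sub = _subset(cm, [condition])
    fracs = set(sub.meta["fraction"])
    if fracs != {"IP", "input"}:
        raise DesignError(f"condition {condition!r} lacks a fraction: has {sorted(fracs)}")
    design = make_design(sub.meta, fraction=True)
    fit = fit_nb_glm(sub, design, size_factors=_sf(sub, size_factors), **fit_kwargs)
    return wald_contrast(fit, "fraction_IP", name=f"enrichment:{condition}")


def differential_enrichment(
    cm: CountMatrix,
    condition: str,
    reference: str = "naive",
    size_factors: pd.Series | None = None,
    paired: bool = False,
    **fit_kwargs,
) -> InteractionResult:
    """Fraction x condition interaction: change of enrichment after injury.

    Fits ``~ condition + fraction + fraction:condition`` on the four sample
    groups (both fractions of ``condition`` and ``reference``); the
    interaction coefficient equals Log2FC(IP/input) in ``condition`` minus
    Log2FC(IP/input) in ``reference``.
    """
    sub = _subset(cm, [reference, condition])
    for cond in (reference, condition):
        fracs = set(sub.meta.loc[sub.meta["condition"] == cond, "fraction"])
        if fracs != {"IP", "input"}:
            raise DesignError(f"condition {cond!r} lacks a fraction: has {sorted(fracs)}")
    design = make_design(
        sub.meta, condition_ref=reference, fraction=True, interaction=True, paired=paired
    )
    fit = fit_nb_glm(sub, design, size_factors=_sf(sub, size_factors), **fit_kwargs)
    res = wald_contrast(
        fit, f"fraction_IP:cond_{condition}", name=f"delta-enrichment:{condition}"
    )
    table = res.table.rename(columns={"log2fc": "delta"})
    return InteractionResult(condition=condition, reference=reference, table=table)


def lrt_any_interaction(
    cm: CountMatrix,
    reference: str = "naive",
    size_factors: pd.Series | None = None,
    **fit_kwargs,
) -> DEResult:
    """LRT for an RNA-origin-specific effect at one or more timepoints.

    Compares the full model (condition + fraction + all fraction:condition
    interactions) to the reduced additive model across every condition in
    the matrix; df equals the number of non-reference conditions.
    """
    sf = _sf(cm, size_factors)
    full = make_design(cm.meta, condition_ref=reference, fraction=True, interaction=True)
    reduced = make_design(cm.meta, condition_ref=reference, fraction=True)
    fit_full = fit_nb_glm(cm, full, size_factors=sf, **fit_kwargs)
    fit_reduced = fit_nb_glm(
        cm, reduced, size_factors=sf,
        dispersion=fit_full.dispersion, **{k: v for k, v in fit_kwargs.items()
                                           if k != "dispersion"},
    )
    return lrt_full_vs_reduced(fit_full, fit_reduced)
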