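"""Synthetic paired IP/input translatome experiments with known ground truth.

The generator emulates a Ribotag-style design: a tagged cell type (by default
oligodendrocytes, "OL") whose ribosome-bound mRNA is immunoprecipitated from
a tissue that is a mixture of cell types, alongside a total-RNA "input"
library from the same tissue. Injury is modelled through two channels that
the downstream analysis must disentangle:

* genuine translational regulation in the tagged cell type
  (per-gene, per-condition log2 fold-changes), and
* shifts in tissue composition plus induction in *other* cell types, which
  change the ambient mRNA pool. A tunable fraction of each IP library is
  drawn from that ambient pool, modelling non-specific co-purification of
  abundant non-target transcripts with the beads.

Expected counts follow the convex-mixture model

    E[IP count]    = L_s * [ (1-c) * p_target(g) + c * p_ambient(g) ]
    E[input count] = L_s * p_ambient(g)

where ``p_target`` is the tagged cell type's (capture-bias weighted)
transcript pool normalised to proportions, ``p_ambient`` the
proportion-weighted mixture over all cell types, ``c`` the contamination
fraction and ``L_s`` a per-sample library size drawn log-uniformly.
Counts are negative-binomially distributed around these means with per-gene
dispersion ``alpha`` (variance ``mu + alpha * mu**2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CountMatrix, GeneSetCollection

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_experiment",
    "expected_proportions",
    "paper_like_config",
    "PAPER_LIKE_CONDITIONS",
]

PAPER_LIKE_CONDITIONS = ("naive", "dpi2", "dpi10", "dpi42")
PAPER_LIKE_CELL_TYPES = ("OL", "microglia", "astrocyte", "neuron")


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic experiment.

    Arrays are indexed gene x cell-type (baseline) and
    gene x cell-type x condition (injury log2 fold-changes). The first
    condition is the uninjured reference and must carry zero injury effects.
    """

    gene_ids: list[str]
    cell_types: list[str]
    conditions: list[str]
    proportions: pd.DataFrame          # conditions x cell types, rows sum to 1
    baseline_expression: np.ndarray    # (G, T) non-negative rates
    injury_lfc: np.ndarray             # (G, T, C) log2 fold-changes
    dispersion: np.ndarray             # (G,) NB dispersion > 0
    seed: int | None
    n_replicates_per_group: int = 3
    contamination_fraction: float = 0.1
    ip_capture_bias: np.ndarray | float = 1.0
    library_size_range: tuple[float, float] = (1e6, 3e6)
    tagged_cell_type: str = "OL"

    def __post_init__(self) -> None:
        G, T, C = len(self.gene_ids), len(self.cell_types), len(self.conditions)
        self.baseline_expression = np.asarray(self.baseline_expression, dtype=float)
        self.injury_lfc = np.asarray(self.injury_lfc, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if np.isscalar(self.ip_capture_bias):
            self.ip_capture_bias = np.full(G, float(self.ip_capture_bias))
        self.ip_capture_bias = np.asarray(self.ip_capture_bias, dtype=float)
        if self.baseline_expression.shape != (G, T):
            raise ConfigError(
                f"baseline_expression shape {self.baseline_expression.shape} != {(G, T)}"
            )
        if self.injury_lfc.shape != (G, T, C):
            raise ConfigError(f"injury_lfc shape {self.injury_lfc.shape} != {(G, T, C)}")
        if self.dispersion.shape != (G,) or np.any(self.dispersion <= 0):
            raise ConfigError("dispersion must be a positive (G,) vector")
        if self.ip_capture_bias.shape != (G,) or np.any(self.ip_capture_bias < 0):
            raise ConfigError("ip_capture_bias must be a non-negative (G,) vector")
        if not (0 <= self.contamination_fraction < 1):
            raise ConfigError("contamination_fraction must lie in [0, 1)")
        if self.n_replicates_per_group < 1:
            raise ConfigError("n_replicates_per_group must be >= 1")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be a positive interval")
        if self.tagged_cell_type not in self.cell_types:
            raise ConfigError(f"tagged cell type {self.tagged_cell_type!r} not declared")
        props = self.proportions.loc[list(self.conditions), list(self.cell_types)]
        arr = props.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ConfigError("cell-type proportions must lie in [0, 1]")
        rowsum = arr.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            bad = [c for c, s in zip(self.conditions, rowsum) if abs(s - 1) > 1e-9]
            raise ConfigError(f"proportions must sum to 1 per condition; bad: {bad}")
        self.proportions = props
        if not np.all(np.isfinite(self.baseline_expression)) or np.any(
            self.baseline_expression < 0
        ):
            raise ConfigError("baseline_expression must be finite and >= 0")
        if np.any(self.injury_lfc[:, :, 0] != 0.0):
            raise ConfigError(
                f"reference condition {self.conditions[0]!r} must have zero injury_lfc"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``true_ol_de`` flags genes whose tagged-cell-type log2 fold-change
    magnitude reaches the DE threshold; ``contaminant_driven`` flags genes
    with no tagged-cell change whose ambient abundance nevertheless shifted
    (composition change and/or induction in other cell types);
    ``true_enrichment`` is the log2 ratio of target-pool to ambient-pool
    proportions, the quantity the IP/input contrast estimates.
    """

    true_ol_de: pd.DataFrame        # genes x conditions, bool
    contaminant_driven: pd.DataFrame  # genes x conditions, bool
    true_enrichment: pd.DataFrame   # genes x conditions, float
    true_ol_lfc: pd.DataFrame       # genes x conditions, float (tagged cell type)
    ambient_lfc: pd.DataFrame       # genes x conditions, float (vs reference)

    def table(self) -> pd.DataFrame:
        """Tidy gene x condition table for TSV export."""
        frames = []
        for cond in self.true_ol_de.columns:
            frames.append(pd.DataFrame({
                "gene": self.true_ol_de.index,
                "condition": cond,
                "true_ol_de": self.true_ol_de[cond].to_numpy(),
                "contaminant_driven": self.contaminant_driven[cond].to_numpy(),
                "true_enrichment": self.true_enrichment[cond].to_numpy(),
                "true_ol_lfc": self.true_ol_lfc[cond].to_numpy(),
                "ambient_lfc": self.ambient_lfc[cond].to_numpy(),
            }))
        return pd.concat(frames, ignore_index=True)


def expected_proportions(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition expected library proportions for IP and input fractions.

    Returns ``(p_ip, p_input)``, each genes x conditions; multiply by a
    library size to obtain an expected count.
    """
    expr = _expression_tensor(config)           # (G, T, C)
    p_amb = _ambient_proportions(config, expr)  # (G, C)
    p_tgt = _target_proportions(config, expr)   # (G, C)
    c = config.contamination_fraction
    p_ip = (1 - c) * p_tgt + c * p_amb
    idx = pd.Index(config.gene_ids, name="gene")
    cols = list(config.conditions)
    return (pd.DataFrame(p_ip, index=idx, columns=cols),
            pd.DataFrame(p_amb, index=idx, columns=cols))


def _expression_tensor(config: SimConfig) -> np.ndarray:
    return config.baseline_expression[:, :, None] * np.exp2(config.injury_lfc)


def _ambient_proportions(config: SimConfig, expr: np.ndarray) -> np.ndarray:
    props = config.proportions.to_numpy()              # (C, T)
    ambient = np.einsum("gtc,ct->gc", expr, props)
    total = ambient.sum(axis=0)
    if np.any(total <= 0):
        raise ConfigError("ambient pool is empty in at least one condition")
    return ambient / total


def _target_proportions(config: SimConfig, expr: np.ndarray) -> np.ndarray:
    t = config.cell_types.index(config.tagged_cell_type)
    target = config.ip_capture_bias[:, None] * expr[:, t, :]
    total = target.sum(axis=0)
    if np.any(total <= 0):
        raise ConfigError("tagged cell type expresses nothing in at least one condition")
    return target / total


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, variance mu + alpha mu^2) via the gamma-Poisson mixture."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_experiment(
    config: SimConfig,
    de_threshold: float = 1.0,
    ambient_threshold: float = 1.0,
) -> tuple[CountMatrix, SimTruth]:
    """Draw one experiment and its ground truth from ``config``.

    Identical configs (including the seed) yield byte-identical outputs.
    ``de_threshold``/``ambient_threshold`` control the truth flags only, not
    the counts: a gene is ``true_ol_de`` in a condition when its tagged-cell
    |log2FC| > ``de_threshold`` and ``contaminant_driven`` when its tagged
    cell is silent (|log2FC| < 0.1) while its ambient |log2FC| exceeds
    ``ambient_threshold``.
    """
    if config.seed is None:
        raise ConfigError("a seed is required: simulations must be reproducible")
    rng = np.random.default_rng(config.seed)

    expr = _expression_tensor(config)
    p_amb = _ambient_proportions(config, expr)
    p_tgt = _target_proportions(config, expr)
    c = config.contamination_fraction
    p_ip = (1 - c) * p_tgt + c * p_amb

    lo, hi = config.library_size_range
    n_rep = config.n_replicates_per_group
    alpha = config.dispersion

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for ci, cond in enumerate(config.conditions):
        for rep in range(1, n_rep + 1):
            pair = f"{cond}_rep{rep}"
            for fraction, p in (("IP", p_ip[:, ci]), ("input", p_amb[:, ci])):
                lib = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                sample = f"{pair}_{fraction}"
                columns[sample] = _nb_draw(rng, lib * p, alpha)
                meta_rows.append({
                    "sample": sample, "fraction": fraction, "condition": cond,
                    "pair_id": pair, "library_size": f"{lib:.1f}",
                })
    counts = pd.DataFrame(columns, index=pd.Index(config.gene_ids, name="gene"))
    meta = pd.DataFrame(meta_rows).set_index("sample")
    cm = CountMatrix(counts, meta)

    t = config.cell_types.index(config.tagged_cell_type)
    ol_lfc = config.injury_lfc[:, t, :]                      # (G, C)
    with np.errstate(divide="ignore"):
        amb_lfc = np.log2(p_amb) - np.log2(p_amb[:, [0]])
        # center per condition (median over genes), mirroring what
        # median-of-ratios normalization removes: a surge of a few very
        # abundant transcripts must not flag every unchanged gene
        amb_lfc = amb_lfc - np.nanmedian(amb_lfc, axis=0, keepdims=True)
        true_enr = np.log2(p_tgt) - np.log2(p_amb)
    idx = pd.Index(config.gene_ids, name="gene")
    cols = list(config.conditions)
    truth = SimTruth(
        true_ol_de=pd.DataFrame(np.abs(ol_lfc) > de_threshold, index=idx, columns=cols),
        contaminant_driven=pd.DataFrame(
            (np.abs(ol_lfc) < 0.1) & (np.abs(amb_lfc) > ambient_threshold),
            index=idx, columns=cols,
        ),
        true_enrichment=pd.DataFrame(true_enr, index=idx, columns=cols),
        true_ol_lfc=pd.DataFrame(ol_lfc, index=idx, columns=cols),
        ambient_lfc=pd.DataFrame(amb_lfc, index=idx, columns=cols),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# the default desk-scale scenario
# ---------------------------------------------------------------------------

#: Cell-type proportions per condition: an inflammatory (microglia/macrophage)
#: expansion peaking acutely after injury and resolving over time, with the
#: tagged OL population transiently diluted.
PAPER_LIKE_PROPORTIONS = pd.DataFrame(
    [
        [0.20, 0.10, 0.30, 0.40],   # naive
        [0.12, 0.45, 0.23, 0.20],   # dpi2: acute inflammatory expansion
        [0.15, 0.30, 0.30, 0.25],   # dpi10
        [0.20, 0.15, 0.35, 0.30],   # dpi42: largely resolved
    ],
    index=list(PAPER_LIKE_CONDITIONS),
    columns=list(PAPER_LIKE_CELL_TYPES),
)


def paper_like_config(
    seed: int,
    n_genes: int = 2000,
    contamination_fraction: float = 0.1,
    true_de_fraction: float = 0.05,
    true_de_lfc: float = 2.0,
    n_replicates_per_group: int = 3,
) -> tuple[SimConfig, GeneSetCollection]:
    """Desk-scale default scenario: 4 conditions x 2 fractions x 3 replicates.

    Gene architecture: 10% OL markers, 10% microglia markers, 7.5% astrocyte
    markers, 7.5% neuron markers (each expressed ~50x higher in its own cell
    type), remainder broadly expressed housekeeping genes. Injury effects:

    * ``true_de_fraction`` of genes (drawn from OL-expressed genes) receive a
      genuine OL log2 fold-change of +/-``true_de_lfc`` at dpi2, a random
      half persisting at dpi10 and ~30% at dpi42;
    * 60% of microglia markers are induced (+2..+4 log2) in microglia at
      dpi2, decaying over time — combined with the proportion surge these
      are the ambient/contaminant-driven genes;
    * a smaller reactive-astrocyte program (+1..+2 log2) at dpi2/dpi10.

    Returns the config and the marker panel (one gene set per cell type).
    """
    rng = np.random.default_rng([int(seed), 2_000_003])
    cell_types = list(PAPER_LIKE_CELL_TYPES)
    conditions = list(PAPER_LIKE_CONDITIONS)
    T, C = len(cell_types), len(conditions)

    n_ol = round(0.10 * n_genes)
    n_mg = round(0.10 * n_genes)
    n_as = round(0.075 * n_genes)
    n_ne = round(0.075 * n_genes)
    n_hk = n_genes - n_ol - n_mg - n_as - n_ne
    if n_hk <= 0:
        raise ConfigError("n_genes too small for the paper-like architecture")
    blocks = [("OL", n_ol), ("MG", n_mg), ("AS", n_as), ("NE", n_ne), ("HK", n_hk)]
    gene_ids: list[str] = []
    for tag, n in blocks:
        gene_ids += [f"{tag}_{i:04d}" for i in range(n)]

    baseline = np.empty((n_genes, T))
    marker_of = {"OL": "OL", "MG": "microglia", "AS": "astrocyte", "NE": "neuron"}
    row = 0
    for tag, n in blocks:
        own = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n)
        if tag == "HK":
            base = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=n)
            jitter = rng.lognormal(mean=0.0, sigma=0.25, size=(n, T))
            baseline[row:row + n] = base[:, None] * jitter
        else:
            # strong markers: ~500x specific for their own cell type, so the
            # tagged-cell leak channel stays far below the ambient channel
            t_own = cell_types.index(marker_of[tag])
            leak = 0.002 * own[:, None] * rng.lognormal(0.0, 0.25, size=(n, T))
            block = leak
            block[:, t_own] = own
            baseline[row:row + n] = block
        row += n

    lfc = np.zeros((n_genes, T, C))
    t_ol = cell_types.index("OL")
    t_mg = cell_types.index("microglia")
    t_as = cell_types.index("astrocyte")

    # genuine OL regulation, drawn from OL-expressed genes (OL markers + HK)
    ol_expressed = np.array(
        [i for i, g in enumerate(gene_ids) if g.startswith(("OL_", "HK_"))]
    )
    n_de = round(true_de_fraction * n_genes)
    de_idx = rng.choice(ol_expressed, size=n_de, replace=False)
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    lfc[de_idx, t_ol, conditions.index("dpi2")] = signs * true_de_lfc
    persist10 = rng.random(n_de) < 0.5
    persist42 = rng.random(n_de) < 0.3
    lfc[de_idx[persist10], t_ol, conditions.index("dpi10")] = (
        signs[persist10] * true_de_lfc
    )
    lfc[de_idx[persist42], t_ol, conditions.index("dpi42")] = (
        signs[persist42] * true_de_lfc
    )

    # inflammatory induction in microglia (ambient surge after injury)
    mg_idx = np.array([i for i, g in enumerate(gene_ids) if g.startswith("MG_")])
    inflam = rng.choice(mg_idx, size=round(0.6 * len(mg_idx)), replace=False)
    amp = rng.uniform(2.0, 4.0, size=len(inflam))
    lfc[inflam, t_mg, conditions.index("dpi2")] = amp
    lfc[inflam, t_mg, conditions.index("dpi10")] = 0.5 * amp
    lfc[inflam, t_mg, conditions.index("dpi42")] = 0.2 * amp

    # milder reactive-astrocyte program
    as_idx = np.array([i for i, g in enumerate(gene_ids) if g.startswith("AS_")])
    reactive = rng.choice(as_idx, size=round(0.3 * len(as_idx)), replace=False)
    amp_as = rng.uniform(1.0, 2.0, size=len(reactive))
    lfc[reactive, t_as, conditions.index("dpi2")] = amp_as
    lfc[reactive, t_as, conditions.index("dpi10")] = amp_as

    dispersion = np.clip(
        rng.lognormal(mean=np.log(0.05), sigma=0.4, size=n_genes), 0.005, 0.5
    )

    config = SimConfig(
        gene_ids=gene_ids,
        cell_types=cell_types,
        conditions=conditions,
        proportions=PAPER_LIKE_PROPORTIONS.copy(),
        baseline_expression=baseline,
        injury_lfc=lfc,
        dispersion=dispersion,
        seed=int(seed),
        n_replicates_per_group=n_replicates_per_group,
        contamination_fraction=contamination_fraction,
    )
    panel = GeneSetCollection(
        sets={
            marker_of[tag]: {g for g in gene_ids if g.startswith(tag + "_")}
            for tag in ("OL", "MG", "AS", "NE")
        },
        descriptions={ct: f"synthetic {ct} marker genes" for ct in marker_of.values()},
        source="synthetic",
    )
    return config, panel
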