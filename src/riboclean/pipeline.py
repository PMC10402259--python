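"""End-to-end orchestration: simulate/load -> QC -> DE -> filtration -> set stats.

A run is a pure function of its configuration and root seed: every stage
seed is derived from the root seed, every stage output is written as TSV
under the output directory, and a provenance record (config hash, seed,
package version) accompanies the results. ``run.log`` records stage
wall-times and parameter echoes; it is the only output file that is not
byte-reproducible across identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .de import de_between_conditions, differential_enrichment, enrichment_for_condition
from .errors import ConfigError
from .filtration import (FiltrationReport, Thresholds, classify_enrichment,
                         two_arm_filter)
from .io import (CountMatrix, GeneSetCollection, read_counts, read_gmt,
                 write_counts, write_gmt, write_table, write_yaml)
from .norm import filter_low_counts, rle_size_factors
from .qc import marker_enrichment, pca_summary
from .setstats import operon_zscore_table, overlap_table
from .simulate import generate_experiment, paper_like_config

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``counts_path``/``meta_path`` point at an existing experiment, or
    ``scenario: "paper-like"`` asks for a synthetic one (24 samples:
    4 conditions x 2 fractions x 3 replicates, 2000 genes, contamination
    0.1 by default). ``thresholds`` carries every filtration cutoff plus
    ``min_total`` (low-count filter), ``z`` and ``n_resamples`` for the
    operon statistic.
    """

    seed: int
    scenario: str | None = "paper-like"
    counts_path: str | None = None
    meta_path: str | None = None
    markers_gmt: str | None = None
    operons_gmt: str | None = None
    reference: str = "naive"
    n_genes: int = 2000
    contamination_fraction: float = 0.1
    true_de_fraction: float = 0.05
    true_de_lfc: float = 2.0
    n_replicates: int = 3
    min_total: int = 10
    z_threshold: float = 5.0
    n_resamples: int = 1000
    paired: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("run config requires a seed")
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        if self.scenario is None and (self.counts_path is None or self.meta_path is None):
            raise ConfigError("either a scenario or counts+meta paths are required")
        if self.scenario not in (None, "paper-like"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.min_total < 0 or self.n_resamples < 2:
            raise ConfigError("min_total must be >= 0 and n_resamples >= 2")

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "thresholds"}
        d["thresholds"] = self.thresholds.as_dict()
        return d

    def digest(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, data: dict, seed: int | None = None) -> "RunConfig":
        if seed is not None:
            data = {**data, "seed": seed}
        if "seed" not in data:
            raise ConfigError("a seed is required (config 'seed' or --seed)")
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _synthetic_operons(
    truth, expressed: list[str], seed: int, n_random: int = 5, size: int = 200
) -> GeneSetCollection:
    """Synthetic stand-in operon sets for simulation-mode runs.

    One target set deliberately overlapping the genes truly regulated in the
    tagged cell type (emulating a de-silenced regulon) plus random control
    sets of the same size drawn from the expressed background.
    """
    rng = np.random.default_rng(seed)
    expressed_arr = np.asarray(sorted(expressed))
    up = [g for g in truth.true_ol_de.index
          if truth.true_ol_de.loc[g].any() and g in set(expressed)]
    take = rng.choice(len(up), size=min(len(up), size // 2), replace=False)
    target = {up[i] for i in take}
    pad = rng.choice(expressed_arr, size=max(0, size - len(target)), replace=False)
    sets = {"synthetic_target_operon": target | set(pad.tolist())}
    for i in range(n_random):
        members = rng.choice(expressed_arr, size=size, replace=False)
        sets[f"synthetic_random_operon_{i + 1}"] = set(members.tolist())
    return GeneSetCollection(
        sets, {k: "synthetic operon stand-in" for k in sets}, source="synthetic"
    )


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage and write all artifacts under ``outdir``.

    Returns the in-memory artifacts keyed by stage name. Any stage failure
    is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t_start = time.perf_counter()
    artifacts: dict[str, Any] = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is None:
                    log_lines.append(f"stage={name} status=ok wall_s={dt:.2f}")
                else:
                    log_lines.append(f"stage={name} status=failed error={exc}")
                    log_lines.append(f"run aborted in stage {name!r}")
                    _flush_log()
                return False

        return _Stage()

    def _flush_log():
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    log_lines.append(
        f"riboclean {__version__} seed={config.seed} config_sha={config.digest()}"
    )
    log_lines.append("config " + json.dumps(config.as_dict(), sort_keys=True))
    write_yaml(config.as_dict(), outdir / "config.yaml")
    (outdir / "provenance.txt").write_text(
        f"version\t{__version__}\nseed\t{config.seed}\nconfig_sha256\t{config.digest()}\n"
    )

    # ----- inputs -----------------------------------------------------
    truth = None
    markers: GeneSetCollection | None = None
    with stage("input"):
        if config.scenario == "paper-like":
            sim_config, markers = paper_like_config(
                seed=_stage_seed(config.seed, "simulate"),
                n_genes=config.n_genes,
                contamination_fraction=config.contamination_fraction,
                true_de_fraction=config.true_de_fraction,
                true_de_lfc=config.true_de_lfc,
                n_replicates_per_group=config.n_replicates,
            )
            cm, truth = generate_experiment(
                sim_config, de_threshold=config.thresholds.de_lfc
            )
            write_counts(cm, outdir / "counts.tsv", outdir / "samples.tsv")
            write_table(truth.table().set_index("gene"), outdir / "truth.tsv")
            write_gmt(markers, outdir / "markers.gmt")
        else:
            cm = read_counts(config.counts_path, config.meta_path)
        if config.markers_gmt:
            markers = read_gmt(config.markers_gmt)
    artifacts["counts"] = cm
    artifacts["truth"] = truth

    # ----- qc ---------------------------------------------------------
    with stage("qc"):
        sf_all = rle_size_factors(cm)
        pca = pca_summary(cm, size_factors=sf_all)
        write_table(
            pca.coordinates.assign(
                fraction=cm.meta["fraction"], condition=cm.meta["condition"]
            ),
            outdir / "pca.tsv", index_label="sample",
        )
        write_table(
            pd.DataFrame({"variance_fraction": pca.variance_fraction},
                         index=[f"PC{i+1}" for i in range(len(pca.variance_fraction))]),
            outdir / "pca_variance.tsv", index_label="component",
        )
        if markers is not None:
            qc_report = marker_enrichment(cm, markers, size_factors=sf_all)
            write_table(
                pd.DataFrame({
                    "median_fold": qc_report.median_folds,
                    "verdict": qc_report.verdicts,
                }),
                outdir / "qc_report.tsv", index_label="cell_type",
            )
            artifacts["qc"] = qc_report
        artifacts["pca"] = pca

    # ----- normalization / DE ----------------------------------------
    with stage("normalize"):
        filtered = filter_low_counts(cm, config.min_total)
        sf = rle_size_factors(filtered)
        write_table(sf.to_frame(), outdir / "size_factors.tsv", index_label="sample")
    artifacts["filtered"] = filtered
    artifacts["size_factors"] = sf

    reference = config.reference
    sci_conditions = [c for c in filtered.conditions if c != reference]
    de_results, delta_results, enrich_results = {}, {}, {}
    with stage("de"):
        for cond in sci_conditions:
            de_results[cond] = de_between_conditions(
                filtered, cond, reference=reference, fraction="IP", size_factors=sf
            )
            write_table(de_results[cond].table, outdir / f"de_{cond}_IP.tsv")
    with stage("enrich"):
        for cond in filtered.conditions:
            enrich_results[cond] = enrichment_for_condition(
                filtered, cond, size_factors=sf
            )
            write_table(enrich_results[cond].table, outdir / f"enrich_{cond}.tsv")
    with stage("enrich-delta"):
        for cond in sci_conditions:
            delta_results[cond] = differential_enrichment(
                filtered, cond, reference=reference, size_factors=sf,
                paired=config.paired,
            )
            write_table(delta_results[cond].table, outdir / f"delta_{cond}.tsv")
    artifacts["de"] = de_results
    artifacts["delta"] = delta_results
    artifacts["enrich"] = enrich_results

    # ----- filtration -------------------------------------------------
    reports: dict[str, FiltrationReport] = {}
    with stage("filter"):
        profile = classify_enrichment(enrich_results, config.thresholds)
        write_table(profile.table().set_index("gene"), outdir / "enrichment_profile.tsv")
        rows = []
        for cond in sci_conditions:
            reports[cond] = two_arm_filter(
                de_results[cond], delta_results[cond], profile,
                thresholds=config.thresholds, reference=reference,
            )
            write_table(reports[cond].table, outdir / f"filtration_{cond}.tsv")
            rows.append(reports[cond].summary())
            log_lines.append(
                f"filter condition={cond} " +
                " ".join(f"{k}={v}" for k, v in reports[cond].summary().items()
                         if k != "condition")
            )
        summary = pd.DataFrame(rows).set_index("condition")
        write_table(summary, outdir / "summary.tsv", index_label="condition")
    artifacts["profile"] = profile
    artifacts["filtration"] = reports
    artifacts["summary"] = summary

    # ----- set statistics --------------------------------------------
    with stage("overlap"):
        universe = set(filtered.gene_ids)
        if markers is not None:
            for cond in sci_conditions:
                query = set(reports[cond].passing("up"))
                if query:
                    tab = overlap_table(query, markers, universe)
                    write_table(tab, outdir / f"overlap_{cond}.tsv", index_label="set")
                    artifacts.setdefault("overlap", {})[cond] = tab

    with stage("operon-z"):
        ip_only = cm.subset_samples(cm.meta["fraction"] == "IP")
        expressed = list(filter_low_counts(ip_only, config.min_total).gene_ids)
        if config.operons_gmt:
            operons = read_gmt(config.operons_gmt)
        elif truth is not None:
            operons = _synthetic_operons(
                truth, expressed, seed=_stage_seed(config.seed, "operons")
            )
            write_gmt(operons, outdir / "operons.gmt")
        else:
            operons = None
        if operons is not None:
            for cond in sci_conditions:
                query = set(reports[cond].passing("up"))
                if len(query) < 2:
                    continue
                tab = operon_zscore_table(
                    query, operons, expressed,
                    n_resamples=config.n_resamples,
                    seed=_stage_seed(config.seed, f"operon-z:{cond}"),
                    z_threshold=config.z_threshold,
                )
                write_table(tab, outdir / f"operon_z_{cond}.tsv", index_label="set")
                artifacts.setdefault("operon_z", {})[cond] = tab

    # ----- truth-based evaluation (simulation mode only) --------------
    if truth is not None:
        with stage("evaluate"):
            rows = []
            for cond in sci_conditions:
                rows.append(evaluate_against_truth(reports[cond], de_results[cond],
                                                   truth, cond))
            evaluation = pd.DataFrame(rows).set_index("condition")
            write_table(evaluation, outdir / "evaluation.tsv", index_label="condition")
            artifacts["evaluation"] = evaluation

    log_lines.append(f"run complete wall_s={time.perf_counter() - t_start:.2f}")
    _flush_log()
    return artifacts


def evaluate_against_truth(
    report: FiltrationReport, de: "Any", truth, condition: str
) -> dict:
    """Recovery/contamination metrics of one condition's calls vs the truth.

    Recovery: fraction of truly regulated (tagged-cell) genes present in the
    analysed universe that pass the final filter. Contaminant fraction: share
    of final-pass genes that are contaminant-driven per the generator.
    """
    genes = report.table.index
    true_de = truth.true_ol_de.loc[genes, condition]
    contam = truth.contaminant_driven.loc[genes, condition]
    final = report.table["final"]
    de_sig = report.table["de_pass"]
    n_true = int(true_de.sum())
    n_final = int(final.sum())
    return {
        "condition": condition,
        "n_true_de": n_true,
        "n_de_calls": int(de_sig.sum()),
        "n_final": n_final,
        "recovery": float((final & true_de).sum() / n_true) if n_true else np.nan,
        "contaminant_frac_unfiltered": float((de_sig & contam).sum() / de_sig.sum())
        if de_sig.sum() else np.nan,
        "contaminant_frac_final": float((final & contam).sum() / n_final)
        if n_final else 0.0,
    }
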