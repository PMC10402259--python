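"""Readers and writers for on-disk artifacts.

Canonical table dialect is TSV (tab-separated, UTF-8, ``.`` decimal): count
matrices, sample metadata and result tables are all plain TSV so every
intermediate of a run is diff-able. Gene sets use the GMT dialect
(``name<TAB>description<TAB>member...``) and run configuration uses YAML.

Gene identifiers are treated as opaque, case-sensitive strings; no
symbol/accession mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, StructuralError

logger = logging.getLogger(__name__)

#: Allowed values of the ``fraction`` metadata column.
FRACTIONS = ("IP", "input")

META_COLUMNS = ("fraction", "condition", "pair_id")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample annotations.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows, samples as columns.
    meta
        DataFrame indexed by sample id with at least the columns
        ``fraction`` (``"IP"`` or ``"input"``), ``condition`` and ``pair_id``.
        Each IP sample is expected to share its ``pair_id`` with exactly one
        input sample from the same tissue; unpaired IP samples are reported
        as a warning, not an error.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        counts, meta = self.counts, self.meta
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate gene ids: {dup[:5]}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate sample ids: {dup[:5]}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("counts contain non-numeric entries")
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count for gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(arr != np.round(arr))[0]
            raise ParseError(
                f"non-integer count for gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        self.counts = counts.astype(np.int64)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise StructuralError(f"metadata missing required columns: {missing}")
        if set(meta.index) != set(counts.columns):
            only_meta = sorted(set(meta.index) - set(counts.columns))
            only_counts = sorted(set(counts.columns) - set(meta.index))
            raise StructuralError(
                "metadata/count sample mismatch: "
                f"only in metadata {only_meta[:5]}, only in counts {only_counts[:5]}"
            )
        bad = sorted(set(meta["fraction"]) - set(FRACTIONS))
        if bad:
            raise StructuralError(f"unknown fraction labels {bad}; expected {FRACTIONS}")
        # align metadata row order to the count columns
        self.meta = meta.loc[counts.columns]

    def unpaired_ip_samples(self) -> list[str]:
        """IP samples without exactly one same-pair input partner."""
        unpaired = []
        for sample, row in self.meta[self.meta["fraction"] == "IP"].iterrows():
            partners = self.meta[
                (self.meta["pair_id"] == row["pair_id"])
                & (self.meta["fraction"] == "input")
            ]
            if len(partners) != 1:
                unpaired.append(sample)
        return unpaired

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.meta["condition"]))

    def subset_samples(self, mask: pd.Series | list[str]) -> "CountMatrix":
        """Return a new matrix restricted to the given samples."""
        if isinstance(mask, pd.Series):
            samples = mask.index[mask.to_numpy().astype(bool)]
        else:
            samples = pd.Index(mask)
        return CountMatrix(self.counts[samples], self.meta.loc[samples])

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.meta)


@dataclass
class GeneSetCollection:
    """Named gene sets (marker panels, ChIP-seq operon target sets, ...)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if any((not isinstance(m, str)) or m == "" for m in members):
                raise ParseError(f"gene set {name!r} has empty/non-string members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix plus its sample metadata table.

    The count TSV has a leading gene-id column and one column per sample;
    the metadata TSV is indexed by its ``sample`` column and must cover
    exactly the samples in the count header.
    """
    path, meta_path = Path(path), Path(meta_path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample", dtype=str)
    cm = CountMatrix(counts, meta)
    unpaired = cm.unpaired_ip_samples()
    if unpaired:
        logger.warning("unpaired IP samples: %s", unpaired)
    return cm


def write_counts(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(path, sep="\t")
    cm.meta.rename_axis("sample").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB member...`` per line.

    Duplicate members within a set are de-duplicated with a logged warning;
    an empty file yields an empty collection.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m != ""]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r has %d duplicate members (de-duplicated)",
                    path, lineno, name, len(members) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, source=source)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# generic result tables / gene lists / YAML config
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    """Write a result table as TSV with a stable float format."""
    table.rename_axis(index_label).to_csv(path, sep="\t", float_format="%.10g")


def read_table(path: str | Path, index_col: int | str = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if loaded is None:
        return {}
    if not isinstance(loaded, Mapping):
        raise ParseError(f"{path}: expected a YAML mapping at top level")
    return dict(loaded)


def write_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)
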