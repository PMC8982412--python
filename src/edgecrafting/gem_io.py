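"""Reading and writing gene expression matrices, labels and networks.

The GEM exchange format used here is the plain tab-separated layout of
the unified GTEx/TCGA matrices: a header row of sample identifiers, a
first column of gene identifiers, and numeric (or NA) expression cells.
Expression is assumed non-negative (log-scale FPKM-like); any negative
cell is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GEM",
    "GEMValidationError",
    "read_gem",
    "write_gem",
    "read_labels",
    "write_labels",
    "canonical_pair",
    "write_network",
    "read_edge_list",
    "EDGE_LIST_COLUMNS",
]

#: Fixed column order of the edge-list TSV output.
EDGE_LIST_COLUMNS = [
    "gene_a", "gene_b", "nmi",
    "blobs_log", "blobs_dog", "blobs_doh", "n_passing_methods",
]

NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "None"}


class GEMValidationError(ValueError):
    """Raised for structurally invalid GEMs, labels or networks."""


@dataclass
class GEM:
    """A genes x samples expression matrix.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``; missing values are NaN, all non-missing values
    are >= 0.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise GEMValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise GEMValidationError(f"duplicate {name} IDs: {dupes[:5]}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise GEMValidationError(
                    "negative expression values found; only positive "
                    "expression levels are considered"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def global_max(self) -> float:
        m = np.nanmax(self.values)
        if not np.isfinite(m) or m <= 0:
            raise GEMValidationError("GEM has no positive expression values")
        return float(m)

    def expression(self, gene_id: str) -> np.ndarray:
        """Expression vector (over samples) of one gene."""
        if not hasattr(self, "_gene_index"):
            self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in GEM") from None


def read_gem(path: str | Path) -> GEM:
    """Parse a tab-separated GEM (header = sample IDs, first column = gene IDs)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.isnull().any():
        raise GEMValidationError(f"{path}: missing gene identifiers")
    values = df.replace(list(NA_TOKENS), np.nan)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise GEMValidationError(f"{path}: non-numeric cell: {exc}") from exc
    return GEM(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values.to_numpy(),
    )


def write_gem(gem: GEM, path: str | Path) -> None:
    """Write a GEM in the same TSV dialect :func:`read_gem` reads."""
    df = pd.DataFrame(gem.values, index=gem.gene_ids, columns=gem.sample_ids)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a mapping.

    A header line is tolerated (detected as the literal pair
    ``sample/label``-style names or skipped silently if the first row
    repeats on join). Duplicate samples with conflicting groups raise;
    exact duplicates collapse.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GEMValidationError(
                    f"{path}:{ln}: expected 2 tab-separated fields, got {len(parts)}"
                )
            sample, group = (p.strip() for p in parts)
            if ln == 1 and sample.lower() in {"sample", "sample_id", "id"}:
                continue
            if sample in mapping and mapping[sample] != group:
                raise GEMValidationError(
                    f"{path}: sample {sample!r} labeled both "
                    f"{mapping[sample]!r} and {group!r}"
                )
            mapping[sample] = group
    if not mapping:
        warnings.warn(f"{path}: no sample labels parsed", stacklevel=2)
    return mapping


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")


def match_labels(labels: Mapping[str, str], gem: GEM) -> tuple[dict[str, str], int]:
    """Restrict labels to samples present in the GEM.

    Returns the restricted mapping and the count of unknown samples
    (tolerated, but reported so upstream joins can warn).
    """
    known = set(gem.sample_ids)
    matched = {s: g for s, g in labels.items() if s in known}
    n_unknown = len(labels) - len(matched)
    if n_unknown:
        warnings.warn(f"{n_unknown} labeled samples not present in the GEM",
                      stacklevel=2)
    return matched, n_unknown


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Order an unordered gene pair lexicographically.

    Self-pairs are rejected: an edge relates two distinct genes.
    """
    if gene_a == gene_b:
        raise ValueError(f"self-edge {gene_a!r} is not a valid gene pair")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def write_network(network, path: str | Path, format: str = "edge_list_tsv") -> None:
    """Write a network as a sorted edge-list TSV or as GraphML.

    The TSV columns are fixed (:data:`EDGE_LIST_COLUMNS`) and rows are
    sorted by (gene_a, gene_b) so repeated runs are byte-identical.
    """
    edges = sorted(network.edges, key=lambda e: (e.gene_a, e.gene_b))
    if format == "edge_list_tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(EDGE_LIST_COLUMNS) + "\n")
            for e in edges:
                fh.write(
                    f"{e.gene_a}\t{e.gene_b}\t{e.nmi:.10f}\t"
                    f"{e.blob_counts['LoG']}\t{e.blob_counts['DoG']}\t"
                    f"{e.blob_counts['DoH']}\t{e.n_methods_multimodal}\n"
                )
    elif format == "graphml":
        g = nx.Graph()
        for node in sorted(network.nodes):
            g.add_node(node)
        for e in edges:
            g.add_edge(
                e.gene_a, e.gene_b,
                nmi=float(e.nmi),
                blobs_log=int(e.blob_counts["LoG"]),
                blobs_dog=int(e.blob_counts["DoG"]),
                blobs_doh=int(e.blob_counts["DoH"]),
                n_passing_methods=int(e.n_methods_multimodal),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read back an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise GEMValidationError(f"{path}: missing edge-list columns {missing}")
    return df
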