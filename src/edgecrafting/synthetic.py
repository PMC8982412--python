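"""Synthetic gene expression matrices with known planted edge structure.

The generator emulates the statistical shape of a unified bulk RNA-seq
compendium: non-negative bounded log-scale expression, several sample
groups (e.g. one normal and three tumour subtypes), and gene pairs that
are either unrelated (null), globally linearly related, or multimodal —
the hallmark pattern this pipeline targets, in which one subset of
sample groups occupies a distinct bivariate expression location from
the rest.

Patterns
--------
null
    Both genes drawn independently from a right-skewed Gamma(2, 2)
    background, clipped to the value range — the shape of log-scale
    FPKM backgrounds.
linear
    ``gene_b = gene_a + N(0, noise_sd)``, a globally correlated pair
    with no subpopulation structure.
multimodal
    The designated sample group(s) sit around bivariate mean ``mu1``,
    every other group around ``mu2``, with ``|mu1 - mu2| >=
    separation``.  Within a subpopulation the two genes share one
    latent deviation of s.d. ``noise_sd`` (common biological
    variation), so gene_b tracks gene_a exactly up to the per-cluster
    offset plus an optional independent jitter (default 0).  The shared
    latent keeps a planted pair's binned mutual information near 1 by
    construction while each coordinate still scatters with s.d.
    ``noise_sd`` inside its cluster.

All values are clipped to ``[0, max_expression]``; clipping (rather
than rejection sampling) slightly inflates the boundary bins.  The
default ``max_expression`` of 18.89 makes the fixture grids reproduce
the 19/38/76 bin counts of the kidney compendium, and the default
groups are its four phenotype groups (158 normal, 60 KICH, 475 KIRC,
236 KIRP; 929 samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gem_io import GEM, canonical_pair
from .network_builder import Network

__all__ = [
    "KIDNEY_GROUPS",
    "PlantedEdge",
    "SyntheticSpec",
    "generate_gem",
    "default_spec",
    "ground_truth_confusion",
    "write_ground_truth",
]

#: Sample-group sizes of the unified kidney compendium.
KIDNEY_GROUPS: tuple[tuple[str, int], ...] = (
    ("normal", 158), ("KICH", 60), ("KIRC", 475), ("KIRP", 236),
)

PATTERNS = ("null", "linear", "multimodal")


@dataclass(frozen=True)
class PlantedEdge:
    """One planted gene pair and its generative pattern."""

    gene_a: str
    gene_b: str
    pattern: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic GEM.

    ``separation`` (expression units) is the distance between the two
    cluster centers of a multimodal edge; ``noise_sd`` the within-group
    scatter.  Defaults mirror the kidney compendium's group structure
    and value range.
    """

    groups: tuple[tuple[str, int], ...] = KIDNEY_GROUPS
    n_genes: int = 100
    planted_edges: tuple[PlantedEdge, ...] = ()
    max_expression: float = 18.89
    noise_sd: float = 0.5
    separation: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.groups):
            raise ValueError("all group sizes must be >= 1")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)


def default_spec(n_multimodal: int = 20, n_linear: int = 20, n_null: int = 60,
                 seed: int = 0, **overrides) -> SyntheticSpec:
    """The standard 100-gene benchmark recipe.

    20 multimodal and 20 linear pairs each claim two exclusive genes;
    the 60 null pairs are drawn among the remaining background genes
    (null genes are independent draws, so pairs may share genes).
    The multimodal edges rotate the shifted group across the spec's
    sample groups so that genes from different planted pairs are not
    mutually informative.
    """
    groups = overrides.get("groups", KIDNEY_GROUPS)
    n_structured = 2 * (n_multimodal + n_linear)
    n_genes = overrides.pop("n_genes", max(100, n_structured + 10))
    n_background = n_genes - n_structured
    if n_null > 0 and n_null > n_background * (n_background - 1) // 2:
        raise ValueError(
            f"{n_null} null pairs requested but only {n_background} "
            "background genes are available"
        )
    names = [f"G{i:04d}" for i in range(n_genes)]
    edges: list[PlantedEdge] = []
    g = 0
    group_labels = [label for label, _ in groups]
    for i in range(n_multimodal):
        edges.append(PlantedEdge(
            names[g], names[g + 1], "multimodal",
            {"shift_groups": [group_labels[i % len(group_labels)]]},
        ))
        g += 2
    for _ in range(n_linear):
        edges.append(PlantedEdge(names[g], names[g + 1], "linear"))
        g += 2
    background = names[g:]
    rng = np.random.default_rng(seed + 1_000_003)
    k = 0
    seen = set()
    while k < n_null:
        i, j = rng.choice(len(background), size=2, replace=False)
        pair = canonical_pair(background[i], background[j])
        if pair in seen:
            continue
        seen.add(pair)
        edges.append(PlantedEdge(pair[0], pair[1], "null"))
        k += 1
    return SyntheticSpec(n_genes=n_genes, planted_edges=tuple(edges),
                         seed=seed, **overrides)


def _background(rng: np.random.Generator, n: int, max_expr: float) -> np.ndarray:
    return np.clip(rng.gamma(shape=2.0, scale=2.0, size=n), 0.0, max_expr)


def generate_gem(spec: SyntheticSpec) -> tuple[GEM, dict[str, str], pd.DataFrame]:
    """Generate (GEM, sample labels, ground-truth edge table) from a spec.

    Fully deterministic in ``spec.seed``.  A gene may appear in at most
    one linear/multimodal pair (its values are dictated by that pair);
    null pairs may reuse background genes freely.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    group_of = np.empty(spec.n_samples, dtype=object)
    i = 0
    for label, n in spec.groups:
        for k in range(n):
            sid = f"{label}_{k:04d}"
            sample_ids.append(sid)
            labels[sid] = label
            group_of[i] = label
            i += 1

    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    known = set(gene_ids)
    structured: set[str] = set()
    seen_pairs: set[tuple[str, str]] = set()
    for e in spec.planted_edges:
        pair = canonical_pair(e.gene_a, e.gene_b)
        if pair in seen_pairs:
            raise ValueError(f"planted pair {pair} duplicated")
        seen_pairs.add(pair)
        for gname in pair:
            if gname not in known:
                raise ValueError(f"planted gene {gname!r} not among the "
                                 f"{spec.n_genes} generated genes")
        if e.pattern != "null":
            for gname in pair:
                if gname in structured:
                    raise ValueError(
                        f"gene {gname!r} appears in more than one "
                        "linear/multimodal planted pair"
                    )
                structured.add(gname)

    n = spec.n_samples
    values = {g: _background(rng, n, spec.max_expression) for g in gene_ids}

    for e in spec.planted_edges:
        if e.pattern == "null":
            continue  # background draws already independent
        a, b = e.gene_a, e.gene_b
        if e.pattern == "linear":
            base = _background(rng, n, spec.max_expression)
            noise = rng.normal(0.0, e.params.get("noise_sd", spec.noise_sd), n)
            values[a] = base
            values[b] = np.clip(base + noise, 0.0, spec.max_expression)
        else:  # multimodal
            sep = e.params.get("separation", spec.separation)
            sd = e.params.get("noise_sd", spec.noise_sd)
            jitter_sd = e.params.get("jitter_sd", 0.0)
            shift_groups = set(e.params.get(
                "shift_groups", [spec.groups[0][0]]
            ))
            mu1 = np.asarray(e.params.get("mu1", (3.0, 3.0)), dtype=float)
            direction = np.array([1.0, 1.0]) / np.sqrt(2.0)
            mu2 = np.asarray(e.params.get("mu2", mu1 + sep * direction),
                             dtype=float)
            in_shift = np.isin(group_of, list(shift_groups))
            mu_a = np.where(in_shift, mu1[0], mu2[0])
            mu_b = np.where(in_shift, mu1[1], mu2[1])
            latent = rng.normal(0.0, sd, n)  # shared within-cluster deviation
            va = mu_a + latent
            vb = mu_b + latent
            if jitter_sd > 0:
                va = va + rng.normal(0.0, jitter_sd, n)
                vb = vb + rng.normal(0.0, jitter_sd, n)
            values[a] = np.clip(va, 0.0, spec.max_expression)
            values[b] = np.clip(vb, 0.0, spec.max_expression)

    matrix = np.vstack([values[g] for g in gene_ids])
    gem = GEM(gene_ids=gene_ids, sample_ids=sample_ids, values=matrix)
    truth = pd.DataFrame(
        [
            {"gene_a": canonical_pair(e.gene_a, e.gene_b)[0],
             "gene_b": canonical_pair(e.gene_a, e.gene_b)[1],
             "pattern": e.pattern}
            for e in spec.planted_edges
        ],
        columns=["gene_a", "gene_b", "pattern"],
    )
    return gem, labels, truth


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def ground_truth_confusion(network: Network, truth: pd.DataFrame
                           ) -> dict[str, float]:
    """Score a recovered network against the planted multimodal edges.

    TP: planted multimodal pairs present in the network.  FP: network
    edges that are not planted multimodal pairs.  FN: planted
    multimodal pairs the network missed.  Precision and recall follow
    the standard definitions (1.0 on empty denominators).
    """
    planted = {
        canonical_pair(r.gene_a, r.gene_b)
        for r in truth.itertuples()
        if r.pattern == "multimodal"
    }
    found = network.edge_set()
    tp = len(planted & found)
    fp = len(found - planted)
    fn = len(planted - found)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
    }
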