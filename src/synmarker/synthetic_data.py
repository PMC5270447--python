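"""Synthetic interactomes and two-class expression with planted modules.

The generator emulates the shape of the real inputs the method targets:
a sparse scale-free interactome (preferential attachment), two-class
expression cohorts with a 1:2 positive:negative imbalance, and a handful
of connected gene modules whose members share a latent factor (pairwise
correlation rho) and a coordinated mean shift delta in the positive
class.  The shared factor makes module genes genuinely synergistic —
their combined LLR t exceeds the singles — which is exactly the signal
the similarity's min-term is built to reward.  Replicate datasets share
the planted truth but draw independent noise and receive a per-gene
lognormal scale jitter emulating platform differences between cohorts.

What it does not emulate: probe-level microarray artifacts, batch
effects beyond the scale jitter, or survival/censoring structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_network import ExpressionDataset, InteractionNetwork

PLATFORM_JITTER_SD = 0.1


@dataclass
class SyntheticSpec:
    """Study-condition knobs for one synthetic benchmark instance."""

    n_genes: int = 2000
    attachment: int = 2
    n_modules: int = 5
    module_size_range: tuple = (8, 15)
    delta: float = 1.5
    rho: float = 0.5
    n_pos: int = 100
    n_neg: int = 200
    n_replicate_datasets: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.module_size_range[0] < 3:
            raise ValueError("module sizes must be >= 3")
        if self.module_size_range[0] > self.module_size_range[1]:
            raise ValueError("module_size_range must be (min, max) with min <= max")
        if self.module_size_range[1] > self.n_genes:
            raise ValueError("module size cannot exceed the gene count")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        for name in ("n_genes", "n_modules", "n_pos", "n_neg", "n_replicate_datasets"):
            if getattr(self, name) < 0 or (name != "n_modules" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted module memberships and per-gene effect sizes."""

    module_memberships: list = field(default_factory=list)
    effect_sizes: dict = field(default_factory=dict)

    @property
    def planted_genes(self) -> set:
        out = set()
        for m in self.module_memberships:
            out |= set(m)
        return out


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_network(spec: SyntheticSpec):
    """Preferential-attachment graph with connected, disjoint planted modules.

    Each module is grown by breadth-first search from a random unused
    seed node, so its genes induce a connected subgraph; a seed whose
    unused BFS reach is too small is redrawn, up to 10 attempts per
    module.
    """
    rng = np.random.default_rng(spec.seed)
    graph = nx.barabasi_albert_graph(
        spec.n_genes, spec.attachment, seed=int(rng.integers(2**31))
    )
    graph = nx.relabel_nodes(graph, {i: _gene_name(i) for i in graph.nodes})
    truth = GroundTruth()
    used = set()
    for _ in range(spec.n_modules):
        size = int(rng.integers(spec.module_size_range[0], spec.module_size_range[1] + 1))
        module = None
        for _attempt in range(10):
            candidates = sorted(set(graph.nodes) - used)
            start = candidates[int(rng.integers(len(candidates)))]
            module = _grow_module(graph, start, size, used, rng)
            if module is not None:
                break
        if module is None:
            raise RuntimeError(
                f"could not place a connected module of size {size}; "
                "the unused part of the graph is too fragmented"
            )
        used |= module
        truth.module_memberships.append(set(module))
        for g in module:
            truth.effect_sizes[g] = spec.delta
    network = InteractionNetwork(graph=graph)
    return network, truth


def _grow_module(graph, start, size, used, rng):
    """BFS growth from ``start`` avoiding used genes; None if it stalls."""
    module = {start}
    frontier = [start]
    while len(module) < size and frontier:
        nxt = []
        for node in frontier:
            nbrs = sorted(set(graph.neighbors(node)) - module - used)
            rng.shuffle(nbrs)
            for nb in nbrs:
                module.add(nb)
                nxt.append(nb)
                if len(module) == size:
                    return module
        frontier = nxt
    return module if len(module) == size else None


def generate_expression(network: InteractionNetwork, truth: GroundTruth, spec: SyntheticSpec):
    """Replicate two-class datasets sharing the planted truth.

    Background genes are standard normal in both classes.  A module
    gene's value is sqrt(rho) * F + sqrt(1-rho) * eps (unit variance,
    pairwise within-module correlation rho) plus delta in positive
    samples.  Each replicate applies an independent per-gene lognormal
    scale factor (sd 0.1 on the log scale) to mimic platform effects.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(network.nodes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_samples = spec.n_pos + spec.n_neg
    labels = np.array([True] * spec.n_pos + [False] * spec.n_neg)
    datasets = []
    for d in range(spec.n_replicate_datasets):
        values = rng.standard_normal((len(genes), n_samples))
        for module in truth.module_memberships:
            factor = rng.standard_normal(n_samples)
            for g in sorted(module):
                i = gene_pos[g]
                values[i] = np.sqrt(spec.rho) * factor + np.sqrt(1.0 - spec.rho) * values[i]
                values[i, labels] += truth.effect_sizes[g]
        scale = np.exp(rng.normal(0.0, PLATFORM_JITTER_SD, size=len(genes)))
        values *= scale[:, None]
        datasets.append(
            ExpressionDataset(
                gene_ids=list(genes),
                values=values,
                sample_ids=[f"S{j:04d}" for j in range(n_samples)],
                labels=labels.copy(),
                name=f"replicate-{d + 1}",
            )
        )
    return datasets


def recovery_score(found_markers, truth: GroundTruth) -> list:
    """Best Jaccard index of each planted module against any found marker."""
    marker_sets = [
        set(m.members) if hasattr(m, "members") else set(m) for m in found_markers
    ]
    out = []
    for module in truth.module_memberships:
        best = 0.0
        for ms in marker_sets:
            union = module | ms
            if union:
                best = max(best, len(module & ms) / len(union))
        out.append(best)
    return out


def write_fixture(out_dir, network: InteractionNetwork, truth: GroundTruth, datasets) -> dict:
    """Write the TSV/JSON fixture files the loaders read; returns the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {"network": os.path.join(out_dir, "network.tsv")}
    with open(paths["network"], "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")
    for idx, ds in enumerate(datasets, 1):
        expr = os.path.join(out_dir, f"expression_rep{idx}.tsv")
        lab = os.path.join(out_dir, f"labels_rep{idx}.tsv")
        with open(expr, "w") as fh:
            fh.write("gene\t" + "\t".join(ds.sample_ids) + "\n")
            for i, g in enumerate(ds.gene_ids):
                row = "\t".join(f"{v:.10g}" for v in ds.values[i])
                fh.write(f"{g}\t{row}\n")
        with open(lab, "w") as fh:
            for s, is_pos in zip(ds.sample_ids, ds.labels):
                fh.write(f"{s}\t{'metastatic' if is_pos else 'non-metastatic'}\n")
        paths[f"expression_rep{idx}"] = expr
        paths[f"labels_rep{idx}"] = lab
    paths["truth"] = os.path.join(out_dir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "modules": [sorted(m) for m in truth.module_memberships],
                "effect_sizes": dict(sorted(truth.effect_sizes.items())),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
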