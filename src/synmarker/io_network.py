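"""Loading of expression matrices, sample labels, and interaction networks.

Expression files are tab-separated with gene identifiers in the first
column and a header row of sample identifiers.  Labels are a two-column
TSV mapping sample id to a class string (defaults ``metastatic`` /
``non-metastatic``).  Networks are two-column TSV edge lists; a
three-column SIF dialect is accepted with the middle (interaction type)
column ignored.

Identifier matching is exact string match after whitespace trimming; any
alias or probe-annotation mapping is expected to happen upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateClassError,
    DegenerateNetworkError,
    FormatError,
    LabelError,
)

DEFAULT_POSITIVE = "metastatic"
DEFAULT_NEGATIVE = "non-metastatic"


@dataclass
class ExpressionDataset:
    """A labeled genes-by-samples expression matrix.

    Attributes
    ----------
    gene_ids : list of str
        Row identifiers, unique.
    values : ndarray, shape (n_genes, n_samples)
        Real expression values, no missing entries.
    sample_ids : list of str
        Column identifiers, aligned with ``labels``.
    labels : ndarray of bool
        True for positive-class (e.g. metastatic) samples.
    name : str
        Free-text dataset name used in reports.
    """

    gene_ids: list
    values: np.ndarray
    sample_ids: list
    labels: np.ndarray
    name: str = ""
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers in dataset")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.labels.shape != (len(self.sample_ids),):
            raise LabelError("labels length does not match sample count")
        if np.isnan(self.values).any():
            raise FormatError("expression matrix contains missing values")
        n_pos = int(self.labels.sum())
        n_neg = len(self.labels) - n_pos
        if n_pos < 2 or n_neg < 2:
            raise DegenerateClassError(
                f"each class needs >= 2 samples (got {n_pos} positive, {n_neg} negative)"
            )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def pos_mask(self) -> np.ndarray:
        return self.labels

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        return self.values[self._index[gene_id]]

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._index

    def subset_samples(self, indices, name: str | None = None) -> "ExpressionDataset":
        """New dataset restricted to the given sample indices (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            values=self.values[:, indices],
            sample_ids=[self.sample_ids[i] for i in indices],
            labels=self.labels[indices],
            name=name if name is not None else self.name,
        )

    def subset_genes(self, genes, name: str | None = None) -> "ExpressionDataset":
        idx = [self._index[g] for g in genes]
        return ExpressionDataset(
            gene_ids=list(genes),
            values=self.values[idx, :],
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            name=name if name is not None else self.name,
        )


@dataclass
class InteractionNetwork:
    """Undirected protein-protein interaction graph.

    ``dist2_pairs`` holds the ordered gene pairs at shortest-path
    distance 1 or 2; it is the sparsity pattern of the similarity
    structure and is populated by :func:`induce_common` (or
    :meth:`compute_dist2_pairs`), not at load time.
    """

    graph: nx.Graph
    dist2_pairs: set = field(default_factory=set)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def compute_dist2_pairs(self) -> None:
        """Populate ``dist2_pairs`` by breadth-first search of depth 2."""
        pairs = set()
        for u in self.graph.nodes:
            reach = nx.single_source_shortest_path_length(self.graph, u, cutoff=2)
            for v, d in reach.items():
                if v != u and 1 <= d <= 2:
                    pairs.add((u, v))
        self.dist2_pairs = pairs


def load_expression(
    path,
    label_path,
    positive_label: str = DEFAULT_POSITIVE,
    negative_label: str = DEFAULT_NEGATIVE,
    collapse: str = "mean",
    impute_missing: bool = False,
    name: str | None = None,
) -> ExpressionDataset:
    """Read an expression TSV plus a label TSV into an ExpressionDataset.

    Duplicate gene rows (e.g. multiple probes per gene) are collapsed by
    per-sample mean by default (``collapse="mean"``; also ``"first"`` or
    ``"error"``).  Missing values are rejected unless ``impute_missing``
    is set, in which case they are replaced by the per-gene mean.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    if frame.index.has_duplicates:
        if collapse == "mean":
            frame = frame.groupby(level=0, sort=False).mean()
        elif collapse == "first":
            frame = frame[~frame.index.duplicated(keep="first")]
        else:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene rows: {dups}")
    if frame.isna().any().any():
        if impute_missing:
            frame = frame.apply(lambda r: r.fillna(r.mean()), axis=1)
        else:
            raise FormatError(f"missing values in {path}; pass impute_missing=True to fill")

    labels = _read_labels(label_path)
    missing = [s for s in frame.columns if s not in labels]
    if missing:
        raise LabelError(f"samples absent from label file: {missing}")
    classes = []
    for s in frame.columns:
        cls = labels[s]
        if cls == positive_label:
            classes.append(True)
        elif cls == negative_label:
            classes.append(False)
        else:
            raise LabelError(
                f"sample {s!r} has unknown class {cls!r} "
                f"(expected {positive_label!r} or {negative_label!r})"
            )
    return ExpressionDataset(
        gene_ids=frame.index.tolist(),
        values=frame.to_numpy(dtype=float),
        sample_ids=frame.columns.tolist(),
        labels=np.array(classes, dtype=bool),
        name=name if name is not None else str(path),
    )


def _read_labels(path) -> dict:
    labels = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            labels[parts[0]] = parts[1]
    return labels


def load_network(path) -> InteractionNetwork:
    """Read a two-column TSV edge list (or three-column SIF) into a graph.

    Duplicate edges and self-loops are dropped.  ``dist2_pairs`` is left
    empty; call :func:`induce_common` to populate it on the gene set the
    analysis will actually use.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) == 3:  # SIF: source, interaction type, target
                a, _, b = parts
            elif len(parts) == 2:
                a, b = parts
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 (edge list) or 3 (SIF) columns, "
                    f"got {len(parts)}"
                )
            if a == b:
                continue
            graph.add_edge(a, b)
    return InteractionNetwork(graph=graph)


def induce_common(network: InteractionNetwork, datasets) -> InteractionNetwork:
    """Restrict the network to genes measured in every supplied dataset.

    Mirrors the construction of the induced interactome: proteins with
    no corresponding gene in all datasets are removed, and the ordered
    pair set at shortest-path distance <= 2 is computed on the induced
    graph by depth-2 BFS.
    """
    if not datasets:
        raise ValueError("induce_common needs at least one dataset")
    keep = set(network.graph.nodes)
    for ds in datasets:
        keep &= set(ds.gene_ids)
    if not keep:
        raise DegenerateNetworkError(
            "no network gene is measured in all supplied datasets"
        )
    induced = InteractionNetwork(graph=network.graph.subgraph(keep).copy())
    induced.compute_dist2_pairs()
    return induced
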