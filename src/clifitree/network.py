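"""Feature-interaction distance matrices and LAVA neighbourhoods.

The latent-split models need, for every feature, the set of features it is
allowed to co-vary with.  That set comes from a feature-level interaction
graph built from (i) a feature → gene mapping, where features sharing a gene
are adjacent, and (ii) a STRING-style gene-gene interaction edge list kept
above a confidence threshold (0.7 by default, matching the usual STRING
"high confidence" cut).  Distances are shortest-path hop counts over this
adjacency graph; the distance parameter θ then selects each feature's
neighbourhood as every feature within θ hops (always including itself).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionEdge",
    "FeatureDistanceMatrix",
    "parse_interaction_table",
    "build_feature_distance_matrix",
    "neighbourhoods",
    "identity_neighbourhoods",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected gene/protein interaction with a confidence in [0, 1]."""

    id_a: str
    id_b: str
    confidence: float

    def key(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


@dataclass
class FeatureDistanceMatrix:
    """p × p hop distances between features; unreachable pairs are +inf."""

    values: pd.DataFrame  # index/columns = feature names

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.diag(v) == 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def feature_names(self) -> list[str]:
        return self.values.index.tolist()

    def to_csv(self, path) -> None:
        out = self.values.replace(np.inf, "inf")
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        df = df.replace("inf", np.inf).astype(float)
        return cls(df)


def parse_interaction_table(
    source, confidence_threshold: float = 0.7
) -> list[InteractionEdge]:
    """Read a STRING-style edge table (two ids + combined score).

    Accepts a path or text stream, tab- or comma-separated.  Scores above 1
    are taken to be on STRING's 0-1000 scale and divided by 1000.  Edges
    below ``confidence_threshold`` are dropped; duplicates (in either
    orientation) collapse to the highest-confidence copy; malformed rows are
    skipped with a log message.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh: io.TextIOBase = open(source)
        close = True
    else:
        fh = source
        close = False
    best: dict[frozenset, InteractionEdge] = {}
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 3:
                logger.warning("skipping malformed row %d: %r", lineno, line)
                continue
            a, b = parts[0].strip(), parts[1].strip()
            try:
                score = float(parts[2])
            except ValueError:
                # likely a header row
                logger.info("skipping non-numeric row %d: %r", lineno, line)
                continue
            if score > 1.0:
                score /= 1000.0
            if score < confidence_threshold:
                continue
            edge = InteractionEdge(a, b, score)
            k = edge.key()
            if k not in best or best[k].confidence < score:
                best[k] = edge
    finally:
        if close:
            fh.close()
    if not best:
        logger.warning("no edges passed the confidence threshold")
    return list(best.values())


def build_feature_distance_matrix(
    edges: list[InteractionEdge],
    feature_to_gene: dict[str, str | list[str]],
    feature_names: list[str] | None = None,
) -> FeatureDistanceMatrix:
    """Hop distances between features through the gene-interaction graph.

    Two features are adjacent (distance 1) when they map to a common gene or
    their genes interact; longer distances are shortest-path hop counts over
    those adjacencies.  Features with no gene mapping (or unmatched
    identifiers) keep a self-only neighbourhood: distance 0 to themselves,
    +inf elsewhere.
    """
    if feature_names is None:
        feature_names = list(feature_to_gene)
    genes_of: dict[str, set[str]] = {}
    for f in feature_names:
        g = feature_to_gene.get(f)
        if g is None:
            logger.warning("feature %r has no gene mapping; self-only", f)
            genes_of[f] = set()
        elif isinstance(g, str):
            genes_of[f] = {g.strip()}
        else:
            genes_of[f] = {x.strip() for x in g}

    gene_graph = nx.Graph()
    for e in edges:
        gene_graph.add_edge(e.id_a, e.id_b)

    G = nx.Graph()
    G.add_nodes_from(feature_names)
    for i, a in enumerate(feature_names):
        for b in feature_names[i + 1:]:
            ga, gb = genes_of[a], genes_of[b]
            if ga & gb:
                G.add_edge(a, b)
                continue
            if any(
                gene_graph.has_edge(x, y) for x in ga for y in gb
            ):
                G.add_edge(a, b)

    p = len(feature_names)
    mat = np.full((p, p), np.inf)
    np.fill_diagonal(mat, 0.0)
    pos = {f: i for i, f in enumerate(feature_names)}
    for f, lengths in nx.all_pairs_shortest_path_length(G):
        for g, d in lengths.items():
            mat[pos[f], pos[g]] = float(d)
    return FeatureDistanceMatrix(pd.DataFrame(mat, index=feature_names, columns=feature_names))


def neighbourhoods(matrix: FeatureDistanceMatrix, theta: float) -> list[np.ndarray]:
    """θ-thresholded neighbour sets: sorted indices with distance ≤ θ.

    ``theta=0`` yields identity neighbourhoods (every feature alone), under
    which the LAVA models reduce exactly to their plain counterparts.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    v = matrix.values.to_numpy()
    return [np.flatnonzero(v[j] <= theta) for j in range(v.shape[0])]


def identity_neighbourhoods(p: int) -> list[np.ndarray]:
    """Each feature alone — the θ=0 neighbourhood index."""
    return [np.array([j]) for j in range(p)]
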