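"""Protein similarity graph construction and Markov clustering (MCL).

Protein similarity is supplied as BLAST bit scores.  Each score is normalized
by the larger of the two self scores,

    norm_score(x, y) = bit_score(x, y) / max(bit_score(x, x), bit_score(y, y)),

so a protein compared with itself scores 1.  Because the distribution of
normalized scores between two organisms depends on their phylogenetic
distance, scores within each unordered species pair are then divided by the
98th percentile of that pair's score distribution.  The resulting graph is
clustered with MCL; running MCL repeatedly at increasing inflation yields a
hierarchy of progressively finer protein sub-families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)


def normalize_scores(edges: pd.DataFrame) -> pd.DataFrame:
    """Symmetrize directed BLAST hits and normalize by the max self score.

    ``edges`` must have columns ``query, subject, bitscore`` and contain a
    self hit for every node that appears in any row.  Asymmetric hit pairs
    (x→y and y→x) are symmetrized by taking the maximum bit score before
    normalization.  The result has canonical undirected rows (``x`` <= ``y``)
    with columns ``x, y, bitscore, norm_score``; self rows are retained with
    ``norm_score`` 1.
    """
    self_rows = edges[edges["query"] == edges["subject"]]
    self_score = dict(zip(self_rows["query"], self_rows["bitscore"]))

    nodes = pd.unique(pd.concat([edges["query"], edges["subject"]], ignore_index=True))
    missing = [n for n in nodes if n not in self_score]
    if missing:
        raise ValueError(
            f"no self score for node(s) {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
            + "; self hits are required for normalization"
        )

    x = edges[["query", "subject"]].min(axis=1)
    y = edges[["query", "subject"]].max(axis=1)
    sym = (
        pd.DataFrame({"x": x, "y": y, "bitscore": edges["bitscore"].to_numpy()})
        .groupby(["x", "y"], sort=False, as_index=False)["bitscore"]
        .max()
    )
    denom = np.maximum(sym["x"].map(self_score), sym["y"].map(self_score))
    sym["norm_score"] = sym["bitscore"] / denom
    over = sym["norm_score"] > 1.0
    if over.any():
        logger.warning(
            "%d edges have bit score above both self scores (norm_score > 1); "
            "input anomaly", int(over.sum()),
        )
    return sym


def rescale_by_species_pair(
    edges: pd.DataFrame,
    gene_species: Mapping[str, str],
    percentile: float = 98.0,
) -> pd.DataFrame:
    """Divide each norm_score by its species pair's ``percentile`` value.

    Each edge belongs to the unordered pair of species of its endpoints;
    within-species edges form their own pair.  Percentiles use linear
    interpolation between order statistics.  Self rows (x == y) are excluded
    both from the percentile distributions and from the output: graph
    self-loops are re-derived by MCL.  A pair with fewer than two edges uses
    its single score as divisor (rescaled 1.0), with a warning.

    Adds columns ``species_pair`` and ``rescaled_score``; rescaled values may
    exceed 1 (capping is applied at graph construction).
    """
    edges = edges[edges["x"] != edges["y"]].copy()
    sp_x = edges["x"].map(gene_species)
    sp_y = edges["y"].map(gene_species)
    unknown = edges.loc[sp_x.isna() | sp_y.isna()]
    if len(unknown):
        raise ValueError(
            f"species unknown for genes in edges such as "
            f"{unknown.iloc[0][['x', 'y']].tolist()}"
        )
    edges["species_pair"] = [
        "|".join(sorted((a, b))) for a, b in zip(sp_x, sp_y)
    ]
    divisors = {}
    for pair, grp in edges.groupby("species_pair"):
        vals = grp["norm_score"].to_numpy()
        if len(vals) < 2:
            logger.warning(
                "species pair %s has a single edge; using its own score as "
                "rescaling divisor", pair,
            )
            divisors[pair] = float(vals[0]) if vals[0] > 0 else 1.0
        else:
            d = float(np.percentile(vals, percentile))
            divisors[pair] = d if d > 0 else 1.0
    edges["rescaled_score"] = edges["norm_score"] / edges["species_pair"].map(divisors)
    return edges


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over gene ids with a sparse weight matrix."""

    nodes: list[str]
    matrix: sparse.csr_matrix  # symmetric, non-negative, no explicit diagonal

    @classmethod
    def from_edges(
        cls,
        edges: pd.DataFrame,
        weight_col: str = "rescaled_score",
        nodes: Sequence[str] | None = None,
        cap: bool = True,
    ) -> "SimilarityGraph":
        """Build the graph from canonical undirected edge rows.

        ``nodes`` may add isolated vertices (e.g. proteins with only a self
        hit).  With ``cap`` (default), weights above 1 are saturated to 1.0:
        the top ~2% of each species pair are saturated by design of the
        98th-percentile rescaling.
        """
        node_list = list(dict.fromkeys(
            (list(nodes) if nodes is not None else [])
            + list(edges["x"]) + list(edges["y"])
        ))
        index = {n: i for i, n in enumerate(node_list)}
        w = edges[weight_col].to_numpy(dtype=float)
        if cap:
            w = np.minimum(w, 1.0)
        if (w < 0).any():
            raise ValueError("negative edge weights")
        i = edges["x"].map(index).to_numpy()
        j = edges["y"].map(index).to_numpy()
        off = i != j
        n = len(node_list)
        m = sparse.coo_matrix(
            (np.concatenate([w[off], w[off]]),
             (np.concatenate([i[off], j[off]]), np.concatenate([j[off], i[off]]))),
            shape=(n, n),
        ).tocsr()
        return cls(nodes=node_list, matrix=m)

    def subgraph(self, members: Sequence[str]) -> "SimilarityGraph":
        pos = {n: i for i, n in enumerate(self.nodes)}
        idx = [pos[m] for m in members]
        sub = self.matrix[idx, :][:, idx]
        return SimilarityGraph(nodes=list(members), matrix=sub.tocsr())


def _normalize_columns(m: sparse.csc_matrix) -> sparse.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return (m @ sparse.diags(1.0 / sums)).tocsc()


def _prune(m: sparse.csc_matrix, threshold: float) -> sparse.csc_matrix:
    """Drop entries below threshold, always keeping each column's maximum."""
    m = m.tocsc()
    if m.nnz == 0:
        return m
    col_of_entry = np.repeat(np.arange(m.shape[1]), np.diff(m.indptr))
    colmax = np.zeros(m.shape[1])
    np.maximum.at(colmax, col_of_entry, m.data)
    keep = (m.data >= threshold) | (m.data >= colmax[col_of_entry])
    m.data[~keep] = 0.0
    m.eliminate_zeros()
    return m


def mcl(
    graph: "SimilarityGraph | sparse.spmatrix | np.ndarray",
    inflation: float,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
    add_self_loops: bool = True,
) -> list[list]:
    """Markov clustering of a non-negative weighted graph.

    The column-stochastic transition matrix is alternately expanded (matrix
    power ``expansion``) and inflated (entrywise power ``inflation`` followed
    by column renormalization), pruning entries below ``prune_threshold``,
    until the iterate changes by less than ``tol`` or ``max_iter`` is hit
    (warned).  Clusters are the connected components of the converged
    attractor structure and always partition the node set.

    Self-loops of weight equal to each node's maximum incident weight are
    added before normalization (weight 1 for isolated nodes), which makes the
    chain aperiodic.

    Returns clusters as lists of node labels (indices for raw matrices),
    each sorted, ordered by first member.
    """
    if isinstance(graph, SimilarityGraph):
        labels: Sequence = graph.nodes
        m = graph.matrix
    else:
        m = sparse.csr_matrix(graph)
        labels = list(range(m.shape[0]))
    n = m.shape[0]
    if n == 0:
        return []
    if (m.data < 0).any():
        raise ValueError("MCL requires non-negative weights")

    m = m.tolil()
    m.setdiag(0.0)
    m = m.tocsc()
    if add_self_loops:
        incident_max = np.zeros(n)
        if m.nnz:
            col_of_entry = np.repeat(np.arange(n), np.diff(m.indptr))
            np.maximum.at(incident_max, col_of_entry, m.data)
        incident_max[incident_max == 0] = 1.0
        m = (m + sparse.diags(incident_max)).tocsc()
    m = _normalize_columns(m)

    converged = False
    for _ in range(max_iter):
        prev = m
        for _ in range(expansion - 1):
            m = (m @ prev).tocsc()
        m.data = np.power(m.data, inflation)
        m = _prune(m, prune_threshold)
        m = _normalize_columns(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations; "
                       "interpreting current iterate", max_iter)

    interp_threshold = max(prune_threshold, 1e-8)
    m.data[m.data < interp_threshold] = 0.0
    m.eliminate_zeros()
    pattern = m + m.T
    n_comp, assignment = connected_components(pattern, directed=False)
    clusters: dict[int, list] = {}
    for node_idx, comp in enumerate(assignment):
        clusters.setdefault(comp, []).append(labels[node_idx])
    out = [sorted(c) for c in clusters.values()]
    out.sort(key=lambda c: c[0])
    assert sum(len(c) for c in out) == n, "MCL output must partition the nodes"
    return out


@dataclass
class ClusterNode:
    """A node of the inflation-sweep cluster hierarchy."""

    members: list[str]
    inflation: float | None
    children: list["ClusterNode"] = field(default_factory=list)

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def to_dict(self) -> dict:
        return {
            "inflation": self.inflation,
            "members": list(self.members),
            "children": [c.to_dict() for c in self.children],
        }

    def to_nested_string(self) -> str:
        """Newick-like nesting of cluster sizes, for display."""
        if not self.children:
            return str(len(self.members))
        return "(" + ",".join(c.to_nested_string() for c in self.children) + ")"


def cluster_hierarchy(
    graph: SimilarityGraph,
    inflation_schedule: Sequence[float],
    **mcl_kwargs,
) -> ClusterNode:
    """Hierarchical partitioning by MCL at increasing inflation (stringency).

    Level 0 clusters the full graph at the lowest inflation; each cluster is
    then re-clustered on its induced subgraph at the next inflation, and so
    on.  By construction every child's member set is a subset of its
    parent's.  The schedule must be strictly increasing.
    """
    schedule = list(inflation_schedule)
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError(f"inflation schedule must be strictly increasing: {schedule}")
    root = ClusterNode(members=list(graph.nodes), inflation=None)

    def _expand(node: ClusterNode, sub: SimilarityGraph, level: int) -> None:
        if level >= len(schedule):
            return
        for members in mcl(sub, inflation=schedule[level], **mcl_kwargs):
            child = ClusterNode(members=list(members), inflation=schedule[level])
            assert set(child.members) <= set(node.members)
            node.children.append(child)
            _expand(child, sub.subgraph(members), level + 1)

    _expand(root, graph, 0)
    return root


def classify_fnr_fixk(
    members: Iterable[str],
    msa: Mapping[str, str],
    cys_columns: Sequence[int],
) -> dict[str, set[str]]:
    """Split a mixed FNR/FixK group on the 4 iron-sulfur-cluster cysteines.

    FNR-type proteins coordinate an O2-labile [4Fe-4S] cluster through 4
    conserved cysteines; FixK-type proteins lack one or more of them.  A
    member is classified FNR iff the residue at all four supplied alignment
    columns (1-based) is ``C``; gaps count as non-cysteine.

    Returns ``{"FNR": set, "FixK": set}``.
    """
    cols = list(cys_columns)
    if len(set(cols)) != 4:
        raise ValueError("cys_columns must be 4 distinct alignment columns")
    fnr: set[str] = set()
    fixk: set[str] = set()
    for m in members:
        if m not in msa:
            raise ValueError(f"member {m!r} absent from the alignment")
        aligned = msa[m].upper()
        for c in cols:
            if not 1 <= c <= len(aligned):
                raise ValueError(
                    f"alignment column {c} out of range for member {m!r} "
                    f"(alignment length {len(aligned)})"
                )
        if all(aligned[c - 1] == "C" for c in cols):
            fnr.add(m)
        else:
            fixk.add(m)
    return {"FNR": fnr, "FixK": fixk}
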