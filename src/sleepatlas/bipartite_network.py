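"""Bipartite network construction and structural metrics.

The significance network links sleep phenotypes (rows) to metabolites
(columns), with an edge wherever the Model-1 association is significant; it
can be consolidated to sleep domains x metabolite sub- or superpathways, in
which case cell weights count the significant associations aggregated into
the cell and the binary incidence is their indicator.

Structural metrics follow the ecology-network tradition:

* connectance-style cluster coefficient, realized links / possible links;
* NODF nestedness (0–100, 100 = perfectly nested) based on paired overlap
  between nodes with strictly decreasing marginal totals, reported together
  with its reversed orientation (100 − NODF, so 0 = highly nested);
* a weighted NODF-style nestedness in [0, 1] that credits a pair only where
  the busier node's cell weights strictly dominate;
* Barber bipartite modularity Q maximized by a seeded label-switching
  heuristic with restarts;
* per-pair shared-partner counts and a Fruchterman–Reingold force-directed
  layout (via networkx) for visualization coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


class NetworkError(ValueError):
    pass


@dataclass
class BipartiteIncidence:
    row_labels: list
    col_labels: list
    binary: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.binary = np.asarray(self.binary, dtype=int)
        self.weights = np.asarray(self.weights)
        if self.binary.shape != (len(self.row_labels), len(self.col_labels)):
            raise NetworkError("matrix dimensions must match labels")
        if self.weights.shape != self.binary.shape:
            raise NetworkError("binary and weight matrices must share a shape")
        if np.any(self.weights < 0):
            raise NetworkError("weights must be nonnegative")
        if not np.array_equal(self.binary, (self.weights > 0).astype(int)):
            raise NetworkError("binary must be the indicator of positive weights")

    @property
    def shape(self):
        return self.binary.shape

    @property
    def n_links(self) -> int:
        return int(self.binary.sum())


@dataclass
class NetworkMetrics:
    links_per_node: float
    connected_rows: int
    connected_cols: int
    cluster_coefficient: float
    nestedness: float           # paper orientation: 0 = perfectly nested
    nodf: float                 # 0..100, 100 = perfectly nested
    weighted_nestedness: float  # 0..1, 1 = perfect nestedness
    modularity_Q: float
    mean_shared_partners_rows: float
    mean_shared_partners_cols: float

    def to_dict(self) -> dict:
        return asdict(self)


def build_incidence(results: pd.DataFrame, row_level: str = "phenotype",
                    col_level: str = "metabolite") -> BipartiteIncidence:
    """Incidence matrix of significant Model-1 associations.

    ``row_level`` in {phenotype, domain}; ``col_level`` in {metabolite,
    subpathway, superpathway}.  Consolidated cells sum the underlying
    significant-association counts; all-zero rows/columns are pruned.
    """
    if row_level not in ("phenotype", "domain"):
        raise NetworkError(f"unknown row level {row_level!r}")
    if col_level not in ("metabolite", "subpathway", "superpathway"):
        raise NetworkError(f"unknown column level {col_level!r}")
    sig = results.loc[results["significant"].astype(bool)]
    if sig.empty:
        return BipartiteIncidence([], [], np.zeros((0, 0), int), np.zeros((0, 0), int))
    weights = (
        sig.groupby([row_level, col_level]).size().unstack(fill_value=0).sort_index(axis=0).sort_index(axis=1)
    )
    W = weights.to_numpy(dtype=int)
    keep_r = W.sum(axis=1) > 0
    keep_c = W.sum(axis=0) > 0
    W = W[np.ix_(keep_r, keep_c)]
    return BipartiteIncidence(
        row_labels=list(weights.index[keep_r]),
        col_labels=list(weights.columns[keep_c]),
        binary=(W > 0).astype(int),
        weights=W,
    )


def cluster_coefficient(inc: BipartiteIncidence) -> float:
    """Network-level connectance: realized links / possible links."""
    R, C = inc.shape
    if R == 0 or C == 0:
        raise NetworkError("empty incidence matrix")
    return inc.n_links / (R * C)


def _mean_shared(binary: np.ndarray) -> float:
    n = binary.shape[0]
    if n < 2:
        return 0.0
    overlap = binary @ binary.T
    iu = np.triu_indices(n, k=1)
    return float(overlap[iu].mean())


def degree_stats(inc: BipartiteIncidence) -> dict:
    """Degree-based summaries: links per node and mean shared partners."""
    R, C = inc.shape
    if R == 0 or C == 0:
        raise NetworkError("empty incidence matrix")
    L = inc.n_links
    return {
        "links_per_node": L / (R + C),
        "connected_rows": int((inc.binary.sum(axis=1) > 0).sum()),
        "connected_cols": int((inc.binary.sum(axis=0) > 0).sum()),
        "mean_shared_partners_rows": _mean_shared(inc.binary),
        "mean_shared_partners_cols": _mean_shared(inc.binary.T),
    }


def nestedness_nodf(binary) -> float:
    """NODF nestedness of a binary matrix, in [0, 100].

    For every pair of rows with strictly decreasing marginal totals the
    paired overlap is the percentage of the sparser row's links also present
    in the busier row (0 when totals are tied); likewise for columns.  NODF
    averages all pair contributions.  100 = perfectly nested.
    """
    B = np.asarray(binary, dtype=int)
    if B.ndim != 2 or min(B.shape) < 1 or B.shape == (1, 1):
        raise NetworkError("NODF needs a matrix with at least two rows or columns")
    if np.any(B.sum(axis=1) == 0) or np.any(B.sum(axis=0) == 0):
        raise NetworkError("NODF requires no all-zero rows or columns")

    def _pairs(M: np.ndarray) -> list:
        fills = M.sum(axis=1)
        contrib = []
        for i, j in combinations(range(M.shape[0]), 2):
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            if fills[hi] == fills[lo]:
                contrib.append(0.0)
            else:
                shared = int((M[hi] & M[lo]).sum())
                contrib.append(100.0 * shared / fills[lo])
        return contrib

    contribs = _pairs(B) + _pairs(B.T)
    return float(np.mean(contribs)) if contribs else 0.0


def weighted_nestedness(weights) -> float:
    """Weighted NODF-style nestedness, normalized to [0, 1].

    A row pair contributes only when the busier row's marginal total is
    strictly larger; its contribution is the fraction of the sparser row's
    occupied cells whose weight is strictly exceeded in the busier row.
    Columns analogously.  Rank-based: invariant to scaling all weights.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.size == 0:
        raise NetworkError("need a nonempty weight matrix")
    if np.any(W < 0):
        raise NetworkError("weights must be nonnegative")

    def _pairs(M: np.ndarray) -> list:
        totals = M.sum(axis=1)
        contrib = []
        for i, j in combinations(range(M.shape[0]), 2):
            hi, lo = (i, j) if totals[i] > totals[j] else (j, i)
            occupied = M[lo] > 0
            if totals[hi] == totals[lo] or occupied.sum() == 0:
                contrib.append(0.0)
            else:
                dominated = (M[hi] > M[lo]) & occupied
                contrib.append(dominated.sum() / occupied.sum())
        return contrib

    contribs = _pairs(W) + _pairs(W.T)
    return float(np.mean(contribs)) if contribs else 0.0


# ---------------------------------------------------------------------------
# Barber bipartite modularity
# ---------------------------------------------------------------------------

def modularity_value(weights, row_modules, col_modules) -> float:
    """Barber bipartite modularity of a given partition.

    ``Q = (1/W) * sum_ij (A_ij - k_i d_j / W) [g_row(i) == g_col(j)]`` with
    ``W`` the total edge weight, ``k`` row strengths and ``d`` column
    strengths.
    """
    A = np.asarray(weights, dtype=float)
    W = A.sum()
    if W <= 0:
        raise NetworkError("total edge weight must be positive")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    Btil = A - np.outer(k, d) / W
    rm = np.asarray(row_modules)
    cm = np.asarray(col_modules)
    same = rm[:, None] == cm[None, :]
    return float((Btil * same).sum() / W)


def bipartite_modularity(weights, n_restarts: int = 20, seed: int = 0, max_sweeps: int = 200):
    """Maximize Barber modularity by label switching with seeded restarts.

    Returns ``(Q, partition)`` where ``partition`` maps row indices
    ``("row", i)`` and column indices ``("col", j)`` to module labels.
    The search always includes the single-module partition, so the returned
    Q is never below 0.
    """
    A = np.asarray(weights, dtype=float)
    if A.ndim != 2 or A.sum() <= 0:
        raise NetworkError("need a weight matrix with positive total weight")
    R, C = A.shape
    W = A.sum()
    Btil = A - np.outer(A.sum(axis=1), A.sum(axis=0)) / W
    rng = np.random.default_rng(seed)
    n_mod = max(R, C)

    best_Q, best_rm, best_cm = -np.inf, None, None
    for restart in range(n_restarts):
        if restart == 0:
            rm = np.zeros(R, dtype=int)  # single-module start
            cm = np.zeros(C, dtype=int)
        elif restart == 1:
            rm = np.arange(R) % n_mod    # every row its own module
            cm = rng.integers(0, n_mod, C)
        else:
            rm = rng.integers(0, n_mod, R)
            cm = rng.integers(0, n_mod, C)
        for _ in range(max_sweeps):
            changed = False
            # columns: assign to the module maximizing the summed affinity
            M = np.zeros((n_mod, C))
            for s in range(n_mod):
                M[s] = Btil[rm == s].sum(axis=0)
            new_cm = M.argmax(axis=0)
            gain = M[new_cm, np.arange(C)] > M[cm, np.arange(C)] + 1e-12
            if gain.any():
                cm = np.where(gain, new_cm, cm)
                changed = True
            # rows likewise
            Mr = np.zeros((n_mod, R))
            for s in range(n_mod):
                Mr[s] = Btil[:, cm == s].sum(axis=1)
            new_rm = Mr.argmax(axis=0)
            gain = Mr[new_rm, np.arange(R)] > Mr[rm, np.arange(R)] + 1e-12
            if gain.any():
                rm = np.where(gain, new_rm, rm)
                changed = True
            if not changed:
                # agglomerative escape: merge the module pair with the largest
                # positive cross-affinity, then resume switching
                mods = [s for s in range(n_mod) if (rm == s).any() or (cm == s).any()]
                best_gain, best_pair = 1e-12, None
                for a_i in range(len(mods)):
                    for b_i in range(a_i + 1, len(mods)):
                        s, t = mods[a_i], mods[b_i]
                        g = Btil[np.ix_(rm == s, cm == t)].sum() + Btil[np.ix_(rm == t, cm == s)].sum()
                        if g > best_gain:
                            best_gain, best_pair = g, (s, t)
                if best_pair is None:
                    break
                s, t = best_pair
                rm = np.where(rm == t, s, rm)
                cm = np.where(cm == t, s, cm)
        Q = modularity_value(A, rm, cm)
        if Q > best_Q:
            best_Q, best_rm, best_cm = Q, rm.copy(), cm.copy()

    partition = {("row", i): int(best_rm[i]) for i in range(R)}
    partition.update({("col", j): int(best_cm[j]) for j in range(C)})
    return best_Q, partition


# ---------------------------------------------------------------------------
# layout and reporting
# ---------------------------------------------------------------------------

def to_graph(inc: BipartiteIncidence) -> nx.Graph:
    """The univariate (projected-node) graph of the bipartite incidence."""
    G = nx.Graph()
    for i, r in enumerate(inc.row_labels):
        G.add_node(("row", r), bipartite=0)
    for j, c in enumerate(inc.col_labels):
        G.add_node(("col", c), bipartite=1)
    for i, r in enumerate(inc.row_labels):
        for j, c in enumerate(inc.col_labels):
            if inc.binary[i, j]:
                G.add_edge(("row", r), ("col", c), weight=float(inc.weights[i, j]))
    return G


def fr_layout(inc: BipartiteIncidence, iterations: int = 200, seed: int = 0) -> dict:
    """Fruchterman–Reingold force-directed coordinates, deterministic by seed."""
    G = to_graph(inc)
    if G.number_of_nodes() == 0:
        raise NetworkError("empty network has no layout")
    if G.number_of_nodes() == 1:
        return {next(iter(G.nodes)): np.zeros(2)}
    return nx.spring_layout(G, iterations=iterations, seed=seed, weight="weight")


def network_metrics(inc: BipartiteIncidence, seed: int = 0, n_restarts: int = 20) -> NetworkMetrics:
    """All structural metrics of one (consolidated) incidence matrix."""
    deg = degree_stats(inc)
    nodf = nestedness_nodf(inc.binary) if min(inc.shape) >= 1 and inc.shape != (1, 1) else np.nan
    Q, _ = bipartite_modularity(inc.weights, n_restarts=n_restarts, seed=seed)
    return NetworkMetrics(
        links_per_node=deg["links_per_node"],
        connected_rows=deg["connected_rows"],
        connected_cols=deg["connected_cols"],
        cluster_coefficient=cluster_coefficient(inc),
        nodf=nodf,
        nestedness=100.0 - nodf if np.isfinite(nodf) else np.nan,
        weighted_nestedness=weighted_nestedness(inc.weights),
        modularity_Q=Q,
        mean_shared_partners_rows=deg["mean_shared_partners_rows"],
        mean_shared_partners_cols=deg["mean_shared_partners_cols"],
    )


def restrict_to_superpathway(results: pd.DataFrame, superpathway: str) -> pd.DataFrame:
    return results.loc[results["superpathway"] == superpathway]


def metrics_report(results: pd.DataFrame, seed: int = 0, col_level: str = "subpathway") -> dict:
    """Per-superpathway metric breakdown of the domain x pathway network.

    Keys are superpathway names plus ``"all"``; subsets whose restricted
    network is degenerate (no significant cells, or a single row and column)
    are reported as null.
    """
    report = {}
    subsets = {"all": results}
    for sp in sorted(results["superpathway"].dropna().unique()):
        subsets[sp] = restrict_to_superpathway(results, sp)
    for name, sub in subsets.items():
        inc = build_incidence(sub, row_level="domain", col_level=col_level)
        if inc.n_links == 0 or inc.shape == (1, 1):
            report[name] = None
            continue
        report[name] = network_metrics(inc, seed=seed).to_dict()
    return report


def write_network(outdir, inc: BipartiteIncidence, results: pd.DataFrame,
                  seed: int = 0, iterations: int = 200) -> dict:
    """Write edge list, node table (with module and layout) and metric report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges = []
    for i, r in enumerate(inc.row_labels):
        for j, c in enumerate(inc.col_labels):
            if inc.binary[i, j]:
                edges.append({"row": r, "col": c, "weight": int(inc.weights[i, j])})
    pd.DataFrame(edges).to_csv(outdir / "edges.tsv", sep="\t", index=False)

    _, partition = bipartite_modularity(inc.weights, seed=seed)
    pos = fr_layout(inc, iterations=iterations, seed=seed)
    nodes = []
    for i, r in enumerate(inc.row_labels):
        nodes.append({"id": r, "type": "row", "degree": int(inc.binary[i].sum()),
                      "module": partition[("row", i)],
                      "x": pos[("row", r)][0], "y": pos[("row", r)][1]})
    for j, c in enumerate(inc.col_labels):
        nodes.append({"id": c, "type": "col", "degree": int(inc.binary[:, j].sum()),
                      "module": partition[("col", j)],
                      "x": pos[("col", c)][0], "y": pos[("col", c)][1]})
    pd.DataFrame(nodes).to_csv(outdir / "nodes.tsv", sep="\t", index=False)

    report = metrics_report(results, seed=seed)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return {
        "edges": str(outdir / "edges.tsv"),
        "nodes": str(outdir / "nodes.tsv"),
        "metrics": str(outdir / "metrics.json"),
    }
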