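"""Non-overlapping SNP windows and per-window neighbor-joining genealogies.

The genome is cut into consecutive blocks of exactly ``window_snps`` sites
(default 100); any trailing remainder is dropped.  Within each window an
unrooted NJ tree is built over haplotypes from p-distances on co-called
sites.  Any allele mismatch counts as a difference, so the multiallelic
dialect is handled transparently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geno_io import (
    MISSING,
    AnalysisConfig,
    GenomicWindow,
    HaplotypeMatrix,
)

logger = logging.getLogger("tigerwing")


class UndefinedDistanceError(ValueError):
    """A haplotype pair shares no co-called site; the window tree is undefined."""


# ---------------------------------------------------------------------------
# unrooted trees
# ---------------------------------------------------------------------------

class Tree:
    """A small unrooted tree over named leaves.

    Stored as an undirected adjacency map with branch lengths.  This is all
    the topology-weighting stage needs: leaf enumeration, topological (edge
    count) distances, bipartitions and newick serialization.
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.leaf_name: dict[int, str] = {}
        self._next = 0

    # -- construction ------------------------------------------------------

    def add_node(self, name: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if name is not None:
            self.leaf_name[nid] = name
        return nid

    def add_edge(self, a: int, b: int, length: float) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    # -- queries -----------------------------------------------------------

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_name)

    @property
    def leaf_names(self) -> list[str]:
        return [self.leaf_name[i] for i in self.leaves]

    def node_for(self, name: str) -> int:
        for nid, nm in self.leaf_name.items():
            if nm == name:
                return nid
        raise KeyError(f"leaf {name!r} not in tree")

    def total_length(self) -> float:
        return sum(l for a in self.adj for l in self.adj[a].values()) / 2.0

    def topo_distances(self, names: Sequence[str]) -> np.ndarray:
        """Edge-count distances between the named leaves (BFS per leaf)."""
        ids = [self.node_for(n) for n in names]
        k = len(ids)
        out = np.zeros((k, k), dtype=np.int32)
        for a, src in enumerate(ids):
            dist = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in self.adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            for b, dst in enumerate(ids):
                out[a, b] = dist[dst]
        return out

    def path_distances(self, names: Sequence[str]) -> np.ndarray:
        """Branch-length (patristic) distances between named leaves."""
        ids = [self.node_for(n) for n in names]
        k = len(ids)
        out = np.zeros((k, k), dtype=float)
        for a, src in enumerate(ids):
            dist = {src: 0.0}
            frontier = [src]
            while frontier:
                nxt = []
                for u in frontier:
                    for v, l in self.adj[u].items():
                        if v not in dist:
                            dist[v] = dist[u] + l
                            nxt.append(v)
                frontier = nxt
            for b, dst in enumerate(ids):
                out[a, b] = dist[dst]
        return out

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions of the leaf-name set, one per internal edge."""
        names = set(self.leaf_name.values())
        out: set[frozenset] = set()

        def side(u: int, v: int) -> frozenset:
            # leaves reachable from v without crossing edge (u, v)
            seen = {u, v}
            stack = [v]
            found = []
            while stack:
                x = stack.pop()
                if x in self.leaf_name:
                    found.append(self.leaf_name[x])
                for y in self.adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            return frozenset(found)

        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    s = side(u, v)
                    if 1 < len(s) < len(names) - 1:
                        out.add(frozenset({s, frozenset(names - s)}))
        return out

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        # root at the largest-id internal node (deterministic)
        internal = [n for n in self.adj if n not in self.leaf_name]
        root = max(internal) if internal else next(iter(self.adj))

        def rec(u: int, parent: int | None) -> str:
            kids = [v for v in self.adj[u] if v != parent]
            if not kids:
                return self.leaf_name.get(u, str(u))
            parts = []
            for v in sorted(kids):
                parts.append(f"{rec(v, u)}:{self.adj[u][v]:.10g}")
            label = self.leaf_name.get(u, "")
            return f"({','.join(parts)}){label}"

        return rec(root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        """Parse a newick string (via dendropy) into a Tree."""
        import dendropy

        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        t = cls()
        ids: dict = {}
        for node in dt.preorder_node_iter():
            name = node.taxon.label if node.taxon is not None else None
            nid = t.add_node(name)
            ids[node] = nid
            if node.parent_node is not None:
                l = node.edge.length if node.edge.length is not None else 0.0
                t.add_edge(ids[node.parent_node], nid, float(l))
        # suppress a degree-2 artificial root, if any
        for nid in list(t.adj):
            if nid not in t.leaf_name and len(t.adj[nid]) == 2:
                (a, la), (b, lb) = list(t.adj[nid].items())
                del t.adj[a][nid]
                del t.adj[b][nid]
                del t.adj[nid]
                t.add_edge(a, b, la + lb)
        return t


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(
    hm: HaplotypeMatrix, cfg: AnalysisConfig | None = None
) -> list[GenomicWindow]:
    """Consecutive blocks of exactly cfg.window_snps sites; remainder dropped.

    The bp span of a window is [first position, last position + 1) in the
    0-based half-open internal convention.
    """
    cfg = cfg or AnalysisConfig()
    w = cfg.window_snps
    n_full = hm.n_sites // w
    if n_full == 0:
        logger.warning(
            "fewer than %d sites (%d); no windows", w, hm.n_sites
        )
        return []
    out = []
    for k in range(n_full):
        lo, hi = k * w, (k + 1) * w
        out.append(
            GenomicWindow(
                chrom=hm.chrom,
                start=int(hm.positions[lo]),
                end=int(hm.positions[hi - 1]) + 1,
                site_lo=lo,
                site_hi=hi,
            )
        )
    return out


def pairwise_distance(
    hm: HaplotypeMatrix,
    window: GenomicWindow,
    hap_idx: np.ndarray | None = None,
) -> np.ndarray:
    """p-distance matrix over haplotypes in a window.

    d(i, j) = (# co-called sites with differing alleles) / (# co-called
    sites).  A pair with zero co-called sites makes the tree undefined and
    raises :class:`UndefinedDistanceError`.
    """
    a = hm.alleles[window.site_lo:window.site_hi]
    if hap_idx is not None:
        a = a[:, hap_idx]
    called = a != MISSING
    both = called[:, :, None] & called[:, None, :]
    neq = a[:, :, None] != a[:, None, :]
    diff = (neq & both).sum(axis=0)
    co = both.sum(axis=0)
    off = ~np.eye(co.shape[0], dtype=bool)
    if (co[off] == 0).any():
        raise UndefinedDistanceError(
            f"haplotype pair with no co-called sites in window "
            f"[{window.start}, {window.end})"
        )
    with np.errstate(invalid="ignore"):
        D = diff / co
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: np.ndarray, labels: Sequence[str]) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    When several Q-matrix entries attain the minimum, the lexicographically
    smallest index pair (in current working order) is joined.  Negative
    branch-length estimates are clamped to zero after estimation; the
    topology is kept.
    """
    D = np.array(D, dtype=float)
    n = len(labels)
    if n < 4:
        raise ValueError("neighbor joining needs at least 4 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have zero diagonal")

    tree = Tree()
    nodes = [tree.add_node(lab) for lab in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, 1)
        k = int(np.argmin(Q[iu]))  # first minimum => smallest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = tree.add_node()
        tree.add_edge(nodes[i], parent, max(0.0, li))
        tree.add_edge(nodes[j], parent, max(0.0, lj))
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        last = np.append(dnew[keep], 0.0)
        D = np.hstack([D, last[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    # final star join of the last three nodes
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = tree.add_node()
    tree.add_edge(nodes[a], center, max(0.0, la))
    tree.add_edge(nodes[b], center, max(0.0, lb))
    tree.add_edge(nodes[c], center, max(0.0, lc))
    return tree


# ---------------------------------------------------------------------------
# track
# ---------------------------------------------------------------------------

@dataclass
class WindowTreeTrack:
    """Per-window unrooted genealogies with interval coordinates.

    Windows whose distance matrix is undefined (a haplotype pair with no
    co-called sites) are dropped and counted in ``n_dropped``.
    """

    windows: list[GenomicWindow]
    trees: list[Tree]
    n_sites_used: list[int]
    labels: list[str]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.windows)

    def to_newick_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for w, t in zip(self.windows, self.trees):
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{t.to_newick()}\n")


def build_window_trees(
    hm: HaplotypeMatrix,
    cfg: AnalysisConfig | None = None,
    hap_subset: Sequence[str] | None = None,
) -> WindowTreeTrack:
    """Windows plus one NJ genealogy per window.

    ``hap_subset`` (haplotype labels, "<sample>_1"/"<sample>_2") restricts
    the genealogies to the quartet's haplotypes; by default all are used.
    """
    cfg = cfg or AnalysisConfig()
    all_labels = hm.hap_labels
    if hap_subset is None:
        hap_idx = None
        labels = all_labels
    else:
        lookup = {lab: i for i, lab in enumerate(all_labels)}
        hap_idx = np.array([lookup[l] for l in hap_subset], dtype=np.intp)
        labels = list(hap_subset)
    if len(labels) < 4:
        raise ValueError("need at least 4 haplotypes for window trees")

    windows = make_windows(hm, cfg)
    kept_w, trees, n_used = [], [], []
    dropped = 0
    for w in windows:
        try:
            D = pairwise_distance(hm, w, hap_idx)
        except UndefinedDistanceError:
            dropped += 1
            logger.warning(
                "dropping window [%d, %d): undefined distances", w.start, w.end
            )
            continue
        trees.append(nj_tree(D, labels))
        kept_w.append(w)
        n_used.append(w.n_sites)
    return WindowTreeTrack(
        windows=kept_w,
        trees=trees,
        n_sites_used=n_used,
        labels=labels,
        n_dropped=dropped,
    )
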