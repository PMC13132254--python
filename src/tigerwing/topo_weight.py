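"""Topology weighting of window genealogies over a two-species quartet.

For a quartet of taxon groups — subspecies sspA1, sspA2 of species A and
sspB1, sspB2 of species B — each window tree is summarized by the fraction
of one-leaf-per-group tuples whose induced quartet matches each of the three
possible unrooted group topologies:

* species topology      (sspA1, sspA2 | sspB1, sspB2)
* introgression topology (sspA1, sspB1 | sspA2, sspB2) — the co-mimics cluster
* third topology        (sspA1, sspB2 | sspA2, sspB1)

Which topology counts as introgression-compatible is fixed by the declared
group roles, never inferred from the data.  A window is *intro95* when the
introgression-topology weight is at least 0.95.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geno_io import AnalysisConfig, GenomicWindow
from .windows_trees import Tree, WindowTreeTrack

logger = logging.getLogger("tigerwing")

TOPOLOGIES = ("species", "introgression", "third")


@dataclass(frozen=True)
class QuartetSpec:
    """Four disjoint nonempty haplotype groups with fixed roles.

    ``g1`` = sspA1, ``g2`` = sspA2, ``g3`` = sspB1, ``g4`` = sspB2.  The
    species topology is g1g2|g3g4, the introgression topology g1g3|g2g4
    (clustering of the co-mimetic sspA1 and sspB1) and the third topology
    g1g4|g2g3.
    """

    g1: tuple[str, ...]
    g2: tuple[str, ...]
    g3: tuple[str, ...]
    g4: tuple[str, ...]
    labels: tuple[str, str, str, str] = ("sspA1", "sspA2", "sspB1", "sspB2")

    def __post_init__(self) -> None:
        groups = [self.g1, self.g2, self.g3, self.g4]
        if any(len(g) == 0 for g in groups):
            raise ValueError("quartet groups must be nonempty")
        flat = list(itertools.chain.from_iterable(groups))
        if len(set(flat)) != len(flat):
            raise ValueError("quartet groups must be disjoint")

    @property
    def groups(self) -> list[tuple[str, ...]]:
        return [self.g1, self.g2, self.g3, self.g4]

    @property
    def all_members(self) -> list[str]:
        return list(itertools.chain.from_iterable(self.groups))

    def n_tuples(self) -> int:
        return len(self.g1) * len(self.g2) * len(self.g3) * len(self.g4)

    def swap_species(self) -> "QuartetSpec":
        """Relabel species A <-> B: (g1,g2,g3,g4) -> (g3,g4,g1,g2)."""
        return QuartetSpec(self.g3, self.g4, self.g1, self.g2, self.labels)


# ---------------------------------------------------------------------------
# quartet topology of four leaves
# ---------------------------------------------------------------------------

def quartet_topology(tree: Tree, a: str, b: str, c: str, d: str) -> str:
    """The split of the 4-leaf subtree induced by leaves a, b, c, d.

    Returns ``"ab|cd"``, ``"ac|bd"`` or ``"ad|bc"``.  In a fully resolved
    (binary) unrooted tree every induced 4-leaf subtree is resolved, and the
    pairing whose two connecting paths are disjoint minimizes the sum of
    topological path lengths — strictly, because the internal path of the
    Steiner subtree contains at least one edge.
    """
    names = [a, b, c, d]
    if len(set(names)) != 4:
        raise ValueError("quartet leaves must be distinct")
    D = tree.topo_distances(names)
    sums = (D[0, 1] + D[2, 3], D[0, 2] + D[1, 3], D[0, 3] + D[1, 2])
    return ("ab|cd", "ac|bd", "ad|bc")[int(np.argmin(sums))]


def _weights_from_topo_matrix(
    D: np.ndarray,
    idx: list[np.ndarray],
    exhaustive_cap: int,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str]:
    """Topology weights from an edge-count distance matrix over quartet leaves.

    ``idx`` holds, per group, the row indices of its members in ``D``.
    Returns (weights over (species, introgression, third), method string).
    """
    i1, i2, i3, i4 = idx
    n_tuples = len(i1) * len(i2) * len(i3) * len(i4)
    if n_tuples <= exhaustive_cap:
        s_species = (
            D[np.ix_(i1, i2)][:, :, None, None]
            + D[np.ix_(i3, i4)][None, None, :, :]
        )
        s_intro = (
            D[np.ix_(i1, i3)][:, None, :, None]
            + D[np.ix_(i2, i4)][None, :, None, :]
        )
        s_third = (
            D[np.ix_(i1, i4)][:, None, None, :]
            + D[np.ix_(i2, i3)][None, :, :, None]
        )
        stacked = np.stack(
            [s_species, s_intro, s_third]
        ).reshape(3, -1)
        winner = np.argmin(stacked, axis=0)
        counts = np.bincount(winner, minlength=3)
        return counts / n_tuples, "exhaustive"
    # Monte Carlo: with-replacement sampling of tuples
    a = rng.choice(i1, n_draws)
    b = rng.choice(i2, n_draws)
    c = rng.choice(i3, n_draws)
    d = rng.choice(i4, n_draws)
    s = np.stack([D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c]])
    counts = np.bincount(np.argmin(s, axis=0), minlength=3)
    return counts / n_draws, f"montecarlo({n_draws})"


def weight_window(
    tree: Tree,
    quartet: QuartetSpec,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """(w_species, w_intro, w_third) for one window tree; weights sum to 1.

    Exhaustive enumeration of one-leaf-per-group tuples up to
    ``cfg.exhaustive_cap`` tuples (default 50,000); beyond that, Monte Carlo
    with ``cfg.mc_draws`` with-replacement draws.
    """
    cfg = cfg or AnalysisConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    members = quartet.all_members
    D = tree.topo_distances(members)
    offsets = np.cumsum([0] + [len(g) for g in quartet.groups])
    idx = [
        np.arange(offsets[k], offsets[k + 1], dtype=np.intp) for k in range(4)
    ]
    w, _method = _weights_from_topo_matrix(
        D, idx, cfg.exhaustive_cap, cfg.mc_draws, rng
    )
    return float(w[0]), float(w[1]), float(w[2])


# ---------------------------------------------------------------------------
# track-level weighting
# ---------------------------------------------------------------------------

@dataclass
class TopologyWeightTrack:
    """Per-window weights of the three quartet topologies.

    ``weights`` is an (n_windows, 3) array in the order (species,
    introgression, third); each row sums to 1 (exactly for exhaustive
    enumeration, by count construction for Monte Carlo).
    """

    windows: list[GenomicWindow]
    weights: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.windows), 3):
            raise ValueError("weights must be n_windows x 3")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def w_species(self) -> np.ndarray:
        return self.weights[:, 0]

    @property
    def w_intro(self) -> np.ndarray:
        return self.weights[:, 1]

    @property
    def w_third(self) -> np.ndarray:
        return self.weights[:, 2]

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([w.midpoint for w in self.windows])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "window_id": np.arange(len(self)),
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "w_species": self.weights[:, 0],
                "w_intro": self.weights[:, 1],
                "w_third": self.weights[:, 2],
                "method": self.method,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TopologyWeightTrack":
        df = pd.read_csv(path, sep="\t")
        windows = [
            GenomicWindow(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()
        ]
        w = df[["w_species", "w_intro", "w_third"]].to_numpy(float)
        method = str(df["method"].iloc[0]) if len(df) else "exhaustive"
        return cls(windows=windows, weights=w, method=method)


def weight_track(
    track: WindowTreeTrack,
    quartet: QuartetSpec,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> TopologyWeightTrack:
    """Topology weights for every window tree in a track."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(seed)
    members = quartet.all_members
    offsets = np.cumsum([0] + [len(g) for g in quartet.groups])
    idx = [
        np.arange(offsets[k], offsets[k + 1], dtype=np.intp) for k in range(4)
    ]
    rows = np.empty((len(track), 3), dtype=float)
    method = "exhaustive"
    for k, tree in enumerate(track.trees):
        D = tree.topo_distances(members)
        rows[k], method = _weights_from_topo_matrix(
            D, idx, cfg.exhaustive_cap, cfg.mc_draws, rng
        )
    return TopologyWeightTrack(
        windows=list(track.windows), weights=rows, method=method, seed=seed
    )


def intro95_count(
    track: TopologyWeightTrack,
    region: GenomicWindow,
    cfg: AnalysisConfig | None = None,
) -> int:
    """Windows whose midpoint lies in ``region`` and whose introgression
    weight is at least ``cfg.weight_threshold`` (the intro95 statistic)."""
    cfg = cfg or AnalysisConfig()
    if len(track) == 0:
        return 0
    mids = track.midpoints
    span_lo = track.windows[0].start
    span_hi = track.windows[-1].end
    if region.end <= span_lo or region.start >= span_hi:
        logger.warning(
            "focal region [%d, %d) outside track span [%d, %d)",
            region.start, region.end, span_lo, span_hi,
        )
        return 0
    inside = (mids >= region.start) & (mids < region.end)
    return int(np.sum(inside & (track.w_intro >= cfg.weight_threshold)))
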