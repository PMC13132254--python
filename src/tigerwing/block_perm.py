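"""Block-permutation significance test for localized introgression.

The observed statistic is the intro95 count inside a fixed focal region (the
association peak).  The null is built by shuffling the order of contiguous
100 kb blocks of the topology-weight track: windows travel with their block,
preserving within-block order, so local autocorrelation of the weights is
kept while any localized excess is dispersed.  The focal region stays fixed
in genomic coordinates while the content moves, and the intro95 count is
recomputed per shuffle.  The p-value uses the add-one convention
p = (1 + #{null >= observed}) / (1 + n_perm), so p is never zero and equals
1 when no introgression-compatible window exists anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geno_io import AnalysisConfig, GenomicWindow
from .topo_weight import TopologyWeightTrack, intro95_count

logger = logging.getLogger("tigerwing")


@dataclass
class PermTestResult:
    observed: int
    null_counts: np.ndarray
    n_perm: int
    p_value: float
    block_bp: int
    focal: GenomicWindow
    seed: int
    degenerate: bool = False  # observed 0 with an all-zero null

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts)
        if len(self.null_counts) != self.n_perm:
            raise ValueError("null_counts length must equal n_perm")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "chrom\tfocal_start\tfocal_end\tobserved\tn_perm\tp_value"
                "\tblock_bp\tseed\tdegenerate\n"
            )
            fh.write(
                f"{self.focal.chrom}\t{self.focal.start}\t{self.focal.end}\t"
                f"{self.observed}\t{self.n_perm}\t{self.p_value:.8g}\t"
                f"{self.block_bp}\t{self.seed}\t{int(self.degenerate)}\n"
            )


def assign_blocks(
    track: TopologyWeightTrack, block_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Map windows to contiguous blocks tiling [track start, track end).

    Returns (block index per window, block spans).  Windows are assigned by
    midpoint with half-open blocks (a midpoint exactly on a boundary belongs
    to the right-hand block).  The trailing partial block is kept.
    """
    if block_bp <= 0:
        raise ValueError("block_bp must be positive")
    if len(track) == 0:
        raise ValueError("empty topology-weight track")
    t0 = track.windows[0].start
    t1 = track.windows[-1].end
    n_blocks = int(np.ceil((t1 - t0) / block_bp))
    mids = track.midpoints
    block_of = np.minimum(
        ((mids - t0) // block_bp).astype(np.intp), n_blocks - 1
    )
    edges = t0 + block_bp * np.arange(n_blocks + 1, dtype=np.int64)
    edges[-1] = t1
    spans = np.diff(edges)
    return block_of, spans


def permute_and_test(
    track: TopologyWeightTrack,
    focal: GenomicWindow,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> PermTestResult:
    """Observed intro95 in the focal region against the block-shuffle null."""
    cfg = cfg or AnalysisConfig()
    if cfg.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t0 = track.windows[0].start
    t1 = track.windows[-1].end
    if focal.end <= t0 or focal.start >= t1:
        raise ValueError("focal region does not overlap the track span")

    observed = intro95_count(track, focal, cfg)
    mids = track.midpoints
    in_focal = (mids >= focal.start) & (mids < focal.end)
    if not in_focal.any():
        logger.warning("focal region contains zero windows")

    block_of, spans = assign_blocks(track, cfg.perm_block_bp)
    n_blocks = len(spans)
    block_starts = t0 + np.concatenate([[0], np.cumsum(spans[:-1])])
    flagged = track.w_intro >= cfg.weight_threshold

    # per block: sorted offsets (midpoint - block start) of flagged windows
    offsets = [
        np.sort(mids[flagged & (block_of == b)] - block_starts[b])
        for b in range(n_blocks)
    ]

    rng = np.random.default_rng(seed)
    # one permutation of block order per row
    keys = rng.random((cfg.n_perm, n_blocks))
    order = np.argsort(keys, axis=1)  # order[p, k] = block placed at slot k
    # new start of the block occupying slot k
    slot_spans = spans[order]
    slot_starts = (
        t0
        + np.concatenate(
            [np.zeros((cfg.n_perm, 1), dtype=np.int64),
             np.cumsum(slot_spans[:, :-1], axis=1)],
            axis=1,
        )
    )
    # invert: new start per block id
    new_start = np.empty_like(slot_starts)
    rows = np.arange(cfg.n_perm)[:, None]
    new_start[rows, order] = slot_starts

    null = np.zeros(cfg.n_perm, dtype=np.int64)
    for b in range(n_blocks):
        off = offsets[b]
        if off.size == 0:
            continue
        lo = focal.start - new_start[:, b]
        hi = focal.end - new_start[:, b]
        null += np.searchsorted(off, hi, side="left") - np.searchsorted(
            off, lo, side="left"
        )

    p = (1.0 + np.sum(null >= observed)) / (1.0 + cfg.n_perm)
    degenerate = observed == 0 and not null.any()
    return PermTestResult(
        observed=observed,
        null_counts=null,
        n_perm=cfg.n_perm,
        p_value=float(p),
        block_bp=cfg.perm_block_bp,
        focal=focal,
        seed=seed,
        degenerate=degenerate,
    )
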