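"""f4 statistics with weighted block jackknife, and windowed fd/fdM scans.

The f4 statistic over four populations arranged as (A, B; C, D) is the mean
over usable sites of (pA - pB)(pC - pD).  The test arrangement used
throughout places the two sympatric same-location pairs as (A, C), so a
positive f4 indicates excess allele sharing between sympatric species —
the signature of local gene flow between co-mimics.

Standard errors come from a delete-one-block weighted jackknife over
non-overlapping 500 kb blocks (weights proportional to the number of usable
sites per block, following Busing, Meijer & van der Leeden 1999).

fd and fdM are window-scaled versions of the ABBA-BABA asymmetry for a trio
(P1, P2, P3) plus outgroup O, computed on derived-allele frequencies:

    num  = sum_sites [(1-p1) p2 p3 (1-pO) - p1 (1-p2) p3 (1-pO)]
    fd   = num / (same sum with pD = max(p2, p3) substituted for p2 and p3)

fd is reported only for windows with a positive numerator; fdM substitutes
the P1-donor maximum when the numerator is negative, retaining the sign, so
it is symmetric for the two possible recipient populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, AnalysisConfig, GenomicWindow, GenotypeMatrix

logger = logging.getLogger("tigerwing")


@dataclass
class FrequencyTable:
    """Per-site alternate (or derived) allele frequencies for 4 populations."""

    chrom: str
    positions: np.ndarray
    freqs: np.ndarray                  # n_sites x 4, NaN where undefined
    counts: np.ndarray | None = None   # n_sites x 4 called-allele counts
    pop_names: tuple[str, str, str, str] = ("P1", "P2", "P3", "P4")

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.positions), 4):
            raise ValueError("freqs must be n_sites x 4")
        finite = self.freqs[np.isfinite(self.freqs)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.freqs.shape:
                raise ValueError("counts shape mismatch")
            if (self.counts < 0).any():
                raise ValueError("counts must be nonnegative")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def usable(self) -> np.ndarray:
        """Sites where all four frequencies are defined."""
        ok = np.all(np.isfinite(self.freqs), axis=1)
        if self.counts is not None:
            ok &= np.all(self.counts > 0, axis=1)
        return ok

    @classmethod
    def from_genotypes(
        cls,
        gm: GenotypeMatrix,
        pops: Sequence[Sequence[str]],
        pop_names: Sequence[str] | None = None,
        ancestral: np.ndarray | None = None,
    ) -> "FrequencyTable":
        """Alternate-allele frequencies per population; with ``ancestral``
        (0=REF, 1=ALT per site) frequencies are polarized to derived."""
        if len(pops) != 4:
            raise ValueError("exactly four populations required")
        freqs = np.full((gm.n_sites, 4), np.nan)
        counts = np.zeros((gm.n_sites, 4), dtype=np.int64)
        for k, members in enumerate(pops):
            g = gm.genotypes[:, gm.sample_indices(members)]
            called = g != MISSING
            n = 2 * called.sum(axis=1)
            alt = np.where(called, g, 0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freqs[:, k] = np.where(n > 0, alt / n, np.nan)
            counts[:, k] = n
        if ancestral is not None:
            anc = np.asarray(ancestral)
            flip = anc == 1          # ALT ancestral: derived allele is REF
            freqs[flip] = 1.0 - freqs[flip]
            freqs[anc == MISSING] = np.nan
        names = tuple(pop_names) if pop_names is not None else ("P1", "P2", "P3", "P4")
        return cls(
            chrom=gm.chrom, positions=gm.positions.copy(),
            freqs=freqs, counts=counts, pop_names=names,
        )


@dataclass
class F4Estimate:
    f4: float
    jackknife_se: float
    z: float
    n_blocks: int
    n_sites: int
    arrangement: tuple[str, str, str, str]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("arrangement\tf4\tse\tz\tn_blocks\tn_sites\n")
            fh.write(
                f"({','.join(self.arrangement)})\t{self.f4:.8g}\t"
                f"{self.jackknife_se:.8g}\t{self.z:.8g}\t"
                f"{self.n_blocks}\t{self.n_sites}\n"
            )


def weighted_jackknife(
    estimates_minus_block: np.ndarray,
    block_sizes: np.ndarray,
    full_estimate: float,
) -> float:
    """Delete-one-block weighted jackknife standard error (Busing et al.)."""
    m = np.asarray(block_sizes, dtype=float)
    theta_mb = np.asarray(estimates_minus_block, dtype=float)
    g = len(m)
    n = m.sum()
    h = n / m
    theta_j = g * full_estimate - np.sum((1.0 - m / n) * theta_mb)
    tau = h * full_estimate - (h - 1.0) * theta_mb
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return float(np.sqrt(var))


def f4(
    tab: FrequencyTable,
    arrangement: Sequence[int] = (0, 1, 2, 3),
    cfg: AnalysisConfig | None = None,
) -> F4Estimate:
    """f4 = mean over usable sites of (pA - pB)(pC - pD), with jackknife SE.

    ``arrangement`` gives the column order (A, B, C, D).  Blocks are tiled on
    absolute physical coordinates (position // jackknife_block_bp); empty
    blocks drop out.  With fewer than two nonempty blocks the SE and z are
    reported as NaN.
    """
    cfg = cfg or AnalysisConfig()
    a, b, c, d = arrangement
    ok = tab.usable()
    if not ok.any():
        raise ValueError("no usable sites for f4")
    p = tab.freqs[ok]
    pos = tab.positions[ok]
    site_f4 = (p[:, a] - p[:, b]) * (p[:, c] - p[:, d])
    est = float(site_f4.mean())
    n_sites = len(site_f4)

    block_id = pos // cfg.jackknife_block_bp
    uniq, inv = np.unique(block_id, return_inverse=True)
    g = len(uniq)
    names = tuple(tab.pop_names[i] for i in arrangement)
    if g < 2:
        logger.warning("f4: fewer than 2 nonempty jackknife blocks; SE undefined")
        return F4Estimate(est, float("nan"), float("nan"), g, n_sites, names)

    sums = np.bincount(inv, weights=site_f4, minlength=g)
    sizes = np.bincount(inv, minlength=g).astype(float)
    total = site_f4.sum()
    theta_mb = (total - sums) / (n_sites - sizes)
    se = weighted_jackknife(theta_mb, sizes, est)
    z = est / se if se > 0 else float("nan")
    return F4Estimate(est, se, z, g, n_sites, names)


# ---------------------------------------------------------------------------
# fd / fdM
# ---------------------------------------------------------------------------

@dataclass
class FdTrack:
    """Per-window fd and fdM with informative-site counts.

    fd is NaN where the window D-numerator is not positive or the window is
    masked for too few informative sites; the raw numerator is retained.
    """

    windows: list[GenomicWindow]
    fd: np.ndarray
    fdM: np.ndarray
    numerator: np.ndarray
    n_informative: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "fd": self.fd,
                "fdM": self.fdM,
                "numerator": self.numerator,
                "n_informative": self.n_informative,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="NA")


def _abba_baba_terms(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site numerator and the two donor-substituted denominators."""
    p1, p2, p3, pO = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    num = (1 - p1) * p2 * p3 * (1 - pO) - p1 * (1 - p2) * p3 * (1 - pO)
    pd23 = np.maximum(p2, p3)
    den23 = (1 - p1) * pd23 * pd23 * (1 - pO) - p1 * (1 - pd23) * pd23 * (1 - pO)
    pd13 = np.maximum(p1, p3)
    den13 = (1 - pd13) * p2 * pd13 * (1 - pO) - pd13 * (1 - p2) * pd13 * (1 - pO)
    return num, den23, den13


def fd_window(
    tab: FrequencyTable,
    windows: Sequence[GenomicWindow],
    cfg: AnalysisConfig | None = None,
) -> FdTrack:
    """Windowed fd/fdM over a trio-plus-outgroup frequency table.

    The table columns must already be polarized derived-allele frequencies
    ordered (P1, P2, P3, O).  Windows with fewer than ``cfg.fd_min_sites``
    informative sites are masked; windows with a nonpositive numerator get
    fd = NaN with the numerator retained.
    """
    cfg = cfg or AnalysisConfig()
    ok = tab.usable()
    p = tab.freqs[ok]
    pos = tab.positions[ok]
    num, den23, den13 = _abba_baba_terms(p)
    informative = (num != 0) | (den23 != 0)

    n_w = len(windows)
    fd = np.full(n_w, np.nan)
    fdM = np.full(n_w, np.nan)
    numer = np.full(n_w, np.nan)
    n_inf = np.zeros(n_w, dtype=np.int64)
    for k, w in enumerate(windows):
        sel = (pos >= w.start) & (pos < w.end)
        n_inf[k] = int(np.sum(informative & sel))
        if not sel.any():
            continue
        N = num[sel].sum()
        numer[k] = N
        if n_inf[k] < cfg.fd_min_sites:
            continue  # masked
        D23 = den23[sel].sum()
        if N > 0 and D23 > 0:
            fd[k] = N / D23
        if N >= 0:
            if D23 > 0:
                fdM[k] = N / D23
        else:
            D13 = np.abs(den13[sel].sum())
            if D13 > 0:
                fdM[k] = N / D13
    return FdTrack(
        windows=list(windows), fd=fd, fdM=fdM,
        numerator=numer, n_informative=n_inf,
    )
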