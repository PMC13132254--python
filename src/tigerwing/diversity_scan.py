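"""Pooled multispecies nucleotide diversity and trans-species polymorphisms.

Nucleotide diversity is the invariant-site-aware ratio-of-sums estimator:
per window, pi = (sum over sites of discordant called-allele pairs) /
(sum over sites of all called-allele pairs), computed over a pooled sample
of individuals from several species.  The input genotype matrix must
therefore include invariant sites — omitting them inflates pi.

A biallelic site is *trans-species polymorphic* when (i) at least four
species are polymorphic, when more than three species have data at the site,
(ii) all species are polymorphic when three or fewer are present, and
(iii) each allele is carried by at least six total copies across species.
Such sites, far older than the species splits, are the footprint of
long-term balancing selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, AnalysisConfig, GenomicWindow, GenotypeMatrix

logger = logging.getLogger("tigerwing")


@dataclass
class DiversityTrack:
    """Per-window pooled pi with its numerator/denominator provenance."""

    windows: list[GenomicWindow]
    pi: np.ndarray
    diff_sum: np.ndarray
    comp_sum: np.ndarray
    n_sites_with_data: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "pi": self.pi,
                "diff_sum": self.diff_sum,
                "comp_sum": self.comp_sum,
                "n_sites_with_data": self.n_sites_with_data,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="NA")


def pooled_pi(
    gm: GenotypeMatrix,
    windows: Sequence[GenomicWindow],
    sample_subset: Sequence[str] | None = None,
) -> DiversityTrack:
    """Ratio-of-sums nucleotide diversity per window over pooled samples.

    Per site, with a alternate and r reference called alleles in the pool:
    discordant pairs = a * r, total pairs = C(a + r, 2).  Windows whose
    comparison denominator is zero get pi = NaN.
    """
    if len(windows) == 0:
        raise ValueError("window list is empty")
    g = gm.genotypes
    if sample_subset is not None:
        g = g[:, gm.sample_indices(sample_subset)]
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=1).astype(np.int64)
    n = 2 * called.sum(axis=1).astype(np.int64)
    ref = n - alt
    diff = alt * ref
    comp = n * (n - 1) // 2
    has_data = n >= 2

    n_w = len(windows)
    diff_sum = np.zeros(n_w, dtype=np.int64)
    comp_sum = np.zeros(n_w, dtype=np.int64)
    n_data = np.zeros(n_w, dtype=np.int64)
    pos = gm.positions
    for k, w in enumerate(windows):
        sel = (pos >= w.start) & (pos < w.end) & has_data
        diff_sum[k] = diff[sel].sum()
        comp_sum[k] = comp[sel].sum()
        n_data[k] = int(sel.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(comp_sum > 0, diff_sum / np.maximum(comp_sum, 1), np.nan)
    pi = np.where(comp_sum > 0, pi, np.nan)
    return DiversityTrack(
        windows=list(windows), pi=pi, diff_sum=diff_sum,
        comp_sum=comp_sum, n_sites_with_data=n_data,
    )


# ---------------------------------------------------------------------------
# trans-species polymorphism
# ---------------------------------------------------------------------------

RULE_NONE = "none"
RULE_I = "i"    # >3 species present: at least 4 polymorphic
RULE_II = "ii"  # <=3 species present: all polymorphic


@dataclass
class TransPolyTable:
    """Per-site species polymorphism flags and the classification outcome."""

    positions: np.ndarray
    species: list[str]
    poly_flags: np.ndarray          # n_sites x n_species booleans
    ref_copies: np.ndarray          # total called REF alleles across species
    alt_copies: np.ndarray
    is_transpolymorphic: np.ndarray
    rule_fired: list[str]
    chrom: str = "chrom"

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "n_poly_species": self.poly_flags.sum(axis=1),
                "ref_copies": self.ref_copies,
                "alt_copies": self.alt_copies,
                "transpolymorphic": self.is_transpolymorphic.astype(int),
                "rule": self.rule_fired,
            }
        )
        df.to_csv(path, sep="\t", index=False)


def classify_transpoly(
    gm: GenotypeMatrix,
    species_map: Mapping[str, Sequence[str]],
    cfg: AnalysisConfig | None = None,
) -> TransPolyTable:
    """Classify every biallelic site by the trans-polymorphism rules.

    A species is polymorphic at a site when both alleles occur among its
    called alleles (no per-species count floor beyond one copy each).  A
    species is *present* at a site when it has at least one called allele.
    Allele copies for the copy rule are counted across all species.
    """
    cfg = cfg or AnalysisConfig()
    species = sorted(species_map)
    if len(species) < 2:
        raise ValueError("need at least two species")

    n_sites = gm.n_sites
    n_sp = len(species)
    poly = np.zeros((n_sites, n_sp), dtype=bool)
    present = np.zeros((n_sites, n_sp), dtype=bool)
    ref_tot = np.zeros(n_sites, dtype=np.int64)
    alt_tot = np.zeros(n_sites, dtype=np.int64)
    for k, sp in enumerate(species):
        g = gm.genotypes[:, gm.sample_indices(species_map[sp])]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        ref = n - alt
        present[:, k] = n > 0
        poly[:, k] = (alt > 0) & (ref > 0)
        ref_tot += ref
        alt_tot += alt

    n_present = present.sum(axis=1)
    n_poly = poly.sum(axis=1)
    rule_i = (n_present > 3) & (n_poly >= cfg.transpoly_min_poly_species)
    rule_ii = (
        (n_present <= 3) & (n_present >= 2) & (n_poly == n_present)
    )
    copies_ok = (
        (ref_tot >= cfg.transpoly_min_allele_copies)
        & (alt_tot >= cfg.transpoly_min_allele_copies)
    )
    is_tp = (rule_i | rule_ii) & copies_ok
    rule = [
        RULE_I if (t and ri) else (RULE_II if t else RULE_NONE)
        for t, ri in zip(is_tp, rule_i)
    ]
    n_dark = int((n_present == 0).sum())
    if n_dark:
        logger.warning("%d sites with all calls missing", n_dark)
    return TransPolyTable(
        positions=gm.positions.copy(),
        species=species,
        poly_flags=poly,
        ref_copies=ref_tot,
        alt_copies=alt_tot,
        is_transpolymorphic=is_tp,
        rule_fired=rule,
        chrom=gm.chrom,
    )


def transpoly_window_counts(
    tp: TransPolyTable, windows: Sequence[GenomicWindow]
) -> np.ndarray:
    """Number of trans-polymorphic sites per window (default 10 kb tiling)."""
    pos = tp.positions[tp.is_transpolymorphic]
    out = np.zeros(len(windows), dtype=np.int64)
    for k, w in enumerate(windows):
        out[k] = int(np.sum((pos >= w.start) & (pos < w.end)))
    return out
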