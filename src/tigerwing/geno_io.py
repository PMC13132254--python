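"""Genotype and haplotype containers, VCF/metadata I/O, grouping and site filters.

Conventions
-----------
* Internal coordinates are 0-based, half-open.  VCF input/output converts to
  and from the 1-based inclusive positions of the format.
* Genotypes are stored as the count of the alternate allele in {0, 1, 2},
  with ``-1`` marking missing calls.  Haplotype alleles are integer codes
  (0 = REF, 1.. = ALT order), again with ``-1`` for missing.
* Two I/O dialects exist: the default *biallelic* dialect drops multiallelic
  records (every allele-frequency statistic consumes this), and a
  *multiallelic* dialect keeps them with integer codes (used only by the
  window-genealogy stage, where any allele mismatch counts as a difference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tigerwing")

MISSING = -1

#: Valid phenotype codes: solid form 1, intermediate striped form 0.5,
#: alternative form 0; NaN marks unscored individuals.
PHENOTYPE_CODES = (0.0, 0.5, 1.0)


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Numerical thresholds shared by the analysis stages.

    Defaults follow the study design this package implements: sites enter
    association scans at minor allele frequency >= 10% and missingness < 25%;
    genealogies are built in non-overlapping 100-SNP windows; a window is
    introgression-compatible when the introgression-topology weight is at
    least 0.95 ("intro95"); significance comes from shuffling 100 kb blocks
    50,000 times; f4 standard errors use a 500 kb block jackknife; pooled
    nucleotide diversity uses 50 kb windows; a site is trans-polymorphic when
    at least four species are polymorphic (all species, if three or fewer are
    present) and each allele has at least six copies across species.
    """

    maf_min: float = 0.10
    missingness_max: float = 0.25
    window_snps: int = 100
    weight_threshold: float = 0.95
    perm_block_bp: int = 100_000
    n_perm: int = 50_000
    jackknife_block_bp: int = 500_000
    pi_window_bp: int = 50_000
    transpoly_window_bp: int = 10_000
    transpoly_min_poly_species: int = 4
    transpoly_min_allele_copies: int = 6
    alpha: float = 0.05
    exhaustive_cap: int = 50_000
    mc_draws: int = 10_000
    fd_window_bp: int = 20_000
    fd_min_sites: int = 20

    def __post_init__(self) -> None:
        for name in (
            "maf_min", "missingness_max", "window_snps", "weight_threshold",
            "perm_block_bp", "n_perm", "jackknife_block_bp", "pi_window_bp",
            "transpoly_window_bp", "transpoly_min_poly_species",
            "transpoly_min_allele_copies", "alpha", "exhaustive_cap",
            "mc_draws", "fd_window_bp", "fd_min_sites",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"AnalysisConfig.{name} must be positive")
        if self.maf_min >= 0.5:
            raise ValueError("maf_min must be < 0.5")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample species/subspecies/locality/phenotype annotations.

    The phenotype column uses the categorical codes 0, 0.5 and 1 (NaN when
    unscored); every grouping used by downstream stages (quartet roles,
    species pools, association cohorts) is resolved through this table.
    """

    df: pd.DataFrame

    REQUIRED = ("sample", "species", "subspecies", "locality", "phenotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if self.df["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in sample table")
        phen = self.df["phenotype"].dropna()
        bad = ~phen.isin(PHENOTYPE_CODES)
        if bad.any():
            raise ValueError(
                f"invalid phenotype codes: {sorted(phen[bad].unique())}"
            )
        self.df = self.df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.df["sample"])

    def __len__(self) -> int:
        return len(self.df)

    def samples_where(self, **criteria: str) -> list[str]:
        """Sample ids matching all column=value criteria (e.g. species="spA")."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in criteria.items():
            mask &= self.df[col] == val
        return list(self.df.loc[mask, "sample"])

    def phenotypes(self, samples: Sequence[str]) -> np.ndarray:
        ser = self.df.set_index("sample")["phenotype"]
        return ser.reindex(samples).to_numpy(dtype=float)

    def species_map(self) -> dict[str, list[str]]:
        """species label -> sample ids."""
        return {
            sp: list(sub["sample"])
            for sp, sub in self.df.groupby("species", sort=True)
        }

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes: sites x samples alternate-allele counts."""

    chrom: str
    positions: np.ndarray          # 0-based, strictly increasing
    ref: list[str]
    alt: list[str]                 # "" for invariant records
    genotypes: np.ndarray          # int8, sites x samples, -1 missing
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in samples], dtype=np.intp)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[idx],
            ref=[self.ref[i] for i in np.atleast_1d(idx)],
            alt=[self.alt[i] for i in np.atleast_1d(idx)],
            genotypes=self.genotypes[idx],
            samples=list(self.samples),
        )


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: sites x haplotypes integer allele codes.

    ``hap_to_sample`` maps haplotype column -> (sample_id, 1|2).  Exactly two
    haplotypes per diploid, in sample order, first then second.
    """

    chrom: str
    positions: np.ndarray
    ref: list[str]
    alt: list[list[str]]           # per-site list of ALT alleles
    alleles: np.ndarray            # int8, sites x haplotypes, -1 missing
    hap_to_sample: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.positions), len(self.hap_to_sample)):
            raise ValueError("haplotype matrix shape mismatch")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.hap_to_sample) % 2 != 0:
            raise ValueError("odd haplotype count; diploids expected")
        for k in range(0, len(self.hap_to_sample), 2):
            (s1, a), (s2, b) = self.hap_to_sample[k], self.hap_to_sample[k + 1]
            if s1 != s2 or (a, b) != (1, 2):
                raise ValueError("haplotypes must come in (sample,1),(sample,2) pairs")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_haps(self) -> int:
        return len(self.hap_to_sample)

    @property
    def samples(self) -> list[str]:
        return [s for s, phase in self.hap_to_sample if phase == 1]

    @property
    def hap_labels(self) -> list[str]:
        return [f"{s}_{phase}" for s, phase in self.hap_to_sample]

    def hap_indices_for_samples(self, samples: Iterable[str]) -> np.ndarray:
        wanted = set(samples)
        return np.array(
            [i for i, (s, _) in enumerate(self.hap_to_sample) if s in wanted],
            dtype=np.intp,
        )

    def to_genotype_matrix(self, biallelic_only: bool = True) -> GenotypeMatrix:
        """Collapse phased haplotypes to alternate-allele counts."""
        keep = np.arange(self.n_sites)
        if biallelic_only:
            keep = np.array(
                [i for i in range(self.n_sites) if len(self.alt[i]) <= 1],
                dtype=np.intp,
            )
        a = self.alleles[keep]
        h1, h2 = a[:, 0::2], a[:, 1::2]
        miss = (h1 == MISSING) | (h2 == MISSING)
        g = (h1 > 0).astype(np.int8) + (h2 > 0).astype(np.int8)
        g[miss] = MISSING
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[keep],
            ref=[self.ref[i] for i in keep],
            alt=[(self.alt[i][0] if self.alt[i] else "") for i in keep],
            genotypes=g,
            samples=self.samples,
        )


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open [start, end) interval, optionally carrying site indices."""

    chrom: str
    start: int
    end: int
    site_lo: int = 0
    site_hi: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty window [{self.start}, {self.end})")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def n_sites(self) -> int:
        return self.site_hi - self.site_lo


def tile_windows(chrom: str, start: int, end: int, size: int) -> list[GenomicWindow]:
    """Non-overlapping size-bp windows tiling [start, end); trailing partial kept."""
    if size <= 0:
        raise ValueError("window size must be positive")
    out = []
    for s in range(start, end, size):
        out.append(GenomicWindow(chrom, s, min(s + size, end)))
    return out


def windows_to_bed(windows: Sequence[GenomicWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    mode: str = "biallelic",
    phased: bool = False,
    allow_unphased: bool = False,
) -> GenotypeMatrix | HaplotypeMatrix:
    """Read a single-chromosome VCF into a genotype or haplotype matrix.

    Parameters
    ----------
    mode
        ``"biallelic"`` drops records with more than one ALT allele;
        ``"multiallelic"`` keeps them with integer allele codes.
    phased
        When True, return a :class:`HaplotypeMatrix`; every genotype must use
        the ``|`` separator unless ``allow_unphased`` is set (homozygous and
        missing calls are tolerated either way, as their phase is immaterial).
    """
    from cyvcf2 import VCF

    if mode not in ("biallelic", "multiallelic"):
        raise ValueError(f"unknown VCF dialect {mode!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    positions: list[int] = []
    refs: list[str] = []
    alts: list[list[str]] = []
    rows: list[np.ndarray] = []
    chrom = None
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    n = len(samples)
    last_pos = -1
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("multi-chromosome VCFs are not supported here")
        alt_alleles = [a for a in var.ALT if a not in (".", "")]
        if mode == "biallelic" and len(alt_alleles) > 1:
            continue
        pos0 = var.POS - 1
        if pos0 <= last_pos:
            raise ValueError(f"VCF positions unsorted or duplicated at {var.POS}")
        last_pos = pos0
        gts = var.genotypes  # [[a1, a2, phased_flag], ...]
        row = np.empty(2 * n, dtype=np.int8)
        for j, g in enumerate(gts):
            a1, a2 = g[0], g[1]
            is_phased = bool(g[2]) if len(g) > 2 else False
            if phased and not is_phased and not allow_unphased:
                het = a1 >= 0 and a2 >= 0 and a1 != a2
                if het:
                    raise ValueError(
                        f"unphased heterozygote at {var.CHROM}:{var.POS} "
                        f"sample {samples[j]}; phasing step appears to be missing"
                    )
            row[2 * j] = a1 if a1 >= 0 else MISSING
            row[2 * j + 1] = a2 if a2 >= 0 else MISSING
        positions.append(pos0)
        refs.append(var.REF)
        alts.append(alt_alleles)
        rows.append(row)

    if chrom is None:
        chrom = "chrom"
    allele_mat = (
        np.array(rows, dtype=np.int8) if rows else np.zeros((0, 2 * n), np.int8)
    )
    hap_to_sample = [(s, phase) for s in samples for phase in (1, 2)]
    hm = HaplotypeMatrix(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        ref=refs,
        alt=alts,
        alleles=allele_mat,
        hap_to_sample=hap_to_sample,
    )
    if phased:
        return hm
    return hm.to_genotype_matrix(biallelic_only=(mode == "biallelic"))


def write_vcf(
    hm: HaplotypeMatrix,
    path: str | Path,
    contig_length: int | None = None,
) -> None:
    """Write phased haplotypes as a VCF 4.2 text file with '|' genotypes."""
    if hm.n_haps == 0:
        raise ValueError("refusing to write a VCF with zero samples")
    samples = hm.samples
    if contig_length is None:
        contig_length = int(hm.positions[-1]) + 1 if hm.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hm.chrom},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for i in range(hm.n_sites):
            alt = ",".join(hm.alt[i]) if hm.alt[i] else "."
            row = hm.alleles[i]
            gts = []
            for k in range(0, hm.n_haps, 2):
                a1 = "." if row[k] == MISSING else str(int(row[k]))
                a2 = "." if row[k + 1] == MISSING else str(int(row[k + 1]))
                gts.append(f"{a1}|{a2}")
            fh.write(
                f"{hm.chrom}\t{int(hm.positions[i]) + 1}\t.\t{hm.ref[i]}\t{alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# ancestral-allele assignment
# ---------------------------------------------------------------------------

#: which rule assigned the ancestral state per site
ANC_OUTGROUP = 0
ANC_FALLBACK = 1
ANC_MISSING = 2


def assign_ancestral(
    gm: GenotypeMatrix,
    outgroup_samples: Sequence[str],
    fallback_samples: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ancestral allele (0=REF, 1=ALT, -1 undetermined) plus rule flags.

    The ancestral allele is the outgroup major allele wherever at least one
    outgroup call exists; at sites missing in the outgroup it falls back to
    the most frequent allele over ``fallback_samples`` (the genus-wide pool).
    Frequency ties resolve to the reference allele.
    """
    if len(outgroup_samples) == 0:
        raise ValueError("outgroup_samples must be nonempty")

    def _major(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = gm.genotypes[:, idx]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=1)
        tot = 2 * called.sum(axis=1)
        has = tot > 0
        # ref wins ties: ancestral alt only on strict majority
        major = np.where(alt * 2 > tot, 1, 0).astype(np.int8)
        return major, has

    out_major, out_has = _major(gm.sample_indices(outgroup_samples))
    fb_major, fb_has = _major(gm.sample_indices(fallback_samples)) if len(
        fallback_samples
    ) else (np.zeros(gm.n_sites, np.int8), np.zeros(gm.n_sites, bool))

    ancestral = np.full(gm.n_sites, MISSING, dtype=np.int8)
    rule = np.full(gm.n_sites, ANC_MISSING, dtype=np.int8)
    ancestral[out_has] = out_major[out_has]
    rule[out_has] = ANC_OUTGROUP
    fb_only = ~out_has & fb_has
    ancestral[fb_only] = fb_major[fb_only]
    rule[fb_only] = ANC_FALLBACK
    n_dark = int((rule == ANC_MISSING).sum())
    if n_dark:
        logger.warning("%d sites have no calls anywhere; ancestral state missing", n_dark)
    return ancestral, rule


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def filter_sites(
    gm: GenotypeMatrix, cfg: AnalysisConfig | None = None
) -> tuple[GenotypeMatrix, int]:
    """Retain sites with MAF >= maf_min (on called genotypes) and missing
    fraction strictly below missingness_max.  Returns (matrix, n_retained)."""
    cfg = cfg or AnalysisConfig()
    g = gm.genotypes
    called = g != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(af, 1.0 - af)
    miss_frac = 1.0 - n_called / gm.n_samples
    keep = (
        (n_called > 0)
        & (maf >= cfg.maf_min)
        & (miss_frac < cfg.missingness_max)
    )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn("filter_sites retained zero sites", stacklevel=2)
    return gm.take_sites(idx), int(idx.size)
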