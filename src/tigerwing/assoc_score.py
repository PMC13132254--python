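"""Association post-processing: filters, Bonferroni, rho-squared scoring,
fully-associated intervals, genotype-matrix export and the diagnostic
k-mer motif scan.

The association scan here is deliberately lightweight plumbing: a
Cochran-Armitage-style trend test of genotype dose {0, 1, 2} against the
categorical phenotype code, without any relatedness correction.  The
substantive post-processing steps are what this module owns: Bonferroni
thresholding, squared Spearman rank correlation (rho2) at significant SNPs,
the minimal interval spanning the fully associated SNPs (rho2 = 1), a
clustered genotype-matrix export, and the search for fixed-SNP diagnostic
sequence motifs distinguishing the two homozygote classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .geno_io import MISSING, AnalysisConfig, GenotypeMatrix, SampleTable

logger = logging.getLogger("tigerwing")

MAX_NEG_LOG10_P = 320.0
RHO2_ONE_TOL = 1e-9


# ---------------------------------------------------------------------------
# trend-test scan
# ---------------------------------------------------------------------------

def association_scan(
    gm: GenotypeMatrix, phenotype: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP two-sided trend-test p-values.

    The statistic is N * r^2 with r the Pearson correlation between genotype
    dose and phenotype code over called samples, referred to chi-square with
    one degree of freedom (the Cochran-Armitage score test; it extends
    unchanged to the 0/0.5/1 phenotype coding).  SNPs that are monomorphic
    among called samples, have a constant phenotype, or fewer than three
    called samples get p = 1 with a flag.

    Returns (p_values, degenerate_flags).
    """
    y = np.asarray(phenotype, dtype=float)
    y_ok = np.isfinite(y)
    if np.unique(y[y_ok]).size < 2:
        raise ValueError("phenotype is constant; association undefined")
    g = gm.genotypes.astype(float)
    called = (gm.genotypes != MISSING) & y_ok[None, :]
    g = np.where(called, g, 0.0)
    yv = np.where(y_ok, y, 0.0)

    n = called.sum(axis=1).astype(float)
    sg = g.sum(axis=1)
    sy = called @ yv
    sgg = (g * g).sum(axis=1)
    syy = called @ (yv * yv)
    sgy = g @ yv  # g already zeroed where not called
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sgy - sg * sy
        var_g = n * sgg - sg**2
        var_y = n * syy - sy**2
        r2 = num**2 / (var_g * var_y)
    degenerate = (n < 3) | (var_g <= 0) | (var_y <= 0)
    stat = np.where(degenerate, 0.0, n * r2)
    p = stats.chi2.sf(stat, df=1)
    p[degenerate] = 1.0
    return p, degenerate


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def rho2(genotypes: np.ndarray, phenotype: np.ndarray) -> float | None:
    """Squared Spearman rank correlation (midrank ties) between genotype dose
    and phenotype code over called samples; None when undefined."""
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = (g != MISSING) & np.isfinite(y)
    g, y = g[ok], y[ok]
    if len(g) < 2 or np.unique(g).size < 2 or np.unique(y).size < 2:
        return None
    rho = stats.spearmanr(g, y).statistic
    return float(rho * rho)


# ---------------------------------------------------------------------------
# association table
# ---------------------------------------------------------------------------

@dataclass
class AssocTable:
    """Per-SNP association results on the focal chromosome.

    ``pos`` is 1-based (reporting convention).  ``rho2`` is computed for
    SNPs below the Bonferroni threshold; ``fully_associated`` marks
    rho2 = 1 among fully genotyped samples.
    """

    chrom: str
    df: pd.DataFrame
    threshold: float

    def to_tsv(self, path: str | Path) -> None:
        self.df.assign(chrom=self.chrom)[
            ["chrom", "pos", "p", "minus_log10_p", "rho2",
             "significant", "fully_associated"]
        ].to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="NA")


def build_assoc_table(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    cfg: AnalysisConfig | None = None,
) -> AssocTable:
    """Run the trend scan on a pre-filtered matrix and score significant SNPs."""
    cfg = cfg or AnalysisConfig()
    p, degen = association_scan(gm, phenotype)
    thr = bonferroni_threshold(gm.n_sites, cfg.alpha)
    significant = p < thr
    r2 = np.full(gm.n_sites, np.nan)
    for i in np.flatnonzero(significant):
        val = rho2(gm.genotypes[i], phenotype)
        r2[i] = np.nan if val is None else val
    fully = significant & (r2 >= 1.0 - RHO2_ONE_TOL)
    with np.errstate(divide="ignore"):
        mlog = np.minimum(-np.log10(np.maximum(p, 0.0)), MAX_NEG_LOG10_P)
    df = pd.DataFrame(
        {
            "pos": gm.positions + 1,  # 1-based reporting
            "p": p,
            "minus_log10_p": mlog,
            "rho2": r2,
            "significant": significant,
            "fully_associated": fully,
            "degenerate": degen,
        }
    )
    return AssocTable(chrom=gm.chrom, df=df, threshold=thr)


@dataclass
class FullyAssociatedInterval:
    start: int       # 1-based inclusive
    end: int         # 1-based inclusive
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def fully_associated_interval(tab: AssocTable) -> FullyAssociatedInterval | None:
    """Minimal 1-based inclusive interval containing all fully associated
    SNPs, or None (with a warning) when there are none."""
    sel = tab.df.loc[tab.df["fully_associated"], "pos"]
    if sel.empty:
        logger.warning("no fully associated SNPs; empty interval")
        return None
    return FullyAssociatedInterval(
        start=int(sel.min()), end=int(sel.max()), n_snps=int(len(sel))
    )


# ---------------------------------------------------------------------------
# genotype-matrix export
# ---------------------------------------------------------------------------

def genotype_matrix_export(
    gm: GenotypeMatrix,
    snp_idx: Sequence[int],
    st: SampleTable,
    tab: AssocTable,
    path: str | Path,
) -> pd.DataFrame:
    """Samples x top-SNPs genotype table, clustered for visual grouping.

    Samples are ordered by average-linkage hierarchical clustering on the
    Hamming distance between genotype vectors (dendrogram leaf order).  The
    input sample order is canonicalized (sorted by genotype vector, then
    sample id) before clustering, so the output is invariant to input
    permutations.  A phenotype column and a -log10 p row annotate the table.
    """
    snp_idx = np.asarray(snp_idx, dtype=np.intp)
    if snp_idx.size == 0:
        raise ValueError("empty SNP set")
    sub = gm.genotypes[snp_idx].T.astype(float)      # samples x snps
    sub[sub == MISSING] = np.nan
    samples = list(gm.samples)

    order0 = sorted(
        range(len(samples)),
        key=lambda i: (tuple(np.nan_to_num(sub[i], nan=3.0)), samples[i]),
    )
    canon = sub[order0]
    canon_names = [samples[i] for i in order0]
    if len(canon_names) > 2:
        filled = np.nan_to_num(canon, nan=3.0)
        d = pdist(filled, metric="hamming")
        order = leaves_list(linkage(d, method="average"))
    else:
        order = np.arange(len(canon_names))

    mlog = tab.df.set_index("pos")["minus_log10_p"]
    positions = gm.positions[snp_idx] + 1
    header = [str(int(p)) for p in positions]
    rows = []
    phen = st.df.set_index("sample")["phenotype"]
    for i in order:
        name = canon_names[i]
        vals = [
            "NA" if not np.isfinite(v) else str(int(v)) for v in canon[i]
        ]
        rows.append([name, str(phen.get(name, np.nan))] + vals)
    out = pd.DataFrame(rows, columns=["sample", "phenotype"] + header)
    with open(path, "w") as fh:
        fh.write("\t".join(out.columns) + "\n")
        mlog_row = ["minus_log10_p", ""] + [
            f"{mlog.get(int(p), np.nan):.4g}" for p in positions
        ]
        fh.write("\t".join(mlog_row) + "\n")
        for _, r in out.iterrows():
            fh.write("\t".join(map(str, r)) + "\n")
    return out


# ---------------------------------------------------------------------------
# diagnostic motif scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    motif: str
    k: int
    frac_a: float
    frac_b: float
    contains_fixed_snp: bool
    diagnostic: bool
    enriched_in: str            # "A" or "B"
    consensus_positions_a: tuple[int, ...]
    consensus_positions_b: tuple[int, ...]


def _consensus(seqs: Sequence[str]) -> str:
    cols = []
    for i in range(len(seqs[0])):
        chars = [s[i] for s in seqs]
        cols.append(max(sorted(set(chars)), key=chars.count))
    return "".join(cols)


def _occurrences(motif: str, seq: str) -> int:
    count = start = 0
    while True:
        j = seq.find(motif, start)
        if j < 0:
            return count
        count += 1
        start = j + 1


def diagnostic_motif_scan(
    group_a_seqs: Sequence[str],
    group_b_seqs: Sequence[str],
    fixed_snp_positions: Sequence[int],
    k_range: tuple[int, int] = (6, 12),
    mode: str = "strict",
    occurrence_filter: tuple[int | None, int | None] | None = None,
) -> list[MotifHit]:
    """Fixed-SNP k-mers that separate the two homozygote groups.

    Candidate motifs are all k-mers (k in ``k_range``, inclusive) that
    overlap at least one fixed SNP position in any sequence of either group.
    Presence is substring containment anywhere in a sequence.  A motif is
    diagnostic in ``strict`` mode when present in 100% of one group and 0%
    of the other; in ``relaxed`` mode, 100% of one group and <5% of the
    other.  ``occurrence_filter`` = (min, max) keeps motifs whose occurrence
    count per containing sequence lies within the bounds.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    if not group_a_seqs or not group_b_seqs:
        raise ValueError("both groups must be nonempty")
    length = len(group_a_seqs[0])
    for s in itertools.chain(group_a_seqs, group_b_seqs):
        if len(s) != length:
            raise ValueError("sequences must be aligned to equal length")
    for p in fixed_snp_positions:
        if not 0 <= p < length:
            raise ValueError(f"fixed SNP position {p} outside the alignment")

    group_a = [s.upper() for s in group_a_seqs]
    group_b = [s.upper() for s in group_b_seqs]
    kmin, kmax = k_range
    candidates: set[str] = set()
    for seq in itertools.chain(group_a, group_b):
        for p in fixed_snp_positions:
            for k in range(kmin, kmax + 1):
                for start in range(max(0, p - k + 1), min(p, length - k) + 1):
                    candidates.add(seq[start:start + k])

    cons_a, cons_b = _consensus(group_a), _consensus(group_b)
    hits: list[MotifHit] = []
    for motif in sorted(candidates):
        in_a = [motif in s for s in group_a]
        in_b = [motif in s for s in group_b]
        fa = sum(in_a) / len(group_a)
        fb = sum(in_b) / len(group_b)
        if mode == "strict":
            diag_a = fa == 1.0 and fb == 0.0
            diag_b = fb == 1.0 and fa == 0.0
        else:
            diag_a = fa == 1.0 and fb < 0.05
            diag_b = fb == 1.0 and fa < 0.05
        if not (diag_a or diag_b):
            continue
        if occurrence_filter is not None:
            lo, hi = occurrence_filter
            counts = [
                _occurrences(motif, s)
                for s, present in zip(
                    itertools.chain(group_a, group_b), in_a + in_b
                )
                if present
            ]
            if lo is not None and any(c < lo for c in counts):
                continue
            if hi is not None and any(c > hi for c in counts):
                continue

        def _positions(cons: str) -> tuple[int, ...]:
            out, start = [], 0
            while True:
                j = cons.find(motif, start)
                if j < 0:
                    return tuple(out)
                out.append(j)
                start = j + 1

        hits.append(
            MotifHit(
                motif=motif,
                k=len(motif),
                frac_a=fa,
                frac_b=fb,
                contains_fixed_snp=True,
                diagnostic=True,
                enriched_in="A" if diag_a else "B",
                consensus_positions_a=_positions(cons_a),
                consensus_positions_b=_positions(cons_b),
            )
        )
    return hits
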