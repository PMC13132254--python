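"""Synthetic multispecies haplotype and allele-frequency data.

The haplotype simulator emulates the quartet setting the introgression test
assumes: two species, each with two morphologically distinct subspecies
(spA: sspA1/sspA2, spB: sspB1/sspB2), where sspA1 and sspB1 are co-mimics
sharing a locality.  Per non-recombining segment (default 5 kb) a genealogy
is drawn from a multispecies Kingman coalescent on the population tree
((sspA1, sspA2), (sspB1, sspB2)) with configurable split times (units of 2N
generations); infinite-sites mutations are dropped on branches as
Poisson(theta_within x branch length) with uniform positions.

Introgression at a focal "color locus" is a migration pulse: each sspA1
haplotype independently carries the donor tract with probability
``introgression_fraction``.  Within tract-overlapping segments those
lineages occupy their own deme (they cannot coalesce with non-migrant sspA1
lineages, nor with sspB1 lineages more recently than the pulse) until
``introgression_time``, when they merge into sspB1's ancestry — so recent
pulses make sspA1 nest inside sspB1's clade.  A causal SNP at ``causal_pos``
carries the derived allele on all sspB1 haplotypes plus the migrant sspA1
haplotypes, and the binary phenotype follows the configured dominance
(recessive: phenotype 1 iff homozygous for the introgressed allele; the
yellow-band allele of the study system is recessive).

A separate Balding-Nichols generator produces 4-population allele-frequency
tables, with an optional admixture edge, for calibrating f4 statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .f_stats import FrequencyTable
from .geno_io import HaplotypeMatrix, SampleTable, write_vcf

import pandas as pd

logger = logging.getLogger("tigerwing")

SUBSPECIES = ("sspA1", "sspA2", "sspB1", "sspB2")
SPECIES_OF = {"sspA1": "spA", "sspA2": "spA", "sspB1": "spB", "sspB2": "spB"}
# co-mimics share a locality: the mimicry-ring structure of the quartet
LOCALITY_OF = {"sspA1": "loc1", "sspB1": "loc1", "sspA2": "loc2", "sspB2": "loc2"}


@dataclass
class SimConfig:
    """Study conditions for the haplotype simulator.

    Times are in coalescent units of 2N generations; ``theta_within`` is the
    expected number of mutations per unit branch length per segment, so the
    expected pairwise within-population diversity per segment is
    2 * theta_within.  ``snp_density`` (expected SNPs per kb), when given,
    overrides theta_within via the panmictic expected tree length — a rough
    calibration, adequate for sizing fixtures.
    """

    seed: int = 0
    n_species: int = 2
    n_subspecies_per_species: int = 2
    n_diploids_per_subspecies: int = 5
    chrom_length: int = 1_000_000
    segment_length: int = 5_000
    snp_density: float | None = None
    split_time_subspecies: float = 0.1
    split_time_species: float = 1.0
    theta_within: float = 20.0
    tract: tuple[int, int] | None = None
    introgression_time: float = 0.05
    introgression_fraction: float = 0.0
    causal_pos: int | None = None
    dominance: str = "recessive"
    chrom: str = "chrom1"

    def __post_init__(self) -> None:
        if (self.n_species, self.n_subspecies_per_species) != (2, 2):
            raise ValueError("only the 2 species x 2 subspecies quartet design is supported")
        if self.n_diploids_per_subspecies < 1:
            raise ValueError("need at least one diploid per subspecies")
        if not 0 < self.split_time_subspecies < self.split_time_species:
            raise ValueError("require 0 < split_time_subspecies < split_time_species")
        if self.theta_within < 0:
            raise ValueError("theta_within must be nonnegative")
        if not 0.0 <= self.introgression_fraction <= 1.0:
            raise ValueError("introgression_fraction must be in [0, 1]")
        if self.dominance not in ("recessive", "dominant"):
            raise ValueError("dominance must be 'recessive' or 'dominant'")
        if self.chrom_length < self.segment_length:
            raise ValueError("chromosome shorter than one segment")
        if self.tract is not None:
            lo, hi = self.tract
            if not (0 <= lo < hi <= self.chrom_length):
                raise ValueError("tract must lie within [0, chrom_length)")
            if self.causal_pos is None:
                raise ValueError("tract set without causal_pos")
            if not lo <= self.causal_pos < hi:
                raise ValueError("causal_pos must lie inside the tract")
            if self.introgression_time >= self.split_time_species:
                raise ValueError(
                    "introgression_time must predate the species split "
                    "(signal undefined otherwise)"
                )
            if self.introgression_time <= 0:
                raise ValueError("introgression_time must be positive")

    @property
    def n_haps_per_pop(self) -> int:
        return 2 * self.n_diploids_per_subspecies

    def effective_theta(self) -> float:
        if self.snp_density is None:
            return self.theta_within
        n = 4 * self.n_haps_per_pop
        harmonic = sum(1.0 / i for i in range(1, n))
        expected_len = 2.0 * harmonic  # panmictic approximation
        return self.snp_density * (self.segment_length / 1000.0) / expected_len


# ---------------------------------------------------------------------------
# structured coalescent over one segment
# ---------------------------------------------------------------------------

def _coalesce_segment(
    rng: np.random.Generator,
    demes: dict[str, list[int]],
    merges: list[tuple[float, int, list[str], str]],
    times: list[float],
    parents: list[int],
) -> int:
    """Run the structured coalescent to the MRCA; returns the root node id.

    ``merges`` are (time, priority, source demes, target deme) events; at
    each, all lineages of the sources move to the target.  ``times`` and
    ``parents`` are extended in place with internal nodes.
    """
    demes = {k: list(v) for k, v in demes.items() if v}
    merges = sorted(merges, key=lambda e: (e[0], e[1]))
    t = 0.0
    ei = 0
    n_lineages = sum(len(v) for v in demes.values())
    while n_lineages > 1:
        names = [k for k, v in demes.items() if len(v) >= 2]
        rates = np.array([len(demes[k]) * (len(demes[k]) - 1) / 2.0 for k in names])
        total = rates.sum()
        t_next = t + rng.exponential(1.0 / total) if total > 0 else math.inf
        if ei < len(merges) and merges[ei][0] <= t_next:
            ev_t, _, sources, target = merges[ei]
            ei += 1
            moved = []
            for s in sources:
                moved.extend(demes.pop(s, []))
            if moved:
                demes.setdefault(target, []).extend(moved)
            t = ev_t
            continue
        if not math.isfinite(t_next):
            raise RuntimeError("coalescent stalled; inconsistent merge schedule")
        t = t_next
        d = names[int(rng.choice(len(names), p=rates / total))]
        lst = demes[d]
        i, j = rng.choice(len(lst), size=2, replace=False)
        i, j = int(i), int(j)
        parent = len(times)
        times.append(t)
        parents.append(-1)
        a, b = lst[i], lst[j]
        parents[a] = parent
        parents[b] = parent
        demes[d] = [x for k, x in enumerate(lst) if k not in (i, j)] + [parent]
        n_lineages -= 1
    (last,) = [v[0] for v in demes.values() if v]
    return last


def simulate_haplotypes(cfg: SimConfig) -> tuple[HaplotypeMatrix, SampleTable]:
    """Phased haplotypes plus sample metadata under the quartet model.

    Deterministic given ``cfg.seed``.  Haplotype order: sspA1 diploids, then
    sspA2, sspB1, sspB2, two haplotypes each.
    """
    rng = np.random.default_rng([int(cfg.seed), 11])
    n_dip = cfg.n_diploids_per_subspecies
    n_pop = cfg.n_haps_per_pop
    n_haps = 4 * n_pop
    theta = cfg.effective_theta()

    # sample metadata -----------------------------------------------------
    sample_ids = []
    rows = []
    for k, ssp in enumerate(SUBSPECIES):
        for d in range(n_dip):
            sid = f"{ssp}_{d:02d}"
            sample_ids.append(sid)
            rows.append(
                {
                    "sample": sid,
                    "species": SPECIES_OF[ssp],
                    "subspecies": ssp,
                    "locality": LOCALITY_OF[ssp],
                    "phenotype": np.nan,
                }
            )

    # migrant haplotypes (within the sspA1 block, hap indices 0..n_pop-1)
    migrants = np.zeros(n_haps, dtype=bool)
    if cfg.tract is not None and cfg.introgression_fraction > 0:
        migrants[:n_pop] = rng.random(n_pop) < cfg.introgression_fraction

    pop_of = np.repeat(np.arange(4), n_pop)
    ts, tS, t_mig = (
        cfg.split_time_subspecies,
        cfg.split_time_species,
        cfg.introgression_time,
    )

    positions: list[int] = []
    columns: list[np.ndarray] = []
    n_segments = math.ceil(cfg.chrom_length / cfg.segment_length)
    for seg in range(n_segments):
        seg_start = seg * cfg.segment_length
        seg_end = min(seg_start + cfg.segment_length, cfg.chrom_length)
        in_tract = (
            cfg.tract is not None
            and seg_start < cfg.tract[1]
            and seg_end > cfg.tract[0]
        )
        demes: dict[str, list[int]] = {name: [] for name in SUBSPECIES}
        demes["A1m"] = []
        for h in range(n_haps):
            if in_tract and migrants[h]:
                demes["A1m"].append(h)
            else:
                demes[SUBSPECIES[pop_of[h]]].append(h)
        merges: list[tuple[float, int, list[str], str]] = [
            (ts, 1, ["sspA1", "sspA2"], "spA"),
            (ts, 1, ["sspB1", "sspB2"], "spB"),
            (tS, 2, ["spA", "spB"], "anc"),
        ]
        if demes["A1m"]:
            target = "sspB1" if t_mig < ts else "spB"
            merges.append((t_mig, 0, ["A1m"], target))
        times = [0.0] * n_haps
        parents = [-1] * n_haps
        _coalesce_segment(rng, demes, merges, times, parents)

        # descendant leaf sets (parents always created after children)
        n_nodes = len(times)
        leafsets = np.zeros((n_nodes, n_haps), dtype=bool)
        leafsets[np.arange(n_haps), np.arange(n_haps)] = True
        for v in range(n_nodes):
            p = parents[v]
            if p >= 0:
                leafsets[p] |= leafsets[v]

        # Poisson mutations per branch
        for v in range(n_nodes):
            p = parents[v]
            if p < 0:
                continue
            branch = times[p] - times[v]
            n_mut = rng.poisson(theta * branch) if theta > 0 else 0
            for _ in range(n_mut):
                pos = int(rng.integers(seg_start, seg_end))
                positions.append(pos)
                columns.append(leafsets[v].astype(np.int8))

    # assemble, sort, deduplicate (infinite sites: drop collisions)
    if positions:
        pos_arr = np.array(positions, dtype=np.int64)
        mat = np.array(columns, dtype=np.int8)
        order = np.argsort(pos_arr, kind="stable")
        pos_arr, mat = pos_arr[order], mat[order]
        keep = np.concatenate([[True], np.diff(pos_arr) > 0])
        pos_arr, mat = pos_arr[keep], mat[keep]
    else:
        pos_arr = np.zeros(0, dtype=np.int64)
        mat = np.zeros((0, n_haps), dtype=np.int8)

    # causal site: derived allele on donor sspB1 plus migrant sspA1 haplotypes
    phenotype = np.full(len(sample_ids), np.nan)
    if cfg.tract is not None:
        causal_col = np.zeros(n_haps, dtype=np.int8)
        causal_col[migrants] = 1
        causal_col[2 * n_pop:3 * n_pop] = 1  # all sspB1
        at = np.searchsorted(pos_arr, cfg.causal_pos)
        if at < len(pos_arr) and pos_arr[at] == cfg.causal_pos:
            mat[at] = causal_col
        else:
            pos_arr = np.insert(pos_arr, at, cfg.causal_pos)
            mat = np.insert(mat, at, causal_col, axis=0)
        dose = causal_col[0::2] + causal_col[1::2]
        if cfg.dominance == "recessive":
            phenotype = (dose == 2).astype(float)
        else:
            phenotype = (dose >= 1).astype(float)

    for r, ph in zip(rows, phenotype):
        r["phenotype"] = ph
    st = SampleTable(pd.DataFrame(rows))
    hm = HaplotypeMatrix(
        chrom=cfg.chrom,
        positions=pos_arr,
        ref=["A"] * len(pos_arr),
        alt=[["T"]] * len(pos_arr),
        alleles=mat,
        hap_to_sample=[(s, phase) for s in sample_ids for phase in (1, 2)],
    )
    return hm, st


# ---------------------------------------------------------------------------
# 4-population allele frequencies (Balding-Nichols)
# ---------------------------------------------------------------------------

@dataclass
class FreqSimConfig:
    """Balding-Nichols drift from a shared ancestral frequency per site.

    Ancestral p ~ Uniform(0.05, 0.95); each population draws
    Beta(p(1-F)/F, (1-p)(1-F)/F).  ``admix_edge`` = (donor, recipient, m)
    replaces the recipient frequency with (1-m) p_recipient + m p_donor.
    """

    seed: int = 0
    n_pops: int = 4
    n_sites: int = 10_000
    F_drift: float | tuple[float, float, float, float] = 0.1
    admix_edge: tuple[int, int, float] | None = None
    site_spacing_bp: int = 500
    chrom: str = "sim4pop"

    def __post_init__(self) -> None:
        if self.n_pops != 4:
            raise ValueError("exactly 4 populations are supported")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        fs = (
            self.F_drift
            if isinstance(self.F_drift, (tuple, list))
            else (self.F_drift,) * 4
        )
        if len(fs) != 4 or any(not 0.0 < f < 1.0 for f in fs):
            raise ValueError("F_drift values must lie strictly in (0, 1)")
        if self.admix_edge is not None:
            donor, recip, m = self.admix_edge
            if donor == recip or not {donor, recip} <= {0, 1, 2, 3}:
                raise ValueError("admix_edge populations must be distinct indices 0..3")
            if not 0.0 <= m <= 1.0:
                raise ValueError("admixture proportion must be in [0, 1]")

    @property
    def drift_per_pop(self) -> tuple[float, float, float, float]:
        if isinstance(self.F_drift, (tuple, list)):
            return tuple(self.F_drift)
        return (self.F_drift,) * 4


def simulate_frequencies(cfg: FreqSimConfig) -> FrequencyTable:
    """4-population frequency table; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng([int(cfg.seed), 12])
    p = rng.uniform(0.05, 0.95, size=cfg.n_sites)
    freqs = np.empty((cfg.n_sites, 4))
    for k, F in enumerate(cfg.drift_per_pop):
        a = p * (1.0 - F) / F
        b = (1.0 - p) * (1.0 - F) / F
        freqs[:, k] = rng.beta(a, b)
    if cfg.admix_edge is not None:
        donor, recip, m = cfg.admix_edge
        freqs[:, recip] = (1.0 - m) * freqs[:, recip] + m * freqs[:, donor]
    positions = np.arange(cfg.n_sites, dtype=np.int64) * cfg.site_spacing_bp
    return FrequencyTable(
        chrom=cfg.chrom,
        positions=positions,
        freqs=freqs,
        counts=None,
        pop_names=("sppA_loc1", "sppA_loc2", "sppB_loc1", "sppB_loc2"),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixture(
    hm: HaplotypeMatrix,
    st: SampleTable,
    outdir: str | Path,
    cfg: SimConfig | None = None,
) -> dict[str, Path]:
    """Write a VCF, a metadata TSV and a config stub usable by the CLI."""
    if hm.n_haps == 0 or len(st) == 0:
        raise ValueError("refusing to write a fixture with zero samples")
    if set(hm.samples) != set(st.samples):
        raise ValueError("haplotype matrix and sample table disagree on samples")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_path = outdir / "sim.vcf"
    tsv_path = outdir / "samples.tsv"
    yml_path = outdir / "config.yaml"
    contig = cfg.chrom_length if cfg is not None else None
    write_vcf(hm, vcf_path, contig_length=contig)
    st.to_tsv(tsv_path)
    stub = {
        "vcf": vcf_path.name,
        "samples": tsv_path.name,
        "quartet": {"g1": "sspA1", "g2": "sspA2", "g3": "sspB1", "g4": "sspB2"},
    }
    if cfg is not None and cfg.tract is not None:
        stub["focal"] = {
            "chrom": cfg.chrom, "start": cfg.tract[0], "end": cfg.tract[1]
        }
    with open(yml_path, "w") as fh:
        yaml.safe_dump(stub, fh, sort_keys=False)
    return {"vcf": vcf_path, "samples": tsv_path, "config": yml_path}
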