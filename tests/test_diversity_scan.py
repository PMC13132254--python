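"""Pooled nucleotide diversity and trans-species polymorphism rules."""

import numpy as np
import pytest

import tigerwing as tw
from tigerwing.geno_io import MISSING

from oracles import pooled_pi_loop, transpoly_loop


def gm_from(genotypes, positions=None, samples=None):
    g = np.array(genotypes, dtype=np.int8)
    if positions is None:
        positions = np.arange(g.shape[0])
    if samples is None:
        samples = [f"s{i}" for i in range(g.shape[1])]
    return tw.GenotypeMatrix(
        chrom="c", positions=np.asarray(positions, np.int64),
        ref=["A"] * g.shape[0], alt=["T"] * g.shape[0],
        genotypes=g, samples=samples,
    )


class TestPooledPi:
    def test_one_het_site_of_ten(self):
        # one diploid: allele pair per site; 1 heterozygous site in 10
        g = np.zeros((10, 1), dtype=np.int8)
        g[3, 0] = 1
        tr = tw.pooled_pi(gm_from(g), [tw.GenomicWindow("c", 0, 100)])
        assert tr.pi[0] == pytest.approx(0.1)
        assert tr.diff_sum[0] == 1 and tr.comp_sum[0] == 10

    def test_invariant_sites_grow_denominator(self):
        rng = np.random.default_rng(0)
        var = rng.integers(0, 3, size=(10, 4)).astype(np.int8)
        invar = np.zeros((10, 4), dtype=np.int8)
        w = [tw.GenomicWindow("c", 0, 100)]
        pi_var = tw.pooled_pi(gm_from(var), w).pi[0]
        both = np.vstack([var, invar])
        pi_both = tw.pooled_pi(gm_from(both), w).pi[0]
        assert pi_both == pytest.approx(pi_var / 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pair_count_oracle_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(60, 6)).astype(np.int8)
        g[rng.random(g.shape) < 0.25] = MISSING
        pos = np.sort(rng.choice(3000, size=60, replace=False))
        gm = gm_from(g, positions=pos)
        wins = [tw.GenomicWindow("c", 0, 1500), tw.GenomicWindow("c", 1500, 3000)]
        tr = tw.pooled_pi(gm, wins)
        exp = pooled_pi_loop(g, pos, [(w.start, w.end) for w in wins])
        for k, (d, c) in enumerate(exp):
            assert tr.diff_sum[k] == d and tr.comp_sum[k] == c

    def test_identical_haplotypes_zero(self):
        g = np.full((50, 5), 2, dtype=np.int8)
        tr = tw.pooled_pi(gm_from(g), [tw.GenomicWindow("c", 0, 100)])
        assert tr.pi[0] == 0.0

    def test_two_diverged_groups_approach_between_fraction(self):
        # two groups fixed for opposite alleles at every 2nd site
        g = np.zeros((100, 4), dtype=np.int8)
        g[::2, 2:] = 2
        tr = tw.pooled_pi(gm_from(g), [tw.GenomicWindow("c", 0, 200)])
        # per divergent site: 4x4 discordant pairs of C(8,2)=28; 50 of 100 sites
        assert tr.pi[0] == pytest.approx(0.5 * 16 / 28)

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tw.pooled_pi(gm_from(np.zeros((5, 2), np.int8)), [])


class TestClassifyTranspoly:
    def five_species(self, doses_per_species):
        """One site; per species a list of diploid doses at that site."""
        cols, samples, smap = [], [], {}
        for sp, doses in doses_per_species.items():
            smap[sp] = []
            for i, d in enumerate(doses):
                name = f"{sp}_{i}"
                samples.append(name)
                smap[sp].append(name)
                cols.append([d])
        g = np.array(cols, dtype=np.int8).T  # sites x samples
        return gm_from(g, samples=samples), smap

    def test_rule_i_with_copy_rule(self):
        # 5 species present, 4 polymorphic; copies (ref, alt) = (42, 8)
        per_sp = {
            "sp1": [1, 1, 1, 1, 1],  # five heterozygotes
            "sp2": [1, 0, 0, 0, 0],
            "sp3": [1, 0, 0, 0, 0],
            "sp4": [1, 0, 0, 0, 0],
            "sp5": [0, 0, 0, 0, 0],  # monomorphic
        }
        gm, smap = self.five_species(per_sp)
        tp = tw.classify_transpoly(gm, smap)
        assert bool(tp.is_transpolymorphic[0])
        assert tp.rule_fired[0] == "i"

    def test_copy_rule_boundary_six_needed(self):
        # 4 polymorphic species but only 5 copies of the minor allele
        doses = {
            "sp1": [1, 0], "sp2": [1, 0], "sp3": [1, 0], "sp4": [1, 1],
            "sp5": [0, 0],
        }
        gm, smap = self.five_species(doses)
        tp = tw.classify_transpoly(gm, smap)
        assert tp.alt_copies[0] == 5
        assert not bool(tp.is_transpolymorphic[0])
        # one more alt copy reaches the >= 6 threshold
        doses["sp5"] = [1, 0]
        gm2, smap2 = self.five_species(doses)
        tp2 = tw.classify_transpoly(gm2, smap2)
        assert tp2.alt_copies[0] == 6
        assert bool(tp2.is_transpolymorphic[0])

    def test_rule_ii_all_species_when_three_or_fewer(self):
        doses = {"sp1": [1, 1], "sp2": [1, 1], "sp3": [1, 1]}
        gm, smap = self.five_species(doses)
        tp = tw.classify_transpoly(gm, smap)
        assert bool(tp.is_transpolymorphic[0]) and tp.rule_fired[0] == "ii"
        # one monomorphic species breaks rule ii
        doses["sp3"] = [0, 0]
        gm2, smap2 = self.five_species(doses)
        assert not bool(tw.classify_transpoly(gm2, smap2).is_transpolymorphic[0])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_rule_by_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sites, n_per_sp, n_sp = 1000, 3, 6
        g = rng.integers(0, 3, size=(n_sites, n_per_sp * n_sp)).astype(np.int8)
        g[rng.random(g.shape) < 0.2] = MISSING
        species_of_col = [f"sp{j // n_per_sp}" for j in range(n_per_sp * n_sp)]
        samples = [f"sp{j // n_per_sp}_{j}" for j in range(n_per_sp * n_sp)]
        gm = gm_from(g, samples=samples)
        smap = {
            sp: [s for s, c in zip(samples, species_of_col) if c == sp]
            for sp in set(species_of_col)
        }
        cfg = tw.AnalysisConfig()
        tp = tw.classify_transpoly(gm, smap, cfg)
        exp = transpoly_loop(
            g, species_of_col, cfg.transpoly_min_poly_species,
            cfg.transpoly_min_allele_copies,
        )
        np.testing.assert_array_equal(tp.is_transpolymorphic, np.array(exp))

    def test_sample_and_species_order_invariance(self, rng):
        g = rng.integers(0, 3, size=(200, 12)).astype(np.int8)
        samples = [f"x{j}" for j in range(12)]
        gm = gm_from(g, samples=samples)
        smap = {"b": samples[0:4], "a": samples[4:8], "c": samples[8:12]}
        tp1 = tw.classify_transpoly(gm, smap)
        perm = list(rng.permutation(12))
        gm2 = gm_from(g[:, perm], samples=[samples[j] for j in perm])
        smap2 = {"c": smap["c"][::-1], "a": smap["a"], "b": smap["b"][::-1]}
        tp2 = tw.classify_transpoly(gm2, smap2)
        np.testing.assert_array_equal(
            tp1.is_transpolymorphic, tp2.is_transpolymorphic
        )

    def test_fewer_than_two_species_rejected(self):
        gm = gm_from(np.zeros((5, 2), np.int8), samples=["a", "b"])
        with pytest.raises(ValueError, match="two species"):
            tw.classify_transpoly(gm, {"sp1": ["a", "b"]})


class TestWindowCounts:
    def test_counts_and_order_invariance(self, rng):
        pos = np.sort(rng.choice(20_000, size=300, replace=False))
        flags = rng.random(300) < 0.3
        tp = tw.TransPolyTable(
            positions=pos, species=["a", "b"],
            poly_flags=np.zeros((300, 2), bool),
            ref_copies=np.zeros(300, np.int64), alt_copies=np.zeros(300, np.int64),
            is_transpolymorphic=flags, rule_fired=["none"] * 300,
        )
        wins = tw.tile_windows("c", 0, 20_000, 10_000)
        counts = tw.transpoly_window_counts(tp, wins)
        assert counts.sum() == flags.sum()
        assert counts[0] == int(np.sum(flags & (pos < 10_000)))

    def test_no_transpoly_all_zero(self):
        tp = tw.TransPolyTable(
            positions=np.arange(10), species=["a", "b"],
            poly_flags=np.zeros((10, 2), bool),
            ref_copies=np.zeros(10, np.int64), alt_copies=np.zeros(10, np.int64),
            is_transpolymorphic=np.zeros(10, bool), rule_fired=["none"] * 10,
        )
        counts = tw.transpoly_window_counts(tp, tw.tile_windows("c", 0, 10, 5))
        assert counts.sum() == 0

    def test_deep_splits_few_transpoly(self):
        """With deep species splits and no introgression, trans-species
        polymorphism among variant sites is rare."""
        cfg = tw.SimConfig(
            seed=21, n_diploids_per_subspecies=4, chrom_length=300_000,
            theta_within=20.0, split_time_subspecies=0.5, split_time_species=4.0,
        )
        hm, st = tw.simulate_haplotypes(cfg)
        gm = hm.to_genotype_matrix()
        tp = tw.classify_transpoly(gm, st.species_map())
        seg = (gm.genotypes > 0).any(axis=1)
        frac = tp.is_transpolymorphic.sum() / max(seg.sum(), 1)
        assert frac < 0.05
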