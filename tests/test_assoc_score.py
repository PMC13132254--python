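"""Association post-processing: trend scan, rho2, intervals, motifs."""

import numpy as np
import pytest
from scipy import stats

import tigerwing as tw
from tigerwing.geno_io import MISSING
from tigerwing.assoc_score import build_assoc_table

from oracles import spearman_rho2_loop


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


class TestAssociationScan:
    def test_null_p_values_uniform(self):
        """Trend-test p-values under permuted phenotypes are calibrated.

        The statistic is discrete (integer doses against a categorical
        code), so the p-value has an atom at 1 from exactly balanced SNPs
        and a continuous-uniform KS test is inappropriate; the operative
        property is tail calibration: P(p <= a) = a within binomial error
        at every working threshold, over >= 1000 null SNPs.
        """
        rng = np.random.default_rng(8)
        n_snp, n = 1500, 120
        afs = rng.uniform(0.1, 0.5, n_snp)
        g = rng.binomial(2, afs[:, None], size=(n_snp, n)).astype(np.int8)
        y = np.zeros(n)
        y[: n // 2] = 1.0
        y = y[rng.permutation(n)]
        p, degen = tw.association_scan(gm_from(g), y)
        p = p[~degen]
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            tol = 3 * np.sqrt(alpha * (1 - alpha) / len(p))
            assert abs(np.mean(p <= alpha) - alpha) <= tol + 1e-3

    def test_degenerate_sites_flagged_p_one(self):
        g = np.array([[0, 0, 0, 0], [1, MISSING, MISSING, MISSING]], dtype=np.int8)
        p, degen = tw.association_scan(gm_from(g), np.array([0, 0, 1, 1.0]))
        assert np.all(p == 1.0) and np.all(degen)

    def test_constant_phenotype_rejected(self):
        g = np.array([[0, 1, 2, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="constant"):
            tw.association_scan(gm_from(g), np.zeros(4))

    def test_perfect_separation_smallest_p(self, rng):
        n = 40
        g = rng.binomial(2, 0.3, size=(100, n)).astype(np.int8)
        y = np.zeros(n)
        y[: n // 2] = 1.0
        causal = np.where(y == 1, 2, 0).astype(np.int8)
        g[50] = causal
        p, _ = tw.association_scan(gm_from(g), y)
        assert np.argmin(p) == 50


class TestBonferroni:
    def test_examples(self):
        assert tw.bonferroni_threshold(1_000_000, 0.05) == pytest.approx(5e-8)
        assert tw.bonferroni_threshold(1, 0.05) == 0.05

    def test_monotone_decreasing(self):
        ts = [tw.bonferroni_threshold(n, 0.05) for n in (1, 10, 100, 10_000)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            tw.bonferroni_threshold(0, 0.05)


class TestRho2:
    def test_perfect_monotone(self):
        assert tw.rho2([0, 0, 2, 2], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert tw.rho2([0, 2, 0, 2], [0, 0, 1, 1]) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_midrank_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, 30)
        y = rng.choice([0.0, 0.5, 1.0], 30)
        if np.unique(g).size < 2 or np.unique(y).size < 2:
            pytest.skip("degenerate draw")
        assert tw.rho2(g, y) == pytest.approx(
            spearman_rho2_loop(g, y), abs=1e-12
        )

    def test_invariant_under_strictly_monotone_recoding(self, rng):
        g = rng.integers(0, 3, 50)
        y = rng.choice([0.0, 0.5, 1.0], 50)
        base = tw.rho2(g, y)
        recoded_g = np.array([0, 10, 11])[g]          # strictly monotone
        recoded_y = y * 7 + 2
        assert tw.rho2(recoded_g, recoded_y) == pytest.approx(base, abs=1e-12)

    def test_constant_input_undefined(self):
        assert tw.rho2([1, 1, 1, 1], [0, 1, 0, 1]) is None


class TestAssocTable:
    def make_table(self, rng, n=60):
        g = rng.binomial(2, 0.4, size=(200, n)).astype(np.int8)
        y = np.zeros(n)
        y[: n // 2] = 1.0
        g[10] = np.where(y == 1, 2, 0)  # fully associated SNP
        return build_assoc_table(gm_from(g), y)

    def test_fully_associated_implies_significant(self, rng):
        tab = self.make_table(rng)
        df = tab.df
        assert df.loc[df["fully_associated"], "significant"].all()
        assert bool(df.loc[10, "fully_associated"])

    def test_interval_single_snp_length_one(self, rng):
        tab = self.make_table(rng)
        iv = tw.fully_associated_interval(tab)
        assert iv.n_snps >= 1
        if iv.n_snps == 1:
            assert iv.length_bp == 1

    def test_interval_none_when_no_full_association(self, rng):
        g = rng.binomial(2, 0.4, size=(50, 40)).astype(np.int8)
        y = np.zeros(40)
        y[:20] = 1.0
        tab = build_assoc_table(gm_from(g), y)
        if not tab.df["fully_associated"].any():
            assert tw.fully_associated_interval(tab) is None

    def test_printed_endpoints_inclusive_length(self):
        """Interval length from 1-based inclusive endpoints 6,877,302 and
        6,878,798 is 1,497 bp (~1.5 kb)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "pos": [6_877_302, 6_877_900, 6_878_798],
                "p": [1e-12] * 3,
                "minus_log10_p": [12.0] * 3,
                "rho2": [1.0] * 3,
                "significant": [True] * 3,
                "fully_associated": [True] * 3,
                "degenerate": [False] * 3,
            }
        )
        tab = tw.AssocTable(chrom="CHROM6", df=df, threshold=1e-8)
        iv = tw.fully_associated_interval(tab)
        assert (iv.start, iv.end) == (6_877_302, 6_878_798)
        assert iv.length_bp == 1497


class TestGenotypeMatrixExport:
    def make(self, g, phen):
        n = g.shape[1]
        samples = [f"s{i}" for i in range(n)]
        gm = gm_from(g, samples=samples)
        import pandas as pd

        st = tw.SampleTable(
            pd.DataFrame(
                {"sample": samples, "species": "sp", "subspecies": "ssp",
                 "locality": "l", "phenotype": phen}
            )
        )
        tab = build_assoc_table(gm, np.asarray(phen, float))
        return gm, st, tab

    def test_two_samples_one_snp_round_trip(self, tmp_path, rng):
        g = np.array([[0, 2], [2, 0], [1, 1]], dtype=np.int8)
        gm, st, tab = self.make(g, [0.0, 1.0])
        out = tw.genotype_matrix_export(gm, [0], st, tab, tmp_path / "m.tsv")
        assert out.shape == (2, 3)
        text = (tmp_path / "m.tsv").read_text().splitlines()
        assert text[0].startswith("sample\tphenotype")
        assert text[1].startswith("minus_log10_p")

    def test_sample_order_invariance(self, tmp_path, rng):
        g = rng.binomial(2, 0.5, size=(6, 10)).astype(np.int8)
        phen = list((rng.random(10) < 0.5).astype(float))
        gm, st, tab = self.make(g, phen)
        out1 = tw.genotype_matrix_export(gm, [0, 2, 4], st, tab, tmp_path / "a.tsv")
        perm = rng.permutation(10)
        gm2 = gm_from(g[:, perm], samples=[gm.samples[i] for i in perm])
        st2 = tw.SampleTable(st.df.iloc[perm].reset_index(drop=True))
        out2 = tw.genotype_matrix_export(gm2, [0, 2, 4], st2, tab, tmp_path / "b.tsv")
        assert list(out1["sample"]) == list(out2["sample"])

    def test_homozygote_values_exact(self, tmp_path, rng):
        g = np.array([[0, 2, 2, 0], [2, 2, 0, 0]], dtype=np.int8)
        gm, st, tab = self.make(g, [0.0, 1.0, 1.0, 0.0])
        out = tw.genotype_matrix_export(gm, [0, 1], st, tab, tmp_path / "m.tsv")
        by_sample = out.set_index("sample")
        for j, s in enumerate(gm.samples):
            assert int(by_sample.loc[s].iloc[1]) == g[0, j]

    def test_empty_snp_set_rejected(self, tmp_path, rng):
        g = np.zeros((2, 4), dtype=np.int8)
        gm, st, tab = self.make(g, [0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="empty"):
            tw.genotype_matrix_export(gm, [], st, tab, tmp_path / "m.tsv")


class TestDiagnosticMotifScan:
    def test_single_fixed_snp_exhaustive_enumeration(self):
        """Groups differing at exactly one fixed site: the diagnostic k-mers
        are exactly the k-mers overlapping that site in either consensus."""
        base = "ACGTACGTTAGCCATGGATCGATCGGTACC"
        pos = 14
        a = base
        b = base[:pos] + "C" + base[pos + 1:]
        hits = tw.diagnostic_motif_scan([a] * 5, [b] * 5, [pos], (6, 6))
        expected = set()
        for seq in (a, b):
            for s in range(pos - 5, pos + 1):
                expected.add(seq[s:s + 6])
        assert {h.motif for h in hits} == expected
        assert all(h.k == 6 for h in hits)

    def test_identical_groups_no_hits(self):
        seqs = ["ACGTACGTAGCTAGCTAA"] * 4
        assert tw.diagnostic_motif_scan(seqs, list(seqs), [5], (6, 8)) == []

    def test_relaxed_mode_tolerates_four_percent(self):
        base = "ACGTACGTTAGCCATGGATCGATCGGTACC"
        pos = 14
        a = base
        b = base[:pos] + "C" + base[pos + 1:]
        group_b = [b] * 24 + [a]  # 1 of 25 (4%) carries the A-form motif
        strict = tw.diagnostic_motif_scan([a] * 5, group_b, [pos], (6, 6), "strict")
        relaxed = tw.diagnostic_motif_scan([a] * 5, group_b, [pos], (6, 6), "relaxed")
        a_enriched_strict = [h for h in strict if h.enriched_in == "A"]
        a_enriched_relaxed = [h for h in relaxed if h.enriched_in == "A"]
        assert not a_enriched_strict
        assert a_enriched_relaxed

    def test_group_label_swap_symmetry(self):
        base = "ACGTACGTTAGCCATGGATCGATCGGTACC"
        pos = 7
        a, b = base, base[:pos] + "A" + base[pos + 1:]
        h_ab = tw.diagnostic_motif_scan([a] * 3, [b] * 3, [pos], (6, 7))
        h_ba = tw.diagnostic_motif_scan([b] * 3, [a] * 3, [pos], (6, 7))
        assert {(h.motif, h.enriched_in) for h in h_ab} == {
            (h.motif, {"A": "B", "B": "A"}[h.enriched_in]) for h in h_ba
        }

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            tw.diagnostic_motif_scan(["ACGT"], ["ACG"], [1], (2, 3))
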