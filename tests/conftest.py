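"""Shared fixtures: small simulated datasets and quartet helpers."""

import numpy as np
import pytest

import tigerwing as tw


def quartet_single_hap(st):
    """One haplotype per subspecies: the small-sample quartet configuration."""
    haps = [
        f"{st.samples_where(subspecies=ssp)[0]}_1"
        for ssp in ("sspA1", "sspA2", "sspB1", "sspB2")
    ]
    return haps, tw.QuartetSpec((haps[0],), (haps[1],), (haps[2],), (haps[3],))


def quartet_all_haps(st):
    """All haplotypes per subspecies."""
    groups = [
        tuple(
            f"{s}_{p}"
            for s in st.samples_where(subspecies=ssp)
            for p in (1, 2)
        )
        for ssp in ("sspA1", "sspA2", "sspB1", "sspB2")
    ]
    return tw.QuartetSpec(*groups)


@pytest.fixture(scope="session")
def small_sim():
    """A small neutral quartet simulation shared across read-only tests."""
    cfg = tw.SimConfig(
        seed=11,
        n_diploids_per_subspecies=2,
        chrom_length=400_000,
        theta_within=25.0,
        split_time_subspecies=0.2,
        split_time_species=0.4,
    )
    hm, st = tw.simulate_haplotypes(cfg)
    return cfg, hm, st


@pytest.fixture(scope="session")
def introgressed_sim():
    """A forced-introgression simulation (tract = [100 kb, 300 kb))."""
    cfg = tw.SimConfig(
        seed=5,
        n_diploids_per_subspecies=1,
        chrom_length=500_000,
        theta_within=25.0,
        split_time_subspecies=0.2,
        split_time_species=0.4,
        tract=(100_000, 300_000),
        causal_pos=200_000,
        introgression_fraction=1.0,
        introgression_time=0.01,
    )
    hm, st = tw.simulate_haplotypes(cfg)
    return cfg, hm, st


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
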