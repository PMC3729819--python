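"""Synthetic-data generator: determinism, planted signal, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from dsbscape import (
    ConditionParams,
    ParSpec,
    SimConfig,
    generate_genome,
    plant_truth,
    simulate_fragments,
    simulate_h3k4me3_tags,
)
from dsbscape.errors import SizingError, ValidationError
from dsbscape.motifs import scan_consensus, scan_sequence, ConsensusPattern
from dsbscape.simulate import hotspot_means


def one_mb_config(**kw):
    base = dict(
        chrom_lengths={"chr1": 1_000_000},
        n_hotspots=10,
        gal4_fraction=0.5,
        subtelomere_end_width=100_000,
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_planted_sites_are_exact_matches(self):
        genome, truth = generate_genome(one_mb_config())
        assert len(genome["chr1"]) == 1_000_000
        assert truth.hotspots["has_gal4"].sum() == 5
        sites = scan_consensus(genome)
        found = set(zip(sites["chrom"], sites["start"]))
        for row in truth.motif_sites.itertuples(index=False):
            assert (row.chrom, row.start) in found

    def test_site_midpoint_at_hotspot_center(self):
        _, truth = generate_genome(one_mb_config())
        flagged = truth.hotspots.loc[truth.hotspots["has_gal4"]]
        mids = (truth.motif_sites["start"] + truth.motif_sites["end"]) // 2
        assert sorted(mids) == sorted(flagged["center"])

    def test_byte_identical_given_seed(self):
        g1, t1 = generate_genome(one_mb_config())
        g2, t2 = generate_genome(one_mb_config())
        assert g1 == g2
        pd.testing.assert_frame_equal(t1.hotspots, t2.hotspots)

    def test_seed_changes_genome(self):
        g1, _ = generate_genome(one_mb_config(seed=1))
        g2, _ = generate_genome(one_mb_config(seed=2))
        assert g1 != g2

    def test_accidental_site_rejection_near_centers(self):
        cfg = one_mb_config(gal4_fraction=0.0, reject_accidental_sites=True)
        genome, truth = generate_genome(cfg)
        pattern = ConsensusPattern()
        for row in truth.hotspots.itertuples(index=False):
            window = genome[row.chrom][row.center - 1_000 : row.center + 1_000]
            assert len(scan_sequence(window, pattern)) == 0

    def test_chromosome_too_short_raises(self):
        with pytest.raises(SizingError):
            plant_truth(one_mb_config(chrom_lengths={"chr1": 20_000}, n_hotspots=50))

    def test_par_outside_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            one_mb_config(par=ParSpec(chrom="chr1", start=990_000, width=40_000))


class TestFragments:
    def test_zero_signal_leaves_only_background(self):
        cfg = one_mb_config(background_per_mb=50.0)
        truth = plant_truth(cfg)
        frags, book = simulate_fragments(
            cfg, truth, ConditionParams(signal_factor=0.0), seed=3
        )
        assert book["hotspot_draws"].sum() == 0
        assert len(frags) >= 1
        assert book["n_distinct"] == book["n_background"]

    def test_poisson_mean_recovered_over_seeds(self):
        """One hotspot with expected 1,000 fragments, no background: the
        Monte-Carlo mean over 10 seeds lands within [900, 1100]."""
        cfg = SimConfig(
            chrom_lengths={"chr1": 1_000_000}, n_hotspots=1,
            strength_scale=1.0, background_per_mb=0.0, duplicate_rate=0.0,
            subtelomere_end_width=1, seed=9,
        )
        truth = plant_truth(cfg)
        truth.hotspots.loc[0, "strength"] = 1_000.0
        counts = [
            len(simulate_fragments(cfg, truth, seed=s)[0]) for s in range(10)
        ]
        assert 900 <= np.mean(counts) <= 1_100

    def test_no_duplicates_when_rate_zero(self):
        cfg = one_mb_config(duplicate_rate=0.0)
        truth = plant_truth(cfg)
        frags, _ = simulate_fragments(cfg, truth, seed=4)
        keys = frags[["chrom", "start", "end", "strand"]]
        assert not keys.duplicated().any()

    def test_duplicates_are_exact_copies(self):
        cfg = one_mb_config(duplicate_rate=2.0, background_per_mb=0.0)
        truth = plant_truth(cfg)
        frags, book = simulate_fragments(cfg, truth, seed=4)
        assert book["n_emitted"] == len(frags)
        assert book["n_emitted"] > book["n_distinct"]

    def test_fragment_count_conservation(self):
        cfg = one_mb_config()
        truth = plant_truth(cfg)
        frags, book = simulate_fragments(cfg, truth, seed=8)
        assert book["n_distinct"] == book["n_background"] + book["hotspot_draws"].sum()
        assert book["n_emitted"] == len(frags)

    def test_fragments_clipped_to_chromosome(self):
        cfg = one_mb_config()
        truth = plant_truth(cfg)
        frags, _ = simulate_fragments(cfg, truth, seed=12)
        assert (frags["start"] >= 0).all()
        assert (frags["end"] <= 1_000_000).all()
        assert (frags["end"] > frags["start"]).all()

    def test_centers_cluster_with_configured_dispersion(self):
        cfg = SimConfig(
            chrom_lengths={"chr1": 1_000_000}, n_hotspots=1,
            strength_scale=500.0, strength_shape=5.0,
            background_per_mb=0.0, duplicate_rate=0.0,
            fragment_dispersion=500, subtelomere_end_width=1, seed=2,
        )
        truth = plant_truth(cfg)
        frags, _ = simulate_fragments(cfg, truth, seed=2)
        mids = (frags["start"] + frags["end"]) // 2
        center = truth.hotspots["center"].iloc[0]
        offs = mids - center
        assert abs(offs.mean()) < 100  # symmetric about the hotspot center
        # truncation at 3 sigma (plus fragment-end clipping slack)
        assert offs.abs().max() <= 3 * 500 + 5

    def test_determinism(self):
        cfg = one_mb_config()
        truth = plant_truth(cfg)
        f1, _ = simulate_fragments(cfg, truth, seed=6)
        f2, _ = simulate_fragments(cfg, truth, seed=6)
        pd.testing.assert_frame_equal(f1, f2)

    def test_condition_multipliers_compose(self):
        cfg = one_mb_config(
            par=ParSpec(chrom="chr1", start=950_000, width=40_000,
                        total_strength=200.0),
        )
        truth = plant_truth(cfg)
        cond = ConditionParams(
            efficiency=0.5, subtelomere_factor=0.1, par_factor=0.01,
            gal4_factor=2.0,
        )
        means = hotspot_means(truth.hotspots, cfg, cond)
        hs = truth.hotspots
        for i in range(len(hs)):
            expect = hs["strength"].iloc[i] * 0.5
            near = (
                hs["center"].iloc[i] < 100_000
                or hs["center"].iloc[i] >= 900_000
            )
            if near:
                expect *= 0.1
            if hs["in_par"].iloc[i]:
                expect *= 0.01
            if hs["has_gal4"].iloc[i]:
                expect *= 2.0
            assert means[i] == pytest.approx(expect)


class TestH3K4me3:
    def test_zero_hotspots_zero_tags(self):
        cfg = one_mb_config(n_hotspots=0, gal4_fraction=0.0)
        truth = plant_truth(cfg)
        tags, peaks = simulate_h3k4me3_tags(truth, seed=1)
        assert len(tags) == 0 and len(peaks) == 0

    def test_determinism(self):
        truth = plant_truth(one_mb_config())
        t1, p1 = simulate_h3k4me3_tags(truth, seed=5)
        t2, p2 = simulate_h3k4me3_tags(truth, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_tags_ignore_subtelomere_suppression(self):
        """Tag counts track true strength at every hotspot, including
        those a DSB condition would suppress (end-bin share stays flat)."""
        cfg = one_mb_config(n_hotspots=40, gal4_fraction=0.0)
        truth = plant_truth(cfg)
        tags, _ = simulate_h3k4me3_tags(truth, seed=7)
        hs = truth.hotspots
        near = (hs["center"] < 100_000) | (hs["center"] >= 900_000)
        expected_share = hs.loc[near, "strength"].sum() / hs["strength"].sum()
        mids = (tags["start"] + tags["end"]) // 2
        got_share = ((mids < 100_000) | (mids >= 900_000)).mean()
        assert got_share == pytest.approx(expected_share, abs=0.05)


class TestParCluster:
    def test_twenty_overlapping_hotspots_in_40kb(self):
        cfg = one_mb_config(
            par=ParSpec(chrom="chr1", start=950_000, width=40_000,
                        total_strength=400.0)
        )
        truth = plant_truth(cfg)
        par_hs = truth.hotspots.loc[truth.hotspots["in_par"]]
        assert len(par_hs) == 20
        assert (par_hs["center"] >= 950_000).all()
        assert (par_hs["center"] < 990_000).all()
        assert par_hs["strength"].sum() == pytest.approx(400.0)
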