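"""Central-window overlap semantics, classification partitioning,
strength correlation and motif-centered profiles."""

import numpy as np
import pandas as pd
import pytest

from dsbscape import (
    central_window,
    classify_hotspots,
    motif_center_profile,
    overlap_fraction,
    strength_correlation,
)
from dsbscape.errors import UndefinedResultError
from dsbscape.intervals import percent
from dsbscape.overlaps import classification_summary, overlap_flags


def hs_table(centers, chrom="chr1", strength=None, width=2_000):
    centers = np.asarray(centers, dtype=np.int64)
    return pd.DataFrame({
        "chrom": chrom,
        "start": centers - width // 2,
        "end": centers + width // 2,
        "center": centers,
        "strength": strength if strength is not None else np.full(len(centers), 10),
        "qvalue": 0.01,
    })


def naive_overlap_count(set_a, set_b, wa, wb):
    """All-pairs quadratic oracle for the central-window overlap count."""
    def windows(df, w):
        out = []
        for r in df.itertuples(index=False):
            c = getattr(r, "center", None)
            if c is None:
                c = (r.start + r.end) // 2
            if w == 0:
                out.append((r.chrom, r.start, r.end))
            else:
                out.append((r.chrom, max(c - w // 2, 0), c + w // 2))
        return out

    awins, bwins = windows(set_a, wa), windows(set_b, wb)
    n = 0
    for ca, sa, ea in awins:
        if any(ca == cb and sa < eb and sb < ea for cb, sb, eb in bwins):
            n += 1
    return n


class TestCentralWindow:
    def test_arithmetic(self):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [1_000], "end": [3_000]})
        win = central_window(iv, 400)
        assert (win["start"].iloc[0], win["end"].iloc[0]) == (1_800, 2_200)

    def test_window_may_exceed_narrow_interval(self):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [120]})
        win = central_window(iv, 400, {"chr1": 10_000})
        assert (win["start"].iloc[0], win["end"].iloc[0]) == (0, 310)

    def test_width_equal_to_interval(self):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [1_000], "end": [1_400]})
        win = central_window(iv, 400)
        assert (win["start"].iloc[0], win["end"].iloc[0]) == (1_000, 1_400)

    def test_explicit_center_takes_precedence(self):
        iv = pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [10_000], "center": [9_000],
        })
        win = central_window(iv, 400)
        assert (win["start"].iloc[0], win["end"].iloc[0]) == (8_800, 9_200)


class TestOverlapFraction:
    def test_motif_in_central_2kb(self):
        hs = hs_table([10_000])
        motif = pd.DataFrame({"chrom": ["chr1"], "start": [9_900], "end": [9_917]})
        n, total, pct = overlap_fraction(hs, motif, 2_000, 0)
        assert (n, total, pct) == (1, 1, 100.0)

    def test_disjoint_chromosomes(self):
        a = hs_table([10_000], chrom="chr1")
        b = hs_table([10_000], chrom="chr2")
        assert overlap_fraction(a, b, 400, 400)[0] == 0

    def test_printed_count_arithmetic(self):
        assert percent(12_730, 13_445) == 94.7

    def test_self_overlap_is_total(self):
        hs = hs_table([5_000, 9_000, 40_000])
        n, total, pct = overlap_fraction(hs, hs, 400, 400)
        assert (n, total, pct) == (3, 3, 100.0)

    def test_symmetry_of_predicate(self, rng):
        a = hs_table(np.sort(rng.integers(5_000, 500_000, 40)))
        b = hs_table(np.sort(rng.integers(5_000, 500_000, 40)))
        fa = overlap_flags(a, b, 400, 400)
        fb = overlap_flags(b, a, 400, 400)
        # the predicate is symmetric pairwise, so total pair existence agrees
        assert fa.any() == fb.any()

    def test_matches_all_pairs_oracle(self, rng):
        for trial in range(5):
            na, nb = int(rng.integers(1, 200)), int(rng.integers(1, 200))
            chroms_a = rng.choice(["chr1", "chr2"], na)
            chroms_b = rng.choice(["chr1", "chr2"], nb)
            a = hs_table(rng.integers(2_000, 300_000, na))
            a["chrom"] = chroms_a
            b = hs_table(rng.integers(2_000, 300_000, nb))
            b["chrom"] = chroms_b
            for wa, wb in ((400, 400), (2_000, 0), (1_000, 1_000)):
                got = overlap_fraction(a, b, wa, wb)[0]
                assert got == naive_overlap_count(a, b, wa, wb)


class TestClassification:
    def test_partition_counts(self):
        """shared&motif + specific&motif equals total motif-bearing; the
        546 = 292 + 254 style split is exact."""
        query = hs_table(np.arange(20) * 10_000 + 10_000)
        reference = hs_table(np.arange(10) * 10_000 + 10_000)  # first 10 shared
        motif_centers = np.arange(20) * 10_000 + 10_000
        motifs = pd.DataFrame({
            "chrom": "chr1",
            "start": motif_centers - 8,
            "end": motif_centers + 9,
        })
        out = classify_hotspots(query, reference=reference, motifs=motifs)
        s = classification_summary(out)
        assert s["n_motif"] == 20
        assert s["n_shared_motif"] + s["n_specific_motif"] == s["n_motif"]
        assert s["n_shared_motif"] == 10
        assert s["n_specific_motif"] == 10

    def test_empty_reference_all_specific(self):
        query = hs_table([10_000, 20_000])
        out = classify_hotspots(query, reference=None)
        assert (~out["shared"]).all()

    def test_planted_specific_motif_hotspots_counted(self, rng):
        """Gal4-flagged hotspots planted only in the query condition are
        all classified specific-with-motif."""
        shared_c = np.arange(10) * 50_000 + 25_000
        gal4_c = np.arange(5) * 50_000 + 1_000_000
        query = hs_table(np.concatenate([shared_c, gal4_c]))
        reference = hs_table(shared_c)
        motifs = pd.DataFrame({
            "chrom": "chr1", "start": gal4_c - 8, "end": gal4_c + 9,
        })
        out = classify_hotspots(query, reference=reference, motifs=motifs)
        s = classification_summary(out)
        assert s["n_specific_motif"] == 5
        assert s["n_shared_motif"] == 0


class TestStrengthCorrelation:
    def test_identical_sets_rho_one(self):
        hs = hs_table(np.arange(50) * 10_000 + 5_000,
                      strength=np.arange(50) + 1)
        assert strength_correlation(hs, hs) == pytest.approx(1.0)

    def test_permuted_strengths_rho_small(self, rng):
        centers = np.arange(1_000) * 5_000 + 2_500
        strengths = rng.pareto(1.5, 1_000) * 10 + 1
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = hs_table(centers, strength=strengths)
            b = hs_table(centers, strength=r.permutation(strengths))
            assert abs(strength_correlation(a, b)) < 0.2

    def test_replicate_simulations_correlate(self):
        from dsbscape import ConditionParams, SimConfig, call_hotspots, plant_truth, simulate_fragments

        cfg = SimConfig(
            chrom_lengths={"chr1": 5_000_000}, n_hotspots=60,
            strength_scale=50.0, background_per_mb=10.0,
            duplicate_rate=0.0, low_quality_fraction=0.0,
            gal4_fraction=0.0, subtelomere_end_width=1, seed=31,
        )
        truth = plant_truth(cfg)
        f1, _ = simulate_fragments(cfg, truth, ConditionParams(), seed=1)
        f2, _ = simulate_fragments(cfg, truth, ConditionParams(), seed=2)
        h1 = call_hotspots(f1, cfg.chrom_lengths)
        h2 = call_hotspots(f2, cfg.chrom_lengths)
        assert strength_correlation(h1, h2) >= 0.9

    def test_too_few_pairs_rejected(self):
        a = hs_table([10_000])
        b = hs_table([10_000])
        with pytest.raises(UndefinedResultError):
            strength_correlation(a, b)


class TestMotifCenterProfile:
    def test_sites_at_centers_peak_centrally(self):
        centers = np.arange(30) * 20_000 + 10_000
        hs = hs_table(centers)
        sites = pd.DataFrame({
            "chrom": "chr1", "start": centers - 8, "end": centers + 9,
        })
        prof = motif_center_profile(hs, sites)
        # all 17 planted bp land in the central bins
        assert prof["coverage"].sum() == pytest.approx(17.0)
        central = prof.loc[prof["offset"].abs() <= 50, "coverage"].sum()
        assert central == pytest.approx(17.0)
        peak_offset = prof.loc[prof["coverage"].idxmax(), "offset"]
        assert abs(peak_offset) <= 50

    def test_no_sites_all_zero(self):
        hs = hs_table([10_000])
        prof = motif_center_profile(hs, pd.DataFrame({"chrom": [], "start": [], "end": []}))
        assert (prof["coverage"] == 0).all()

    def test_uniform_random_sites_flat(self, rng):
        """Sites placed uniformly at random show no central enrichment."""
        centers = np.arange(200) * 50_000 + 25_000
        hs = hs_table(centers)
        for seed in range(5):
            r = np.random.default_rng(seed)
            starts = r.integers(0, 10_000_000, 3_000)
            sites = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 17})
            prof = motif_center_profile(hs, sites)
            mean = prof["coverage"].mean()
            assert prof["coverage"].max() < mean * 3 + 0.5
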