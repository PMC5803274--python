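"""Trimming, classification, counting, coverage and the NB test."""

import numpy as np
import pandas as pd
import pytest

from dsbrna import smallrna, synthdata
from dsbrna.sites import WindowSpec, site_at
from dsbrna.smallrna import (CLASS_HIERARCHY, DEFAULT_ADAPTER, CountMatrix,
                             SmallRead, classify_reads, coverage_profile,
                             nb_differential_test, region_counts, size_factors,
                             size_filter, trim_read, trim_reads, volcano_table)


class TestTrim:
    def test_constructed_read_inverts_to_insert(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        insert = "".join(rng.choice(bases, 21))
        raw = "".join(rng.choice(bases, 4)) + insert + \
            "".join(rng.choice(bases, 4)) + DEFAULT_ADAPTER
        assert trim_read(raw) == insert

    def test_no_adapter_is_discarded(self):
        assert trim_read("ACGT" * 10) is None

    def test_adapter_only_read_is_discarded(self):
        assert trim_read("ACGT" + DEFAULT_ADAPTER) is None

    def test_adapter_prefix_at_read_end_accepted(self):
        insert = "ACGTACGTACGTACGTACGTA"  # 21 nt
        raw = "AAAA" + insert + "TTTT" + DEFAULT_ADAPTER[:12]
        assert trim_read(raw) == insert

    def test_short_adapter_prefix_not_accepted(self):
        insert = "ACGTACGTACGTACGTACGTA"
        raw = "AAAA" + insert + "TTTT" + DEFAULT_ADAPTER[:6]
        assert trim_read(raw) is None

    def test_minimum_insert_enforced(self):
        # 14-nt insert after 4N removal -> below the 15-nt floor
        raw = "AAAA" + "ACGTACGTACGTAC" + "TTTT" + DEFAULT_ADAPTER
        assert trim_read(raw) is None

    def test_batch_tallies_discards(self):
        good = "AAAA" + "ACGTACGTACGTACGTACGTA" + "TTTT" + DEFAULT_ADAPTER
        kept, tally = trim_reads([good, "ACGTACGT"])
        assert tally == {"kept": 1, "discarded": 1}
        assert len(kept) == 1

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            trim_read("")


def brute_force_classify(read, annotations):
    for cls in CLASS_HIERARCHY:
        for chrom, s, e in annotations.get(cls, ()):
            if chrom == read.chrom and read.start < e and read.end > s:
                return cls
    return "residual"


class TestClassify:
    def test_hierarchy_mirna_beats_trna(self):
        read = SmallRead("c", 100, 122, "+")
        ann = {"tRNA": [("c", 90, 130)], "miRNA": [("c", 110, 140)]}
        (out,) = classify_reads([read], ann)
        assert out.annotation_class == "miRNA"

    def test_no_overlap_is_residual(self):
        (out,) = classify_reads([SmallRead("c", 0, 21, "+")],
                                {"miRNA": [("c", 500, 600)]})
        assert out.annotation_class == "residual"

    def test_unknown_class_name_rejected(self):
        with pytest.raises(ValueError, match="unknown annotation class"):
            classify_reads([], {"piRNA": [("c", 0, 10)]})

    def test_random_reads_match_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        ann = {
            cls: [("c", int(p), int(p) + int(rng.integers(50, 300)))
                  for p in rng.integers(0, 50_000, size=8)]
            for cls in CLASS_HIERARCHY
        }
        reads = [SmallRead("c", int(p), int(p) + int(rng.integers(18, 30)),
                           "+")
                 for p in rng.integers(0, 50_000, size=500)]
        got = [r.annotation_class for r in classify_reads(reads, ann)]
        assert got == [brute_force_classify(r, ann) for r in reads]


class TestSizeFilter:
    @pytest.mark.parametrize("length,size_class,kept", [
        (21, "21-23", True), (20, "21-23", False), (20, "19-20", True),
        (24, "24-26", True), (27, "24-26", False),
    ])
    def test_closed_range_membership(self, length, size_class, kept):
        reads = [SmallRead("c", 0, length, "+")]
        assert (len(size_filter(reads, size_class)) == 1) is kept

    def test_counts_match_length_histogram(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(15, 35, size=100)
        reads = [SmallRead("c", 0, int(n), "+") for n in lengths]
        for name, (lo, hi) in smallrna.SIZE_CLASSES.items():
            expected = int(np.sum((lengths >= lo) & (lengths <= hi)))
            assert len(size_filter(reads, name)) == expected

    def test_empty_input(self):
        assert size_filter([], "21-23") == []


class TestRegionCounts:
    def _site(self):
        return site_at("c", 9_996, site_id="s0")  # anchor 10 000

    def test_read_inside_window_counted(self):
        cm = region_counts({"a": [SmallRead("c", 10_100, 10_121, "+")]},
                           [self._site()])
        assert cm.counts.loc["s0", "a"] == 1

    def test_single_bp_edge_overlap_counted(self):
        # window is [5000, 15000); read [4980, 5001) overlaps by 1 bp
        cm = region_counts({"a": [SmallRead("c", 4_980, 5_001, "+")]},
                           [self._site()])
        assert cm.counts.loc["s0", "a"] == 1
        cm2 = region_counts({"a": [SmallRead("c", 4_979, 5_000, "+")]},
                            [self._site()])
        assert cm2.counts.loc["s0", "a"] == 0

    def test_containment_mode_excludes_edge_reads(self):
        cm = region_counts({"a": [SmallRead("c", 4_980, 5_001, "+")]},
                           [self._site()], containment=True)
        assert cm.counts.loc["s0", "a"] == 0

    def test_read_in_two_windows_counts_once_per_site(self):
        s1 = site_at("c", 9_996, site_id="s1")
        s2 = site_at("c", 10_996, site_id="s2")
        cm = region_counts({"a": [SmallRead("c", 10_400, 10_421, "+")]},
                           [s1, s2])
        assert cm.counts["a"].tolist() == [1, 1]

    def test_no_reads_gives_zero_matrix(self):
        cm = region_counts({"a": []}, [self._site()], library_sizes={"a": 1})
        assert (cm.counts.to_numpy() == 0).all()

    def test_oracle_equivalence_random_instance(self):
        rng = np.random.default_rng(9)
        sites_ = [site_at("c", int(p), site_id=f"s{i}")
                  for i, p in enumerate(rng.integers(6_000, 90_000, size=5))]
        reads = [SmallRead("c", int(p), int(p) + int(rng.integers(18, 30)),
                           "+")
                 for p in rng.integers(0, 100_000, size=1_000)]
        cm = region_counts({"a": reads}, sites_)
        for site in sites_:
            lo, hi = site.cut_anchor - 5_000, site.cut_anchor + 5_000
            expected = sum(r.start < hi and r.end > lo for r in reads)
            assert cm.counts.loc[site.name, "a"] == expected


class TestCoverageProfile:
    def test_single_plus_read_sums_to_its_length(self):
        site = site_at("c", 9_996, site_id="s0")
        spec = WindowSpec(half_width=100, bin_size=10)
        reads = [SmallRead("c", 9_950, 9_971, "+")]
        prof = coverage_profile(reads, [site], spec, library_size=10**6)
        assert prof.per_site.to_numpy().sum() == pytest.approx(21.0)

    def test_minus_strand_flips_sign(self):
        site = site_at("c", 9_996, site_id="s0")
        spec = WindowSpec(half_width=100, bin_size=10)
        reads = [SmallRead("c", 9_950, 9_971, "-")]
        prof = coverage_profile(reads, [site], spec, library_size=10**6)
        assert prof.per_site.to_numpy().sum() == pytest.approx(-21.0)

    def test_no_reads_all_zero(self):
        prof = coverage_profile([], [site_at("c", 9_996)],
                                WindowSpec(100, 10), library_size=10)
        assert not prof.mean.any()

    def test_library_size_must_be_positive(self):
        with pytest.raises(ValueError):
            coverage_profile([], [site_at("c", 9_996)], WindowSpec(100, 10),
                             library_size=0)

    def test_per_base_oracle_equivalence(self):
        rng = np.random.default_rng(11)
        site = site_at("c", 5_000, site_id="s0")
        spec = WindowSpec(half_width=200, bin_size=10)
        reads = [SmallRead("c", int(p), int(p) + int(rng.integers(18, 30)),
                           "+" if rng.random() < 0.5 else "-")
                 for p in rng.integers(4_700, 5_400, size=200)]
        prof = coverage_profile(reads, [site], spec, library_size=10**6)
        anchor = site.cut_anchor
        expected = np.zeros(spec.n_bins)
        for b, off in enumerate(range(-200, 200, 10)):
            bs, be = anchor + off, anchor + off + 10
            for r in reads:
                ov = max(0, min(r.end, be) - max(r.start, bs))
                expected[b] += ov if r.strand == "+" else -ov
        np.testing.assert_allclose(prof.per_site.to_numpy()[0], expected)

    def test_signed_sum_bounded_by_read_bases(self):
        rng = np.random.default_rng(13)
        site = site_at("c", 5_000, site_id="s0")
        spec = WindowSpec(half_width=200, bin_size=10)
        # single-strand fixture: no plus/minus cancellation possible
        reads = [SmallRead("c", int(p), int(p) + 21, "+")
                 for p in rng.integers(4_810, 5_170, size=50)]
        prof = coverage_profile(reads, [site], spec, library_size=10**6)
        assert np.abs(prof.per_site.to_numpy()).sum() == pytest.approx(
            sum(r.length for r in reads))


def _matrix(values, samples):
    df = pd.DataFrame(np.asarray(values, dtype=np.int64),
                      index=[f"s{i}" for i in range(len(values))],
                      columns=samples)
    return CountMatrix(counts=df, library_sizes=df.sum(axis=0) * 10 + 100)


class TestNBDifferentialTest:
    def test_identical_groups_give_zero_fold_change(self):
        cm = _matrix([[10, 12, 10, 12], [50, 55, 50, 55]],
                     ["c1", "c2", "d1", "d2"])
        res = nb_differential_test(cm, ["c1", "c2"], ["d1", "d2"])
        for r in res:
            assert r.log2_fold_change == pytest.approx(0.0)

    def test_all_zero_site_flagged(self):
        cm = _matrix([[0, 0, 0, 0], [50, 55, 52, 49]],
                     ["c1", "c2", "d1", "d2"])
        res = nb_differential_test(cm, ["c1", "c2"], ["d1", "d2"])
        assert res[0].all_zero and res[0].p_unadjusted == 1.0
        assert res[0].log2_fold_change == 0.0
        assert not res[1].all_zero

    def test_requires_two_samples_per_group(self):
        cm = _matrix([[5, 6, 7]], ["c1", "d1", "d2"])
        with pytest.raises(ValueError):
            nb_differential_test(cm, ["c1"], ["d1", "d2"])

    def test_size_factors_scale_invariance(self):
        """Doubling one sample's depth does not shift fold changes."""
        rng = np.random.default_rng(2)
        base = rng.poisson(100, size=(50, 4))
        scaled = base.copy()
        scaled[:, 0] = rng.poisson(base[:, 0] * 2)
        samples = ["c1", "c2", "d1", "d2"]
        res_a = nb_differential_test(_matrix(base, samples), samples[:2],
                                     samples[2:])
        res_b = nb_differential_test(_matrix(scaled, samples), samples[:2],
                                     samples[2:])
        fc_a = np.array([r.log2_fold_change for r in res_a])
        fc_b = np.array([r.log2_fold_change for r in res_b])
        assert np.abs(fc_a - fc_b).mean() < 0.1

    def test_null_rejection_rate_near_nominal(self):
        cm, ctrl, dmg = synthdata.simulate_region_counts(
            n_sites=200, mu=50.0, alpha=0.05, n_control=4, n_damage=4,
            seed=17)
        res = nb_differential_test(cm, ctrl, dmg)
        rate = np.mean([r.p_unadjusted < 0.05 for r in res])
        # 0.05 +/- 3 binomial sigmas at n=200
        assert 0.05 - 0.047 <= rate <= 0.05 + 0.047

    def test_planted_shift_ranks_first(self):
        cm, ctrl, dmg = synthdata.simulate_region_counts(
            n_sites=200, mu=50.0, alpha=0.05, planted_site=7,
            planted_fold=8.0, seed=23)
        res = nb_differential_test(cm, ctrl, dmg)
        best = min(res, key=lambda r: r.p_unadjusted)
        assert best.site_id == "site_7"
        assert best.log2_fold_change > 2.0

    def test_median_of_ratios_requires_informative_sites(self):
        df = pd.DataFrame(np.zeros((3, 4), dtype=np.int64),
                          columns=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            size_factors(df)


class TestVolcano:
    def test_axis_mapping(self):
        res = [
            smallrna.DifferentialResult("a", 1.5, 1.0, 1.0),
            smallrna.DifferentialResult("b", -0.5, 0.01, 0.1),
        ]
        table = volcano_table(res)
        assert len(table) == 2
        assert table.loc[0, "neg_log10_p"] == pytest.approx(0.0)
        assert table.loc[1, "neg_log10_p"] == pytest.approx(2.0)


class TestReadLevelPipeline:
    """End-to-end small-RNA stage on simulated libraries."""

    def _counts(self, genome, truth, fold, seed):
        # count over every motif window: the uncut majority anchors the
        # median-of-ratios normalisation, as in the full-genome analysis
        sites_ = truth.sites
        samples = {}
        libs = {}
        for j in range(2):
            libs[f"t0_r{j}"] = 1.0
        for j in range(4):
            libs[f"dmg_r{j}"] = fold
        reads_by_sample = {}
        library_sizes = {}
        for k, (name, f) in enumerate(libs.items()):
            lib = synthdata.simulate_smallrna_library(
                truth, genome, n_reads=4_000, planted_dsb_fold=f,
                seed=seed * 100 + k)
            classified = classify_reads(lib.reads, truth.annotations)
            residual = [r for r in classified
                        if r.annotation_class == "residual"]
            filtered = size_filter(residual, "21-23")
            reads_by_sample[name] = filtered
            library_sizes[name] = len(residual)
        cm = region_counts(reads_by_sample, sites_,
                           library_sizes=library_sizes)
        return cm, [s for s in libs if s.startswith("t0")], \
            [s for s in libs if s.startswith("dmg")]

    def test_null_libraries_yield_no_bh_hits(self, small_sim):
        genome, truth = small_sim
        clean = 0
        for seed in range(5):
            cm, ctrl, dmg = self._counts(genome, truth, 1.0, seed)
            res = nb_differential_test(cm, ctrl, dmg)
            clean += not any(r.p_bh < 0.05 for r in res)
        assert clean >= 4

    def test_planted_species_detected_at_cut_sites(self, small_sim):
        genome, truth = small_sim
        cm, ctrl, dmg = self._counts(genome, truth, 8.0, seed=50)
        res = nb_differential_test(cm, ctrl, dmg)
        cut_ids = {s.name for s in truth.cut_sites}
        cut_fc = [r.log2_fold_change for r in res if r.site_id in cut_ids]
        uncut_fc = [r.log2_fold_change for r in res
                    if r.site_id not in cut_ids]
        assert min(cut_fc) > max(uncut_fc)
        assert np.mean(cut_fc) > 0.3
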