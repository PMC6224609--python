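"""Crosslink extraction, junction profiles, LOESS smoothing, peak comparison."""

import numpy as np
import pandas as pd
import pytest

from rsjunction.alignio import ReadAlignment
from rsjunction.iclip import (JunctionSite, compare_peak, coverage_normalize,
                              extract_crosslinks, junction_profile,
                              read_crosslink_bed, smooth_profile,
                              write_crosslink_bed)
from rsjunction.smoothing import loess
from rsjunction import synth


def read(name, start, end, strand="+", chrom="c", blocks=None):
    blocks = blocks or ((start, end),)
    return ReadAlignment(name, chrom, strand, tuple(blocks))


class TestExtractCrosslinks:
    def test_pcr_duplicates_collapsed(self):
        reads = [read("r1:AACC", 100, 130), read("r2:AACC", 100, 130)]
        frame = extract_crosslinks(reads, "s")
        assert len(frame) == 1

    def test_distinct_umis_kept(self):
        reads = [read("r1:AACC", 100, 130), read("r2:GGTT", 100, 130)]
        assert len(extract_crosslinks(reads, "s")) == 2

    def test_planted_duplication_rate_collapses_to_manifest(self):
        """30% duplicated reads collapse back to the unique-cDNA count."""
        rng = np.random.default_rng(6)
        unique = [read(f"r{i}:UMI{i}", int(p), int(p) + 30)
                  for i, p in enumerate(rng.integers(0, 10000, 200))]
        dupes = [ReadAlignment(f"d{i}:UMI{i}", "c", "+", unique[i].blocks)
                 for i in range(60)]
        frame = extract_crosslinks(unique + dupes, "s")
        assert len(frame) == len({(r.name.split(":")[1], r.blocks[0][0])
                                  for r in unique})

    def test_truncation_offset_and_minus_strand(self):
        plus = extract_crosslinks([read("r:U1", 100, 130)], "s")
        assert plus["pos"].iloc[0] == 99  # one nt upstream of the read start
        minus = extract_crosslinks([read("r:U1", 100, 130, strand="-")], "s")
        assert minus["pos"].iloc[0] == 130  # 5' end is the right edge
        zero = extract_crosslinks([read("r:U1", 100, 130)], "s", offset=0)
        assert zero["pos"].iloc[0] == 100

    def test_gapped_flag_follows_blocks(self):
        spliced = read("r:U1", 100, 220, blocks=((100, 130), (200, 220)))
        frame = extract_crosslinks([spliced, read("q:U2", 10, 40)], "s")
        assert list(frame["gapped"]) == [True, False]

    def test_missing_umi_warned_or_strict(self, caplog):
        with caplog.at_level("WARNING"):
            frame = extract_crosslinks([read("noumi", 1, 30)], "s")
        assert len(frame) == 1 and "UMI" in caplog.text
        with pytest.raises(ValueError):
            extract_crosslinks([read("noumi", 1, 30)], "s", strict=True)

    def test_bed_round_trip(self, tmp_path):
        frame = extract_crosslinks(
            [read("a:U1", 50, 80), read("b:U2", 50, 80), read("c:U3", 99, 120)],
            "s")
        path = tmp_path / "x.bed"
        write_crosslink_bed(frame, path)
        back = read_crosslink_bed(path, "s")
        assert sorted(back["pos"]) == sorted(frame["pos"])


def peak_truth(seed=61, enrichment=5.0, n_crosslinks=20000, n_replicates=2):
    _, _, truth = synth.make_genome_annotation(n_genes=20, rs_fraction=0.4,
                                               seed=seed)
    libs, sites = synth.simulate_iclip(truth, n_replicates=n_replicates,
                                       n_crosslinks=n_crosslinks,
                                       enrichment=enrichment, seed=seed + 1)
    return truth, libs, sites


class TestJunctionProfile:
    def test_planted_peak_in_rs_group_only(self):
        _, libs, sites = peak_truth()
        reps = {f"{c}_{r}": df for (c, r), df in libs.items() if c == "control"}
        profiles = junction_profile(reps, sites, gapped=True)
        for p in profiles:
            peak_at = p.distances[np.argmax(p.frequency)]
            if p.group == "RS":
                assert abs(peak_at - (-13)) <= 1
            else:
                # background only: no position dominates
                assert p.frequency.max() < 3 * p.frequency.mean()

    def test_doubling_a_library_leaves_profile_unchanged(self):
        _, libs, sites = peak_truth(n_replicates=1)
        df = libs[("control", 0)]
        single = junction_profile({"a": df}, sites, gapped=True)
        doubled = junction_profile({"a": pd.concat([df, df])}, sites,
                                   gapped=True)
        for p1, p2 in zip(single, doubled):
            assert np.allclose(p1.frequency, p2.frequency)

    def test_normalizer_counts_junctions_and_library(self):
        sites = [JunctionSite("c", "+", 1000, "G")]
        df = pd.DataFrame({"sample_id": "s", "chrom": "c", "strand": "+",
                           "pos": [987] * 10, "gapped": True})
        (p,) = junction_profile({"s": df}, sites, gapped=True)
        assert p.frequency[p.distances == -13][0] == 10 / (1 * 10)

    def test_single_read_junctions_excluded(self):
        sites = [JunctionSite("c", "+", 1000, "G", "j1"),
                 JunctionSite("c", "+", 5000, "G", "j2")]
        df = pd.DataFrame({"sample_id": "s", "chrom": "c", "strand": "+",
                           "pos": [990, 991, 4990], "gapped": True})
        (p,) = junction_profile({"s": df}, sites, gapped=True)
        assert p.n_junctions == 1  # the single-read junction is dropped
        (p_all,) = junction_profile({"s": df}, sites, gapped=True,
                                    single_read_filter=False)
        assert p_all.n_junctions == 2

    def test_filter_never_removes_two_read_junction(self):
        sites = [JunctionSite("c", "+", 1000, "G", "j1")]
        df1 = pd.DataFrame({"sample_id": "a", "chrom": "c", "strand": "+",
                            "pos": [990], "gapped": True})
        df2 = pd.DataFrame({"sample_id": "b", "chrom": "c", "strand": "+",
                            "pos": [991], "gapped": True})
        (pa, pb) = junction_profile({"a": df1, "b": df2}, sites, gapped=True)
        assert pa.n_junctions == 1  # one read per sample, two in total

    def test_gapped_filter_selects_read_class(self):
        sites = [JunctionSite("c", "+", 1000, "G")]
        df = pd.DataFrame({"sample_id": "s", "chrom": "c", "strand": "+",
                           "pos": [990, 991, 992], "gapped": [True, True, False]})
        (p,) = junction_profile({"s": df}, sites, gapped=True)
        assert p.frequency.sum() * p.n_junctions * p.library_total == 2


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        x = np.arange(-50, 1, dtype=float)
        assert np.allclose(loess(x, np.full(51, 0.4), span=0.2, degree=2), 0.4)

    def test_step_matches_reference_local_regression(self):
        """Degree-1 LOESS equals the lowess oracle at 11 grid points."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(7)
        x = np.arange(51, dtype=float)
        y = np.where(x < 25, 1.0, 3.0) + rng.normal(0, 0.05, 51)
        ref = lowess(y, x, frac=0.3, it=0, delta=0.0, return_sorted=False)
        mine = loess(x, y, span=0.3, degree=1)
        grid = np.linspace(0, 50, 11).astype(int)
        assert np.allclose(mine[grid], ref[grid], atol=1e-9)

    def test_step_smoothed_monotone(self):
        x = np.arange(60, dtype=float)
        y = np.where(x < 30, 0.0, 1.0)
        sm = loess(x, y, span=0.3, degree=1)
        assert np.all(np.diff(sm) >= -1e-9)

    def test_ci_excludes_baseline_at_planted_peak(self):
        _, libs, sites = peak_truth(n_replicates=4)
        reps = {f"{c}_{r}": df for (c, r), df in libs.items() if c == "kd"}
        profiles = [p for p in junction_profile(reps, sites, gapped=True)
                    if p.group == "RS"]
        frame = smooth_profile(profiles, span=0.2)
        at_peak = frame[frame["distance"] == -13].iloc[0]
        baseline = frame[frame["distance"] < -30]["mean"].mean()
        assert at_peak["ci_low"] > baseline

    def test_single_replicate_has_no_ci(self):
        _, libs, sites = peak_truth(n_replicates=1)
        profiles = [p for p in junction_profile(
            {"a": libs[("control", 0)]}, sites, gapped=True) if p.group == "RS"]
        frame = smooth_profile(profiles)
        assert frame["ci_low"].isna().all()


class TestComparePeak:
    def test_identical_replicates_give_zero_t(self):
        _, libs, sites = peak_truth(n_replicates=2)
        profiles = [p for p in junction_profile(
            {f"c_{r}": df for (c, r), df in libs.items() if c == "control"},
            sites, gapped=True) if p.group == "RS"]
        t, p = compare_peak(profiles, profiles)
        assert t == 0.0

    def test_label_swap_negates_t(self):
        _, libs, sites = peak_truth(n_replicates=3)
        ctrl = [p for p in junction_profile(
            {f"c_{r}": df for (c, r), df in libs.items() if c == "control"},
            sites, gapped=True) if p.group == "RS"]
        kd = [p for p in junction_profile(
            {f"k_{r}": df for (c, r), df in libs.items() if c == "kd"},
            sites, gapped=True) if p.group == "RS"]
        t_ab, p_ab = compare_peak(kd, ctrl)
        t_ba, p_ba = compare_peak(ctrl, kd)
        assert t_ab == pytest.approx(-t_ba) and p_ab == pytest.approx(p_ba)
        assert t_ab > 0 and p_ab < 0.05  # 5x enrichment is detected

    def test_requires_two_replicates(self):
        _, libs, sites = peak_truth(n_replicates=1)
        profiles = [p for p in junction_profile(
            {"a": libs[("control", 0)]}, sites, gapped=True)
            if p.group == "RS"]
        with pytest.raises(ValueError):
            compare_peak(profiles, profiles)


class TestCoverageNormalize:
    def test_equal_reference_sums_split_evenly(self):
        cov = {"a": np.ones(10), "b": np.ones(10)}
        ref = {"a": np.full(10, 2.0), "b": np.full(10, 2.0)}
        normalized, factors, dropped = coverage_normalize(cov, ref)
        assert factors == {"a": 0.5, "b": 0.5} and dropped == []
        assert np.allclose(normalized["a"], 2.0)

    def test_single_group_is_identity(self):
        cov = {"a": np.arange(5.0)}
        normalized, factors, _ = coverage_normalize(cov, {"a": np.ones(5)})
        assert factors == {"a": 1.0}
        assert np.allclose(normalized["a"], cov["a"])

    def test_factors_sum_to_one(self):
        rng = np.random.default_rng(8)
        cov = {g: rng.uniform(0, 1, 20) for g in "abcd"}
        ref = {g: rng.uniform(0.1, 1, 20) for g in "abcd"}
        _, factors, _ = coverage_normalize(cov, ref)
        assert sum(factors.values()) == pytest.approx(1.0)

    def test_zero_reference_group_dropped(self):
        cov = {"a": np.ones(5), "b": np.ones(5)}
        ref = {"a": np.ones(5), "b": np.zeros(5)}
        normalized, factors, dropped = coverage_normalize(cov, ref)
        assert dropped == ["b"] and "b" not in normalized
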