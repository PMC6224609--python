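"""Donor scorers, threshold calibration, RS classification, microexon scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rsjunction as rj
from rsjunction.scoring import (KmerPrevalenceScorer, MaxEntDonorScorer,
                                ModelTableError, PwmScorer,
                                SpliceSiteWindow, build_kmer_prevalence_scorer,
                                calibrate_threshold, classify_exons,
                                default_donor_pwm, scan_internal_5ss,
                                score_window, species_rs_proportion,
                                _ME_BGD, _ME_CONS1, _ME_CONS2)

BASES = "ACGT"


def random_9mers(n, seed):
    rng = np.random.default_rng(seed)
    return ["".join(BASES[i] for i in rng.integers(0, 4, 9)) for _ in range(n)]


def brute_force_maxent(seq, table):
    """Independent re-derivation of the maximum-entropy donor score."""
    rest = seq[:3] + seq[5:]
    idx = 0
    for b in rest:
        idx = idx * 4 + BASES.index(b)
    consensus = (_ME_CONS1[seq[3]] * _ME_CONS2[seq[4]]) / (
        _ME_BGD[seq[3]] * _ME_BGD[seq[4]])
    return math.log2(consensus * table[idx])


@pytest.fixture(scope="module")
def maxent_table(tmp_path_factory):
    """A synthetic model table written in the plain float-list format."""
    rng = np.random.default_rng(42)
    table = rng.uniform(0.01, 2.0, size=4 ** 7)
    path = tmp_path_factory.mktemp("maxent") / "me5ss.txt"
    path.write_text("\n".join(str(float(v)) for v in table) + "\n")
    return table, str(path)


class TestMaxEntScorer:
    def test_bit_for_bit_against_brute_force(self, maxent_table):
        """Loaded-table scores equal an independent in-test re-derivation."""
        table, path = maxent_table
        scorer = MaxEntDonorScorer.from_table(path)
        for seq in random_9mers(1000, seed=7):
            assert scorer.score(seq) == brute_force_maxent(seq, table)

    def test_keyed_format_equivalent(self, maxent_table, tmp_path):
        table, path = maxent_table
        plain = MaxEntDonorScorer.from_table(path)
        lines = []
        for i in range(4 ** 7):
            kmer = ""
            x = i
            for _ in range(7):
                kmer = BASES[x % 4] + kmer
                x //= 4
            lines.append(f"{kmer}\t{float(table[i])}")
        keyed = tmp_path / "keyed.txt"
        keyed.write_text("\n".join(lines) + "\n")
        scorer = MaxEntDonorScorer.from_table(str(keyed))
        for seq in random_9mers(50, seed=8):
            assert scorer.score(seq) == plain.score(seq)

    def test_gt_consensus_beats_mutant(self, maxent_table):
        """+1 G>C substitution strictly lowers the score, table-independent."""
        _, path = maxent_table
        scorer = MaxEntDonorScorer.from_table(path)
        assert scorer.score("CAGCTAAGT") < scorer.score("CAGGTAAGT")

    def test_n_is_unscorable(self, maxent_table):
        _, path = maxent_table
        scorer = MaxEntDonorScorer.from_table(path)
        assert score_window(scorer, SpliceSiteWindow("CANGTAAGT")) is None

    def test_missing_or_truncated_table(self, tmp_path):
        with pytest.raises(ModelTableError):
            MaxEntDonorScorer.from_table(str(tmp_path / "absent.txt"))
        bad = tmp_path / "short.txt"
        bad.write_text("1.0\n2.0\n")
        with pytest.raises(ModelTableError):
            MaxEntDonorScorer.from_table(str(bad))


class TestPwmScorer:
    def test_consensus_dominates_random_panel(self, pwm):
        """CAGGTAAGT is the PWM argmax, so it tops any random 9-mer panel."""
        panel = random_9mers(1000, seed=3) + ["CAGGTAAGT"]
        scores = [pwm.score(s) for s in panel]
        assert max(scores) == pwm.score("CAGGTAAGT")

    def test_determinism(self, pwm):
        assert pwm.score("ACGTACGTA") == pwm.score("ACGTACGTA")


class TestCalibrateThreshold:
    def test_integer_grid(self):
        """On scores 1..100 at 90% detection the threshold is 10 and exactly
        91 scores lie at or above it."""
        scores = np.arange(1, 101, dtype=float)
        t = calibrate_threshold(scores, 0.90)
        assert t == 10
        assert int((scores >= t).sum()) == 91

    def test_all_equal_scores(self):
        assert calibrate_threshold([5.0] * 20, 0.9) == 5.0

    def test_only_positive_scores_used(self):
        t = calibrate_threshold(list(range(-50, 0)) + list(range(1, 101)), 0.90)
        assert t == 10

    def test_monotone_in_detect_fraction(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0.5, 12, 500)
        t75, t90, t95 = (calibrate_threshold(scores, f)
                         for f in (0.75, 0.90, 0.95))
        assert t95 <= t90 <= t75

    def test_guarantee_holds_exactly(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0.1, 10, 137)
        for f in (0.75, 0.9, 0.95):
            t = calibrate_threshold(scores, f)
            assert (scores >= t).mean() >= f

    def test_empty_positive_set_errors(self):
        with pytest.raises(ValueError):
            calibrate_threshold([-1.0, -2.0], 0.9)


class _DictScorer:
    kind = "dict"

    def __init__(self, table):
        self.table = table

    def score(self, seq):
        return self.table.get(seq, 0.0)


class TestClassifyExons:
    def test_strict_inequality_at_threshold(self, mini_locus):
        genome, trio = mini_locus
        window = rj.junction_9mer(genome, trio)
        canon = "CAGGTGAGT"
        for score, expected in [(5.53, "RS"), (5.52, "nonRS"), (-10.0, "nonRS")]:
            scorer = _DictScorer({window: score, canon: 0.0})
            rec = classify_exons([trio], genome, scorer, threshold=5.52)[0]
            assert rec.label == expected
            assert not rec.unscorable

    def test_unscorable_window_flagged_nonrs(self, mini_locus):
        from rsjunction.genome import GenomeSequence
        from conftest import MINI_SEQ

        _, trio = mini_locus
        seq = MINI_SEQ[:70] + "N" + MINI_SEQ[71:]  # N at A's first base
        genome = GenomeSequence({"chrM": seq})
        rec = classify_exons([trio], genome, default_donor_pwm(), 0.0)[0]
        assert rec.label == "nonRS" and rec.unscorable

    def test_planted_labels_recovered(self, small_dataset, trios, pwm,
                                      calibrated_threshold):
        """No false negatives or positives on planted strong donors."""
        genome, _, truth = small_dataset
        records = classify_exons(trios, genome, pwm, calibrated_threshold)
        predicted = {r.exon_id for r in records if r.label == "RS"}
        assert predicted == set(truth.rs_exons())


class TestScanInternal5ss:
    def test_exhaustive_window_oracle(self, pwm):
        """Candidates equal a brute-force scan over every eligible window."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(BASES[i] for i in rng.integers(0, 4, 40))
            found = scan_internal_5ss(seq, pwm, min_score=2.0, host_exon_id="h")
            expected = [(k, pwm.score(seq[k:k + 9])) for k in range(16)
                        if pwm.score(seq[k:k + 9]) >= 2.0]
            assert [(c.offset, c.score) for c in found] == expected

    def test_planted_offset_six_microexon(self, pwm):
        """A donor shifted 6 nt into the exon implies a 6-nt microexon."""
        host = "GCACAG" + "GTAAGT" + "C" * 20
        found = scan_internal_5ss("CAG" + host, pwm, min_score=5.52)
        offsets = [c.offset for c in found]
        assert offsets == [6]
        assert found[0].microexon_length == 6

    def test_offset_zero_is_rs_5ss(self, pwm):
        host = "GTAAGT" + "C" * 20
        found = scan_internal_5ss("CAG" + host, pwm, min_score=5.52)
        assert [c.offset for c in found] == [0]

    def test_short_host_yields_nothing(self, pwm):
        assert scan_internal_5ss("CAG" + "G" * 20, pwm, min_score=-99) == []

    def test_min_score_is_inclusive(self, pwm):
        host = "GTAAGT" + "C" * 20
        s = pwm.score("CAGGTAAGT")
        assert scan_internal_5ss("CAG" + host, pwm, min_score=s)


class TestKmerPrevalence:
    def test_membership_matches_brute_force_ranks(self):
        rng = np.random.default_rng(9)
        pool = random_9mers(40, seed=10)
        windows = [pool[i] for i in rng.integers(0, 40, size=2000)]
        scorer = build_kmer_prevalence_scorer(windows, top_k=10)
        from collections import Counter

        counts = Counter(windows)
        ranked = sorted(counts, key=lambda k: (-counts[k], k))[:10]
        assert scorer.members == frozenset(ranked)
        assert scorer.score(ranked[0]) == 1.0
        assert scorer.score("AAAAAAAAA") in (0.0, 1.0)

    def test_absent_window_scores_zero(self):
        scorer = KmerPrevalenceScorer(["CAGGTAAGT"])
        assert scorer.score("TTTTTTTTT") == 0.0
        assert scorer.score("CAGGTAAGT") == 1.0

    def test_fewer_than_top_k_keeps_all_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            scorer = build_kmer_prevalence_scorer(["CAGGTAAGT", "AAGGTAAGT"],
                                                  top_k=1000)
        assert len(scorer.members) == 2
        assert "top_k" in caplog.text


class TestSpeciesProportion:
    def test_recovers_planted_fraction_and_is_deterministic(self, small_dataset,
                                                            pwm):
        _, annotation, truth = small_dataset
        genome = small_dataset[0]
        a = species_rs_proportion(annotation, genome, pwm, 0.90)
        b = species_rs_proportion(annotation, genome, pwm, 0.90)
        assert a == b
        assert a.n_exons == len(truth.exons)
        assert a.n_rs == len(truth.rs_exons())
        assert a.proportion == a.n_rs / a.n_exons

    def test_rejecting_scorer_gives_zero(self, small_dataset):
        genome, annotation, _ = small_dataset

        class Negative:
            def score(self, seq):
                return 1e-6  # positive so calibration works, but below nothing

        # constant scores make every canonical donor equal; the threshold
        # equals the constant and the strict > rule classifies nothing
        summary = species_rs_proportion(annotation, genome, Negative(), 0.9)
        assert summary.n_rs == 0 and summary.proportion == 0.0


def test_rs_fraction_monotone_in_threshold():
    """The fraction of exons above a strict threshold never increases with it."""
    rng = np.random.default_rng(2)
    scores = rng.normal(0, 8, 500)
    fractions = [(scores > t).mean() for t in np.arange(-20, 9)]
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 100), min_size=10, max_size=200),
       st.floats(0.5, 0.99))
def test_calibration_detection_guarantee(scores, fraction):
    """At least the requested fraction of positive scores meet the threshold."""
    t = calibrate_threshold(scores, fraction)
    arr = np.asarray(scores)
    assert (arr[arr > 0] >= t).mean() >= fraction
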