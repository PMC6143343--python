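import numpy as np
import pytest
from scipy import stats

from iespipe.analyses import (
    EndMotifPWM,
    SizePeakSpec,
    compare_lengths,
    end_motif_pwm,
    excised_set_overlap,
    irs_histogram,
    mannwhitney_exact,
    pwm_from_intervals,
    size_peak_fractions,
    ta_positions,
    top_retained_lengths,
)
from iespipe.errors import PARTIAL_INTERNAL
from iespipe.retention import RetentionResult
from iespipe.simulate import SimConfig, generate_genomes, simulate_reads
from oracles import mannwhitney_enumerated


def _res(ies_id, irs):
    return RetentionResult(ies_id, irs, irs, irs)


class TestIrsHistogram:
    def test_all_zero_in_first_bin(self):
        counts, edges, undefined = irs_histogram([_res(f"i{k}", 0.0) for k in range(5)])
        assert counts[0] == 5 and counts[1:].sum() == 0
        assert undefined == 0

    def test_bin_edges_split_at_threshold(self):
        counts, _, _ = irs_histogram([_res("a", 0.024), _res("b", 0.026)])
        assert counts[0] == 1 and counts[1] == 1

    def test_undefined_reported_separately_and_conservation(self):
        results = [_res("a", 0.5), RetentionResult("b", None, None, None)]
        counts, _, undefined = irs_histogram(results)
        assert counts.sum() == 1 and undefined == 1

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([
            np.clip(rng.normal(0.05, 0.02, 300), 0, 1),
            np.clip(rng.normal(0.95, 0.02, 300), 0, 1),
        ])
        counts, edges, _ = irs_histogram([_res(str(i), float(v)) for i, v in enumerate(vals)])
        lows = counts[: len(counts) // 2].sum()
        highs = counts[len(counts) // 2 :].sum()
        assert lows == 300 and highs == 300
        # two local maxima near the planted modes
        assert counts[:8].max() > counts[10:30].max()
        assert counts[-8:].max() > counts[10:30].max()


class TestOverlap:
    def test_identical_sets(self):
        assert excised_set_overlap({"a", "b"}, {"a", "b"}) == (0, 2, 0, 1.0)

    def test_disjoint_sets(self):
        assert excised_set_overlap({"a"}, {"b"}) == (1, 0, 1, 0.0)

    def test_nested_sets(self):
        only_a, inter, only_b, frac = excised_set_overlap({"a", "b", "c"}, {"a", "b"})
        assert (only_a, inter, only_b) == (1, 2, 0)
        assert frac == 1.0


class TestCompareLengths:
    def test_identical_samples_p_one(self):
        med_a, med_b, _, p = compare_lengths([30, 40, 50], [30, 40, 50])
        assert med_a == med_b == 40
        assert p == pytest.approx(1.0)

    def test_shifted_samples_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(80, 10, 200)
        b = a - 30
        _, _, _, p = compare_lengths(a, b)
        assert p < 1e-3

    def test_single_observation_exact(self):
        # with n=1 vs n=1 both assignments are equally extreme: p = 1
        _, _, _, p = compare_lengths([10.0], [20.0])
        assert p == pytest.approx(mannwhitney_enumerated([10.0], [20.0]))
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_enumeration_matches_scipy_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 7)  # continuous: no ties
        u, p = mannwhitney_exact(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_exact_matches_independent_enumeration_with_ties(self):
        a = [26, 28, 28, 46]
        b = [28, 46, 56, 56]
        _, p = mannwhitney_exact(a, b)
        assert p == pytest.approx(mannwhitney_enumerated(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_lengths([], [1.0])


class TestSizePeaks:
    def test_all_in_first_window(self):
        df = size_peak_fractions([27, 27, 27])
        assert df.loc[df.peak == "26-28", "fraction"].item() == 1.0
        assert df.fraction.sum() == 1.0

    def test_empty_window_zero(self):
        df = size_peak_fractions([27])
        assert df.loc[df.peak == "75-77", "fraction"].item() == 0.0

    def test_reference_side_by_side(self):
        df = size_peak_fractions([76, 76], reference_lengths=[27, 76])
        row = df.loc[df.peak == "75-77"]
        assert row.fraction.item() == 1.0
        assert row.reference_fraction.item() == 0.5

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            SizePeakSpec([("a", 26, 30), ("b", 29, 35)]).validate()


@pytest.fixture(scope="module")
def genome_with_consensus():
    cfg = SimConfig(n_scaffolds=2, scaffold_len=30_000, n_ies=200, seed=23)
    return generate_genomes(cfg)


class TestEndMotifs:
    def test_ta_anchor_is_absolute(self, genome_with_consensus):
        germline, _, annotation = genome_with_consensus
        pwm = end_motif_pwm(annotation, germline)
        freqs = pwm.frequencies("both")
        assert freqs[0, 3] == 1.0  # T
        assert freqs[1, 0] == 1.0  # A
        assert pwm.n_boundaries["both"] == 2 * len(annotation)

    def test_degenerate_positions_respect_consensus(self, genome_with_consensus):
        germline, _, annotation = genome_with_consensus
        freqs = end_motif_pwm(annotation, germline).frequencies("both")
        acgt = "ACGT"
        # position 3 is Y (C/T), 4 is A, 5 is G, 6 is Y, 8 is R (A/G)
        assert freqs[2, acgt.index("A")] == 0.0 and freqs[2, acgt.index("G")] == 0.0
        assert freqs[3, acgt.index("A")] == 1.0
        assert freqs[4, acgt.index("G")] == 1.0
        assert freqs[5, acgt.index("C")] + freqs[5, acgt.index("T")] == 1.0
        assert freqs[7, acgt.index("C")] == 0.0 and freqs[7, acgt.index("T")] == 0.0

    def test_column_sums_constant(self, genome_with_consensus):
        germline, _, annotation = genome_with_consensus
        pwm = end_motif_pwm(annotation, germline)
        for side in ("left", "right", "both"):
            sums = pwm.counts[side].sum(axis=1)
            assert (sums == pwm.n_boundaries[side]).all()

    def test_alternative_boundaries_not_consensus(self):
        # planted alternative TAs at offset 12-13 sit in the random core:
        # beyond the TA the motif should be near uniform
        cfg = SimConfig(
            n_scaffolds=2, scaffold_len=35_000, n_ies=250, coverage=1,
            retention_prob=0.0, error_rate=1.0,
            error_class_mix={PARTIAL_INTERNAL: 1.0},
            shift_model={12: 0.5, 13: 0.5}, seed=29,
        )
        germline, somatic, annotation = generate_genomes(cfg)
        _, truth = simulate_reads(cfg, (germline, somatic), annotation)
        intervals = [(ev.scaffold, ev.start, ev.end) for ev in truth.planted_events]
        pwm = pwm_from_intervals(intervals, germline)
        # pick the octamer of the shifted (non-canonical) side only
        shifted = pwm.frequencies("left")
        # TA anchor still absolute on whichever side is non-canonical; at the
        # inner positions no base should dominate like the consensus does
        inner = np.vstack([pwm.frequencies(s)[2:, :] for s in ("left", "right")])
        assert inner.max() < 0.75


class TestTaPositions:
    def test_manual_offsets(self):
        germline = {"sc": "G" * 20 + "TATACGGGGCCCGGGCCCGGGGGGCC" + "TA" + "G" * 20}
        rec_ann = [pytest.importorskip("iespipe.annotation").IesRecord("sc", 20, 46, "i")]
        counts = ta_positions(rec_ann, germline, window=10)
        assert counts["left"][1] == 1  # TA at offset 2 (TATA start)
        assert counts["left"][0] == 0  # offset 1 is "AT"
        assert counts["left"][2:].sum() == 0

    def test_window_validation(self):
        germline = {"sc": "G" * 20 + "TACGCGATCGATCGGCTAGCTAGCAA" + "TA" + "G" * 20}
        from iespipe.annotation import IesRecord

        with pytest.raises(ValueError):
            ta_positions([IesRecord("sc", 20, 46, "i")], germline, window=40)

    def test_uniform_core_ta_frequency(self):
        # closed form: in a uniform ACGT core, P(TA at a given offset) = 1/16
        cfg = SimConfig(n_scaffolds=4, scaffold_len=30_000, n_ies=400, seed=31,
                        consensus_fidelity=1.0)
        germline, _, annotation = generate_genomes(cfg)
        counts = ta_positions(annotation, germline, window=20)
        # offsets 9..18 sit in the random core for most IESs (>= 26 bp)
        core = np.concatenate([counts["left"][8:18], counts["right"][8:18]])
        freq = core / len(annotation)
        assert abs(freq.mean() - 1 / 16) < 0.02


class TestTopRetained:
    def test_picks_highest_irs(self):
        from iespipe.annotation import IesRecord

        ann = [IesRecord("sc", 100 * i, 100 * i + 26 + i, f"I{i}") for i in range(4)]
        results = [_res(f"I{i}", irs) for i, irs in enumerate([0.1, 0.9, 0.5, None])]
        results[3] = RetentionResult("I3", None, None, None)
        lengths = top_retained_lengths(results, ann, 2)
        assert lengths == [27, 28]  # I1 (irs .9) then I2 (irs .5)
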