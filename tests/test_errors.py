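import numpy as np
import pytest

from iespipe.annotation import IesRecord
from iespipe.errors import (
    CORRECT,
    EXTERNAL,
    INTERNAL,
    OVERLAPPING,
    PARTIAL_EXTERNAL,
    PARTIAL_INTERNAL,
    UNMATCHED,
    ExcisionEvent,
    class_distribution,
    classify_event,
    collapse_events,
    de_novo_errors,
    error_prone_fraction,
    error_read_fraction,
    shift_spectrum,
    summarize,
)
from iespipe.mapper import JunctionEvidence, build_index, classify_reads
from iespipe.retention import RetentionResult
from iespipe.simulate import SimConfig, generate_genomes, simulate_reads
from oracles import brute_force_classify

ANN = [IesRecord("sc", 100, 160, "IES.00000")]


def _event(a, b, klass, lo, ro, reads=1, ies="IES.00000"):
    return ExcisionEvent("sc", a, b, reads, ies, klass, lo, ro)


class TestClassifyEvent:
    def test_correct(self):
        ies, klass, offsets, _ = classify_event(("sc", 100, 160), ANN)
        assert (ies, klass, offsets) == ("IES.00000", CORRECT, (0, 0))

    def test_partial_internal_right_shift(self):
        ies, klass, offsets, _ = classify_event(("sc", 100, 150), ANN)
        assert (klass, offsets) == (PARTIAL_INTERNAL, (0, -10))

    def test_partial_external(self):
        _, klass, offsets, _ = classify_event(("sc", 90, 160), ANN)
        assert (klass, offsets) == (PARTIAL_EXTERNAL, (-10, 0))

    def test_internal(self):
        _, klass, offsets, _ = classify_event(("sc", 110, 150), ANN)
        assert (klass, offsets) == (INTERNAL, (10, -10))

    def test_external_both_flanks(self):
        _, klass, offsets, _ = classify_event(("sc", 90, 170), ANN)
        assert (klass, offsets) == (EXTERNAL, (-10, 10))

    def test_overlapping(self):
        _, klass, _, _ = classify_event(("sc", 110, 170), ANN)
        assert klass == OVERLAPPING

    def test_unmatched(self):
        ies, klass, offsets, _ = classify_event(("sc", 300, 340), ANN)
        assert (ies, klass, offsets) == (None, UNMATCHED, (None, None))

    def test_tie_breaks_to_max_overlap(self):
        ann = [
            IesRecord("sc", 100, 160, "IES.00000"),
            IesRecord("sc", 200, 260, "IES.00001"),
        ]
        # spans both; 50 bp overlap with the first, 30 with the second
        ies, _, _, multi = classify_event(("sc", 110, 230), ann)
        assert ies == "IES.00000"
        assert multi

    def test_agrees_with_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(5)
        ann = [
            IesRecord("sc", int(s), int(s) + int(l), f"IES.{i:05d}")
            for i, (s, l) in enumerate(
                zip(rng.integers(50, 5000, 20) * 10, rng.integers(26, 80, 20))
            )
        ]
        ann = sorted(ann)
        for _ in range(1000):
            rec = ann[int(rng.integers(0, len(ann)))]
            a = int(rec.start + rng.integers(-30, rec.length - 2))
            b = int(a + 2 + rng.integers(0, rec.length + 40))
            got = classify_event(("sc", a, b), ann)
            exp = brute_force_classify("sc", a, b, ann)
            assert (got[0], got[1], got[2]) == exp


class TestCollapse:
    def test_reads_aggregate_to_one_junction(self):
        evs = [
            JunctionEvidence(f"r{i}", "ALT_DELETION", None, "sc", 100, 150)
            for i in range(7)
        ]
        events = collapse_events(evs, ANN)
        assert len(events) == 1
        assert events[0].read_count == 7
        assert events[0].klass == PARTIAL_INTERNAL

    def test_distinct_junctions_stay_distinct(self):
        evs = [
            JunctionEvidence("r1", "ALT_DELETION", None, "sc", 100, 150),
            JunctionEvidence("r2", "ALT_DELETION", None, "sc", 100, 148),
        ]
        assert len(collapse_events(evs, ANN)) == 2

    def test_empty_input(self):
        assert collapse_events([], ANN) == []

    def test_non_deletion_kinds_ignored(self):
        evs = [JunctionEvidence("r1", "IES_PLUS_LEFT", "IES.00000")]
        assert collapse_events(evs, ANN) == []


class TestDeNovo:
    def test_set_difference(self):
        auto = [_event(100, 150, PARTIAL_INTERNAL, 0, -10),
                _event(100, 148, PARTIAL_INTERNAL, 0, -12),
                _event(110, 160, PARTIAL_INTERNAL, 10, 0)]
        parental = [_event(100, 148, PARTIAL_INTERNAL, 0, -12)]
        de_novo, rate = de_novo_errors(auto, parental, 10**6)
        assert de_novo == {("sc", 100, 150), ("sc", 110, 160)}
        assert rate == pytest.approx(2.0)

    def test_self_subtraction_and_empty_parental(self):
        auto = [_event(100, 150, PARTIAL_INTERNAL, 0, -10)]
        assert de_novo_errors(auto, auto, 100)[0] == set()
        assert de_novo_errors(auto, [], 100)[0] == {("sc", 100, 150)}

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            de_novo_errors([], [], 0)

    def test_normalization_linearity(self):
        auto = [_event(100, 150, PARTIAL_INTERNAL, 0, -10, reads=4)]
        _, r1 = de_novo_errors(auto, [], 1000)
        _, r2 = de_novo_errors(auto, [], 2000)
        assert r1 == pytest.approx(2 * r2)


class TestFractionsAndSpectrum:
    def test_error_read_fraction(self):
        events = [_event(100, 160, CORRECT, 0, 0, reads=97),
                  _event(100, 150, PARTIAL_INTERNAL, 0, -10, reads=3)]
        assert error_read_fraction(events) == pytest.approx(0.03)
        assert error_read_fraction([_event(100, 160, CORRECT, 0, 0, reads=5)]) == 0.0

    def test_shift_spectrum_mode_and_filter(self):
        events = [
            _event(100, 150, PARTIAL_INTERNAL, 0, -10),
            _event(100, 149, PARTIAL_INTERNAL, 0, -11),
            _event(110, 160, PARTIAL_INTERNAL, 10, 0),
            _event(100, 158, PARTIAL_INTERNAL, 0, -2),  # below threshold
            _event(100, 160, CORRECT, 0, 0),
        ]
        counts, mode = shift_spectrum(events, min_shift=3)
        assert counts == {10: 2, 11: 1}
        assert mode == 10

    def test_shift_two_excluded(self):
        counts, mode = shift_spectrum([_event(102, 160, PARTIAL_INTERNAL, 2, 0)])
        assert counts == {} and mode is None

    def test_class_distribution_sums_to_one(self):
        events = [_event(100, 150, PARTIAL_INTERNAL, 0, -10),
                  _event(90, 170, EXTERNAL, -10, 10),
                  _event(100, 160, CORRECT, 0, 0)]
        dist = class_distribution(events)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert dist[PARTIAL_INTERNAL] == pytest.approx(0.5)

    def test_error_prone_fraction_strata(self):
        results = [
            RetentionResult("IES.00000", 0.0, 0.0, 0.0),
            RetentionResult("IES.00001", 0.01, 0.01, 0.01),
            RetentionResult("IES.00002", 0.9, 0.9, 0.9),
        ]
        events = [_event(100, 150, PARTIAL_INTERNAL, 0, -10, ies="IES.00000")]
        out = error_prone_fraction(results, events)
        assert out["fully_excised"]["n_ies"] == 2
        assert out["fully_excised"]["fraction"] == pytest.approx(0.5)
        assert out["strongly_retained"]["fraction"] == 0.0

    def test_all_excised_with_errors_fraction_one(self):
        results = [RetentionResult(f"IES.{i:05d}", 0.0, 0.0, 0.0) for i in range(5)]
        events = [
            _event(100, 150, PARTIAL_INTERNAL, 0, -10, ies=f"IES.{i:05d}")
            for i in range(5)
        ]
        out = error_prone_fraction(results, events)
        assert out["fully_excised"]["fraction"] == 1.0


class TestSimulatedErrorAccounting:
    def test_planted_error_read_fraction_recovered(self):
        cfg = SimConfig(n_scaffolds=1, scaffold_len=9000, n_ies=10, coverage=120,
                        retention_prob=0.0, error_rate=0.05, seed=19)
        germline, somatic, annotation = generate_genomes(cfg)
        index = build_index(germline, somatic, annotation)
        reads, _ = simulate_reads(cfg, (germline, somatic), annotation)
        events = collapse_events(classify_reads(reads, index), annotation)
        frac = error_read_fraction(events)
        from oracles import binomial_ci

        total = sum(ev.read_count for ev in events)
        lo, hi = binomial_ci(int(round(frac * total)), total, level=0.999)
        assert lo <= 0.05 <= hi

    def test_summary_against_truth(self, small_sim):
        index = small_sim["index"]
        annotation = small_sim["annotation"]
        events = collapse_events(classify_reads(small_sim["reads"], index), annotation)
        parental = collapse_events(
            classify_reads(small_sim["parental_reads"], index), annotation
        )
        summary = summarize(events, parental, len(small_sim["reads"]))
        truth = small_sim["truth"]
        n_parental_marked = sum(ev.parental for ev in truth.planted_events)
        assert n_parental_marked == 5
        # all 20 planted junctions observed, 5 of them already parental
        assert summary.total_error_junctions == 20
        assert summary.de_novo_junctions == 15
        assert summary.de_novo_per_million == pytest.approx(
            15 / len(small_sim["reads"]) * 1e6
        )
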