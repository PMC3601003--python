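import numpy as np
import pytest

from ltrhmm.detection import (
    Hit,
    choose_threshold,
    evaluate,
    filter_fragments,
    non_maximum_suppression,
    scan,
)
from ltrhmm.io_formats import Annotation, SequenceRecord
from ltrhmm.model_build import train_with_noise
from ltrhmm.simulate import LTRFamilySpec, make_family, make_genome


def _annot(start, end, cons_end=None, cons_len=None, seq_id="g", source=None):
    return Annotation(seq_id, start, end, "+", "fam",
                      consensus_start=1, consensus_end=cons_end,
                      consensus_length=cons_len, source_id=source)


class TestFragmentFilter:
    def test_short_fragment_discarded(self):
        assert filter_fragments([_annot(0, 80, cons_end=500, cons_len=500)]) == []

    def test_three_prime_proximal_fragment_kept(self):
        a = _annot(0, 150, cons_end=450, cons_len=500)  # 50 bp from 3' end
        assert filter_fragments([a]) == [a]

    def test_three_prime_distal_fragment_discarded(self):
        a = _annot(0, 150, cons_end=350, cons_len=500)  # 150 bp from 3' end
        assert filter_fragments([a]) == []

    def test_missing_consensus_fields_excluded(self):
        assert filter_fragments([_annot(0, 150)]) == []


class TestEvaluate:
    def test_full_detection(self):
        truth = [_annot(100, 200, 100, 100), _annot(500, 600, 100, 100)]
        hits = [Hit("g", 90, 210, "+", 30.0), Hit("g", 480, 610, "+", 28.0)]
        rep = evaluate(hits, truth)
        assert (rep.detected, rep.missed, rep.additional_positives) == (2, 0, 0)
        assert rep.sensitivity == 100.0

    def test_no_hits(self):
        rep = evaluate([], [_annot(100, 200, 100, 100)])
        assert (rep.detected, rep.sensitivity, rep.additional_positives) == (0, 0.0, 0)

    def test_partial_detection_with_strays(self):
        truth = [_annot(i * 1000, i * 1000 + 100, 100, 100) for i in range(4)]
        hits = [Hit("g", i * 1000, i * 1000 + 100, "+", 30.0) for i in range(3)]
        hits += [Hit("g", 8000, 8100, "+", 25.0), Hit("g", 9000, 9100, "+", 24.0)]
        rep = evaluate(hits, truth)
        assert (rep.detected, rep.missed) == (3, 1)
        assert rep.sensitivity == pytest.approx(75.0)
        assert rep.additional_positives == 2

    def test_half_coverage_rule(self):
        truth = [_annot(100, 300, 200, 200)]
        barely = [Hit("g", 200, 320, "+", 30.0)]  # covers exactly 50%
        under = [Hit("g", 210, 320, "+", 30.0)]   # covers 45%
        assert evaluate(barely, truth).detected == 1
        assert evaluate(under, truth).detected == 0

    def test_training_set_dual_accounting(self):
        truth = [
            _annot(100, 200, 100, 100, source="train_1"),
            _annot(500, 600, 100, 100, source="new_1"),
        ]
        hits = [Hit("g", 100, 200, "+", 30.0)]
        rep = evaluate(hits, truth, training_ids={"train_1"})
        assert rep.detected == 1 and rep.missed == 1
        assert rep.excluded_training_matches == 1
        assert rep.outside_training.detected == 0
        assert rep.outside_training.missed == 1

    def test_inconsistent_seq_ids_rejected(self):
        with pytest.raises(ValueError):
            evaluate([Hit("chrX", 0, 10, "+", 1.0)], [_annot(0, 150, 100, 100)])

    def test_detected_plus_missed_equals_truth(self):
        rng = np.random.default_rng(0)
        truth = [_annot(int(s), int(s) + 120, 120, 120)
                 for s in rng.choice(50_000, size=8, replace=False) * 1]
        hits = [Hit("g", a.start, a.end, "+", 20.0) for a in truth[:5]]
        rep = evaluate(hits, truth)
        assert rep.detected + rep.missed == len(truth)


class TestChooseThreshold:
    def _windows(self, scores_on_truth, background_scores):
        hits, truth = [], []
        pos = 0
        for s in scores_on_truth:
            truth.append(_annot(pos, pos + 100, 100, 100))
            hits.append(Hit("g", pos, pos + 100, "+", s))
            pos += 1000
        for s in background_scores:
            hits.append(Hit("g", pos, pos + 100, "+", s))
            pos += 1000
        return hits, truth

    def test_infimum_grid_point_with_zero_budget(self):
        hits, truth = self._windows([30, 28, 25], [20])
        assert choose_threshold(hits, truth, max_additional=0) == 25

    def test_budget_admits_lower_threshold(self):
        hits, truth = self._windows([30, 28, 25], [20])
        assert choose_threshold(hits, truth, max_additional=1) == 20

    def test_sensitivity_sacrificed_under_tight_budget(self):
        hits, truth = self._windows([30, 28, 25], [26])
        assert choose_threshold(hits, truth, max_additional=0) == 28

    def test_no_feasible_threshold_returns_sentinel(self):
        hits, truth = self._windows([25], [40])
        assert choose_threshold(hits, truth, max_additional=0) == float("inf")

    def test_empty_truth_rejected(self):
        hits, _ = self._windows([25], [])
        with pytest.raises(ValueError):
            choose_threshold(hits, [], max_additional=0)


class TestNMS:
    def test_keeps_best_scoring_representative(self):
        hits = [
            Hit("g", 0, 100, "+", 10.0),
            Hit("g", 50, 150, "+", 20.0),
            Hit("g", 140, 240, "+", 5.0),
            Hit("g", 500, 600, "-", 7.0),
        ]
        kept = non_maximum_suppression(hits)
        assert [(h.start, h.score) for h in sorted(kept, key=lambda h: h.start)] == [
            (50, 20.0), (500, 7.0)
        ]


@pytest.fixture(scope="module")
def scan_setup():
    """A small genome with implants of a trained synthetic family."""
    spec = LTRFamilySpec(n_sequences=20, core_length=60,
                         motifs=[("SIR_5prime", "TGTTRNR", 0),
                                 ("AATAAA", "AATAAA", 28),
                                 ("SIR_3prime", "YNYAACA", 53)],
                         substitution_rate=0.05, indel_rate=0.01, seed=21)
    seqs, _ = make_family(spec)
    model, _ = train_with_noise(seqs, M=60, z=0.05, seed=21, max_iter=20, tol=1e-2)
    genome, truth = make_genome(8000, gc=0.45, implants=[(seqs, 3, 0.0)],
                                seed=22, min_spacing=800)
    return model, genome, truth, seqs


class TestScan:
    def test_all_n_genome_yields_no_hits(self, scan_setup):
        model, *_ = scan_setup
        genome = SequenceRecord("n", "N" * 2000)
        assert scan(model, genome, threshold=0.0, stride=20) == []

    def test_implants_recovered(self, scan_setup):
        model, genome, truth, _ = scan_setup
        windows = scan(model, genome, threshold=None, stride=5)
        thr = choose_threshold(windows, truth.annotations, max_additional=2)
        hits = [h for h in windows if h.score >= thr]
        rep = evaluate(hits, truth.annotations, threshold=thr)
        assert rep.sensitivity >= 2 / 3 * 100 - 1e-9

    def test_minus_strand_coordinates_round_trip(self, scan_setup):
        model, genome, truth, _ = scan_setup
        minus = [a for a in truth.annotations if a.strand == "-"]
        windows = scan(model, genome, threshold=None, stride=5)
        for a in minus:
            covering = [
                h for h in windows
                if h.strand == "-" and min(h.end, a.end) - max(h.start, a.start)
                >= 0.5 * a.length
            ]
            assert covering, f"minus-strand implant at {a.start} not covered"

    def test_reverse_complement_mirror(self, scan_setup):
        from ltrhmm.simulate import _revcomp

        model, genome, _, _ = scan_setup
        sub = SequenceRecord("sub", genome.residues[:3000])
        rc = SequenceRecord("sub", _revcomp(sub.residues))
        fwd_hits = scan(model, sub, threshold=5.0, stride=7)
        rc_hits = scan(model, rc, threshold=5.0, stride=7)
        L = len(sub.residues)
        mirrored = {(L - h.end, L - h.start, "-" if h.strand == "+" else "+")
                    for h in rc_hits}
        direct = {(h.start, h.end, h.strand) for h in fwd_hits}
        assert direct == mirrored

    def test_sensitivity_monotone_in_threshold(self, scan_setup):
        model, genome, truth, _ = scan_setup
        windows = scan(model, genome, threshold=None, stride=5)
        sens = []
        for t in np.linspace(-20, 60, 9):
            hits = [h for h in windows if h.score >= t]
            sens.append(evaluate(hits, truth.annotations).sensitivity)
        assert all(b <= a + 1e-9 for a, b in zip(sens, sens[1:]))

    def test_invalid_stride_rejected(self, scan_setup):
        model, genome, *_ = scan_setup
        with pytest.raises(ValueError):
            scan(model, genome, threshold=0.0, stride=0)
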