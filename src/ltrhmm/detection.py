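"""Genome screening with a trained profile and truth-set evaluation.

A genome is scanned with sliding windows spanning 0.8-1.25x the model
length (three window sizes, fixed stride), each window Viterbi-scored in
log-odds bits on both strands; overlapping above-threshold windows are
merged by non-maximum suppression so each locus yields one hit. Evaluation
against an annotation truth set follows the per-element accounting of
repeat-annotation benchmarks: an annotation counts as detected when a hit
covers at least half of it, hits covering no annotation are additional
positives, and sensitivity is detected / (detected + missed) in percent.
The truth set is first cleaned by the fragment filter: fragments shorter
than 100 bp, or ending more than 100 bp from the 3' end of the family
consensus, are discarded — the 3' end is where most LTR conservation
resides. The scan threshold is chosen to maximise sensitivity while
keeping additional positives at or below a bound (default 100).
"""

from __future__ import annotations

import bisect
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .hmm_core import ProfileHMM, encode, viterbi_scores_batch, LN2, _log
from .io_formats import Annotation, SequenceRecord

logger = logging.getLogger(__name__)

_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


@dataclass
class Hit:
    """A scan hit: 0-based half-open genomic interval with a bits score."""

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DetectionReport:
    """Detected / missed / additional-positive accounting for one scan."""

    detected: int
    missed: int
    additional_positives: int
    sensitivity: float            # percent
    threshold: float              # bits
    excluded_training_matches: int = 0
    outside_training: "DetectionReport | None" = None

    def __post_init__(self) -> None:
        if min(self.detected, self.missed, self.additional_positives) < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.sensitivity <= 100.0 or math.isnan(self.sensitivity)):
            raise ValueError("sensitivity must be within [0, 100]")

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _window_lengths(model: ProfileHMM, factors=(0.8, 1.0, 1.25)) -> list[int]:
    span = model.expected_span()
    return sorted({max(2, int(round(f * span))) for f in factors})


def scan(
    model: ProfileHMM,
    genome: SequenceRecord,
    threshold: float | None = None,
    stride: int = 10,
    both_strands: bool = True,
    window_factors: tuple[float, ...] = (0.8, 1.0, 1.25),
    max_n_fraction: float = 0.5,
    batch_size: int = 2048,
) -> list[Hit]:
    """Scan a genome for model occurrences.

    Windows of 0.8x/1.0x/1.25x the model span are advanced by ``stride``
    and Viterbi-scored in log-odds bits; the minus strand is scanned on the
    reverse complement with coordinates mapped back. Windows with more than
    ``max_n_fraction`` N are skipped (counted in the log). Overlapping
    windows at or above ``threshold`` are merged to the best-scoring
    representative; pass ``threshold=None`` to obtain all merged candidate
    windows for threshold selection. Hits are sorted by (seq_id, start).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    x_fwd = encode(genome.residues)
    L = len(x_fwd)
    lengths = _window_lengths(model, window_factors)
    if L < min(lengths):
        raise ValueError("genome shorter than the minimum scan window")
    lb = _log(np.concatenate([model.background, [0.25]]))

    strands = [("+", x_fwd)]
    if both_strands:
        strands.append(("-", _COMPLEMENT_IDX[x_fwd[::-1]]))

    raw: list[Hit] = []
    n_skipped = 0
    for strand, x in strands:
        for wlen in lengths:
            if L < wlen:
                continue
            starts = np.arange(0, L - wlen + 1, stride)
            view = np.lib.stride_tricks.sliding_window_view(x, wlen)[starts]
            n_frac = (view == 4).mean(axis=1)
            keep = n_frac <= max_n_fraction
            n_skipped += int((~keep).sum())
            starts, view = starts[keep], view[keep]
            if len(starts) == 0:
                continue
            bg = lb[view].sum(axis=1)
            for lo in range(0, len(starts), batch_size):
                sl = slice(lo, lo + batch_size)
                nats = viterbi_scores_batch(model, view[sl])
                bits = (nats - bg[sl]) / LN2
                for s0, b in zip(starts[sl], bits):
                    if strand == "+":
                        g0, g1 = int(s0), int(s0 + wlen)
                    else:
                        g0, g1 = int(L - s0 - wlen), int(L - s0)
                    raw.append(Hit(genome.id, g0, g1, strand, float(b), model.model_id))
    if n_skipped:
        logger.info("scan: skipped %d N-rich windows", n_skipped)
    if threshold is not None:
        raw = [h for h in raw if h.score >= threshold]
    merged = non_maximum_suppression(raw)
    merged.sort(key=lambda h: (h.seq_id, h.start, h.end))
    return merged


def non_maximum_suppression(hits: Sequence[Hit]) -> list[Hit]:
    """Merge overlapping hits, keeping the best-scoring window per locus."""
    kept_starts: list[int] = []
    kept: list[Hit] = []
    max_len = max((h.length for h in hits), default=0)
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.end, h.strand)):
        i = bisect.bisect_left(kept_starts, h.start - max_len)
        overlap = False
        while i < len(kept):
            other = kept[i]
            if other.start >= h.end:
                break
            if other.seq_id == h.seq_id and other.end > h.start:
                overlap = True
                break
            i += 1
        if not overlap:
            j = bisect.bisect_left(kept_starts, h.start)
            kept_starts.insert(j, h.start)
            kept.insert(j, h)
    return kept


def filter_fragments(
    annots: Sequence[Annotation], min_len: int = 100, max_3prime_gap: int = 100
) -> list[Annotation]:
    """Discard truth fragments too short or too far from the consensus 3' end.

    Keeps annotations at least ``min_len`` bp long whose consensus-relative
    end lies within ``max_3prime_gap`` bp of the consensus 3' end.
    Annotations missing consensus coordinates are excluded with a warning.
    """
    out: list[Annotation] = []
    n_missing = 0
    for a in annots:
        if a.consensus_end is None or a.consensus_length is None:
            n_missing += 1
            continue
        if a.length >= min_len and (a.consensus_length - a.consensus_end) <= max_3prime_gap:
            out.append(a)
    if n_missing:
        logger.warning(
            "filter_fragments: %d annotations lacked consensus coordinates",
            n_missing,
        )
    return out


def _overlap(hit: Hit, annot: Annotation) -> int:
    if hit.seq_id != annot.seq_id:
        return 0
    return max(0, min(hit.end, annot.end) - max(hit.start, annot.start))


def _single_report(
    hits: Sequence[Hit],
    truth: Sequence[Annotation],
    threshold: float,
    min_coverage: float,
) -> tuple[DetectionReport, set[int]]:
    detected = 0
    covering_hit_ids: set[int] = set()
    for a in truth:
        need = min_coverage * a.length
        hit_found = False
        for h in hits:
            if _overlap(h, a) >= need:
                hit_found = True
            if _overlap(h, a) > 0:
                covering_hit_ids.add(id(h))
        if hit_found:
            detected += 1
    missed = len(truth) - detected
    additional = sum(1 for h in hits if id(h) not in covering_hit_ids)
    sensitivity = 100.0 * detected / len(truth) if truth else float("nan")
    return (
        DetectionReport(
            detected=detected,
            missed=missed,
            additional_positives=additional,
            sensitivity=sensitivity,
            threshold=threshold,
        ),
        covering_hit_ids,
    )


def evaluate(
    hits: Sequence[Hit],
    truth: Sequence[Annotation],
    training_ids: set[str] | frozenset[str] = frozenset(),
    min_coverage: float = 0.5,
    threshold: float = float("nan"),
) -> DetectionReport:
    """Score a hit list against a (filtered) truth set.

    An annotation is detected when a single hit covers at least
    ``min_coverage`` of its length; hits overlapping no annotation at all
    are additional positives. The report is computed twice: over all truth
    records, and over the records whose ``source_id`` (fallback: family) is
    not in ``training_ids`` — elements the model was trained on are
    expected to be found more easily, so the second accounting is the
    honest generalisation measure.
    """
    if hits and truth:
        if not {h.seq_id for h in hits} & {a.seq_id for a in truth}:
            raise ValueError("hits and truth share no seq_id")
    report, _ = _single_report(hits, truth, threshold, min_coverage)
    if training_ids:
        outside = [
            a for a in truth
            if (a.source_id if a.source_id is not None else a.family) not in training_ids
        ]
        sub, _ = _single_report(hits, outside, threshold, min_coverage)
        report.outside_training = sub
        report.excluded_training_matches = len(truth) - len(outside)
    return report


def choose_threshold(
    scored_windows: Sequence[Hit],
    truth: Sequence[Annotation],
    max_additional: int = 100,
    min_coverage: float = 0.5,
) -> float:
    """Pick the scan threshold from candidate window scores.

    Candidates are the scores of the merged windows; the chosen value is
    the smallest candidate whose evaluation keeps additional positives at
    or below ``max_additional`` and, among those, maximises sensitivity.
    Returns +inf (with a warning) when no candidate satisfies the bound.
    """
    if not truth:
        raise ValueError("cannot choose a threshold without truth annotations")
    if not scored_windows:
        raise ValueError("no scored windows supplied")
    # per-hit: does it overlap truth at all / best-covering score per truth
    covering = []
    for h in scored_windows:
        covering.append(any(_overlap(h, a) > 0 for a in truth))
    best_cover_score = []
    for a in truth:
        need = min_coverage * a.length
        scores = [h.score for h in scored_windows if _overlap(h, a) >= need]
        best_cover_score.append(max(scores) if scores else None)

    add_scores = np.sort([h.score for h, c in zip(scored_windows, covering) if not c])
    det_scores = np.sort([s for s in best_cover_score if s is not None])
    n_truth = len(truth)

    best_t, best_sens = None, -1.0
    for t in sorted({h.score for h in scored_windows}):
        additional = len(add_scores) - np.searchsorted(add_scores, t)
        if additional > max_additional:
            continue
        detected = len(det_scores) - np.searchsorted(det_scores, t)
        sens = detected / n_truth
        if sens > best_sens or (sens == best_sens and best_t is not None and t < best_t):
            best_t, best_sens = float(t), sens
    if best_t is None:
        logger.warning(
            "choose_threshold: no threshold keeps additional positives <= %d",
            max_additional,
        )
        return float("inf")
    return best_t
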