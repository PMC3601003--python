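"""Consensus extraction, information content and IUPAC motif analysis.

This layer turns a trained profile into the objects one inspects for LTR
structure: the per-match-state logo matrix (emission probabilities and
information content in bits, 2 bits = a fully conserved column under the
uniform background), plain and degenerate consensus strings, motif scans
for the conserved LTR elements (AATAAA, TATA/TATATA, INR, GT-rich runs),
and the short-inverted-repeat report that checks the complementarity of
the two LTR termini.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .hmm_core import ProfileHMM, _RESIDUES
from .io_formats import SequenceRecord

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_CLASS_TO_LETTER = {v: k for k, v in IUPAC.items()}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class LogoMatrix:
    """Per-match-state emission probabilities and information content."""

    probs: np.ndarray          # (M, 4) over A, C, G, T
    bits: np.ndarray           # (M,) in [0, 2]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tA\tC\tG\tT\tbits\n")
            for i, (row, b) in enumerate(zip(self.probs, self.bits), start=1):
                cols = "\t".join(f"{p:.6f}" for p in row)
                fh.write(f"{i}\t{cols}\t{b:.6f}\n")


@dataclass
class MotifHit:
    pattern: str
    start: int
    matched_text: str

    def __post_init__(self) -> None:
        if len(self.matched_text) != len(self.pattern):
            raise ValueError("matched_text length must equal pattern length")


@dataclass
class SIRReport:
    """Degenerate 5'/3' terminal motifs and their complementarity."""

    five_prime: str
    three_prime: str
    complementarity: float     # fraction of compatible positions
    window: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


def column_bits(probs: Sequence[float]) -> float:
    """Information content of a nucleotide column: 2 - H2(p), in [0, 2].

    A point-mass column scores exactly 2 bits (100% conservation), the
    uniform column 0. No small-sample correction is applied.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (4,) or not np.isclose(p.sum(), 1.0, atol=1e-6) or (p < 0).any():
        raise ValueError("probs must be a length-4 distribution")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return 2.0 - entropy


def logo_matrix(model: ProfileHMM, background_weighted: bool = False) -> LogoMatrix:
    """Logo matrix of a model's match states.

    With ``background_weighted`` the per-column height is the relative
    entropy against the model background instead of 2 - H2.
    """
    probs = model.match_emissions.copy()
    if background_weighted:
        bits = (probs * np.log2(probs / model.background)).sum(axis=1)
    else:
        bits = np.array([column_bits(row) for row in probs])
    return LogoMatrix(probs=probs, bits=bits)


def consensus_from_model(model: ProfileHMM) -> SequenceRecord:
    """Length-M consensus: per column the argmax residue (ties: alphabetical)."""
    idx = np.argmax(model.match_emissions, axis=1)  # first max = alphabetical
    return SequenceRecord(
        f"{model.model_id}_consensus", "".join(_RESIDUES[i] for i in idx)
    )


def iupac_consensus(
    model: ProfileHMM, major_threshold: float = 0.6, minor_threshold: float = 0.25
) -> str:
    """Degenerate consensus: single residue if its probability reaches
    ``major_threshold``, else the minimal IUPAC class covering residues at
    or above ``minor_threshold`` (all four if none reach it)."""
    if not 0 < minor_threshold <= major_threshold <= 1:
        raise ValueError("need 0 < minor_threshold <= major_threshold <= 1")
    letters = []
    for row in model.match_emissions:
        top = int(np.argmax(row))
        if row[top] >= major_threshold:
            letters.append(_RESIDUES[top])
            continue
        members = frozenset(
            _RESIDUES[i] for i in range(4) if row[i] >= minor_threshold
        )
        if not members:
            members = frozenset("ACGT")
        letters.append(_CLASS_TO_LETTER[members])
    return "".join(letters)


def find_motif(target: str, pattern: str) -> list[MotifHit]:
    """All (possibly overlapping) IUPAC-pattern matches, left to right."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    for c in pattern.upper():
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {c!r}")
    pat = pattern.upper()
    regex = "".join(
        c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
        for c in pat
    )
    target_u = target.upper()
    hits = []
    for m in re.finditer(f"(?=({regex}))", target_u):
        hits.append(MotifHit(pat, m.start(), m.group(1)))
    return hits


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse complement of a degenerate pattern; an involution."""
    out = []
    for c in reversed(pattern.upper()):
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {c!r}")
        comp = frozenset(_COMPLEMENT[b] for b in IUPAC[c])
        out.append(_CLASS_TO_LETTER[comp])
    return "".join(out)


def sir_report(
    model: ProfileHMM,
    window: int = 7,
    major_threshold: float = 0.6,
    minor_threshold: float = 0.25,
) -> SIRReport:
    """Check the short-inverted-repeat structure of the LTR termini.

    Extracts the degenerate consensus of the first and last ``window`` match
    states (7 bp by default — the conservation of the SIRs extends about
    that far into the LTR) and scores the fraction of positions where the
    3' letter's class intersects the reverse complement of the 5' letter's
    class; perfectly complementary termini score 1.0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if model.M < 2 * window:
        raise ValueError(f"model too short (M={model.M}) for window {window}")
    full = iupac_consensus(model, major_threshold, minor_threshold)
    five = full[:window]
    three = full[-window:]
    rc5 = reverse_complement_iupac(five)
    compatible = sum(
        1 for a, b in zip(rc5, three) if IUPAC[a] & IUPAC[b]
    )
    return SIRReport(
        five_prime=five,
        three_prime=three,
        complementarity=compatible / window,
        window=window,
    )


def motif_report(
    consensus: str,
    patterns: dict[str, str] | None = None,
) -> dict[str, list[dict]]:
    """Scan a consensus for the standard conserved LTR motifs.

    Default inventory: the polyadenylation signal AATAAA, the plant TATA
    box TATATA, a TATA core, the initiator TCAKTY and a GT-rich run, plus
    the SIR consensus termini TGTTRNR / YNYAACA.
    """
    if patterns is None:
        patterns = {
            "AATAAA": "AATAAA",
            "TATATA": "TATATA",
            "TATA": "TATAWA",
            "INR": "TCAKTY",
            "GT_rich": "GKGKGK",
            "SIR_5prime": "TGTTRNR",
            "SIR_3prime": "YNYAACA",
        }
    return {
        name: [hit.__dict__ for hit in find_motif(consensus, pat)]
        for name, pat in patterns.items()
    }
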