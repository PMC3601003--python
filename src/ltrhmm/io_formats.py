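"""Readers and writers for the external formats the pipeline touches.

Internally every interval is 0-based half-open; the only conversions happen
here, at the format boundary (RepeatMasker .out is 1-based inclusive).
Sequences are uppercase over {A, C, G, T, N}; by default characters outside
that alphabet are mapped to N with a warning, strict mode rejects them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class SequenceRecord:
    """A nucleotide sequence with an identifier.

    ``residues`` is uppercase over {A, C, G, T, N}.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Annotation:
    """A repeat annotation on a genomic sequence.

    ``start``/``end`` are 0-based half-open. ``consensus_start`` and
    ``consensus_end`` are 1-based positions within the family consensus, as
    RepeatMasker reports them; ``consensus_length`` is the full consensus
    span in bp. ``source_id`` optionally names the individual element a
    (synthetic) copy derives from, for training-set exclusion accounting.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    family: str = ""
    consensus_start: int | None = None
    consensus_end: int | None = None
    consensus_length: int | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.seq_id}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if (
            self.consensus_start is not None
            and self.consensus_end is not None
            and self.consensus_start > self.consensus_end
        ):
            raise ValueError("consensus_start must be <= consensus_end")

    @property
    def length(self) -> int:
        return self.end - self.start


def _clean_residues(raw: str, record_id: str, strict: bool) -> tuple[str, int]:
    seq = raw.upper().replace("U", "T")
    bad = [c for c in set(seq) if c not in DNA_ALPHABET]
    n_mapped = 0
    if bad:
        if strict:
            raise FormatError(
                f"record {record_id!r} contains characters outside ACGTN: "
                f"{sorted(bad)}"
            )
        table = str.maketrans({c: "N" for c in bad})
        n_mapped = sum(seq.count(c) for c in bad)
        seq = seq.translate(table)
    return seq, n_mapped


def read_fasta(path: str | Path, strict: bool = False) -> list[SequenceRecord]:
    """Read a (possibly gapless) FASTA file into SequenceRecords.

    Residues are uppercased; characters outside {A,C,G,T,N} are mapped to N
    with a logged warning, or rejected when ``strict`` is true. Raises
    :class:`FormatError` on empty files or text before the first header,
    naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")

    records: list[SequenceRecord] = []
    total_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        seq, n_mapped = _clean_residues(str(rec.seq), rec.id, strict)
        total_mapped += n_mapped
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if total_mapped:
        logger.warning(
            "%s: mapped %d non-ACGTN characters to N", path, total_mapped
        )
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records as FASTA with lines wrapped at ``wrap`` characters.

    Gapped (aligned) residues are written verbatim, so round trips through
    :func:`read_fasta` are exact for plain nucleotide records.
    """
    if not records:
        raise ValueError("cannot write an empty record list")
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


def parse_repeatmasker_out(path: str | Path) -> list[Annotation]:
    """Parse a RepeatMasker .out table into annotations.

    The 1-based inclusive query coordinates become 0-based half-open;
    orientation "C" becomes strand "-", with the repeat-consensus columns
    read in the reversed order RepeatMasker uses for complement hits
    ("(left) end begin" instead of "begin end (left)").
    """
    path = Path(path)
    annotations: list[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            # header lines start with "SW"/"score" or are blank
            if not fields[0].lstrip("-").replace(".", "").isdigit():
                continue
            try:
                qseq = fields[4]
                qbegin, qend = int(fields[5]), int(fields[6])
                orient = fields[8]
                family = fields[9]
                if orient == "+":
                    cbegin = int(fields[11])
                    cend = int(fields[12])
                    cleft = int(fields[13].strip("()"))
                else:
                    cleft = int(fields[11].strip("()"))
                    cend = int(fields[12])
                    cbegin = int(fields[13])
                annotations.append(
                    Annotation(
                        seq_id=qseq,
                        start=qbegin - 1,
                        end=qend,
                        strand="-" if orient in {"C", "-"} else "+",
                        family=family,
                        consensus_start=cbegin,
                        consensus_end=cend,
                        consensus_length=cend + cleft,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"{path}: row {lineno}: cannot parse RepeatMasker record "
                    f"({exc})"
                ) from exc
    return annotations


def write_bed(items: Iterable, path: str | Path) -> None:
    """Write annotations or hits as BED6 (0-based half-open, verbatim)."""
    with open(path, "w") as fh:
        for item in items:
            name = getattr(item, "family", "") or getattr(item, "model_id", ".") or "."
            score = getattr(item, "score", 0)
            fh.write(
                f"{item.seq_id}\t{item.start}\t{item.end}\t{name}\t"
                f"{score:g}\t{item.strand}\n"
            )


def read_bed(path: str | Path) -> list[Annotation]:
    """Read BED6 intervals back into annotations (coordinates verbatim)."""
    path = Path(path)
    out: list[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected BED6")
            try:
                start, end = int(fields[1]), int(fields[2])
                if start < 0:
                    raise ValueError("negative coordinate")
                out.append(
                    Annotation(
                        seq_id=fields[0],
                        start=start,
                        end=end,
                        strand=fields[5].strip(),
                        family=fields[3],
                    )
                )
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return out


def write_newick(tree, path: str | Path, rooted: bool | None = None) -> None:
    """Serialise a tree (PhyloTree or skbio TreeNode) to Newick.

    Branch lengths are kept; integer bootstrap supports appear as internal
    node labels. ``rooted`` asserts the expected rootedness: a bifurcating
    root is "rooted", a trifurcating root "unrooted"; a mismatch raises
    instead of silently rewriting the topology.
    """
    root_attr = getattr(tree, "root", None)
    node = root_attr if root_attr is not None and not callable(root_attr) else tree
    if rooted is not None:
        n_children = len(node.children)
        is_rooted = n_children == 2
        if rooted != is_rooted:
            raise ValueError(
                f"tree root has {n_children} children "
                f"({'rooted' if is_rooted else 'unrooted'}), "
                f"but rooted={rooted} was requested"
            )
    node.write(str(path), format="newick")
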