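"""Seeded generators of synthetic LTR families, genomes and superfamilies.

The generators emulate the conserved LTR architecture: short inverted
repeats at both termini (TGTTRNR ... YNYAACA, complementary), a TATA /
TATATA region, the polyadenylation signal AATAAA, a GT-rich downstream
stretch, and a C-depleted low-complexity filler standing in for U3.
Descendant copies diverge by i.i.d. point substitutions and
geometric-length indels, producing the length variation a profile HMM has
to absorb. Genomes receive full and fragmentary implanted copies with an
exact truth record per implant, so the detection accounting and the
fragment filter are exercisable without external data.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consensus_motifs import IUPAC, reverse_complement_iupac
from .io_formats import Annotation, SequenceRecord
from skbio import TreeNode

_RESIDUES = "ACGT"
_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _default_motifs(core_length: int) -> list[tuple[str, str, int]]:
    """(name, IUPAC pattern, offset) for the canonical LTR layout."""
    L = core_length
    return [
        ("SIR_5prime", "TGTTRNR", 0),
        ("TATA", "TATATA", int(0.30 * L)),
        ("AATAAA", "AATAAA", int(0.55 * L)),
        ("GT_rich", "GTGGTGGT", int(0.70 * L)),
        ("SIR_3prime", "YNYAACA", L - 7),
    ]


@dataclass
class LTRFamilySpec:
    """Blueprint of a synthetic LTR family.

    Motifs are (name, IUPAC pattern, offset) placed on the ancestor;
    degenerate letters are resolved once at the ancestor so the family is
    internally consistent at SIR positions. The background is C-depleted by
    default, mimicking the low-complexity U3 filler. Rates are per site.
    """

    n_sequences: int = 30
    core_length: int = 100
    motifs: list[tuple[str, str, int]] | None = None
    substitution_rate: float = 0.05
    indel_rate: float = 0.01
    indel_mean_len: float = 3.0
    background: tuple[float, float, float, float] = (0.32, 0.13, 0.23, 0.32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motifs is None:
            self.motifs = _default_motifs(self.core_length)
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        spans = []
        for name, pat, off in self.motifs:
            if off < 0 or off + len(pat) > self.core_length:
                raise ValueError(f"motif {name} outside core_length")
            spans.append((off, off + len(pat), name))
        spans.sort()
        for (s0, e0, n0), (s1, e1, n1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(f"motifs {n0} and {n1} overlap")


@dataclass
class MotifTruth:
    """Realised coordinates of a planted motif in one descendant."""

    name: str
    start: int | None           # None if fully deleted
    end: int | None
    intact: bool                # survives verbatim (no sub or indel inside)


@dataclass
class ImplantTruth:
    """Ground truth for implanted LTR copies in a synthetic genome."""

    genome_id: str
    annotations: list[Annotation]

    def __post_init__(self) -> None:
        for a in self.annotations:
            if a.seq_id != self.genome_id:
                raise ValueError("implant annotation on wrong genome")
            if (
                a.consensus_start is not None
                and a.consensus_end is not None
                and (a.consensus_end - a.consensus_start + 1) != a.length
            ):
                raise ValueError("consensus coordinates inconsistent with length")


def _sample_background(rng, length: int, probs) -> str:
    return "".join(rng.choice(list(_RESIDUES), size=length, p=probs))


def _resolve_iupac(rng, pattern: str) -> str:
    return "".join(rng.choice(sorted(IUPAC[c])) for c in pattern.upper())


def _mutate(
    rng,
    parent: str,
    substitution_rate: float,
    indel_rate: float,
    indel_mean_len: float,
    background,
) -> tuple[str, np.ndarray]:
    """One descendant plus a coordinate map parent-position -> child-position
    (-1 where the parent base was deleted)."""
    child: list[str] = []
    coord = np.full(len(parent), -1, dtype=int)
    geo_p = 1.0 / max(indel_mean_len, 1.0)
    i = 0
    while i < len(parent):
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(geo_p))
            if rng.random() < 0.5:  # insertion before parent[i]
                child.extend(rng.choice(list(_RESIDUES), size=length, p=background))
            else:                   # deletion of up to `length` parent bases
                i += length
                continue
        c = parent[i]
        if rng.random() < substitution_rate:
            c = _OTHER[c][rng.integers(3)]
        coord[i] = len(child)
        child.append(c)
        i += 1
    return "".join(child), coord


def make_family(spec: LTRFamilySpec) -> tuple[list[SequenceRecord], dict]:
    """Generate a synthetic family and its per-sequence motif truth.

    Returns the descendant sequences and a truth map
    ``{"ancestor": str, "ancestor_motifs": {name: (start, end)},
    "per_sequence": {seq_id: [MotifTruth, ...]}}``.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.background, float)
    probs = probs / probs.sum()
    ancestor = list(_sample_background(rng, spec.core_length, probs))
    anc_motifs: dict[str, tuple[int, int]] = {}
    realised_patterns: list[tuple[str, str]] = []  # (pattern, realised string)
    for name, pattern, off in spec.motifs:
        # paired inverted repeats (e.g. the SIR termini TGTTRNR / YNYAACA)
        # are realised complementarily, as integrase recognition implies
        rc_pat = reverse_complement_iupac(pattern)
        prior = next((s for p, s in realised_patterns if p == rc_pat), None)
        realised = _revcomp(prior) if prior else _resolve_iupac(rng, pattern)
        realised_patterns.append((pattern.upper(), realised))
        ancestor[off : off + len(realised)] = realised
        anc_motifs[name] = (off, off + len(realised))
    ancestor_str = "".join(ancestor)

    records: list[SequenceRecord] = []
    per_sequence: dict[str, list[MotifTruth]] = {}
    for i in range(spec.n_sequences):
        child, coord = _mutate(
            rng, ancestor_str, spec.substitution_rate, spec.indel_rate,
            spec.indel_mean_len, probs,
        )
        sid = f"fam{spec.seed}_seq{i}"
        records.append(SequenceRecord(sid, child))
        truths = []
        for name, (a0, a1) in anc_motifs.items():
            positions = coord[a0:a1]
            kept = positions[positions >= 0]
            if len(kept) == 0:
                truths.append(MotifTruth(name, None, None, False))
                continue
            start, end = int(kept.min()), int(kept.max()) + 1
            segment = child[start:end]
            intact = segment == ancestor_str[a0:a1]
            truths.append(MotifTruth(name, start, end, intact))
        per_sequence[sid] = truths
    truth = {
        "ancestor": ancestor_str,
        "ancestor_motifs": anc_motifs,
        "per_sequence": per_sequence,
    }
    return records, truth


def make_genome(
    background_length: int,
    gc: float,
    implants: Sequence[tuple[Sequence[SequenceRecord], int, float]],
    seed: int = 0,
    min_spacing: int = 1000,
    genome_id: str = "synth_genome",
) -> tuple[SequenceRecord, ImplantTruth]:
    """A random genome with implanted full and fragmentary LTR copies.

    ``implants`` lists (family sequences, copy count, fragment fraction).
    Implant positions are drawn uniformly with at least ``min_spacing`` bp
    between insertion points; each copy picks a random family member and
    strand. Fragmentary copies are truncated at a random end to a uniform
    30-70% of their length, with consensus-relative coordinates recorded so
    the fragment filter has something to act on. The genome length is the
    background length plus the implanted bases.
    """
    rng = np.random.default_rng(seed)
    p_gc = gc / 2.0
    probs = np.array([0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc])
    background = _sample_background(rng, background_length, probs)

    n_total = sum(count for _, count, _ in implants)
    if n_total * min_spacing >= background_length:
        raise ValueError("implants cannot be placed with the required spacing")
    for _ in range(200):
        points = np.sort(rng.integers(0, background_length, size=n_total))
        if n_total <= 1 or np.diff(points).min() >= min_spacing:
            break
    else:
        raise ValueError("failed to draw implant positions with spacing")

    jobs = []
    for family_seqs, count, fragment_fraction in implants:
        for _ in range(count):
            jobs.append((family_seqs, fragment_fraction))
    order = rng.permutation(n_total)

    pieces: list[str] = []
    annotations: list[Annotation] = []
    prev = 0
    offset = 0  # bases inserted so far
    for point, job_idx in zip(points, order):
        family_seqs, fragment_fraction = jobs[job_idx]
        member = family_seqs[int(rng.integers(len(family_seqs)))]
        seq = member.residues
        full_len = len(seq)
        cons_start, cons_end = 1, full_len
        fragmentary = rng.random() < fragment_fraction
        if fragmentary:
            keep = max(1, int(round(full_len * rng.uniform(0.3, 0.7))))
            if rng.random() < 0.5:   # keep the 3' end
                seq = seq[full_len - keep:]
                cons_start = full_len - keep + 1
            else:                    # keep the 5' end
                seq = seq[:keep]
                cons_end = keep
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = _revcomp(seq)
        pieces.append(background[prev:point])
        start = point + offset
        pieces.append(seq)
        annotations.append(
            Annotation(
                seq_id=genome_id,
                start=start,
                end=start + len(seq),
                strand=strand,
                family=member.id.rsplit("_seq", 1)[0],
                consensus_start=cons_start,
                consensus_end=cons_end,
                consensus_length=full_len,
                source_id=member.id,
            )
        )
        offset += len(seq)
        prev = point
    pieces.append(background[prev:])
    genome = SequenceRecord(genome_id, "".join(pieces))
    truth = ImplantTruth(genome_id=genome_id, annotations=annotations)
    for a in truth.annotations:
        if a.end > len(genome.residues):
            raise RuntimeError("implant outside genome bounds")
    return genome, truth


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def make_superfamily_system(
    k_families: int,
    divergence_between: float,
    divergence_within: float,
    seed: int = 0,
    n_per_family: int = 12,
    core_length: int = 100,
    family_rate: float = 0.02,
) -> tuple[dict[str, list[SequenceRecord]], TreeNode]:
    """Two superfamilies of LTR families with a known family tree.

    A root LTR (with the canonical motif layout) is evolved along a
    bifurcating tree: two clade ancestors separated by
    ``divergence_between`` substitutions per site, family founders within a
    clade separated by ``divergence_within``. Each family then yields
    ``n_per_family`` descendants at ``family_rate``. Returns the per-family
    sequence sets and the true tree (branch lengths in expected
    substitutions per site); its deepest bipartition separates the clades.
    """
    if k_families < 3:
        raise ValueError("k_families must be >= 3")
    rng = np.random.default_rng(seed)
    spec = LTRFamilySpec(
        n_sequences=1, core_length=core_length,
        substitution_rate=0.0, indel_rate=0.0, seed=seed,
    )
    _, truth = make_family(spec)
    root_seq = truth["ancestor"]

    def _evolve(parent: str, rate: float) -> str:
        child, _ = _mutate(rng, parent, rate, 0.0, 1.0,
                           np.full(4, 0.25))
        return child

    half_between = max(divergence_between - divergence_within, 0.0) / 2.0
    half_within = divergence_within / 2.0
    k1 = k_families // 2
    clades = [list(range(k1)), list(range(k1, k_families))]
    family_sets: dict[str, list[SequenceRecord]] = {}
    clade_nodes = []
    for clade_members in clades:
        clade_anc = _evolve(root_seq, half_between)
        children = []
        for fi in clade_members:
            founder = _evolve(clade_anc, half_within)
            fam = f"family{fi}"
            seqs = []
            for i in range(n_per_family):
                child, _ = _mutate(rng, founder, family_rate, 0.0, 1.0,
                                   np.full(4, 0.25))
                seqs.append(SequenceRecord(f"{fam}_seq{i}", child))
            family_sets[fam] = seqs
            children.append(TreeNode(name=fam, length=half_within))
        clade_nodes.append(TreeNode(children=children, length=half_between))
    true_tree = TreeNode(children=clade_nodes)
    return family_sets, true_tree
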