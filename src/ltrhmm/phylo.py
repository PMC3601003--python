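"""Consensus phylogeny via a general profile and a "SuperViterbi" alignment.

The per-family consensus sequences are used to train a single general LTR
profile; Viterbi-aligning each consensus to that profile places homologous
match states in shared columns, giving a multiple alignment ("SuperViterbi"
alignment) of the consensuses. Pairwise p-distances (proportion of
differing nucleotides, gapped columns excluded under pairwise deletion)
feed a neighbour-joining tree; column bootstrap gives edge supports, and a
grid over consensus length, general-model length and the noise level z is
searched for the tree with the highest mean bootstrap value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .hmm_core import ProfileHMM, viterbi
from .io_formats import SequenceRecord
from .model_build import train_with_noise
from .consensus_motifs import consensus_from_model

logger = logging.getLogger(__name__)


@dataclass
class MSA:
    """A gapped alignment: equal-length rows plus column origin labels.

    ``col_is_match[c]`` is True for columns backed by a match state of the
    aligning profile, False for insert-run padding columns. Ungapping any
    row (and uppercasing: insert residues are written lowercase) returns
    the input sequence exactly.
    """

    ids: list[str]
    rows: list[str]
    col_is_match: list[bool]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        if self.rows and len(self.rows[0]) != len(self.col_is_match):
            raise ValueError("col_is_match length must match row length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "").upper()

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(i, r) for i, r in zip(self.ids, self.rows)]


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal.

    :func:`p_distance` produces entries in [0, 1]; the container itself also
    accepts general additive distances so NJ can be used on them directly.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match id count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be non-negative and finite")


@dataclass
class PhyloTree:
    """An (unrooted) NJ tree with bootstrap supports on internal edges."""

    root: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)
    mean_bootstrap: float = float("nan")

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def bipartitions(self) -> set[frozenset]:
        return _internal_bipartitions(self.root)

    def newick(self) -> str:
        return str(self.root).strip()


def _internal_bipartitions(root: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, each as the frozenset of tip names on one
    side (canonicalised to the smaller side, ties by sorted names)."""
    all_tips = frozenset(t.name for t in root.tips())
    out = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        other = all_tips - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def build_super_hmm(
    consensuses: Sequence[SequenceRecord],
    M: int,
    z: float = 0.0,
    seed: int = 0,
    max_iter: int = 40,
    tol: float = 1e-3,
) -> ProfileHMM:
    """Train the general LTR profile on the set of family consensuses."""
    if len(consensuses) < 3:
        raise ValueError("need at least 3 consensuses for a general model")
    model, _ = train_with_noise(
        list(consensuses), M, z, seed=seed, max_iter=max_iter, tol=tol,
        model_id="super",
    )
    return model


def superviterbi_align(
    model: ProfileHMM, consensuses: Sequence[SequenceRecord]
) -> MSA:
    """Viterbi-align each consensus to the general profile.

    Match states define shared columns (uppercase; '-' for deletions);
    insert runs are written lowercase and right-padded per run to the
    longest run over all rows. Row order follows the input.
    """
    M = model.M
    per_row: list[dict] = []
    max_insert = np.zeros(M + 1, dtype=int)  # insert run after node k
    for rec in consensuses:
        path = viterbi(model, rec)
        match_col: dict[int, str] = {}
        inserts: dict[int, list[str]] = {}
        pos = 0
        for state, k in path.states:
            if state == "M":
                match_col[k] = rec.residues[pos]
                pos += 1
            elif state == "I":
                inserts.setdefault(k, []).append(rec.residues[pos].lower())
                pos += 1
            # deletions leave match_col[k] absent
        per_row.append({"match": match_col, "inserts": inserts})
        for k, run in inserts.items():
            max_insert[k] = max(max_insert[k], len(run))

    rows = []
    for info in per_row:
        chunks = []
        for k in range(0, M + 1):
            if k > 0:
                chunks.append(info["match"].get(k, "-"))
            run = info["inserts"].get(k, [])
            chunks.append("".join(run) + "-" * (max_insert[k] - len(run)))
        rows.append("".join(chunks))

    # column order mirrors the row chunks: I_0 run, then (M_k, I_k run) per node
    col_is_match: list[bool] = []
    for k in range(0, M + 1):
        if k > 0:
            col_is_match.append(True)
        col_is_match.extend([False] * int(max_insert[k]))

    msa = MSA(ids=[r.id for r in consensuses], rows=rows, col_is_match=col_is_match)
    for i, rec in enumerate(consensuses):
        if msa.ungapped(i) != rec.residues.upper():
            raise RuntimeError(f"ungapping row {rec.id} does not recover the input")
    return msa


def p_distance(msa: MSA, gap_mode: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing nucleotides per pair of rows.

    ``pairwise`` (default) excludes, per pair, the columns where either row
    is gapped; ``complete`` drops every column containing any gap before
    comparing. A pair with no comparable columns raises, naming the pair.
    """
    if len(msa.rows) < 2:
        raise ValueError("p_distance needs at least 2 rows")
    mat = np.array([list(r.upper()) for r in msa.rows])
    gap = mat == "-"
    if gap_mode == "complete":
        keep = ~gap.any(axis=0)
        mat, gap = mat[:, keep], gap[:, keep]
    elif gap_mode != "pairwise":
        raise ValueError("gap_mode must be 'pairwise' or 'complete'")
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = ~(gap[i] | gap[j])
        n_ok = int(ok.sum())
        if n_ok == 0:
            raise ValueError(
                f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
            )
        diff = int((mat[i, ok] != mat[j, ok]).sum())
        d[i, j] = d[j, i] = diff / n_ok
    return DistanceMatrix(ids=list(msa.ids), values=d)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining; negative branch lengths clamped to 0."""
    if len(D.ids) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    skdm = _SkbioDM(D.values, ids=D.ids)
    tree = _skbio_nj(skdm, neg_as_zero=True)
    return PhyloTree(root=tree)


def bootstrap_support(
    msa: MSA, n_replicates: int = 1000, seed: int = 0, gap_mode: str = "pairwise"
) -> PhyloTree:
    """Column bootstrap of the NJ tree.

    The point-estimate tree is built from the full alignment; each
    replicate resamples alignment columns with replacement and rebuilds an
    NJ tree. Each internal edge of the point tree is annotated with the
    percentage of replicates containing its bipartition; replicates where
    some pair has no comparable columns are skipped and counted.
    ``mean_bootstrap`` averages supports over the internal edges.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = neighbor_joining(p_distance(msa, gap_mode))
    target = _internal_bipartitions(point.root)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    n_used = 0
    n_skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = MSA(
            ids=list(msa.ids),
            rows=["".join(row[c] for c in cols) for row in msa.rows],
            col_is_match=[msa.col_is_match[c] for c in cols],
        )
        try:
            rep_tree = neighbor_joining(p_distance(rep, gap_mode))
        except ValueError:
            n_skipped += 1
            continue
        n_used += 1
        rep_bps = _internal_bipartitions(rep_tree.root)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if n_skipped:
        logger.warning("bootstrap: skipped %d degenerate replicates", n_skipped)
    if n_used == 0:
        raise RuntimeError("all bootstrap replicates were degenerate")
    supports = {bp: 100.0 * c / n_used for bp, c in counts.items()}
    mean_bs = float(np.mean(list(supports.values()))) if supports else float("nan")
    _annotate_supports(point.root, supports)
    return PhyloTree(root=point.root, supports=supports, mean_bootstrap=mean_bs)


def _annotate_supports(root: TreeNode, supports: dict[frozenset, float]) -> None:
    all_tips = frozenset(t.name for t in root.tips())
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        if canon in supports:
            node.name = str(int(round(supports[canon])))


@dataclass
class GridRecord:
    consensus_M: int
    general_M: int
    z: float
    mean_bootstrap: float
    failed: bool = False


def select_best_tree(
    family_sets: dict[str, Sequence[SequenceRecord]],
    general_M_grid: Sequence[int],
    z_grid: Sequence[float],
    consensus_M_grid: Sequence[int],
    n_replicates: int = 1000,
    seed: int = 0,
    max_iter: int = 30,
) -> tuple[PhyloTree, list[GridRecord]]:
    """Full factorial grid search for the highest-mean-bootstrap tree.

    For each consensus length, every family's profile is retrained at that
    M (and the cell's z) and its consensus extracted; the consensuses train
    the general profile of the cell's general M, are SuperViterbi-aligned
    and bootstrapped. The tree with the highest mean bootstrap wins.
    """
    if not (general_M_grid and z_grid and consensus_M_grid):
        raise ValueError("all grids must be non-empty")
    if len(family_sets) < 3:
        raise ValueError("need at least 3 families")
    records: list[GridRecord] = []
    best: tuple[float, PhyloTree] | None = None
    consensus_cache: dict[tuple[int, float], list[SequenceRecord]] = {}
    for cons_M in consensus_M_grid:
        for z in z_grid:
            key = (cons_M, float(z))
            if key not in consensus_cache:
                cons_list = []
                for fam, seqs in family_sets.items():
                    model, _ = train_with_noise(
                        list(seqs), cons_M, z, seed=seed, max_iter=max_iter,
                        model_id=fam,
                    )
                    cons = consensus_from_model(model)
                    cons_list.append(SequenceRecord(fam, cons.residues))
                consensus_cache[key] = cons_list
            consensuses = consensus_cache[key]
            for gen_M in general_M_grid:
                try:
                    super_model = build_super_hmm(
                        consensuses, gen_M, z=z, seed=seed, max_iter=max_iter
                    )
                    msa = superviterbi_align(super_model, consensuses)
                    tree = bootstrap_support(msa, n_replicates, seed=seed)
                    records.append(GridRecord(cons_M, gen_M, z, tree.mean_bootstrap))
                    if best is None or tree.mean_bootstrap > best[0]:
                        best = (tree.mean_bootstrap, tree)
                except (ValueError, RuntimeError) as exc:
                    logger.warning(
                        "grid cell (cons_M=%d, gen_M=%d, z=%g) failed: %s",
                        cons_M, gen_M, z, exc,
                    )
                    records.append(
                        GridRecord(cons_M, gen_M, z, float("nan"), failed=True)
                    )
    if best is None:
        raise RuntimeError("every grid cell failed")
    return best[1], records
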