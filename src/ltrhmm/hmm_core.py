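"""Linear nucleotide profile HMM: training, alignment and scoring.

The model is a classic Krogh-style linear profile: M match states flanked by
insert states I_0..I_M and delete states D_1..D_M, with begin/end anchors and
the full nine-transition topology (match/insert/delete to match/insert/delete)
at every node. Sequences are aligned globally, end to end — an LTR is
modelled from its 5' short inverted repeat to its 3' one; locality for
genome screening is obtained by windowing in :mod:`ltrhmm.detection`.

All dynamic programming runs in natural-log space. The delete states form a
non-emitting chain within each residue layer; both forward/backward and
Viterbi evaluate that chain with a prefix scan (``logaddexp.accumulate`` /
``maximum.accumulate``) so the per-sequence cost is an O(L) Python loop over
vectorised O(M) steps. Public scores are log-odds against a background
residue model, in bits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import SequenceRecord

LN2 = math.log(2.0)
_RESIDUES = "ACGT"
_RES_INDEX = {c: i for i, c in enumerate(_RESIDUES)}
# transition source/destination codes within a node
_M, _I, _D = 0, 1, 2


class ProfileHMMError(ValueError):
    pass


@dataclass
class ProfileHMM:
    """A linear profile HMM over the DNA alphabet.

    Parameters
    ----------
    M:
        Number of match states (the model length).
    match_emissions:
        (M, 4) row-stochastic emission probabilities over A, C, G, T.
    insert_emissions:
        (M+1, 4) row-stochastic emissions for I_0..I_M.
    transitions:
        (M+1, 3, 3) array ``t[k, src, dst]``: at node k the source states
        are M_k (k=0 is begin), I_k and D_k; destinations are M_{k+1}
        (end when k=M), I_k and D_{k+1}. ``t[0, D, :]`` and ``t[M, :, D]``
        are structurally zero.
    background:
        Length-4 residue frequencies used for log-odds scoring.
    pseudocount:
        Probability floor / additive Dirichlet pseudocount used in training.
    """

    M: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    pseudocount: float = 1e-6
    model_id: str = "profile"
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.M < 1:
            raise ProfileHMMError("M must be >= 1")
        if self.match_emissions.shape != (self.M, 4):
            raise ProfileHMMError("match_emissions must be (M, 4)")
        if self.insert_emissions.shape != (self.M + 1, 4):
            raise ProfileHMMError("insert_emissions must be (M+1, 4)")
        if self.transitions.shape != (self.M + 1, 3, 3):
            raise ProfileHMMError("transitions must be (M+1, 3, 3)")
        for name, rows in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
        ):
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ProfileHMMError(f"{name} rows must sum to 1")
            if (rows <= 0).any():
                raise ProfileHMMError(f"{name} must be strictly positive")
        mask = transition_mask(self.M)
        sums = np.where(mask, self.transitions, 0.0).sum(axis=2)
        row_has = mask.any(axis=2)
        if not np.allclose(sums[row_has], 1.0, atol=1e-9):
            raise ProfileHMMError("transition rows must sum to 1")
        if (self.transitions[mask] <= 0).any():
            raise ProfileHMMError("legal transitions must be positive")
        if (np.abs(self.transitions[~mask]) > 0).any():
            raise ProfileHMMError("illegal transitions must be zero")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ProfileHMMError("background must sum to 1")

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_id": self.model_id,
            "M": self.M,
            "alphabet": _RESIDUES,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": self.transitions.tolist(),
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ProfileHMM":
        """Load a model from a JSON file path or a JSON string."""
        if isinstance(source, Path):
            text = source.read_text()
        elif source.lstrip().startswith("{"):
            text = source
        else:
            text = Path(source).read_text()
        d = json.loads(text)
        model = cls(
            M=int(d["M"]),
            match_emissions=np.asarray(d["match_emissions"], float),
            insert_emissions=np.asarray(d["insert_emissions"], float),
            transitions=np.asarray(d["transitions"], float),
            background=np.asarray(d["background"], float),
            pseudocount=float(d.get("pseudocount", 1e-6)),
            model_id=d.get("model_id", "profile"),
            metadata=d.get("metadata", {}),
        )
        model.validate()
        return model

    def expected_span(self) -> int:
        """Expected emitted length, approximated by the model length M."""
        return self.M


@dataclass
class AlignmentPath:
    """A Viterbi state path: (state_type, index) triples plus its score.

    ``states`` runs from the first post-begin state to the last pre-end
    state; types are "M", "I", "D". ``score_bits`` is the log-odds of the
    Viterbi path against the background model, ``log_prob`` its natural-log
    joint probability.
    """

    states: list[tuple[str, int]]
    log_prob: float
    score_bits: float

    def emitted_count(self) -> int:
        return sum(1 for t, _ in self.states if t in ("M", "I"))


def transition_mask(M: int) -> np.ndarray:
    """Boolean (M+1, 3, 3) mask of structurally legal transitions."""
    mask = np.ones((M + 1, 3, 3), dtype=bool)
    mask[0, _D, :] = False  # D_0 does not exist
    mask[M, :, _D] = False  # no D_{M+1}
    return mask


def encode(residues: str) -> np.ndarray:
    """Map residues to 0..3, with N (and gaps) as 4."""
    return np.fromiter(
        (_RES_INDEX.get(c, 4) for c in residues.upper()), dtype=np.int64,
        count=len(residues),
    )


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _emission_table(probs: np.ndarray) -> np.ndarray:
    """Log emissions with an extra neutral column for N (= log 1/4)."""
    n_col = np.full((probs.shape[0], 1), 0.25)
    return _log(np.hstack([probs, n_col]))


def init_profile(
    M: int,
    pseudocount: float = 1e-6,
    seed: int = 0,
    jitter: float = 1e-2,
    model_id: str = "profile",
) -> ProfileHMM:
    """A near-uniform profile with seeded jitter to break EM symmetry.

    Transitions favour the match path (0.8/0.1/0.1) so training anchors the
    register on the match backbone; emissions are uniform up to a relative
    jitter of ``jitter``.
    """
    if M < 1:
        raise ProfileHMMError("M must be >= 1")
    rng = np.random.default_rng(seed)

    def _jittered(shape, base):
        x = base * (1.0 + jitter * rng.standard_normal(shape))
        x = np.clip(x, 1e-12, None)
        return x / x.sum(axis=-1, keepdims=True)

    match = _jittered((M, 4), np.full((M, 4), 0.25))
    insert = _jittered((M + 1, 4), np.full((M + 1, 4), 0.25))
    base_t = np.array([[0.8, 0.1, 0.1]] * 3)
    trans = np.zeros((M + 1, 3, 3))
    mask = transition_mask(M)
    for k in range(M + 1):
        for s in range(3):
            if not mask[k, s].any():
                continue
            row = base_t[s] * (1.0 + jitter * rng.standard_normal(3))
            row = np.clip(row, 1e-12, None) * mask[k, s]
            trans[k, s] = row / row.sum()
    model = ProfileHMM(
        M=M,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        background=np.full(4, 0.25),
        pseudocount=pseudocount,
        model_id=model_id,
        metadata={"init_seed": seed, "init_jitter": jitter},
    )
    model.validate()
    return model


def make_peaked_profile(
    consensus: str,
    peak: float = 0.99,
    match_stay: float = 0.98,
    pseudocount: float = 1e-9,
    model_id: str = "peaked",
) -> ProfileHMM:
    """A profile strongly peaked on a consensus string (test/benchmark aid)."""
    cons = encode(consensus)
    if (cons > 3).any():
        raise ProfileHMMError("consensus must be over ACGT")
    M = len(cons)
    match = np.full((M, 4), (1.0 - peak) / 3.0)
    match[np.arange(M), cons] = peak
    insert = np.full((M + 1, 4), 0.25)
    off = (1.0 - match_stay) / 2.0
    trans = np.zeros((M + 1, 3, 3))
    mask = transition_mask(M)
    for k in range(M + 1):
        for s in range(3):
            if not mask[k, s].any():
                continue
            row = np.array([match_stay, off, off]) * mask[k, s]
            trans[k, s] = row / row.sum()
    model = ProfileHMM(M, match, insert, trans, np.full(4, 0.25),
                       pseudocount=pseudocount, model_id=model_id)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# dynamic programming
# ---------------------------------------------------------------------------

def _log_tables(model: ProfileHMM):
    lm = _emission_table(model.match_emissions)      # (M, 5)
    li = _emission_table(model.insert_emissions)     # (M+1, 5)
    lt = np.where(transition_mask(model.M), model.transitions, 0.0)
    lt = _log(lt)                                    # (M+1, 3, 3), -inf illegal
    return lm, li, lt


def _delete_prefix_sums(lt: np.ndarray, M: int) -> np.ndarray:
    """S[m] = sum_{i=1..m} log t[D_i -> D_{i+1}], m = 0..M-1."""
    if M == 1:
        return np.zeros(1)
    dd = lt[1:M, _D, _D]
    return np.concatenate([[0.0], np.cumsum(dd)])


def _forward_scan_delete(fm_row, fi_row, lt, S, M):
    """Delete-chain layer: fD[k] for k=1..M from same-layer M/I values."""
    entry = np.logaddexp(fm_row[:M] + lt[:M, _M, _D], fi_row[:M] + lt[:M, _I, _D])
    vals = entry - S
    acc = np.logaddexp.accumulate(vals)
    out = np.full(M + 1, -np.inf)
    out[1:] = S + acc
    return out


def _viterbi_scan_delete(vm_row, vi_row, lt, S, M):
    entry = np.maximum(vm_row[:M] + lt[:M, _M, _D], vi_row[:M] + lt[:M, _I, _D])
    acc = np.maximum.accumulate(entry - S)
    out = np.full(M + 1, -np.inf)
    out[1:] = S + acc
    return out


def _forward_matrices(model: ProfileHMM, x: np.ndarray):
    """Full forward lattice; returns (fM, fI, fD, loglik)."""
    M, L = model.M, len(x)
    lm, li, lt = _log_tables(model)
    S = _delete_prefix_sums(lt, M)
    fM = np.full((L + 1, M + 1), -np.inf)
    fI = np.full((L + 1, M + 1), -np.inf)
    fD = np.full((L + 1, M + 1), -np.inf)
    fM[0, 0] = 0.0
    fD[0] = _forward_scan_delete(fM[0], fI[0], lt, S, M)
    for j in range(1, L + 1):
        c = x[j - 1]
        pM, pI, pD = fM[j - 1], fI[j - 1], fD[j - 1]
        into_m = np.logaddexp(
            np.logaddexp(pM[:M] + lt[:M, _M, _M], pI[:M] + lt[:M, _I, _M]),
            pD[:M] + lt[:M, _D, _M],
        )
        fM[j, 1:] = lm[:, c] + into_m
        into_i = np.logaddexp(
            np.logaddexp(pM + lt[:, _M, _I], pI + lt[:, _I, _I]),
            pD + lt[:, _D, _I],
        )
        fI[j] = li[:, c] + into_i
        fD[j] = _forward_scan_delete(fM[j], fI[j], lt, S, M)
    ll = np.logaddexp(
        np.logaddexp(fM[L, M] + lt[M, _M, _M], fI[L, M] + lt[M, _I, _M]),
        fD[L, M] + lt[M, _D, _M],
    )
    return fM, fI, fD, float(ll)


def _backward_matrices(model: ProfileHMM, x: np.ndarray):
    M, L = model.M, len(x)
    lm, li, lt = _log_tables(model)
    S = _delete_prefix_sums(lt, M)
    bM = np.full((L + 1, M + 1), -np.inf)
    bI = np.full((L + 1, M + 1), -np.inf)
    bD = np.full((L + 1, M + 1), -np.inf)

    def _bd_row(exit_vals):
        # bD[k] = logsumexp_{k'>=k} exit[k'] + S[k'-1] - S[k-1], k = 1..M
        w = exit_vals + S  # exit_vals indexed k'=1..M -> S[k'-1]
        racc = np.logaddexp.accumulate(w[::-1])[::-1]
        out = np.full(M + 1, -np.inf)
        out[1:] = racc - S
        return out

    # layer j = L: only delete chains to end remain
    exit_L = np.full(M, -np.inf)
    exit_L[M - 1] = lt[M, _D, _M]
    bD[L] = _bd_row(exit_L)
    bM[L, M] = lt[M, _M, _M]
    bI[L, M] = lt[M, _I, _M]
    if M > 1:
        bM[L, 1:M] = np.logaddexp(bM[L, 1:M], lt[1:M, _M, _D] + bD[L, 2:])
        bI[L, 1:M] = np.logaddexp(bI[L, 1:M], lt[1:M, _I, _D] + bD[L, 2:])
    bM[L, 0] = lt[0, _M, _D] + bD[L, 1]
    bI[L, 0] = lt[0, _I, _D] + bD[L, 1]

    for j in range(L - 1, -1, -1):
        c = x[j]
        nM, nI = bM[j + 1], bI[j + 1]
        # exit of D_{k'} (k'=1..M): emit next residue via M_{k'+1} or I_{k'}
        exit_vals = np.full(M, -np.inf)
        if M > 1:
            exit_vals[: M - 1] = np.logaddexp(
                lt[1:M, _D, _M] + lm[1:M, c] + nM[2:],
                lt[1:M, _D, _I] + li[1:M, c] + nI[1:M],
            )
        exit_vals[M - 1] = lt[M, _D, _I] + li[M, c] + nI[M]
        bD[j] = _bd_row(exit_vals)
        to_match = np.full(M + 1, -np.inf)
        to_match[:M] = lm[:, c] + nM[1:]
        em = np.logaddexp(lt[:, _M, _M] + to_match, lt[:, _M, _I] + li[:, c] + nI)
        ei = np.logaddexp(lt[:, _I, _M] + to_match, lt[:, _I, _I] + li[:, c] + nI)
        em[:M] = np.logaddexp(em[:M], lt[:M, _M, _D] + bD[j, 1:])
        ei[:M] = np.logaddexp(ei[:M], lt[:M, _I, _D] + bD[j, 1:])
        bM[j] = em
        bI[j] = ei
    return bM, bI, bD


def forward_log_likelihood(model: ProfileHMM, seq: SequenceRecord | str) -> float:
    """Total (summed-over-paths) log probability, natural log."""
    residues = seq if isinstance(seq, str) else seq.residues
    return _forward_matrices(model, encode(residues))[3]


def _background_logprob(model: ProfileHMM, x: np.ndarray) -> float:
    lb = _log(np.concatenate([model.background, [0.25]]))
    return float(lb[x].sum())


def viterbi(model: ProfileHMM, seq: SequenceRecord | str) -> AlignmentPath:
    """Maximum-probability global state path for a sequence.

    Ties are broken preferring match over delete over insert (then the lower
    node index, implied by the scan keeping the earliest entry point). An
    empty sequence yields the all-delete path, which has finite probability.
    """
    model.validate()
    residues = seq if isinstance(seq, str) else seq.residues
    x = encode(residues)
    M, L = model.M, len(x)
    lm, li, lt = _log_tables(model)
    S = _delete_prefix_sums(lt, M)
    vM = np.full((L + 1, M + 1), -np.inf)
    vI = np.full((L + 1, M + 1), -np.inf)
    vD = np.full((L + 1, M + 1), -np.inf)
    vM[0, 0] = 0.0
    vD[0] = _viterbi_scan_delete(vM[0], vI[0], lt, S, M)
    for j in range(1, L + 1):
        c = x[j - 1]
        pM, pI, pD = vM[j - 1], vI[j - 1], vD[j - 1]
        into_m = np.maximum(
            np.maximum(pM[:M] + lt[:M, _M, _M], pI[:M] + lt[:M, _I, _M]),
            pD[:M] + lt[:M, _D, _M],
        )
        vM[j, 1:] = lm[:, c] + into_m
        vI[j] = li[:, c] + np.maximum(
            np.maximum(pM + lt[:, _M, _I], pI + lt[:, _I, _I]),
            pD + lt[:, _D, _I],
        )
        vD[j] = _viterbi_scan_delete(vM[j], vI[j], lt, S, M)

    finals = np.array([
        vM[L, M] + lt[M, _M, _M],
        vD[L, M] + lt[M, _D, _M],
        vI[L, M] + lt[M, _I, _M],
    ])  # preference order M, D, I
    best = int(np.argmax(finals))
    log_prob = float(finals[best])
    cur_type = ("M", "D", "I")[best]

    # traceback, recomputing local argmaxes with the M > D > I preference
    path: list[tuple[str, int]] = []
    j, k = L, M
    vals = {"M": vM, "I": vI, "D": vD}
    while not (j == 0 and k == 0 and cur_type == "M"):
        path.append((cur_type, k))
        if cur_type == "M":
            pj, pk, dst = j - 1, k - 1, _M
        elif cur_type == "I":
            pj, pk, dst = j - 1, k, _I
        else:
            pj, pk, dst = j, k - 1, _D
        if pj == 0 and pk == 0:
            # predecessor can only be begin (M_0) or I_0/D chain start
            cand = [
                ("M", vals["M"][pj, pk] + lt[pk, _M, dst]),
                ("I", vals["I"][pj, pk] + lt[pk, _I, dst]),
            ]
        else:
            cand = [
                ("M", vals["M"][pj, pk] + lt[pk, _M, dst]),
                ("D", vals["D"][pj, pk] + lt[pk, _D, dst]),
                ("I", vals["I"][pj, pk] + lt[pk, _I, dst]),
            ]
        best_val = max(v for _, v in cand)
        for name, v in cand:
            if v == best_val:
                cur_type = name
                break
        j, k = pj, pk
    path.reverse()
    emitted = sum(1 for t, _ in path if t in ("M", "I"))
    if emitted != L:
        raise ProfileHMMError("traceback emitted-count mismatch")
    score_bits = (log_prob - _background_logprob(model, x)) / LN2
    return AlignmentPath(states=path, log_prob=log_prob, score_bits=score_bits)


def viterbi_scores_batch(model: ProfileHMM, windows: np.ndarray) -> np.ndarray:
    """Viterbi log probabilities (nats) for a batch of equal-length windows.

    ``windows`` is (B, L) of encoded residues. Used by the genome scanner;
    no traceback is produced.
    """
    B, L = windows.shape
    M = model.M
    lm, li, lt = _log_tables(model)
    S = _delete_prefix_sums(lt, M)
    vM = np.full((B, M + 1), -np.inf)
    vI = np.full((B, M + 1), -np.inf)
    vM[:, 0] = 0.0

    def scan_delete(vm, vi):
        entry = np.maximum(vm[:, :M] + lt[:M, _M, _D], vi[:, :M] + lt[:M, _I, _D])
        acc = np.maximum.accumulate(entry - S, axis=1)
        out = np.full((B, M + 1), -np.inf)
        out[:, 1:] = S + acc
        return out

    vD = scan_delete(vM, vI)
    for j in range(L):
        c = windows[:, j]
        into_m = np.maximum(
            np.maximum(vM[:, :M] + lt[:M, _M, _M], vI[:, :M] + lt[:M, _I, _M]),
            vD[:, :M] + lt[:M, _D, _M],
        )
        new_M = np.full((B, M + 1), -np.inf)
        new_M[:, 1:] = lm[:, c].T + into_m
        new_I = li[:, c].T + np.maximum(
            np.maximum(vM + lt[:, _M, _I], vI + lt[:, _I, _I]),
            vD + lt[:, _D, _I],
        )
        vM, vI = new_M, new_I
        vD = scan_delete(vM, vI)
    return np.maximum(
        np.maximum(vM[:, M] + lt[M, _M, _M], vI[:, M] + lt[M, _I, _M]),
        vD[:, M] + lt[M, _D, _M],
    )


def log_odds_score(model: ProfileHMM, seq: SequenceRecord | str) -> float:
    """Viterbi log probability minus background log probability, in bits."""
    return viterbi(model, seq).score_bits


def mean_test_score(model: ProfileHMM, test_seqs: Sequence) -> float:
    """Arithmetic mean of per-sequence log-odds scores over a held-out set."""
    if not test_seqs:
        raise ValueError("mean_test_score requires at least one sequence")
    return float(np.mean([log_odds_score(model, s) for s in test_seqs]))


# ---------------------------------------------------------------------------
# Baum-Welch training
# ---------------------------------------------------------------------------

def _expected_counts(model: ProfileHMM, x: np.ndarray):
    """One E-step: expected emission and transition counts for a sequence."""
    M, L = model.M, len(x)
    lm, li, lt = _log_tables(model)
    fM, fI, fD, ll = _forward_matrices(model, x)
    bM, bI, bD = _backward_matrices(model, x)

    cm = np.zeros((M, 4))
    ci = np.zeros((M + 1, 4))
    ct = np.zeros((M + 1, 3, 3))
    if L > 0:
        postM = np.exp(fM[1:, 1:] + bM[1:, 1:] - ll)   # (L, M)
        postI = np.exp(fI[1:, :] + bI[1:, :] - ll)     # (L, M+1)
        for a in range(4):
            sel = x == a
            if sel.any():
                cm[:, a] += postM[sel].sum(axis=0)
                ci[:, a] += postI[sel].sum(axis=0)
        selN = x == 4
        if selN.any():
            cm += postM[selN].sum(axis=0)[:, None] * 0.25
            ci += postI[selN].sum(axis=0)[:, None] * 0.25

        E = lm[:, x].T    # (L, M): emission of x[j] by M_{k+1}
        EI = li[:, x].T   # (L, M+1)
        for s, fS in ((_M, fM), (_I, fI), (_D, fD)):
            # -> match (incl. next-residue emission), k = 0..M-1
            A = fS[:L, :M] + lt[:M, s, _M] + E + bM[1:, 1:]
            ct[:M, s, _M] += np.exp(A - ll).sum(axis=0)
            # -> end
            ct[M, s, _M] += math.exp(min(fS[L, M] + lt[M, s, _M] - ll, 0.0))
            # -> insert, k = 0..M
            A = fS[:L, :] + lt[:, s, _I] + EI + bI[1:, :]
            ct[:, s, _I] += np.exp(A - ll).sum(axis=0)
            # -> delete, k = 0..M-1, any consumed count j = 0..L
            A = fS[:, :M] + lt[:M, s, _D] + bD[:, 1:]
            ct[:M, s, _D] += np.exp(A - ll).sum(axis=0)
    else:
        # empty sequence: pure delete chain
        for s, fS in ((_M, fM), (_I, fI), (_D, fD)):
            ct[M, s, _M] += math.exp(min(fS[0, M] + lt[M, s, _M] - ll, 0.0))
            A = fS[0, :M] + lt[:M, s, _D] + bD[0, 1:]
            ct[:M, s, _D] += np.exp(A - ll)
    return cm, ci, ct, ll


def train_baum_welch(
    model: ProfileHMM,
    seqs: Sequence[SequenceRecord],
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int | None = None,
) -> tuple[ProfileHMM, list[float]]:
    """Expectation-maximisation training of a profile HMM.

    Returns the trained model and the per-iteration total log-likelihood
    trace (natural log, evaluated before each parameter update), which is
    non-decreasing up to the tiny perturbation of the pseudocount floor.
    ``seed`` is recorded in the model metadata; the EM itself is
    deterministic given the initial model.
    """
    if not seqs:
        raise ValueError("training set must be non-empty")
    encoded = [encode(s.residues if hasattr(s, "residues") else s) for s in seqs]
    if all(len(x) == 0 for x in encoded):
        raise ValueError("training set contains only empty sequences")
    if len(encoded) < 2:
        raise ValueError("training requires at least 2 sequences")
    model.validate()
    M = model.M
    pc = model.pseudocount
    mask = transition_mask(M)
    cur = model
    trace: list[float] = []
    for _ in range(max_iter):
        cm = np.zeros((M, 4))
        ci = np.zeros((M + 1, 4))
        ct = np.zeros((M + 1, 3, 3))
        total_ll = 0.0
        for x in encoded:
            dcm, dci, dct, ll = _expected_counts(cur, x)
            if not np.isfinite(ll):
                raise ProfileHMMError("sequence has -inf likelihood under model")
            cm += dcm
            ci += dci
            ct += dct
            total_ll += ll
        trace.append(total_ll)
        match = _normalise_rows(cm + pc)
        insert = _normalise_rows(ci + pc)
        trans = np.zeros_like(ct)
        for k in range(M + 1):
            for s in range(3):
                row_mask = mask[k, s]
                if not row_mask.any():
                    continue
                row = (ct[k, s] + pc) * row_mask
                trans[k, s] = row / row.sum()
        new = ProfileHMM(
            M=M,
            match_emissions=match,
            insert_emissions=insert,
            transitions=trans,
            background=cur.background.copy(),
            pseudocount=pc,
            model_id=cur.model_id,
            metadata=dict(cur.metadata, train_seed=seed),
        )
        new.validate()
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            cur = new
            break
        cur = new
    cur.metadata["loglik_trace_len"] = len(trace)
    return cur, trace


def _normalise_rows(rows: np.ndarray) -> np.ndarray:
    return rows / rows.sum(axis=1, keepdims=True)


def emit_sequences(
    model: ProfileHMM, n: int, seed: int, id_prefix: str = "sample"
) -> list[SequenceRecord]:
    """Sample n sequences i.i.d. from the model's generative process."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        residues = []
        k, state = 0, _M  # begin
        while True:
            probs = model.transitions[k, state]
            dst = rng.choice(3, p=probs / probs.sum())
            if dst == _M:
                if k == model.M:
                    break  # end
                k += 1
                residues.append(_RESIDUES[rng.choice(4, p=model.match_emissions[k - 1])])
                state = _M
            elif dst == _I:
                residues.append(_RESIDUES[rng.choice(4, p=model.insert_emissions[k])])
                state = _I
            else:
                k += 1
                state = _D
        out.append(SequenceRecord(f"{id_prefix}_{i}", "".join(residues)))
    return out
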