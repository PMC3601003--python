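"""Independent oracles used across the suite.

These deliberately avoid the package's dynamic programming and tree code:
path enumeration is a plain recursion over legal state paths, and additive
distance matrices come from explicit path sums over a randomly built tree.
"""

from __future__ import annotations

import math

import numpy as np

from ltrhmm.hmm_core import ProfileHMM, encode, transition_mask, init_profile


def enumerate_paths(model: ProfileHMM, seq: str):
    """All legal begin->end state paths emitting ``seq`` with log probs."""
    x = encode(seq)
    L, M = len(x), model.M
    t = model.transitions
    me, ie = model.match_emissions, model.insert_emissions
    results = []

    def rec(k, state, j, lp, path):
        for dst in range(3):
            p = t[k, state, dst]
            if p <= 0:
                continue
            lp2 = lp + math.log(p)
            if dst == 0:  # to M_{k+1} / end
                if k == M:
                    if j == L:
                        results.append((tuple(path), lp2))
                    continue
                if j < L:
                    e = 0.25 if x[j] == 4 else me[k, x[j]]
                    rec(k + 1, 0, j + 1, lp2 + math.log(e), path + [("M", k + 1)])
            elif dst == 1:  # to I_k
                if j < L:
                    e = 0.25 if x[j] == 4 else ie[k, x[j]]
                    rec(k, 1, j + 1, lp2 + math.log(e), path + [("I", k)])
            else:  # to D_{k+1}
                if k < M:
                    rec(k + 1, 2, j, lp2, path + [("D", k + 1)])

    rec(0, 0, 0, 0.0, [])
    return results


def random_model(rng, M: int) -> ProfileHMM:
    """A fully random (valid) profile for oracle comparisons."""
    m = init_profile(M, seed=int(rng.integers(2**31)))
    m.match_emissions = rng.dirichlet(np.ones(4), size=M)
    m.insert_emissions = rng.dirichlet(np.ones(4), size=M + 1)
    mask = transition_mask(M)
    for k in range(M + 1):
        for s in range(3):
            if mask[k, s].any():
                row = rng.dirichlet(np.ones(int(mask[k, s].sum())))
                m.transitions[k, s] = 0.0
                m.transitions[k, s][mask[k, s]] = row
    m.validate()
    return m


def brute_force_motif_positions(target: str, members_per_letter) -> list[int]:
    """Position-by-position IUPAC matching without regular expressions."""
    pattern_sets = members_per_letter
    hits = []
    n, m = len(target), len(pattern_sets)
    for i in range(n - m + 1):
        if all(target[i + j] in pattern_sets[j] for j in range(m)):
            hits.append(i)
    return hits


def random_additive_tree(rng, n_leaves: int):
    """A random unrooted binary tree and its exact additive distance matrix.

    Returns (names, D, splits) where splits is the set of non-trivial
    bipartitions, each canonicalised as the (smaller, lexicographically
    first) frozenset of leaf names.
    """
    names = [f"t{i}" for i in range(n_leaves)]
    idx = {n: i for i, n in enumerate(names)}
    D = np.zeros((n_leaves, n_leaves))
    # subtrees as (leafset, dict leaf -> distance to the subtree's junction);
    # cross-subtree distances are fixed at merge time, when the path through
    # the new junction is determined.
    nodes = [({n}, {n: 0.0}) for n in names]
    splits = []
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (si, di), (sj, dj) = nodes[i], nodes[j]
        bi = float(rng.uniform(0.05, 1.0))
        bj = float(rng.uniform(0.05, 1.0))
        for x in si:
            for y in sj:
                d = di[x] + bi + bj + dj[y]
                D[idx[x], idx[y]] = D[idx[y], idx[x]] = d
        merged = si | sj
        dist = {k: v + bi for k, v in di.items()}
        dist.update({k: v + bj for k, v in dj.items()})
        if len(merged) >= 2 and n_leaves - len(merged) >= 2:
            splits.append(frozenset(merged))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((merged, dist))
    (sa, da), (sb, db) = nodes
    edge = float(rng.uniform(0.05, 1.0))
    for x in sa:
        for y in sb:
            D[idx[x], idx[y]] = D[idx[y], idx[x]] = da[x] + edge + db[y]
    all_names = frozenset(names)

    def canon(s):
        s = frozenset(s)
        o = all_names - s
        return min(s, o, key=lambda t: (len(t), tuple(sorted(t))))

    canon_splits = {canon(s) for s in splits if 2 <= len(s) <= n_leaves - 2}
    return names, D, canon_splits
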