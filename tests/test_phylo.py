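import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import random_additive_tree
from ltrhmm.hmm_core import make_peaked_profile, emit_sequences
from ltrhmm.io_formats import SequenceRecord
from ltrhmm.phylo import (
    MSA,
    DistanceMatrix,
    bootstrap_support,
    build_super_hmm,
    neighbor_joining,
    p_distance,
    select_best_tree,
    superviterbi_align,
    _internal_bipartitions,
)
from ltrhmm.simulate import make_superfamily_system


def _msa(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return MSA(ids=ids, rows=list(rows), col_is_match=[True] * len(rows[0]))


class TestSuperViterbiAlign:
    def test_identical_inputs_align_identically(self, peaked_model):
        cons = "TGTTACAATAAAGTGGTGTAACA"
        recs = [SequenceRecord("a", cons), SequenceRecord("b", cons)]
        msa = superviterbi_align(peaked_model, recs)
        assert msa.rows[0] == msa.rows[1]
        assert msa.ids == ["a", "b"]

    def test_ungapping_recovers_inputs(self, peaked_model):
        recs = emit_sequences(peaked_model, 6, seed=3)
        msa = superviterbi_align(peaked_model, recs)
        for i, rec in enumerate(recs):
            assert msa.ungapped(i) == rec.residues
        assert len({len(r) for r in msa.rows}) == 1

    def test_match_columns_reproduce_generating_states(self):
        model = make_peaked_profile("TGTTACATTA", peak=0.995, match_stay=0.995)
        recs = emit_sequences(model, 5, seed=1)
        msa = superviterbi_align(model, recs)
        match_cols = [c for c, is_m in enumerate(msa.col_is_match) if is_m]
        assert len(match_cols) == model.M
        consensus_rows = [
            "".join(row[c] for c in match_cols) for row in msa.rows
        ]
        # most sampled rows equal the consensus on match columns
        frac = np.mean([r == "TGTTACATTA" for r in consensus_rows])
        assert frac >= 0.6


class TestPDistance:
    def test_known_values(self):
        msa = _msa(["ACGT", "ACGA"])
        assert p_distance(msa).values[0, 1] == pytest.approx(0.25)
        assert p_distance(_msa(["ACGT", "ACGT"])).values[0, 1] == 0.0
        assert p_distance(_msa(["AC-T", "ACGT"])).values[0, 1] == 0.0

    def test_complete_deletion_mode(self):
        msa = _msa(["AC-T", "ACGA"])
        pairwise = p_distance(msa, "pairwise").values[0, 1]
        complete = p_distance(msa, "complete").values[0, 1]
        assert pairwise == pytest.approx(1 / 3)
        assert complete == pytest.approx(1 / 3)

    def test_no_comparable_columns_names_pair(self):
        msa = _msa(["A---", "---T"], ids=["left", "right"])
        with pytest.raises(ValueError, match="left.*right"):
            p_distance(msa)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matrix_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(2, 6)), int(rng.integers(4, 20))
        rows = [
            "".join(rng.choice(list("ACGT-"), size=L, p=[0.22] * 4 + [0.12]))
            for _ in range(n)
        ]
        try:
            d = p_distance(_msa(rows))
        except ValueError:
            return  # a pair without comparable columns is a legal rejection
        v = d.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0)
        assert ((v >= 0) & (v <= 1)).all()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dab, dac, dbc = 0.3, 0.5, 0.6
        D = DistanceMatrix(ids=list("ABC"), values=np.array([
            [0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]]))
        tree = neighbor_joining(D)
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths["A"] == pytest.approx((dab + dac - dbc) / 2)
        assert lengths["B"] == pytest.approx((dab + dbc - dac) / 2)
        assert lengths["C"] == pytest.approx((dac + dbc - dab) / 2)

    def test_four_taxon_additive_recovery(self):
        # ((A,B),(C,D)) with every branch length 1
        D = DistanceMatrix(ids=list("ABCD"), values=np.array([
            [0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float))
        tree = neighbor_joining(D)
        assert frozenset("AB") in tree.bipartitions() or frozenset("CD") in tree.bipartitions()
        tt = tree.root.tip_tip_distances()
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert tt[a, b] == pytest.approx(D.values[i, j], abs=1e-9)

    def test_small_perturbation_keeps_topology(self):
        base = np.array([
            [0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float)
        pert = base.copy()
        pert[0, 2] = pert[2, 0] = base[0, 2] * 1.05
        tree = neighbor_joining(DistanceMatrix(ids=list("ABCD"), values=base / 3))
        tree2 = neighbor_joining(DistanceMatrix(ids=list("ABCD"), values=pert / 3.2))
        assert tree.bipartitions() == tree2.bipartitions()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2))))

    def test_random_additive_trees_recovered_exactly(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            names, D, splits = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(ids=names, values=D / (D.max() + 1)))
            assert tree.bipartitions() == splits
            tt = tree.root.tip_tip_distances()
            for i, a in enumerate(names):
                for j, b in enumerate(names):
                    assert tt[a, b] * (D.max() + 1) == pytest.approx(
                        D[i, j], abs=1e-8)


class TestBootstrap:
    def _two_clade_msa(self, seed=0, L=200, within=0.02, between=0.4, n=6):
        rng = np.random.default_rng(seed)
        root = rng.choice(list("ACGT"), size=L)

        def mutate(parent, rate):
            child = parent.copy()
            hit = rng.random(L) < rate
            for i in np.nonzero(hit)[0]:
                child[i] = rng.choice([c for c in "ACGT" if c != parent[i]])
            return child

        anc1, anc2 = mutate(root, between / 2), mutate(root, between / 2)
        rows, ids = [], []
        for c, anc in ((0, anc1), (1, anc2)):
            for i in range(n // 2):
                rows.append("".join(mutate(anc, within / 2)))
                ids.append(f"c{c}_t{i}")
        return MSA(ids=ids, rows=rows, col_is_match=[True] * L)

    def test_clean_separation_gets_full_support(self):
        msa = self._two_clade_msa(seed=5)
        tree = bootstrap_support(msa, n_replicates=100, seed=11)
        clade = frozenset(i for i in msa.ids if i.startswith("c0"))
        other = frozenset(msa.ids) - clade
        canon = min(clade, other, key=lambda s: (len(s), tuple(sorted(s))))
        assert tree.supports[canon] == 100.0
        assert 0 <= tree.mean_bootstrap <= 100

    def test_seeded_determinism(self):
        msa = self._two_clade_msa(seed=6)
        a = bootstrap_support(msa, n_replicates=50, seed=3)
        b = bootstrap_support(msa, n_replicates=50, seed=3)
        assert a.supports == b.supports

    def test_single_replicate_supports_are_binary(self):
        msa = self._two_clade_msa(seed=7)
        tree = bootstrap_support(msa, n_replicates=1, seed=4)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_leaf_order_permutation_invariance(self):
        msa = self._two_clade_msa(seed=8)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(msa.ids))
        shuffled = MSA(ids=[msa.ids[i] for i in perm],
                       rows=[msa.rows[i] for i in perm],
                       col_is_match=msa.col_is_match)
        a = bootstrap_support(msa, n_replicates=50, seed=9)
        b = bootstrap_support(shuffled, n_replicates=50, seed=9)
        clade = frozenset(i for i in msa.ids if i.startswith("c0"))
        canon = min(clade, frozenset(msa.ids) - clade,
                    key=lambda s: (len(s), tuple(sorted(s))))
        assert a.supports[canon] == b.supports[canon]


class TestSuperHMM:
    def test_requires_three_consensuses(self):
        recs = [SequenceRecord("a", "ACGTACGT"), SequenceRecord("b", "ACGTACGA")]
        with pytest.raises(ValueError):
            build_super_hmm(recs, M=8)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        recs = [
            SequenceRecord(f"c{i}", "".join(rng.choice(list("ACGT"), size=30)))
            for i in range(4)
        ]
        a = build_super_hmm(recs, M=30, z=0.05, seed=5, max_iter=8)
        b = build_super_hmm(recs, M=30, z=0.05, seed=5, max_iter=8)
        assert np.allclose(a.match_emissions, b.match_emissions)


class TestSelectBestTree:
    def test_grid_report_and_winner(self):
        fams, _ = make_superfamily_system(4, 0.4, 0.05, seed=31,
                                          n_per_family=8, core_length=60)
        tree, records = select_best_tree(
            fams, general_M_grid=[50, 70], z_grid=[0.0],
            consensus_M_grid=[60], n_replicates=30, seed=32, max_iter=10,
        )
        assert len(records) == 2
        ok = [r for r in records if not r.failed]
        assert tree.mean_bootstrap == pytest.approx(
            max(r.mean_bootstrap for r in ok))
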