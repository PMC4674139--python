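"""Constraint ranking, match rescoring and i-RMSD evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockmine import docking
from dockmine.docking import (
    Constraint,
    DockingMatch,
    irmsd,
    reference_constraints,
    rescore,
    residue_confidence,
    select_constraints,
    success_rate,
)


class TestConfidence:
    @pytest.mark.parametrize("n_and,n_or,expected", [
        (2, 1, 5),    # 2+2+1
        (0, 1, 1),    # minimal case
        (12, 0, 10),  # capped
        (5, 0, 10),   # exactly at the cap
        (4, 1, 9),
    ])
    def test_weighted_sum_with_cap(self, n_and, n_or, expected):
        assert residue_confidence(n_and, n_or) == expected

    def test_needs_at_least_one_abstract(self):
        with pytest.raises(ValueError):
            residue_confidence(0, 0)

    @given(st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_cap_and_monotonicity(self, n_and, n_or):
        if n_and + n_or == 0:
            return
        f = residue_confidence(n_and, n_or)
        assert 1 <= f <= 10
        assert f == min(10, 2 * n_and + n_or)


class TestSelectConstraints:
    def _c(self, num, conf, n_and=0, side=1):
        return Constraint(side, "A", num, "SER", conf, n_and=n_and)

    def test_top_five_by_confidence(self):
        cons = [self._c(i, conf) for i, conf in enumerate([3, 9, 1, 7, 5, 8, 2])]
        kept = select_constraints(cons, k=5)
        assert sorted(c.confidence for c in kept) == [3, 5, 7, 8, 9]

    def test_fewer_than_k_all_kept(self):
        cons = [self._c(i, 5) for i in range(3)]
        assert len(select_constraints(cons, k=5)) == 3

    def test_and_contributions_break_ties_at_cut(self):
        cons = [self._c(i, conf) for i, conf in enumerate([10, 9, 8, 7])]
        cons += [self._c(10, 6, n_and=2), self._c(11, 6, n_and=1), self._c(12, 6, n_and=0)]
        kept = select_constraints(cons, k=5, seed=0)
        tied_kept = [c for c in kept if c.confidence == 6]
        assert len(tied_kept) == 1 and tied_kept[0].n_and == 2

    def test_symmetric_ties_random_but_seeded(self):
        cons = [self._c(i, 6) for i in range(8)]
        a = select_constraints(cons, k=5, seed=1)
        b = select_constraints(cons, k=5, seed=1)
        assert [c.number for c in a] == [c.number for c in b]
        picks = {tuple(sorted(c.number for c in select_constraints(cons, k=5, seed=s)))
                 for s in range(30)}
        assert len(picks) > 1  # selection varies across seeds

    def test_per_side_independence(self):
        cons = [self._c(i, 9, side=1) for i in range(6)]
        cons += [self._c(i, 9, side=2) for i in range(2)]
        kept = select_constraints(cons, k=5)
        assert sum(1 for c in kept if c.side == 1) == 5
        assert sum(1 for c in kept if c.side == 2) == 2


class TestReferenceConstraints:
    def test_closest_ca_pair_first(self, toy):
        pairs = reference_constraints(toy.bound, ["A"], ["B"])
        assert len(pairs) == 3
        # verify against an all-pairs distance oracle
        i1, i2 = toy.interface_receptor, toy.interface_ligand
        best = None
        for r1 in (toy.bound.find(*rid) for rid in sorted(i1)):
            for r2 in (toy.bound.find(*rid) for rid in sorted(i2)):
                d = float(np.linalg.norm(r1.ca - r2.ca))
                if best is None or d < best[0]:
                    best = (d, r1.id, r2.id)
        c1, c2 = pairs[0]
        assert (c1.chain, c1.number, c1.icode) == (best[1][0], best[1][1], best[1][2])
        assert (c2.chain, c2.number, c2.icode) == (best[2][0], best[2][1], best[2][2])
        assert all(c.confidence == 10 for pair in pairs for c in pair)

    def test_small_interface_returns_fewer_pairs(self):
        from test_surface import _gly
        from dockmine.structures import Structure

        s = Structure([_gly("A", 1, (0, 0, 0)), _gly("B", 1, (0, 0, 5.0))])
        pairs = reference_constraints(s, ["A"], ["B"], n_pairs=3)
        assert len(pairs) == 1

    def test_tied_distances_stable_order(self):
        from test_surface import _gly
        from dockmine.structures import Structure

        # two exactly symmetric cross-chain pairs
        s = Structure([
            _gly("A", 1, (0, 0, 0)), _gly("A", 2, (20, 0, 0)),
            _gly("B", 1, (0, 0, 5.0)), _gly("B", 2, (20, 0, 5.0)),
        ])
        pairs = reference_constraints(s, ["A"], ["B"], n_pairs=2)
        ordered = [(c1.number, c2.number) for c1, c2 in pairs]
        assert ordered == [(1, 1), (2, 2)]  # lexicographic by (chain, number)


def _true_interface_constraints(toy):
    cons = []
    for side, iface in ((1, toy.interface_receptor), (2, toy.interface_ligand)):
        for rid in sorted(iface):
            res = toy.bound.find(*rid)
            cons.append(Constraint(side, res.chain, res.number, res.name, 10))
    return cons


class TestRescore:
    def test_near_native_ranked_first_with_true_constraints(self, toy):
        cons = _true_interface_constraints(toy)
        out = rescore(toy.matches, cons, toy.unbound_receptor, toy.unbound_ligand)
        assert out[0].rank == toy.near_native.rank
        assert out[0].tm_score > 0
        assert all(m.tm_score == 0 for m in out[1:])  # decoys share no constraints

    def test_no_constraints_preserves_scan_order(self, toy):
        out = rescore(toy.matches, [], toy.unbound_receptor, toy.unbound_ligand)
        assert [m.rank for m in out] == [m.rank for m in toy.matches]
        assert all(m.tm_score == 0 for m in out)

    def test_multiset_of_matches_unchanged(self, toy):
        cons = _true_interface_constraints(toy)
        out = rescore(toy.matches, cons, toy.unbound_receptor, toy.unbound_ligand)
        assert sorted(m.rank for m in out) == sorted(m.rank for m in toy.matches)

    def test_equal_scores_keep_scan_order(self, toy):
        out = rescore(toy.matches, [], toy.unbound_receptor, toy.unbound_ligand)
        assert [m.rank for m in out] == sorted(m.rank for m in out)

    def test_confidence_monotonicity(self, toy):
        """Raising a constraint's confidence never lowers the rank of a
        match containing it."""
        cons = _true_interface_constraints(toy)
        low = [Constraint(c.side, c.chain, c.number, c.aa, 1) for c in cons[:1]]
        high = [Constraint(c.side, c.chain, c.number, c.aa, 10) for c in cons[:1]]
        out_low = rescore(toy.matches, low, toy.unbound_receptor, toy.unbound_ligand)
        out_high = rescore(toy.matches, high, toy.unbound_receptor, toy.unbound_ligand)
        nn = toy.near_native.rank
        pos_low = [m.rank for m in out_low].index(nn)
        pos_high = [m.rank for m in out_high].index(nn)
        assert pos_high <= pos_low

    def test_malformed_pose_is_named_error(self, toy):
        bad = DockingMatch(rank=99, rotation=np.eye(2), translation=np.zeros(3))
        with pytest.raises(ValueError, match="99"):
            rescore([bad], _true_interface_constraints(toy),
                    toy.unbound_receptor, toy.unbound_ligand)


class TestIrmsd:
    def _args(self, toy):
        return (toy.bound, ["A"], ["B"], toy.unbound_receptor, toy.unbound_ligand)

    def test_near_native_is_near_zero(self, toy):
        r, n = irmsd(toy.near_native, *self._args(toy))
        assert r < 1.0
        assert n == len(toy.interface_ligand)

    def test_rigid_translation_gives_that_distance(self, toy):
        shifted = DockingMatch(
            rank=0,
            rotation=toy.near_native.rotation,
            translation=np.asarray(toy.near_native.translation) + np.array([3.0, 0, 0]),
        )
        r, _ = irmsd(shifted, *self._args(toy))
        assert r == pytest.approx(3.0, abs=0.05)

    def test_matches_direct_rmsd_oracle(self, toy):
        """For an arbitrary pose, i-RMSD equals a direct coordinate-wise
        RMSD computed independently over the interface Calphas."""
        rng = np.random.default_rng(5)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
        pose = DockingMatch(rank=0, rotation=rot, translation=rng.uniform(-20, 20, 3))
        r, _ = irmsd(pose, *self._args(toy))

        # oracle: build reference coordinates explicitly with two fits
        from dockmine.docking import kabsch

        b_rec_ca = toy.bound.ca_coords(["A"])
        u_rec_ca = toy.unbound_receptor.ca_coords()
        R1, t1 = kabsch(b_rec_ca, u_rec_ca)
        lig_u = toy.unbound_ligand
        b_lig = toy.bound.subset(["B"])
        u_ca = np.vstack([lig_u.find(*res.id).ca for res in b_lig.residues()])
        R2, t2 = kabsch(u_ca, b_lig.ca_coords())
        diffs = []
        for rid in sorted(toy.interface_ligand):
            ca_u = lig_u.find(*rid).ca
            ref = R1 @ (R2 @ ca_u + t2) + t1
            docked = rot @ ca_u + np.asarray(pose.translation)
            diffs.append(((docked - ref) ** 2).sum())
        oracle = float(np.sqrt(np.mean(diffs)))
        assert r == pytest.approx(oracle, abs=1e-6)

    def test_decoys_are_far(self, toy):
        for decoy in toy.decoys[:5]:
            r, _ = irmsd(decoy, *self._args(toy))
            assert r > 10.0


class TestSuccessRate:
    def test_boundaries_inclusive(self):
        ranked = [20.0] * 9 + [4.9]  # rank 10 exactly at 5 Å threshold
        assert success_rate([ranked], "strict") == 100.0
        assert success_rate([[5.1] + [20.0] * 9], "strict") == 0.0

    def test_relaxed_window(self):
        ranked = [20.0] * 99 + [8.0]
        assert success_rate([ranked], "relaxed") == 100.0
        assert success_rate([[8.2] * 200], "relaxed") == 0.0

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(0)
        cohort = []
        planted = 0
        for i in range(40):
            if rng.random() < 0.4:
                planted += 1
                ranked = [3.0] + list(rng.uniform(10, 40, 30))
            else:
                ranked = list(rng.uniform(10, 40, 31))
            cohort.append(ranked)
        assert success_rate(cohort, "strict") == pytest.approx(100.0 * planted / 40)


class TestPoseIO:
    def test_roundtrip(self, toy, tmp_path):
        path = tmp_path / "poses.tsv"
        docking.write_matches(toy.matches, path)
        back = docking.read_matches(path)
        assert [m.rank for m in back] == [m.rank for m in toy.matches]
        assert np.allclose(back[-1].rotation, toy.near_native.rotation, atol=1e-5)

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1 0.0 0.0\n")
        with pytest.raises(ValueError, match="malformed"):
            docking.read_matches(path)
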