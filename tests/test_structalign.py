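"""Superposition, TM-score, and the heuristic alignment search."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from phagescan import structalign as sa
from phagescan import synthetic_data as sd
from phagescan.structalign import (all_vs_all, kabsch_superpose,
                                   structure_align, tm_d0, tm_from_pairs)


def oracle_kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Brute-force minimal RMSD: Euler-angle grid + Nelder-Mead refinement.

    Independent of the SVD route: parameterizes rotation by ZYX Euler
    angles and minimizes numerically (translation handled by centering).
    """
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_of(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return float(np.sqrt((((Pc @ R.T) - Qc) ** 2).sum() / len(P)))

    best = np.inf
    grid = np.deg2rad(np.arange(0, 360, 60))
    for a in grid:
        for b in np.deg2rad(np.arange(-90, 91, 45)):
            for c in grid:
                res = minimize(rmsd_of, x0=[a, b, c], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 2000})
                best = min(best, res.fun)
    return best


def oracle_tm(query, target, pairs, L_norm, n_rot=300, seed=0) -> float:
    """Dense rotation sampling + close-subset Kabsch refinement."""
    qi = np.array([p[0] for p in pairs])
    ti = np.array([p[1] for p in pairs])
    P, Q = query.coords[qi], target.coords[ti]
    d0 = tm_d0(L_norm)
    cutoff = max(2 * d0, 4.5)
    Pc = P - P.mean(axis=0)
    Qm = Q.mean(axis=0)

    def tm_of(R, t):
        d2 = ((P @ R.T + t - Q) ** 2).sum(axis=1)
        return (1 / (1 + d2 / d0 ** 2)).sum() / L_norm

    best = -1.0
    rots = Rotation.random(n_rot, rng=np.random.default_rng(seed))
    for R in rots.as_matrix():
        t = Qm - R @ P.mean(axis=0)
        tm = tm_of(R, t)
        # refine by iterating Kabsch on the close subset
        for _ in range(30):
            d = np.linalg.norm(P @ R.T + t - Q, axis=1)
            sel = d < cutoff
            if sel.sum() < 3:
                break
            R, t, _ = kabsch_superpose(P[sel], Q[sel])
            tm_new = tm_of(R, t)
            if tm_new <= tm + 1e-9:
                tm = max(tm, tm_new)
                break
            tm = tm_new
        best = max(best, tm)
    return best


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, 0, atol=1e-12)
        assert rmsd == pytest.approx(0, abs=1e-12)

    def test_exact_recovery_of_random_rigid_transform(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        R0 = Rotation.random(rng=rng).as_matrix()
        t0 = rng.normal(size=3)
        Q = P @ R0.T + t0
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0, abs=1e-9)
        np.testing.assert_allclose(R, R0, atol=1e-9)
        np.testing.assert_allclose(t, t0, atol=1e-9)

    def test_matches_euler_grid_oracle_on_noisy_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            P = rng.normal(size=(8, 3))
            Q = P @ Rotation.random(rng=rng).as_matrix().T \
                + rng.normal(size=3) + rng.normal(scale=0.3, size=(8, 3))
            _, _, rmsd = kabsch_superpose(P, Q)
            assert rmsd == pytest.approx(oracle_kabsch_rmsd(P, Q), abs=1e-6)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            R, _, _ = kabsch_superpose(P, Q)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_degenerate_still_returns_minimizer(self):
        P = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        Q = np.stack([np.zeros(5), np.arange(5.0), np.zeros(5)], axis=1)
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        bad = np.full((4, 3), np.nan)
        with pytest.raises(ValueError):
            kabsch_superpose(bad, np.zeros((4, 3)))


class TestD0:
    def test_closed_form_at_100(self):
        # 1.24 * 85**(1/3) - 1.8, evaluated independently
        assert tm_d0(100) == pytest.approx(3.652, abs=1e-3)

    def test_floor_engaged_for_short_chains(self):
        assert tm_d0(15) == 0.5
        assert tm_d0(21) == 0.5  # 1.24*6^(1/3)-1.8 = 0.453 < 0.5
        assert tm_d0(22) > 0.5

    def test_monotone_non_decreasing(self):
        vals = [tm_d0(L) for L in range(1, 501)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestTmFromPairs:
    def test_identity_pairs_identical_structures(self):
        m = sd.gen_fold("helix_hairpin", 50, seed=1)
        pairs = [(i, i) for i in range(50)]
        tm, rmsd, R, t, trace = tm_from_pairs(m, m, pairs, 50)
        assert tm == pytest.approx(1.0, abs=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_tm_one(self):
        m = sd.gen_fold("helix", 40, seed=2)
        m2 = sd.perturb_structure(m, sigma=0.0, rigid=True, seed=3)
        pairs = [(i, i) for i in range(40)]
        tm, _, _, _, _ = tm_from_pairs(m, m2, pairs, 40)
        assert tm == pytest.approx(1.0, abs=1e-9)

    def test_running_best_is_monotone(self):
        m = sd.gen_fold("helix", 40, seed=4)
        m2 = sd.perturb_structure(m, sigma=1.5, rigid=True, seed=5)
        pairs = [(i, i) for i in range(40)]
        _, _, _, _, trace = tm_from_pairs(m, m2, pairs, 40)
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_matches_dense_sampling_oracle(self):
        m = sd.gen_fold("helix", 40, seed=6)
        m2 = sd.perturb_structure(m, sigma=1.0, rigid=True, seed=7)
        pairs = [(i, i) for i in range(40)]
        tm, _, _, _, _ = tm_from_pairs(m, m2, pairs, 40)
        assert tm == pytest.approx(oracle_tm(m, m2, pairs, 40), abs=0.02)

    def test_too_few_pairs_error(self):
        m = sd.gen_fold("helix", 12, seed=8)
        with pytest.raises(ValueError):
            tm_from_pairs(m, m, [(0, 0), (1, 1)], 12)


class TestStructureAlign:
    @pytest.mark.parametrize("arch", sd.ARCHETYPES)
    def test_self_alignment_identity(self, arch):
        m = sd.gen_fold(arch, 40, seed=11)
        aln = structure_align(m, m)
        assert aln.tm_query == pytest.approx(1.0, abs=1e-6)
        assert aln.tm_target == pytest.approx(1.0, abs=1e-6)
        assert aln.rmsd == pytest.approx(0.0, abs=1e-6)
        assert aln.pairs == [(i, i) for i in range(40)]

    def test_rigid_invariance_of_tm(self):
        a = sd.gen_fold("helix_hairpin", 50, seed=12)
        b = sd.perturb_structure(a, sigma=1.0, rigid=False, seed=13)
        base = structure_align(a, b)
        b_moved = sd.perturb_structure(b, sigma=0.0, rigid=True, seed=14)
        moved = structure_align(a, b_moved)
        assert moved.tm_query == pytest.approx(base.tm_query, abs=1e-6)
        assert moved.tm_target == pytest.approx(base.tm_target, abs=1e-6)
        assert moved.tm_shorter == pytest.approx(base.tm_shorter, abs=1e-6)

    def test_truncated_rigid_copy_recovered(self):
        a = sd.gen_fold("helix_hairpin", 60, seed=15)
        trunc = sd.StructureModel("trunc", a.coords[:55].copy(),
                                  a.residues[:55])
        moved = sd.perturb_structure(trunc, sigma=0.0, rigid=True, seed=16)
        aln = structure_align(moved, a)
        assert aln.tm_shorter >= 0.95
        # verify against the TM of the known planted correspondence
        planted = [(i, i) for i in range(55)]
        tm_planted, _, _, _, _ = tm_from_pairs(moved, a, planted, 55)
        assert aln.tm_shorter >= tm_planted - 0.02

    def test_cross_archetype_below_similarity_call(self):
        helix = sd.gen_fold("helix", 60, seed=17)
        strand = sd.gen_fold("strand", 60, seed=18)
        aln = structure_align(helix, strand)
        assert aln.tm_shorter < 0.6

    def test_pairs_strictly_increasing_and_rotation_proper(self):
        a = sd.gen_fold("helix_hairpin", 48, seed=19)
        b = sd.perturb_structure(a, sigma=1.2, rigid=True, seed=20)
        aln = structure_align(a, b)
        qs = [p[0] for p in aln.pairs]
        ts = [p[1] for p in aln.pairs]
        assert qs == sorted(qs) and len(set(qs)) == len(qs)
        assert ts == sorted(ts) and len(set(ts)) == len(ts)
        np.testing.assert_allclose(aln.rotation @ aln.rotation.T, np.eye(3),
                                   atol=1e-9)
        assert np.linalg.det(aln.rotation) == pytest.approx(1.0, abs=1e-9)
        assert aln.tm_shorter in (aln.tm_query, aln.tm_target)

    def test_deterministic(self):
        a = sd.gen_fold("coil", 45, seed=21)
        b = sd.gen_fold("coil", 45, seed=22)
        a1 = structure_align(a, b)
        a2 = structure_align(a, b)
        assert a1.pairs == a2.pairs
        assert a1.tm_shorter == a2.tm_shorter


class TestAllVsAll:
    def test_identical_models_all_tm_one(self):
        base = sd.gen_fold("helix", 30, seed=23)
        models = [sd.StructureModel(f"m{i}", base.coords.copy(),
                                    base.residues) for i in range(3)]
        alns = all_vs_all(models)
        assert len(alns) == 3
        assert all(a.tm_shorter == pytest.approx(1.0, abs=1e-6) for a in alns)

    def test_pair_count_and_ordering(self):
        models = [sd.gen_fold("coil", 30, seed=s) for s in range(24, 28)]
        alns = all_vs_all(models)
        assert len(alns) == 6
        assert all(a.query_id < a.target_id for a in alns)

    def test_same_archetype_pair_is_the_unique_similar_pair(self):
        a1 = sd.gen_fold("helix_hairpin", 50, seed=30)
        a2 = sd.perturb_structure(a1, sigma=0.8, rigid=True, seed=31)
        a2 = sd.StructureModel("hp_twin", a2.coords, a2.residues)
        b = sd.gen_fold("helix", 50, seed=32)
        c = sd.gen_fold("strand", 50, seed=33)
        alns = all_vs_all([a1, a2, b, c])
        similar = {(a.query_id, a.target_id) for a in alns
                   if a.tm_shorter > 0.6}
        assert similar == {tuple(sorted((a1.protein_id, "hp_twin")))}

    def test_matrix_view(self):
        models = [sd.gen_fold("helix", 30, seed=40),
                  sd.gen_fold("strand", 30, seed=41)]
        mat = sa.tm_matrix(all_vs_all(models))
        assert mat.shape == (2, 2)
        assert (mat.values.T == mat.values).all()
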