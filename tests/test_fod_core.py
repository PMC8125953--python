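from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oildrop.errors import ConfigurationError, DegenerateGeometryError
from oildrop.fod_core import (
    contact_weight,
    hydro_profile,
    kl_divergence,
    o_distribution,
    orient_and_fit,
    rd_score,
    t_distribution,
)

from conftest import make_unit
from oracles import brute_envelope_sigma, brute_kl, brute_o


def rigid_transform(coords, rng):
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    shift = rng.uniform(-50, 50, size=3)
    return np.asarray(coords) @ rot.T + shift


class TestEnvelope:
    def test_octahedron_sigma(self):
        pts = [(3, 0, 0), (-3, 0, 0), (0, 3, 0), (0, -3, 0), (0, 0, 3), (0, 0, -3)]
        env = orient_and_fit(make_unit(pts))
        assert np.allclose(env.center, 0.0)
        assert np.allclose(sorted(env.sigma), [1.0, 1.0, 1.0])

    def test_rigid_motion_leaves_sigma(self, rng):
        coords = rng.normal(scale=8.0, size=(40, 3))
        env1 = orient_and_fit(make_unit(coords))
        env2 = orient_and_fit(make_unit(rigid_transform(coords, rng)))
        assert np.allclose(env1.sigma, env2.sigma, atol=1e-6)

    def test_matches_brute_oracle(self, rng):
        coords = rng.normal(scale=10.0, size=(50, 3))
        env = orient_and_fit(make_unit(coords))
        assert np.allclose(np.sort(env.sigma), np.sort(brute_envelope_sigma(coords)), atol=1e-9)

    def test_rotation_is_proper_orthonormal(self, rng):
        coords = rng.normal(scale=5.0, size=(20, 3))
        env = orient_and_fit(make_unit(coords))
        assert np.allclose(env.rotation @ env.rotation.T, np.eye(3), atol=1e-10)
        assert np.isclose(np.linalg.det(env.rotation), 1.0)

    def test_coincident_points_rejected(self):
        unit = make_unit([(1, 1, 1)] * 5)
        with pytest.raises(DegenerateGeometryError):
            orient_and_fit(unit)


class TestTDistribution:
    def test_two_symmetric_residues_split_evenly(self):
        unit = make_unit([(-4, 0, 0), (4, 0, 0)])
        env = orient_and_fit(unit)
        assert np.allclose(t_distribution(unit, env), [0.5, 0.5])

    def test_center_vs_three_sigma_ratio(self):
        # residue at center vs residue at 3 sigma along x: raw ratio exp(0):exp(-4.5)
        unit = make_unit([(0, 0, 0), (6, 0, 0), (-6, 0, 0)])
        env = orient_and_fit(unit)  # sigma_x = 6/3 = 2
        t = t_distribution(unit, env)
        assert np.isclose(t[1] / t[0], np.exp(-4.5), rtol=1e-9)

    def test_normalized(self, rng):
        unit = make_unit(rng.normal(scale=6.0, size=(25, 3)))
        t = t_distribution(unit, orient_and_fit(unit))
        assert np.isclose(t.sum(), 1.0, atol=1e-9)
        assert np.all(t > 0)


class TestODistribution:
    def test_weight_endpoints(self):
        assert contact_weight(0.0) == 1.0
        assert np.isclose(contact_weight(1.0), 0.0, atol=1e-12)
        assert contact_weight(1.5) == 0.0

    def test_two_identical_residues_split_evenly(self):
        unit = make_unit([(0, 0, 0), (5, 0, 0)], hydro=[0.3, 0.3])
        assert np.allclose(o_distribution(unit), [0.5, 0.5])

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(-8, 8, size=(4, 3))
        hydro = np.array([0.1, 0.9, 0.4, 0.7])
        unit = make_unit(coords, hydro)
        got = o_distribution(unit)
        raw = brute_o(coords, hydro)
        assert np.allclose(got, raw / raw.sum(), atol=1e-12)

    def test_no_contacts_falls_back_to_uniform(self):
        unit = make_unit([(0, 0, 0), (50, 0, 0), (0, 50, 0)])
        with pytest.warns(UserWarning, match="uniform"):
            o = o_distribution(unit)
        assert np.allclose(o, 1 / 3)

    def test_negative_cutoff_rejected(self):
        unit = make_unit([(0, 0, 0), (5, 0, 0)])
        with pytest.raises(ConfigurationError):
            o_distribution(unit, cutoff_c=-1.0)


class TestKLDivergence:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == 0.0

    def test_closed_form_two_point(self):
        expected = 0.75 * np.log2(1.5) + 0.25 * np.log2(0.5)
        assert np.isclose(kl_divergence([0.75, 0.25], [0.5, 0.5]), expected, atol=1e-15)

    def test_gibbs_inequality_and_oracle_agreement(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            d = kl_divergence(p, q)
            assert d >= 0.0
            assert np.isclose(d, brute_kl(p, q), atol=1e-12)

    def test_zero_in_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])


class TestRDScore:
    # Two concentric square rings (outer radius 10 Å, inner 3.5 Å, rotated
    # 45°).  By symmetry T and O are constant on each ring, so a single
    # hydrophobicity unknown (solved with the independent brute-force
    # weight matrix) pins the two-value O distribution to any target ratio.
    @staticmethod
    def _two_ring_coords(a=10.0, c=3.5):
        s = c / np.sqrt(2.0)
        return np.array(
            [(a, 0, 0), (0, a, 0), (-a, 0, 0), (0, -a, 0),
             (s, s, 0), (-s, s, 0), (-s, -s, 0), (s, -s, 0)],
            dtype=float,
        )

    @classmethod
    def _solve_outer_h(cls, target_outer, target_inner):
        """Outer-ring H making raw O proportional to the target (inner H = 1)."""
        from oracles import interaction_matrix

        pts = cls._two_ring_coords()
        M = interaction_matrix(pts)
        e_out = np.concatenate([np.ones(4), np.zeros(4)])
        e_in = 1.0 - e_out
        uo, ui = M @ e_out, M @ e_in
        h = (ui[4] * target_outer - ui[0] * target_inner) / (
            uo[0] * target_inner - uo[4] * target_outer
        )
        assert 0.0 <= h <= 1.0
        return pts, np.concatenate([np.full(4, h), np.ones(4)])

    def test_constructed_accordant_unit_scores_zero(self):
        """A unit whose solved O equals T exactly scores RD = 0."""
        pts = self._two_ring_coords()
        t_raw = orient_and_fit(make_unit(pts)).density(pts)
        pts, hydro = self._solve_outer_h(t_raw[0], t_raw[4])
        result = rd_score(make_unit(pts, hydro))
        assert result.dkl_OT < 1e-12
        assert result.dkl_OR > 0.1  # T is genuinely non-uniform here
        assert result.rd < 1e-9

    def test_constructed_uniform_unit_scores_one(self):
        """A unit whose O equals R exactly (T non-uniform) scores RD = 1.

        With hydrophobicity only on the outer ring, each outer residue's
        self-collected sum equals each inner residue's gathered sum (the
        rings see identical distance multisets), so O is exactly uniform
        while T still peaks at the inner ring.
        """
        pts = self._two_ring_coords()
        hydro = np.concatenate([np.full(4, 0.5), np.zeros(4)])
        unit = make_unit(pts, hydro)
        t = t_distribution(unit, orient_and_fit(unit))
        assert not np.allclose(t, 1.0 / len(pts))
        result = rd_score(unit)
        assert result.dkl_OR < 1e-12
        assert np.isclose(result.rd, 1.0, atol=1e-9)

    def test_rd_bounded(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            unit = make_unit(rng.normal(scale=7.0, size=(n, 3)), rng.uniform(0, 1, n))
            assert 0.0 <= rd_score(unit).rd <= 1.0

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(scale=7.0, size=(30, 3))
        hydro = rng.uniform(0, 1, 30)
        base = rd_score(make_unit(coords, hydro)).rd
        for _ in range(5):
            moved = rd_score(make_unit(rigid_transform(coords, rng), hydro)).rd
            assert abs(moved - base) <= 1e-6

    def test_residue_order_invariance(self, rng):
        coords = rng.normal(scale=7.0, size=(20, 3))
        hydro = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        assert np.isclose(
            rd_score(make_unit(coords, hydro)).rd,
            rd_score(make_unit(coords[perm], hydro[perm])).rd,
            atol=1e-12,
        )

    def test_hydro_scaling_invariance(self, rng):
        coords = rng.normal(scale=7.0, size=(20, 3))
        hydro = rng.uniform(0.2, 1.0, 20)
        assert np.isclose(
            rd_score(make_unit(coords, hydro)).rd,
            rd_score(make_unit(coords, 0.5 * hydro)).rd,
            atol=1e-12,
        )

    def test_parent_envelope_renormalizes_subset(self, rng):
        parent = make_unit(rng.normal(scale=8.0, size=(30, 3)), rng.uniform(0, 1, 30))
        child = parent[:12]
        prof = hydro_profile(child, envelope_source="parent", parent_unit=parent)
        assert np.isclose(prof.T.sum(), 1.0, atol=1e-9)
        assert np.isclose(prof.O.sum(), 1.0, atol=1e-9)
        # parent-frame T differs from refitting on the child alone
        self_prof = hydro_profile(child, envelope_source="self")
        assert not np.allclose(prof.T, self_prof.T)

    def test_parent_without_unit_rejected(self, rng):
        unit = make_unit(rng.normal(size=(5, 3)))
        with pytest.raises(ConfigurationError):
            hydro_profile(unit, envelope_source="parent")

    def test_tiny_unit_rejected(self):
        with pytest.raises(ConfigurationError):
            rd_score(make_unit([(0, 0, 0)]))
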