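"""Classical MDS, line angles, RDMs, jackknife group geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import vwmgeom as vg
from vwmgeom.geometry import angle_between_deg


class TestClassicalMds:
    def test_unit_square_round_trip(self):
        d = np.array([
            [0, 1, np.sqrt(2), 1],
            [1, 0, 1, np.sqrt(2)],
            [np.sqrt(2), 1, 0, 1],
            [1, np.sqrt(2), 1, 0],
        ])
        emb = vg.classical_mds(d)
        assert np.abs(squareform(pdist(emb.coords)) - d).max() < 1e-9

    def test_regular_tetrahedron_equidistant(self):
        d = np.ones((4, 4)) - np.eye(4)
        emb = vg.classical_mds(d)
        rec = pdist(emb.coords)
        assert np.allclose(rec, rec[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_euclidean_round_trip_random_3d_points(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 3))
        d = squareform(pdist(x))
        emb = vg.classical_mds(d)
        assert np.abs(squareform(pdist(emb.coords)) - d).max() < 1e-9

    def test_embedding_centered_and_eigenvalue_ordered(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.normal(size=(4, 3))))
        emb = vg.classical_mds(d)
        assert np.allclose(emb.coords.mean(axis=0), 0, atol=1e-12)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)

    def test_non_symmetric_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            vg.classical_mds(d)

    def test_negative_eigenvalue_mass_reported(self):
        # violate the triangle inequality to force non-Euclidean structure
        d = np.array([
            [0, 1, 1, 2.9],
            [1, 0, 1, 1],
            [1, 1, 0, 1],
            [2.9, 1, 1, 0],
        ], dtype=float)
        emb = vg.classical_mds(d)
        assert emb.truncated_mass > 0


class TestLineAngle:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 0, 0), (2, 0, 0), 0.0),
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (1, 1, 0), 45.0),
        ((1, 0, 0), (-1, 0, 0), 0.0),  # lines, not vectors: folded
    ])
    def test_worked_examples(self, a, b, expected):
        z = np.zeros(3)
        assert vg.line_angle(z, np.array(a), z, np.array(b)) == \
            pytest.approx(expected, abs=1e-9)

    def test_zero_length_rejected(self):
        z = np.zeros(3)
        with pytest.raises(ValueError, match="degenerate"):
            vg.line_angle(z, z, z, np.ones(3))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_fold_contract(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 3))
        ang = angle_between_deg(a, b)
        assert 0.0 <= ang <= 90.0
        assert angle_between_deg(a, -b) == pytest.approx(ang, abs=1e-6)


class TestRdm4:
    def test_quartet_counts(self):
        assert len(vg.enumerate_quartets("exp1", "exp1-cross-distractor")) == 6
        assert len(vg.enumerate_quartets("exp1", "exp1-distractor-presence")) == 12
        assert len(vg.enumerate_quartets("exp2", "exp2-target-cross")) == 6
        with pytest.raises(ValueError):
            vg.enumerate_quartets("exp2", "exp2-order")

    def test_symmetric_zero_diagonal(self, noisy_exp1):
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[0]
        rdm = vg.build_rdm4(noisy_exp1.data, q)
        assert np.allclose(rdm.values, rdm.values.T)
        assert np.all(np.diag(rdm.values) == 0)

    def test_identical_means_give_chance_entries(self):
        """Four conditions with the same mean: nothing to decode."""
        params = vg.GeometryParams(target_amplitude=0.0, context_amplitude=0.0,
                                   seed=31, n_vertices=80)
        ds = vg.generate_dataset(params, "exp1")
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[0]
        rdm = vg.build_rdm4(ds.data, q)
        vals = rdm.values[np.triu_indices(4, 1)]
        assert np.abs(vals).max() < 0.25  # above-chance entries near 0

    def test_noiseless_quartet_saturates_equally(self, noiseless_exp1):
        _, _, ds = noiseless_exp1
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[0]
        rdm = vg.build_rdm4(ds.data, q)
        vals = rdm.values[np.triu_indices(4, 1)]
        assert np.allclose(vals, 0.5)  # all pairs separable: accuracy 1

    def test_entry_conventions(self, noisy_exp1):
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[0]
        above = vg.build_rdm4(noisy_exp1.data, q, entry="above-chance")
        raw = vg.build_rdm4(noisy_exp1.data, q, entry="accuracy")
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(raw.values[off] - 0.5, above.values[off])
        with pytest.raises(ValueError):
            vg.build_rdm4(noisy_exp1.data, q, entry="nonsense")


class TestAngles:
    def test_noiseless_participant_angle_equals_planted(self):
        for theta in (0.0, 90.0):
            params = vg.GeometryParams(theta_deg=theta, noise_sd=0.0, seed=8,
                                       n_vertices=60, context_amplitude=0.6)
            ds = vg.sample_patterns(vg.plant_geometry(params, "exp1"),
                                    experiment="exp1", noise_sd=0.0, seed=2)
            # noiseless decoding saturates; measure geometry on the means
            q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[0]
            keys = [cs[0] for cs in q.condition_sets]
            x = ds.means.loc[keys].to_numpy()
            d = squareform(pdist(x))
            angles = vg.rdm_angles(d)
            assert angles["target_target"] == pytest.approx(theta, abs=1e-6)

    def test_jackknife_returns_n_estimates(self, noisy_exp1):
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[:1]
        rdms = np.stack([vg.participant_rdms([noisy_exp1.data], q)[0]] * 5)
        jack = vg.jackknife_group_angles(rdms, q)
        assert len(jack) == 5

    def test_identical_participants_identical_estimates(self, noisy_exp1):
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[:1]
        rdms = np.stack([vg.participant_rdms([noisy_exp1.data], q)[0]] * 4)
        jack = vg.jackknife_group_angles(rdms, q)
        assert jack.target_target.nunique() == 1

    def test_jackknife_needs_three(self, noisy_exp1):
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[:1]
        rdms = vg.participant_rdms([noisy_exp1.data] * 2, q)
        with pytest.raises(ValueError):
            vg.jackknife_group_angles(rdms, q)

    def test_jackknife_reduces_noise_bias_at_theta_zero(self):
        """Averaging RDMs before embedding cancels independent noise,
        so the group angle sits below the participant-level mean."""
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[:1]
        datasets = [vg.generate_dataset(
            vg.GeometryParams(theta_deg=0.0, seed=700 + p, n_vertices=120),
            "exp1").data for p in range(8)]
        rdms = vg.participant_rdms(datasets, q)
        part = vg.participant_angles(rdms, q)
        jack = vg.jackknife_group_angles(rdms, q)
        assert jack.target_target.mean() < part.target_target.mean()
        for table in (part, jack):
            assert ((table.target_target >= 0) &
                    (table.target_target <= 90)).all()

    def test_summarize_angles(self, noisy_exp1):
        q = vg.enumerate_quartets("exp1", "exp1-cross-distractor")[:1]
        datasets = [noisy_exp1.data] * 3
        rdms = vg.participant_rdms(datasets, q)
        summ = vg.summarize_angles(vg.participant_angles(rdms, q))
        assert list(summ["kind"]) == ["target_target", "context_context"]
        assert (summ["se_deg"] == 0).all()
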