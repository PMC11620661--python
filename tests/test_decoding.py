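"""Z-normalization, task enumeration, split-rotation decoding, probit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vwmgeom as vg
from vwmgeom.decoding import DecodingTask, znorm_rows


class TestZnorm:
    def test_worked_example(self):
        assert np.allclose(vg.znorm(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_idempotent(self):
        x = vg.znorm(np.array([4.0, -1.0, 2.5, 0.0]))
        assert np.allclose(vg.znorm(x), x)

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_output_moments(self, values):
        from hypothesis import assume
        x = np.asarray(values)
        if x.std(ddof=1) == 0:
            with pytest.raises(ValueError):
                vg.znorm(x)
        else:
            # near-constant inputs amplify rounding noise; not meaningful
            assume(x.std(ddof=1) > 1e-6 * max(1.0, np.abs(x).max()))
            z = vg.znorm(x)
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            vg.znorm(np.ones(10))
        with pytest.raises(ValueError):
            vg.znorm(np.array([1.0]))


class TestProbit:
    def test_chance_maps_to_zero(self):
        assert vg.probit_transform(0.5) == 0.0

    def test_inverse_normal_oracle(self):
        # Phi(1) = 0.841345...; probit must invert it
        assert vg.probit_transform(0.841345) == pytest.approx(1.0, abs=1e-4)

    def test_extremes_clipped_finite(self):
        from scipy.stats import norm
        assert vg.probit_transform(1.0) == pytest.approx(norm.ppf(1 - 1 / 56))
        assert np.isfinite(vg.probit_transform(0.0))

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            vg.probit_transform(1.2)


class TestEnumerateTasks:
    @pytest.mark.parametrize("experiment,analysis,n_within,n_cross", [
        ("exp1", "exp1-cross-distractor", 12, 12),  # 6 pairs x (2 + 2 dirs)
        ("exp1", "exp1-distractor-presence", 18, 24),
        ("exp1", "exp1-distractor-decoding", 12, 0),
        ("exp2", "exp2-target-cross", 12, 12),
        ("exp2", "exp2-order", 6, 0),  # 4 choose 2 pairs
    ])
    def test_task_counts(self, experiment, analysis, n_within, n_cross):
        tasks = vg.enumerate_tasks(experiment, analysis)
        assert sum(t.mode == "within" for t in tasks) == n_within
        assert sum(t.mode == "cross" for t in tasks) == n_cross

    def test_cross_tasks_come_in_both_directions(self):
        tasks = vg.enumerate_tasks("exp1", "exp1-cross-distractor")
        cross = {(t.train_a, t.test_a) for t in tasks if t.mode == "cross"}
        for tr, te in cross:
            assert (te, tr) in cross

    def test_exp2_partners_are_the_remaining_objects(self):
        tasks = vg.enumerate_tasks("exp2", "exp2-target-cross")
        for t in tasks:
            objs = {int(ch) for key in t.conditions for ch in key[1:]}
            if t.mode == "cross":
                assert objs == {1, 2, 3, 4}  # targets + both partners
            else:
                assert len(objs) == 3  # target pair + one shared partner

    def test_experiment_analysis_mismatch(self):
        with pytest.raises(ValueError):
            vg.enumerate_tasks("exp2", "exp1-cross-distractor")
        with pytest.raises(ValueError):
            vg.enumerate_tasks("exp1", "no-such-analysis")

    def test_class_sets_disjoint(self):
        for analysis in ("exp1-cross-distractor", "exp2-target-cross"):
            exp = analysis.split("-")[0]
            for t in vg.enumerate_tasks(exp, analysis):
                assert not set(t.train_a) & set(t.train_b)
                assert not set(t.test_a) & set(t.test_b)


def _within_task(a="T1D3", b="T2D3"):
    return DecodingTask(analysis="test", mode="within", train_a=(a,),
                        train_b=(b,), test_a=(a,), test_b=(b,))


class TestRunDecoding:
    def test_noiseless_separable_is_perfect(self, noiseless_exp1):
        _, _, ds = noiseless_exp1
        res = vg.run_decoding(ds.data, _within_task())
        assert res.accuracy == 1.0

    def test_train_test_sizes_21_and_7(self, noisy_exp1):
        res = vg.run_decoding(noisy_exp1.data, _within_task())
        assert res.n_train_per_class == 21  # 3 splits x 7 estimates
        assert res.n_test_per_class == 7
        assert len(res.per_rotation) == 4

    def test_determinism(self, noisy_exp1):
        r1 = vg.run_decoding(noisy_exp1.data, _within_task())
        r2 = vg.run_decoding(noisy_exp1.data, _within_task())
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.per_rotation, r2.per_rotation)

    def test_missing_condition_rejected(self, noisy_exp1):
        sub = noisy_exp1.data.select(conditions=["T1D3"])
        with pytest.raises(ValueError, match="missing"):
            vg.run_decoding(sub, _within_task())

    def test_cross_direction_average_symmetric(self, noisy_exp1):
        a, b, c, d = "T1D3", "T2D3", "T1D4", "T2D4"
        fwd = DecodingTask(analysis="x", mode="cross", train_a=(a,),
                           train_b=(b,), test_a=(c,), test_b=(d,))
        rev = DecodingTask(analysis="x", mode="cross", train_a=(c,),
                           train_b=(d,), test_a=(a,), test_b=(b,))
        m1 = (vg.run_decoding(noisy_exp1.data, fwd).accuracy
              + vg.run_decoding(noisy_exp1.data, rev).accuracy) / 2
        # swapping the roles enumerates the same directed pair set
        m2 = (vg.run_decoding(noisy_exp1.data, rev).accuracy
              + vg.run_decoding(noisy_exp1.data, fwd).accuracy) / 2
        assert m1 == m2

    def test_permuted_labels_near_chance(self):
        accs = []
        for rep in range(12):
            ds = vg.generate_dataset(
                vg.GeometryParams(seed=500 + rep, n_vertices=80), "exp1")
            null = vg.permute_labels_within_splits(
                ds.data, ["T1D3", "T2D3"], seed=rep)
            accs.append(vg.run_decoding(null, _within_task()).accuracy)
        assert 0.40 < np.mean(accs) < 0.60

    def test_accuracy_monotone_in_signal_to_noise(self):
        """Spearman rho = 1 over a 5-point amplitude grid."""
        from scipy.stats import spearmanr
        amps = [0.3, 0.8, 1.3, 1.9, 2.6]
        mean_acc = []
        for amp in amps:
            accs = []
            for rep in range(4):
                ds = vg.generate_dataset(
                    vg.GeometryParams(target_amplitude=amp, seed=900 + rep,
                                      n_vertices=100), "exp1")
                accs.append(vg.run_decoding(ds.data, _within_task()).accuracy)
            mean_acc.append(np.mean(accs))
        rho = spearmanr(amps, mean_acc).statistic
        assert rho >= 0.999

    def test_exp2_order_pooling_gives_double_counts(self, noisy_exp2):
        tasks = [t for t in vg.enumerate_tasks("exp2", "exp2-target-cross")
                 if t.mode == "within"]
        res = vg.run_decoding(noisy_exp2.data, tasks[0])
        assert res.n_train_per_class == 42  # 2 pooled orders x 21
        assert res.n_test_per_class == 14


class TestTimecourse:
    def test_thirty_accuracies_in_unit_interval(self, small_glm_run):
        ds, fir, betas = small_glm_run
        per_tr = vg.decode_per_tr_patterns(betas)
        assert len(per_tr) == 30
        accs = vg.decode_timecourse(per_tr, _within_task())
        assert accs.shape == (30,)
        assert np.all((accs >= 0) & (accs <= 1))

    def test_pre_onset_lags_at_chance_delay_lags_above(self, small_glm_run):
        """No signal is planted before ~1.6 s; the delay lags carry it."""
        ds, fir, betas = small_glm_run
        per_tr = vg.decode_per_tr_patterns(betas)
        accs = vg.decode_timecourse(per_tr, _within_task())
        assert np.mean(accs[:2]) < np.mean(accs[10:15])
        assert np.mean(accs[10:15]) > 0.9  # low-noise fixture
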