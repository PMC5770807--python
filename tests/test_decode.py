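import numpy as np
import pytest

import regionrsa as rr
from regionrsa import design
from regionrsa.decode import TRAIN_SIZE, TEST_SIZE, _averaging_matrices


def _epochs_from(data, n_per_cond):
    n = data.shape[2]
    stim = np.tile(np.repeat(np.arange(1, 7), n_per_cond), 2)
    sec = np.repeat([1, 2], 6 * n_per_cond)
    order = np.tile(np.arange(1, n_per_cond + 1), 12)
    return rr.SourceEpochs(
        data=data, time_ms=np.arange(data.shape[1]) * 10.0 - 100.0,
        stimulus=stim[:n], section=sec[:n], presentation_order=order[:n],
    )


class TestResample:
    def test_millisecond_input_gives_81_bins(self):
        t = np.arange(-500.0, 1001.0)  # 1 kHz epoch -500..1000 ms
        rng = np.random.default_rng(0)
        ep = rr.SourceEpochs(
            data=rng.standard_normal((3, t.size, 2)), time_ms=t,
            stimulus=np.array([1, 2]), section=np.array([1, 1]),
            presentation_order=np.array([1, 1]),
        )
        out = rr.resample_epochs(ep, window_ms=(-100, 700))
        assert out.time_ms.size == 81
        assert out.time_ms[0] == -100 and out.time_ms[-1] == 700
        # first bin is the mean of the first ten 1 ms samples
        first = ep.data[:, (t >= -100) & (t < -90), :].mean(axis=1)
        assert out.data[:, 0, :] == pytest.approx(first)

    def test_constant_signal_preserved(self):
        t = np.arange(-100.0, 701.0)
        ep = rr.SourceEpochs(
            data=np.full((2, t.size, 1), 3.5), time_ms=t,
            stimulus=np.array([1]), section=np.array([1]),
            presentation_order=np.array([1]),
        )
        out = rr.resample_epochs(ep)
        assert np.all(out.data == 3.5)

    def test_ten_ms_input_passes_through(self):
        t = np.arange(-200.0, 701.0, 10.0)
        rng = np.random.default_rng(1)
        ep = rr.SourceEpochs(
            data=rng.standard_normal((2, t.size, 1)), time_ms=t,
            stimulus=np.array([1]), section=np.array([1]),
            presentation_order=np.array([1]),
        )
        out = rr.resample_epochs(ep, window_ms=(-100, 700))
        assert out.time_ms.size == 81
        assert np.array_equal(out.data, ep.data[:, t >= -100, :])

    def test_window_outside_epoch_rejected(self):
        t = np.arange(0.0, 701.0, 10.0)
        ep = rr.SourceEpochs(
            data=np.zeros((1, t.size, 1)), time_ms=t,
            stimulus=np.array([1]), section=np.array([1]),
            presentation_order=np.array([1]),
        )
        with pytest.raises(ValueError, match="outside"):
            rr.resample_epochs(ep, window_ms=(-100, 700))


class TestRegionComponents:
    def test_three_vertex_region_reconstructs_exactly(self):
        parc = rr.build_synthetic_parcellation(1, 3, seed=0)
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 8, 12))
        ep = _epochs_from(data, 1)
        comp = rr.extract_region_components(ep, parc)
        u = comp.loadings[0]
        assert u.T @ u == pytest.approx(np.eye(3), abs=1e-10)
        mean = data.reshape(3, -1).mean(axis=1)
        recon = np.einsum("vk,ktn->vtn", u, comp.scores[0]) + mean[:, None, None]
        assert recon == pytest.approx(data, abs=1e-10)

    def test_rank_one_signal_dominates_first_component(self):
        parc = rr.build_synthetic_parcellation(1, 8, seed=0)
        rng = np.random.default_rng(3)
        pattern = rng.standard_normal(8)
        tc = rng.standard_normal((6, 24))
        data = pattern[:, None, None] * tc[None] + 1e-4 * rng.standard_normal((8, 6, 24))
        comp = rr.extract_region_components(_epochs_from(data, 2), parc)
        assert comp.explained_variance[0, 0] > 0.99

    def test_explained_variance_sorted_fractions(self, null_subject):
        _, _, _, comp = null_subject
        ev = comp.explained_variance
        assert np.all(ev >= 0) and np.all(ev <= 1)
        assert np.all(np.diff(ev, axis=1) <= 1e-12)

    def test_small_region_error_names_region(self):
        parc = rr.Parcellation(n_vertices=7, assignment=np.array([0, 0, 0, 1, 1, 1, 1]))
        ep = _epochs_from(np.zeros((7, 4, 12)), 1)
        bad = rr.Parcellation.__new__(rr.Parcellation)  # bypass validation to hit the op's check
        object.__setattr__(bad, "n_vertices", 7)
        object.__setattr__(bad, "assignment", np.array([0, 0, 1, 1, 1, 1, 1]))
        with pytest.raises(ValueError, match="region 0"):
            rr.extract_region_components(ep, bad)
        rr.extract_region_components(ep, parc)  # valid parcellation is fine


class TestPseudoTrials:
    @pytest.mark.parametrize(
        "n_trials, expected_sizes",
        [(80, [8] * 10), (73, [8, 8, 8, 7, 7, 7, 7, 7, 7, 7]), (50, [5] * 10)],
    )
    def test_group_sizes_partition_trials(self, n_trials, expected_sizes):
        assert list(design.segment_sizes(n_trials)) == expected_sizes
        assert sum(expected_sizes) == n_trials

    def test_conditions_below_minimum_excluded(self):
        parc = rr.build_synthetic_parcellation(1, 3, seed=0)
        # condition (1, 1) gets only 49 trials, everything else 50
        n = 12 * 50
        data = np.zeros((3, 4, n - 1))
        stim = np.tile(np.repeat(np.arange(1, 7), 50), 2)[1:]
        sec = np.repeat([1, 2], 300)[1:]
        order = np.concatenate([[np.arange(1, 50)] if i == 0 else [np.arange(1, 51)]
                                for i in range(12)], axis=None)
        ep = rr.SourceEpochs(data=data, time_ms=np.arange(4.0), stimulus=stim,
                             section=sec, presentation_order=order)
        comp = rr.extract_region_components(ep, parc)
        pt = rr.make_pseudo_trials(comp, min_trials=50, seed=0)
        assert pt.excluded == [design.entry_index(1, 1)]
        assert len(pt.entries) == 11
        assert pt.data.shape[-1] == 10
        assert np.all((pt.group_sizes >= 5) & (pt.group_sizes <= 8))

    def test_averages_match_manual_computation(self, null_subject):
        _, _, _, comp = null_subject
        pt = rr.make_pseudo_trials(comp, min_trials=10, seed=5)
        # reconstruct the same grouping and check one condition's averages sum
        e = pt.entries[0]
        idx = comp.condition_trials(*design.ENTRIES[e])
        total_from_groups = np.einsum("rktg,g->rkt", pt.data[0], pt.group_sizes[0].astype(float))
        assert total_from_groups == pytest.approx(comp.scores[..., idx].sum(axis=-1))


class TestPairDecoding:
    def test_cv_fold_sizes(self):
        assert TRAIN_SIZE == 18 and TEST_SIZE == 2
        rng = np.random.default_rng(0)
        mats = _averaging_matrices(50, 4, rng)
        # each randomization averages all 50 trials across its 10 groups
        assert np.allclose(mats.sum(axis=2), 1.0)  # rows are means
        assert np.all((mats > 0).sum(axis=(1, 2)) == 50)

    def test_separable_classes_decode_perfectly(self):
        rng = np.random.default_rng(4)
        t, n = 5, 60
        a = rng.standard_normal((3, t, n)) * 0.05
        b = rng.standard_normal((3, t, n)) * 0.05
        a[0] += 5.0  # disjoint ranges on component 1
        acc, w = rr.decode_pair_timecourse(a, b, n_randomizations=20, seed=0)
        assert np.all(acc == 1.0)
        assert np.all(np.abs(w[:, 0]) > 0.95)  # boundary ~ (+-1, 0, 0)

    def test_identical_distributions_decode_at_chance(self):
        rng = np.random.default_rng(5)
        accs = []
        for i in range(10):
            a = rng.standard_normal((3, 4, 50))
            b = rng.standard_normal((3, 4, 50))
            acc, _ = rr.decode_pair_timecourse(a, b, n_randomizations=25, seed=i)
            accs.append(acc)
        mean = np.mean(accs)
        # 10*4 time bins x 50 test classifications, correlated; generous 3 SE band
        assert abs(mean - 0.5) < 0.03

    def test_accuracy_invariant_to_common_rotation_and_scaling(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((3, 3, 40)) + np.array([0.8, 0, 0])[:, None, None]
        b = rng.standard_normal((3, 3, 40))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        transform = 2.7 * q  # rotation + global scaling commutes with the ridge
        a2 = np.einsum("ij,jtn->itn", transform, a)
        b2 = np.einsum("ij,jtn->itn", transform, b)
        acc1, _ = rr.decode_pair_timecourse(a, b, n_randomizations=30, seed=7)
        acc2, _ = rr.decode_pair_timecourse(a2, b2, n_randomizations=30, seed=7)
        assert acc1 == pytest.approx(acc2)

    def test_boundary_direction_matches_analytic_lda(self):
        """Class difference along component 3 with anisotropic noise: the
        discriminant normal must approximate Sigma^-1 (mu_a - mu_b)."""
        rng = np.random.default_rng(7)
        cov = np.diag([4.0, 1.0, 0.25])
        chol = np.linalg.cholesky(cov)
        n = 400
        noise_a = np.einsum("ij,jtn->itn", chol, rng.standard_normal((3, 1, n)))
        noise_b = np.einsum("ij,jtn->itn", chol, rng.standard_normal((3, 1, n)))
        delta = np.array([1.0, 0.0, 1.0])
        a = noise_a + delta[:, None, None] / 2
        b = noise_b - delta[:, None, None] / 2
        _, w = rr.decode_pair_timecourse(a, b, n_randomizations=100, seed=8)
        expected = np.linalg.solve(cov / 10.0, delta)  # pseudo-trials of ~10 shrink the cov
        expected /= np.linalg.norm(expected)
        assert np.abs(w[0] @ expected) > 0.97

    def test_all_pairs_covers_66_unordered_pairs(self, null_subject):
        _, _, _, comp = null_subject
        dec = rr.decode_all_pairs(comp, min_trials=10, n_randomizations=5, seed=0)
        assert len(dec.pairs) == 66
        assert len(set(dec.pairs)) == 66
        assert all(a < b for a, b in dec.pairs)
        assert dec.accuracy.shape == (4, 81, 66)
        assert np.all((dec.accuracy >= 0) & (dec.accuracy <= 1))
        norms = np.linalg.norm(dec.boundary_weights, axis=-1)
        assert norms == pytest.approx(1.0, abs=1e-9)
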