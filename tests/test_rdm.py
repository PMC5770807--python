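import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import regionrsa as rr
from regionrsa import design
from regionrsa.decode import DecodingResult
from regionrsa.rdm import _rank_correlate


def brute_spearman(x, y):
    """Independent oracle: average-rank Spearman via explicit rank assignment."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _fake_decoding(accuracy_by_pair, drop_entries=()):
    pairs = [(a, b) for a, b in design.ENTRY_PAIRS
             if a not in drop_entries and b not in drop_entries]
    acc = np.array([[[accuracy_by_pair(a, b) for a, b in pairs]]])
    return DecodingResult(
        accuracy=acc, boundary_weights=np.zeros(acc.shape + (3,)), pairs=pairs,
        entries=[e for e in range(12) if e not in drop_entries],
        excluded=list(drop_entries), time_ms=np.array([0.0]), n_randomizations=1,
    )


class TestModelRDMs:
    def test_stimulus_recognizer_counts(self):
        m = rr.build_model_rdm(rr.MODEL_NAMES["recognizer"])
        vals, valid = m.upper_cells()
        assert valid.sum() == 66
        assert (vals[valid] == 0).sum() == 6  # same stimulus across sections
        assert (vals[valid] == 1).sum() == 60

    @pytest.mark.parametrize("name", ["face_vs_nonsense", "tool_vs_nonsense"])
    def test_category_vs_nonsense_counts(self, name):
        m = rr.build_model_rdm(rr.MODEL_NAMES[name])
        vals, valid = m.upper_cells()
        assert valid.sum() == 24  # 28 cells among the 8 entries minus 4 masked
        assert (vals[valid] == 1).sum() == 16  # 4 category x 4 nonsense entries
        assert (vals[valid] == 0).sum() == 8

    @pytest.mark.parametrize("name", ["face_specific", "tool_specific", "meaningful"])
    def test_one_vs_rest_counts(self, name):
        m = rr.build_model_rdm(rr.MODEL_NAMES[name])
        vals, valid = m.upper_cells()
        assert valid.sum() == 60  # 66 minus all 6 same-stimulus cross-section cells
        assert (vals[valid] == 1).sum() == 32
        assert (vals[valid] == 0).sum() == 28

    def test_masks_symmetric_and_binary_values(self):
        for spec in rr.MODEL_NAMES.values():
            m = rr.build_model_rdm(spec)
            assert np.array_equal(m.mask, m.mask.T)
            assert set(np.unique(m.values[m.mask])) <= {0.0, 1.0}
            assert not np.any(np.diag(m.mask))

    def test_type2_support_subset_of_type3(self):
        t2 = rr.build_model_rdm(rr.MODEL_NAMES["face_vs_nonsense"])
        t3 = rr.build_model_rdm(rr.MODEL_NAMES["face_specific"])
        assert np.all(~t2.mask | t3.mask)  # every valid type-2 cell is valid in type 3
        assert t3.mask.sum() > t2.mask.sum()

    def test_unknown_spec_rejected(self):
        with pytest.raises(ValueError):
            rr.ModelSpec("one_vs_rest", None)
        with pytest.raises(ValueError):
            rr.ModelSpec("nonsense_model")


class TestEmpiricalRDM:
    def test_all_entries_give_66_valid_cells(self):
        dec = _fake_decoding(lambda a, b: 0.5 + 0.001 * (a + b))
        rdm = rr.build_empirical_rdm(dec, 0, 0)
        _, valid = rdm.upper_cells()
        assert valid.sum() == 66
        assert np.allclose(rdm.values, rdm.values.T)

    def test_excluded_entry_gives_55_valid_cells(self):
        dec = _fake_decoding(lambda a, b: 0.6, drop_entries=(3,))
        rdm = rr.build_empirical_rdm(dec, 0, 0)
        _, valid = rdm.upper_cells()
        assert valid.sum() == 55  # C(11, 2)
        assert not rdm.mask[3].any()


class TestCorrelation:
    def test_identical_and_reversed_rankings(self):
        model = rr.build_model_rdm(rr.MODEL_NAMES["recognizer"])
        same = rr.RDM(values=model.values.copy(), mask=model.mask.copy())
        assert rr.correlate_rdms(same, model) == pytest.approx(1.0)
        flipped = rr.RDM(values=np.where(model.mask, 1 - model.values, 0.0),
                         mask=model.mask.copy())
        assert rr.correlate_rdms(flipped, model) == pytest.approx(-1.0)

    def test_hand_vector_value(self):
        # model (0,0,1,1) vs empirical (0.52, 0.55, 0.71, 0.66): rho = 0.8944
        assert brute_spearman([0.52, 0.55, 0.71, 0.66], [0, 0, 1, 1]) == pytest.approx(
            0.894427, abs=1e-6
        )
        rho = _rank_correlate(np.array([0.52, 0.55, 0.71, 0.66]), np.array([0.0, 0, 1, 1]))
        assert rho == pytest.approx(0.894427, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 5), min_size=4, max_size=30),
           st.lists(st.integers(0, 3), min_size=4, max_size=30))
    def test_rank_correlation_matches_brute_force_and_scipy(self, xs, ys):
        m = min(len(xs), len(ys))
        x, y = np.array(xs[:m], dtype=float), np.array(ys[:m], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        expected = brute_spearman(x, y)
        assert _rank_correlate(x, y) == pytest.approx(expected, abs=1e-12)
        assert sps.spearmanr(x, y).statistic == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        emp = rr.build_model_rdm(rr.MODEL_NAMES["recognizer"])
        noisy = np.where(emp.mask, 0.5 + 0.3 * rng.random((12, 12)), 0.0)
        noisy = np.triu(noisy, 1)
        noisy = noisy + noisy.T
        e1 = rr.RDM(values=noisy, mask=emp.mask.copy())
        e2 = rr.RDM(values=np.exp(3 * noisy) * emp.mask, mask=emp.mask.copy())
        model = rr.build_model_rdm(rr.MODEL_NAMES["face_specific"])
        assert rr.correlate_rdms(e1, model) == pytest.approx(rr.correlate_rdms(e2, model))

    def test_degenerate_inputs_flagged_as_missing(self):
        model = rr.build_model_rdm(rr.MODEL_NAMES["recognizer"])
        # constant model: valid cells but no variation
        const = rr.RDM(values=np.where(model.mask, 1.0, 0.0), mask=model.mask.copy())
        assert np.isnan(rr.correlate_rdms(const, const))
        # fewer than 3 joint cells
        tiny_mask = np.zeros((12, 12), dtype=bool)
        tiny_mask[0, 1] = tiny_mask[1, 0] = True
        tiny = rr.RDM(values=np.zeros((12, 12)), mask=tiny_mask)
        assert np.isnan(rr.correlate_rdms(tiny, model))


class TestFisher:
    def test_known_values_and_antisymmetry(self):
        assert rr.fisher_z(0.0) == 0.0
        assert rr.fisher_z(0.5) == pytest.approx(np.arctanh(0.5))  # 0.549306
        r = np.linspace(-0.9, 0.9, 7)
        assert rr.fisher_z(-r) == pytest.approx(-rr.fisher_z(r))

    def test_perfect_correlation_clipped_finite(self):
        assert np.isfinite(rr.fisher_z(1.0))
        assert np.isfinite(rr.fisher_z(-1.0))


class TestZmapsIntegration:
    def test_face_binding_raises_face_model_z_only_in_target(self, face_effect_run):
        """A face category-binding effect in region 0 drives the face
        one-vs-rest model there; the tool model stays near zero."""
        _, _, _, decs = face_effect_run
        z = np.stack([rr.rsa_zmaps(d, ["face_specific", "tool_specific"])[0] for d in decs])
        time_ms = decs[0].time_ms
        window = (time_ms >= 140) & (time_ms <= 170)
        face_target = z[:, 0, window, 0]
        assert np.all(face_target.mean(axis=(1,)) > 0.3)  # every subject
        tool_there = z[:, 0, window, 1].mean()
        assert abs(tool_there) < 0.15
        null_region = z[:, 2, window, 0].mean()
        assert abs(null_region) < 0.15

    def test_zmaps_match_cellwise_rdm_route(self, face_effect_run):
        """The vectorized map equals correlate_rdms cell by cell."""
        _, _, _, decs = face_effect_run
        dec = decs[0]
        z, names = rr.rsa_zmaps(dec, ["recognizer", "meaningful"])
        model = rr.build_model_rdm(rr.MODEL_NAMES["recognizer"])
        for (r, t) in [(0, 14), (1, 30), (2, 70)]:
            emp = rr.build_empirical_rdm(dec, r, t)
            expected = rr.fisher_z(rr.correlate_rdms(emp, model))
            assert z[r, t, 0] == pytest.approx(float(expected), abs=1e-10)
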