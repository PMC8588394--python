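"""Architecture catalog: parameter audit, forward smoke, risk transform,
Gaussian likelihood head, ensemble averaging."""

import numpy as np
import pytest

from glybench.errors import AlignmentError, InvalidPredictionError
from glybench.zoo import (
    BASE_SPEC_IDS,
    ENSEMBLE_MEMBERS,
    N_RISK_BINS,
    PRINTED_PARAM_COUNTS,
    SPEC_IDS,
    build_model,
    count_parameters,
    ensemble_predict,
    gaussian_nll,
    risk_decode,
    risk_encode,
    risk_transform,
)


@pytest.fixture(scope="module")
def batch(rng=np.random.default_rng(7)):
    # scaled glucose around 1.4, event channels in [0, 1]
    x = rng.normal(1.4, 0.2, size=(8, 25, 4))
    x[:, :, 1:] = rng.uniform(0, 1, size=(8, 25, 3))
    return x


class TestCatalog:
    @pytest.mark.parametrize("spec_id,printed", sorted(PRINTED_PARAM_COUNTS.items()))
    def test_parameter_counts_match_published_tables(self, spec_id, printed):
        assert count_parameters(build_model(spec_id)) == printed

    @pytest.mark.parametrize("spec_id", SPEC_IDS)
    def test_every_spec_builds_and_predicts_finite(self, spec_id, batch):
        model = build_model(spec_id, seed=3)
        if spec_id == "khadem":
            # stacked model predicts only after fitting; its bases must build
            assert count_parameters(model) > 0
            for net in model.nn_bases.values():
                out = net.forward(batch)
                assert np.all(np.isfinite(out.data))
            return
        preds = model.predict(batch) if spec_id not in ENSEMBLE_MEMBERS else None
        if preds is None:
            preds = model.predict(batch)
        assert preds.shape == (len(batch),)
        assert np.all(np.isfinite(preds))
        assert np.all((preds >= 40.0) & (preds <= 400.0))

    def test_unknown_spec_rejected(self):
        with pytest.raises(KeyError):
            build_model("nonexistent")

    def test_catalog_serializes_every_spec(self):
        from glybench.zoo import catalog

        doc = catalog()
        assert set(doc["models"]) == set(SPEC_IDS)
        for spec, entry in doc["models"].items():
            if entry["published_parameters"] is not None:
                assert entry["built_parameters"] == entry["published_parameters"]

    def test_seeded_build_is_reproducible(self, batch):
        a = build_model("sun", seed=9).predict(batch)
        b = build_model("sun", seed=9).predict(batch)
        np.testing.assert_array_equal(a, b)

    def test_meijner_scale_head_strictly_positive(self, batch):
        net = build_model("meijner")
        _, sigma = net.forward(batch)
        assert np.all(sigma.data > 0)


class TestGaussianNLL:
    def test_value_at_mode_unit_sigma(self):
        y = np.array([1.0, 2.0, 3.0])
        val = gaussian_nll(y, y, np.ones(3))
        assert val == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_one_sigma_error_adds_half(self):
        y = np.zeros(4)
        sigma = np.full(4, 2.0)
        at_mode = gaussian_nll(y, y, sigma)
        off = gaussian_nll(y + sigma, y, sigma)
        assert off - at_mode == pytest.approx(0.5, abs=1e-12)

    def test_doubling_sigma_adds_log_two_at_mode(self):
        y = np.zeros(4)
        assert gaussian_nll(y, y, np.full(4, 2.0)) - gaussian_nll(
            y, y, np.ones(4)
        ) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_nll(np.zeros(2), np.zeros(2), np.array([1.0, 0.0]))


class TestRiskBins:
    def test_roundtrip_within_one_bin(self):
        bg = np.arange(40.0, 401.0)
        back = risk_decode(risk_encode(bg))
        # bin width in glucose units varies; bound by local bin span
        edges = risk_decode(np.arange(N_RISK_BINS))
        max_span = np.max(np.diff(edges)) * 1.2
        assert np.max(np.abs(back - bg)) < max_span

    def test_encode_monotone(self):
        bg = np.arange(40.0, 401.0)
        assert np.all(np.diff(risk_encode(bg)) >= 0)

    def test_order_preserved(self):
        assert risk_encode(70.0) < risk_encode(180.0)

    def test_transform_spans_minus_two_to_two(self):
        assert risk_transform(40.0) == pytest.approx(-2.0, abs=1e-12)
        assert risk_transform(400.0) == pytest.approx(2.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            risk_encode(30.0)
        with pytest.raises(ValueError):
            risk_decode(np.array([100]))


class TestEnsemble:
    def test_arithmetic_mean(self):
        out = ensemble_predict([np.array([100.0]), np.array([110.0]), np.array([120.0])])
        assert out[0] == pytest.approx(110.0)

    def test_identical_members_idempotent(self):
        m = np.array([90.0, 180.0])
        np.testing.assert_allclose(ensemble_predict([m, m, m]), m)

    def test_clipping_applied_after_mean(self):
        out = ensemble_predict([np.array([500.0])] * 3)
        assert out[0] == 400.0

    def test_permutation_invariant_and_bounded(self, rng):
        members = [rng.uniform(50, 350, size=20) for _ in range(4)]
        a = ensemble_predict(members)
        b = ensemble_predict(members[::-1])
        np.testing.assert_allclose(a, b, rtol=1e-12)  # summation order only
        assert np.all(a >= np.min(members, axis=0)) and np.all(a <= np.max(members, axis=0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            ensemble_predict([np.zeros(3) + 100, np.zeros(4) + 100])

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([np.array([100.0])])

    def test_catalog_membership(self):
        assert ENSEMBLE_MEMBERS["ensemble_mms"] == ("mirshekarian", "meijner", "sun")
        assert ENSEMBLE_MEMBERS["ensemble_mmsz"] == (
            "mirshekarian",
            "meijner",
            "sun",
            "zhu",
        )

    def test_non_finite_member_mean_rejected(self):
        with pytest.raises(InvalidPredictionError):
            ensemble_predict([np.array([np.inf]), np.array([100.0])])
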