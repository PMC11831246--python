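"""Observation models: similarities, endorsement rules, likelihoods."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protomix.errors import ConfigurationError, DataError, UndefinedCorrelationError
from protomix.models import (
    EndorsementData,
    ItemDistances,
    ModelSpec,
    ParameterSet,
    endorsement_probability,
    log_likelihood,
    mixture_similarity_vector,
    predict_endorsement,
    similarity_correlation,
    similarity_to_exemplars,
    similarity_to_prototype,
)

finite = dict(allow_nan=False, allow_infinity=False)


class TestSimilarity:
    @pytest.mark.parametrize("d,c,expected", [
        (0.0, 2.3, 1.0),          # identity at zero distance
        (4.2, 0.0, 1.0),          # degenerate sensitivity
        (2.0, 0.5, math.exp(-1)),  # closed form
    ])
    def test_prototype_similarity_closed_form(self, d, c, expected):
        assert similarity_to_prototype(d, c) == pytest.approx(expected)

    def test_exemplar_similarity_closed_form(self):
        assert similarity_to_exemplars([1.0, 2.0], 1.0) == pytest.approx(
            math.exp(-1) + math.exp(-2))
        assert similarity_to_exemplars(np.zeros(12), 0.0) == pytest.approx(12.0)
        assert similarity_to_exemplars([0.0], 3.0) == pytest.approx(1.0)

    def test_self_term_contributes_one(self, stimset, training_distances):
        # a training member evaluated against the set containing itself
        i = list(training_distances.item_ids).index("trm01")
        terms = np.exp(-1.3 * training_distances.d_ex[i])
        assert terms[0] == pytest.approx(1.0)  # self distance is zero

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            similarity_to_prototype(-1.0, 1.0)
        with pytest.raises(ConfigurationError):
            similarity_to_exemplars([], 1.0)


class TestEndorsementProbability:
    def test_guess_is_half_everywhere(self):
        r = endorsement_probability("GUESS", ParameterSet(), s_proto=np.linspace(0, 1, 17))
        assert (r == 0.5).all()

    def test_balance_point(self):
        p = ParameterSet(c=1.0, k=0.4)
        assert endorsement_probability("PROTO", p, s_proto=0.4) == pytest.approx(0.5)

    def test_mix_beta_one_equals_proto(self):
        p = ParameterSet(c=1.0, k=0.3, beta=1.0)
        s_p, s_e = np.array([0.2, 0.9]), np.array([1.5, 4.0])
        r_mix = endorsement_probability("MIX", p, s_proto=s_p, s_ex=s_e)
        r_proto = endorsement_probability("PROTO", ParameterSet(c=1.0, k=0.3), s_proto=s_p)
        assert np.allclose(r_mix, r_proto)

    def test_gamma_one_equals_restricted(self):
        s_e = np.array([0.4, 2.0])
        r_g = endorsement_probability("EX_G", ParameterSet(c=1.0, k=0.3, gamma=1.0), s_ex=s_e)
        r = endorsement_probability("EX", ParameterSet(c=1.0, k=0.3), s_ex=s_e)
        assert np.allclose(r_g, r)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            endorsement_probability("PROTO", ParameterSet(c=1.0, k=0.0), s_proto=0.5)
        with pytest.raises(ConfigurationError):
            endorsement_probability("MIX", ParameterSet(c=1.0, k=0.3, beta=1.5),
                                    s_proto=0.5, s_ex=0.5)

    @given(s=st.floats(1e-6, 12.0, **finite), k=st.floats(1e-6, 1.0, **finite),
           beta=st.floats(0.0, 1.0, **finite))
    @settings(max_examples=200, deadline=None)
    def test_probabilities_in_unit_interval(self, s, k, beta):
        p = ParameterSet(c=1.0, k=k, beta=beta)
        r = endorsement_probability("MIX", p, s_proto=min(s, 1.0), s_ex=s)
        assert 0.0 < r < 1.0

    @given(k=st.floats(0.05, 1.0, **finite))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_similarity_and_criterion(self, k):
        p_lo = endorsement_probability("PROTO", ParameterSet(c=1.0, k=k), s_proto=0.2)
        p_hi = endorsement_probability("PROTO", ParameterSet(c=1.0, k=k), s_proto=0.6)
        assert p_hi > p_lo
        stricter = endorsement_probability("PROTO", ParameterSet(c=1.0, k=min(1.0, k + 0.05)),
                                           s_proto=0.4)
        lax = endorsement_probability("PROTO", ParameterSet(c=1.0, k=k * 0.5), s_proto=0.4)
        assert lax > stricter


class TestModelSpec:
    def test_free_parameter_lists(self):
        assert ModelSpec("PROTO").free_parameters == ("c", "k")
        assert ModelSpec("MIX_2C_G").free_parameters == ("c_proto", "c_ex", "k", "beta", "gamma")
        assert ModelSpec("GUESS").free_parameters == ()

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("RULEX")


class TestLogLikelihood:
    def test_guess_closed_form(self, transfer_distances):
        ids = transfer_distances.item_ids[:24]
        data = EndorsementData.from_binary(ids, np.ones(24))
        ll = log_likelihood("GUESS", None, data, transfer_distances)
        assert ll == pytest.approx(24 * math.log(0.5))
        assert ll == pytest.approx(-16.636, abs=5e-4)

    def test_matches_bruteforce_trial_sum(self, transfer_distances):
        # independent oracle: loop over items and trials with scalar math
        rng = np.random.default_rng(1)
        ids = transfer_distances.item_ids[:3]
        counts = np.array([3.0, 0.0, 7.0])
        nobs = np.array([8.0, 8.0, 8.0])
        data = EndorsementData.from_counts(ids, counts, nobs)
        for c in (0.2, 1.0, 3.0):
            for k in (0.1, 0.5, 1.0):
                for beta in (0.0, 0.4, 1.0):
                    p = ParameterSet(c=c, k=k, beta=beta)
                    expected = 0.0
                    for i, pid in enumerate(ids):
                        row = list(transfer_distances.item_ids).index(pid)
                        s_p = math.exp(-c * transfer_distances.d_proto[row])
                        s_e = sum(math.exp(-c * d) for d in transfer_distances.d_ex[row])
                        r = beta * s_p / (s_p + k) + (1 - beta) * s_e / (s_e + k)
                        for t in range(int(nobs[i])):
                            expected += math.log(r if t < counts[i] else 1 - r)
                    got = log_likelihood("MIX", p, data, transfer_distances)
                    assert got == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_item_order(self, transfer_distances, rng):
        ids = np.array(transfer_distances.item_ids)
        counts = rng.integers(0, 9, len(ids)).astype(float)
        nobs = np.full(len(ids), 8.0)
        p = ParameterSet(c=0.8, k=0.4, beta=0.6)
        perm = rng.permutation(len(ids))
        ll1 = log_likelihood("MIX", p, EndorsementData.from_counts(ids, counts, nobs),
                             transfer_distances)
        ll2 = log_likelihood("MIX", p, EndorsementData.from_counts(ids[perm], counts[perm],
                                                                   nobs[perm]),
                             transfer_distances)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_timeouts_drop_out(self, transfer_distances):
        ids = transfer_distances.item_ids[:5]
        with_na = EndorsementData.from_binary(ids, [1, 0, np.nan, 1, np.nan])
        kept = EndorsementData.from_binary(ids[[0, 1, 3]], [1, 0, 1])
        p = ParameterSet(c=0.5, k=0.3)
        assert log_likelihood("PROTO", p, with_na, transfer_distances) == pytest.approx(
            log_likelihood("PROTO", p, kept, transfer_distances))

    def test_unknown_item_is_lookup_error(self, transfer_distances):
        data = EndorsementData.from_binary(["nope"], [1.0])
        with pytest.raises(DataError, match="nope"):
            log_likelihood("PROTO", ParameterSet(c=1.0, k=0.5), data, transfer_distances)


class TestSimilarityVectors:
    def test_mixture_blend_arithmetic(self):
        v = mixture_similarity_vector([0.4], [0.8], beta=0.5)
        assert v.s_mix[0] == pytest.approx(0.6)

    @pytest.mark.parametrize("beta,which", [(1.0, "s_proto"), (0.0, "s_ex")])
    def test_mixture_endpoints(self, beta, which, rng):
        s_p, s_e = rng.random(10), rng.random(10) * 3
        v = mixture_similarity_vector(s_p, s_e, beta=beta)
        assert np.allclose(v.s_mix, getattr(v, which))

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            mixture_similarity_vector([0.1, 0.2], [0.3], beta=0.5)

    def test_correlation_limits(self):
        x = np.array([0.1, 0.5, 0.9, 0.3])
        assert similarity_correlation(x, 2 * x) == pytest.approx(1.0)
        assert similarity_correlation(x, -x) == pytest.approx(-1.0)
        with pytest.raises(UndefinedCorrelationError):
            similarity_correlation(x, np.ones(4))
        with pytest.raises(ConfigurationError):
            similarity_correlation(x[:2], x[:2])

    def test_training_member_correlation_positive(self, stimset, training_distances):
        # prototype vs exemplar similarity over generated training members
        rows = [i for i, pid in enumerate(training_distances.item_ids)
                if str(pid).startswith("trm")]
        s_p = np.exp(-0.3 * training_distances.d_proto[rows])
        s_e = np.exp(-0.3 * training_distances.d_ex[rows]).sum(axis=1)
        assert similarity_correlation(s_p, s_e) > 0


class TestEndorsementDataValidation:
    def test_counts_above_denominator_rejected(self):
        with pytest.raises(DataError):
            EndorsementData.from_counts(["a"], [9.0], [8.0])

    def test_duplicate_items_rejected(self):
        with pytest.raises(DataError):
            EndorsementData.from_binary(["a", "a"], [1, 0])
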