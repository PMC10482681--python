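"""Categorical HMM: initialisation, forward likelihood, EM, Viterbi, labelling."""

import numpy as np
import pytest

from coldstate.ethogram import BehaviorVocabulary, ObservationSequence, encode_observations
from coldstate import hmm
from coldstate.synthetic_data import EthogramGenConfig, simulate_ethogram

from oracle_utils import (
    em_one_step_oracle,
    enumerate_best_path,
    enumerate_log_likelihood,
    random_params,
)


def obs(codes, V):
    return ObservationSequence(codes=np.asarray(codes), V=V)


# ------------------------------------------------------------- init_params
def test_init_uniform_transitions(vocab):
    p = hmm.init_params(3, vocab)
    assert np.allclose(p.A, 1.0 / 3) and np.allclose(p.pi, 1.0 / 3)
    assert np.allclose(p.B.sum(axis=1), 1.0)


def test_init_degenerate_single_state(vocab):
    p = hmm.init_params(1, vocab)
    assert p.A.tolist() == [[1.0]] and p.pi.tolist() == [1.0]


def test_init_jitter_deterministic_per_seed(vocab):
    a = hmm.init_params(3, vocab, jitter=0.1, seed=7)
    b = hmm.init_params(3, vocab, jitter=0.1, seed=7)
    c = hmm.init_params(3, vocab, jitter=0.1, seed=8)
    assert np.array_equal(a.B, b.B) and not np.array_equal(a.B, c.B)


def test_init_rejects_zero_row_template(vocab):
    tmpl = np.zeros((3, vocab.size))
    tmpl[0, 0] = 1.0
    tmpl[1, 1] = 1.0
    with pytest.raises(ValueError, match="zero row"):
        hmm.init_params(3, vocab, emission_template=tmpl)


# ------------------------------------------------- forward log-likelihood
def test_forward_single_state_is_product_of_emissions():
    p = hmm.HMMParams(pi=[1.0], A=[[1.0]], B=[[0.8, 0.2]])
    ll = hmm.forward_log_likelihood(p, obs([0, 0, 1], 2))
    assert np.isclose(ll, np.log(0.8 * 0.8 * 0.2))


def test_forward_length_one_mixture_collapses():
    b = 0.3
    p = hmm.HMMParams(
        pi=[0.5, 0.5], A=[[0.5, 0.5]] * 2, B=[[b, 1 - b], [b, 1 - b]]
    )
    assert np.isclose(hmm.forward_log_likelihood(p, obs([0], 2)), np.log(b))


def test_forward_matches_enumeration(rng):
    for _ in range(30):
        K, V, T = rng.integers(1, 4), rng.integers(2, 5), rng.integers(2, 9)
        p = random_params(K, V, rng)
        codes = rng.integers(0, V, T)
        got = hmm.forward_log_likelihood(p, obs(codes, V))
        want = enumerate_log_likelihood(p, codes)
        assert abs(got - want) <= 1e-10 * abs(want)


def test_forward_impossible_observation_is_neg_inf():
    p = hmm.HMMParams(pi=[1.0], A=[[1.0]], B=[[1.0, 0.0]])
    assert hmm.forward_log_likelihood(p, obs([0, 1], 2)) == -np.inf


def test_forward_agrees_with_hmmlearn(rng):
    """Independent cross-check against an external categorical-HMM library."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    p = random_params(3, 5, rng)
    codes = rng.integers(0, 5, 200)
    m = hmmlearn.CategoricalHMM(n_components=3)
    m.startprob_, m.transmat_, m.emissionprob_ = p.pi, p.A, p.B
    want = m.score(codes.reshape(-1, 1))
    got = hmm.forward_log_likelihood(p, obs(codes, 5))
    assert np.isclose(got, want, rtol=1e-10)


# -------------------------------------------------------------- Baum-Welch
def test_single_state_mstep_is_symbol_counting():
    p0 = hmm.HMMParams(pi=[1.0], A=[[1.0]], B=[[0.5, 0.3, 0.2]])
    codes = [0, 1, 0, 0, 2, 0]
    fit = hmm.baum_welch_fit(p0, [obs(codes, 3)], max_iter=1)
    freqs = np.bincount(codes, minlength=3) / len(codes)
    assert np.allclose(fit.params.B[0], freqs, atol=1e-6)


def test_one_em_iteration_matches_enumeration_oracle():
    p0 = hmm.HMMParams(
        pi=[0.5, 0.5], A=[[0.5, 0.5], [0.5, 0.5]], B=[[0.9, 0.1], [0.1, 0.9]]
    )
    codes = np.array([0, 1, 0])
    pi_o, A_o, B_o = em_one_step_oracle(p0, codes)
    fit = hmm.baum_welch_fit(p0, [obs(codes, 2)], max_iter=1)
    assert np.allclose(fit.params.pi, pi_o, atol=1e-9)
    assert np.allclose(fit.params.A, A_o, atol=1e-9)
    assert np.allclose(fit.params.B, B_o, atol=1e-7)  # emission floor slack


def test_em_monotone_and_stochastic(rng):
    for _ in range(10):
        K, V, T = rng.integers(2, 4), rng.integers(2, 6), 60
        p0 = random_params(K, V, rng)
        codes = rng.integers(0, V, T)
        fit = hmm.baum_welch_fit(p0, [obs(codes, V)], tol=1e-10, max_iter=25)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
        assert np.allclose(fit.params.A.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(fit.params.B.sum(axis=1), 1.0, atol=1e-9)
        assert np.isclose(fit.params.pi.sum(), 1.0, atol=1e-9)


def test_posteriors_sum_to_one(rng):
    p = random_params(3, 6, rng)
    codes = rng.integers(0, 6, 300)
    _, gamma, _ = hmm.posteriors(p, obs(codes, 6))
    assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


def test_degenerate_constant_sequence_converges_to_point_mass():
    p0 = random_params(2, 3, np.random.default_rng(0))
    fit = hmm.baum_welch_fit(p0, [obs([1] * 50, 3)], max_iter=50)
    assert fit.params.B[:, 1].min() > 0.999


def test_multi_sequence_pooling_uses_all_sequences(vocab, rng):
    cfg = EthogramGenConfig(duration_s=400, n_animals=3, seed=5)
    ethos, _ = simulate_ethogram(cfg)
    obs_list = [encode_observations(e, vocab) for e in ethos]
    p0 = hmm.init_params(3, vocab, jitter=0.2, seed=5)
    fit_all = hmm.baum_welch_fit(p0, obs_list, max_iter=10)
    fit_one = hmm.baum_welch_fit(p0, obs_list[:1], max_iter=10)
    assert not np.allclose(fit_all.params.B, fit_one.params.B)
    with pytest.raises(ValueError):
        hmm.baum_welch_fit(p0, [])


# ------------------------------------------------------------------ Viterbi
def test_viterbi_forced_path_when_emissions_partition():
    B = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    p = hmm.HMMParams(pi=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3), B=B)
    codes = [2, 0, 1, 1, 2]
    seq, _ = hmm.viterbi_decode(p, obs(codes, 3))
    assert seq.states.tolist() == codes


def test_viterbi_identical_states_tie_to_lowest_index():
    p = hmm.HMMParams(
        pi=[0.5, 0.5], A=[[0.5, 0.5]] * 2, B=[[0.4, 0.6], [0.4, 0.6]]
    )
    seq, _ = hmm.viterbi_decode(p, obs([0, 1, 1, 0], 2))
    assert seq.states.tolist() == [0, 0, 0, 0]
    assert not seq.semantic


def test_viterbi_matches_enumeration(rng):
    for _ in range(30):
        K, V, T = rng.integers(1, 4), rng.integers(2, 5), rng.integers(2, 7)
        p = random_params(K, V, rng)
        codes = rng.integers(0, V, T)
        seq, score = hmm.viterbi_decode(p, obs(codes, V))
        _, score_o = enumerate_best_path(p, codes)
        assert abs(score - score_o) <= 1e-10
        # the returned path itself achieves the enumerated maximum
        lp = np.log(p.pi[seq.states[0]] * p.B[seq.states[0], codes[0]])
        for t in range(1, T):
            lp += np.log(p.A[seq.states[t - 1], seq.states[t]] * p.B[seq.states[t], codes[t]])
        assert abs(lp - score_o) <= 1e-10


def test_viterbi_impossible_observation_names_step():
    p = hmm.HMMParams(pi=[1.0], A=[[1.0]], B=[[1.0, 0.0]])
    with pytest.raises(ValueError, match="step 2"):
        hmm.viterbi_decode(p, obs([0, 0, 1], 2))


# ------------------------------------------------------- semantic labelling
def _params_with_B(B):
    B = np.asarray(B, dtype=float)
    return hmm.HMMParams(pi=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3), B=B)


def test_semantic_assignment_by_emission_profile(vocab):
    B = np.full((3, vocab.size), 1e-3)
    B[0, vocab.code("sitting")] = 0.9
    B[1, vocab.code("eating")] = 0.9
    B[2, vocab.code("walking")] = 0.9
    B /= B.sum(axis=1, keepdims=True)
    m = hmm.assign_semantic_labels(_params_with_B(B), vocab)
    assert m.mapping == {0: 1, 1: 2, 2: 3}


def test_semantic_assignment_tie_breaks_to_lower_index(vocab):
    B = np.full((3, vocab.size), 1.0 / vocab.size)  # all rows equal
    m = hmm.assign_semantic_labels(_params_with_B(B), vocab)
    assert m.mapping == {1: 1, 0: 2, 2: 3}  # state 0 wins eating; then 1 wins sitting


def test_semantic_assignment_requires_three_states(vocab):
    p = hmm.HMMParams(pi=[1.0], A=[[1.0]], B=[np.full(vocab.size, 1 / vocab.size)])
    with pytest.raises(ValueError, match="three-state"):
        hmm.assign_semantic_labels(p, vocab)


def test_relabel_maps_and_flags():
    m = hmm.StateLabelMap({0: 1, 1: 2, 2: 3})
    raw = hmm.StateSequence(states=[0, 0, 1], semantic=False)
    sem = hmm.relabel(raw, m)
    assert sem.states.tolist() == [1, 1, 2] and sem.semantic
    with pytest.raises(ValueError, match="already"):
        hmm.relabel(sem, m)


def test_relabel_unknown_index_errors():
    m = hmm.StateLabelMap({0: 1, 1: 2})
    with pytest.raises(ValueError, match="not in label map"):
        hmm.relabel(hmm.StateSequence(states=[0, 2]), m)


# ------------------------------------------------------------ model file IO
def test_model_save_load_round_trip(tmp_path, vocab, rng):
    p = random_params(3, vocab.size, rng)
    m = hmm.assign_semantic_labels(p, vocab)
    hmm.save_model(tmp_path / "m.json", p, vocab, m)
    p2, v2, m2 = hmm.load_model(tmp_path / "m.json")
    assert np.allclose(p.A, p2.A) and np.allclose(p.B, p2.B)
    assert v2.actions == vocab.actions and m2.mapping == m.mapping


# --------------------------------------------------------- end-to-end fit
def test_parameter_recovery_on_synthetic_session(vocab):
    """Fit on generated ethograms and recover the generating chain."""
    cfg = EthogramGenConfig(seed=42)
    ethos, truths = simulate_ethogram(cfg)
    obs_list = [encode_observations(e, vocab) for e in ethos]
    p0 = hmm.init_params(3, vocab, jitter=0.3, seed=42)
    fit = hmm.baum_welch_fit(p0, obs_list, tol=1e-6, max_iter=200)
    label_map = hmm.assign_semantic_labels(fit.params, vocab)
    inv = {v: k for k, v in label_map.mapping.items()}
    A_hat = np.array(
        [[fit.params.A[inv[i], inv[j]] for j in (1, 2, 3)] for i in (1, 2, 3)]
    )
    assert np.abs(A_hat - cfg.params.A).max() <= 0.05
    acc = []
    for o, tr in zip(obs_list, truths):
        raw, _ = hmm.viterbi_decode(fit.params, o)
        acc.append(np.mean(hmm.relabel(raw, label_map).states == tr.states))
    assert np.mean(acc) >= 0.9
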