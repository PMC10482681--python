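"""Categorical hidden Markov model for behavioural-state segmentation.

The model has K hidden states (K=3 for the cold-exposure analysis: state 1 =
energy conservation, state 2 = exploration with feeding, state 3 =
exploration without feeding) emitting symbols from a V-symbol behaviour
vocabulary (V=15 by default).  Fitting uses multi-sequence Baum–Welch EM with
Rabiner-style per-step scaling of the forward/backward recursions, which is
numerically equivalent to log-space recursion and does not underflow on
multi-hour 1-Hz sequences.  Decoding uses log-space Viterbi with
lowest-index tie-breaking, so results are fully deterministic.

Because EM state indices are arbitrary (label switching), fitted states are
mapped to the semantic 1/2/3 labels from their emission profiles:
the state most likely to emit "eating" is state 2; of the remaining two, the
state with the most sitting+shivering mass is state 1 (energy conservation);
the remainder is state 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ethogram import BehaviorVocabulary, ObservationSequence

__all__ = [
    "HMMParams",
    "FitResult",
    "StateSequence",
    "StateLabelMap",
    "default_emission_template",
    "init_params",
    "forward_log_likelihood",
    "baum_welch_fit",
    "viterbi_decode",
    "assign_semantic_labels",
    "relabel",
    "save_model",
    "load_model",
]

_ROW_TOL = 1e-9
EMISSION_FLOOR = 1e-8


def _check_stochastic(v: np.ndarray, name: str) -> None:
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    sums = v.sum(axis=-1)
    if not np.allclose(sums, 1.0, rtol=0, atol=1e-6):
        raise ValueError(f"{name} rows must sum to 1 (got {sums})")


@dataclass
class HMMParams:
    """Initial distribution pi (K), transition matrix A (K,K), emissions B (K,V)."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.shape != (self.K, self.K):
            raise ValueError("A must be K x K")
        if self.B.shape[0] != self.K:
            raise ValueError("B must have K rows")
        _check_stochastic(self.pi, "pi")
        _check_stochastic(self.A, "A")
        _check_stochastic(self.B, "B")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def V(self) -> int:
        return self.B.shape[1]


@dataclass
class FitResult:
    params: HMMParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class StateSequence:
    """Decoded state path; ``semantic`` marks 1/2/3 labels vs raw 0..K-1 indices."""

    states: np.ndarray
    semantic: bool = False
    animal_id: str = ""
    bin_s: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.bin_s * np.arange(len(self.states))


@dataclass
class StateLabelMap:
    """Bijective raw-index -> semantic-label map (label-switching resolution)."""

    mapping: dict[int, int]

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("label map must be bijective")

    def __getitem__(self, raw: int) -> int:
        return self.mapping[raw]


def default_emission_template(
    vocab: BehaviorVocabulary | None = None, K: int = 3
) -> np.ndarray:
    """Informative K=3 emission starting guess over the 15-action vocabulary.

    State 1 mass sits on immobile/thermogenic actions, state 2 on
    feeding-related actions, state 3 on locomotor/exploratory and grooming
    actions, with a small floor elsewhere so no emission starts at zero.
    """
    vocab = vocab or BehaviorVocabulary.default()
    if K != 3:
        raise ValueError("the default template is defined for K=3")
    idx = vocab.index
    groups = (
        ("sitting", "shivering"),
        ("eating", "moving out", "moving back", "drinking"),
        (
            "walking",
            "digging",
            "bedding retrieval",
            "pushing bedding",
            "standing up",
            "head grooming",
            "lower body grooming",
            "grooming tail",
            "turning",
        ),
    )
    B = np.full((K, vocab.size), 0.01)
    for k, actions in enumerate(groups):
        present = [idx[a] for a in actions if a in idx]
        B[k, present] += 0.9 / len(present)
    return B / B.sum(axis=1, keepdims=True)


def init_params(
    K: int,
    vocab: BehaviorVocabulary | None = None,
    emission_template: np.ndarray | None = None,
    jitter: float = 0.0,
    seed: int = 0,
) -> HMMParams:
    """Uniform pi/A (no a-priori transition information) with templated B.

    ``jitter`` applies multiplicative log-normal noise to the template before
    row renormalisation, to break symmetry between EM restarts.
    """
    vocab = vocab or BehaviorVocabulary.default()
    if K < 1:
        raise ValueError("K must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if emission_template is None:
        if K == 3:
            B = default_emission_template(vocab, K)
        else:
            B = np.full((K, vocab.size), 1.0 / vocab.size)
    else:
        B = np.asarray(emission_template, dtype=float).copy()
        if B.shape != (K, vocab.size):
            raise ValueError("emission template must be K x V")
        if np.any(B.sum(axis=1) <= 0):
            raise ValueError("emission template has a zero row-sum")
    if jitter > 0:
        rng = np.random.default_rng(seed)
        B = B * np.exp(jitter * rng.standard_normal(B.shape))
    B = B / B.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 1.0 / K)
    return HMMParams(pi=pi, A=A, B=B)


def _scaled_forward(
    params: HMMParams, codes: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaled forward pass.

    Returns ``(loglik, alpha_hat, c)`` where ``alpha_hat[t]`` sums to 1 and
    ``loglik = sum(log c)``; ``loglik`` is -inf if the sequence is impossible.
    """
    T = len(codes)
    K = params.K
    Bobs = params.B[:, codes]  # (K, T)
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = params.pi * Bobs[:, 0]
    c[0] = a.sum()
    if c[0] == 0.0:
        return -np.inf, alpha, c
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ params.A) * Bobs[:, t]
        c[t] = a.sum()
        if c[t] == 0.0:
            return -np.inf, alpha, c
        alpha[t] = a / c[t]
    return float(np.log(c).sum()), alpha, c


def forward_log_likelihood(params: HMMParams, obs: ObservationSequence) -> float:
    """log P(obs | params); -inf when no state path has positive probability."""
    codes = np.asarray(obs.codes if isinstance(obs, ObservationSequence) else obs)
    if np.any(codes >= params.V) or np.any(codes < 0):
        raise ValueError("observation codes outside emission alphabet")
    ll, _, _ = _scaled_forward(params, codes)
    return ll


def _scaled_backward(params: HMMParams, codes: np.ndarray, c: np.ndarray) -> np.ndarray:
    T = len(codes)
    K = params.K
    Bobs = params.B[:, codes]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (params.A @ (Bobs[:, t + 1] * beta[t + 1])) / c[t + 1]
    return beta


def posteriors(
    params: HMMParams, obs: ObservationSequence
) -> tuple[float, np.ndarray, np.ndarray]:
    """E-step quantities for one sequence.

    Returns ``(loglik, gamma, xi_sum)`` with ``gamma`` of shape (T, K) the
    per-step state posteriors and ``xi_sum`` of shape (K, K) the expected
    transition counts summed over t.
    """
    codes = np.asarray(obs.codes if isinstance(obs, ObservationSequence) else obs)
    ll, alpha, c = _scaled_forward(params, codes)
    if not np.isfinite(ll):
        raise ValueError("observation sequence impossible under current model")
    beta = _scaled_backward(params, codes, c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    Bobs = params.B[:, codes]
    T = len(codes)
    xi_sum = np.zeros((params.K, params.K))
    for t in range(T - 1):
        xi = (
            alpha[t][:, None]
            * params.A
            * (Bobs[:, t + 1] * beta[t + 1])[None, :]
            / c[t + 1]
        )
        xi_sum += xi
    return ll, gamma, xi_sum


def baum_welch_fit(
    params0: HMMParams,
    obs_list: list[ObservationSequence],
    tol: float = 1e-6,
    max_iter: int = 500,
    emission_floor: float = EMISSION_FLOOR,
) -> FitResult:
    """Multi-sequence Baum–Welch EM.

    Expected counts are pooled across sequences (one shared model for all
    animals); each sequence restarts from pi.  Iteration stops when the
    relative log-likelihood improvement drops below ``tol``.  After each
    M-step, emission entries below ``emission_floor`` are raised to the floor
    and rows renormalised, so behaviours unseen in the data cannot freeze at
    exact zero probability.
    """
    if not obs_list:
        raise ValueError("need at least one observation sequence")
    for obs in obs_list:
        if len(obs) < 2:
            raise ValueError("each sequence must have length >= 2")
        if np.any(np.asarray(obs.codes) >= params0.V):
            raise ValueError("observation codes outside emission alphabet")
    params = HMMParams(pi=params0.pi.copy(), A=params0.A.copy(), B=params0.B.copy())
    K, V = params.K, params.V
    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        total_ll = 0.0
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        gamma_from_acc = np.zeros(K)  # occupancy over t = 0..T-2
        emit_acc = np.zeros((K, V))
        occ_acc = np.zeros(K)
        for obs in obs_list:
            codes = np.asarray(obs.codes)
            ll, gamma, xi_sum = posteriors(params, obs)
            total_ll += ll
            pi_acc += gamma[0]
            xi_acc += xi_sum
            gamma_from_acc += gamma[:-1].sum(axis=0)
            occ_acc += gamma.sum(axis=0)
            np.add.at(emit_acc.T, codes, gamma)
        trace.append(total_ll)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(total_ll - prev) <= tol * abs(prev):
                converged = True
                break
        # M-step
        pi = pi_acc / pi_acc.sum()
        A = np.where(
            gamma_from_acc[:, None] > 0, xi_acc / gamma_from_acc[:, None], 1.0 / K
        )
        A = A / A.sum(axis=1, keepdims=True)
        B = np.where(occ_acc[:, None] > 0, emit_acc / occ_acc[:, None], 1.0 / V)
        B = np.maximum(B, emission_floor)
        B = B / B.sum(axis=1, keepdims=True)
        params = HMMParams(pi=pi, A=A, B=B)
    return FitResult(
        params=params,
        loglik_trace=np.asarray(trace),
        n_iter=len(trace),
        converged=converged,
    )


def viterbi_decode(
    params: HMMParams, obs: ObservationSequence
) -> tuple[StateSequence, float]:
    """Most probable state path (raw indices) and its log-probability.

    Ties at every backtrack step break toward the lowest state index, so the
    returned path is unique and deterministic.
    """
    codes = np.asarray(obs.codes if isinstance(obs, ObservationSequence) else obs)
    if np.any(codes >= params.V) or np.any(codes < 0):
        raise ValueError("observation codes outside emission alphabet")
    T = len(codes)
    K = params.K
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
        log_B = np.log(params.B)
    delta = log_pi + log_B[:, codes[0]]
    if np.all(np.isneginf(delta)):
        raise ValueError("observation impossible under the model at step 0")
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_A  # (from, to)
        psi[t] = np.argmax(cand, axis=0)  # argmax picks the lowest index on ties
        delta = cand[psi[t], np.arange(K)] + log_B[:, codes[t]]
        if np.all(np.isneginf(delta)):
            raise ValueError(f"observation impossible under the model at step {t}")
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta))
    best = float(delta[path[T - 1]])
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    animal_id = obs.animal_id if isinstance(obs, ObservationSequence) else ""
    return StateSequence(states=path, semantic=False, animal_id=animal_id), best


def assign_semantic_labels(
    params: HMMParams, vocab: BehaviorVocabulary | None = None
) -> StateLabelMap:
    """Map raw fitted states to semantic labels 1/2/3 from emission profiles.

    The state with the highest eating probability becomes state 2
    (exploration with feeding); of the remaining two, the state with the
    largest sitting+shivering mass becomes state 1 (energy conservation); the
    remainder is state 3.  Ties break toward the lower raw index.
    """
    vocab = vocab or BehaviorVocabulary.default()
    if params.K != 3:
        raise ValueError("semantic labels are defined for the three-state model")
    idx = vocab.index
    for needed in ("eating", "sitting"):
        if needed not in idx:
            raise ValueError(f"vocabulary lacks required action {needed!r}")
    eat = params.B[:, idx["eating"]]
    s2 = int(np.argmax(eat))
    rest = [k for k in range(3) if k != s2]
    conserve = params.B[:, idx["sitting"]]
    if "shivering" in idx:
        conserve = conserve + params.B[:, idx["shivering"]]
    s1 = rest[0] if conserve[rest[0]] >= conserve[rest[1]] else rest[1]
    s3 = rest[1] if s1 == rest[0] else rest[0]
    return StateLabelMap(mapping={s1: 1, s2: 2, s3: 3})


def relabel(states: StateSequence, label_map: StateLabelMap) -> StateSequence:
    """Element-wise raw-index -> semantic relabelling."""
    if states.semantic:
        raise ValueError("sequence already carries semantic labels")
    try:
        mapped = np.asarray([label_map[int(s)] for s in states.states], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"raw state index {exc.args[0]} not in label map") from None
    return StateSequence(
        states=mapped,
        semantic=True,
        animal_id=states.animal_id,
        bin_s=states.bin_s,
        t0=states.t0,
    )


def save_model(
    path,
    params: HMMParams,
    vocab: BehaviorVocabulary | None = None,
    label_map: StateLabelMap | None = None,
    fit: FitResult | None = None,
) -> None:
    """Serialise a fitted model (pi, A, B, vocabulary, label map, fit metadata)."""
    vocab = vocab or BehaviorVocabulary.default()
    payload: dict = {
        "pi": params.pi.tolist(),
        "A": params.A.tolist(),
        "B": params.B.tolist(),
        "vocab": list(vocab.actions),
    }
    if label_map is not None:
        payload["label_map"] = {str(k): v for k, v in label_map.mapping.items()}
    if fit is not None:
        payload["fit"] = {
            "n_iter": fit.n_iter,
            "converged": fit.converged,
            "loglik_trace": fit.loglik_trace.tolist(),
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> tuple[HMMParams, BehaviorVocabulary, StateLabelMap | None]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    params = HMMParams(
        pi=np.asarray(payload["pi"]),
        A=np.asarray(payload["A"]),
        B=np.asarray(payload["B"]),
    )
    vocab = BehaviorVocabulary(tuple(payload["vocab"]))
    label_map = None
    if "label_map" in payload:
        label_map = StateLabelMap(
            {int(k): int(v) for k, v in payload["label_map"].items()}
        )
    return params, vocab, label_map
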