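"""Independent brute-force oracles for the HMM tests.

These enumerate every hidden-state path explicitly and never share code with
the recursions they check.
"""

from __future__ import annotations

import numpy as np

from coldstate.hmm import HMMParams


def all_paths(K: int, T: int) -> np.ndarray:
    """All K^T state paths as an array of shape (T, K^T)."""
    return np.indices((K,) * T).reshape(T, -1)


def _path_log_probs(params: HMMParams, codes: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
        log_B = np.log(params.B)
    paths = all_paths(params.K, len(codes))
    lp = log_pi[paths[0]] + log_B[paths[0], codes[0]]
    for t in range(1, len(codes)):
        lp = lp + log_A[paths[t - 1], paths[t]] + log_B[paths[t], codes[t]]
    return lp


def enumerate_log_likelihood(params: HMMParams, codes: np.ndarray) -> float:
    """log P(obs) as a sum over every state path."""
    lp = _path_log_probs(params, codes)
    finite = lp[np.isfinite(lp)]
    if len(finite) == 0:
        return -np.inf
    m = finite.max()
    return float(m + np.log(np.exp(finite - m).sum()))


def enumerate_best_path(params: HMMParams, codes: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-probability path and its log-probability by enumeration.

    Among ties, the lexicographically smallest path is returned, matching the
    lowest-index tie-break of the recursive decoder.
    """
    lp = _path_log_probs(params, codes)
    best = lp.max()
    paths = all_paths(params.K, len(codes))
    tied = paths[:, np.isclose(lp, best, rtol=0, atol=1e-12)]
    order = np.lexsort(tied[::-1])
    return tied[:, order[0]].copy(), float(best)


def random_params(K: int, V: int, rng: np.random.Generator) -> HMMParams:
    return HMMParams(
        pi=rng.dirichlet(np.ones(K)),
        A=rng.dirichlet(np.ones(K), size=K),
        B=rng.dirichlet(np.ones(V), size=K),
    )


def em_one_step_oracle(
    params: HMMParams, codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One exact EM update (pi, A, B) from enumeration posteriors.

    Path posteriors are computed by explicit enumeration; expected counts
    follow by summation.  No forward/backward recursion is involved.
    """
    lp = _path_log_probs(params, codes)
    w = np.exp(lp - lp.max())
    w = w / w.sum()
    paths = all_paths(params.K, len(codes))
    K, V, T = params.K, params.V, len(codes)
    gamma = np.zeros((T, K))
    for t in range(T):
        for k in range(K):
            gamma[t, k] = w[paths[t] == k].sum()
    xi = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi[i, j] += w[(paths[t] == i) & (paths[t + 1] == j)].sum()
    pi_new = gamma[0]
    A_new = xi / gamma[:-1].sum(axis=0)[:, None]
    B_new = np.zeros((K, V))
    for v in range(V):
        B_new[:, v] = gamma[codes == v].sum(axis=0)
    B_new = B_new / gamma.sum(axis=0)[:, None]
    return pi_new, A_new, B_new
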