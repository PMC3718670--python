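"""Independent brute-force oracles used by the test suite.

Everything here enumerates explicitly (all 3**T state paths, or a dense
parameter grid) and never calls the scaled/recursive implementations it
is checking.
"""

import itertools

import numpy as np


def enumerate_paths(T, n_states=3):
    return itertools.product(range(n_states), repeat=T)


def path_log_prob(path, log_b, pi, A):
    p = np.log(pi[path[0]]) + log_b[0, path[0]]
    for t in range(1, len(path)):
        p += np.log(A[path[t - 1], path[t]]) + log_b[t, path[t]]
    return p


def brute_force_loglik(log_b, pi, A):
    """log sum over all state paths of pi * prod A * prod b."""
    T = log_b.shape[0]
    logs = [path_log_prob(p, log_b, pi, A) for p in enumerate_paths(T)]
    m = max(logs)
    return m + np.log(sum(np.exp(v - m) for v in logs))

def brute_force_posteriors(log_b, pi, A):
    """Per-site state posteriors and per-step pair posteriors."""
    T = log_b.shape[0]
    gamma = np.zeros((T, 3))
    xi = np.zeros((max(T - 1, 0), 3, 3))
    weights = []
    paths = list(enumerate_paths(T))
    logs = np.array([path_log_prob(p, log_b, pi, A) for p in paths])
    w = np.exp(logs - logs.max())
    w /= w.sum()
    for path, wt in zip(paths, w):
        for t, s in enumerate(path):
            gamma[t, s] += wt
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += wt
    return gamma, xi


def brute_force_viterbi(log_b, pi, A):
    """Best path by enumeration; ties broken toward the lexicographically
    smallest path (consistent with lower-state-index tie-breaking)."""
    best_path, best_score = None, -np.inf
    for p in enumerate_paths(log_b.shape[0]):
        s = path_log_prob(p, log_b, pi, A)
        if s > best_score + 1e-15:
            best_path, best_score = p, s
    return np.array(best_path), best_score


def grid_argmax_u(obs_seq, weights, step=1e-5):
    """Dense grid maximizer of the weighted expected log-emission term."""
    from snvhmm.hmm_core import site_emission

    grid = np.arange(step, 1.0, step)
    a_list, b_list, m_list, w_list = [], [], [], []
    for obs, w in zip(obs_seq, weights):
        r, q = obs.r, obs.q
        a = 0.25 * (1 - r) + 0.5 * r * (1 - q)
        b = 0.5 * r * (2 * q - 1)
        a_list.append(a)
        b_list.append(b)
        m_list.append(obs.match)
        w_list.append(np.full(obs.L, w))
    a = np.concatenate(a_list)
    b = np.concatenate(b_list)
    m = np.concatenate(m_list)
    w = np.concatenate(w_list)
    p = a[:, None] + b[:, None] * grid[None, :]
    p = np.clip(p, 1e-300, 1 - 1e-16)
    per_read = np.where(m[:, None], np.log(p), np.log1p(-p))
    q3 = w @ per_read
    return grid[int(np.argmax(q3))]


def random_hmm_params(rng):
    from snvhmm.hmm_core import HMMParameters

    pi = rng.dirichlet(np.ones(3) * 2)
    A = np.vstack([rng.dirichlet(np.ones(3) * 2) for _ in range(3)])
    u = np.sort(rng.uniform(0.05, 0.95, size=3))[::-1]
    return HMMParameters(pi=pi, A=A, u=u)


def random_observation(rng, chrom="chr1", pos=1, max_depth=6):
    """A random filtered observation with consistent bookkeeping."""
    from snvhmm.pileup_io import SiteObservation

    L = int(rng.integers(1, max_depth + 1))
    match = rng.random(L) < rng.uniform(0.2, 0.8)
    r = rng.uniform(0.5, 0.999999, size=L)
    q = rng.uniform(0.5, 0.9999, size=L)
    return SiteObservation(
        chrom=chrom,
        pos=pos,
        ref_base="A",
        alt_base="T",
        L=L,
        P=int(match.sum()),
        r=r,
        q=q,
        match=match,
    )


def random_obs_seq(rng, T, **kw):
    return [random_observation(rng, pos=t + 1, **kw) for t in range(T)]
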