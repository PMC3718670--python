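"""3-genotype-state HMM: emission model, training, decoding.

The hidden states are the genotypes aa / ab / bb of each covered genome
position.  Emissions are a generalized binomial over the site's reads in
which every read contributes a match probability that blends its mapping
correctness ``r``, base-call correctness ``q`` and the state's
reference-allele frequency ``u``:

    p(u) = 0.25*(1 - r) + 0.5*r*(q*u + (1 - q)*(1 - u))

Training is Baum-Welch with closed-form updates for the initial
distribution and transition matrix and a damped Newton step for the
per-state ``u`` parameters; decoding is Viterbi.  All trellis work is
scaled per step so chains of millions of sites stay finite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import gammaln

from .pileup_io import SiteObservation

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "GenotypeState",
    "HMMParameters",
    "PriorHyperparameters",
    "TrainConfig",
    "TrellisCache",
    "N_STATES",
    "U_EPS",
    "per_read_match_prob",
    "site_emission",
    "emission_table",
    "init_from_priors",
    "forward_backward",
    "forward_backward_logb",
    "update_initial",
    "update_transitions",
    "update_u_newton",
    "baum_welch_train",
    "viterbi_decode",
    "viterbi_decode_logb",
    "save_params",
    "load_params",
]

N_STATES = 3
U_EPS = 1e-6


class GenotypeState(enum.IntEnum):
    """Genotype hidden states; AB and BB are the SNV states."""

    AA = 1
    AB = 2
    BB = 3

    @property
    def index(self) -> int:
        return self.value - 1

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_index(cls, i: int) -> "GenotypeState":
        return cls(i + 1)

    @classmethod
    def from_label(cls, s: str) -> "GenotypeState":
        return cls[s.upper()]

    @property
    def is_snv(self) -> bool:
        return self is not GenotypeState.AA


@dataclass
class HMMParameters:
    """lambda = (pi, A, u): initial distribution, transitions, per-state
    reference-allele frequency."""

    pi: np.ndarray
    A: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.pi.shape != (N_STATES,) or self.A.shape != (N_STATES, N_STATES):
            raise ValueError("parameter shape mismatch")
        if self.u.shape != (N_STATES,):
            raise ValueError("u must have one entry per state")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if np.max(np.abs(self.A.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("rows of A must sum to 1")
        if np.any(self.u < U_EPS - 1e-15) or np.any(self.u > 1 - U_EPS + 1e-15):
            raise ValueError(f"u entries must lie in [{U_EPS}, {1 - U_EPS}]")

    def copy(self) -> "HMMParameters":
        return HMMParameters(self.pi.copy(), self.A.copy(), self.u.copy())


def _paper_defaults():
    return dict(
        delta=np.array([1000.0, 100.0, 100.0]),
        alpha=np.array([1000.0, 500.0, 1.0]),
        beta=np.array([1.0, 500.0, 1000.0]),
        gamma=np.array(
            [
                [1000.0, 100.0, 100.0],
                [100.0, 1000.0, 100.0],
                [100.0, 100.0, 1000.0],
            ]
        ),
    )


@dataclass
class PriorHyperparameters:
    """Dirichlet/Beta hyperparameters seeding the model.

    Defaults encode the expectation that most positions are homozygous
    reference: delta=(1000,100,100), alpha=(1000,500,1), beta=(1,500,1000)
    and strongly diagonal Dirichlets on the transition rows.
    """

    delta: np.ndarray = field(default_factory=lambda: _paper_defaults()["delta"])
    alpha: np.ndarray = field(default_factory=lambda: _paper_defaults()["alpha"])
    beta: np.ndarray = field(default_factory=lambda: _paper_defaults()["beta"])
    gamma: np.ndarray = field(default_factory=lambda: _paper_defaults()["gamma"])

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("Beta hyperparameters must be positive")
        if np.any(self.delta <= 0) or np.any(self.gamma <= 0):
            raise ValueError("Dirichlet hyperparameters must be positive")


@dataclass
class TrainConfig:
    max_iter: int = 100
    tol: float = 1e-4  # absolute change in total log-likelihood
    newton_steps: int = 8  # Newton iterations per EM step, per state
    u_clamp_eps: float = U_EPS
    seed: int = 0
    init_mode: str = "prior_mean"  # or "prior_sample"
    map_updates: bool = False  # add Dirichlet pseudocounts to pi/A updates

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.init_mode not in ("prior_mean", "prior_sample"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class TrellisCache:
    """Scaled forward/backward variables and the posteriors derived from them."""

    scaled_forward: np.ndarray  # (T, 3)
    scaled_backward: np.ndarray  # (T, 3)
    scale_factors: np.ndarray  # (T,) log scale per forward step
    state_posterior: np.ndarray  # (T, 3) gamma_t(i)
    pair_posterior: np.ndarray  # (T-1, 3, 3) xi_t(i, j)
    log_likelihood: float

    @property
    def T(self) -> int:
        return self.scaled_forward.shape[0]


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------

def match_prob_coeffs(r, q):
    """Coefficients (a, b) such that the per-read reference-match
    probability is ``a + b*u``."""
    r = np.asarray(r, dtype=float)
    q = np.asarray(q, dtype=float)
    a = 0.25 * (1.0 - r) + 0.5 * r * (1.0 - q)
    b = 0.5 * r * (2.0 * q - 1.0)
    return a, b


def per_read_match_prob(r, q, u):
    """Probability that a read shows the reference base, given mapping
    correctness ``r``, base-call correctness ``q`` and state allele
    frequency ``u``.  Shared by the emission model and the simulator."""
    a, b = match_prob_coeffs(r, q)
    return a + b * u


def _check_u(u_i: float) -> None:
    if not (0.0 <= u_i <= 1.0):
        raise ValueError(f"u must lie in [0, 1], got {u_i}")


def site_emission(obs: SiteObservation, u_i: float) -> float:
    """Log emission likelihood of one site under allele frequency ``u_i``.

    ``C(L, P) * prod_match p_j(u_i) * prod_mismatch (1 - p_j(u_i))`` in
    log space; an empty observation has log-likelihood 0 (likelihood 1).
    """
    _check_u(u_i)
    if obs.L == 0:
        return 0.0
    p = per_read_match_prob(obs.r, obs.q, u_i)
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    log_c = gammaln(obs.L + 1) - gammaln(obs.P + 1) - gammaln(obs.L - obs.P + 1)
    return float(
        log_c
        + np.log(p[obs.match]).sum()
        + np.log1p(-p[~obs.match]).sum()
    )


class _PackedChain:
    """Flattened read-level arrays for one chain, for vectorized emissions.

    Reads from all sites are concatenated; ``site_idx`` maps each read
    back to its site so per-site sums become bincounts.
    """

    __slots__ = ("T", "site_idx", "a", "b", "match", "log_c")

    def __init__(self, obs_seq: Sequence[SiteObservation]):
        self.T = len(obs_seq)
        L = np.array([o.L for o in obs_seq], dtype=np.int64)
        P = np.array([o.P for o in obs_seq], dtype=np.int64)
        self.site_idx = np.repeat(np.arange(self.T, dtype=np.int64), L)
        if len(self.site_idx):
            r = np.concatenate([o.r for o in obs_seq])
            q = np.concatenate([o.q for o in obs_seq])
            self.match = np.concatenate([o.match for o in obs_seq])
        else:
            r = q = np.empty(0)
            self.match = np.empty(0, dtype=bool)
        self.a, self.b = match_prob_coeffs(r, q)
        self.log_c = gammaln(L + 1) - gammaln(P + 1) - gammaln(L - P + 1)

    def log_emissions(self, u: np.ndarray) -> np.ndarray:
        """(T, 3) matrix of log emission likelihoods."""
        out = np.empty((self.T, N_STATES))
        for i in range(N_STATES):
            p = np.clip(self.a + self.b * u[i], 1e-300, 1.0 - 1e-16)
            per_read = np.where(self.match, np.log(p), np.log1p(-p))
            out[:, i] = self.log_c + np.bincount(
                self.site_idx, weights=per_read, minlength=self.T
            )
        return out


def emission_table(
    obs_seq: Sequence[SiteObservation], u: np.ndarray
) -> np.ndarray:
    """(T, 3) log-emission matrix; entry (t, i) is site_emission(obs_t, u_i)."""
    if len(obs_seq) == 0:
        raise ValueError("empty observation sequence")
    for u_i in u:
        _check_u(float(u_i))
    return _PackedChain(obs_seq).log_emissions(np.asarray(u, dtype=float))


# ---------------------------------------------------------------------------
# Initialization from priors
# ---------------------------------------------------------------------------

def init_from_priors(
    hyper: Optional[PriorHyperparameters] = None,
    mode: str = "prior_mean",
    seed: Optional[int] = None,
) -> HMMParameters:
    """Seed lambda from the Dirichlet/Beta hyperparameters.

    ``prior_mean`` takes the analytic means; ``prior_sample`` draws from
    the prior distributions (seed required).
    """
    hyper = hyper if hyper is not None else PriorHyperparameters()
    if mode == "prior_mean":
        pi = hyper.delta / hyper.delta.sum()
        A = hyper.gamma / hyper.gamma.sum(axis=1, keepdims=True)
        u = hyper.alpha / (hyper.alpha + hyper.beta)
    elif mode == "prior_sample":
        if seed is None:
            raise ValueError("prior_sample mode requires a seed")
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(hyper.delta)
        A = np.vstack([rng.dirichlet(row) for row in hyper.gamma])
        u = rng.beta(hyper.alpha, hyper.beta)
        pi = pi / pi.sum()
        A = A / A.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    u = np.clip(u, U_EPS, 1.0 - U_EPS)
    return HMMParameters(pi=pi, A=A, u=u)


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fb_kernel(Bs, pi, A):  # pragma: no cover - numba-compiled
    """Scaled forward-backward on row-scaled linear emissions ``Bs``.

    Returns alpha_hat, log forward scales, beta_hat (independently
    scaled), gamma, xi, and the two partial log-likelihoods (forward /
    backward), each missing the shared sum of emission row maxima.
    """
    T, I = Bs.shape
    alpha = np.empty((T, I))
    c_log = np.empty(T)
    # forward
    s = 0.0
    for i in range(I):
        alpha[0, i] = pi[i] * Bs[0, i]
        s += alpha[0, i]
    c_log[0] = np.log(s)
    for i in range(I):
        alpha[0, i] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(I):
            acc = 0.0
            for i in range(I):
                acc += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = acc * Bs[t, j]
            s += alpha[t, j]
        c_log[t] = np.log(s)
        for j in range(I):
            alpha[t, j] /= s
    # backward, with its own per-step scaling
    beta = np.empty((T, I))
    ll_bwd = 0.0
    for i in range(I):
        beta[T - 1, i] = 1.0
    for t in range(T - 2, -1, -1):
        s = 0.0
        for i in range(I):
            acc = 0.0
            for j in range(I):
                acc += A[i, j] * Bs[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc
            s += acc
        ll_bwd += np.log(s)
        for i in range(I):
            beta[t, i] /= s
    s = 0.0
    for i in range(I):
        s += pi[i] * Bs[0, i] * beta[0, i]
    ll_bwd += np.log(s)
    # posteriors
    gamma = np.empty((T, I))
    for t in range(T):
        s = 0.0
        for i in range(I):
            gamma[t, i] = alpha[t, i] * beta[t, i]
            s += gamma[t, i]
        for i in range(I):
            gamma[t, i] /= s
    xi = np.empty((T - 1, I, I))
    for t in range(T - 1):
        s = 0.0
        for i in range(I):
            for j in range(I):
                v = alpha[t, i] * A[i, j] * Bs[t + 1, j] * beta[t + 1, j]
                xi[t, i, j] = v
                s += v
        for i in range(I):
            for j in range(I):
                xi[t, i, j] /= s
    ll_fwd = c_log.sum()
    return alpha, c_log, beta, gamma, xi, ll_fwd, ll_bwd


def forward_backward_logb(
    log_b: np.ndarray, pi: np.ndarray, A: np.ndarray
) -> TrellisCache:
    """Forward-backward over an explicit (T, 3) log-emission matrix."""
    log_b = np.asarray(log_b, dtype=float)
    T = log_b.shape[0]
    if T == 0:
        raise ValueError("empty observation sequence")
    row_max = log_b.max(axis=1)
    bad = np.where(~np.isfinite(row_max))[0]
    if len(bad):
        raise FloatingPointError(
            f"all-zero emission row at position index {bad[0]}"
        )
    Bs = np.exp(log_b - row_max[:, None])
    alpha, c_log, beta, gamma, xi, ll_fwd, ll_bwd = _fb_kernel(
        Bs, np.asarray(pi, dtype=float), np.asarray(A, dtype=float)
    )
    shift = row_max.sum()
    ll_fwd += shift
    ll_bwd += shift
    if abs(ll_fwd - ll_bwd) > 1e-8 * max(1.0, abs(ll_fwd)):
        raise FloatingPointError(
            f"forward/backward likelihood mismatch: {ll_fwd} vs {ll_bwd}"
        )
    return TrellisCache(
        scaled_forward=alpha,
        scaled_backward=beta,
        scale_factors=c_log + row_max,
        state_posterior=gamma,
        pair_posterior=xi,
        log_likelihood=float(ll_fwd),
    )


def forward_backward(
    obs_seq: Sequence[SiteObservation], params: HMMParameters
) -> TrellisCache:
    """Scaled forward-backward over an observation chain."""
    log_b = emission_table(obs_seq, params.u)
    return forward_backward_logb(log_b, params.pi, params.A)


# ---------------------------------------------------------------------------
# Baum-Welch updates
# ---------------------------------------------------------------------------

def update_initial(cache: TrellisCache) -> np.ndarray:
    """New pi: the state posterior of the first position."""
    pi = cache.state_posterior[0].copy()
    return pi / pi.sum()


def update_transitions(
    cache: TrellisCache, prev_A: Optional[np.ndarray] = None
) -> np.ndarray:
    """New A: expected transition counts over expected occupancies, rows
    renormalized.  A state with zero expected occupancy keeps its
    previous row (uniform if no previous A is supplied)."""
    if cache.T < 2:
        raise ValueError("transition update needs T >= 2")
    num = cache.pair_posterior.sum(axis=0)
    den = cache.state_posterior[:-1].sum(axis=0)
    A = np.empty((N_STATES, N_STATES))
    for i in range(N_STATES):
        if den[i] <= 1e-300:
            A[i] = prev_A[i] if prev_A is not None else np.full(N_STATES, 1 / 3)
        else:
            A[i] = num[i] / den[i]
    return A / A.sum(axis=1, keepdims=True)


def _q3_terms(packed: _PackedChain, w: np.ndarray, u: float):
    """Value, first and second derivative of the expected log-emission
    term Q3(u) = sum_t gamma_t(i) log f(o_t; u) for one state."""
    wr = w[packed.site_idx]
    p = np.clip(packed.a + packed.b * u, 1e-300, 1.0 - 1e-16)
    m = packed.match
    g = np.where(m, packed.b / p, -packed.b / (1.0 - p))
    val = float(
        np.dot(wr, np.where(m, np.log(p), np.log1p(-p)))
        + np.dot(w, packed.log_c)
    )
    d1 = float(np.dot(wr, g))
    d2 = -float(np.dot(wr, g * g))
    return val, d1, d2


def _newton_maximize_u(
    packed: _PackedChain, w: np.ndarray, u0: float, steps: int, eps: float
) -> float:
    """Damped Newton ascent of the concave Q3; clamped to [eps, 1-eps]."""
    u = min(max(u0, eps), 1.0 - eps)
    val, d1, d2 = _q3_terms(packed, w, u)
    if not (math.isfinite(d1) and math.isfinite(d2)):
        raise FloatingPointError("non-finite derivative in u update")
    for _ in range(steps):
        if d2 >= 0.0:  # all b_j ~ 0: u unidentifiable, keep current value
            break
        step = -d1 / d2
        u_new = min(max(u + step, eps), 1.0 - eps)
        val_new = _q3_terms(packed, w, u_new)[0]
        halvings = 0
        while val_new < val - 1e-12 and halvings < 40:
            step *= 0.5
            u_new = min(max(u + step, eps), 1.0 - eps)
            val_new = _q3_terms(packed, w, u_new)[0]
            halvings += 1
        if abs(u_new - u) < 1e-12:
            break
        u = u_new
        val, d1, d2 = _q3_terms(packed, w, u)
        if not (math.isfinite(d1) and math.isfinite(d2)):
            raise FloatingPointError("non-finite derivative in u update")
    return u


def update_u_newton(
    obs_seq: Sequence[SiteObservation],
    cache: TrellisCache,
    u_old: np.ndarray,
    config: Optional[TrainConfig] = None,
) -> np.ndarray:
    """Newton-maximize the expected log-emission term per state."""
    config = config if config is not None else TrainConfig()
    packed = obs_seq if isinstance(obs_seq, _PackedChain) else _PackedChain(obs_seq)
    if packed.T != cache.T:
        raise ValueError("cache not aligned with observation sequence")
    u_new = np.empty(N_STATES)
    for i in range(N_STATES):
        try:
            u_new[i] = _newton_maximize_u(
                packed,
                cache.state_posterior[:, i],
                float(u_old[i]),
                config.newton_steps,
                config.u_clamp_eps,
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"state {i + 1}: {exc}") from exc
    return u_new


def _as_chains(obs) -> List[Sequence[SiteObservation]]:
    if len(obs) == 0:
        raise ValueError("empty observation sequence")
    if isinstance(obs[0], SiteObservation):
        return [obs]
    return [c for c in obs if len(c)]


def baum_welch_train(
    obs_seq,
    init: Optional[HMMParameters] = None,
    hyper: Optional[PriorHyperparameters] = None,
    config: Optional[TrainConfig] = None,
) -> Tuple[HMMParameters, List[float], bool]:
    """EM training; accepts one chain or a list of per-chromosome chains.

    Returns (parameters, per-iteration log-likelihood trace, converged).
    The trace is non-decreasing up to the damped-Newton tolerance.
    """
    config = config if config is not None else TrainConfig()
    hyper = hyper if hyper is not None else PriorHyperparameters()
    if init is None:
        init = init_from_priors(hyper, mode=config.init_mode, seed=config.seed)
    chains = _as_chains(obs_seq)
    packed = [_PackedChain(c) for c in chains]
    all_packed = _PackedChain([o for c in chains for o in c])

    params = init.copy()
    trace: List[float] = []
    converged = False
    for _ in range(config.max_iter):
        caches = [
            forward_backward_logb(p.log_emissions(params.u), params.pi, params.A)
            for p in packed
        ]
        ll = sum(c.log_likelihood for c in caches)
        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break
        # M-step: pi from first-position posteriors across chains
        pi_num = np.sum([c.state_posterior[0] for c in caches], axis=0)
        xi_sum = np.zeros((N_STATES, N_STATES))
        occ_sum = np.zeros(N_STATES)
        for c in caches:
            if c.T >= 2:
                xi_sum += c.pair_posterior.sum(axis=0)
                occ_sum += c.state_posterior[:-1].sum(axis=0)
        if config.map_updates:
            pi_num = pi_num + (hyper.delta - 1.0)
            xi_sum = xi_sum + (hyper.gamma - 1.0)
            occ_sum = occ_sum + (hyper.gamma - 1.0).sum(axis=1)
        pi = np.clip(pi_num, 0.0, None)
        pi = pi / pi.sum()
        A = np.empty((N_STATES, N_STATES))
        for i in range(N_STATES):
            if occ_sum[i] <= 1e-300:
                A[i] = params.A[i]
            else:
                A[i] = np.clip(xi_sum[i], 0.0, None) / occ_sum[i]
        A = A / A.sum(axis=1, keepdims=True)
        # u via damped Newton on the concatenated chains
        gamma_all = np.vstack([c.state_posterior for c in caches])
        u = np.empty(N_STATES)
        for i in range(N_STATES):
            u[i] = _newton_maximize_u(
                all_packed,
                gamma_all[:, i],
                float(params.u[i]),
                config.newton_steps,
                config.u_clamp_eps,
            )
        params = HMMParameters(pi=pi, A=A, u=u)
    return params, trace, converged


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

@njit(cache=True)
def _viterbi_kernel(log_b, log_pi, log_A):  # pragma: no cover
    T, I = log_b.shape
    delta = np.empty((T, I))
    psi = np.zeros((T, I), dtype=np.int64)
    for i in range(I):
        delta[0, i] = log_pi[i] + log_b[0, i]
    for t in range(1, T):
        for j in range(I):
            best = delta[t - 1, 0] + log_A[0, j]
            arg = 0
            for i in range(1, I):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:  # strict: ties resolve to the lower index
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            psi[t, j] = arg
    best = delta[T - 1, 0]
    arg = 0
    for i in range(1, I):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            arg = i
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


def viterbi_decode_logb(
    log_b: np.ndarray, pi: np.ndarray, A: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Viterbi over an explicit log-emission matrix.

    Returns (0-based state index path, path log-probability); ties break
    toward the lower state index.
    """
    log_b = np.asarray(log_b, dtype=float)
    if log_b.shape[0] == 0:
        raise ValueError("empty observation sequence")
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(pi, dtype=float))
        log_A = np.log(np.asarray(A, dtype=float))
    path, score = _viterbi_kernel(log_b, log_pi, log_A)
    return path, float(score)


def viterbi_decode(
    obs_seq: Sequence[SiteObservation], params: HMMParameters
) -> Tuple[np.ndarray, float]:
    """Most probable genotype-state path for one chain."""
    log_b = emission_table(obs_seq, params.u)
    return viterbi_decode_logb(log_b, params.pi, params.A)


# ---------------------------------------------------------------------------
# Parameter serialization (plain-text key/value)
# ---------------------------------------------------------------------------

def save_params(
    path,
    params: HMMParameters,
    hyper: Optional[PriorHyperparameters] = None,
    n_iter: Optional[int] = None,
    log_likelihood: Optional[float] = None,
) -> None:
    """Write lambda (and optional training metadata) as key/value text."""
    hyper = hyper if hyper is not None else PriorHyperparameters()

    def fmt(v):
        return " ".join(repr(float(x)) for x in np.asarray(v).ravel())

    lines = [
        "# snvhmm trained parameters",
        f"pi = {fmt(params.pi)}",
        f"A = {fmt(params.A)}",
        f"u = {fmt(params.u)}",
        f"delta = {fmt(hyper.delta)}",
        f"alpha = {fmt(hyper.alpha)}",
        f"beta = {fmt(hyper.beta)}",
        f"gamma = {fmt(hyper.gamma)}",
    ]
    if n_iter is not None:
        lines.append(f"n_iter = {int(n_iter)}")
    if log_likelihood is not None:
        lines.append(f"log_likelihood = {log_likelihood!r}")
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")


def load_params(path) -> Tuple[HMMParameters, dict]:
    """Read a parameter file written by :func:`save_params`.

    Returns the parameters plus a metadata dict holding hyperparameters
    and any recorded training info.
    """
    kv = {}
    with open(path, "r", encoding="ascii") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed parameter line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
    try:
        params = HMMParameters(
            pi=np.fromstring(kv["pi"], sep=" "),
            A=np.fromstring(kv["A"], sep=" ").reshape(N_STATES, N_STATES),
            u=np.fromstring(kv["u"], sep=" "),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed parameter file {path}: {exc}") from exc
    meta: dict = {}
    if all(k in kv for k in ("delta", "alpha", "beta", "gamma")):
        meta["hyper"] = PriorHyperparameters(
            delta=np.fromstring(kv["delta"], sep=" "),
            alpha=np.fromstring(kv["alpha"], sep=" "),
            beta=np.fromstring(kv["beta"], sep=" "),
            gamma=np.fromstring(kv["gamma"], sep=" ").reshape(N_STATES, N_STATES),
        )
    if "n_iter" in kv:
        meta["n_iter"] = int(kv["n_iter"])
    if "log_likelihood" in kv:
        meta["log_likelihood"] = float(kv["log_likelihood"])
    return params, meta
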