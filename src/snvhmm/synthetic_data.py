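"""Ground-truth pileup simulation under the generative model the HMM assumes.

Genotype states follow the 3-state Markov chain; each site draws a
truncated-at-1 Poisson depth and per-read Phred qualities, and each read
shows the reference base with exactly the per-read probability used by the
emission model (the function is shared, so generator and inference cannot
drift apart).  Output is a syntactically valid 7-column pileup plus a
truth TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .hmm_core import (
    GenotypeState,
    HMMParameters,
    PriorHyperparameters,
    TrainConfig,
    baum_welch_train,
    forward_backward,
    init_from_priors,
    per_read_match_prob,
    viterbi_decode,
)

__all__ = [
    "SimulationConfig",
    "default_true_params",
    "simulate_truth_path",
    "simulate_pileup",
    "recovery_experiment",
]

_BASES = "ACGT"


def default_true_params() -> HMMParameters:
    """A plausible tumor-like ground truth: mostly aa, sticky states."""
    return HMMParameters(
        pi=np.array([0.85, 0.10, 0.05]),
        A=np.array(
            [
                [0.90, 0.06, 0.04],
                [0.10, 0.80, 0.10],
                [0.08, 0.12, 0.80],
            ]
        ),
        u=np.array([0.99, 0.50, 0.01]),
    )


@dataclass
class SimulationConfig:
    n_sites: int = 10_000
    mean_depth: float = 10.0
    true_params: HMMParameters = field(default_factory=default_true_params)
    base_qual_range: Tuple[int, int] = (10, 40)
    map_qual_range: Tuple[int, int] = (20, 60)
    error_third_allele_rate: float = 0.0
    seed: int = 0
    chrom: str = "sim1"

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not self.mean_depth > 0:
            raise ValueError("mean_depth must be positive")
        for lo, hi in (self.base_qual_range, self.map_qual_range):
            if lo < 0 or hi < lo:
                raise ValueError("invalid quality range")
        if not (0.0 <= self.error_third_allele_rate < 1.0):
            raise ValueError("third-allele rate must be in [0, 1)")


def simulate_truth_path(
    params: HMMParameters, n_sites: int, seed: int
) -> np.ndarray:
    """Sample a state path (0-based indices): s_1 ~ pi, s_{t+1} ~ A[s_t]."""
    rng = np.random.default_rng(seed)
    path = np.empty(n_sites, dtype=np.int64)
    path[0] = rng.choice(3, p=params.pi)
    # pre-drawn uniforms + per-row CDFs keep this O(n) without a Python RNG
    # call per site
    cdf = np.cumsum(params.A, axis=1)
    unif = rng.random(n_sites)
    for t in range(1, n_sites):
        path[t] = np.searchsorted(cdf[path[t - 1]], unif[t])
    return path


def _truncated_poisson(rng, mean: float, n: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1, via resampling."""
    out = rng.poisson(mean, size=n)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(mean, size=int(zero.sum()))
        zero = out == 0
    return out


def simulate_pileup(
    states: np.ndarray,
    config: SimulationConfig,
    pileup_path,
    truth_path,
) -> List[Tuple[int, int]]:
    """Write a pileup file and truth TSV for a given state path.

    Returns per-site bookkeeping [(L, P), ...] where P counts
    reference-matching reads before third-allele injection, for
    round-trip checks.
    """
    rng = np.random.default_rng(config.seed + 1)
    u = config.true_params.u
    bq_lo, bq_hi = config.base_qual_range
    mq_lo, mq_hi = config.map_qual_range
    depths = _truncated_poisson(rng, config.mean_depth, len(states))
    book: List[Tuple[int, int]] = []
    with open(pileup_path, "w", encoding="ascii") as pf, open(
        truth_path, "w", encoding="ascii"
    ) as tf:
        for t, (s, depth) in enumerate(zip(states, depths)):
            pos = t + 1
            ref_i = int(rng.integers(4))
            alt_i = int((ref_i + 1 + rng.integers(3)) % 4)
            third_i = next(
                i for i in range(4) if i not in (ref_i, alt_i)
            )
            ref, alt, third = _BASES[ref_i], _BASES[alt_i], _BASES[third_i]
            bq = rng.integers(bq_lo, bq_hi + 1, size=depth)
            mq = rng.integers(mq_lo, mq_hi + 1, size=depth)
            r = 1.0 - 10.0 ** (-mq / 10.0)
            q = 1.0 - 10.0 ** (-bq / 10.0)
            p = per_read_match_prob(r, q, u[s])
            match = rng.random(depth) < p
            bases = np.where(match, ref, alt).astype("U1")
            if config.error_third_allele_rate > 0.0:
                err = rng.random(depth) < config.error_third_allele_rate
                bases[err] = third
            base_str = "".join(
                "." if b == ref else b for b in bases
            )
            bq_str = "".join(chr(v + 33) for v in bq)
            mq_str = "".join(chr(v + 33) for v in mq)
            pf.write(
                f"{config.chrom}\t{pos}\t{ref}\t{depth}\t"
                f"{base_str}\t{bq_str}\t{mq_str}\n"
            )
            tf.write(
                f"{config.chrom}\t{pos}\t{GenotypeState.from_index(int(s)).label}\n"
            )
            book.append((int(depth), int(match.sum())))
    return book


def recovery_experiment(
    config: SimulationConfig,
    train_config: Optional[TrainConfig] = None,
    hyper: Optional[PriorHyperparameters] = None,
    workdir=None,
) -> dict:
    """Simulate, self-train from prior-mean initialization, and report
    parameter-recovery error plus Viterbi state accuracy.

    Runs fully in memory (the pileup round trip is exercised elsewhere).
    """
    import tempfile

    from .pileup_io import FilterConfig, stream_observations

    train_config = train_config if train_config is not None else TrainConfig()
    hyper = hyper if hyper is not None else PriorHyperparameters()
    states = simulate_truth_path(
        config.true_params, config.n_sites, config.seed
    )
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        pileup = f"{tmp}/sim.pileup"
        truth = f"{tmp}/sim.truth.tsv"
        simulate_pileup(states, config, pileup, truth)
        obs = list(stream_observations(pileup, FilterConfig()))
    init = init_from_priors(
        hyper, mode=train_config.init_mode, seed=train_config.seed
    )
    params, trace, converged = baum_welch_train(
        obs, init=init, hyper=hyper, config=train_config
    )
    path, _ = viterbi_decode(obs, params)
    true_states = states[: len(path)]
    accuracy = float(np.mean(path == true_states))
    tp = config.true_params
    return {
        "n_sites": config.n_sites,
        "mean_depth": config.mean_depth,
        "converged": converged,
        "n_iter": len(trace),
        "log_likelihood": trace[-1],
        "max_u_error": float(np.max(np.abs(params.u - tp.u))),
        "max_A_error": float(np.max(np.abs(params.A - tp.A))),
        "state_accuracy": accuracy,
        "params": params,
        "trace": trace,
    }
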