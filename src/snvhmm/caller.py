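"""Turn decoded state paths into SNV calls and write TSV/VCF output.

A site is reported as an SNV when its decoded state is ab or bb AND its
filtered coverage reaches the minimum valid coverage (MVC).  Sites below
MVC keep their decoded state but are never flagged as SNVs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .hmm_core import GenotypeState, TrellisCache
from .pileup_io import FilterConfig, SiteObservation

__all__ = ["SiteCall", "call_sites", "write_calls_tsv", "write_calls_vcf"]

logger = logging.getLogger(__name__)


@dataclass
class SiteCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: Optional[str]
    depth: int
    state: GenotypeState
    posterior: np.ndarray  # (3,)
    is_snv: bool
    mvc_pass: bool


def call_sites(
    obs_seq: Sequence[SiteObservation],
    path: np.ndarray,
    cache: TrellisCache,
    filt: FilterConfig,
) -> List[SiteCall]:
    """One SiteCall per observation, gated by MVC.

    ``path`` holds 0-based decoded state indices aligned with
    ``obs_seq`` and ``cache``.
    """
    if not (len(obs_seq) == len(path) == cache.T):
        raise ValueError(
            f"length mismatch: {len(obs_seq)} observations, "
            f"{len(path)} states, trellis T={cache.T}"
        )
    calls = []
    for obs, s_idx, post in zip(obs_seq, path, cache.state_posterior):
        state = GenotypeState.from_index(int(s_idx))
        mvc_pass = obs.L >= filt.mvc
        calls.append(
            SiteCall(
                chrom=obs.chrom,
                pos=obs.pos,
                ref_base=obs.ref_base,
                alt_base=obs.alt_base,
                depth=obs.L,
                state=state,
                posterior=np.asarray(post, dtype=float),
                is_snv=state.is_snv and mvc_pass,
                mvc_pass=mvc_pass,
            )
        )
    return calls


_TSV_HEADER = "chrom\tpos\tref\talt\tdepth\tstate\tp_aa\tp_ab\tp_bb\tis_snv"


def write_calls_tsv(calls: Sequence[SiteCall], path) -> None:
    """Deterministic tab-separated call table, posteriors to 6 decimals."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write(_TSV_HEADER + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.pos),
                        c.ref_base,
                        c.alt_base if c.alt_base else ".",
                        str(c.depth),
                        c.state.label,
                        f"{c.posterior[0]:.6f}",
                        f"{c.posterior[1]:.6f}",
                        f"{c.posterior[2]:.6f}",
                        "1" if c.is_snv else "0",
                    ]
                )
                + "\n"
            )


_VCF_GT = {GenotypeState.AB: "0/1", GenotypeState.BB: "1/1"}


def _qual(c: SiteCall) -> float:
    err = 1.0 - float(c.posterior[c.state.index])
    if err <= 0.0:
        return 9999.0
    return min(-10.0 * math.log10(err), 9999.0)


def write_calls_vcf(
    calls: Sequence[SiteCall], path, reference_name: str = "unknown"
) -> int:
    """Minimal VCFv4.2 with one record per SNV call; returns record count."""
    n = 0
    with open(path, "w", encoding="ascii") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,'
            'Description="Filtered read depth">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n"
        )
        for c in calls:
            if not c.is_snv:
                continue
            if c.alt_base is None:
                logger.warning(
                    "SNV call at %s:%d has no alternate allele; skipped",
                    c.chrom,
                    c.pos,
                )
                continue
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.pos),
                        ".",
                        c.ref_base,
                        c.alt_base,
                        f"{_qual(c):.2f}",
                        "PASS",
                        f"DP={c.depth}",
                        "GT",
                        _VCF_GT[c.state],
                    ]
                )
                + "\n"
            )
            n += 1
    return n
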