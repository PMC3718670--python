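"""Pileup text parsing and reduction to per-site HMM observations.

Supports the samtools 6-column pileup/mpileup layout with an optional 7th
per-read mapping-quality column, plus a best-effort Maq dialect mapped onto
the same record.  Phred qualities are decoded to correctness probabilities
(``1 - 10**(-Q/10)``) and the per-site read set is reduced to the two most
frequent alleles before the HMM ever sees it.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "PileupRecord",
    "SiteObservation",
    "FilterConfig",
    "PileupParseError",
    "phred_to_prob",
    "parse_pileup_line",
    "reduce_to_observation",
    "stream_observations",
    "split_chains",
]

#: Phred value assigned to every read when the pileup carries no
#: mapping-quality column.
DEFAULT_MAP_QUAL = 30

_NUCLEOTIDES = frozenset("ACGTN")


class PileupParseError(ValueError):
    """Raised when a pileup line cannot be decoded."""


@dataclass(frozen=True)
class PileupRecord:
    """One raw pileup row: reference context plus per-read (base, BQ, MQ)."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    reads: tuple  # of (base, base_qual, map_qual)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_base not in _NUCLEOTIDES:
            raise ValueError(f"bad reference base {self.ref_base!r}")
        for base, bq, mq in self.reads:
            if bq < 0 or mq < 0:
                raise ValueError("negative Phred quality")

    @property
    def depth(self) -> int:
        return len(self.reads)


@dataclass
class SiteObservation:
    """Filtered per-site observation consumed by the HMM.

    ``L`` reads survive filtering; ``P`` of them carry the reference
    allele.  ``r``/``q`` are mapping/base correctness probabilities and
    ``match`` flags reference-matching reads.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: Optional[str]  # second-most-frequent allele, None if monoallelic
    L: int
    P: int
    r: np.ndarray
    q: np.ndarray
    match: np.ndarray

    def __post_init__(self):
        if not (0 <= self.P <= self.L):
            raise ValueError("P out of range")
        if not (len(self.r) == len(self.q) == len(self.match) == self.L):
            raise ValueError("vector lengths disagree with L")
        if int(np.sum(self.match)) != self.P:
            raise ValueError("P inconsistent with match flags")


@dataclass(frozen=True)
class FilterConfig:
    """Read/site filter thresholds: MQ and BQ minima plus the minimum valid
    coverage (MVC) gate used when reporting SNVs."""

    mq_min: int = 0
    bq_min: int = 0
    mvc: int = 0

    def __post_init__(self):
        if self.mq_min < 0 or self.bq_min < 0 or self.mvc < 0:
            raise ValueError("filter thresholds must be non-negative")


def phred_to_prob(phred: int) -> float:
    """Correctness probability ``1 - 10**(-phred/10)`` of a Phred score."""
    if phred < 0:
        raise ValueError(f"Phred score must be non-negative, got {phred}")
    return 1.0 - 10.0 ** (-phred / 10.0)


def _expand_base_column(bases: str, ref: str, line_no) -> list:
    """Expand the pileup base-string grammar into one symbol per read.

    Returns upper-case nucleotides; '*' placeholders and reference skips
    are kept (as '*') so quality-string alignment is preserved, and are
    dropped later.
    """
    out = []
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(
                    f"line {line_no}: dangling '^' in base string"
                )
            i += 2  # '^' plus the read's mapping-quality character
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(
                    f"line {line_no}: indel marker without length"
                )
            run = int(bases[i + 1 : j])
            i = j + run  # indel sequence is consumed and discarded
        elif c in ".,":
            out.append(ref)
            i += 1
        elif c.upper() in _NUCLEOTIDES:
            out.append(c.upper())
            i += 1
        elif c in "*<>":
            out.append("*")  # deletion / ref-skip placeholder, dropped later
            i += 1
        else:
            raise PileupParseError(
                f"line {line_no}: unexpected character {c!r} in base string"
            )
    return out


def parse_pileup_line(
    line: str,
    dialect: str = "samtools",
    default_mq: int = DEFAULT_MAP_QUAL,
    quality_offset: int = 33,
    line_no="?",
) -> PileupRecord:
    """Decode one pileup row into a :class:`PileupRecord`.

    samtools layout: chrom, pos, ref, depth, bases, base-quals
    [, map-quals].  The Maq dialect is identical except that a leading
    '@' on the base column is tolerated.  Reads on '*' placeholders and
    'N' calls are dropped.
    """
    if dialect not in ("samtools", "maq"):
        raise ValueError(f"unknown pileup dialect {dialect!r}")
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise PileupParseError(
            f"line {line_no}: expected >= 4 tab-separated columns, got {len(fields)}"
        )
    chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
    try:
        pos = int(pos_s)
        depth = int(fields[3])
    except ValueError as exc:
        raise PileupParseError(
            f"line {line_no}: non-numeric position or depth"
        ) from exc
    if ref not in _NUCLEOTIDES:
        raise PileupParseError(f"line {line_no}: bad reference base {ref!r}")

    if depth == 0:
        return PileupRecord(chrom=chrom, pos=pos, ref_base=ref, reads=())

    if len(fields) not in (6, 7):
        raise PileupParseError(
            f"line {line_no}: expected 6 or 7 columns for covered site, "
            f"got {len(fields)}"
        )
    bases_col, bq_col = fields[4], fields[5]
    if dialect == "maq" and bases_col.startswith("@"):
        bases_col = bases_col[1:]
    symbols = _expand_base_column(bases_col, ref, line_no)
    if len(symbols) != depth or len(bq_col) != depth:
        raise PileupParseError(
            f"line {line_no}: depth {depth} disagrees with "
            f"{len(symbols)} bases / {len(bq_col)} base qualities"
        )
    if len(fields) == 7:
        mq_col = fields[6]
        if len(mq_col) != depth:
            raise PileupParseError(
                f"line {line_no}: mapping-quality string length "
                f"{len(mq_col)} != depth {depth}"
            )
        mquals = [ord(c) - quality_offset for c in mq_col]
    else:
        mquals = [default_mq] * depth
    bquals = [ord(c) - quality_offset for c in bq_col]
    if any(v < 0 for v in bquals) or any(v < 0 for v in mquals):
        raise PileupParseError(
            f"line {line_no}: quality character below offset {quality_offset}"
        )

    reads = tuple(
        (b, bq, mq)
        for b, bq, mq in zip(symbols, bquals, mquals)
        if b not in ("*", "N")
    )
    return PileupRecord(chrom=chrom, pos=pos, ref_base=ref, reads=reads)


def reduce_to_observation(
    record: PileupRecord, filt: FilterConfig
) -> Optional[SiteObservation]:
    """Apply MQ/BQ filters and the top-2 allele rule; None when nothing is left.

    Reads below either quality threshold are dropped first; among the
    survivors only the two most frequent alleles are retained (rarer
    alleles are treated as errors).  Sites with an 'N' reference are
    skipped entirely.
    """
    if record.ref_base == "N":
        return None
    kept = [
        (b, bq, mq)
        for b, bq, mq in record.reads
        if mq >= filt.mq_min and bq >= filt.bq_min
    ]
    if not kept:
        return None
    counts = Counter(b for b, _, _ in kept)
    # ties broken by count then alphabetical order, for determinism
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top2 = {allele for allele, _ in ranked[:2]}
    kept = [t for t in kept if t[0] in top2]

    ref = record.ref_base
    non_ref = [a for a, _ in ranked[:2] if a != ref]
    alt = non_ref[0] if non_ref else None

    match = np.array([b == ref for b, _, _ in kept], dtype=bool)
    r = np.array([phred_to_prob(mq) for _, _, mq in kept], dtype=float)
    q = np.array([phred_to_prob(bq) for _, bq, _ in kept], dtype=float)
    return SiteObservation(
        chrom=record.chrom,
        pos=record.pos,
        ref_base=ref,
        alt_base=alt,
        L=len(kept),
        P=int(match.sum()),
        r=r,
        q=q,
        match=match,
    )


def _open_text(path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "r", encoding="ascii")


def stream_observations(
    path,
    filt: FilterConfig,
    dialect: str = "samtools",
    default_mq: int = DEFAULT_MAP_QUAL,
    quality_offset: int = 33,
) -> Iterator[SiteObservation]:
    """Yield filtered observations from a pileup file in file order.

    The yielded order defines the HMM chain order.  Input must be sorted:
    positions strictly increasing within a chromosome, chromosomes in
    contiguous blocks.
    """
    seen_chroms = set()
    cur_chrom, cur_pos = None, -1
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = parse_pileup_line(
                line,
                dialect=dialect,
                default_mq=default_mq,
                quality_offset=quality_offset,
                line_no=line_no,
            )
            if rec.chrom != cur_chrom:
                if rec.chrom in seen_chroms:
                    raise PileupParseError(
                        f"line {line_no}: unsorted input, chromosome "
                        f"{rec.chrom} appears in two blocks"
                    )
                seen_chroms.add(rec.chrom)
                cur_chrom, cur_pos = rec.chrom, -1
            if rec.pos <= cur_pos:
                raise PileupParseError(
                    f"line {line_no}: unsorted input at {rec.chrom}:{rec.pos}"
                )
            cur_pos = rec.pos
            obs = reduce_to_observation(rec, filt)
            if obs is not None:
                yield obs


def split_chains(observations: Iterable[SiteObservation]) -> list:
    """Group an ordered observation stream into per-chromosome chains.

    Consecutive surviving sites are adjacent in the Markov chain
    regardless of genomic gaps; chains break only at chromosome
    boundaries.
    """
    chains: list = []
    cur: list = []
    cur_chrom = None
    for obs in observations:
        if obs.chrom != cur_chrom and cur:
            chains.append(cur)
            cur = []
        cur_chrom = obs.chrom
        cur.append(obs)
    if cur:
        chains.append(cur)
    return chains
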