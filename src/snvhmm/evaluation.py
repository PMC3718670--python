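"""Benchmarking against ground truth: confusion tables, the four summary
statistics, and threshold sweeps over (MQ, BQ, MVC) grids."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .caller import SiteCall, call_sites
from .hmm_core import (
    GenotypeState,
    PriorHyperparameters,
    TrainConfig,
    baum_welch_train,
    viterbi_decode,
    forward_backward,
)
from .pileup_io import FilterConfig, split_chains, stream_observations

__all__ = [
    "ConfusionTable",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "load_truth_tsv",
    "threshold_sweep",
]

logger = logging.getLogger(__name__)

#: Marker for metrics whose denominator is zero.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionTable:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    recall: float
    f_score: float

    def rounded(self) -> dict:
        """Publication-style rounding: percentages to 2 decimals, F to 4."""

        def pct(x):
            return UNDEFINED if math.isnan(x) else round(100.0 * x, 2)

        return {
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "accuracy_pct": pct(self.accuracy),
            "precision_pct": pct(self.precision),
            "f_score": UNDEFINED
            if math.isnan(self.f_score)
            else round(self.f_score, 4),
        }


def load_truth_tsv(path) -> Dict[Tuple[str, int], bool]:
    """Read a truth table (chrom, pos, label) into {(chrom, pos): is_snv}.

    Labels may be genotype strings (aa/ab/bb) or 0/1 flags; ab and bb
    count as SNV.  Duplicate positions are an error.
    """
    truth: Dict[Tuple[str, int], bool] = {}
    with open(path, "r", encoding="ascii") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"truth line {line_no}: expected 3 columns")
            chrom, pos_s, label = fields[0], fields[1], fields[2].lower()
            key = (chrom, int(pos_s))
            if key in truth:
                raise ValueError(
                    f"truth line {line_no}: duplicate position {chrom}:{pos_s}"
                )
            if label in ("aa", "ab", "bb"):
                truth[key] = GenotypeState.from_label(label).is_snv
            elif label in ("0", "1"):
                truth[key] = label == "1"
            else:
                raise ValueError(f"truth line {line_no}: bad label {label!r}")
    return truth


def confusion_counts(
    calls: Sequence[SiteCall], truth: Dict[Tuple[str, int], bool]
) -> ConfusionTable:
    """Tally predictions against truth over the truth positions.

    Truth positions absent from the calls are counted as negative
    predictions (and logged): an uncovered true SNV is a miss.
    """
    predicted = {(c.chrom, c.pos): c.is_snv for c in calls}
    tp = fp = tn = fn = 0
    missing = 0
    for key, is_true_snv in truth.items():
        pred = predicted.get(key)
        if pred is None:
            missing += 1
            pred = False
        if pred and is_true_snv:
            tp += 1
        elif pred and not is_true_snv:
            fp += 1
        elif not pred and is_true_snv:
            fn += 1
        else:
            tn += 1
    if missing:
        logger.info(
            "%d truth positions had no call and were counted as negative",
            missing,
        )
    return ConfusionTable(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined: zero denominator", name)
        return UNDEFINED
    return num / den


def compute_metrics(ct: ConfusionTable) -> MetricsReport:
    """Sensitivity, specificity, accuracy, precision and F-score.

    Zero-denominator metrics come back as NaN markers; F-score is 0 by
    convention when precision + recall == 0.
    """
    if ct.total == 0:
        raise ValueError("empty confusion table")
    sens = _ratio(ct.TP, ct.TP + ct.FN, "sensitivity")
    spec = _ratio(ct.TN, ct.TN + ct.FP, "specificity")
    acc = (ct.TP + ct.TN) / ct.total
    prec = _ratio(ct.TP, ct.TP + ct.FP, "precision")
    recall = sens
    if math.isnan(prec) or math.isnan(recall):
        f = UNDEFINED
    elif prec + recall == 0.0:
        f = 0.0
    else:
        f = 2.0 * prec * recall / (prec + recall)
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        precision=prec,
        recall=recall,
        f_score=f,
    )


def _pipeline_metrics(
    pileup_path,
    truth: Dict[Tuple[str, int], bool],
    filt: FilterConfig,
    hyper: PriorHyperparameters,
    train_config: TrainConfig,
    dialect: str,
    default_mq: int,
) -> Tuple[ConfusionTable, MetricsReport]:
    """Self-train + decode + call + score one filter setting."""
    obs = list(
        stream_observations(
            pileup_path, filt, dialect=dialect, default_mq=default_mq
        )
    )
    if not obs:
        raise ValueError("no observations survive filtering")
    chains = split_chains(obs)
    params, _, _ = baum_welch_train(chains, hyper=hyper, config=train_config)
    calls: List[SiteCall] = []
    for chain in chains:
        path, _ = viterbi_decode(chain, params)
        cache = forward_backward(chain, params)
        calls.extend(call_sites(chain, path, cache, filt))
    ct = confusion_counts(calls, truth)
    return ct, compute_metrics(ct)


def threshold_sweep(
    pileup_path,
    truth: Dict[Tuple[str, int], bool],
    grid: Iterable[Tuple[int, int, int]],
    hyper: Optional[PriorHyperparameters] = None,
    train_config: Optional[TrainConfig] = None,
    dialect: str = "samtools",
    default_mq: int = 30,
) -> pd.DataFrame:
    """Run the full train/call pipeline per (mq, bq, mvc) grid point.

    Returns a tidy table (one row per setting) carrying the confusion
    counts and all metrics, suitable for ROC-style plotting.
    """
    hyper = hyper if hyper is not None else PriorHyperparameters()
    train_config = train_config if train_config is not None else TrainConfig()
    rows = []
    for mq, bq, mvc in grid:
        filt = FilterConfig(mq_min=mq, bq_min=bq, mvc=mvc)
        ct, rep = _pipeline_metrics(
            pileup_path, truth, filt, hyper, train_config, dialect, default_mq
        )
        rows.append(
            {
                "mq": mq,
                "bq": bq,
                "mvc": mvc,
                "TP": ct.TP,
                "FP": ct.FP,
                "TN": ct.TN,
                "FN": ct.FN,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "f_score": rep.f_score,
                "fpr": 1.0 - rep.specificity,
            }
        )
    return pd.DataFrame(rows)
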