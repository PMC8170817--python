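"""Precision / recall / gain evaluation against a simulation truth log.

Per evaluated base: a logged error restored to its true base is a TP; a
logged error left alone is an FN; a logged error rewritten to a different
wrong base counts both FN (the error remains) and FP (a new wrong base was
written); a change at a correct base is an FP; everything else is a TN.
Reads removed as 'out' are excluded from the tallies — they no longer exist
in the corrected set — and are reported separately.

Gain = (TP - FP) / (TP + FN): the net fraction of errors removed without
introducing new ones.  It can be negative when more errors are introduced
than removed, and never exceeds recall.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .io import Read
from .simulate import TruthLog


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Percent-scale metrics; ``gain`` is NaN when undefined (reported NA)."""

    precision: float
    recall: float
    gain: float
    sentinel: bool = False

    def as_strings(self) -> dict:
        fmt = lambda v: "NA" if math.isnan(v) else f"{v:.2f}"
        return {"precision": fmt(self.precision), "recall": fmt(self.recall),
                "gain": fmt(self.gain), "sentinel": str(self.sentinel)}


def _truth_map(truth: Union[TruthLog, Mapping]) -> Mapping:
    if isinstance(truth, TruthLog):
        return {rid: {pos: (t, o) for pos, t, o in entries}
                for rid, entries in truth.entries.items()}
    return truth


def tally(original_reads: Union[Sequence[Read], Mapping[str, Read]],
          corrected_reads: Iterable[Read],
          truth: Union[TruthLog, Mapping]) -> EvalCounts:
    """Tally TP/FP/TN/FN over the corrected reads against the truth log.

    ``original_reads`` must cover every corrected read and every read the
    truth log mentions; corrected reads are matched to originals by id.
    Reads present in the originals but absent from the corrected set (never
    extracted, or removed as 'out') contribute nothing.
    """
    if isinstance(original_reads, Mapping):
        originals = original_reads
    else:
        originals = {r.read_id: r for r in original_reads}
    truth_map = _truth_map(truth)
    for rid in truth_map:
        if rid not in originals:
            raise ValueError(f"truth log references unknown read {rid!r}")
    tp = fp = tn = fn = 0
    for corr in corrected_reads:
        if corr.read_id not in originals:
            raise ValueError(f"corrected read {corr.read_id!r} has no original")
        orig = originals[corr.read_id].seq
        cseq = corr.seq
        if len(orig) != len(cseq):
            raise ValueError(f"read {corr.read_id!r}: length changed")
        tru = truth_map.get(corr.read_id, {})
        o = np.frombuffer(orig.encode(), dtype=np.uint8)
        c = np.frombuffer(cseq.encode(), dtype=np.uint8)
        n_changed = int((o != c).sum())
        changed_at_truth = 0
        for pos, (true_base, _obs) in tru.items():
            cb = cseq[pos]
            if cb != orig[pos]:
                changed_at_truth += 1
            if cb == true_base:
                tp += 1
            elif cb == orig[pos]:
                fn += 1
            else:
                fn += 1
                fp += 1
        fp += n_changed - changed_at_truth
        tn += len(cseq) - len(tru) - (n_changed - changed_at_truth)
    return EvalCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: EvalCounts) -> MetricSet:
    """Precision TP/(TP+FP), Recall TP/(TP+FN), Gain (TP-FP)/(TP+FN), as %.

    Zero denominators use defined sentinels: precision is 100 when nothing
    was changed; recall and gain are 100 when there were no errors and
    nothing was falsely changed; with no errors but false changes the gain
    is undefined (NaN, reported NA).
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    sentinel = False
    if tp + fp == 0:
        precision, sentinel = 100.0, True
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        sentinel = True
        recall = 100.0
        gain = 100.0 if fp == 0 else float("nan")
    else:
        recall = 100.0 * tp / (tp + fn)
        gain = 100.0 * (tp - fp) / (tp + fn)
    return MetricSet(precision=precision, recall=recall, gain=gain,
                     sentinel=sentinel)


def compare_sequences(consensus: str, truth_gene: str):
    """Base-by-base difference between consensus and the true gene.

    Returns (diff_count, compared_length, label): the label is ``"M"`` for
    an identical pair, else ``"d/L"``.  Unequal lengths are compared over
    the shorter sequence with the overhang counted as differences.
    """
    n = min(len(consensus), len(truth_gene))
    length = max(len(consensus), len(truth_gene))
    if n:
        a = np.frombuffer(consensus[:n].encode(), dtype=np.uint8)
        b = np.frombuffer(truth_gene[:n].encode(), dtype=np.uint8)
        diffs = int((a != b).sum()) + (length - n)
    else:
        diffs = length
    label = "M" if diffs == 0 else f"{diffs}/{length}"
    return diffs, length, label
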