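"""Scoring of trimming output against simulator truth, plus label-free
diagnostics usable on real data.

Classification is at the pair level: a pair is *positive* when the truth
says it is adapter-appended, *predicted positive* when the trimmer removed
anything. Site correctness is kept separate as ``exact_site_fraction``
(among true positives, the fraction trimmed at exactly the true insert
length), so "detected at all" and "detected at the right base" are both
visible. Contaminated pairs with a true insert shorter than the scan
prefix ``L`` are algorithmically undetectable (no candidate below ``L``
exists); when ``min_detectable_insert`` is given they are tallied
separately rather than silently deflating sensitivity.

The label-free diagnostics mirror what can be computed without ground
truth: the trimmed/untrimmed ratio (expected 1 under a half-contaminated
benchmark), the distribution of trimmed lengths, and aTP — the number of
trimmed pairs whose trimmed mates are mutual reverse complements, a proxy
for true positives on real libraries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

from pairtrim.fastq_io import ReadPair
from pairtrim.trimmer_core import TrimDecision, count_mismatches, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Pair-level confusion counts with derived summary statistics."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    exact_site_fraction: float
    n_undetectable: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0", name)
        return 0.0
    return num / den


def classify_decisions(
    decisions: Mapping[str, TrimDecision],
    truths: Mapping[str, "TruthRecord"],
    min_detectable_insert: int | None = None,
) -> ConfusionMetrics:
    """Tally TP/FP/TN/FN and derived statistics over matched pair ids.

    With ``min_detectable_insert`` set (normally the trimmer's ``L``),
    contaminated pairs whose true insert is below it are excluded from the
    confusion counts and reported in ``n_undetectable``.
    """
    if set(decisions) != set(truths):
        only_d = sorted(set(decisions) - set(truths))[:3]
        only_t = sorted(set(truths) - set(decisions))[:3]
        raise ValueError(
            f"decision/truth id sets differ; e.g. only in decisions: {only_d}, "
            f"only in truths: {only_t}"
        )
    tp = fp = tn = fn = exact = undetectable = 0
    for pair_id, dec in decisions.items():
        truth = truths[pair_id]
        if (
            truth.contaminated
            and min_detectable_insert is not None
            and truth.insert_length < min_detectable_insert
        ):
            undetectable += 1
            continue
        if truth.contaminated:
            if dec.trimmed:
                tp += 1
                if dec.insert_length == truth.insert_length:
                    exact += 1
            else:
                fn += 1
        else:
            if dec.trimmed:
                fp += 1
            else:
                tn += 1
    total = tp + fp + tn + fn
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        accuracy=_safe_ratio(tp + tn, total, "accuracy"),
        mcc=mcc(tp, fp, tn, fn),
        exact_site_fraction=_safe_ratio(exact, tp, "exact_site_fraction"),
        n_undetectable=undetectable,
    )


def trimmed_untrimmed_ratio(decisions: Iterable[TrimDecision]) -> float:
    """count(trimmed) / count(untrimmed); inf with a warning when none untrimmed."""
    trimmed = untrimmed = 0
    for dec in decisions:
        if dec.trimmed:
            trimmed += 1
        else:
            untrimmed += 1
    if untrimmed == 0:
        logger.warning("no untrimmed pairs; ratio is infinite")
        return math.inf
    return trimmed / untrimmed


def length_distribution(
    decisions: Iterable[TrimDecision], read_length: int
) -> Dict[int, float]:
    """Fraction of trimmed pairs at each insert length 1..read_length-1.

    Fractions sum to 1 over trimmed pairs; all zeros when nothing was
    trimmed.
    """
    counts = {n: 0 for n in range(1, read_length)}
    total = 0
    for dec in decisions:
        if dec.trimmed and dec.insert_length is not None:
            counts[dec.insert_length] += 1
            total += 1
    if total == 0:
        return {n: 0.0 for n in counts}
    return {n: c / total for n, c in counts.items()}


def approximate_true_positives(
    trimmed_pairs: Iterable[ReadPair], tolerance_fraction: float = 0.0
) -> int:
    """aTP: trimmed pairs whose mates are reverse complements.

    A pair counts when the Hamming distance between revcomp(r1) and r2 is
    at most ``floor(length * tolerance_fraction)``. The default tolerance
    of 0 requires strict reverse complementarity.
    """
    count = 0
    for pair in trimmed_pairs:
        length = len(pair.r1)
        budget = math.floor(length * tolerance_fraction)
        if count_mismatches(reverse_complement(pair.r1.sequence), pair.r2.sequence) <= budget:
            count += 1
    return count
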