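"""Two-stage reverse-complement scanning for adapter-junction detection.

For a read pair sequenced from an insert of length ``n`` shorter than the
read length ``N``, the first ``n`` bases of the two mates are mutual
reverse complements and the remaining ``N - n`` bases of each mate are
adapter. The algorithm locates ``n`` without any adapter sequence:

Stage 1
    The reverse complement of the first ``L`` bases of one mate is slid
    along the other mate; every start position ``p`` with at most
    ``floor(L * E1)`` mismatches yields a candidate insert length
    ``n = p + L``. The scan is run in both directions (R1-prefix against
    R2, R2-prefix against R1) giving candidate sets G1 and G2, and only
    sites reported in both — the intersection I — survive.

Stage 2
    Candidates in I are validated largest-first: the putative DNA portions
    must be reverse complements within a mismatch fraction ``E2``, and the
    putative adapter portions must be near-identical within ``E3`` (both
    mates carry the same number of adapter bases, and Illumina forward and
    reverse adapters begin with the same bases, so for typical libraries
    the adapter tails match; set ``E3 = 1`` to disable this check for
    libraries with distinct forward/reverse adapters). A singleton I is
    accepted without validation unless ``strict_singleton`` is set.

Threshold semantics: each ``E`` is a maximum mismatch *fraction*; the
integer budget for a comparison of length ``m`` is ``floor(m * E)``, and a
threshold of 1 disables the check entirely. Mismatch counting is plain
Hamming distance with ``N`` treated as mismatching everything, including
another ``N``; quality scores and indels are ignored.

Per pair the two stage-1 scans consume at most ``2 * L * N`` character
comparisons, so the trimmer runs in time linear in the number of bases;
an instrumentation counter (:func:`comparison_count`) exposes the exact
figure for verification. :func:`brute_force_trim` re-derives the same
decision by exhaustive enumeration and serves as an independent oracle in
the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set

import numpy as np

from pairtrim.fastq_io import NucleotideRead, ReadPair

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_N_BYTE = ord("N")

# module-level instrumentation: characters compared by stage-1 scans
_comparison_counter = 0


def comparison_count() -> int:
    """Characters compared by all stage-1 scans since the last reset."""
    return _comparison_counter


def reset_comparison_count() -> None:
    global _comparison_counter
    _comparison_counter = 0


@dataclass(frozen=True)
class TrimmerParams:
    """Tuning parameters of the two-stage algorithm.

    Attributes
    ----------
    L:
        Prefix length in bases used by stage 1; also the smallest
        detectable insert. Default 30.
    E1, E2, E3:
        Maximum mismatch fractions for the stage-1 scan, the stage-2
        DNA reverse-complementarity check, and the stage-2 adapter
        equality check. Defaults 0.4 / 0.6 / 0.4; a value of 1 disables
        the corresponding check.
    strict_singleton:
        When True, a single surviving candidate is still validated by
        stage 2 instead of being accepted outright.
    """

    L: int = 30
    E1: float = 0.4
    E2: float = 0.6
    E3: float = 0.4
    strict_singleton: bool = False

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        for name in ("E1", "E2", "E3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class TrimDecision:
    """Outcome of trimming one pair.

    ``candidates_stage1`` is the intersection I in ascending order;
    ``validated_candidate`` is the accepted element of I (which may equal
    the read length, in which case nothing is removed and ``trimmed`` is
    False). ``insert_length`` is set only when ``trimmed``.
    """

    trimmed: bool
    insert_length: Optional[int] = None
    candidates_stage1: Sequence[int] = field(default_factory=tuple)
    validated_candidate: Optional[int] = None


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def count_mismatches(a: str, b: str) -> int:
    """Hamming distance; a position with an N in either string mismatches."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(
        ca != cb or ca == "N" or cb == "N" for ca, cb in zip(a, b)
    )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_budget(length: int, tolerance: float) -> int:
    return math.floor(length * tolerance)


def scan_candidates(
    template_read: NucleotideRead,
    target_read: NucleotideRead,
    params: TrimmerParams,
) -> Set[int]:
    """Stage-1 scan: candidate insert lengths from one direction.

    The reverse complement of the template's first ``L`` bases is compared
    at every start position ``p`` in ``[0, N_target - L]``; positions with
    at most ``floor(L * E1)`` mismatches contribute candidate ``p + L``.
    Reads shorter than ``L`` yield the empty set with a warning.
    """
    L = params.L
    if len(template_read) < L or len(target_read) < L:
        logger.warning(
            "read pair shorter than L=%d (%d/%d); no candidates",
            L,
            len(template_read),
            len(target_read),
        )
        return set()
    query = _encode(reverse_complement(template_read.sequence[:L]))
    target = _encode(target_read.sequence)
    windows = np.lib.stride_tricks.sliding_window_view(target, L)
    global _comparison_counter
    _comparison_counter += windows.size
    mismatches = (
        (windows != query) | (windows == _N_BYTE) | (query == _N_BYTE)
    ).sum(axis=1)
    budget = _mismatch_budget(L, params.E1)
    hits = np.nonzero(mismatches <= budget)[0]
    return {int(p) + L for p in hits}


def candidate_intersection(g1: Set[int], g2: Set[int]) -> List[int]:
    """Sites reported by both scan directions, ascending."""
    return sorted(g1 & g2)


def validate_candidate(pair: ReadPair, n: int, params: TrimmerParams) -> bool:
    """Stage-2 validation of one candidate insert length.

    DNA check: the first ``n`` bases of the mates are reverse complements
    within ``floor(n * E2)`` mismatches. Adapter check: the remaining
    bases are equal within ``floor((N - n) * E3)`` mismatches (vacuous at
    ``n == N``). A tolerance of 1 disables its check.
    """
    N = len(pair.r1)
    if len(pair.r2) != N:
        raise ValueError("validate_candidate requires equal mate lengths")
    if not params.L <= n <= N:
        raise ValueError(f"candidate {n} outside [{params.L}, {N}]")
    s1, s2 = pair.r1.sequence, pair.r2.sequence
    if params.E2 < 1.0:
        dna_mm = count_mismatches(reverse_complement(s1[:n]), s2[:n])
        if dna_mm > _mismatch_budget(n, params.E2):
            return False
    if params.E3 < 1.0 and n < N:
        ad_mm = count_mismatches(s1[n:], s2[n:])
        if ad_mm > _mismatch_budget(N - n, params.E3):
            return False
    return True


def _decide(
    pair: ReadPair, candidates: List[int], params: TrimmerParams
) -> TrimDecision:
    """Shared acceptance logic over the sorted intersection I."""
    N = len(pair.r1)
    candidates_t = tuple(candidates)
    if not candidates:
        return TrimDecision(False, candidates_stage1=candidates_t)
    if len(candidates) == 1 and not params.strict_singleton:
        accepted = candidates[0]
    else:
        accepted = None
        for n in reversed(candidates):
            if validate_candidate(pair, n, params):
                accepted = n
                break
        if accepted is None:
            return TrimDecision(False, candidates_stage1=candidates_t)
    if accepted == N:  # zero-length adapter: nothing to remove
        return TrimDecision(
            False, candidates_stage1=candidates_t, validated_candidate=accepted
        )
    return TrimDecision(
        True,
        insert_length=accepted,
        candidates_stage1=candidates_t,
        validated_candidate=accepted,
    )


def trim_pair(pair: ReadPair, params: TrimmerParams = TrimmerParams()) -> TrimDecision:
    """Run the full two-stage algorithm on one pair.

    Pairs with unequal mate lengths or mates shorter than ``L`` are passed
    through untrimmed (the equal-adapter-length premise does not hold);
    callers may tally these via the empty candidate list plus a warning.
    """
    N = len(pair.r1)
    if len(pair.r2) != N or N < params.L:
        logger.warning(
            "pair %s skipped: mate lengths %d/%d, L=%d",
            pair.r1.read_id,
            N,
            len(pair.r2),
            params.L,
        )
        return TrimDecision(False)
    g1 = scan_candidates(pair.r1, pair.r2, params)
    g2 = scan_candidates(pair.r2, pair.r1, params)
    return _decide(pair, candidate_intersection(g1, g2), params)


def apply_trim(pair: ReadPair, decision: TrimDecision) -> ReadPair:
    """Cut both mates (sequence and quality) to the accepted insert length."""
    if not decision.trimmed:
        return pair
    n = decision.insert_length
    assert n is not None
    return ReadPair(
        NucleotideRead(pair.r1.read_id, pair.r1.sequence[:n], pair.r1.quality[:n]),
        NucleotideRead(pair.r2.read_id, pair.r2.sequence[:n], pair.r2.quality[:n]),
    )


def _direction_hit(template: bytes, target: bytes, n: int, L: int, budget: int) -> bool:
    """Stage-1 criterion at one site, recomputed directly (oracle path)."""
    prefix = template[:L]
    rc = bytes(reversed(prefix.translate(_BYTES_COMPLEMENT)))
    p = n - L
    window = target[p : p + L]
    mm = 0
    for x, y in zip(rc, window):
        if x != y or x == _N_BYTE or y == _N_BYTE:
            mm += 1
            if mm > budget:
                return False
    return True


_BYTES_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def brute_force_trim(
    pair: ReadPair, params: TrimmerParams = TrimmerParams()
) -> TrimDecision:
    """Quadratic-time oracle: enumerate every candidate site exhaustively.

    A candidate exists at ``n`` iff the stage-1 criterion holds in both
    scan directions at that site, each recomputed from scratch on plain
    byte strings with no shared scanning machinery; the acceptance logic
    over the resulting candidate list is then identical to
    :func:`trim_pair`. Must agree with :func:`trim_pair` on every input.
    """
    N = len(pair.r1)
    if len(pair.r2) != N or N < params.L:
        return TrimDecision(False)
    b1 = pair.r1.sequence.encode("ascii")
    b2 = pair.r2.sequence.encode("ascii")
    L = params.L
    budget = _mismatch_budget(L, params.E1)
    candidates = [
        n
        for n in range(L, N + 1)
        if _direction_hit(b1, b2, n, L, budget)
        and _direction_hit(b2, b1, n, L, budget)
    ]
    return _decide(pair, candidates, params)


def _trim_chunk(chunk: List[ReadPair], params: TrimmerParams) -> List[TrimDecision]:
    return [trim_pair(pair, params) for pair in chunk]


def trim_stream(
    pairs,
    params: TrimmerParams = TrimmerParams(),
    workers: int = 1,
    chunk_size: int = 2000,
):
    """Yield ``(pair, decision)`` for a stream of pairs, optionally parallel.

    With ``workers > 1`` chunks are dispatched to a process pool; results
    are collected in submission order, so output is identical to serial
    execution for any worker count.
    """
    if workers <= 1:
        for pair in pairs:
            yield pair, trim_pair(pair, params)
        return
    from concurrent.futures import ProcessPoolExecutor
    from itertools import islice

    pairs = iter(pairs)
    with ProcessPoolExecutor(max_workers=workers) as pool:
        pending = []
        exhausted = False
        while not exhausted or pending:
            while not exhausted and len(pending) < workers * 2:
                chunk = list(islice(pairs, chunk_size))
                if not chunk:
                    exhausted = True
                    break
                pending.append((chunk, pool.submit(_trim_chunk, chunk, params)))
            if pending:
                chunk, future = pending.pop(0)
                for pair, decision in zip(chunk, future.result()):
                    yield pair, decision
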