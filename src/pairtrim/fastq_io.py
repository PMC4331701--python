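"""Streaming paired-FASTQ I/O, Phred conversion, and tabular reports.

Readers accept plain or gzip-compressed 4-line FASTQ (compression is
detected from the gzip magic bytes, not the file name); writers gzip when
the output path ends in ``.gz``. Qualities are Phred+33 throughout, with
the offset exposed for legacy encodings. Pairing of the two input files is
positional — record *i* of file 1 with record *i* of file 2 — which is the
standard convention for synchronized paired FASTQ; mismatching identifiers
only produce a warning.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

# trailing mate designators: "/1", "/2", ".1", "_1", or a " 1:N:0:..." comment
_MATE_SUFFIX = re.compile(r"([/._][12]$)|(\s+[12](:[^\s]*)?$)")


class FastqParseError(ValueError):
    """A malformed FASTQ record; the message names the file and record index."""


@dataclass(frozen=True)
class NucleotideRead:
    """A single read: identifier, sequence over {A,C,G,T,N}, Phred+33 quality."""

    read_id: str
    sequence: str
    quality: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    """Forward (r1) and reverse (r2) mates of one sequenced fragment."""

    r1: NucleotideRead
    r2: NucleotideRead

    @property
    def pair_id(self) -> str:
        return strip_mate_suffix(self.r1.read_id)


def strip_mate_suffix(read_id: str) -> str:
    """Drop a trailing mate-number token (``/1``, ``.2``, `` 1:N:0:AC``...)."""
    return _MATE_SUFFIX.sub("", read_id)


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_fastq(path: str | Path) -> Iterator[NucleotideRead]:
    """Yield validated, case-normalized reads from one FASTQ file."""
    path = Path(path)
    handle = _open_maybe_gzip(path)
    index = 0
    try:
        for read_id, seq, qual in FastqGeneralIterator(handle):
            seq = seq.upper()
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record {index}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            if not VALID_BASES.issuperset(seq):
                bad = sorted(set(seq) - VALID_BASES)
                raise FastqParseError(
                    f"{path}: record {index}: invalid characters {bad} "
                    "(alphabet is A,C,G,T,N)"
                )
            yield NucleotideRead(read_id, seq, qual)
            index += 1
    except ValueError as exc:
        if isinstance(exc, FastqParseError):
            raise
        # Biopython signals structural problems ('@'/'+' lines) as ValueError
        raise FastqParseError(f"{path}: record {index}: {exc}") from exc
    finally:
        handle.close()


def read_paired_fastq(
    path_r1: str | Path, path_r2: str | Path
) -> Iterator[ReadPair]:
    """Stream ReadPairs from two synchronized FASTQ files.

    Pairing is positional. Identifier disagreement (after stripping mate
    suffixes) logs one warning per file pair and processing continues.
    Unequal record counts raise :class:`FastqParseError` once the shorter
    file is exhausted.
    """
    it1, it2 = _iter_fastq(path_r1), _iter_fastq(path_r2)
    warned = False
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = path_r1 if r1 is None else path_r2
            raise FastqParseError(
                f"unequal record counts: {short} exhausted after {index} records"
            )
        if not warned and strip_mate_suffix(r1.read_id) != strip_mate_suffix(
            r2.read_id
        ):
            logger.warning(
                "mate identifiers disagree at record %d (%r vs %r); "
                "positional pairing is used",
                index,
                r1.read_id,
                r2.read_id,
            )
            warned = True
        yield ReadPair(r1, r2)
        index += 1


def write_paired_fastq(
    pairs: Iterable[ReadPair], path_r1: str | Path, path_r2: str | Path
) -> int:
    """Write pairs as two 4-line-record FASTQ files; returns pair count.

    Output is gzip-compressed when a path ends in ``.gz`` (with a zeroed
    gzip timestamp so reruns are byte-identical).
    """

    def opener(path: Path) -> IO[str]:
        if path.suffix == ".gz":
            raw = open(path, "wb")
            return gzip.GzipFile(fileobj=raw, mode="wb", mtime=0)  # type: ignore[return-value]
        return open(path, "w")

    def fmt(read: NucleotideRead) -> str:
        return f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n"

    path_r1, path_r2 = Path(path_r1), Path(path_r2)
    n = 0
    h1, h2 = opener(path_r1), opener(path_r2)
    try:
        for pair in pairs:
            rec1, rec2 = fmt(pair.r1), fmt(pair.r2)
            if isinstance(h1, gzip.GzipFile):
                h1.write(rec1.encode())
            else:
                h1.write(rec1)
            if isinstance(h2, gzip.GzipFile):
                h2.write(rec2.encode())
            else:
                h2.write(rec2)
            n += 1
    finally:
        h1.close()
        h2.close()
    return n


def phred_to_error_prob(q_char: str, offset: int = 33) -> float:
    """Decode one quality character to its base-call error probability.

    Phred convention: ``Q = ord(q_char) - offset`` and ``p = 10**(-Q/10)``.
    """
    q = ord(q_char) - offset
    if q < 0:
        raise ValueError(
            f"quality character {q_char!r} below offset {offset}: wrong encoding?"
        )
    return 10.0 ** (-q / 10.0)


def write_trim_report(
    decisions: Sequence[Tuple[str, "TrimDecision"]], path: str | Path
) -> None:
    """Write per-pair trimming outcomes as TSV.

    Columns: pair_id, trimmed (0/1), insert_length (empty when untrimmed),
    n_candidates_stage1, n_candidates_validated.
    """
    with open(path, "w") as out:
        out.write(
            "pair_id\ttrimmed\tinsert_length\t"
            "n_candidates_stage1\tn_candidates_validated\n"
        )
        for pair_id, dec in decisions:
            insert = "" if dec.insert_length is None else str(dec.insert_length)
            n_validated = 0 if dec.validated_candidate is None else 1
            out.write(
                f"{pair_id}\t{int(dec.trimmed)}\t{insert}\t"
                f"{len(dec.candidates_stage1)}\t{n_validated}\n"
            )


def read_trim_report(path: str | Path) -> dict:
    """Load a trim report TSV back into {pair_id: TrimDecision}.

    Only the fields present in the report (trimmed flag and insert length)
    are reconstructed; the candidate audit trail is not round-tripped.
    """
    from pairtrim.trimmer_core import TrimDecision

    decisions = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["pair_id", "trimmed", "insert_length"]:
            raise ValueError(f"{path}: unexpected report header {header}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            trimmed = fields[1] == "1"
            insert = int(fields[2]) if fields[2] else None
            decisions[fields[0]] = TrimDecision(trimmed, insert_length=insert)
    return decisions
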