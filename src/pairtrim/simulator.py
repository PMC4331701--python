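"""Ground-truthed paired-end read simulation for trimmer benchmarking.

The generator reproduces a standard benchmark design for paired-end
adapter trimmers: fixed-length mates (default 101 nt) sampled from a
reference sequence, with exactly half of the pairs adapter-appended. For a
contaminated pair an adapter length ``A`` is drawn from a Gaussian
``N(mu=20, sigma=5)`` (rounded and clamped), an insert of length
``read_length - A`` is cut from the reference, and each mate is the insert
(forward / reverse-complemented) followed by the first ``A`` bases of the
forward / reverse adapter. Clean pairs are two independent windows of the
reference, or — in overlap mode — the two ends of a single fragment of
length ``2 * read_length - 50`` so that the mates share a 50-base overlap
(a deliberate trap for trimmers fooled by internal reverse
complementarity).

Per-base substitution errors are driven by the quality model: each base
mutates to a uniformly chosen different base with probability
``min(1, p * error_scale)`` where ``p`` is the Phred error probability of
its simulated quality score. ``error_scale`` values of ``10**-0.5``, 1 and
``10**+0.5`` give the low / middle / high error-rate dataset variants. No
indels are simulated. A truth table records, per pair, the contamination
flag, true insert length, and mutation counts split by DNA/adapter
portion.

The built-in reference is uniform random A/C/G/T so no genome download is
needed; a user FASTA can be supplied instead, in which case windows
containing N are rejected and redrawn. Quality scores default to a
parametric per-position model whose mean Phred declines from the 5' to the
3' end (mirroring real Illumina profiles); an empirical model can be
learned from any constant-length FASTQ via :func:`learn_quality_model`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from pairtrim.fastq_io import (
    NucleotideRead,
    ReadPair,
    _iter_fastq,
    write_paired_fastq,
)
from pairtrim.trimmer_core import reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Typical Illumina TruSeq-style forward/reverse adapters.
ILLUMINA_FORWARD = (
    "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGACCGATCTCGTATGCCGTCTTCTGCTTG"
)
ILLUMINA_REVERSE = (
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGGTGGTCGCCGTATCATT"
)
#: Unrelated forward/reverse adapters for distinct-adapter library variants.
DISTINCT_FORWARD = (
    "CTAGAGTCAGTCCGGTTAATCCGGATCAGTCGTAGGAATCCAAAAGGTCCGTACGTACCTT"
)
DISTINCT_REVERSE = (
    "ATGGGCCCCTTTTAGTCAGTCAGTGGTTGGCCCTTTAAAATTTTCTCTTGAAGTCCCC"
)


@dataclass(frozen=True)
class AdapterSet:
    """A forward-strand and reverse-strand adapter pair."""

    forward_adapter: str
    reverse_adapter: str
    name: str = ""

    def __post_init__(self) -> None:
        for seq in (self.forward_adapter, self.reverse_adapter):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError("adapters must be non-empty over {A,C,G,T}")


ILLUMINA_ADAPTERS = AdapterSet(ILLUMINA_FORWARD, ILLUMINA_REVERSE, "illumina")
DISTINCT_ADAPTERS = AdapterSet(DISTINCT_FORWARD, DISTINCT_REVERSE, "distinct")


class QualityModel:
    """Per-position discrete distributions of Phred scores.

    ``probs[i, k]`` is the probability of Phred value ``values[k]`` at read
    position ``i``. Sampling draws each position independently.
    """

    def __init__(self, values: np.ndarray, probs: np.ndarray, source: str):
        values = np.asarray(values, dtype=np.int64)
        probs = np.asarray(probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] != values.size:
            raise ValueError("probs must be (read_length, len(values))")
        if not np.allclose(probs.sum(axis=1), 1.0):
            raise ValueError("each position's distribution must sum to 1")
        self.values = values
        self.probs = probs
        self.source = source
        self._cum = np.cumsum(probs, axis=1)
        self._cum[:, -1] = 1.0  # guard against rounding

    @property
    def read_length(self) -> int:
        return self.probs.shape[0]

    def mean_phred(self) -> np.ndarray:
        """Expected Phred score at each position."""
        return self.probs @ self.values

    def sample_matrix(self, n_reads: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an ``(n_reads, read_length)`` integer Phred matrix."""
        u = rng.random((n_reads, self.read_length))
        idx = (u[:, :, None] > self._cum[None, :, :]).sum(axis=2)
        return self.values[idx]

    @classmethod
    def parametric(
        cls,
        read_length: int,
        q_start: float = 38.0,
        q_end: float = 20.0,
        dispersion: float = 3.0,
        q_min: int = 2,
        q_max: int = 40,
    ) -> "QualityModel":
        """Default model: mean Phred declines linearly 5'->3'.

        Each position's distribution is a discretized Gaussian around the
        linearly interpolated mean, truncated to ``[q_min, q_max]`` — a
        stand-in for real per-cycle Illumina quality profiles, capturing
        their dominant feature (error rate rising toward the 3' end).
        """
        values = np.arange(q_min, q_max + 1)
        means = np.linspace(q_start, q_end, read_length)
        logp = -((values[None, :] - means[:, None]) ** 2) / (2 * dispersion**2)
        probs = np.exp(logp)
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(values, probs, "parametric")


def learn_quality_model(fastq_path: str | Path) -> QualityModel:
    """Learn per-position empirical Phred distributions from a FASTQ file.

    All reads must have the same length; variable lengths raise with a
    hint to use the parametric model instead.
    """
    counts: Optional[np.ndarray] = None
    read_length: Optional[int] = None
    max_q = 0
    rows = []
    for read in _iter_fastq(fastq_path):
        if read_length is None:
            read_length = len(read)
        elif len(read) != read_length:
            raise ValueError(
                f"{fastq_path}: variable read lengths ({read_length} vs "
                f"{len(read)}); use QualityModel.parametric instead"
            )
        rows.append(np.frombuffer(read.quality.encode("ascii"), np.uint8) - 33)
    if not rows:
        raise ValueError(f"{fastq_path}: no reads")
    quals = np.stack(rows)
    max_q = int(quals.max())
    values = np.arange(max_q + 1)
    counts = np.zeros((read_length, max_q + 1))
    for i in range(read_length):
        counts[i] = np.bincount(quals[:, i], minlength=max_q + 1)
    probs = counts / counts.sum(axis=1, keepdims=True)
    return QualityModel(values, probs, "empirical")


@dataclass(frozen=True)
class SimulationParams:
    """Benchmark-dataset parameters.

    ``error_scale`` multiplies every per-base error probability: use
    ``10**-0.5`` for the low-error variant, 1 for middle, ``10**+0.5`` for
    high. ``overlap_mode`` builds clean pairs from one fragment of
    ``clean_fragment_length`` (default ``2*read_length - 50``) so the
    mates share a 50-base overlap.
    """

    n_pairs: int = 10_000
    read_length: int = 101
    contaminated_fraction: float = 0.5
    adapter_mu: float = 20.0
    adapter_sigma: float = 5.0
    error_scale: float = 1.0
    adapters: AdapterSet = ILLUMINA_ADAPTERS
    overlap_mode: bool = False
    clean_fragment_length: Optional[int] = None
    reference_length: int = 500_000
    reference_fasta: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.error_scale <= 0:
            raise ValueError("error_scale must be > 0")
        if not 0.0 <= self.contaminated_fraction <= 1.0:
            raise ValueError("contaminated_fraction must be in [0, 1]")

    @property
    def resolved_clean_fragment_length(self) -> int:
        if self.clean_fragment_length is not None:
            return self.clean_fragment_length
        return 2 * self.read_length - 50


@dataclass(frozen=True)
class TruthRecord:
    """Simulator ground truth for one pair.

    ``insert_length`` is ``read_length - A`` for contaminated pairs, the
    clean fragment length in overlap mode, and ``read_length`` for clean
    non-overlapping pairs (each mate entirely DNA). Mutation counts are
    split by portion; adapter counts are 0 for clean pairs.
    """

    pair_id: str
    contaminated: bool
    insert_length: int
    mut_dna_r1: int = 0
    mut_adapter_r1: int = 0
    mut_dna_r2: int = 0
    mut_adapter_r2: int = 0


def generate_reference(length: int, rng: np.random.Generator) -> str:
    """Uniform random A/C/G/T reference of the given length."""
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def load_reference_fasta(path: str | Path) -> str:
    """Concatenated upper-case sequence of the first record of a FASTA."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()


def sample_adapter_length(
    mu: float,
    sigma: float,
    read_length: int,
    adapter_len: int,
    rng: np.random.Generator,
) -> int:
    """Gaussian draw, rounded, clamped into [1, min(read_length-1, adapter_len)]."""
    raw = rng.normal(mu, sigma)
    hi = min(read_length - 1, adapter_len)
    return int(min(max(round(raw), 1), hi))


def sample_quality_string(
    model: QualityModel, read_length: int, rng: np.random.Generator
) -> str:
    """One Phred+33 quality string drawn from the model."""
    if model.read_length < read_length:
        raise ValueError("quality model shorter than read_length")
    q = model.sample_matrix(1, rng)[0, :read_length]
    return (q + 33).astype(np.uint8).tobytes().decode("ascii")


def _phred_to_prob(q: np.ndarray) -> np.ndarray:
    return 10.0 ** (-q / 10.0)


def _mutate_array(
    seq: np.ndarray,
    error_probs: np.ndarray,
    error_scale: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Substitute bases in place of a copy; returns (mutated, mutation mask)."""
    eff = np.minimum(1.0, error_probs * error_scale)
    mask = rng.random(seq.size) < eff
    out = seq.copy()
    if mask.any():
        idx = np.nonzero(mask)[0]
        # uniformly choose a *different* base: offset 1..3 in base index
        orig = np.searchsorted(_BASES, out[idx])
        offs = rng.integers(1, 4, size=idx.size)
        out[idx] = _BASES[(orig + offs) % 4]
    return out, mask


def mutate_sequence(
    seq: str,
    error_probs: Sequence[float],
    error_scale: float,
    rng: np.random.Generator,
) -> Tuple[str, int]:
    """Apply quality-driven substitutions; returns (mutated string, count).

    Per position, with probability ``min(1, p * error_scale)`` the base is
    replaced by a uniformly chosen different base.
    """
    probs = np.asarray(error_probs, dtype=np.float64)
    if probs.size != len(seq):
        raise ValueError("error_probs length must match sequence length")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out, mask = _mutate_array(arr, probs, error_scale, rng)
    return out.tobytes().decode("ascii"), int(mask.sum())


def _sample_window(
    reference: str, length: int, rng: np.random.Generator, reject_n: bool
) -> str:
    if len(reference) < length:
        raise ValueError("reference shorter than required fragment")
    for _ in range(10_000):
        start = int(rng.integers(0, len(reference) - length + 1))
        window = reference[start : start + length]
        if not reject_n or "N" not in window:
            return window
    raise ValueError("no N-free window of the required size in the reference")


def generate_pair(
    reference: str,
    params: SimulationParams,
    contaminated: bool,
    pair_id: str,
    rng: np.random.Generator,
    quality_model: Optional[QualityModel] = None,
) -> Tuple[ReadPair, TruthRecord]:
    """Build one pair plus its truth record.

    Contaminated: insert of length ``read_length - A`` from the reference;
    r1 = insert + adapter-forward prefix, r2 = revcomp(insert) +
    adapter-reverse prefix. Clean: two independent windows (or the two
    ends of one overlap-mode fragment). Qualities are sampled from the
    model and drive per-base substitution errors.
    """
    if quality_model is None:
        quality_model = QualityModel.parametric(params.read_length)
    rl = params.read_length
    reject_n = params.reference_fasta is not None
    if contaminated:
        a_len = sample_adapter_length(
            params.adapter_mu,
            params.adapter_sigma,
            rl,
            min(len(params.adapters.forward_adapter), len(params.adapters.reverse_adapter)),
            rng,
        )
        insert_len = rl - a_len
        fragment = _sample_window(reference, insert_len, rng, reject_n)
        seq1 = fragment + params.adapters.forward_adapter[:a_len]
        seq2 = reverse_complement(fragment) + params.adapters.reverse_adapter[:a_len]
    elif params.overlap_mode:
        insert_len = params.resolved_clean_fragment_length
        fragment = _sample_window(reference, insert_len, rng, reject_n)
        seq1 = fragment[:rl]
        seq2 = reverse_complement(fragment[-rl:])
    else:
        insert_len = rl
        seq1 = _sample_window(reference, rl, rng, reject_n)
        seq2 = reverse_complement(_sample_window(reference, rl, rng, reject_n))

    dna_len = min(insert_len, rl)
    reads = []
    quals = []
    muts = []  # (dna_count, adapter_count) per mate
    for seq in (seq1, seq2):
        qual = sample_quality_string(quality_model, rl, rng)
        qarr = np.frombuffer(qual.encode("ascii"), np.uint8).astype(np.float64) - 33
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out, mask = _mutate_array(arr, _phred_to_prob(qarr), params.error_scale, rng)
        muts.append((int(mask[:dna_len].sum()), int(mask[dna_len:].sum())))
        reads.append(out.tobytes().decode("ascii"))
        quals.append(qual)
    pair = ReadPair(
        NucleotideRead(f"{pair_id}/1", reads[0], quals[0]),
        NucleotideRead(f"{pair_id}/2", reads[1], quals[1]),
    )
    return pair, TruthRecord(
        pair_id,
        contaminated,
        insert_len,
        mut_dna_r1=muts[0][0],
        mut_adapter_r1=muts[0][1],
        mut_dna_r2=muts[1][0],
        mut_adapter_r2=muts[1][1],
    )


_TRUTH_COLUMNS = (
    "pair_id",
    "contaminated",
    "insert_length",
    "mut_dna_r1",
    "mut_adapter_r1",
    "mut_dna_r2",
    "mut_adapter_r2",
)


def write_truth_table(records: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for r in records:
            out.write(
                f"{r.pair_id}\t{int(r.contaminated)}\t{r.insert_length}\t"
                f"{r.mut_dna_r1}\t{r.mut_adapter_r1}\t"
                f"{r.mut_dna_r2}\t{r.mut_adapter_r2}\n"
            )


def read_truth_table(path: str | Path) -> dict[str, TruthRecord]:
    truths: dict[str, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth-table header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            truths[f[0]] = TruthRecord(
                f[0], bool(int(f[1])), int(f[2]),
                int(f[3]), int(f[4]), int(f[5]), int(f[6]),
            )
    return truths


def generate_pairs(
    params: SimulationParams,
    quality_model: Optional[QualityModel] = None,
) -> Iterator[Tuple[ReadPair, TruthRecord]]:
    """Yield ``n_pairs`` simulated pairs with ground truth, reproducibly.

    Exactly ``round(n_pairs * contaminated_fraction)`` pairs are
    contaminated; contamination status is shuffled across sequential pair
    identifiers. Everything is a deterministic function of ``params``
    (including ``params.seed``).
    """
    rng = np.random.default_rng(params.seed)
    if params.reference_fasta is not None:
        reference = load_reference_fasta(params.reference_fasta)
    else:
        reference = generate_reference(params.reference_length, rng)
    if quality_model is None:
        quality_model = QualityModel.parametric(params.read_length)
    n_cont = round(params.n_pairs * params.contaminated_fraction)
    flags = np.zeros(params.n_pairs, dtype=bool)
    flags[:n_cont] = True
    rng.shuffle(flags)
    for i in range(params.n_pairs):
        yield generate_pair(
            reference, params, bool(flags[i]), str(i), rng, quality_model
        )


def generate_dataset(
    params: SimulationParams,
    out_r1: str | Path,
    out_r2: str | Path,
    out_truth: str | Path,
    quality_model: Optional[QualityModel] = None,
) -> dict[str, int]:
    """Write a benchmark dataset: paired FASTQ plus a truth TSV.

    Returns summary counts (pairs, contaminated, clean).
    """
    truths: list[TruthRecord] = []

    def pairs() -> Iterator[ReadPair]:
        for pair, truth in generate_pairs(params, quality_model):
            truths.append(truth)
            yield pair

    n = write_paired_fastq(pairs(), out_r1, out_r2)
    write_truth_table(truths, out_truth)
    n_cont = sum(t.contaminated for t in truths)
    logger.info(
        "simulated %d pairs (%d contaminated) -> %s, %s", n, n_cont, out_r1, out_r2
    )
    return {"pairs": n, "contaminated": n_cont, "clean": n - n_cont}
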