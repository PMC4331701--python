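import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairtrim.fastq_io import NucleotideRead, ReadPair
from pairtrim.simulator import SimulationParams, generate_pairs
from pairtrim.trimmer_core import (
    TrimmerParams,
    apply_trim,
    brute_force_trim,
    candidate_intersection,
    comparison_count,
    count_mismatches,
    reset_comparison_count,
    reverse_complement,
    scan_candidates,
    trim_pair,
    trim_stream,
    validate_candidate,
)

from conftest import error_free_quality_model, make_pair

DEFAULTS = TrimmerParams()

seq_strategy = st.text(alphabet="ACGTN", min_size=40, max_size=120)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("AAGATC", "GATCTT"), ("AAAN", "NTTT")],
)
def test_reverse_complement(seq, expected):
    assert reverse_complement(seq) == expected


@pytest.mark.parametrize(
    "a,b,expected",
    [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("ANGT", "ACGT", 1), ("NN", "NN", 2)],
)
def test_count_mismatches(a, b, expected):
    assert count_mismatches(a, b) == expected


def test_count_mismatches_length_contract():
    with pytest.raises(ValueError):
        count_mismatches("ACG", "AC")


def brute_scan(template: str, target: str, L: int, e1: float) -> set:
    """Direct enumeration of the stage-1 definition (test-local oracle)."""
    q = reverse_complement(template[:L])
    budget = int(np.floor(L * e1))
    return {
        p + L
        for p in range(len(target) - L + 1)
        if count_mismatches(q, target[p : p + L]) <= budget
    }


@pytest.mark.parametrize(
    "r1,r2,L,e1,expected",
    [
        ("ACGTTGAGAT", "CAACGTAGAT", 4, 0.0, {6}),
        ("AAAAAAAAAA", "CCCCCCCCCC", 4, 0.0, set()),
        ("ACGTTGAGAT", "CAATGTAGAT", 4, 0.25, {6}),
    ],
)
def test_scan_candidates_examples(r1, r2, L, e1, expected):
    pair = make_pair(r1, r2)
    params = TrimmerParams(L=L, E1=e1)
    got = scan_candidates(pair.r1, pair.r2, params)
    assert got == expected
    assert got == brute_scan(r1, r2, L, e1)


def test_scan_short_read_warns_and_returns_empty(caplog):
    pair = make_pair("ACG", "ACG")
    with caplog.at_level("WARNING"):
        assert scan_candidates(pair.r1, pair.r2, DEFAULTS) == set()
    assert any("shorter than L" in r.message for r in caplog.records)


def test_scan_e1_one_disables_check():
    pair = make_pair("A" * 10, "C" * 10)
    got = scan_candidates(pair.r1, pair.r2, TrimmerParams(L=4, E1=1.0))
    assert got == set(range(4, 11))


@pytest.mark.parametrize(
    "g1,g2,expected",
    [({6, 40}, {6}, [6]), (set(), {6}, []), ({10, 30, 50}, {30, 50, 70}, [30, 50])],
)
def test_candidate_intersection(g1, g2, expected):
    assert candidate_intersection(g1, g2) == expected


def test_validate_candidate_examples():
    pair = make_pair("ACGTTGAGAT", "CAACGTAGAT")
    p4 = TrimmerParams(L=4)
    assert validate_candidate(pair, 6, p4)
    # distinct adapter tails fail E3=0.4 but pass with the check disabled
    distinct = make_pair("ACGTTGAGAT", "CAACGTCTAG")
    assert not validate_candidate(distinct, 6, p4)
    assert validate_candidate(distinct, 6, TrimmerParams(L=4, E3=1.0))
    # n = N: adapter check vacuous, DNA check spans the full reads (8 > floor(6))
    assert not validate_candidate(pair, 10, p4)


def test_validate_candidate_range_contract():
    pair = make_pair("ACGTTGAGAT", "CAACGTAGAT")
    with pytest.raises(ValueError):
        validate_candidate(pair, 3, TrimmerParams(L=4))
    with pytest.raises(ValueError):
        validate_candidate(pair, 11, TrimmerParams(L=4))


def test_trim_pair_contaminated_example():
    pair = make_pair("ACGTTGAGAT", "CAACGTAGAT")
    decision = trim_pair(pair, TrimmerParams(L=4))
    assert decision == brute_force_trim(pair, TrimmerParams(L=4))
    assert decision.trimmed and decision.insert_length == 6
    trimmed = apply_trim(pair, decision)
    assert trimmed.r1.sequence == "ACGTTG"
    assert trimmed.r2.sequence == "CAACGT"
    assert trimmed.r1.quality == pair.r1.quality[:6]


def test_trim_pair_unrelated_reads_untrimmed(rng):
    bases = np.frombuffer(b"ACGT", np.uint8)
    for _ in range(20):
        s1 = rng.choice(bases, 101).tobytes().decode()
        s2 = rng.choice(bases, 101).tobytes().decode()
        pair = make_pair(s1, s2)
        decision = trim_pair(pair)
        assert decision == brute_force_trim(pair)
        assert not decision.trimmed


def test_full_reverse_complement_pair_is_untrimmed():
    """Zero-length adapter: the candidate equals N, nothing to remove."""
    insert = "ACGTTGAGATCCAGTAGGTTACGATCGATTGACGTGCATG"
    pair = make_pair(insert, reverse_complement(insert))
    decision = trim_pair(pair, TrimmerParams(L=30))
    assert not decision.trimmed
    assert decision.validated_candidate == len(insert)
    assert decision == brute_force_trim(pair, TrimmerParams(L=30))


def test_all_tolerances_disabled_is_untrimmed():
    params = TrimmerParams(L=4, E1=1.0, E2=1.0, E3=1.0)
    pair = make_pair("ACGTTGAGAT", "CAACGTAGAT")
    decision = trim_pair(pair, params)
    # every site is a candidate; the largest (N) is accepted -> untrimmed
    assert not decision.trimmed
    assert decision.validated_candidate == 10
    assert list(decision.candidates_stage1) == list(range(4, 11))
    assert decision == brute_force_trim(pair, params)


def test_unequal_or_short_mates_pass_through():
    uneven = ReadPair(
        NucleotideRead("u/1", "ACGTACGTAC", "I" * 10),
        NucleotideRead("u/2", "ACGTACGT", "I" * 8),
    )
    assert not trim_pair(uneven).trimmed
    assert not brute_force_trim(uneven).trimmed
    short = make_pair("ACGT", "ACGT")
    assert not trim_pair(short).trimmed
    assert not brute_force_trim(short).trimmed


def test_strict_singleton_validates():
    # singleton intersection that fails stage-2: accepted by default,
    # rejected in strict mode
    r1 = "ACGTTGAGAT"
    r2 = "CAACGTCTAG"  # adapter part totally different
    pair = make_pair(r1, r2)
    lax = trim_pair(pair, TrimmerParams(L=4))
    strict = trim_pair(pair, TrimmerParams(L=4, strict_singleton=True))
    assert lax.trimmed and lax.insert_length == 6
    assert not strict.trimmed


@settings(max_examples=100, derandomize=True, deadline=None)
@given(seq_strategy, seq_strategy, st.floats(0, 1), st.floats(0, 1))
def test_monotone_tolerance(s1, s2, e_lo, e_hi):
    """Enlarging E1 never shrinks the candidate set."""
    lo, hi = sorted((e_lo, e_hi))
    n = min(len(s1), len(s2))
    pair = make_pair(s1[:n], s2[:n])
    small = scan_candidates(pair.r1, pair.r2, TrimmerParams(L=20, E1=lo))
    large = scan_candidates(pair.r1, pair.r2, TrimmerParams(L=20, E1=hi))
    assert small <= large


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    st.integers(0, 2**31 - 1),
    st.sampled_from([TrimmerParams(), TrimmerParams(E3=1.0), TrimmerParams(L=20, E1=0.2)]),
)
def test_oracle_equivalence_random_pairs(seed, params):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGTN", np.uint8)
    n = int(rng.integers(params.L, 120))
    s1 = rng.choice(bases, n, p=[0.24, 0.24, 0.24, 0.24, 0.04]).tobytes().decode()
    s2 = rng.choice(bases, n, p=[0.24, 0.24, 0.24, 0.24, 0.04]).tobytes().decode()
    pair = make_pair(s1, s2)
    assert trim_pair(pair, params) == brute_force_trim(pair, params)


def test_oracle_equivalence_on_simulated_pairs():
    params = SimulationParams(n_pairs=300, seed=42, reference_length=20_000)
    for pair, _ in generate_pairs(params):
        assert trim_pair(pair) == brute_force_trim(pair)


def test_work_bound_per_pair():
    """Stage-1 scanning uses at most 2*L*N character comparisons per pair."""
    params = SimulationParams(n_pairs=200, seed=5, reference_length=20_000)
    L, N = DEFAULTS.L, 101
    for pair, _ in generate_pairs(params):
        reset_comparison_count()
        trim_pair(pair)
        assert comparison_count() <= 2 * L * N
    reset_comparison_count()


def test_overlap_robustness():
    """Clean pairs with a 50-base mate overlap must never be trimmed."""
    params = SimulationParams(
        n_pairs=500,
        seed=9,
        contaminated_fraction=0.0,
        overlap_mode=True,
        reference_length=50_000,
    )
    model = error_free_quality_model()
    for pair, truth in generate_pairs(params, quality_model=model):
        assert truth.insert_length == 152
        assert not trim_pair(pair).trimmed


def test_mate_symmetry_on_simulated_pairs():
    params = SimulationParams(n_pairs=200, seed=11, reference_length=20_000)
    for pair, _ in generate_pairs(params):
        decision = trim_pair(pair)
        if decision.trimmed:
            out = apply_trim(pair, decision)
            assert len(out.r1) == len(out.r2) == decision.insert_length
            assert pair.r1.quality.startswith(out.r1.quality)
            assert pair.r2.quality.startswith(out.r2.quality)


def test_trim_stream_parallel_matches_serial():
    params = SimulationParams(n_pairs=400, seed=13, reference_length=20_000)
    pairs = [p for p, _ in generate_pairs(params)]
    serial = [d for _, d in trim_stream(pairs, DEFAULTS, workers=1)]
    parallel = [d for _, d in trim_stream(pairs, DEFAULTS, workers=2, chunk_size=37)]
    assert serial == parallel
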