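import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    brute_distinct_kmers,
    brute_distinct_substrings,
    brute_repeat_occupancy,
)
from conftest import make_genome
from seqcomplexity import (
    build_lcp,
    build_suffix_array,
    complexity_profile,
    count_distinct_kmers,
    count_distinct_substrings,
    d_complexity,
    d_k,
    i_complexity,
    k_repeat_intervals,
    oracle_kmer_spectrum,
    r_k,
)
from seqcomplexity.errors import ParameterError, UndefinedStatisticError

dna = st.text(alphabet="ACGT", min_size=1, max_size=100)


def structures(seq):
    sa = build_suffix_array(seq)
    return sa, build_lcp(seq, sa)


@pytest.mark.parametrize(
    "seq, expected", [("ACA", 5), ("AAAA", 4), ("G", 1), ("ACGT", 10)]
)
def test_distinct_substring_count_examples(seq, expected):
    assert count_distinct_substrings(*structures(seq)) == expected
    assert brute_distinct_substrings(seq) == expected


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("G", 0.5),
        ("AAAA", math.log(5) / math.log(4)),
        ("ACA", 2 * math.log(2) / math.log(4) + math.log(1.5) / math.log(4)),
    ],
)
def test_i_complexity_examples(seq, expected):
    assert i_complexity(structures(seq)[1]) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "seq, expected", [("ACGT", 1.0), ("AAAA", 0.4), ("ACA", 5 / 6)]
)
def test_d_complexity_examples(seq, expected):
    n = len(seq)
    count = count_distinct_substrings(*structures(seq))
    assert d_complexity(n, count) == pytest.approx(expected)


def test_d_complexity_domain_errors():
    with pytest.raises(UndefinedStatisticError):
        d_complexity(0, 1)
    with pytest.raises(ParameterError):
        d_complexity(3, 7)  # more than n(n+1)/2 distinct substrings


@pytest.mark.parametrize(
    "seq, k, expected",
    [("ACA", 1, 2), ("AAAA", 2, 1), ("ACGT", 2, 3), ("AAAA", 4, 1)],
)
def test_distinct_kmer_count_examples(seq, k, expected):
    assert count_distinct_kmers(*structures(seq), k) == expected


@pytest.mark.parametrize(
    "seq, k, expected_intervals, expected_occupancy",
    [
        ("AAAA", 1, ((2, 4),), 4),
        ("ACA", 1, ((2, 2),), 2),
        ("ACGT", 1, (), 0),
        ("AAAA", 2, ((3, 4),), 3),
    ],
)
def test_k_repeat_intervals_examples(seq, k, expected_intervals, expected_occupancy):
    _, lcp = structures(seq)
    result = k_repeat_intervals(lcp, k)
    assert result.intervals == expected_intervals
    assert result.total_occurrences == expected_occupancy


@pytest.mark.parametrize(
    "seq, k, expected_dk, expected_rk",
    [
        ("ACA", 1, 2 / 3, 2 / 3),
        ("AAAA", 2, 1 / 3, 1.0),
        ("AAAA", 1, 1 / 4, 1.0),
        ("ACGT", 2, 1.0, 0.0),
    ],
)
def test_dk_rk_examples(seq, k, expected_dk, expected_rk):
    g = make_genome(seq)
    assert d_k(g, k) == pytest.approx(expected_dk)
    assert r_k(g, k) == pytest.approx(expected_rk)


def test_k_out_of_range_errors(tiny_genome):
    with pytest.raises(ParameterError):
        d_k(tiny_genome, 4)
    with pytest.raises(ParameterError):
        r_k(tiny_genome, 0)
    with pytest.raises(ParameterError):
        count_distinct_kmers(*structures("ACA"), 4)


@pytest.mark.parametrize(
    "seq, k, expected",
    [("ACA", 1, {1: 1, 2: 1}), ("AAAA", 1, {4: 1}), ("ACGT", 1, {1: 4})],
)
def test_oracle_kmer_spectrum_examples(seq, k, expected):
    assert oracle_kmer_spectrum(seq, k) == expected


@settings(max_examples=150, deadline=None, derandomize=True)
@given(dna, st.data())
def test_spectrum_mass_identities(seq, data):
    k = data.draw(st.integers(1, len(seq)))
    spectrum = oracle_kmer_spectrum(seq, k)
    assert sum(spectrum.values()) == brute_distinct_kmers(seq, k)
    assert sum(r * c for r, c in spectrum.items()) == len(seq) - k + 1


@settings(max_examples=200, deadline=None, derandomize=True)
@given(dna)
def test_substring_count_matches_enumeration(seq):
    assert count_distinct_substrings(*structures(seq)) == brute_distinct_substrings(seq)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(dna, st.data())
def test_kmer_count_and_occupancy_match_hash_oracle(seq, data):
    k = data.draw(st.integers(1, len(seq)))
    sa, lcp = structures(seq)
    assert count_distinct_kmers(sa, lcp, k) == brute_distinct_kmers(seq, k)
    assert k_repeat_intervals(lcp, k).total_occurrences == brute_repeat_occupancy(
        seq, k
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(dna, st.data())
def test_dk_rk_bounds(seq, data):
    """1 - R_k <= D_k <= 1 - R_k/2: every repeated k-mer occurs >= 2 times."""
    k = data.draw(st.integers(1, len(seq)))
    g = make_genome(seq)
    dk, rk = d_k(g, k), r_k(g, k)
    assert 0 < dk <= 1
    assert 0 <= rk <= 1
    assert 1 - rk <= dk + 1e-12
    assert dk <= 1 - rk / 2 + 1e-12


def test_closed_form_homopolymer():
    """I(A^n) telescopes to log4(n+1)."""
    for n in (1, 2, 7, 64, 300):
        _, lcp = structures("A" * n)
        assert i_complexity(lcp) == pytest.approx(
            math.log(n + 1) / math.log(4), abs=1e-9
        )


def test_profile_bundles_all_measures(tiny_genome):
    profile = complexity_profile(tiny_genome, [1])
    assert profile.genome_id == "tiny"
    assert profile.length == 3
    assert profile.I == pytest.approx(1.292481, abs=1e-6)
    assert profile.D == pytest.approx(5 / 6)
    assert profile.per_k[1] == (pytest.approx(2 / 3), pytest.approx(2 / 3))


def test_profile_drops_out_of_range_k(tiny_genome, caplog):
    profile = complexity_profile(tiny_genome, [2, 50])
    assert set(profile.per_k) == {2}


def test_profile_maximal_diversity():
    profile = complexity_profile(make_genome("ACGT"), [1, 2])
    assert profile.D == 1.0
    assert profile.per_k[1] == (pytest.approx(1.0), pytest.approx(0.0))
    assert profile.per_k[2] == (pytest.approx(1.0), pytest.approx(0.0))
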