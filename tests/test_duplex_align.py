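"""Duplex aligner: pair classification, penalty scoring, DP vs enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirduplex.duplex_align import (
    DEFAULT_SCHEME,
    PairState,
    PenaltyScheme,
    align_duplex,
    classify_pair,
    penalty_score,
    reverse_complement,
)

from conftest import random_rna


# --- independent oracle: enumerate every gapped alignment -------------------

def enumerate_alignments(mirna, site, max_gaps):
    """Yield (aligned_mirna, aligned_target) for all global alignments of the
    miRNA against the reversed site with at most max_gaps gap columns."""
    rev = site[::-1]

    def rec(i, j, gaps, cols_m, cols_t):
        if i == len(mirna) and j == len(rev):
            yield "".join(cols_m), "".join(cols_t)
            return
        if i < len(mirna) and j < len(rev):
            yield from rec(i + 1, j + 1, gaps, cols_m + [mirna[i]], cols_t + [rev[j]])
        if gaps < max_gaps:
            if i < len(mirna):
                yield from rec(i + 1, j, gaps + 1, cols_m + [mirna[i]], cols_t + ["-"])
            if j < len(rev):
                yield from rec(i, j + 1, gaps + 1, cols_m + ["-"], cols_t + [rev[j]])

    yield from rec(0, 0, 0, [], [])


def oracle_penalty(aligned_mirna, aligned_target, scheme):
    """Column-by-column cost of one explicit alignment (no DP involved)."""
    total = 0.0
    for col, (a, b) in enumerate(zip(aligned_mirna, aligned_target), start=1):
        if a == "-" or b == "-":
            cost = scheme.gap
        else:
            comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
            if comp[a] == b:
                cost = 0.0
            elif {a, b} == {"G", "U"}:
                cost = scheme.wobble
            else:
                cost = scheme.mismatch
        lo, hi = scheme.seed_window
        total += cost * (scheme.seed_multiplier if lo <= col <= hi else 1.0)
    return total


def oracle_min_penalty(mirna, site, scheme):
    return min(
        oracle_penalty(am, at, scheme)
        for am, at in enumerate_alignments(mirna, site, scheme.max_gaps)
    )


# --- classify_pair ----------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("G", "C", PairState.MATCH),
        ("A", "U", PairState.MATCH),
        ("U", "A", PairState.MATCH),
        ("G", "U", PairState.WOBBLE),
        ("U", "G", PairState.WOBBLE),
        ("A", "G", PairState.MISMATCH),
        ("C", "C", PairState.MISMATCH),
        ("A", "-", PairState.GAP),
        ("-", "G", PairState.GAP),
    ],
)
def test_classify_pair(a, b, expected):
    assert classify_pair(a, b) is expected


def test_classify_pair_rejects_invalid():
    with pytest.raises(ValueError):
        classify_pair("T", "A")
    with pytest.raises(ValueError):
        classify_pair("-", "-")


# --- penalty_score ----------------------------------------------------------

def test_penalty_score_examples():
    assert penalty_score("M" * 21, (2, 13)) == 0.0
    assert penalty_score("MMMMXMMMMMMMMMMMMMMMM", (2, 13)) == 2.0  # X at 5, doubled
    assert penalty_score("M" * 19 + "W", (2, 13)) == 0.5  # W at 20, outside window
    with pytest.raises(ValueError):
        penalty_score("", (2, 13))


@settings(derandomize=True, deadline=None, max_examples=100)
@given(
    st.lists(st.sampled_from("MWXG"), min_size=1, max_size=25),
    st.data(),
)
def test_penalty_monotone_under_state_degradation(states, data):
    """Turning any M into W/X, or W into X, never decreases the penalty."""
    idx = data.draw(st.integers(0, len(states) - 1))
    worse_of = {"M": ["W", "X", "G"], "W": ["X"]}
    if states[idx] not in worse_of:
        return
    degraded = list(states)
    degraded[idx] = data.draw(st.sampled_from(worse_of[states[idx]]))
    assert penalty_score(degraded, (2, 13)) >= penalty_score(states, (2, 13))


# --- align_duplex -----------------------------------------------------------

def test_perfect_reverse_complement():
    aln = align_duplex("AAGG", "CCUU")
    assert aln.states == "MMMM"
    assert aln.penalty == 0.0


def test_terminal_wobble_four_mer():
    """AAGG vs UCUU: single terminal G:U wobble; the enumeration oracle puts
    the minimum at 1.0 because position 4 sits inside the seed window."""
    aln = align_duplex("AAGG", "UCUU")
    assert aln.states == "MMMW"
    assert aln.penalty == oracle_min_penalty("AAGG", "UCUU", DEFAULT_SCHEME) == 1.0


def test_alignment_invariants_and_oracle(rng):
    scheme = PenaltyScheme(max_gaps=2)
    for _ in range(100):
        m = random_rna(rng, int(rng.integers(4, 11)))
        delta = int(rng.integers(-2, 3))
        s = random_rna(rng, max(2, len(m) + delta))
        if abs(len(m) - len(s)) > scheme.max_gaps:
            continue
        aln = align_duplex(m, s, scheme=scheme)
        # structural invariants
        assert aln.aligned_mirna.replace("-", "") == m
        assert aln.site_sequence == s
        assert aln.states == "".join(
            classify_pair(a, b).value
            for a, b in zip(aln.aligned_mirna, aln.aligned_target)
        )
        # penalty consistent with the scoring function of the state string
        assert aln.penalty == pytest.approx(
            penalty_score(aln.states, scheme.seed_window, scheme)
        )
        # DP equals exhaustive enumeration
        assert aln.penalty == pytest.approx(oracle_min_penalty(m, s, scheme))


def test_alignment_deterministic(rng):
    m = random_rna(rng, 21)
    s = random_rna(rng, 21)
    a1 = align_duplex(m, s)
    a2 = align_duplex(m, s)
    assert a1 == a2


def test_match_count_invariant_under_complementing_both_strands(rng):
    """A:U<->U:A and G:C<->C:G swaps preserve Watson-Crick pairing, so the
    match count of the (unique) gap-free alignment is invariant; wobbles turn
    into mismatches, so only M is asserted."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    gapfree = PenaltyScheme(max_gaps=0)
    for _ in range(20):
        m = random_rna(rng, 10)
        s = random_rna(rng, 10)
        states = align_duplex(m, s, scheme=gapfree).states
        mc = "".join(comp[b] for b in m)
        sc = "".join(comp[b] for b in s)
        states_c = align_duplex(mc, sc, scheme=gapfree).states
        assert states.count("M") == states_c.count("M")


def test_empty_and_invalid_inputs():
    with pytest.raises(ValueError):
        align_duplex("", "ACGU")
    with pytest.raises(ValueError):
        align_duplex("ACGT", "ACGU")  # T is not RNA
    with pytest.raises(ValueError):
        align_duplex("A" * 10, "A" * 20)  # beyond the gap budget


def test_gap_budget_respected(rng):
    for _ in range(30):
        m = random_rna(rng, 8)
        s = random_rna(rng, 10)
        aln = align_duplex(m, s)
        assert aln.states.count("G") <= DEFAULT_SCHEME.max_gaps


def test_render_block():
    aln = align_duplex("AAGG", "UCUU")
    lines = aln.render().splitlines()
    assert len(lines) == 3
    assert "5'" in lines[0] and "3'" in lines[2]
    assert lines[1].strip() == "|||:"


def test_reverse_complement():
    assert reverse_complement("AAGG") == "CCUU"
    with pytest.raises(ValueError):
        reverse_complement("AXGG")
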