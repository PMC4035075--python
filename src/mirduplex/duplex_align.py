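"""miRNA:target-site duplex alignment under an additive penalty scheme.

The duplex is modelled the way plant target-prediction tools score it: the
miRNA (5'->3') is aligned antiparallel against a candidate transcript site,
every aligned column is classified as Watson-Crick match (``M``), G:U wobble
(``W``), mismatch (``X``) or gap/bulge (``G``), and the alignment cost is the
sum of per-state penalties, doubled inside a positional seed window counted
from the miRNA 5' end.  Lower penalties mean better complementarity.

A bounded global dynamic program (at most :attr:`PenaltyScheme.max_gaps` gap
columns) returns the minimum-penalty alignment; ties are broken toward fewer
gaps, then toward gaps placed closer to the miRNA 3' end, which makes the
result deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

GAP_CHAR = "-"
RNA_BASES = frozenset("ACGU")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


class PairState(str, Enum):
    """Per-column classification of a duplex alignment."""

    MATCH = "M"
    WOBBLE = "W"
    MISMATCH = "X"
    GAP = "G"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, G<->C)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"invalid RNA base {exc.args[0]!r} in sequence") from exc


def classify_pair(mirna_base: str, target_base: str) -> PairState:
    """Classify one aligned base pair.

    Watson-Crick pairs (A:U, G:C) are matches, G:U in either orientation is a
    wobble, a gap symbol on either side forces the gap state, and everything
    else is a mismatch.
    """
    if mirna_base == GAP_CHAR or target_base == GAP_CHAR:
        if mirna_base == GAP_CHAR and target_base == GAP_CHAR:
            raise ValueError("column with gaps on both strands is not a valid alignment column")
        other = target_base if mirna_base == GAP_CHAR else mirna_base
        if other not in RNA_BASES:
            raise ValueError(f"invalid RNA base {other!r}")
        return PairState.GAP
    for b in (mirna_base, target_base):
        if b not in RNA_BASES:
            raise ValueError(f"invalid RNA base {b!r}")
    if _COMPLEMENT[mirna_base] == target_base:
        return PairState.MATCH
    if (mirna_base, target_base) in _WOBBLE_PAIRS:
        return PairState.WOBBLE
    return PairState.MISMATCH


@dataclass(frozen=True)
class PenaltyScheme:
    """Additive duplex penalty configuration.

    ``mismatch``/``gap``/``wobble`` are the per-column costs; every column
    whose position (counted 1-based from the miRNA 5' end) falls inside
    ``seed_window`` is multiplied by ``seed_multiplier``.  ``max_gaps`` bounds
    the number of gap columns the aligner will explore.
    """

    mismatch: float = 1.0
    gap: float = 1.0
    wobble: float = 0.5
    seed_window: tuple[int, int] = (2, 13)
    seed_multiplier: float = 2.0
    max_gaps: int = 3

    def state_cost(self, state: PairState) -> float:
        if state is PairState.MATCH:
            return 0.0
        if state is PairState.WOBBLE:
            return self.wobble
        if state is PairState.MISMATCH:
            return self.mismatch
        return self.gap

    def position_multiplier(self, position: int) -> float:
        lo, hi = self.seed_window
        return self.seed_multiplier if lo <= position <= hi else 1.0


DEFAULT_SCHEME = PenaltyScheme()


def penalty_score(
    states: Sequence[PairState] | str,
    seed_window: tuple[int, int] | None = None,
    scheme: PenaltyScheme = DEFAULT_SCHEME,
) -> float:
    """Penalty of a state string: sum of per-state costs, seed positions doubled.

    Positions are 1-based column indices; for gap-free alignments the column
    index is exactly the miRNA position.  ``seed_window`` overrides the
    scheme's window when given.
    """
    if len(states) == 0:
        raise ValueError("empty state string")
    if seed_window is not None:
        scheme = replace(scheme, seed_window=seed_window)
    total = 0.0
    for idx, s in enumerate(states, start=1):
        state = PairState(s)
        total += scheme.state_cost(state) * scheme.position_multiplier(idx)
    return total


@dataclass(frozen=True)
class DuplexAlignment:
    """An aligned miRNA:site duplex.

    ``aligned_mirna`` runs 5'->3'; ``aligned_target`` is the site written
    3'->5' so that column ``i`` pairs the two displayed characters.  The site
    occupies transcript coordinates ``[site_start, site_end]`` (1-based,
    inclusive, on the 5'->3' transcript).
    """

    mirna_id: str
    target_id: str
    site_start: int
    site_end: int
    aligned_mirna: str
    aligned_target: str
    states: str
    penalty: float
    scheme: PenaltyScheme = field(default=DEFAULT_SCHEME, compare=False)

    def __post_init__(self) -> None:
        if not (len(self.aligned_mirna) == len(self.aligned_target) == len(self.states)):
            raise ValueError("aligned strings and state string must have equal length")

    @property
    def mirna_sequence(self) -> str:
        return self.aligned_mirna.replace(GAP_CHAR, "")

    @property
    def site_sequence(self) -> str:
        """Site 5'->3' (the displayed target line reversed)."""
        return self.aligned_target.replace(GAP_CHAR, "")[::-1]

    def state_counts(self) -> dict[str, int]:
        return {s.value: self.states.count(s.value) for s in PairState}

    def render(self) -> str:
        """Three-line text block: miRNA 5'->3', midline, target 3'->5'."""
        mid = []
        for s in self.states:
            mid.append("|" if s == "M" else ":" if s == "W" else " ")
        return (
            f"miR 5' {self.aligned_mirna} 3'\n"
            f"       {''.join(mid)}\n"
            f"tgt 3' {self.aligned_target} 5'"
        )


def _column_states(aligned_mirna: str, aligned_target: str) -> str:
    return "".join(
        classify_pair(a, b).value for a, b in zip(aligned_mirna, aligned_target)
    )


def align_duplex(
    mirna,
    site,
    scheme: PenaltyScheme = DEFAULT_SCHEME,
    mirna_id: str | None = None,
    target_id: str | None = None,
    site_start: int = 1,
) -> DuplexAlignment:
    """Globally align a miRNA against a candidate site, minimizing the penalty.

    ``mirna`` and ``site`` may be plain strings or objects with ``identifier``
    and ``residues`` attributes (:class:`~mirduplex.io_formats.RnaSequence`).
    The site is given 5'->3' and is reversed internally so that miRNA position
    ``i`` faces site position ``len(site) - i + 1`` in the gap-free case.

    The dynamic program explores at most ``scheme.max_gaps`` gap columns.  The
    seed multiplier is applied per column index, which the program tracks
    exactly: after ``i`` miRNA bases and ``j`` site bases with ``g`` gap
    columns, the number of emitted columns is ``(i + j + g) / 2``.
    """
    mirna_seq, mirna_id = _coerce_seq(mirna, mirna_id, "mirna")
    site_seq, target_id = _coerce_seq(site, target_id, "site")

    m, n = len(mirna_seq), len(site_seq)
    if abs(m - n) > scheme.max_gaps:
        raise ValueError(
            f"sequence lengths {m} and {n} differ by more than max_gaps={scheme.max_gaps}"
        )
    rev = site_seq[::-1]  # rev[j] faces mirna position j+1 when gap-free
    gmax = scheme.max_gaps
    inf = math.inf

    # dp[g][i][j]: minimal penalty aligning mirna[:i] with rev[:j] using g gaps.
    dp = [[[inf] * (n + 1) for _ in range(m + 1)] for _ in range(gmax + 1)]
    dp[0][0][0] = 0.0
    for g in range(gmax + 1):
        for i in range(m + 1):
            for j in range(n + 1):
                cur = dp[g][i][j]
                if cur is inf:
                    continue
                col = (i + j + g) // 2 + 1  # index of the next emitted column
                mult = scheme.position_multiplier(col)
                if i < m and j < n:
                    st = classify_pair(mirna_seq[i], rev[j])
                    cand = cur + scheme.state_cost(st) * mult
                    if cand < dp[g][i + 1][j + 1]:
                        dp[g][i + 1][j + 1] = cand
                if g < gmax:
                    gcost = cur + scheme.gap * mult
                    if i < m and gcost < dp[g + 1][i + 1][j]:
                        dp[g + 1][i + 1][j] = gcost  # miRNA base bulged out
                    if j < n and gcost < dp[g + 1][i][j + 1]:
                        dp[g + 1][i][j + 1] = gcost  # target base bulged out

    best_g, best = None, inf
    for g in range(gmax + 1):  # fewer gaps win ties
        if dp[g][m][n] < best - 1e-12:
            best, best_g = dp[g][m][n], g
    if best_g is None:
        raise ValueError("no alignment within the gap budget")

    # Backtrack from the end; preferring gap moves first places gaps at the
    # largest possible column indices, i.e. toward the miRNA 3' end.
    i, j, g = m, n, best_g
    cols_m, cols_t = [], []
    while i > 0 or j > 0:
        col = (i + j + g) // 2  # index of the column being resolved
        mult = scheme.position_multiplier(col)
        cur = dp[g][i][j]
        if g > 0 and j > 0 and _close(dp[g - 1][i][j - 1] + scheme.gap * mult, cur):
            cols_m.append(GAP_CHAR)
            cols_t.append(rev[j - 1])
            j, g = j - 1, g - 1
        elif g > 0 and i > 0 and _close(dp[g - 1][i - 1][j] + scheme.gap * mult, cur):
            cols_m.append(mirna_seq[i - 1])
            cols_t.append(GAP_CHAR)
            i, g = i - 1, g - 1
        else:
            st = classify_pair(mirna_seq[i - 1], rev[j - 1])
            assert _close(dp[g][i - 1][j - 1] + scheme.state_cost(st) * mult, cur)
            cols_m.append(mirna_seq[i - 1])
            cols_t.append(rev[j - 1])
            i, j = i - 1, j - 1
    aligned_mirna = "".join(reversed(cols_m))
    aligned_target = "".join(reversed(cols_t))
    states = _column_states(aligned_mirna, aligned_target)

    return DuplexAlignment(
        mirna_id=mirna_id,
        target_id=target_id,
        site_start=site_start,
        site_end=site_start + n - 1,
        aligned_mirna=aligned_mirna,
        aligned_target=aligned_target,
        states=states,
        penalty=best,
        scheme=scheme,
    )


def _close(a: float, b: float, tol: float = 1e-9) -> bool:
    return abs(a - b) <= tol


def _coerce_seq(seq, ident, kind: str) -> tuple[str, str]:
    if hasattr(seq, "residues"):
        residues = seq.residues
        ident = ident if ident is not None else seq.identifier
    else:
        residues = str(seq)
        ident = ident if ident is not None else kind
    if not residues:
        raise ValueError(f"empty {kind} sequence")
    bad = set(residues) - RNA_BASES
    if bad:
        raise ValueError(f"invalid RNA base(s) {sorted(bad)} in {kind}")
    return residues, ident
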