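"""Duplex-alignment features that separate recovered from missed targets.

Four per-interaction features are computed from the duplex alignment and the
miRNA sequence: miRNA GC fraction, the longest run of continuous Watson-Crick
matches (the "seed region" in the plant-duplex sense), the first stretch of
continuous matches from the first matched base, and the match/mismatch ratio.
Wobbles are intermediate: they break match runs and are counted in neither
term of the ratio; gaps count as mismatches.

On sets of alignments the module computes the position-wise Shannon entropy
profile over the three-state taxonomy {match, wobble, mismatch-or-gap} and
the +1/-1/+0.5 alignment-vector encoding of the first 20 positions, with
complete-linkage hierarchical clustering over Euclidean distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import ranksums

from mirduplex.duplex_align import DuplexAlignment, PairState

VECTOR_LENGTH = 20
MAX_ENTROPY = math.log2(3.0)

_STATE_SCORE = {"M": 1.0, "W": 0.5, "X": -1.0, "G": -1.0}
#: entropy/vector taxonomy: mismatch and gap are one class
_STATE_CLASS = {"M": 0, "W": 1, "X": 2, "G": 2}


@dataclass(frozen=True)
class FeatureVector:
    """The four per-interaction discriminating features.

    ``match_mismatch_ratio`` is ``math.inf`` when the alignment has no
    mismatches or gaps.  ``first_stretch`` and ``max_match_stretch`` are
    independent; neither bounds the other.
    """

    gc_fraction: float
    max_match_stretch: int
    first_stretch: int
    match_mismatch_ratio: float


@dataclass(frozen=True)
class EntropyProfile:
    """Position-indexed Shannon entropy (bits) of a set of alignments."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        for h in self.values:
            if not (-1e-12 <= h <= MAX_ENTROPY + 1e-12):
                raise ValueError(f"entropy {h} outside [0, log2 3]")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> float:
        return self.values[i]


def gc_content(mirna) -> float:
    """Fraction of G or C residues in the miRNA sequence."""
    seq = mirna.residues if hasattr(mirna, "residues") else str(mirna)
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _states(alignment) -> str:
    if isinstance(alignment, DuplexAlignment):
        return alignment.states
    return "".join(PairState(s).value for s in alignment)


def max_match_stretch(alignment) -> int:
    """Length of the longest run of continuous matches; W, X and G all break runs."""
    best = run = 0
    for s in _states(alignment):
        run = run + 1 if s == "M" else 0
        best = max(best, run)
    return best


def first_stretch(alignment) -> int:
    """Continuous matches from the first matched base to the first non-match.

    Leading non-match positions are skipped; an alignment with no match at
    all scores 0.
    """
    states = _states(alignment)
    start = states.find("M")
    if start < 0:
        return 0
    run = 0
    for s in states[start:]:
        if s != "M":
            break
        run += 1
    return run


def match_mismatch_ratio(alignment) -> float:
    """(#matches) / (#mismatches + #gaps); wobbles count in neither term."""
    states = _states(alignment)
    matches = states.count("M")
    mismatches = states.count("X") + states.count("G")
    if mismatches == 0:
        return math.inf
    return matches / mismatches


def feature_vector(alignment: DuplexAlignment, mirna_sequence: str | None = None) -> FeatureVector:
    """All four features for one interaction; GC is taken from the miRNA."""
    seq = mirna_sequence if mirna_sequence is not None else alignment.mirna_sequence
    return FeatureVector(
        gc_fraction=gc_content(seq),
        max_match_stretch=max_match_stretch(alignment),
        first_stretch=first_stretch(alignment),
        match_mismatch_ratio=match_mismatch_ratio(alignment),
    )


def _class_matrix(alignments: Sequence, length: int) -> np.ndarray:
    """Alignments as an (n, length) int matrix of state classes; short
    alignments are padded with the mismatch/gap class."""
    mat = np.full((len(alignments), length), 2, dtype=np.int8)
    for row, aln in enumerate(alignments):
        states = _states(aln)[:length]
        mat[row, : len(states)] = [_STATE_CLASS[s] for s in states]
    return mat


def entropy_profile(alignments: Sequence, length: int = VECTOR_LENGTH) -> EntropyProfile:
    """Per-position Shannon entropy over {M, W, X∪G} across an alignment set.

    ``Hn = -sum_s p(s) log2 p(s)`` with ``0 log 0 = 0``; state frequencies
    are relative frequencies across the set at position ``n``.  Alignments
    are truncated or padded (with the mismatch/gap class) to ``length``.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("entropy_profile requires at least one alignment")
    mat = _class_matrix(alignments, length)
    n = mat.shape[0]
    values = []
    for pos in range(length):
        counts = np.bincount(mat[:, pos], minlength=3)
        p = counts[counts > 0] / n
        values.append(float(-(p * np.log2(p)).sum()))
    return EntropyProfile(tuple(values))


def alignment_vector(alignment, length: int = VECTOR_LENGTH) -> np.ndarray:
    """Numeric encoding of the first ``length`` positions: +1 match,
    +0.5 wobble, -1 mismatch or gap; short alignments padded with -1."""
    vec = np.full(length, -1.0)
    states = _states(alignment)[:length]
    vec[: len(states)] = [_STATE_SCORE[s] for s in states]
    return vec


def cluster_alignment_vectors(vectors: Sequence) -> tuple[np.ndarray, list[int]]:
    """Complete-linkage agglomerative clustering over Euclidean distances.

    Returns the SciPy linkage matrix and the dendrogram leaf order.
    """
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("clustering requires at least two vectors")
    linkage = hierarchy.linkage(arr, method="complete", metric="euclidean")
    leaves = hierarchy.leaves_list(linkage).tolist()
    return linkage, leaves


def compare_feature_distributions(group_a: Iterable[float], group_b: Iterable[float]):
    """Two-sided Wilcoxon rank-sum comparison of a feature between groups.

    Infinite ratio values are legal inputs: the rank-sum statistic depends
    only on order.  Returns the (statistic, pvalue) result object.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    return ranksums(a, b)
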