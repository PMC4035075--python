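"""A self-contained plant-style complementarity scanner.

Slides each miRNA over each transcript, aligns candidate sites with the
penalty-scoring duplex aligner and reports every non-overlapping local-best
site whose penalty is at or below the cutoff.  This is not a re-implementation
of any published tool; it exists so the evaluation pipeline can run
end-to-end on synthetic data with a predictor whose behaviour is fully known.

Scanning is seed-anchored by default: a window is only aligned in full when
the transcript contains the reverse complement of miRNA positions 2-8 with at
most one mismatch.  An exhaustive mode that aligns every window is retained
for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mirduplex.duplex_align import (
    DEFAULT_SCHEME,
    PenaltyScheme,
    align_duplex,
    classify_pair,
    reverse_complement,
)
from mirduplex.io_formats import Prediction, RnaSequence

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class ScanConfig:
    """Scanner configuration: penalty scheme, anchor prefilter, gap budget.

    ``gap_rescue_margin`` is a heuristic used only in anchored mode: an
    anchor whose canonical gap-free window costs more than ``cutoff +
    gap_rescue_margin`` is not aligned in full, on the grounds that gaps
    cannot plausibly recover that much penalty.  Exhaustive mode applies no
    such screen.
    """

    scheme: PenaltyScheme = field(default=DEFAULT_SCHEME)
    seed_anchor: bool = True
    anchor_window: tuple[int, int] = (2, 8)
    anchor_max_mismatches: int = 1
    gap_rescue_margin: float = 8.0


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))


def _anchor_hits(mirna: str, transcript: str, config: ScanConfig) -> list[int]:
    """0-based transcript start positions of the anchor 7-mer (<= k mismatches)."""
    lo, hi = config.anchor_window
    anchor = reverse_complement(mirna[lo - 1 : hi])
    k, L = len(anchor), len(transcript)
    if L < k:
        return []
    t = _encode(transcript)
    a = _encode(anchor)
    n_windows = L - k + 1
    mismatches = np.zeros(n_windows, dtype=np.int16)
    for i in range(k):
        mismatches += t[i : i + n_windows] != a[i]
    return np.nonzero(mismatches <= config.anchor_max_mismatches)[0].tolist()


def _gapfree_window_penalty(mirna: str, window: str, scheme: PenaltyScheme) -> float:
    """Penalty of the gap-free antiparallel pairing of an equal-length window."""
    total = 0.0
    n = len(window)
    for i, base in enumerate(mirna):
        st = classify_pair(base, window[n - 1 - i])
        total += scheme.state_cost(st) * scheme.position_multiplier(i + 1)
    return total


def _candidate_windows(
    mirna: str, transcript: str, cutoff: float, config: ScanConfig
) -> list[tuple[int, int]]:
    """(start, end) 0-based half-open transcript windows to align in full."""
    m, L = len(mirna), len(transcript)
    g = config.scheme.max_gaps
    windows: set[tuple[int, int]] = set()
    if config.seed_anchor:
        lo, hi = config.anchor_window
        for q in _anchor_hits(mirna, transcript, config):
            # anchor spans miRNA positions hi..lo; miRNA position 1 pairs the
            # transcript base just 3' of the anchor
            end = q + (hi - lo + 1) + (lo - 1)  # exclusive
            if end > L:
                continue
            if end - m >= 0:
                canonical = _gapfree_window_penalty(
                    mirna, transcript[end - m : end], config.scheme
                )
                if canonical > cutoff + config.gap_rescue_margin:
                    continue
            for length in range(m - g, m + g + 1):
                start = end - length
                if start >= 0:
                    windows.add((start, end))
    else:
        for end in range(m - g, L + 1):
            for length in range(m - g, m + g + 1):
                start = end - length
                if start >= 0:
                    windows.add((start, end))
    return sorted(windows)


def _cluster_best(candidates: list[Prediction]) -> list[Prediction]:
    """One site per cluster of transitively overlapping candidates: the
    lowest-penalty member, ties to the leftmost."""
    if not candidates:
        return []
    ordered = sorted(candidates, key=lambda p: (p.site_start, p.site_end))
    clusters: list[list[Prediction]] = [[ordered[0]]]
    reach = ordered[0].site_end
    for p in ordered[1:]:
        if p.site_start <= reach:
            clusters[-1].append(p)
        else:
            clusters.append([p])
        reach = max(reach, p.site_end)
    return [min(c, key=lambda p: (p.score, p.site_start, p.site_end)) for c in clusters]


def scan_transcript(
    mirna: RnaSequence,
    transcript: RnaSequence,
    cutoff: float,
    config: ScanConfig = ScanConfig(),
    tool: str = "mirduplex",
) -> list[Prediction]:
    """Predict target sites of one miRNA on one transcript.

    Every candidate window is globally aligned; windows whose penalty exceeds
    ``cutoff`` are dropped, then overlapping survivors are reduced to the
    single best site per cluster.  A transcript shorter than the smallest
    alignable window yields no predictions.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    m, L = len(mirna.residues), len(transcript.residues)
    if L < m - config.scheme.max_gaps:
        return []
    candidates: list[Prediction] = []
    for start, end in _candidate_windows(mirna.residues, transcript.residues, cutoff, config):
        site = transcript.residues[start:end]
        try:
            aln = align_duplex(
                mirna,
                site,
                scheme=config.scheme,
                target_id=transcript.identifier,
                site_start=start + 1,
            )
        except ValueError:
            continue
        if aln.penalty <= cutoff + 1e-9:
            candidates.append(
                Prediction(
                    mirna_id=mirna.identifier,
                    target_id=transcript.identifier,
                    score=aln.penalty,
                    site_start=aln.site_start,
                    site_end=aln.site_end,
                    tool=tool,
                )
            )
    return _cluster_best(candidates)


@dataclass(frozen=True)
class TranscriptomeScan:
    """All predictions plus the average number of called targets per miRNA."""

    predictions: tuple[Prediction, ...]
    mean_predictions_per_mirna: float


def predict_transcriptome(
    mirnas: Sequence[RnaSequence],
    transcripts: Sequence[RnaSequence],
    cutoff: float,
    config: ScanConfig = ScanConfig(),
    tool: str = "mirduplex",
) -> TranscriptomeScan:
    """Scan every miRNA against every transcript."""
    preds: list[Prediction] = []
    for mirna in mirnas:
        for transcript in transcripts:
            preds.extend(scan_transcript(mirna, transcript, cutoff, config, tool))
    mean = len(preds) / len(mirnas) if mirnas else 0.0
    return TranscriptomeScan(tuple(preds), mean)


def gapfree_min_penalty(
    mirna: RnaSequence | str,
    transcript: RnaSequence | str,
    scheme: PenaltyScheme = DEFAULT_SCHEME,
) -> float:
    """Minimum gap-free window penalty of a miRNA over a transcript.

    Vectorized over all windows; used by the decoy rejection sampler as a
    cheap screen before the scanner confirms.
    """
    mseq = mirna.residues if hasattr(mirna, "residues") else str(mirna)
    tseq = transcript.residues if hasattr(transcript, "residues") else str(transcript)
    m, L = len(mseq), len(tseq)
    if L < m:
        return float("inf")
    # cost[a, b] for miRNA base a paired with transcript base b
    cost = np.empty((4, 4))
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    for a, ia in _BASE_INDEX.items():
        for b, ib in _BASE_INDEX.items():
            if comp[a] == b:
                cost[ia, ib] = 0.0
            elif {a, b} == {"G", "U"}:
                cost[ia, ib] = scheme.wobble
            else:
                cost[ia, ib] = scheme.mismatch
    t = _encode(tseq)
    n_windows = L - m + 1
    penalties = np.zeros(n_windows)
    for i, base in enumerate(mseq):  # miRNA position i+1 pairs window offset m-1-i
        mult = scheme.position_multiplier(i + 1)
        row = cost[_BASE_INDEX[base]]
        penalties += mult * row[t[m - 1 - i : m - 1 - i + n_windows]]
    return float(penalties.min())
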