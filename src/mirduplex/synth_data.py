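"""Synthetic study generator with exact ground truth.

Implants miRNA target sites into random transcripts under controlled
duplex-edit profiles so every downstream stage — scanning, evaluation,
feature characterization — can be exercised against known labels.

Two interaction groups are generated.  The validated ("TP-like") group uses
near-perfect duplexes: at most one G:U wobble in the positional seed window
(positions 2-12 from the miRNA 5' end) and at most one edit in the 3'
region.  The divergent ("FN-like") group instantiates the heavier seed-edit
categories observed in duplexes that predictors miss: either two mismatches
plus one wobble, or three mismatches and no wobble, inside the seed window,
plus additional mismatch/gap/wobble edits in the 3' region.  Decoy
transcripts carry no implanted site and are rejection-sampled so that no
window of any miRNA aligns below a guard penalty.

Every generated site is re-aligned with the duplex aligner and the realized
edit counts are checked against the requested profile, so the ground truth
is exact by construction.  All randomness flows from one integer seed;
identical configurations regenerate byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mirduplex.duplex_align import (
    DEFAULT_SCHEME,
    DuplexAlignment,
    PenaltyScheme,
    align_duplex,
    reverse_complement,
)
from mirduplex.io_formats import (
    ARABIDOPSIS,
    NON_ARABIDOPSIS,
    InteractionRecord,
    RnaSequence,
    write_energy_table,
    write_interaction_table,
    write_rna_fasta,
)
from mirduplex.reference_predictor import ScanConfig, gapfree_min_penalty, scan_transcript

_BASES = ("A", "C", "G", "U")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}  # miRNA base -> target base


@dataclass(frozen=True)
class SynthProfile:
    """Requested edit structure of an implanted duplex.

    Seed edits land inside ``seed_window`` (miRNA positions, 1-based
    inclusive); 3'-region edits land strictly after the window.  ``gap``
    edits bulge the miRNA base out (the paired site base is deleted).
    """

    seed_window: tuple[int, int] = (2, 12)
    n_seed_wobbles: int = 0
    n_seed_mismatches: int = 0
    n_three_prime_edits: int = 0
    three_prime_kinds: tuple[str, ...] = ("mismatch",)

    def __post_init__(self) -> None:
        lo, hi = self.seed_window
        if self.n_seed_wobbles + self.n_seed_mismatches > hi - lo + 1:
            raise ValueError("more seed edits than seed-window positions")
        for kind in self.three_prime_kinds:
            if kind not in ("mismatch", "gap", "wobble"):
                raise ValueError(f"unknown 3' edit kind {kind!r}")

    @property
    def total_edits(self) -> int:
        return self.n_seed_wobbles + self.n_seed_mismatches + self.n_three_prime_edits


#: heavier seed-edit categories seen in predictor-missed duplexes, as
#: (n_mismatches, n_wobbles) inside the seed window
FN_SEED_CATEGORIES: tuple[tuple[int, int], ...] = ((2, 1), (3, 0))  # (mismatches, wobbles)


def generate_mirnas(
    n: int,
    length: int = 21,
    gc_target: float | None = None,
    seed: int | np.random.Generator = 0,
) -> list[RnaSequence]:
    """``n`` random miRNA sequences; base composition uniform unless a GC
    target fraction is given."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if gc_target is not None and not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must lie in [0, 1]")
    rng = _as_rng(seed)
    if gc_target is None:
        p = [0.25] * 4
    else:
        p = [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    out = []
    for i in range(n):
        residues = "".join(rng.choice(_BASES, size=length, p=p))
        out.append(RnaSequence(f"syn-miR{i + 1:04d}", residues))
    return out


def generate_transcript(
    length: int,
    identifier: str = "syn-tx",
    gc_target: float | None = None,
    seed: int | np.random.Generator = 0,
) -> RnaSequence:
    """One random transcript of the given length."""
    rng = _as_rng(seed)
    if gc_target is None:
        p = [0.25] * 4
    else:
        p = [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    return RnaSequence(identifier, "".join(rng.choice(_BASES, size=length, p=p)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _build_site(mirna: str, profile: SynthProfile, rng: np.random.Generator) -> str:
    """A site sequence (5'->3') realizing the profile against ``mirna``."""
    m = len(mirna)
    lo, hi = profile.seed_window
    hi = min(hi, m)
    seed_positions = list(range(lo, hi + 1))
    three_prime_positions = list(range(hi + 1, m + 1))

    wobble_candidates = [i for i in seed_positions if mirna[i - 1] in _WOBBLE_PARTNER]
    if len(wobble_candidates) < profile.n_seed_wobbles:
        raise ValueError("miRNA seed window has too few G/U bases for the requested wobbles")
    wobbles = sorted(
        rng.choice(wobble_candidates, size=profile.n_seed_wobbles, replace=False).tolist()
    )
    mismatch_candidates = [i for i in seed_positions if i not in wobbles]
    mismatches = sorted(
        rng.choice(mismatch_candidates, size=profile.n_seed_mismatches, replace=False).tolist()
    )

    edits: dict[int, str] = {i: "wobble" for i in wobbles}
    edits.update({i: "mismatch" for i in mismatches})

    if profile.n_three_prime_edits:
        if len(three_prime_positions) < profile.n_three_prime_edits:
            raise ValueError("not enough 3'-region positions for the requested edits")
        chosen = sorted(
            rng.choice(
                three_prime_positions, size=profile.n_three_prime_edits, replace=False
            ).tolist()
        )
        for i in chosen:
            kind = str(rng.choice(profile.three_prime_kinds))
            if kind == "wobble" and mirna[i - 1] not in _WOBBLE_PARTNER:
                kind = "mismatch"  # wobble infeasible at this base
            edits[i] = kind

    # site index (0-based, 5'->3') pairing miRNA position i is m - i
    site = list(reverse_complement(mirna))
    deletions: list[int] = []
    for i, kind in edits.items():
        j = m - i
        base = mirna[i - 1]
        if kind == "wobble":
            site[j] = _WOBBLE_PARTNER[base]
        elif kind == "mismatch":
            forbidden = {_COMPLEMENT[base], _WOBBLE_PARTNER.get(base)}
            choices = [b for b in _BASES if b not in forbidden]
            site[j] = str(rng.choice(choices))
        else:  # gap: delete the site base, bulging the miRNA base out
            deletions.append(j)
    for j in sorted(deletions, reverse=True):
        del site[j]
    return "".join(site)


def _verify_profile(aln: DuplexAlignment, profile: SynthProfile, mirna_len: int) -> bool:
    """Check the realized per-window edit counts against the request.

    Positions are miRNA positions (gap edits bulge the miRNA, so the aligned
    miRNA string carries no gap characters and column index == position).
    """
    if "-" in aln.aligned_mirna:
        return False
    lo, hi = profile.seed_window
    hi = min(hi, mirna_len)
    seed_states = aln.states[lo - 1 : hi]
    rest_states = aln.states[: lo - 1] + aln.states[hi:]
    return (
        seed_states.count("W") == profile.n_seed_wobbles
        and seed_states.count("X") == profile.n_seed_mismatches
        and seed_states.count("G") == 0
        and sum(rest_states.count(s) for s in "WXG") == profile.n_three_prime_edits
    )


def implant_site(
    transcript: RnaSequence,
    mirna: RnaSequence,
    profile: SynthProfile,
    position: int,
    seed: int | np.random.Generator = 0,
    scheme: PenaltyScheme = DEFAULT_SCHEME,
    retries: int = 50,
) -> tuple[RnaSequence, DuplexAlignment]:
    """Implant a target site for ``mirna`` at ``position`` (1-based).

    The implanted slice replaces transcript bases starting at ``position``.
    The site is re-aligned and the realized edit counts must reproduce the
    profile exactly; edit placements are resampled on failure, with an error
    after ``retries`` attempts.  A perfect profile implants the exact reverse
    complement of the miRNA.
    """
    rng = _as_rng(seed)
    m = len(mirna.residues)
    if position < 1 or position + m - 1 + scheme.max_gaps > len(transcript.residues) + 1:
        raise ValueError("position leaves no room for the site")
    for _ in range(retries):
        site = _build_site(mirna.residues, profile, rng)
        aln = align_duplex(
            mirna,
            site,
            scheme=scheme,
            target_id=transcript.identifier,
            site_start=position,
        )
        if _verify_profile(aln, profile, m):
            new_residues = (
                transcript.residues[: position - 1]
                + site
                + transcript.residues[position - 1 + len(site) :]
            )
            return RnaSequence(transcript.identifier, new_residues), aln
    raise ValueError(
        f"could not realize profile {profile} against {mirna.identifier} "
        f"after {retries} attempts"
    )


@dataclass(frozen=True)
class StudyConfig:
    """Synthetic-study shape: group sizes, sequence geometry, energy model."""

    n_tp: int = 100
    n_fn: int = 100
    n_decoys: int = 20
    mirna_length: int = 21
    gc_target: float | None = 0.5
    transcript_length: tuple[int, int] = (300, 1500)
    seed_window: tuple[int, int] = (2, 12)
    #: ΔG model: slope * length + noise, kcal/mol
    energy_slope: float = -0.05
    energy_noise_sd: float = 10.0
    guard_penalty: float = 6.0
    seed: int = 0


@dataclass(frozen=True)
class SynthStudy:
    """A generated study with exhaustive, disjoint ground truth."""

    mirnas: tuple[RnaSequence, ...]
    transcripts: tuple[RnaSequence, ...]
    validated: tuple[InteractionRecord, ...]       # TP-like implants
    divergent: tuple[InteractionRecord, ...]       # FN-like implants
    decoys: tuple[RnaSequence, ...]
    negatives: tuple[tuple[str, str], ...]
    alignments: dict[tuple[str, str], DuplexAlignment] = field(compare=False)
    energy_records: tuple = ()
    config: StudyConfig = field(default_factory=StudyConfig)

    @property
    def all_transcripts(self) -> tuple[RnaSequence, ...]:
        return self.transcripts + self.decoys

    @property
    def interactions(self) -> tuple[InteractionRecord, ...]:
        return self.validated + self.divergent


def _tp_profile(rng: np.random.Generator, window: tuple[int, int]) -> SynthProfile:
    return SynthProfile(
        seed_window=window,
        n_seed_wobbles=int(rng.integers(0, 2)),  # "less than two G:U wobbles"
        n_seed_mismatches=0,
        n_three_prime_edits=int(rng.integers(0, 2)),
        three_prime_kinds=("mismatch",),
    )


def _fn_profile(rng: np.random.Generator, window: tuple[int, int]) -> SynthProfile:
    mism, wob = FN_SEED_CATEGORIES[int(rng.integers(0, len(FN_SEED_CATEGORIES)))]
    return SynthProfile(
        seed_window=window,
        n_seed_wobbles=wob,
        n_seed_mismatches=mism,
        n_three_prime_edits=2,
        three_prime_kinds=("mismatch", "gap", "wobble"),
    )


def generate_study(config: StudyConfig = StudyConfig()) -> SynthStudy:
    """Generate the full synthetic study described by ``config``.

    One miRNA, one transcript and one implanted site per interaction; the
    TP-like and FN-like groups share the miRNA generator (and its GC target)
    so that duplex features differ between groups while miRNA composition
    does not.  ΔG records are drawn per interaction as
    ``slope * transcript_length + N(0, sd)``.
    """
    from mirduplex.evaluation import EnergyRecord  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    n_total = config.n_tp + config.n_fn
    mirnas = generate_mirnas(
        n_total, length=config.mirna_length, gc_target=config.gc_target, seed=rng
    )

    transcripts: list[RnaSequence] = []
    validated: list[InteractionRecord] = []
    divergent: list[InteractionRecord] = []
    alignments: dict[tuple[str, str], DuplexAlignment] = {}
    energy_records = []

    lo_len, hi_len = config.transcript_length
    for idx, mirna in enumerate(mirnas):
        is_tp = idx < config.n_tp
        group = "tp" if is_tp else "fn"
        tx_len = int(rng.integers(lo_len, hi_len + 1))
        tx_id = f"syn-TX{idx + 1:04d}"
        transcript = generate_transcript(tx_len, tx_id, seed=rng)
        max_start = tx_len - config.mirna_length - DEFAULT_SCHEME.max_gaps
        position = int(rng.integers(1, max_start + 1))
        for attempt in range(20):
            profile = (_tp_profile if is_tp else _fn_profile)(rng, config.seed_window)
            try:
                transcript, aln = implant_site(
                    transcript, mirna, profile, position, seed=rng
                )
                break
            except ValueError:
                if attempt == 19:
                    raise
        transcripts.append(transcript)
        record = InteractionRecord(
            mirna_id=mirna.identifier,
            target_id=tx_id,
            species="synthetic",
            dataset=ARABIDOPSIS if is_tp else NON_ARABIDOPSIS,
            source=f"implant:{group}",
        )
        (validated if is_tp else divergent).append(record)
        alignments[record.pair] = aln
        energy_records.append(
            EnergyRecord(
                mirna_id=mirna.identifier,
                target_id=tx_id,
                delta_g=config.energy_slope * tx_len
                + float(rng.normal(0.0, config.energy_noise_sd)),
                transcript_length=tx_len,
            )
        )

    decoys = _generate_decoys(config, mirnas, rng)
    negatives = tuple(
        (m.identifier, d.identifier) for m in mirnas for d in decoys
    )

    return SynthStudy(
        mirnas=tuple(mirnas),
        transcripts=tuple(transcripts),
        validated=tuple(validated),
        divergent=tuple(divergent),
        decoys=tuple(decoys),
        negatives=negatives,
        alignments=alignments,
        energy_records=tuple(energy_records),
        config=config,
    )


def _generate_decoys(
    config: StudyConfig, mirnas: Sequence[RnaSequence], rng: np.random.Generator
) -> list[RnaSequence]:
    """Rejection-sample transcripts with no alignable site for any miRNA.

    A candidate passes when its best gap-free window penalty against every
    miRNA exceeds the guard, and the seed-anchored scanner confirms no hit
    at the guard cutoff.
    """
    decoys: list[RnaSequence] = []
    scan_cfg = ScanConfig()
    lo_len, hi_len = config.transcript_length
    attempts = 0
    while len(decoys) < config.n_decoys:
        attempts += 1
        if attempts > 200 * max(config.n_decoys, 1):
            raise RuntimeError("decoy rejection sampling failed to converge")
        tx_len = int(rng.integers(lo_len, hi_len + 1))
        candidate = generate_transcript(
            tx_len, f"syn-DECOY{len(decoys) + 1:04d}", seed=rng
        )
        if any(
            gapfree_min_penalty(m, candidate) <= config.guard_penalty for m in mirnas
        ):
            continue
        if any(
            scan_transcript(m, candidate, config.guard_penalty, scan_cfg) for m in mirnas
        ):
            continue
        decoys.append(candidate)
    return decoys


def write_study(study: SynthStudy, outdir) -> dict:
    """Write FASTA/TSV artifacts plus a ground-truth JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_rna_fasta(study.mirnas, outdir / "mirnas.fasta")
    write_rna_fasta(study.all_transcripts, outdir / "transcripts.fasta")
    write_interaction_table(study.interactions, outdir / "interactions.tsv")
    energy = pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "target_id": r.target_id,
                "delta_g": r.delta_g,
                "transcript_length": r.transcript_length,
            }
            for r in study.energy_records
        ]
    )
    write_energy_table(energy, outdir / "energies.tsv")
    manifest = {
        "config": asdict(study.config),
        "validated_pairs": sorted(map(list, (r.pair for r in study.validated))),
        "divergent_pairs": sorted(map(list, (r.pair for r in study.divergent))),
        "negative_pairs": sorted(map(list, study.negatives)),
        "implants": {
            f"{pair[0]}\t{pair[1]}": {
                "site_start": aln.site_start,
                "site_end": aln.site_end,
                "penalty": aln.penalty,
                "states": aln.states,
            }
            for pair, aln in sorted(study.alignments.items())
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Synthetic curated-table stand-in
# ---------------------------------------------------------------------------

def synthetic_curated_tables() -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """A synthetic stand-in for the curated validated-interaction tables.

    Deterministically builds two record lists with the published bookkeeping
    structure of the curated plant interaction resource: 330 unique
    Arabidopsis pairs and 134 unique non-Arabidopsis pairs, of which the
    ambiguous miR414/miR413 families account for 19, so family filtering
    leaves 115.  A handful of exact duplicate rows are included to exercise
    deduplication.  The identifiers are synthetic; only the counts and the
    naming conventions (species prefixes, arm suffixes, lettered variants)
    emulate the real resource.
    """
    arabidopsis: list[InteractionRecord] = []
    for i in range(330):
        family = f"miR{156 + (i % 40)}{'abc'[i % 3]}"
        arabidopsis.append(
            InteractionRecord(
                mirna_id=f"ath-{family}" + ("-5p" if i % 7 == 0 else ""),
                target_id=f"AT{1 + i % 5}G{10000 + i * 7:05d}.1",
                species="Arabidopsis thaliana",
                dataset=ARABIDOPSIS,
                source="synthetic stand-in",
            )
        )
    # duplicate rows (same pair) that deduplication must collapse
    arabidopsis += arabidopsis[:8]

    non_arabidopsis: list[InteractionRecord] = []
    species_cycle = (
        ("osa", "Oryza sativa"),
        ("gma", "Glycine max"),
        ("vvi", "Vitis vinifera"),
    )
    for i in range(115):
        prefix, species = species_cycle[i % 3]
        family = f"miR{160 + (i % 30)}"
        non_arabidopsis.append(
            InteractionRecord(
                mirna_id=f"{prefix}-{family}" + ("-3p" if i % 11 == 0 else ""),
                target_id=f"{prefix.upper()}_T{20000 + i * 13:05d}",
                species=species,
                dataset=NON_ARABIDOPSIS,
                source="synthetic stand-in",
            )
        )
    # the 19 ambiguous-family interactions removed by the blacklist filter
    for i in range(10):
        prefix, species = species_cycle[i % 3]
        non_arabidopsis.append(
            InteractionRecord(
                mirna_id=f"{prefix}-miR414" + ("-5p" if i % 4 == 0 else ""),
                target_id=f"{prefix.upper()}_T{40000 + i * 17:05d}",
                species=species,
                dataset=NON_ARABIDOPSIS,
                source="synthetic stand-in",
            )
        )
    for i in range(9):
        prefix, species = species_cycle[i % 3]
        non_arabidopsis.append(
            InteractionRecord(
                mirna_id=f"{prefix}-miR413",
                target_id=f"{prefix.upper()}_T{50000 + i * 19:05d}",
                species=species,
                dataset=NON_ARABIDOPSIS,
                source="synthetic stand-in",
            )
        )
    non_arabidopsis += non_arabidopsis[:6]
    return arabidopsis, non_arabidopsis
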