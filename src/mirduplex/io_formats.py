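"""External representations: FASTA sequences and the pipeline's TSV tables.

All tabular interchange uses tab-separated text with a mandatory header so
there is a single parsing path to test.  Coordinates are 1-based inclusive
throughout.  DNA input is accepted and silently normalized to RNA (T -> U)
on read.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirduplex.duplex_align import RNA_BASES

ARABIDOPSIS = "arabidopsis"
NON_ARABIDOPSIS = "non_arabidopsis"

INTERACTION_COLUMNS = ["mirna_id", "target_id", "species", "dataset", "source"]
PREDICTION_COLUMNS = ["mirna_id", "target_id", "score", "site_start", "site_end", "tool"]
ENERGY_COLUMNS = ["mirna_id", "target_id", "delta_g", "transcript_length"]

ORIENTATIONS = ("lower_better", "higher_better")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence, 5'->3', residues restricted to A/C/G/U."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("empty sequence identifier")
        if not self.residues:
            raise ValueError(f"empty sequence for {self.identifier!r}")
        bad = set(self.residues) - RNA_BASES
        if bad:
            raise ValueError(
                f"invalid residue(s) {sorted(bad)} in {self.identifier!r}; expected A/C/G/U"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InteractionRecord:
    """One validated miRNA-mRNA interaction."""

    mirna_id: str
    target_id: str
    species: str = ""
    dataset: str = ARABIDOPSIS
    source: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.target_id)


@dataclass(frozen=True)
class Prediction:
    """A scored predicted miRNA-mRNA pair; site coordinates optional."""

    mirna_id: str
    target_id: str
    score: float
    site_start: int | None = None
    site_end: int | None = None
    tool: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.pair}")
        if self.site_start is not None and self.site_end is not None:
            if self.site_start > self.site_end:
                raise ValueError(f"site_start > site_end for {self.pair}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.target_id)


@dataclass(frozen=True)
class PredictionTable:
    """Predictions plus the score orientation needed by threshold sweeps."""

    predictions: tuple[Prediction, ...]
    orientation: str = "lower_better"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")

    def __iter__(self):
        return iter(self.predictions)

    def __len__(self) -> int:
        return len(self.predictions)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_rna_fasta(path) -> list[RnaSequence]:
    """Read a FASTA file as RNA, normalizing T->U; order is preserved.

    Duplicate identifiers and empty records are errors.
    """
    out: list[RnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("T", "U")
        if not residues:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        out.append(RnaSequence(rec.id, residues))
    return out


def write_rna_fasta(sequences: Iterable[RnaSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------

def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; expected header {list(required)}"
        )
    return df


def read_interaction_table(path) -> list[InteractionRecord]:
    """Read a validated-interaction TSV; exact duplicate pairs are collapsed.

    Deduplication keeps the first occurrence of each (mirna_id, target_id)
    pair and is idempotent.
    """
    df = _read_tsv(path, INTERACTION_COLUMNS)
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        rec = InteractionRecord(
            mirna_id=row.mirna_id,
            target_id=row.target_id,
            species=row.species,
            dataset=row.dataset,
            source=row.source,
        )
        if rec.pair in seen:
            continue
        seen.add(rec.pair)
        records.append(rec)
    return records


def write_interaction_table(records: Iterable[InteractionRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=INTERACTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def count_unique_pairs(records: Iterable[InteractionRecord]) -> dict[str, int]:
    """Number of unique (mirna_id, target_id) pairs per dataset label."""
    pairs: dict[str, set[tuple[str, str]]] = {}
    for r in records:
        pairs.setdefault(r.dataset, set()).add(r.pair)
    return {k: len(v) for k, v in sorted(pairs.items())}


_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-", re.IGNORECASE)
_ARM_SUFFIX = re.compile(r"[-._](5p|3p)$", re.IGNORECASE)


def mirna_family(name: str) -> str:
    """miRNA family token: species prefix and mature-arm suffix stripped.

    Lettered variants (miR414a vs miR414) are distinct families and are NOT
    collapsed.
    """
    name = _SPECIES_PREFIX.sub("", name)
    name = _ARM_SUFFIX.sub("", name)
    return name.lower()


def filter_ambiguous_mirnas(
    records: Sequence[InteractionRecord],
    blacklist: Iterable[str],
) -> tuple[list[InteractionRecord], int]:
    """Drop interactions whose miRNA belongs to a blacklisted family.

    Family matching ignores the species prefix (``ath-``, ``osa-``) and the
    mature-arm suffix (``-5p``/``-3p``).  Returns the kept records and the
    number removed.  An empty blacklist is the identity.
    """
    families = {mirna_family(b) for b in blacklist}
    kept = [r for r in records if mirna_family(r.mirna_id) not in families]
    return kept, len(records) - len(kept)


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------

def read_prediction_table(path, score_orientation: str = "lower_better") -> PredictionTable:
    """Read a scored-prediction TSV and record the score orientation."""
    if score_orientation not in ORIENTATIONS:
        raise ValueError(f"score_orientation must be one of {ORIENTATIONS}")
    df = _read_tsv(path, PREDICTION_COLUMNS)
    preds: list[Prediction] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            score = float(row.score)
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric score {row.score!r} at line {idx}"
            ) from None
        preds.append(
            Prediction(
                mirna_id=row.mirna_id,
                target_id=row.target_id,
                score=score,
                site_start=int(row.site_start) if row.site_start else None,
                site_end=int(row.site_end) if row.site_end else None,
                tool=row.tool,
            )
        )
    return PredictionTable(tuple(preds), score_orientation)


def write_prediction_table(predictions: Iterable[Prediction], path) -> None:
    rows = []
    for p in predictions:
        row = asdict(p)
        row["site_start"] = "" if p.site_start is None else p.site_start
        row["site_end"] = "" if p.site_end is None else p.site_end
        rows.append(row)
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Energy tables, feature tables, reports
# ---------------------------------------------------------------------------

def read_energy_table(path) -> pd.DataFrame:
    """Free-energy records: one row per interaction with delta_g (kcal/mol)
    and transcript_length (nt)."""
    df = _read_tsv(path, ENERGY_COLUMNS)
    df["delta_g"] = df["delta_g"].astype(float)
    df["transcript_length"] = df["transcript_length"].astype(int)
    if (df["transcript_length"] <= 0).any():
        raise ValueError(f"{path}: non-positive transcript_length")
    return df


def write_energy_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ENERGY_COLUMNS)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Curated-workbook conversion
# ---------------------------------------------------------------------------

def convert_curated_workbook(
    xlsx_path,
    out_path,
    arabidopsis_sheets: Sequence[str] = ("A", "B", "C"),
    non_arabidopsis_sheets: Sequence[str] = ("E", "F", "G"),
    mirna_column: str = "mirna_id",
    target_column: str = "target_id",
    species_column: str | None = "species",
    source_column: str | None = "source",
) -> list[InteractionRecord]:
    """One-shot converter from a curated interaction workbook to the TSV schema.

    Sheets listed in ``arabidopsis_sheets`` are labelled ``arabidopsis``, the
    rest ``non_arabidopsis``.  Rows lacking a miRNA or target identifier are
    skipped.  Writes the canonical interaction TSV to ``out_path`` and returns
    the (non-deduplicated) records; dedup happens on read.
    """
    import openpyxl  # heavyweight; only needed for this one-time conversion

    wb = openpyxl.load_workbook(xlsx_path, read_only=True, data_only=True)
    records: list[InteractionRecord] = []
    for sheets, dataset in (
        (arabidopsis_sheets, ARABIDOPSIS),
        (non_arabidopsis_sheets, NON_ARABIDOPSIS),
    ):
        for name in sheets:
            if name not in wb.sheetnames:
                continue
            ws = wb[name]
            rows = ws.iter_rows(values_only=True)
            header = [str(c).strip() if c is not None else "" for c in next(rows)]
            col = {h: i for i, h in enumerate(header)}
            for needed in (mirna_column, target_column):
                if needed not in col:
                    raise ValueError(
                        f"sheet {name!r}: missing column {needed!r} in header {header}"
                    )
            for raw in rows:
                mirna = raw[col[mirna_column]]
                target = raw[col[target_column]]
                if not mirna or not target:
                    continue
                records.append(
                    InteractionRecord(
                        mirna_id=str(mirna).strip(),
                        target_id=str(target).strip(),
                        species=str(raw[col[species_column]] or "").strip()
                        if species_column and species_column in col
                        else "",
                        dataset=dataset,
                        source=str(raw[col[source_column]] or "").strip()
                        if source_column and source_column in col
                        else f"sheet:{name}",
                    )
                )
    write_interaction_table(records, out_path)
    return records
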