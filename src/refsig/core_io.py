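"""Data model and readers/writers for ASV count tables and signature tables.

The central container is :class:`AsvTable`: an integer count matrix
(samples x amplicon sequence variants) together with the representative
DNA sequence of every ASV and a binary case/control label per sample.
Everything downstream — feature selection, held-out validation,
cross-cohort sequence matching, differential abundance — consumes and
produces this one type.

:class:`SignatureTable` holds an ordered, ranked list of selected ASVs
with their seven-rank taxonomy (domain through species), the direction of
differential abundance, and per-cohort presence flags. A transcription of
the published 26-ASV autism signature ships with the package and is
loadable via :func:`load_asd_signature`; its nucleotide sequences were
never published, so the packaged copy carries taxonomy, direction and
presence only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AsvTable",
    "LabelVector",
    "SignatureRecord",
    "SignatureTable",
    "TAXONOMY_RANKS",
    "load_asd_signature",
    "read_asv_table",
    "read_signature_table",
    "summarize_taxonomy",
    "write_asv_table",
    "write_signature_table",
]

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

MIN_SEQUENCE_LENGTH = 50

#: accepted spellings for the two classes (lower-cased before lookup)
CASE_ALIASES = frozenset({"case", "asd", "1"})
CONTROL_ALIASES = frozenset({"control", "nt", "0"})

_DNA_ALPHABET = frozenset("ACGT")


class TableValidationError(ValueError):
    """Raised when a count table, sequence set or label set is inconsistent."""


def _normalize_label(raw: str) -> str:
    token = str(raw).strip().lower()
    if token in CASE_ALIASES:
        return "case"
    if token in CONTROL_ALIASES:
        return "control"
    raise TableValidationError(
        f"unrecognized label {raw!r}: expected one of "
        f"{sorted(CASE_ALIASES)} (case) or {sorted(CONTROL_ALIASES)} (control)"
    )


def _clean_sequence(raw: str, asv_id: str) -> str:
    seq = str(raw).strip().upper().replace("U", "T")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise TableValidationError(
            f"sequence for ASV {asv_id!r} contains non-ACGT characters: {sorted(bad)}"
        )
    if len(seq) < MIN_SEQUENCE_LENGTH:
        raise TableValidationError(
            f"sequence for ASV {asv_id!r} is {len(seq)} nt; "
            f"minimum is {MIN_SEQUENCE_LENGTH}"
        )
    return seq


@dataclass
class LabelVector:
    """Binary labels aligned to an ordered list of sample ids."""

    values: np.ndarray  # 0/1 ints, 1 = positive class
    positive_class: str = "case"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if not np.isin(self.values, (0, 1)).all():
            raise TableValidationError("label vector must be binary 0/1")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AsvTable:
    """Samples x ASVs integer count matrix with sequences and labels.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (rows of ``counts``).
    asv_ids
        Ordered, unique ASV identifiers (columns of ``counts``).
    counts
        Non-negative integer matrix of shape ``(len(sample_ids), len(asv_ids))``.
    sequences
        ``asv_id -> DNA string`` over {A, C, G, T}; every sequence is at
        least 50 nt (shorter amplicons do not occur in denoised 16S data).
    labels
        ``sample_id -> "case" | "control"``.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray
    sequences: dict[str, str]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableValidationError("duplicate sample ids")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise TableValidationError("duplicate ASV ids")
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise TableValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.asv_ids)} ASVs)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64, casting="unsafe")
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(as_int != self.counts)[0]
                raise TableValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"ASV {self.asv_ids[bad[1]]!r}"
                )
            self.counts = as_int
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise TableValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"ASV {self.asv_ids[bad[1]]!r}"
            )
        missing = [a for a in self.asv_ids if a not in self.sequences]
        if missing:
            raise TableValidationError(f"missing sequence for ASV(s): {missing[:5]}")
        self.sequences = {a: _clean_sequence(self.sequences[a], a) for a in self.asv_ids}
        unlabeled = [s for s in self.sample_ids if s not in self.labels]
        if unlabeled:
            raise TableValidationError(f"missing label for sample(s): {unlabeled[:5]}")
        self.labels = {s: _normalize_label(self.labels[s]) for s in self.sample_ids}

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def label_vector(self, positive_class: str = "case") -> LabelVector:
        values = np.array(
            [1 if self.labels[s] == positive_class else 0 for s in self.sample_ids]
        )
        return LabelVector(values=values, positive_class=positive_class)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    def subset_asvs(self, asv_ids: Sequence[str]) -> "AsvTable":
        """Restrict to the given ASVs, preserving the given order."""
        missing = [a for a in asv_ids if a not in set(self.asv_ids)]
        if missing:
            raise KeyError(f"ASV id(s) not in table: {missing[:5]}")
        idx = [self.asv_ids.index(a) for a in asv_ids]
        return AsvTable(
            sample_ids=list(self.sample_ids),
            asv_ids=list(asv_ids),
            counts=self.counts[:, idx].copy(),
            sequences={a: self.sequences[a] for a in asv_ids},
            labels=dict(self.labels),
        )

    def equals(self, other: "AsvTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
            and self.sequences == other.sequences
            and self.labels == other.labels
        )


# ---------------------------------------------------------------------------
# count-table / FASTA / label I/O


def _read_delimited(path: Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        # sniff: tab wins if present in the header line
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)


def read_asv_table(
    counts_path: str | Path,
    fasta_path: str | Path,
    labels_path: str | Path,
    *,
    delimiter: str | None = None,
    transpose: bool = False,
) -> AsvTable:
    """Read a count table (TSV/CSV), ASV FASTA, and labels TSV into an AsvTable.

    The count file has sample rows and ASV columns with the sample id in
    the first column; pass ``transpose=True`` for the ASV-as-rows dialect.
    FASTA record ids must match the ASV column names. The labels file has
    columns ``sample_id`` and ``label`` with values among the accepted
    case/control aliases (ASD/NT, 1/0, case/control; case-insensitive).
    """
    counts_path, fasta_path, labels_path = (
        Path(counts_path),
        Path(fasta_path),
        Path(labels_path),
    )
    frame = _read_delimited(counts_path, delimiter)
    if transpose:
        frame = frame.T
    try:
        numeric = frame.astype(np.int64)
    except (ValueError, TypeError):
        for col in frame.columns:
            for idx in frame.index:
                cell = frame.at[idx, col]
                try:
                    value = int(cell)
                except (ValueError, TypeError):
                    raise TableValidationError(
                        f"non-integer count {cell!r} at sample {idx!r}, ASV {col!r}"
                    ) from None
                if str(value) != str(cell).strip():
                    raise TableValidationError(
                        f"non-integer count {cell!r} at sample {idx!r}, ASV {col!r}"
                    )
        raise  # pragma: no cover - loop above always raises first

    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    labels_frame = pd.read_csv(labels_path, sep="\t", dtype=str)
    expected_cols = {"sample_id", "label"}
    if not expected_cols.issubset(labels_frame.columns):
        raise TableValidationError(
            f"labels file must have columns {sorted(expected_cols)}, "
            f"got {list(labels_frame.columns)}"
        )
    labels = dict(zip(labels_frame["sample_id"], labels_frame["label"]))
    return AsvTable(
        sample_ids=list(numeric.index),
        asv_ids=list(numeric.columns),
        counts=numeric.to_numpy(),
        sequences=sequences,
        labels=labels,
    )


def write_asv_table(
    table: AsvTable,
    counts_path: str | Path,
    fasta_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write the table back to TSV + FASTA + labels TSV (round-trip exact)."""
    table.counts_frame().to_csv(counts_path, sep="\t", index_label="sample_id")
    records = [
        SeqRecord(Seq(table.sequences[a]), id=a, description="") for a in table.asv_ids
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {"sample_id": table.sample_ids, "label": [table.labels[s] for s in table.sample_ids]}
    ).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature tables

DIRECTIONS = ("ASD increased", "ASD decreased")


@dataclass
class SignatureRecord:
    index: int
    taxonomy: dict[str, str | None]  # rank -> name or None
    direction: str
    presence: dict[str, str]  # cohort id -> "Yes" | "No"
    sequence: str | None = None

    def rank_name(self, rank: str) -> str | None:
        return self.taxonomy.get(rank)


@dataclass
class SignatureTable:
    """Ordered, ranked list of signature ASVs (the shape of the published table)."""

    records: list[SignatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise TableValidationError("signature table has no records")
        indices = [r.index for r in self.records]
        if sorted(indices) != list(range(1, len(indices) + 1)):
            raise TableValidationError(
                f"signature indices must be consecutive 1..N, got {indices}"
            )
        for rec in self.records:
            if rec.direction not in DIRECTIONS:
                raise TableValidationError(
                    f"record {rec.index}: unknown direction {rec.direction!r}"
                )
            self._check_prefix_consistency(rec)

    @staticmethod
    def _check_prefix_consistency(rec: SignatureRecord) -> None:
        # once a rank is unassigned, all lower ranks must be unassigned too
        seen_na = False
        for rank in TAXONOMY_RANKS:
            name = rec.taxonomy.get(rank)
            if name is None:
                seen_na = True
            elif seen_na:
                raise TableValidationError(
                    f"record {rec.index}: rank {rank!r} named below an unassigned rank"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cohorts(self) -> list[str]:
        seen: list[str] = []
        for rec in self.records:
            for cohort in rec.presence:
                if cohort not in seen:
                    seen.append(cohort)
        return seen

    def presence_counts(self) -> dict[str, int]:
        """Number of signature ASVs flagged present ("Yes") per cohort."""
        return {
            cohort: sum(1 for r in self.records if r.presence.get(cohort) == "Yes")
            for cohort in self.cohorts
        }


_FIXED_SIGNATURE_COLUMNS = ("index", "sequence", "direction") + TAXONOMY_RANKS


def _parse_signature_frame(frame: pd.DataFrame, source: str) -> SignatureTable:
    frame.columns = [str(c).strip().lower() if str(c).strip().lower() in
                     _FIXED_SIGNATURE_COLUMNS else str(c).strip() for c in frame.columns]
    required = {"index", "direction"} | set(TAXONOMY_RANKS)
    missing = required - set(frame.columns)
    if missing:
        raise TableValidationError(f"{source}: missing column(s) {sorted(missing)}")
    cohort_cols = [c for c in frame.columns if c not in _FIXED_SIGNATURE_COLUMNS]
    if frame.empty:
        raise TableValidationError(f"{source}: no records")
    indices = frame["index"].astype(int).tolist()
    if len(set(indices)) != len(indices):
        raise TableValidationError(f"{source}: duplicate index values")

    records = []
    for _, row in frame.iterrows():
        taxonomy = {}
        for rank in TAXONOMY_RANKS:
            cell = row[rank]
            name = None if pd.isna(cell) or str(cell).strip().upper() == "NA" else str(cell).strip()
            taxonomy[rank] = name
        seq_cell = row.get("sequence")
        sequence = None if seq_cell is None or pd.isna(seq_cell) or not str(seq_cell).strip() else str(seq_cell).strip().upper()
        presence = {}
        for cohort in cohort_cols:
            cell = str(row[cohort]).strip().capitalize()
            if cell not in ("Yes", "No"):
                raise TableValidationError(
                    f"{source}: presence flag {row[cohort]!r} for cohort {cohort!r} "
                    "is not Yes/No"
                )
            presence[cohort] = cell
        records.append(
            SignatureRecord(
                index=int(row["index"]),
                taxonomy=taxonomy,
                direction=str(row["direction"]).strip(),
                presence=presence,
                sequence=sequence,
            )
        )
    records.sort(key=lambda r: r.index)
    return SignatureTable(records=records)


def read_signature_table(path: str | Path) -> SignatureTable:
    """Read a signature table TSV (fixed header; NA = taxonomy unassigned)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableValidationError(f"{path}: no records") from None
    frame = frame.where(frame != "", other=np.nan)
    return _parse_signature_frame(frame, str(path))


def write_signature_table(sig: SignatureTable, path: str | Path) -> None:
    cohorts = sig.cohorts
    rows = []
    for rec in sig.records:
        row: dict[str, object] = {"index": rec.index, "sequence": rec.sequence or ""}
        for rank in TAXONOMY_RANKS:
            row[rank] = rec.taxonomy[rank] or "NA"
        row["direction"] = rec.direction
        for cohort in cohorts:
            row[cohort] = rec.presence.get(cohort, "No")
        rows.append(row)
    columns = ["index", "sequence", *TAXONOMY_RANKS, "direction", *cohorts]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def load_asd_signature() -> SignatureTable:
    """Load the packaged 26-ASV autism signature (taxonomy, direction, presence).

    The nucleotide sequences of the published signature are not public, so
    the ``sequence`` field of every record is ``None``.
    """
    ref = resources.files("refsig.data").joinpath("asd_signature_26.tsv")
    frame = pd.read_csv(io.StringIO(ref.read_text()), sep="\t", dtype=str, keep_default_na=False)
    frame = frame.where(frame != "", other=np.nan)
    return _parse_signature_frame(frame, "packaged asd_signature_26.tsv")


def summarize_taxonomy(sig: SignatureTable, rank: str) -> dict[str, int]:
    """Count signature records per taxon name at one rank.

    Unassigned (NA) records are grouped under ``"unassigned"``; the counts
    always sum to the number of records.
    """
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"rank must be one of {TAXONOMY_RANKS}, got {rank!r}")
    counts: dict[str, int] = {}
    for rec in sig.records:
        name = rec.taxonomy.get(rank) or "unassigned"
        counts[name] = counts.get(name, 0) + 1
    return counts
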