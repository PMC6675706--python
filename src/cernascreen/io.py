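"""Domain types and readers/writers for the tabular and sequence formats.

Expression matrices are gene-per-row TSV (first column gene id, header row of
sample ids), the shape of TCGA level-3 tables. Sequences are plain FASTA;
DNA input is normalized to the RNA alphabet (T -> U) on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

Scale = Literal["linear", "log"]


class CernaScreenError(Exception):
    """Base class for errors raised by this package."""


class FormatError(CernaScreenError):
    """Malformed input file or sequence."""


class DegenerateInputError(CernaScreenError):
    """Statistically degenerate input (zero variance, empty overlap...)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table.

    ``data`` holds real-valued normalized expression, genes as the index and
    samples as the columns. ``scale`` records whether values are linear
    abundances (non-negative) or already log-transformed.
    """

    data: pd.DataFrame
    scale: Scale = "linear"

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains non-finite values")
        if self.scale == "linear" and (values < 0).any():
            raise FormatError("linear-scale expression matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def vector(self, gene_id: str) -> np.ndarray:
        """Expression of one gene across all samples, in column order."""
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], scale=self.scale)


_STATUS_VALUES = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class SampleAnnotation:
    """Receptor status (ER/PR/HER2) for one sample."""

    sample_id: str
    er_status: str
    pr_status: str
    her2_status: str

    def __post_init__(self) -> None:
        for name in ("er_status", "pr_status", "her2_status"):
            value = getattr(self, name)
            if value not in _STATUS_VALUES:
                raise ValueError(
                    f"{name}={value!r} for {self.sample_id}: must be one of {_STATUS_VALUES}"
                )


@dataclass(frozen=True)
class TranscriptSequence:
    """A transcript in the RNA alphabet, id taken from its FASTA header."""

    transcript_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"{self.transcript_id}: empty sequence")
        bad = next((i for i, c in enumerate(self.sequence) if c not in RNA_ALPHABET), None)
        if bad is not None:
            raise FormatError(
                f"{self.transcript_id}: illegal character {self.sequence[bad]!r} "
                f"at position {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA written 5'->3'.

    The seed region (nucleotides 2-7 for the 6-nt seed, 2-8 for the 7-nt
    seed) anchors all canonical target-site classes.
    """

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise FormatError(
                f"{self.mirna_id}: mature miRNA must be >= 8 nt, got {len(self.sequence)}"
            )
        bad = next((i for i, c in enumerate(self.sequence) if c not in RNA_ALPHABET), None)
        if bad is not None:
            raise FormatError(
                f"{self.mirna_id}: illegal character {self.sequence[bad]!r} at position {bad + 1}"
            )

    @property
    def seed6(self) -> str:
        """Nucleotides 2-7, 5'->3'."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """Nucleotides 2-8, 5'->3'."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class DEGeneRecord:
    """One row of a differential-expression result table."""

    gene_id: str
    log2fc: float
    pvalue: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValueError(f"{self.gene_id}: log2fc must be finite")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.gene_id}: pvalue must be in (0, 1], got {self.pvalue}")


def _normalize_rna(raw: str) -> str:
    return raw.upper().replace("T", "U")


def read_expression_matrix(path: str | Path, scale: Scale = "linear") -> ExpressionMatrix:
    """Read a gene-per-row TSV expression matrix.

    First column holds gene ids, the header row holds sample ids. Cells may
    be the literal ``NA``; genes with any NA are dropped with a warning so
    that downstream correlations run over complete vectors only.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=["NA"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad_rows[0] if len(bad_rows) else "?"
            raise FormatError(f"{path.name}: non-numeric value in column {col!r}, row {row!r}")
    incomplete = df.index[df.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "%s: dropping %d gene(s) with NA values: %s",
            path.name, len(incomplete), list(incomplete[:5]),
        )
        df = df.drop(index=incomplete)
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as gene-per-row TSV with full float precision."""
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_fasta(path: str | Path) -> list[TranscriptSequence]:
    """Read a multi-record FASTA into RNA-normalized transcripts.

    T and U, upper and lower case are all accepted; sequences are normalized
    to uppercase RNA. The record id is the first whitespace-delimited token
    of the header; the remainder is kept as a description. An empty file
    yields an empty list.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            TranscriptSequence(
                transcript_id=rec.id,
                sequence=_normalize_rna(str(rec.seq)),
                description=desc,
            )
        )
    return records


def write_fasta(transcripts: Iterable[TranscriptSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description=t.description)
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mirna_table(path: str | Path) -> list[MatureMiRNA]:
    """Read a two-column TSV of (mirna_id, mature sequence 5'->3')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "sequence"}.issubset(df.columns):
        raise FormatError(f"{Path(path).name}: need columns 'mirna_id' and 'sequence'")
    return [
        MatureMiRNA(mirna_id=row.mirna_id, sequence=_normalize_rna(row.sequence))
        for row in df.itertuples()
    ]


def write_mirna_table(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    pd.DataFrame(
        [(m.mirna_id, m.sequence) for m in mirnas], columns=["mirna_id", "sequence"]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample-annotation TSV (sample_id, er_status, pr_status, her2_status)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "er_status", "pr_status", "her2_status"}
    if not required.issubset(df.columns):
        raise FormatError(f"{Path(path).name}: need columns {sorted(required)}")
    return [
        SampleAnnotation(
            sample_id=row.sample_id,
            er_status=row.er_status,
            pr_status=row.pr_status,
            her2_status=row.her2_status,
        )
        for row in df.itertuples()
    ]


def write_annotations(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.sample_id, a.er_status, a.pr_status, a.her2_status) for a in annotations],
        columns=["sample_id", "er_status", "pr_status", "her2_status"],
    ).to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> list[DEGeneRecord]:
    """Read a DE result TSV with columns gene_id, log2fc, pvalue."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue"}
    if not required.issubset(df.columns):
        raise FormatError(f"{Path(path).name}: need columns {sorted(required)}")
    return [
        DEGeneRecord(gene_id=str(row.gene_id), log2fc=float(row.log2fc), pvalue=float(row.pvalue))
        for row in df.itertuples()
    ]
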