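"""miRNA target-site prediction by seed complementarity.

A canonical site is anchored by a Watson-Crick match of the transcript to
the reverse complement of the miRNA seed (nucleotides 2-7). Flanking
nucleotides refine the class:

* ``8mer``     — seed match extended to position 8 of the miRNA, plus an
  adenosine opposite miRNA position 1;
* ``7mer-m8``  — seed match extended to position 8;
* ``7mer-A1``  — seed match plus the position-1 adenosine;
* ``6mer``     — the bare seed match.

G:U wobble pairs are not allowed. One physical locus (one seed-core match)
is reported once, with the highest class it supports (8mer > 7mer-m8 >
7mer-A1 > 6mer). Coordinates are 1-based inclusive on the transcript,
5' -> 3'.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import MatureMiRNA, TranscriptSequence

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
# descending binding-strength hierarchy used for per-locus collapsing
_SITE_RANK = {name: i for i, name in enumerate(SITE_TYPES)}

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the RNA alphabet."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedMatch:
    """A predicted miRNA site on a transcript (1-based inclusive span)."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    site_type: str
    site_sequence: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end}]")
        length = self.end - self.start + 1
        if length != len(self.site_sequence):
            raise ValueError("site span and site_sequence length disagree")
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if length != expected:
            raise ValueError(f"{self.site_type} site must span {expected} nt, got {length}")


def seed_site_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """Expected transcript substrings for each canonical site class.

    Patterns are written 5'->3' in transcript orientation: the 6mer is the
    reverse complement of miRNA nucleotides 2-7, the 7mer-m8 of nucleotides
    2-8; the A1 classes append the adenosine opposite miRNA position 1.
    """
    rc6 = reverse_complement(mirna.seed6)
    rc7 = reverse_complement(mirna.seed7)
    return {
        "6mer": rc6,
        "7mer-A1": rc6 + "A",
        "7mer-m8": rc7,
        "8mer": rc7 + "A",
    }


def find_seed_matches(
    mirna: MatureMiRNA,
    transcript: TranscriptSequence,
    site_types: Iterable[str] = SITE_TYPES,
) -> list[SeedMatch]:
    """Scan a transcript for canonical seed sites of one miRNA.

    Every seed-core occurrence is examined (overlapping cores included) and
    reported once with the best class it supports among the requested
    ``site_types``. Results are sorted by start coordinate.
    """
    requested = list(dict.fromkeys(site_types))
    unknown = [t for t in requested if t not in SITE_TYPES]
    if unknown:
        raise ValueError(f"unknown site types: {unknown}")
    if not requested:
        raise ValueError("site_types must be non-empty")

    seq = transcript.sequence
    patterns = seed_site_patterns(mirna)
    core = patterns["6mer"]
    m8 = patterns["7mer-m8"][0]  # transcript base pairing miRNA position 8

    matches: list[SeedMatch] = []
    pos = seq.find(core)
    while pos != -1:
        has_m8 = pos > 0 and seq[pos - 1] == m8
        has_a1 = pos + 6 < len(seq) and seq[pos + 6] == "A"
        supported = ["6mer"]
        if has_a1:
            supported.append("7mer-A1")
        if has_m8:
            supported.append("7mer-m8")
        if has_m8 and has_a1:
            supported.append("8mer")
        best = min(
            (t for t in supported if t in requested),
            key=_SITE_RANK.__getitem__,
            default=None,
        )
        if best is not None:
            if best in ("8mer", "7mer-m8"):
                start0 = pos - 1
            else:
                start0 = pos
            end0 = pos + 6 if best in ("8mer", "7mer-A1") else pos + 5
            matches.append(
                SeedMatch(
                    mirna_id=mirna.mirna_id,
                    transcript_id=transcript.transcript_id,
                    start=start0 + 1,
                    end=end0 + 1,
                    site_type=best,
                    site_sequence=seq[start0 : end0 + 1],
                )
            )
        pos = seq.find(core, pos + 1)
    matches.sort(key=lambda m: (m.start, m.end))
    return matches


def targets_table(
    mirnas: Sequence[MatureMiRNA],
    transcripts: Sequence[TranscriptSequence],
    site_types: Iterable[str] = SITE_TYPES,
) -> list[SeedMatch]:
    """All-vs-all seed scan: union of find_seed_matches over the cross product.

    A (miRNA, transcript) pair counts as a target relationship iff it
    contributes at least one match.
    """
    if not mirnas or not transcripts:
        raise ValueError("mirnas and transcripts must be non-empty")
    site_types = list(site_types)
    out: list[SeedMatch] = []
    for transcript in transcripts:
        for mirna in mirnas:
            out.extend(find_seed_matches(mirna, transcript, site_types))
    return out


def target_pairs(matches: Iterable[SeedMatch]) -> set[tuple[str, str]]:
    """Distinct (mirna_id, transcript_id) relationships in a match list."""
    return {(m.mirna_id, m.transcript_id) for m in matches}


def write_targets_tsv(matches: Sequence[SeedMatch], path: str | Path, bed: bool = False) -> None:
    """Write matches as TSV; ``bed=True`` selects the 0-based BED dialect."""
    if bed:
        df = pd.DataFrame(
            [(m.transcript_id, m.start - 1, m.end, m.mirna_id, m.site_type) for m in matches],
            columns=["transcript_id", "start", "end", "mirna_id", "site_type"],
        )
    else:
        df = pd.DataFrame(
            [
                (m.mirna_id, m.transcript_id, m.start, m.end, m.site_type, m.site_sequence)
                for m in matches
            ],
            columns=["mirna_id", "transcript_id", "start", "end", "site_type", "site_sequence"],
        )
    df.to_csv(path, sep="\t", index=False)


def read_targets_tsv(path: str | Path) -> list[SeedMatch]:
    """Read the native 1-based target TSV written by write_targets_tsv."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "transcript_id": str})
    return [
        SeedMatch(
            mirna_id=row.mirna_id,
            transcript_id=row.transcript_id,
            start=int(row.start),
            end=int(row.end),
            site_type=row.site_type,
            site_sequence=row.site_sequence,
        )
        for row in df.itertuples()
    ]
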