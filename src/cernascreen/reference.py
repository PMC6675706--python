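"""Worked-example reference objects for the HCP5 / miR-219a-5p / BIRC3 axis.

``MIR_219A_5P`` is the mature hsa-miR-219a-5p guide strand (5'->3'), whose
seed (GAUUGUC at positions 2-8) defines the site patterns ACAAUC (6mer),
GACAAUC (7mer-m8) and GACAAUCA (8mer) on a target transcript.

The transcript builders below are SYNTHETIC stand-ins, generated with fixed
seeds, for sequences this package does not ship: a lncRNA carrying the
documented miR-219a-5p 6mer site at positions 110-115 (the HCP5 site
location) and a 3'UTR carrying a 7mer site at 1268-1274 (the BIRC3 site
location). They reproduce the documented site coordinates and classes on a
random background; they are NOT the RefSeq sequences. To scan the real
accessions, download them and pass the FASTA through ``read_fasta`` and
``find_seed_matches`` unchanged.
"""

from __future__ import annotations

from .io import MatureMiRNA, TranscriptSequence
from .simulate import simulate_sequences

MIR_219A_5P = MatureMiRNA(mirna_id="hsa-miR-219a-5p", sequence="UGAUUGUCCAAACGCAAUUCU")

# site coordinates documented for the HCP5 transcript and the BIRC3 3'UTR
HCP5_SITE_START, HCP5_SITE_END = 110, 115
BIRC3_SITE_START, BIRC3_SITE_END = 1268, 1274

_FIXTURE_SEED_HCP5 = 1103
_FIXTURE_SEED_BIRC3 = 1104


def synthetic_hcp5_like_transcript(length: int = 1500) -> TranscriptSequence:
    """Synthetic lncRNA with the miR-219a-5p 6mer site at positions 110-115.

    Deterministic stand-in for the HCP5 transcript (NR_040662.1): same site
    class and coordinates, random background elsewhere.
    """
    return simulate_sequences(
        [MIR_219A_5P],
        transcript_length=length,
        embed=[(MIR_219A_5P.mirna_id, HCP5_SITE_START, "6mer")],
        rng_seed=_FIXTURE_SEED_HCP5,
        transcript_id="HCP5_synthetic",
    )


def synthetic_birc3_like_utr(length: int = 1400) -> TranscriptSequence:
    """Synthetic 3'UTR with a miR-219a-5p 7mer site at positions 1268-1274.

    Deterministic stand-in for the BIRC3 mRNA 3'UTR: same site class span
    and coordinates, random background elsewhere.
    """
    return simulate_sequences(
        [MIR_219A_5P],
        transcript_length=length,
        embed=[(MIR_219A_5P.mirna_id, BIRC3_SITE_START, "7mer-m8")],
        rng_seed=_FIXTURE_SEED_BIRC3,
        transcript_id="BIRC3_3UTR_synthetic",
    )
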