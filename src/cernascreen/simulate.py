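"""Sponge-model synthetic data with known ground truth.

The generator plants (lncRNA, miRNA, mRNA) triplets wired by a minimal
saturable sponge mechanism and surrounds them with independent log-normal
decoys, so the triplet screen can be benchmarked against a known answer.

Per sample ``s`` of a planted triplet:

* lncRNA abundance   ``L_s ~ LogNormal(mu_L, sigma)``
* total miRNA pool   ``Mtot_s ~ LogNormal(mu_M, sigma)``; the free pool is
  depleted by sequestration, ``M_s = Mtot_s / (1 + k * L_s)``
* mRNA target        ``T_s = B_s / (1 + g * M_s)`` with baseline
  ``B_s ~ LogNormal(mu_B, sigma)``

so that in expectation corr(L, M) < 0, corr(M, T) < 0 and corr(L, T) > 0 —
the ceRNA sign pattern. ``k`` (sponge strength) and ``g`` (repression
strength) set how strongly each coupling operates; ``sigma`` is biological
noise on the log scale. Baseline medians put both occupancy terms
(``k*L ~ 10``, ``g*M ~ 9`` at defaults) in their sensitive regimes so a
planted triplet represents a genuinely coupled sponge. An optional
negative-binomial rendering converts abundances to overdispersed counts.

One global seed feeds a SeedSequence split per matrix, so enlarging a decoy
pool never perturbs the planted-gene draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MatureMiRNA, SampleAnnotation, TranscriptSequence
from .screen import CeRNATriplet
from .targets import SITE_TYPES, SeedMatch, find_seed_matches, seed_site_patterns

# log-scale baseline medians of the planted sponge components
_MU_LNC = float(np.log(2.0))
_MU_MIR_TOTAL = float(np.log(20.0))
_MU_MRNA_BASE = float(np.log(10.0))
# decoy genes: per-gene latent mean ~ Normal(_MU_DECOY, _SD_DECOY_MEAN^2)
_MU_DECOY = float(np.log(5.0))
_SD_DECOY_MEAN = 0.5

_RNA_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Pool sizes count all genes in a matrix, planted genes included; the
    default emulates a 58-sample triple-negative cohort with one planted
    triplet among 50 decoy miRNAs and 200 decoy mRNAs.
    """

    n_samples: int = 58
    n_lnc: int = 1
    n_mir: int = 51
    n_mrna: int = 201
    planted: tuple[tuple[str, str, str], ...] = (("LNC0001", "MIR0001", "MRNA0001"),)
    sponge_strength: float = 5.0
    repression_strength: float = 5.0
    noise_sd: float = 0.2
    nb_dispersion: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_lnc, self.n_mir, self.n_mrna) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.sponge_strength < 0 or self.repression_strength < 0 or self.noise_sd < 0:
            raise ValueError("sponge_strength, repression_strength and noise_sd must be >= 0")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive when given")
        lnc_pool = set(self.lnc_ids)
        mir_pool = set(self.mir_ids)
        mrna_pool = set(self.mrna_ids)
        seen: set[str] = set()
        for lnc, mir, mrna in self.planted:
            if lnc not in lnc_pool or mir not in mir_pool or mrna not in mrna_pool:
                raise ValueError(f"planted triplet ({lnc}, {mir}, {mrna}) outside the id pools")
            for gene in (lnc, mir, mrna):
                if gene in seen:
                    raise ValueError(f"gene {gene} appears in more than one planted triplet")
                seen.add(gene)

    @property
    def lnc_ids(self) -> list[str]:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lnc)]

    @property
    def mir_ids(self) -> list[str]:
        return [f"MIR{i + 1:04d}" for i in range(self.n_mir)]

    @property
    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i + 1:04d}" for i in range(self.n_mrna)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    planted: list[tuple[str, str, str]]
    latent_means: dict[str, float]
    edge_signs: list[dict[str, int]]  # realized sign per planted edge

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [list(t) for t in self.planted],
            "latent_means": self.latent_means,
            "edge_signs": self.edge_signs,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted=[tuple(t) for t in payload["planted"]],
            latent_means=payload["latent_means"],
            edge_signs=payload["edge_signs"],
        )


def _sign(value: float) -> int:
    return int(np.sign(value))


def simulate_cerna_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Draw (lncRNA, miRNA, mRNA) matrices with planted sponge triplets.

    Returns linear-scale matrices plus the ground truth. All randomness is
    driven by ``config.rng_seed``; the same config reproduces bit-identical
    matrices.
    """
    n = config.n_samples
    k = config.sponge_strength
    g = config.repression_strength
    sigma = config.noise_sd

    ss = np.random.SeedSequence(config.rng_seed)
    planted_ss, lnc_ss, mir_ss, mrna_ss, nb_ss = ss.spawn(5)
    planted_rng = np.random.default_rng(planted_ss)

    values = {
        "lnc": pd.DataFrame(0.0, index=config.lnc_ids, columns=config.sample_ids),
        "mir": pd.DataFrame(0.0, index=config.mir_ids, columns=config.sample_ids),
        "mrna": pd.DataFrame(0.0, index=config.mrna_ids, columns=config.sample_ids),
    }
    latent_means: dict[str, float] = {}
    edge_signs: list[dict[str, int]] = []

    for lnc_id, mir_id, mrna_id in config.planted:
        L = planted_rng.lognormal(_MU_LNC, sigma, size=n)
        M_tot = planted_rng.lognormal(_MU_MIR_TOTAL, sigma, size=n)
        B = planted_rng.lognormal(_MU_MRNA_BASE, sigma, size=n)
        M = M_tot / (1.0 + k * L)
        T = B / (1.0 + g * M)
        values["lnc"].loc[lnc_id] = L
        values["mir"].loc[mir_id] = M
        values["mrna"].loc[mrna_id] = T
        latent_means.update(
            {lnc_id: _MU_LNC, mir_id: _MU_MIR_TOTAL, mrna_id: _MU_MRNA_BASE}
        )
        logL, logM, logT = np.log(L), np.log(M), np.log(T)
        edge_signs.append(
            {
                "lnc_mir": _sign(np.corrcoef(logL, logM)[0, 1]),
                "mir_mrna": _sign(np.corrcoef(logM, logT)[0, 1]),
                "lnc_mrna": _sign(np.corrcoef(logL, logT)[0, 1]),
            }
        )

    planted_genes = {gene for triplet in config.planted for gene in triplet}
    for key, child in (("lnc", lnc_ss), ("mir", mir_ss), ("mrna", mrna_ss)):
        rng = np.random.default_rng(child)
        frame = values[key]
        decoy_ids = [gid for gid in frame.index if gid not in planted_genes]
        if decoy_ids:
            means = rng.normal(_MU_DECOY, _SD_DECOY_MEAN, size=len(decoy_ids))
            draws = rng.lognormal(means[:, None], sigma, size=(len(decoy_ids), n))
            frame.loc[decoy_ids] = draws
            latent_means.update(dict(zip(decoy_ids, means.astype(float))))

    if config.nb_dispersion is not None:
        nb_rng = np.random.default_rng(nb_ss)
        for key in ("lnc", "mir", "mrna"):
            mu = values[key].to_numpy() * 100.0  # library-depth scaling
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            values[key].loc[:, :] = nb_rng.negative_binomial(r, p).astype(float)

    truth = SimTruth(
        planted=[tuple(t) for t in config.planted],
        latent_means=latent_means,
        edge_signs=edge_signs,
    )
    return (
        ExpressionMatrix(values["lnc"], scale="linear"),
        ExpressionMatrix(values["mir"], scale="linear"),
        ExpressionMatrix(values["mrna"], scale="linear"),
        truth,
    )


def simulate_mirnas(n: int, rng_seed: int, length: int = 21) -> list[MatureMiRNA]:
    """Random mature miRNAs with pairwise-distinct 7-nt seeds."""
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    out: list[MatureMiRNA] = []
    seeds: set[str] = set()
    while len(out) < n:
        seq = "".join(rng.choice(_RNA_BASES, size=length))
        candidate = MatureMiRNA(mirna_id=f"MIR{len(out) + 1:04d}", sequence=seq)
        if candidate.seed7 in seeds:
            continue
        seeds.add(candidate.seed7)
        out.append(candidate)
    return out


def simulate_sequences(
    mirnas: Sequence[MatureMiRNA],
    transcript_length: int,
    embed: Sequence[tuple[str, int, str]],
    rng_seed: int,
    transcript_id: str = "SIMTX",
) -> TranscriptSequence:
    """Random transcript with seed sites written at exact positions.

    ``embed`` lists (mirna_id, start, site_type) with 1-based site starts.
    The background is rejection-corrected until a full scan reports exactly
    the requested sites for the listed miRNAs — no accidental sites, and no
    embedded site silently upgraded to a higher class by its flanks.
    """
    by_id = {m.mirna_id: m for m in mirnas}
    site_len = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
    spans: list[tuple[int, int]] = []  # 0-based [start, end) of embedded patterns
    for mirna_id, start, site_type in embed:
        if mirna_id not in by_id:
            raise ValueError(f"embed references unknown miRNA {mirna_id!r}")
        if site_type not in site_len:
            raise ValueError(f"unknown site_type {site_type!r}")
        lo, hi = start - 1, start - 1 + site_len[site_type]
        if lo < 0 or hi > transcript_length:
            raise ValueError(f"embedded site [{start}, {hi}] outside transcript bounds")
        for other_lo, other_hi in spans:
            if lo < other_hi and other_lo < hi:
                raise ValueError("embedded sites overlap")
        spans.append((lo, hi))

    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    seq = rng.choice(_RNA_BASES, size=transcript_length)
    for (mirna_id, start, site_type), (lo, hi) in zip(embed, spans):
        pattern = seed_site_patterns(by_id[mirna_id])[site_type]
        seq[lo:hi] = list(pattern)

    expected = {(mid, start, stype) for mid, start, stype in embed}
    embedded_positions = {i for lo, hi in spans for i in range(lo, hi)}
    for _ in range(200):
        transcript = TranscriptSequence(transcript_id=transcript_id, sequence="".join(seq))
        stray_positions: set[int] = set()
        found: set[tuple[str, int, str]] = set()
        for mirna in mirnas:
            for match in find_seed_matches(mirna, transcript, SITE_TYPES):
                key = (match.mirna_id, match.start, match.site_type)
                if key in expected:
                    found.add(key)
                else:
                    stray_positions.update(range(match.start - 1, match.end))
        if not stray_positions and found == expected:
            return transcript
        mutable = sorted(stray_positions - embedded_positions)
        if not mutable:
            raise ValueError("cannot remove a stray site overlapping an embedded site")
        for pos in mutable:
            seq[pos] = rng.choice(_RNA_BASES)
    raise RuntimeError("failed to build a clean background after 200 correction rounds")


def simulate_study_sequences(
    config: SimConfig,
    mirnas: Sequence[MatureMiRNA] | None = None,
    lnc_length: int = 1500,
    mrna_length: int = 1000,
) -> tuple[list[MatureMiRNA], list[TranscriptSequence]]:
    """Transcript sequences matching a simulated dataset's gene pools.

    Each lncRNA and mRNA gets a random-background transcript; every planted
    (lncRNA, miRNA) and (miRNA, mRNA) pair additionally gets one embedded
    8mer site, so planted triplets always carry target evidence. Chance
    seed sites in the random background are left in place — decoy pairs
    acquire target support at the sparsity random sequence dictates, as
    chance sites do in real transcriptomes. Seeded from ``config.rng_seed``
    independently of the expression draws.
    """
    if mirnas is None:
        mirnas = simulate_mirnas(config.n_mir, rng_seed=config.rng_seed)
        mirnas = [
            MatureMiRNA(mirna_id=mid, sequence=m.sequence)
            for mid, m in zip(config.mir_ids, mirnas)
        ]
    by_id = {m.mirna_id: m for m in mirnas}
    embeds: dict[str, list[str]] = {}  # transcript id -> miRNA ids to embed
    for lnc_id, mir_id, mrna_id in config.planted:
        embeds.setdefault(lnc_id, []).append(mir_id)
        embeds.setdefault(mrna_id, []).append(mir_id)

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x5E9]))
    transcripts: list[TranscriptSequence] = []
    for tx_id, length in [(g, lnc_length) for g in config.lnc_ids] + [
        (g, mrna_length) for g in config.mrna_ids
    ]:
        seq = rng.choice(_RNA_BASES, size=length)
        for i, mir_id in enumerate(embeds.get(tx_id, [])):
            pattern = seed_site_patterns(by_id[mir_id])["8mer"]
            start = 20 + 30 * i  # 0-based, spaced to keep embeds disjoint
            seq[start : start + 8] = list(pattern)
        transcripts.append(TranscriptSequence(transcript_id=tx_id, sequence="".join(seq)))
    return list(mirnas), transcripts


def universal_target_support(
    mirna_ids: Sequence[str], transcript_ids: Sequence[str]
) -> list[SeedMatch]:
    """Synthetic target-evidence stub: one nominal 8mer per (miRNA, transcript).

    Grants every pair target support so the correlation stage of the screen
    can be benchmarked in isolation; the site coordinates and sequence are
    placeholders, not scan results.
    """
    return [
        SeedMatch(
            mirna_id=mid,
            transcript_id=tid,
            start=1,
            end=8,
            site_type="8mer",
            site_sequence="ACGUACGU",
        )
        for tid in transcript_ids
        for mid in mirna_ids
    ]


@dataclass(frozen=True)
class RecoveryResult:
    precision: float
    recall: float
    precision_defined: bool


def evaluate_recovery(predicted: Sequence[CeRNATriplet], truth: SimTruth) -> RecoveryResult:
    """Precision/recall of predicted triplets against the planted set.

    With no predictions, precision is undefined (flagged, reported as 0
    unless the planted set is also empty, in which case both are 1).
    """
    predicted_set = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in predicted}
    planted_set = {tuple(t) for t in truth.planted}
    hits = len(predicted_set & planted_set)
    if not predicted_set and not planted_set:
        return RecoveryResult(precision=1.0, recall=1.0, precision_defined=True)
    if not predicted_set:
        return RecoveryResult(precision=0.0, recall=0.0, precision_defined=False)
    precision = hits / len(predicted_set)
    recall = hits / len(planted_set) if planted_set else 1.0
    return RecoveryResult(precision=precision, recall=recall, precision_defined=True)


def tnbc_annotations(sample_ids: Sequence[str]) -> list[SampleAnnotation]:
    """Annotations marking every simulated sample triple-negative."""
    return [
        SampleAnnotation(
            sample_id=sid, er_status="negative", pr_status="negative", her2_status="negative"
        )
        for sid in sample_ids
    ]
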