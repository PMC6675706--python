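"""Pearson correlation with significance, expression filtering, and the
sign-constrained ceRNA triplet screen.

The screen encodes the competing-endogenous-RNA expectation: a lncRNA that
sponges a miRNA is anti-correlated with it, the miRNA is anti-correlated
with its mRNA targets, and sponge and target are positively correlated.
A (lncRNA, miRNA, mRNA) triplet survives iff all three edges carry the
expected sign at p < alpha and both RNAs have seed-match support for the
miRNA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEGeneRecord, DegenerateInputError, ExpressionMatrix
from .targets import SITE_TYPES, SeedMatch

logger = logging.getLogger(__name__)

_TINY_P = 5e-324  # smallest subnormal double; reported instead of p = 0


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one RNA pair over n samples."""

    id_a: str
    id_b: str
    r: float
    n: int
    t: float
    pvalue: float


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable thresholds of the triplet screen.

    alpha: per-edge two-sided significance level (no multiplicity
        correction by default, matching single-edge testing practice).
    expression_fraction: minimum fraction of samples with nonzero abundance
        for a gene to count as expressed.
    site_types: site classes accepted as target evidence.
    bh_correction: apply Benjamini-Hochberg within each edge family before
        thresholding (off by default).
    """

    alpha: float = 0.05
    expression_fraction: float = 0.5
    site_types: tuple[str, ...] = SITE_TYPES
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 <= self.expression_fraction <= 1.0):
            raise ValueError(
                f"expression_fraction must be in [0, 1], got {self.expression_fraction}"
            )
        unknown = [t for t in self.site_types if t not in SITE_TYPES]
        if unknown:
            raise ValueError(f"unknown site types: {unknown}")


@dataclass(frozen=True)
class CeRNATriplet:
    """A surviving (lncRNA, miRNA, mRNA) candidate with its edge evidence."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    edge_lnc_mir: CorrelationResult
    edge_mir_mrna: CorrelationResult
    edge_lnc_mrna: CorrelationResult
    lnc_target_support: bool = True
    mrna_target_support: bool = True


def pearson(x: Sequence[float], y: Sequence[float], id_a: str = "x", id_b: str = "y") -> CorrelationResult:
    """Pearson correlation with the t-based two-sided p-value.

    r is the usual product-moment coefficient; the test statistic is
    t = r * sqrt((n-2) / (1-r^2)) referred to a t distribution with n-2
    degrees of freedom. Perfect correlation reports the smallest positive
    double as p rather than zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need at least 3 paired samples, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        which = id_a if ssx == 0.0 else id_b
        raise DegenerateInputError(f"zero variance in {which!r}: correlation undefined")
    r = float(dx @ dy) / math.sqrt(ssx * ssy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
        p = _TINY_P
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = min(max(p, _TINY_P), 1.0)
    return CorrelationResult(id_a=id_a, id_b=id_b, r=r, n=n, t=t, pvalue=p)


def _common_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> list[str]:
    common = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not common:
        raise DegenerateInputError("matrices share no sample identifiers")
    return common


def _log_if_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    """Correlations run on log2(x+1) values when the matrix is linear-scale."""
    if m.scale == "log":
        return m
    return ExpressionMatrix(np.log2(m.data + 1.0), scale="log")


def correlate_pairs(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    transform: bool = True,
) -> tuple[list[CorrelationResult], list[tuple[str, str]]]:
    """Correlate (id_a, id_b) pairs over the common samples of two matrices.

    Returns (results, skipped): degenerate pairs (zero variance over the
    overlap) land in the skipped list instead of being silently dropped.
    """
    common = _common_samples(a, b)
    if len(common) < 3:
        raise DegenerateInputError(f"only {len(common)} common samples; need >= 3")
    a_sub = a.subset_samples(common)
    b_sub = b.subset_samples(common)
    if transform:
        a_sub = _log_if_linear(a_sub)
        b_sub = _log_if_linear(b_sub)
    results: list[CorrelationResult] = []
    skipped: list[tuple[str, str]] = []
    for id_a, id_b in pairs:
        try:
            results.append(pearson(a_sub.vector(id_a), b_sub.vector(id_b), id_a, id_b))
        except DegenerateInputError:
            skipped.append((id_a, id_b))
    if skipped:
        logger.warning("correlate_pairs: skipped %d degenerate pair(s)", len(skipped))
    return results, skipped


def filter_expressed(m: ExpressionMatrix, expression_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep genes with nonzero abundance in >= expression_fraction of samples."""
    if not (0.0 <= expression_fraction <= 1.0):
        raise ValueError("expression_fraction must be in [0, 1]")
    nonzero = (m.data != 0).sum(axis=1) / m.data.shape[1]
    keep = nonzero >= expression_fraction
    return ExpressionMatrix(m.data.loc[keep], scale=m.scale)


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = pvalues.size
    order = np.argsort(pvalues)
    ranked = pvalues[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _passing(results: list[CorrelationResult], sign: int, config: ScreenConfig) -> list[CorrelationResult]:
    """Edges with the required correlation sign and p below alpha."""
    if not results:
        return []
    pvals = np.array([r.pvalue for r in results])
    if config.bh_correction:
        pvals = _bh_adjust(pvals)
    return [
        res
        for res, p in zip(results, pvals)
        if p < config.alpha and (res.r < 0 if sign < 0 else res.r > 0)
    ]


def screen_triplets(
    lnc: ExpressionMatrix,
    mir: ExpressionMatrix,
    mrna: ExpressionMatrix,
    lnc_targets: Sequence[SeedMatch],
    mrna_targets: Sequence[SeedMatch],
    candidate_mrnas: Iterable[str] | None = None,
    config: ScreenConfig = ScreenConfig(),
) -> list[CeRNATriplet]:
    """Run the full sign-constrained ceRNA screen.

    Pipeline: (1) drop unexpressed genes from all three matrices; (2) for
    each lncRNA, candidate miRNAs are those with >= 1 seed match on it
    (``lnc_targets``); (3) keep miRNAs anti-correlated with the lncRNA at
    p < alpha; (4) candidate mRNAs are that miRNA's seed-match targets
    (``mrna_targets``), optionally intersected with a candidate panel;
    (5) keep anti-correlated miRNA-mRNA edges; (6) keep triplets whose
    lncRNA-mRNA correlation is positive at p < alpha. Output is sorted by
    |r(lncRNA, mRNA)| descending, ties broken lexicographically.
    """
    allowed_types = set(config.site_types)
    lnc_targets = [m for m in lnc_targets if m.site_type in allowed_types]
    mrna_targets = [m for m in mrna_targets if m.site_type in allowed_types]

    lnc_f = filter_expressed(lnc, config.expression_fraction)
    mir_f = filter_expressed(mir, config.expression_fraction)
    mrna_f = filter_expressed(mrna, config.expression_fraction)

    mir_ids = set(mir_f.gene_ids)
    mrna_ids = set(mrna_f.gene_ids)
    panel = set(candidate_mrnas) if candidate_mrnas is not None else None

    # target maps restricted to expressed genes
    mirs_on_lnc: dict[str, set[str]] = {}
    for match in lnc_targets:
        if match.transcript_id in lnc_f.data.index and match.mirna_id in mir_ids:
            mirs_on_lnc.setdefault(match.transcript_id, set()).add(match.mirna_id)
    mrnas_of_mir: dict[str, set[str]] = {}
    for match in mrna_targets:
        if match.mirna_id in mir_ids and match.transcript_id in mrna_ids:
            if panel is not None and match.transcript_id not in panel:
                continue
            mrnas_of_mir.setdefault(match.mirna_id, set()).add(match.transcript_id)

    triplets: list[CeRNATriplet] = []
    for lnc_id in lnc_f.gene_ids:
        candidate_mirs = sorted(mirs_on_lnc.get(lnc_id, ()))
        if not candidate_mirs:
            continue
        lnc_mir_edges, _ = correlate_pairs(lnc_f, mir_f, [(lnc_id, m) for m in candidate_mirs])
        for edge_lm in _passing(lnc_mir_edges, sign=-1, config=config):
            mir_id = edge_lm.id_b
            targets = sorted(mrnas_of_mir.get(mir_id, ()))
            if not targets:
                continue
            mir_mrna_edges, _ = correlate_pairs(mir_f, mrna_f, [(mir_id, t) for t in targets])
            for edge_mt in _passing(mir_mrna_edges, sign=-1, config=config):
                mrna_id = edge_mt.id_b
                lnc_mrna_edges, _ = correlate_pairs(lnc_f, mrna_f, [(lnc_id, mrna_id)])
                kept = _passing(lnc_mrna_edges, sign=+1, config=config)
                if kept:
                    triplets.append(
                        CeRNATriplet(
                            lncrna_id=lnc_id,
                            mirna_id=mir_id,
                            mrna_id=mrna_id,
                            edge_lnc_mir=edge_lm,
                            edge_mir_mrna=edge_mt,
                            edge_lnc_mrna=kept[0],
                        )
                    )
    triplets.sort(
        key=lambda t: (-abs(t.edge_lnc_mrna.r), t.lncrna_id, t.mirna_id, t.mrna_id)
    )
    return triplets


def edges_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.id_a, e.id_b, e.r, e.n, e.t, e.pvalue) for e in results],
        columns=["id_a", "id_b", "r", "n", "t", "pvalue"],
    )


def triplets_to_frame(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    """Flatten surviving triplets (all edge statistics) into a DataFrame."""
    rows = []
    for t in triplets:
        row: dict[str, object] = {
            "lncrna_id": t.lncrna_id,
            "mirna_id": t.mirna_id,
            "mrna_id": t.mrna_id,
        }
        for label, edge in (
            ("lnc_mir", t.edge_lnc_mir),
            ("mir_mrna", t.edge_mir_mrna),
            ("lnc_mrna", t.edge_lnc_mrna),
        ):
            row[f"r_{label}"] = edge.r
            row[f"n_{label}"] = edge.n
            row[f"t_{label}"] = edge.t
            row[f"p_{label}"] = edge.pvalue
        row["lnc_target_support"] = t.lnc_target_support
        row["mrna_target_support"] = t.mrna_target_support
        rows.append(row)
    columns = (
        ["lncrna_id", "mirna_id", "mrna_id"]
        + [f"{s}_{label}" for label in ("lnc_mir", "mir_mrna", "lnc_mrna") for s in "rntp"]
        + ["lnc_target_support", "mrna_target_support"]
    )
    return pd.DataFrame(rows, columns=columns)


def de_filter(
    records: Sequence[DEGeneRecord],
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Split a DE table into up/down gene lists by strict thresholds.

    up: p < p_threshold and log2FC > lfc_threshold;
    down: p < p_threshold and log2FC < -lfc_threshold.
    Both inequalities are strict, so |log2FC| exactly at the threshold is
    excluded.
    """
    up = [r.gene_id for r in records if r.pvalue < p_threshold and r.log2fc > lfc_threshold]
    down = [r.gene_id for r in records if r.pvalue < p_threshold and r.log2fc < -lfc_threshold]
    return up, down
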