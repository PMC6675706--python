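"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the Pearson oracle
is a plain-Python textbook covariance formula, and the site-scan oracle
enumerates every window of the transcript and compares it against patterns
built with Biopython's complement table.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

_SITE_LEN = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}
_RANK = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}


def brute_force_pearson(x, y) -> tuple[float, float]:
    """(r, t) from the textbook sum-of-products formula, pure Python."""
    n = len(x)
    mean_x = sum(x) / n
    mean_y = sum(y) / n
    sxy = sum((xi - mean_x) * (yi - mean_y) for xi, yi in zip(x, y))
    sxx = sum((xi - mean_x) ** 2 for xi in x)
    syy = sum((yi - mean_y) ** 2 for yi in y)
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1.0:
        return r, math.inf if r > 0 else -math.inf
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, t


def oracle_patterns(mirna_sequence: str) -> dict[str, str]:
    """Site patterns via Biopython's RNA complement (independent table)."""
    rc6 = str(Seq(mirna_sequence[1:7]).reverse_complement_rna())
    rc7 = str(Seq(mirna_sequence[1:8]).reverse_complement_rna())
    return {"6mer": rc6, "7mer-A1": rc6 + "A", "7mer-m8": rc7, "8mer": rc7 + "A"}


def window_scan_oracle(mirna_sequence: str, transcript: str, site_types) -> list[tuple[int, int, str]]:
    """All-window scan collapsed to the best class per seed-core locus.

    Returns 1-based inclusive (start, end, site_type) tuples sorted by
    start. Every window of the transcript is compared against every
    requested pattern by plain substring equality; windows sharing a seed
    core keep only the highest-ranked class.
    """
    patterns = oracle_patterns(mirna_sequence)
    candidates: dict[int, tuple[int, int, str]] = {}  # core start -> site
    for site_type in sorted(site_types, key=_RANK.__getitem__, reverse=True):
        pattern = patterns[site_type]
        width = _SITE_LEN[site_type]
        for i in range(len(transcript) - width + 1):
            if transcript[i : i + width] != pattern:
                continue
            # 0-based start of the 6-nt seed core within this window
            core = i + 1 if site_type in ("8mer", "7mer-m8") else i
            candidates[core] = (i + 1, i + width, site_type)  # higher ranks overwrite
    return sorted(candidates.values())


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
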