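"""Pairwise relatedness screening: KING-robust kinship, R0, R1.

All counts are taken over pairwise-complete sites (both calls present).
phi = (N_hethet - 2*N_IBS0) / (N_het_i + N_het_j)
R0  = N_IBS0 / N_hethet
R1  = N_hethet / (N_het_i + N_het_j - N_hethet)   (het-union denominator)
Degenerate denominators yield NaN (undefined-marker).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable


class PairCounts(NamedTuple):
    n_sites: int
    n_ibs0: int
    n_hethet: int
    n_het_i: int
    n_het_j: int


@dataclass
class KinshipResult:
    sample_i: str
    sample_j: str
    counts: PairCounts
    phi: float
    r0: float
    r1: float
    flagged: bool = False
    advisory: bool = False


def pair_counts(vt: VariantTable, i, j) -> PairCounts:
    """Opposite-homozygote / het-sharing counts for one sample pair.

    ``i``/``j`` may be sample names or column indices. Raises on zero
    pairwise-complete sites.
    """
    ci = vt.sample_index(i) if isinstance(i, str) else int(i)
    cj = vt.sample_index(j) if isinstance(j, str) else int(j)
    a = vt.dosage[:, ci]
    b = vt.dosage[:, cj]
    m = (a != MISSING) & (b != MISSING)
    if not m.any():
        raise ValueError("no pairwise-complete sites for this pair")
    a, b = a[m], b[m]
    ibs0 = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    hethet = int(((a == 1) & (b == 1)).sum())
    return PairCounts(int(m.sum()), ibs0, hethet, int((a == 1).sum()), int((b == 1).sum()))


def king_phi(c: PairCounts) -> float:
    den = c.n_het_i + c.n_het_j
    return (c.n_hethet - 2 * c.n_ibs0) / den if den > 0 else float("nan")


def r0(c: PairCounts) -> float:
    return c.n_ibs0 / c.n_hethet if c.n_hethet > 0 else float("nan")


def r1(c: PairCounts) -> float:
    den = c.n_het_i + c.n_het_j - c.n_hethet
    return c.n_hethet / den if den > 0 else float("nan")


def kinship_pair(vt: VariantTable, i: str, j: str) -> KinshipResult:
    c = pair_counts(vt, i, j)
    return KinshipResult(i, j, c, king_phi(c), r0(c), r1(c))


def kinship_table(
    vt: VariantTable, samples: Sequence[str] | None = None
) -> list[KinshipResult]:
    """All unordered pairs among ``samples`` (default: ingroup samples)."""
    names = list(samples) if samples is not None else vt.ingroup_samples()
    out = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            out.append(kinship_pair(vt, names[a], names[b]))
    return out


def flag_related(
    results: Sequence[KinshipResult],
    phi_min: float = 0.20,
    r0_max: float = 0.1,
    r1_min: float = 0.5,
) -> list[KinshipResult]:
    """Set ``flagged`` when all three thresholds hold, ``advisory`` when exactly two."""
    for res in results:
        conds = [
            (not np.isnan(res.phi)) and res.phi >= phi_min,
            (not np.isnan(res.r0)) and res.r0 <= r0_max,
            (not np.isnan(res.r1)) and res.r1 >= r1_min,
        ]
        n = sum(conds)
        res.flagged = n == 3
        res.advisory = n == 2
    return [r for r in results if r.flagged]


def results_to_frame(results: Sequence[KinshipResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        flag = "related" if r.flagged else ("advisory" if r.advisory else "")
        rows.append(
            {
                "sample_i": r.sample_i,
                "sample_j": r.sample_j,
                "nSites": r.counts.n_sites,
                "n_ibs0": r.counts.n_ibs0,
                "n_hethet": r.counts.n_hethet,
                "phi": r.phi,
                "R0": r.r0,
                "R1": r.r1,
                "flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_i", "sample_j", "nSites", "n_ibs0", "n_hethet",
            "phi", "R0", "R1", "flag",
        ],
    )


def exclusion_set(vt: VariantTable, results: Sequence[KinshipResult]) -> list[str]:
    """One member per fully-flagged pair: the one with more missing calls
    (tie: lexicographically larger id). Deterministic; advisory pairs untouched."""
    drop: set[str] = set()
    for r in results:
        if not r.flagged:
            continue
        if r.sample_i in drop or r.sample_j in drop:
            continue
        miss_i = int((vt.dosage[:, vt.sample_index(r.sample_i)] == MISSING).sum())
        miss_j = int((vt.dosage[:, vt.sample_index(r.sample_j)] == MISSING).sum())
        if miss_i > miss_j:
            drop.add(r.sample_i)
        elif miss_j > miss_i:
            drop.add(r.sample_j)
        else:
            drop.add(max(r.sample_i, r.sample_j))
    return sorted(drop)
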