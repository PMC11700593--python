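"""Individual heterozygosity, folded SFS, and windowed nucleotide diversity."""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable


def individual_heterozygosity(
    vt: VariantTable, sample: str, callable_total: int | None = None
) -> float:
    """Ho = heterozygous calls / callable calls.

    With ``callable_total`` given, the denominator is that number
    (normalising a variant-only table by genome-wide callable sites);
    otherwise it is the sample's non-missing call count across the table.
    """
    col = vt.dosage[:, vt.sample_index(sample)]
    n_het = int((col == 1).sum())
    denom = callable_total if callable_total is not None else int((col != MISSING).sum())
    if not denom or denom <= 0:
        raise ValueError("zero callable denominator")
    return n_het / denom


def folded_sfs(vt: VariantTable, samples: Sequence[str] | None = None) -> np.ndarray:
    """Minor-allele-count spectrum; bins 0..n_alleles//2; sums to n_sites."""
    cols = vt.sample_cols(samples)
    if len(cols) == 0:
        raise ValueError("population has no samples")
    alt, tot = vt.allele_counts(
        [vt.samples[c] for c in cols] if samples is not None else None
    )
    minor = np.minimum(alt, tot - alt)
    n_bins = (2 * len(cols)) // 2 + 1
    sfs = np.zeros(n_bins, dtype=np.int64)
    for m in minor:
        sfs[int(m)] += 1
    return sfs


def site_pi(alt_count: int, n_alleles: int) -> float:
    """Per-site pairwise diversity 2c(n-c)/(n(n-1))."""
    if n_alleles < 2:
        raise ValueError("need at least two alleles")
    c = alt_count
    return 2.0 * c * (n_alleles - c) / (n_alleles * (n_alleles - 1))


def windowed_pi(
    vt: VariantTable,
    samples: Sequence[str] | None = None,
    window_bp: int = 100_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity in non-overlapping windows tiling each chromosome.

    Window pi is the sum of per-site pi over variant sites in
    [start, start + window) divided by the full window length (the
    numerator uses variant sites only; the denominator is ``window_bp``).
    Sites with fewer than two non-missing alleles are skipped and counted
    in ``df.attrs['n_skipped_sites']``. Output starts are 0-based
    (BED-like half-open).
    """
    alt, tot = vt.allele_counts(samples)
    rows = []
    skipped = 0
    for c in vt.chromosomes():
        block = np.flatnonzero(vt.chrom == c)
        max_pos = int(vt.pos[block].max())
        length = (
            int(chrom_lengths[c]) if chrom_lengths and c in chrom_lengths else max_pos
        )
        n_win = max(1, -(-length // window_bp))
        sums = np.zeros(n_win)
        counts = np.zeros(n_win, dtype=np.int64)
        for i in block:
            if tot[i] < 2:
                skipped += 1
                continue
            w = (int(vt.pos[i]) - 1) // window_bp
            if w >= n_win:  # variant beyond the declared chromosome length
                continue
            sums[w] += site_pi(int(alt[i]), int(tot[i]))
            counts[w] += 1
        for w in range(n_win):
            rows.append(
                {
                    "chrom": c,
                    "start0": w * window_bp,
                    "end": min((w + 1) * window_bp, length) if chrom_lengths else (w + 1) * window_bp,
                    "n_variants": int(counts[w]),
                    "pi": sums[w] / window_bp,
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start0", "end", "n_variants", "pi"])
    df.attrs["n_skipped_sites"] = skipped
    return df


def ho_frame(
    vt: VariantTable,
    samples: Sequence[str] | None = None,
    callable_total: int | None = None,
) -> pd.DataFrame:
    names = list(samples) if samples is not None else vt.ingroup_samples()
    return pd.DataFrame(
        {
            "sample": names,
            "Ho": [individual_heterozygosity(vt, s, callable_total) for s in names],
        }
    )
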