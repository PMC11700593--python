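"""Effective population size from linkage disequilibrium.

Closed-form drift-LD estimators: for unlinked loci
E[r2] = 1/(3*Ne) + 1/n, inverted as Ne = 1/(3*(mean_r2 - 1/n)); for loci
at recombination fraction c, E[r2] = 1/(1 + 4*Ne*c) + 1/n with the LD at
distance c reflecting Ne roughly t = 1/(2c) generations ago. The 1/n
sample-size correction (n diploid individuals) is a documented
calibration choice.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .roh import RecombinationModel
from .variants import VariantTable, pair_r2_matrix


@dataclass
class NeEstimate:
    method: str
    ne: float  # NaN when undefined
    n_pairs: int
    mean_r2: float
    n_individuals: int
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": self.method, "Ne": self.ne, "n_pairs": self.n_pairs,
                    "mean_r2": self.mean_r2, "n_individuals": self.n_individuals,
                    "note": self.note,
                }
            ]
        )


def _dosage_for(vt: VariantTable, samples: Sequence[str] | None):
    if samples is None:
        samples = vt.ingroup_samples()
    cols = vt.sample_cols(samples)
    return vt.dosage[:, cols], len(cols)


def _permute_within_chromosomes(D: np.ndarray, chrom_codes: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Shuffle sample columns independently per chromosome.

    Destroys cross-chromosome (and within-chromosome) LD while preserving
    every site's genotype composition — the permuted data's mean r² is an
    empirical estimate of the pure sampling floor.
    """
    out = D.copy()
    for c in np.unique(chrom_codes):
        rows = np.flatnonzero(chrom_codes == c)
        out[rows] = out[np.ix_(rows, rng.permutation(D.shape[1]))]
    return out


def _cross_chrom_pairs(n: int, chrom_codes: np.ndarray, n_pairs: int,
                       rng: np.random.Generator):
    ii_all, jj_all = [], []
    got = 0
    while got < n_pairs:
        draw = max(int((n_pairs - got) * 1.5), 1000)
        i = rng.integers(0, n, size=draw)
        j = rng.integers(0, n, size=draw)
        ok = chrom_codes[i] != chrom_codes[j]
        ii_all.append(i[ok])
        jj_all.append(j[ok])
        got += int(ok.sum())
    return np.concatenate(ii_all)[:n_pairs], np.concatenate(jj_all)[:n_pairs]


def interchrom_r2(
    vt: VariantTable,
    n_pairs: int = 20_000,
    seed: int = 0,
    samples: Sequence[str] | None = None,
) -> tuple[float, int]:
    """Mean r² over a seeded random sample of cross-chromosome site pairs."""
    D, _ = _dosage_for(vt, samples)
    chrom_codes = pd.factorize(vt.chrom)[0]
    if len(np.unique(chrom_codes)) < 2:
        raise ValueError("need at least two chromosomes")
    rng = np.random.default_rng(seed)
    ii, jj = _cross_chrom_pairs(vt.n_sites, chrom_codes, n_pairs, rng)
    vals = pair_r2_matrix(D, ii, jj)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no defined cross-chromosome pairs")
    return float(vals.mean()), int(len(vals))


def interchrom_floor(
    vt: VariantTable,
    n_pairs: int = 20_000,
    seed: int = 0,
    samples: Sequence[str] | None = None,
    n_reps: int = 2,
) -> float:
    """Empirical sampling floor: mean cross-chromosome r² after permuting
    sample columns independently per chromosome (``n_reps`` permutations)."""
    D, _ = _dosage_for(vt, samples)
    chrom_codes = pd.factorize(vt.chrom)[0]
    if len(np.unique(chrom_codes)) < 2:
        raise ValueError("need at least two chromosomes")
    rng = np.random.default_rng(seed)
    means = []
    for _ in range(n_reps):
        P = _permute_within_chromosomes(D, chrom_codes, rng)
        ii, jj = _cross_chrom_pairs(vt.n_sites, chrom_codes, n_pairs, rng)
        vals = pair_r2_matrix(P, ii, jj)
        means.append(float(np.nanmean(vals)))
    return float(np.mean(means))


def ne_unlinked(
    mean_r2: float,
    n_individuals: int,
    n_pairs: int = 0,
    floor: float | None = None,
) -> NeEstimate:
    """Contemporary Ne from unlinked-locus drift LD.

    r2_drift = mean_r2 - floor; Ne = 1 / (3 * r2_drift). The default
    floor is the classical 1/n (n diploid individuals); pass an explicit
    floor — e.g. 1/(n-1), or an empirical permutation floor from
    :func:`interchrom_floor` — for small samples, where 1/n is measurably
    too small. NaN with a diagnostic note when the drift component is
    non-positive (sample too small or population too large to resolve).
    """
    if mean_r2 <= 0 or n_individuals < 2:
        raise ValueError("need mean_r2 > 0 and n >= 2")
    if floor is None:
        floor = 1.0 / n_individuals
    drift = mean_r2 - floor
    if drift <= 0:
        return NeEstimate(
            "unlinked_ld", float("nan"), n_pairs, mean_r2, n_individuals,
            note="r2 at or below the sampling floor",
        )
    return NeEstimate("unlinked_ld", 1.0 / (3.0 * drift), n_pairs, mean_r2,
                      n_individuals)


def estimate_ne_unlinked(
    vt: VariantTable,
    n_pairs: int = 20_000,
    seed: int = 0,
    samples: Sequence[str] | None = None,
    floor_method: str = "permutation",
) -> NeEstimate:
    """Convenience wrapper: cross-chromosome mean r² -> :func:`ne_unlinked`.

    ``floor_method``: "permutation" (empirical, default), "n-1", or "1/n".
    """
    _, n_ind = _dosage_for(vt, samples)
    mean_r2, used = interchrom_r2(vt, n_pairs, seed, samples)
    if floor_method == "permutation":
        floor = interchrom_floor(vt, n_pairs, seed + 1, samples)
    elif floor_method == "n-1":
        floor = 1.0 / (n_ind - 1)
    elif floor_method == "1/n":
        floor = 1.0 / n_ind
    else:
        raise ValueError(f"unknown floor_method {floor_method!r}")
    return ne_unlinked(mean_r2, n_ind, used, floor=floor)


def default_c_bins(n_bins: int = 20, c_min: float = 0.0005,
                   c_max: float = 0.05) -> np.ndarray:
    """Log-spaced recombination-fraction bin edges (t ~ 10..1000 generations)."""
    return np.geomspace(c_min, c_max, n_bins + 1)


def ne_trajectory(
    vt: VariantTable,
    rec: RecombinationModel,
    n_individuals: int | None = None,
    c_bins: np.ndarray | None = None,
    n_pairs: int = 200_000,
    seed: int = 0,
    samples: Sequence[str] | None = None,
    min_pairs_per_bin: int = 50,
) -> pd.DataFrame:
    """Recent-history Ne from distance-binned within-chromosome LD.

    Samples within-chromosome site pairs, converts physical separation to
    recombination fraction c via the constant-rate model, and inverts the
    Sved relation per bin: Ne(c) = (1/r2_drift - 1)/(4c) at
    t(c) = 1/(2c). Bins with too few pairs or a non-positive drift
    component are dropped (recorded in ``df.attrs['dropped_bins']``).
    """
    D, n_ind = _dosage_for(vt, samples)
    if n_individuals is None:
        n_individuals = n_ind
    if c_bins is None:
        c_bins = default_c_bins()
    rng = np.random.default_rng(seed)
    chrom_codes = pd.factorize(vt.chrom)[0]
    n = vt.n_sites
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    same = (chrom_codes[i] == chrom_codes[j]) & (i != j)
    i, j = i[same], j[same]
    dist_bp = np.abs(vt.pos[i] - vt.pos[j])
    c = np.minimum(dist_bp / 1e6 * rec.rate / 100.0, 0.5)
    which = np.digitize(c, c_bins) - 1
    ok = (which >= 0) & (which < len(c_bins) - 1)
    i, j, which = i[ok], j[ok], which[ok]
    r2v = pair_r2_matrix(D, i, j)
    keep = ~np.isnan(r2v)
    r2v, which = r2v[keep], which[keep]

    rows, dropped = [], []
    for b in range(len(c_bins) - 1):
        sel = which == b
        c_mid = float(np.sqrt(c_bins[b] * c_bins[b + 1]))  # geometric midpoint
        npair = int(sel.sum())
        if npair < min_pairs_per_bin:
            dropped.append((b, "too few pairs"))
            continue
        mean_r2 = float(r2v[sel].mean())
        drift = mean_r2 - 1.0 / n_individuals
        if drift <= 0:
            dropped.append((b, "r2 at or below sampling floor"))
            continue
        ne = (1.0 / drift - 1.0) / (4.0 * c_mid)
        rows.append(
            {
                "c_low": float(c_bins[b]), "c_high": float(c_bins[b + 1]),
                "c_mid": c_mid, "t": 1.0 / (2.0 * c_mid), "Ne": ne,
                "n_pairs": npair, "mean_r2": mean_r2,
            }
        )
    df = pd.DataFrame(
        rows, columns=["c_low", "c_high", "c_mid", "t", "Ne", "n_pairs", "mean_r2"]
    )
    df.attrs["dropped_bins"] = dropped
    return df
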