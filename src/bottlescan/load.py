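"""Genetic-load accounting: outgroup polarization, derived-allele
orientation, impact classification, and masked/realized/total counts.

Masked load = heterozygous derived genotypes (fitness cost deferred);
realized load = homozygous derived genotypes (current cost); total =
masked + realized, per individual and impact category.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

CATEGORIES = ("LOW", "MOD-TOL", "MOD-DEL", "HIGH")


@dataclass
class Polarization:
    ancestral: str | None
    derived: str | None
    tag: str  # agreeing_outgroups | single_outgroup | tie_random | unresolved


def polarize(ref: str, alt: str, outgroup_alleles: Sequence[str | None],
             rng: np.random.Generator) -> Polarization:
    """Assign ancestral/derived states from up to two outgroup base calls.

    Both outgroups agreeing on an allele in {ref, alt} wins; a single
    usable outgroup decides alone; one-ref-one-alt is broken by a seeded
    coin flip (tag ``tie_random``); anything else is ``unresolved``.
    """
    usable = [a for a in outgroup_alleles if a in (ref, alt)]
    n_given = sum(a is not None for a in outgroup_alleles)
    if n_given == 0 or not usable:
        return Polarization(None, None, "unresolved")
    if len(usable) == 2:
        if usable[0] == usable[1]:
            anc = usable[0]
            tag = "agreeing_outgroups"
        else:
            anc = usable[int(rng.integers(2))]
            tag = "tie_random"
    else:
        anc = usable[0]
        tag = "single_outgroup"
    der = alt if anc == ref else ref
    return Polarization(anc, der, tag)


def polarize_sites(vt: VariantTable, outgroup_alleles: np.ndarray,
                   seed: int = 0) -> pd.DataFrame:
    """Polarize every site; ``outgroup_alleles`` is (n_sites, 2) base calls."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(vt.n_sites):
        p = polarize(vt.ref[i], vt.alt[i], list(outgroup_alleles[i]), rng)
        rows.append(
            {"chrom": vt.chrom[i], "pos": vt.pos[i], "ref": vt.ref[i],
             "alt": vt.alt[i], "ancestral": p.ancestral, "derived": p.derived,
             "tag": p.tag}
        )
    return pd.DataFrame(rows)


def orient_derived(polarized: pd.DataFrame) -> tuple[np.ndarray, dict[str, int]]:
    """Retain sites whose derived state is the ALT allele.

    Returns (boolean retention mask, report counts). After this mask the
    ALT dosage counts derived-allele copies directly.
    """
    derived_is_alt = (polarized["derived"] == polarized["alt"]).to_numpy()
    unresolved = (polarized["tag"] == "unresolved").to_numpy()
    retained = derived_is_alt & ~unresolved
    report = {
        "retained": int(retained.sum()),
        "derived_is_ref": int((~derived_is_alt & ~unresolved).sum()),
        "unresolved": int(unresolved.sum()),
    }
    return retained, report


def classify(impact: str | None, sift_score: float | None = None) -> str | None:
    """Map impact (+ SIFT for MODERATE) to a load category, or None (excluded)."""
    if impact == "LOW":
        return "LOW"
    if impact == "HIGH":
        return "HIGH"
    if impact == "MODERATE":
        if sift_score is None or (isinstance(sift_score, float) and math.isnan(sift_score)):
            return None  # MODERATE without a SIFT score is excluded
        return "MOD-TOL" if sift_score >= 0.05 else "MOD-DEL"
    return None


def classify_sites(annotations: pd.DataFrame) -> np.ndarray:
    """Vector of categories (object array, None = excluded) per site."""
    out = np.full(len(annotations), None, dtype=object)
    for i, (imp, sift) in enumerate(
        zip(annotations["impact"], annotations["sift_score"])
    ):
        imp = None if (isinstance(imp, float) and math.isnan(imp)) else imp
        out[i] = classify(imp, sift)
    return out


def load_counts(
    vt: VariantTable,
    retained: np.ndarray,
    categories: np.ndarray,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Masked/realized/total genotype counts per individual and category.

    ``retained`` is the orientation mask; ``categories`` the per-site
    category vector (None excluded). Missing calls are excluded from both
    numerator and denominator; a category with zero callable sites gets a
    NaN derived-allele frequency.
    """
    names = list(samples) if samples is not None else vt.ingroup_samples()
    retained = np.asarray(retained, dtype=bool)
    rows = []
    for s in names:
        col = vt.dosage[:, vt.sample_index(s)]
        for cat in CATEGORIES:
            sel = retained & (categories == cat)
            d = col[sel]
            call = d != MISSING
            masked = int((d == 1).sum())
            realized = int((d == 2).sum())
            callable_n = int(call.sum())
            freq = (
                (masked + 2 * realized) / (2 * callable_n)
                if callable_n > 0
                else float("nan")
            )
            rows.append(
                {
                    "sample": s, "category": cat, "masked": masked,
                    "realized": realized, "total": masked + realized,
                    "derived_freq": freq, "callable": callable_n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "category", "masked", "realized", "total",
                 "derived_freq", "callable"],
    )


# ------------------------------------------------------------ exact rank test
_MAX_ENUM = 20_000_000


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Exact two-tailed Mann-Whitney p by full enumeration.

    Midranks handle ties; the null distribution is generated by
    enumerating every assignment of the pooled observations to the two
    groups. p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))). Group
    sizes must lie in [2, 20] and the combination count below the
    enumeration cap; larger problems raise (use a normal approximation,
    which is out of scope here).
    """
    a = list(map(float, values_a))
    b = list(map(float, values_b))
    n, m = len(a), len(b)
    if not (2 <= n <= 20 and 2 <= m <= 20):
        raise ValueError("group sizes must be in [2, 20]")
    if math.comb(n + m, n) > _MAX_ENUM:
        raise ValueError(
            "too many rank assignments to enumerate; use a normal approximation"
        )
    pooled = np.array(a + b)
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_v = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # midrank
        i = j + 1

    offset = n * (n + 1) / 2.0
    u_obs = ranks[:n].sum() - offset
    tol = 1e-9
    le = ge = total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = sum(ranks[k] for k in combo) - offset
        total += 1
        if u <= u_obs + tol:
            le += 1
        if u >= u_obs - tol:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(1.0, p)
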