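"""Synthetic diploid genotype datasets with bottleneck structure.

Founder populations (the oldest, equilibrium epoch) are drawn per
chromosome from a neutral coalescent (msprime, binary mutation model, so
the ancestral state of every site is known). More recent epochs — the
bottleneck, recovery, viability selection on deleterious classes, and
appended pedigree pairs — are simulated with a forward-in-time diploid
Wright-Fisher model with Poisson crossovers. Forward mutation is off:
forward windows are at most tens of generations at desk scale, so the
new-mutation contribution to diversity is negligible.

Everything is deterministic given ``SimConfig.seed``.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

CLASSES = ("NEUTRAL", "LOW", "MODERATE", "HIGH")
_BASES = np.array(list("ACGT"), dtype=object)


@dataclass
class SelectionParams:
    """Gamma-distributed selection coefficients with dominance ``h``."""

    s_mean: float = 0.03
    s_shape: float = 0.3
    h: float = 0.2


def _default_class_probs() -> dict[str, float]:
    return {"NEUTRAL": 0.90, "LOW": 0.05, "MODERATE": 0.04, "HIGH": 0.01}


def _default_selection() -> dict[str, SelectionParams]:
    return {
        "MODERATE": SelectionParams(s_mean=0.03, s_shape=0.3, h=0.2),
        "HIGH": SelectionParams(s_mean=0.2, s_shape=0.3, h=0.2),
    }


@dataclass
class SimConfig:
    """Configuration of a synthetic dataset.

    ``ne_trajectory`` lists (span_generations, diploid_N) epochs most
    recent first; the last epoch (span may be None) is the equilibrium
    founder epoch simulated by the coalescent, all earlier epochs run
    forward in time. ``bottleneck=(start_gen, end_gen, N)`` is a
    convenience overlay on a single-epoch trajectory.
    """

    n_chromosomes: int = 4
    chrom_length: int = 20_000_000
    mu: float = 1e-8
    rec_rate: float = 1.3459  # cM/Mb
    ne_trajectory: tuple = ((None, 500),)
    bottleneck: tuple | None = None  # (start_gen, end_gen, N)
    sample_size: int = 12
    class_probs: dict[str, float] = field(default_factory=_default_class_probs)
    sift_del_frac: float = 0.5  # MODERATE mass below 0.05
    selection: dict[str, SelectionParams] = field(default_factory=_default_selection)
    outgroup_divergence: int = 20_000  # generations
    n_pedigree_pairs: int = 0
    ref_flip_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.mu < 0 or self.rec_rate <= 0 or self.outgroup_divergence < 0:
            raise ValueError("rates must be non-negative (rec_rate positive)")
        probs = [self.class_probs.get(c, 0.0) for c in CLASSES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must be a distribution over " + str(CLASSES))
        for span, n in self.resolve_epochs():
            if n <= 0:
                raise ValueError("non-positive population size in an epoch")
            if span is not None and span < 0:
                raise ValueError("negative epoch span")

    def resolve_epochs(self) -> list[tuple[int | None, int]]:
        """Most-recent-first epoch list with any bottleneck overlay applied."""
        epochs = [(span, int(n)) for span, n in self.ne_trajectory]
        if self.bottleneck is None:
            return epochs
        if len(epochs) != 1:
            raise ValueError("bottleneck overlay requires a single-epoch ne_trajectory")
        start, end, nb = self.bottleneck
        if not 0 <= start < end:
            raise ValueError("bottleneck must satisfy 0 <= start < end")
        n0 = epochs[0][1]
        out: list[tuple[int | None, int]] = []
        if start > 0:
            out.append((int(start), n0))
        out.append((int(end - start), int(nb)))
        out.append((None, n0))
        return out

    @property
    def rec_per_bp(self) -> float:
        """Recombination probability per bp per generation."""
        return self.rec_rate / 100.0 / 1e6

    @property
    def chrom_morgans(self) -> float:
        return self.chrom_length * self.rec_per_bp


@dataclass
class SimTruth:
    """Ground-truth channel for parameter-recovery tests."""

    ancestral: np.ndarray  # per-site ancestral base
    derived: np.ndarray  # per-site derived base
    vclass: np.ndarray  # per-site class in CLASSES
    sift: np.ndarray  # true SIFT score, NaN unless MODERATE
    sel_s: np.ndarray  # per-site selection coefficient
    outgroup_alleles: np.ndarray  # (n_sites, 2) bases
    pedigree: list[tuple[str, str]]  # (parent, offspring)
    outgroup_samples: list[str]
    epochs: list
    seed: int

    def annotation_frame(self, vt: VariantTable) -> pd.DataFrame:
        """Sidecar annotation table (NEUTRAL written as snpEff-style MODIFIER)."""
        impact = np.where(self.vclass == "NEUTRAL", "MODIFIER", self.vclass)
        return pd.DataFrame(
            {
                "chrom": [str(c) for c in vt.chrom],
                "pos": vt.pos,
                "impact": impact,
                "sift_score": self.sift,
            }
        )

    def outgroup_frame(self, vt: VariantTable) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [str(c) for c in vt.chrom],
                "pos": vt.pos,
                "out1": self.outgroup_alleles[:, 0],
                "out2": self.outgroup_alleles[:, 1],
            }
        )

    def to_json(self, path, vt: VariantTable) -> None:
        obj = {
            "seed": self.seed,
            "epochs": [[s, n] for s, n in self.epochs],
            "pedigree": [list(p) for p in self.pedigree],
            "outgroup_samples": self.outgroup_samples,
            "sites": {
                "chrom": [str(c) for c in vt.chrom],
                "pos": vt.pos.tolist(),
                "ancestral": self.ancestral.tolist(),
                "derived": self.derived.tolist(),
                "class": self.vclass.tolist(),
                "sift": [None if np.isnan(s) else float(s) for s in self.sift],
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


# ------------------------------------------------------------------ fixtures
def make_fixture(
    spec: Mapping[str, tuple[Sequence[int], Mapping[str, str]]]
) -> VariantTable:
    """Build a deterministic table from explicit genotype strings.

    ``spec`` maps chromosome -> (positions, {sample: genotype_string})
    where genotype strings are over ``{0,1,2,.}`` ('.' = missing), one
    symbol per position.
    """
    sample_names: list[str] = []
    for _, (_, geno) in spec.items():
        for s in geno:
            if s not in sample_names:
                sample_names.append(s)
    chrom, pos, rows = [], [], []
    for c, (positions, geno) in spec.items():
        for s, gstr in geno.items():
            if len(gstr) != len(positions):
                raise ValueError(
                    f"sample {s!r} on {c!r}: {len(gstr)} symbols for {len(positions)} positions"
                )
        for k, p in enumerate(positions):
            chrom.append(c)
            pos.append(int(p))
            row = np.full(len(sample_names), MISSING, dtype=np.int8)
            for j, s in enumerate(sample_names):
                if s not in geno:
                    continue
                sym = geno[s][k]
                if sym == ".":
                    row[j] = MISSING
                elif sym in "012":
                    row[j] = np.int8(int(sym))
                else:
                    raise ValueError(f"bad genotype symbol {sym!r}")
            rows.append(row)
    n = len(pos)
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        dosage=np.array(rows, dtype=np.int8).reshape(n, len(sample_names)),
        samples=sample_names,
    )


# ------------------------------------------------------------- forward engine
def _gamete(h0, h1, pos, chrom_len, morgans, rng):
    k = rng.poisson(morgans)
    start = int(rng.integers(2))
    if k == 0:
        return (h1 if start else h0).copy()
    cross = np.sort(rng.uniform(0, chrom_len, size=k))
    phase = (start + np.searchsorted(cross, pos)) % 2
    return np.where(phase == 1, h1, h0).astype(np.int8)


def _fitness(haps, sel_idx, sel_s, sel_h):
    n = haps[0].shape[0] // 2
    logw = np.zeros(n)
    for hap, idx, s, h in zip(haps, sel_idx, sel_s, sel_h):
        if len(idx) == 0:
            continue
        g = hap[0::2][:, idx].astype(np.int16) + hap[1::2][:, idx]
        logw += (g == 1) @ np.log1p(-h * s) + (g == 2) @ np.log1p(-s)
    return logw


def _wf_generation(haps, positions, cfg, sel_idx, sel_s, sel_h, n_next, rng):
    n = haps[0].shape[0] // 2
    logw = _fitness(haps, sel_idx, sel_s, sel_h)
    w = np.exp(logw - logw.max())
    p = w / w.sum()
    parents = rng.choice(n, size=(n_next, 2), p=p)
    out = []
    for hap, pos in zip(haps, positions):
        new = np.empty((2 * n_next, hap.shape[1]), dtype=np.int8)
        for k in range(n_next):
            for slot in (0, 1):
                par = parents[k, slot]
                new[2 * k + slot] = _gamete(
                    hap[2 * par], hap[2 * par + 1], pos, cfg.chrom_length,
                    cfg.chrom_morgans, rng,
                )
        out.append(new)
    return out


def _founders(cfg: SimConfig, n_found: int, n_anc: int, rng):
    """msprime founders per chromosome -> (haplotype list, position list)."""
    import msprime

    haps, positions = [], []
    for _ in range(cfg.n_chromosomes):
        s1, s2 = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=n_found,
            population_size=n_anc,
            sequence_length=cfg.chrom_length,
            recombination_rate=cfg.rec_per_bp,
            discrete_genome=True,
            random_seed=int(s1),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=cfg.mu,
            model=msprime.BinaryMutationModel(),
            random_seed=int(s2),
        )
        g = mts.genotype_matrix().astype(np.int8)  # sites x haplotypes
        pos = mts.sites_position.astype(np.int64) + 1  # 1-based
        uniq, first = np.unique(pos, return_index=True)
        haps.append(np.ascontiguousarray(g[np.sort(first)].T))
        positions.append(pos[np.sort(first)])
    return haps, positions


def simulate_population(config: SimConfig) -> tuple[VariantTable, SimTruth]:
    """Simulate genotypes plus truth channel. See module docstring.

    Returns a :class:`VariantTable` containing ``sample_size`` ingroup
    individuals, one appended offspring per pedigree pair, and two
    outgroup columns (population label "OUT"), plus the matching
    :class:`SimTruth`. Monomorphic sites are excluded under joint-calling
    semantics: a site is kept iff the ingroup segregates or an outgroup
    call differs from the ingroup's fixed allele.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    epochs = config.resolve_epochs()
    forward = epochs[:-1]
    n_anc = epochs[-1][1]
    n_found = forward[-1][1] if forward else max(config.sample_size, 2)

    haps, positions = _founders(config, n_found, n_anc, rng)

    # per-site class / selection assignment (per chromosome)
    probs = np.array([config.class_probs.get(c, 0.0) for c in CLASSES])
    vclass_c, sift_c, s_c = [], [], []
    sel_idx, sel_s, sel_h = [], [], []
    for pos in positions:
        ns = len(pos)
        cls = np.array(CLASSES, dtype=object)[rng.choice(len(CLASSES), size=ns, p=probs)]
        sift = np.full(ns, np.nan)
        mod = cls == "MODERATE"
        deleterious = rng.random(ns) < config.sift_del_frac
        sift[mod & deleterious] = rng.uniform(0.0, 0.05, size=int((mod & deleterious).sum()))
        sift[mod & ~deleterious] = rng.uniform(0.05, 1.0, size=int((mod & ~deleterious).sum()))
        s = np.zeros(ns)
        h = np.zeros(ns)
        for name, sp in config.selection.items():
            m = cls == name
            if m.any() and sp.s_mean > 0:
                s[m] = np.clip(
                    rng.gamma(sp.s_shape, sp.s_mean / sp.s_shape, size=int(m.sum())),
                    0.0,
                    0.95,
                )
                h[m] = sp.h
        vclass_c.append(cls)
        sift_c.append(sift)
        s_c.append(s)
        idx = np.flatnonzero(s > 0)
        sel_idx.append(idx)
        sel_s.append(s[idx])
        sel_h.append(h[idx])

    # forward epochs, oldest first
    for span, n_epoch in reversed(forward):
        for _ in range(int(span)):
            haps = _wf_generation(
                haps, positions, config, sel_idx, sel_s, sel_h, n_epoch, rng
            )

    n_final = haps[0].shape[0] // 2
    if n_final < config.sample_size:
        raise ValueError(
            f"final population ({n_final}) smaller than sample_size ({config.sample_size})"
        )
    chosen = np.sort(rng.choice(n_final, size=config.sample_size, replace=False))
    sample_names = [f"S{i:03d}" for i in range(config.sample_size)]

    # pedigree offspring appended after the samples
    pedigree: list[tuple[str, str]] = []
    offspring_haps = [[] for _ in haps]
    for k in range(config.n_pedigree_pairs):
        pi = int(rng.integers(config.sample_size))  # parent among sampled
        parent_pop_idx = int(chosen[pi])
        if n_final < 2:
            raise ValueError("pedigree pairs need at least two individuals")
        mate = parent_pop_idx
        while mate == parent_pop_idx:  # no selfing
            mate = int(rng.integers(n_final))
        name = f"PED{k:02d}"
        pedigree.append((sample_names[pi], name))
        for c, (hap, pos) in enumerate(zip(haps, positions)):
            g1 = _gamete(
                hap[2 * parent_pop_idx], hap[2 * parent_pop_idx + 1], pos,
                config.chrom_length, config.chrom_morgans, rng,
            )
            g2 = _gamete(
                hap[2 * mate], hap[2 * mate + 1], pos,
                config.chrom_length, config.chrom_morgans, rng,
            )
            offspring_haps[c].append((g1, g2))

    ingroup_names = sample_names + [p[1] for p in pedigree]

    # dosage of the derived allele, per chromosome, for ingroup columns
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    chrom_all, pos_all = [], []
    dos_blocks, cls_all, sift_all, s_all = [], [], [], []
    for c, (hap, pos) in enumerate(zip(haps, positions)):
        cols = []
        for i in chosen:
            cols.append(hap[2 * i] + hap[2 * i + 1])
        for g1, g2 in offspring_haps[c]:
            cols.append(g1 + g2)
        block = np.stack(cols, axis=1).astype(np.int8)  # sites x ingroup
        dos_blocks.append(block)
        chrom_all.extend([chrom_names[c]] * len(pos))
        pos_all.append(pos)
        cls_all.append(vclass_c[c])
        sift_all.append(sift_c[c])
        s_all.append(s_c[c])

    dosage_der = np.concatenate(dos_blocks, axis=0)
    pos_arr = np.concatenate(pos_all)
    vclass = np.concatenate(cls_all)
    sift = np.concatenate(sift_all)
    sel_coeff = np.concatenate(s_all)
    n_sites = len(pos_arr)

    # base assignment and ref/alt orientation
    anc_code = rng.integers(0, 4, size=n_sites)
    der_code = (anc_code + rng.integers(1, 4, size=n_sites)) % 4
    anc = _BASES[anc_code]
    der = _BASES[der_code]
    flip = rng.random(n_sites) < config.ref_flip_prob
    ref = np.where(flip, der, anc).astype(object)
    alt = np.where(flip, anc, der).astype(object)
    dosage_in = np.where(flip[:, None], 2 - dosage_der, dosage_der).astype(np.int8)

    # outgroups: substitution away from the ancestral base
    q = -np.expm1(-2.0 * config.mu * config.outgroup_divergence)
    og = np.empty((n_sites, 2), dtype=object)
    for j in range(2):
        code = anc_code.copy()
        sub = rng.random(n_sites) < q
        nsub = int(sub.sum())
        if nsub:
            code[sub] = (code[sub] + rng.integers(1, 4, size=nsub)) % 4
        og[:, j] = _BASES[code]
    og_dos = np.full((n_sites, 2), MISSING, dtype=np.int8)
    for j in range(2):
        og_dos[og[:, j] == ref, j] = 0
        og_dos[og[:, j] == alt, j] = 2

    # monomorphic-site exclusion under joint-calling semantics: a site is
    # kept if the ingroup segregates, or if the ingroup is fixed but an
    # outgroup call differs from the fixed allele (so bottleneck-fixed
    # derived alleles remain visible, as in a VCF jointly called with the
    # outgroups)
    ing_sum = dosage_in.sum(axis=1, dtype=np.int64)
    n_ing_alleles = 2 * dosage_in.shape[1]
    seg = (ing_sum > 0) & (ing_sum < n_ing_alleles)
    fixed_base = np.where(ing_sum == 0, ref, alt)
    og_diverged = (og[:, 0] != fixed_base) | (og[:, 1] != fixed_base)
    keep = seg | og_diverged

    chrom_all = [c for c, k in zip(chrom_all, keep) if k]
    pos_arr = pos_arr[keep]
    ref, alt = ref[keep], alt[keep]
    anc, der = anc[keep], der[keep]
    vclass, sift, sel_coeff = vclass[keep], sift[keep], sel_coeff[keep]
    og, og_dos = og[keep], og_dos[keep]
    dosage_in = dosage_in[keep]

    outgroup_names = ["OUT1", "OUT2"]
    samples = ingroup_names + outgroup_names
    dosage = np.concatenate([dosage_in, og_dos], axis=1)
    populations = {s: "POP" for s in ingroup_names}
    populations.update({s: "OUT" for s in outgroup_names})

    vt = VariantTable(
        chrom=np.array(chrom_all, dtype=object),
        pos=pos_arr,
        ref=ref,
        alt=alt,
        dosage=dosage,
        samples=samples,
        populations=populations,
    )
    truth = SimTruth(
        ancestral=anc,
        derived=der,
        vclass=vclass,
        sift=sift,
        sel_s=sel_coeff,
        outgroup_alleles=og,
        pedigree=pedigree,
        outgroup_samples=outgroup_names,
        epochs=epochs,
        seed=config.seed,
    )
    vt.annotations = truth.annotation_frame(vt)[["impact", "sift_score"]]
    return vt, truth
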