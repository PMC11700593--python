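"""Variant tables, VCF IO, site filtering, and LD pruning.

The central data structure is :class:`VariantTable`: a sites-by-samples
matrix of alternate-allele dosages (0/1/2, ``MISSING`` = -1) with per-site
chromosome, 1-based position, REF/ALT alleles, optional QUAL and per-call
depth, and optional per-site annotations (impact category, SIFT score).

Coordinates are 1-based inclusive throughout (VCF convention).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bottlescan
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


@dataclass
class VariantTable:
    """Sites-by-samples genotype matrix with site metadata.

    Parameters
    ----------
    chrom, pos, ref, alt
        Per-site arrays. ``pos`` is 1-based and must be strictly increasing
        within each chromosome; chromosome blocks must be contiguous.
        Multi-allelic ALT is a comma-joined string (removed by the
        biallelic filter).
    dosage
        ``(n_sites, n_samples)`` int8 array of ALT-allele dosages;
        ``MISSING`` (-1) marks missing calls.
    samples
        Sample identifiers, one per dosage column.
    qual, depth
        Optional per-site QUAL (NaN = absent) and per-call depth
        (-1 = unrecorded).
    populations
        Optional sample -> population-label mapping (default "POP").
    annotations
        Optional per-site DataFrame with columns ``impact`` and
        ``sift_score``, row-aligned with the sites.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    qual: np.ndarray | None = None
    depth: np.ndarray | None = None
    populations: dict[str, str] = field(default_factory=dict)
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.samples = list(self.samples)
        if self.dosage.ndim != 2 or self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage must be (n_sites, n_samples)")
        if self.qual is not None:
            self.qual = np.asarray(self.qual, dtype=float)
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set = set()
        prev_chrom = None
        for i in range(self.n_sites):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome block for {c!r} is not contiguous")
                seen.add(c)
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on {c!r} at index {i}"
                )

    # ------------------------------------------------------------------ basic
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def sample_cols(self, samples: Sequence[str] | None = None) -> np.ndarray:
        if samples is None:
            return np.arange(self.n_samples)
        return np.array([self.sample_index(s) for s in samples], dtype=int)

    def population_of(self, sample: str) -> str:
        return self.populations.get(sample, "POP")

    def ingroup_samples(self, exclude_pop: str = "OUT") -> list[str]:
        return [s for s in self.samples if self.population_of(s) != exclude_pop]

    def chromosomes(self) -> list:
        out, seen = [], set()
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    # -------------------------------------------------------------- subsetting
    def take_sites(self, sel) -> "VariantTable":
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return VariantTable(
            chrom=self.chrom[sel],
            pos=self.pos[sel],
            ref=self.ref[sel],
            alt=self.alt[sel],
            dosage=self.dosage[sel],
            samples=list(self.samples),
            qual=None if self.qual is None else self.qual[sel],
            depth=None if self.depth is None else self.depth[sel],
            populations=dict(self.populations),
            annotations=None
            if self.annotations is None
            else self.annotations.iloc[sel].reset_index(drop=True),
        )

    def take_samples(self, samples: Sequence[str]) -> "VariantTable":
        cols = self.sample_cols(samples)
        return VariantTable(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[:, cols],
            samples=[self.samples[c] for c in cols],
            qual=self.qual,
            depth=None if self.depth is None else self.depth[:, cols],
            populations={s: self.population_of(s) for s in samples},
            annotations=self.annotations,
        )

    # ------------------------------------------------------------- statistics
    def allele_counts(self, samples: Sequence[str] | None = None):
        """Per-site (alt_allele_count, total_non_missing_alleles)."""
        d = self.dosage[:, self.sample_cols(samples)]
        present = d != MISSING
        alt = np.where(present, d, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * present.sum(axis=1).astype(np.int64)

    def maf(self, samples: Sequence[str] | None = None) -> np.ndarray:
        alt, tot = self.allele_counts(samples)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(f, 1.0 - f)

    def present_fraction(self, samples: Sequence[str] | None = None) -> np.ndarray:
        d = self.dosage[:, self.sample_cols(samples)]
        return (d != MISSING).mean(axis=1)

    def mean_depth(self) -> np.ndarray | None:
        if self.depth is None:
            return None
        ok = self.depth >= 0
        with np.errstate(invalid="ignore"):
            return np.where(
                ok.any(axis=1),
                np.where(ok, self.depth, 0).sum(axis=1) / np.maximum(ok.sum(axis=1), 1),
                np.nan,
            )

    def is_biallelic_snp(self) -> np.ndarray:
        out = np.empty(self.n_sites, dtype=bool)
        for i in range(self.n_sites):
            r, a = self.ref[i], self.alt[i]
            out[i] = len(r) == 1 and len(a) == 1 and a in "ACGT" and r in "ACGT"
        return out

    def equals(self, other: "VariantTable") -> bool:
        if self.samples != other.samples or self.n_sites != other.n_sites:
            return False
        same = (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.dosage, other.dosage)
        )
        if not same:
            return False
        for a, b in ((self.qual, other.qual), (self.depth, other.depth)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.allclose(a, b, equal_nan=True):
                return False
        return True


# ============================================================== VCF input/output
def read_vcf(path, annotation_path=None) -> VariantTable:
    """Read a VCF 4.x (plain or gzip) into a :class:`VariantTable`.

    Missing GT becomes ``MISSING``; calls carrying an allele other than
    REF/ALT1 at multi-allelic records are coded missing (such records are
    dropped later by the biallelic filter). Positions must be sorted and
    chromosome blocks contiguous; records on contigs absent from the header
    raise an error.
    """
    from cyvcf2 import VCF

    v = VCF(str(path))
    samples = list(v.samples)
    header_contigs = set(v.seqnames)
    chrom, pos, ref, alt, qual = [], [], [], [], []
    dosage_rows, depth_rows = [], []
    any_depth = False
    last: dict = {}
    order: list = []
    for var in v:
        c = var.CHROM
        if header_contigs and c not in header_contigs:
            raise ValueError(f"record on unknown contig {c!r}")
        if c not in last:
            if c in set(order[:-1]):
                raise ValueError(f"chromosome {c!r} appears in two blocks")
            order.append(c)
            last[c] = -1
        elif order[-1] != c:
            raise ValueError(f"chromosome {c!r} appears in two blocks")
        if var.POS <= last[c]:
            raise ValueError(f"unsorted positions on {c!r} at {var.POS}")
        last[c] = var.POS
        chrom.append(c)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(",".join(var.ALT) if var.ALT else ".")
        qual.append(np.nan if var.QUAL is None else float(var.QUAL))
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if any(a < 0 for a in alleles) or any(a > 1 for a in alleles):
                row[j] = MISSING
            else:
                row[j] = sum(alleles)
        dosage_rows.append(row)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_depth = True
            dp = dp.reshape(-1).astype(np.int64)
            dp = np.where(dp < 0, -1, dp)
            depth_rows.append(dp.astype(np.int32))
        else:
            depth_rows.append(np.full(len(samples), -1, dtype=np.int32))
    v.close()
    n = len(pos)
    vt = VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=np.array(dosage_rows, dtype=np.int8).reshape(n, len(samples)),
        samples=samples,
        qual=np.array(qual, dtype=float),
        depth=np.array(depth_rows, dtype=np.int32).reshape(n, len(samples))
        if any_depth
        else None,
    )
    if annotation_path is not None:
        attach_annotations(vt, read_annotations(annotation_path))
    return vt


def write_vcf(vt: VariantTable, path, chrom_lengths: dict | None = None) -> None:
    """Write a plain-text VCF 4.2 with GT (and DP when depth is present)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in vt.chromosomes():
            ln = (
                chrom_lengths[c]
                if chrom_lengths and c in chrom_lengths
                else int(vt.pos[vt.chrom == c].max())
            )
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.samples)
            + "\n"
        )
        has_dp = vt.depth is not None
        fmt = "GT:DP" if has_dp else "GT"
        for i in range(vt.n_sites):
            q = "."
            if vt.qual is not None and not np.isnan(vt.qual[i]):
                q = f"{vt.qual[i]:g}"
            calls = []
            for j in range(vt.n_samples):
                gt = gt_map[int(vt.dosage[i, j])]
                if has_dp:
                    dp = int(vt.depth[i, j])
                    gt += ":" + (str(dp) if dp >= 0 else ".")
                calls.append(gt)
            fh.write(
                f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}\t{q}\t.\t.\t{fmt}\t"
                + "\t".join(calls)
                + "\n"
            )


def read_annotations(path) -> pd.DataFrame:
    """Read a sidecar TSV with columns chrom, pos, impact, sift_score."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "pos", "impact"}
    if not need.issubset(df.columns):
        raise ValueError(f"annotation file must have columns {sorted(need)}")
    if "sift_score" not in df.columns:
        df["sift_score"] = np.nan
    return df


def attach_annotations(vt: VariantTable, ann: pd.DataFrame) -> None:
    """Align an annotation frame to the table's sites (left join on chrom, pos)."""
    sites = pd.DataFrame({"chrom": [str(c) for c in vt.chrom], "pos": vt.pos})
    merged = sites.merge(
        ann.drop_duplicates(subset=["chrom", "pos"]), on=["chrom", "pos"], how="left"
    )
    vt.annotations = merged[["impact", "sift_score"]].reset_index(drop=True)


# ==================================================================== filtering
@dataclass
class FilterConfig:
    """Site-filter thresholds (defaults follow common resequencing practice).

    ``max_missing`` is the minimum fraction of genotypes that must be
    present (vcftools ``--max-missing`` semantics).
    """

    biallelic_only: bool = True
    maf_min: float = 0.05
    max_missing: float = 0.9
    min_qual: float = 30.0
    min_dp: int = 5
    min_mean_dp: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    removed: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "sites_removed": v} for k, v in self.removed.items()]
        rows.append({"criterion": "kept", "sites_removed": self.n_kept})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_CRITERIA = ("biallelic", "qual", "mean_depth", "missingness", "maf")


def apply_site_filters(
    vt: VariantTable, cfg: FilterConfig, samples: Sequence[str] | None = None
) -> tuple[VariantTable, FilterReport]:
    """Apply per-call depth masking then site-level filters.

    Calls with recorded depth below ``min_dp`` are set missing first, so
    the missingness and MAF criteria see the masked matrix. A removed site
    is attributed to the first failing criterion in the order:
    biallelic, qual, mean-depth, missingness, MAF. QUAL and depth criteria
    are skipped when the corresponding data are absent. Idempotent.

    ``samples`` optionally restricts the metric computation (e.g. to the
    ingroup), while all columns are retained in the output.
    """
    removed = {k: 0 for k in _CRITERIA}
    warns: list[str] = []
    if vt.n_sites == 0:
        warns.append("empty input table")
        return vt, FilterReport(0, 0, removed, warns)

    masked = vt
    if cfg.min_dp and vt.depth is not None:
        d = vt.dosage.copy()
        d[(vt.depth >= 0) & (vt.depth < cfg.min_dp)] = MISSING
        masked = dataclasses.replace(vt, dosage=d)

    fails = np.zeros(vt.n_sites, dtype=int)  # 0 = pass, else 1-based criterion idx

    def _mark(bad: np.ndarray, idx: int) -> None:
        sel = bad & (fails == 0)
        fails[sel] = idx

    if cfg.biallelic_only:
        _mark(~masked.is_biallelic_snp(), 1)
    if cfg.min_qual is not None and masked.qual is not None:
        with np.errstate(invalid="ignore"):
            _mark(~np.isnan(masked.qual) & (masked.qual < cfg.min_qual), 2)
    md = masked.mean_depth()
    if cfg.min_mean_dp is not None and md is not None:
        _mark(~np.isnan(md) & (md < cfg.min_mean_dp), 3)
    _mark(masked.present_fraction(samples) < cfg.max_missing, 4)
    maf = masked.maf(samples)
    _mark(np.isnan(maf) | (maf < cfg.maf_min), 5)

    for i, name in enumerate(_CRITERIA, start=1):
        removed[name] = int((fails == i).sum())
    out = masked.take_sites(fails == 0)
    return out, FilterReport(vt.n_sites, out.n_sites, removed, warns)


# =================================================================== LD pruning
@dataclass
class LDPruneConfig:
    window_kb: float = 10.0
    step_sites: int = 5
    r2_max: float = 0.5

    def __post_init__(self):
        if self.window_kb <= 0 or self.step_sites <= 0 or self.r2_max <= 0:
            raise ValueError("LDPruneConfig fields must be positive")


def r2(vt: VariantTable, site_a: int, site_b: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples.

    Returns NaN (undefined-marker) when fewer than two complete pairs
    exist or either site is monomorphic among the complete pairs.
    """
    x = vt.dosage[site_a].astype(float)
    y = vt.dosage[site_b].astype(float)
    m = (x >= 0) & (y >= 0)
    if m.sum() < 2:
        return float("nan")
    x, y = x[m], y[m]
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def pair_r2_matrix(dosage: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Vectorised r² for site-index pairs (rows of ``dosage``); NaN when undefined."""
    X = dosage[ii].astype(float)
    Y = dosage[jj].astype(float)
    m = (X >= 0) & (Y >= 0)
    n = m.sum(axis=1)
    X = np.where(m, X, 0.0)
    Y = np.where(m, Y, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx, sy = X.sum(1), Y.sum(1)
        cov = (X * Y).sum(1) - sx * sy / n
        vx = (X * X).sum(1) - sx * sx / n
        vy = (Y * Y).sum(1) - sy * sy / n
        out = cov * cov / (vx * vy)
    out[(n < 2) | (vx <= 0) | (vy <= 0)] = np.nan
    return out


def _window_members(vt, keep, block, s_off, window_bp):
    start_idx = block[s_off]
    limit = vt.pos[start_idx] + window_bp
    members = []
    for i in block[s_off:]:
        if vt.pos[i] >= limit:
            break
        if keep[i]:
            members.append(i)
    return members


def ld_prune(
    vt: VariantTable,
    cfg: LDPruneConfig = LDPruneConfig(),
    samples: Sequence[str] | None = None,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept site indices.

    Scans each chromosome left to right with windows of ``window_kb``
    anchored at every ``step_sites``-th site index; while any kept pair in
    the window has r² > ``r2_max``, the member of the worst pair with the
    smaller MAF is removed (ties: larger position). Deterministic.
    """
    sub = vt if samples is None else vt.take_samples(list(samples))
    keep = np.ones(vt.n_sites, dtype=bool)
    mafs = vt.maf(samples)
    window_bp = int(cfg.window_kb * 1000)
    for c in vt.chromosomes():
        block = np.flatnonzero(vt.chrom == c)
        for s_off in range(0, len(block), cfg.step_sites):
            while True:
                members = _window_members(vt, keep, block, s_off, window_bp)
                if len(members) < 2:
                    break
                worst, worst_pair = cfg.r2_max, None
                for a_i in range(len(members)):
                    for b_i in range(a_i + 1, len(members)):
                        a, b = members[a_i], members[b_i]
                        v = r2(sub, a, b)
                        if not np.isnan(v) and v > worst:
                            worst, worst_pair = v, (a, b)
                if worst_pair is None:
                    break
                a, b = worst_pair
                if mafs[a] < mafs[b]:
                    drop = a
                elif mafs[b] < mafs[a]:
                    drop = b
                else:
                    drop = max(a, b, key=lambda i: (vt.pos[i], i))
                keep[drop] = False
    return np.flatnonzero(keep)


def ld_prune_violations(
    vt: VariantTable,
    kept: np.ndarray,
    cfg: LDPruneConfig,
    samples: Sequence[str] | None = None,
) -> list[tuple[int, int, float]]:
    """Exhaustive post-hoc scan: kept pairs sharing a scan window with r² > threshold."""
    sub = vt if samples is None else vt.take_samples(list(samples))
    keep = np.zeros(vt.n_sites, dtype=bool)
    keep[np.asarray(kept)] = True
    window_bp = int(cfg.window_kb * 1000)
    bad = []
    for c in vt.chromosomes():
        block = np.flatnonzero(vt.chrom == c)
        for s_off in range(0, len(block), cfg.step_sites):
            members = _window_members(vt, keep, block, s_off, window_bp)
            for a_i in range(len(members)):
                for b_i in range(a_i + 1, len(members)):
                    a, b = members[a_i], members[b_i]
                    v = r2(sub, a, b)
                    if not np.isnan(v) and v > cfg.r2_max:
                        bad.append((a, b, v))
    return bad


def sites_to_tsv(vt: VariantTable, path) -> None:
    pd.DataFrame({"chrom": vt.chrom, "pos": vt.pos}).to_csv(path, sep="\t", index=False)
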