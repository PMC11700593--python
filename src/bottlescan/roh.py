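"""Runs of homozygosity: window-based detection, FROH, size classes,
coalescence dating, and bottleneck-window SROH attribution.

Detection follows the window-vote scheme of the classic genotype-based
caller:

1. every contiguous block of ``window_snps`` SNPs is *accepted* iff it
   contains at most ``window_het_max`` heterozygous and
   ``window_missing_max`` missing calls;
2. a SNP's hit fraction is (accepted windows covering it) / (windows
   covering it) — the denominator counts only windows that actually fit,
   so chromosome ends carry no phantom windows — and the SNP is
   ROH-eligible iff the fraction reaches ``hit_threshold``;
3. maximal runs of eligible SNPs are split where adjacent SNPs are more
   than ``gap_kb`` apart;
4. runs are reported iff length >= ``min_kb``, SNP count >= ``min_snps``
   and mean inter-SNP spacing <= ``max_kb_per_snp``.

Coalescence dating uses t = 100 / (2 * L_cM) with genetic lengths from a
constant recombination rate (cM/Mb).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

DEFAULT_GENOME_LENGTH = 2_222_501_653  # autosomal bp covered by SNP positions


@dataclass
class RecombinationModel:
    rate: float = 1.3459  # cM per Mb

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("recombination rate must be positive")

    def cm(self, length_bp: float) -> float:
        return length_bp / 1e6 * self.rate


@dataclass
class ROHParams:
    min_kb: float = 100.0
    min_snps: int = 100
    max_kb_per_snp: float = 50.0
    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    gap_kb: float = 1000.0
    hit_threshold: float = 0.05

    def __post_init__(self):
        if min(self.min_kb, self.min_snps, self.max_kb_per_snp, self.window_snps,
               self.gap_kb) <= 0:
            raise ValueError("ROH parameters must be positive")
        if not 0.0 < self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must be in (0, 1]")


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # 1-based, at SNP positions, inclusive
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ROHProfile:
    sample: str
    nroh: int
    sroh: int
    froh: float
    sroh_short: int  # [100 kb, 1 Mb)
    sroh_intermediate: int  # [1 Mb, 10 Mb)
    sroh_long: int  # >= 10 Mb


def _call_chrom(pos: np.ndarray, dos: np.ndarray, chrom, sample: str,
                p: ROHParams) -> list[ROHSegment]:
    n = len(pos)
    w = p.window_snps
    if n < w:
        return []
    het = dos == 1
    miss = dos == MISSING
    cs_het = np.concatenate([[0], np.cumsum(het)])
    cs_mis = np.concatenate([[0], np.cumsum(miss)])
    hw = cs_het[w:] - cs_het[:-w]
    mw = cs_mis[w:] - cs_mis[:-w]
    accepted = (hw <= p.window_het_max) & (mw <= p.window_missing_max)
    n_win = n - w + 1
    cs_acc = np.concatenate([[0], np.cumsum(accepted)])
    k = np.arange(n)
    lo = np.maximum(0, k - w + 1)
    hi = np.minimum(k, n_win - 1)
    hits = cs_acc[hi + 1] - cs_acc[lo]
    cover = hi - lo + 1
    eligible = hits / cover >= p.hit_threshold

    gap_bp = p.gap_kb * 1000.0
    segments: list[ROHSegment] = []
    run_start = None
    for i in range(n + 1):
        in_run = i < n and eligible[i]
        if in_run and run_start is not None and pos[i] - pos[i - 1] > gap_bp:
            _close(segments, pos, het, chrom, sample, run_start, i - 1, p)
            run_start = i
        elif in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            _close(segments, pos, het, chrom, sample, run_start, i - 1, p)
            run_start = None
    return segments


def _close(segments, pos, het, chrom, sample, a, b, p: ROHParams) -> None:
    length = int(pos[b] - pos[a] + 1)
    n_snps = b - a + 1
    if length < p.min_kb * 1000:
        return
    if n_snps < p.min_snps:
        return
    if length / n_snps > p.max_kb_per_snp * 1000:
        return
    segments.append(
        ROHSegment(sample, str(chrom), int(pos[a]), int(pos[b]), n_snps,
                   int(het[a:b + 1].sum()))
    )


def call_roh(vt: VariantTable, sample: str,
             params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Call ROH segments for one sample (see module docstring for the rules)."""
    col = vt.dosage[:, vt.sample_index(sample)]
    out: list[ROHSegment] = []
    for c in vt.chromosomes():
        block = np.flatnonzero(vt.chrom == c)
        out.extend(_call_chrom(vt.pos[block], col[block], c, sample, params))
    return out


def summarize_roh(
    segments: list[ROHSegment],
    genome_length: int = DEFAULT_GENOME_LENGTH,
    samples: list[str] | None = None,
) -> dict[str, ROHProfile]:
    """Per-sample NROH / SROH / FROH and size-class decomposition.

    Class bounds: short [100 kb, 1 Mb), intermediate [1 Mb, 10 Mb),
    long >= 10 Mb (boundary lengths go to the longer class).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    names = list(samples) if samples is not None else sorted({s.sample for s in segments})
    out: dict[str, ROHProfile] = {}
    for name in names:
        segs = [s for s in segments if s.sample == name]
        sroh = sum(s.length for s in segs)
        short = sum(s.length for s in segs if s.length < 1_000_000)
        inter = sum(s.length for s in segs if 1_000_000 <= s.length < 10_000_000)
        long_ = sum(s.length for s in segs if s.length >= 10_000_000)
        out[name] = ROHProfile(
            sample=name, nroh=len(segs), sroh=sroh, froh=froh(sroh, genome_length),
            sroh_short=short, sroh_intermediate=inter, sroh_long=long_,
        )
    return out


def froh(sroh_bp: float, genome_length: int = DEFAULT_GENOME_LENGTH) -> float:
    """Inbreeding coefficient: SROH over the autosomal genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return sroh_bp / genome_length


def roh_age(length_bp: float, rec: RecombinationModel = RecombinationModel()) -> float:
    """Coalescence time in generations: t = 100 / (2 * L_cM). Unrounded."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    return 100.0 / (2.0 * rec.cm(length_bp))


def length_for_age(t: float, rec: RecombinationModel = RecombinationModel()) -> float:
    """Exact inverse of :func:`roh_age`: expected ROH length (bp) for age ``t``."""
    if t <= 0:
        raise ValueError("t must be positive")
    return 100.0 / (2.0 * t) / rec.rate * 1e6


def bottleneck_window_fraction(
    segments: list[ROHSegment],
    g_old: float,
    g_recent: float,
    rec: RecombinationModel = RecombinationModel(),
    post_gens: float = 5.0,
) -> float:
    """Fraction of pooled SROH in the length band formed during the
    bottleneck (ages g_old..g_recent) and ``post_gens`` generations after.

    Band = [length_for_age(g_old), length_for_age(g_recent - post_gens)],
    inclusive. NaN on an empty segment set.
    """
    if not g_old > g_recent >= post_gens >= 0:
        raise ValueError("need g_old > g_recent >= post_gens >= 0")
    if not segments:
        return float("nan")
    lo = length_for_age(g_old, rec)
    hi = length_for_age(g_recent - post_gens, rec)
    total = sum(s.length for s in segments)
    band = sum(s.length for s in segments if lo <= s.length <= hi)
    return band / total


def generations_to_years(g: float, gen_years: float, reference_year: float) -> float:
    """Calendar year ``g`` generations before ``reference_year``."""
    if g < 0 or gen_years <= 0:
        raise ValueError("need g >= 0 and gen_years > 0")
    return reference_year - g * gen_years


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample, "chrom": s.chrom, "start": s.start,
                "end": s.end, "length_bp": s.length, "n_snps": s.n_snps,
                "n_het": s.n_het,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "length_bp", "n_snps", "n_het"],
    )


def profiles_to_frame(profiles: dict[str, ROHProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": p.sample, "NROH": p.nroh, "SROH": p.sroh, "FROH": p.froh,
                "SROH_short": p.sroh_short, "SROH_intermediate": p.sroh_intermediate,
                "SROH_long": p.sroh_long,
            }
            for p in profiles.values()
        ],
        columns=["sample", "NROH", "SROH", "FROH", "SROH_short",
                 "SROH_intermediate", "SROH_long"],
    )
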