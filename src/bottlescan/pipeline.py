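"""End-to-end orchestration: simulate/load -> filter -> kinship ->
diversity / ROH / Ne / load, with a manifest and TSV outputs.

Stage SNP sets follow common practice: the MAF filter is applied for the
kinship/Ne set and skipped for the diversity/ROH/load set (MAF filtering
distorts SFS- and ROH-based statistics); both are toggleable. Reruns with
the same config and seed are bit-identical (no timestamps in outputs).
"""
from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .variants import (FilterConfig, LDPruneConfig, VariantTable,
                       apply_site_filters, attach_annotations, read_annotations,
                       read_vcf, write_vcf)
from .simdata import SimConfig, SelectionParams, simulate_population
from .kinship import (exclusion_set, flag_related, kinship_table,
                      results_to_frame)
from .diversity import folded_sfs, ho_frame, windowed_pi
from .roh import (DEFAULT_GENOME_LENGTH, ROHParams, RecombinationModel,
                  call_roh, profiles_to_frame, segments_to_frame, summarize_roh)
from .ne import estimate_ne_unlinked, ne_trajectory


@dataclass
class PipelineConfig:
    vcf: str | None = None
    annotations: str | None = None
    outgroups: str | None = None  # TSV chrom,pos,out1,out2
    simulate: SimConfig | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    maf_for_diversity_set: bool = False
    ld_prune: LDPruneConfig | None = None
    roh_params: ROHParams = field(default_factory=ROHParams)
    recombination: RecombinationModel = field(default_factory=RecombinationModel)
    genome_length: int = DEFAULT_GENOME_LENGTH
    exclude_flagged_relatives: bool = False
    ne_pairs: int = 20_000
    seed: int = 0
    outdir: str = "out"
    stages: tuple = ("filter", "kinship", "diversity", "roh", "ne", "load")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "selection" in sim:
                sim["selection"] = {
                    k: SelectionParams(**v) for k, v in sim["selection"].items()
                }
            for key in ("ne_trajectory", "bottleneck"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(tuple(x) for x in sim[key]) if key == "ne_trajectory" else tuple(sim[key])
            kwargs["simulate"] = SimConfig(**sim)
        if "filter" in raw:
            kwargs["filter"] = FilterConfig(**raw["filter"])
        if "roh_params" in raw:
            kwargs["roh_params"] = ROHParams(**raw["roh_params"])
        if "recombination" in raw:
            kwargs["recombination"] = RecombinationModel(**raw["recombination"])
        if "ld_prune" in raw and raw["ld_prune"] is not None:
            kwargs["ld_prune"] = LDPruneConfig(**raw["ld_prune"])
        for key in ("vcf", "annotations", "outgroups", "genome_length",
                    "exclude_flagged_relatives", "ne_pairs", "seed", "outdir",
                    "maf_for_diversity_set"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        return cls(**kwargs)


def _log(stage: str, msg: str) -> None:
    print(f"[bottlescan:{stage}] {msg}", file=sys.stderr)


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        vt, truth = simulate_population(sim)
        write_vcf(vt, outdir / "sim.vcf",
                  {c: sim.chrom_length for c in vt.chromosomes()})
        truth.annotation_frame(vt).to_csv(outdir / "annotations.tsv", sep="\t",
                                          index=False)
        truth.outgroup_frame(vt).to_csv(outdir / "outgroups.tsv", sep="\t",
                                        index=False)
        truth.to_json(outdir / "truth.json", vt)
        og = truth.outgroup_alleles
        _log("simulate", f"{vt.n_sites} sites, {vt.n_samples} columns")
        return vt, og
    if cfg.vcf is None:
        raise ValueError("config must provide either a VCF path or a simulate block")
    vt = read_vcf(cfg.vcf, annotation_path=cfg.annotations)
    og = None
    if cfg.outgroups:
        og_df = pd.read_csv(cfg.outgroups, sep="\t", dtype={"chrom": str})
        sites = pd.DataFrame({"chrom": [str(c) for c in vt.chrom], "pos": vt.pos})
        merged = sites.merge(og_df, on=["chrom", "pos"], how="left")
        og = merged[["out1", "out2"]].to_numpy(dtype=object)
        og = np.where(pd.isna(og), None, og)
    return vt, og


def run(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "counts": {},
    }

    vt, outgroup_alleles = _load_inputs(cfg, outdir)
    ingroup = vt.ingroup_samples()
    manifest["counts"]["input_sites"] = vt.n_sites
    manifest["counts"]["input_samples"] = len(ingroup)

    # two per-stage site sets (see module docstring)
    base_cfg = dataclasses.replace(cfg.filter, maf_min=0.0) \
        if not cfg.maf_for_diversity_set else cfg.filter
    vt_div, rep_div = apply_site_filters(vt, base_cfg, samples=ingroup)
    vt_maf, rep_maf = apply_site_filters(vt, cfg.filter, samples=ingroup)
    if "filter" in cfg.stages:
        rep_div.to_tsv(outdir / "filter_report_diversity_set.tsv")
        rep_maf.to_tsv(outdir / "filter_report_maf_set.tsv")
        _log("filter", f"diversity set {vt_div.n_sites}, maf set {vt_maf.n_sites}")
    manifest["counts"]["sites_diversity_set"] = vt_div.n_sites
    manifest["counts"]["sites_maf_set"] = vt_maf.n_sites

    excluded: list[str] = []
    if "kinship" in cfg.stages:
        results = kinship_table(vt_maf, samples=ingroup)
        flag_related(results)
        results_to_frame(results).to_csv(outdir / "kinship.tsv", sep="\t",
                                         index=False)
        if cfg.exclude_flagged_relatives:
            excluded = exclusion_set(vt_maf, results)
        _log("kinship", f"{len(results)} pairs, excluded={excluded}")
    analysis_samples = [s for s in ingroup if s not in excluded]
    manifest["counts"]["excluded_relatives"] = excluded
    manifest["counts"]["analysis_samples"] = len(analysis_samples)

    if "diversity" in cfg.stages:
        ho_frame(vt_div, samples=analysis_samples).to_csv(
            outdir / "ho.tsv", sep="\t", index=False)
        windowed_pi(vt_div, samples=analysis_samples).to_csv(
            outdir / "pi_windows.tsv", sep="\t", index=False)
        sfs = folded_sfs(vt_div, samples=analysis_samples)
        pd.DataFrame({"minor_count": np.arange(len(sfs)), "n_sites": sfs}).to_csv(
            outdir / "sfs.tsv", sep="\t", index=False)
        _log("diversity", "Ho / pi / SFS written")

    if "roh" in cfg.stages:
        segments = []
        for s in analysis_samples:
            segments.extend(call_roh(vt_div, s, cfg.roh_params))
        segments_to_frame(segments).to_csv(outdir / "roh_segments.tsv", sep="\t",
                                           index=False)
        profiles = summarize_roh(segments, cfg.genome_length,
                                 samples=analysis_samples)
        profiles_to_frame(profiles).to_csv(outdir / "roh_profile.tsv", sep="\t",
                                           index=False)
        manifest["counts"]["roh_segments"] = len(segments)
        _log("roh", f"{len(segments)} segments")

    if "ne" in cfg.stages:
        try:
            est = estimate_ne_unlinked(vt_maf, n_pairs=cfg.ne_pairs,
                                       seed=cfg.seed, samples=analysis_samples)
            est.to_frame().to_csv(outdir / "ne.tsv", sep="\t", index=False)
        except ValueError as exc:
            _log("ne", f"unlinked estimate unavailable: {exc}")
        traj = ne_trajectory(vt_maf, cfg.recombination, len(analysis_samples),
                             seed=cfg.seed, samples=analysis_samples)
        traj.to_csv(outdir / "ne_trajectory.tsv", sep="\t", index=False)
        _log("ne", f"{len(traj)} trajectory bins")

    if "load" in cfg.stages:
        if outgroup_alleles is None or vt_div.annotations is None:
            _log("load", "skipped: outgroups or annotations unavailable")
        else:
            from .load import (classify_sites, load_counts, orient_derived,
                               polarize_sites)
            # align outgroup calls to the diversity-set sites
            key_all = {(str(c), int(p)): k
                       for k, (c, p) in enumerate(zip(vt.chrom, vt.pos))}
            idx = np.array([key_all[(str(c), int(p))]
                            for c, p in zip(vt_div.chrom, vt_div.pos)])
            og = np.asarray(outgroup_alleles, dtype=object)[idx]
            polar = polarize_sites(vt_div, og, seed=cfg.seed)
            retained, report = orient_derived(polar)
            cats = classify_sites(vt_div.annotations)
            table = load_counts(vt_div, retained, cats, samples=analysis_samples)
            table.to_csv(outdir / "load.tsv", sep="\t", index=False)
            polar.assign(retained=retained).to_csv(
                outdir / "polarization.tsv", sep="\t", index=False)
            manifest["counts"]["orientation"] = report
            _log("load", f"retained {report['retained']} sites")

    manifest["config"] = _config_echo(cfg)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_echo(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    # outdir omitted: it is where the manifest lives, and including it would
    # make otherwise-identical runs into different bundles
    return {f.name: enc(getattr(cfg, f.name))
            for f in dataclasses.fields(cfg) if f.name != "outdir"}
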