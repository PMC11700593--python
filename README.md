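# bottlescan

Population-genomic erosion analysis for diploid SNP data, built around the
question of what a historical bottleneck leaves behind in a genome: reduced
diversity, long runs of homozygosity, depressed effective population size,
and deleterious variation poised to shift from masked to realized load.

The package takes a multi-sample VCF (plus optional impact annotations and
outgroup allele calls) through:

- **variants** — VCF read/write, site filters (biallelic, MAF, missingness,
  QUAL, per-call and mean depth), and greedy windowed LD pruning.
- **kinship** — KING-robust kinship φ with R0/R1, threshold flagging
  (φ ≥ 0.20, R0 ≤ 0.1, R1 ≥ 0.5) and optional relative exclusion.
- **diversity** — individual heterozygosity, folded SFS, and nucleotide
  diversity in 100-kb windows.
- **roh** — window-vote ROH detection (50-SNP windows, ≤1 het, ≤5 missing,
  1-Mb gap split; segments ≥100 kb, ≥100 SNPs, ≤50 kb/SNP), NROH/SROH/FROH
  with size classes, coalescence dating via t = 100/(2·L_cM) at a constant
  recombination rate (default 1.3459 cM/Mb), and bottleneck-window SROH
  attribution.
- **ne** — contemporary Ne from cross-chromosome drift LD
  (Ne = 1/(3·(r̄² − floor)); the floor can be 1/n, 1/(n−1), or an empirical
  per-chromosome permutation floor) and a recent-history Ne trajectory from
  distance-binned within-chromosome LD via the Sved relation, t ≈ 1/(2c).
- **load** — two-outgroup polarization (random seeded tie-break),
  derived-equals-ALT orientation, LOW / MOD-TOL / MOD-DEL / HIGH
  classification (SIFT 0.05 split), masked (het) / realized (hom-derived) /
  total genotype counts per individual, and an exact enumeration
  Mann-Whitney test for small groups.
- **simdata** — synthetic datasets with the structure the analysis assumes:
  msprime-founded, forward-simulated Wright-Fisher populations with
  recombination, a configurable bottleneck, deleterious classes with
  dominance, two diverged outgroups, and known parent-offspring pairs, all
  with a full ground-truth channel.
- **pipeline / cli** — end-to-end orchestration with YAML config, seeded
  determinism, TSV outputs and a JSON manifest.

## CLI

```sh
bottlescan simulate --n-chromosomes 4 --chrom-length 20000000 \
    --mu 1e-7 --sample-size 12 --seed 1 --out out/
bottlescan filter --vcf out/sim.vcf --out out/filtered
bottlescan run-all --config config.yaml --seed 1 --out out/run
```

A minimal `config.yaml` for a simulated run:

```yaml
simulate:
  n_chromosomes: 4
  chrom_length: 10000000
  mu: 2.0e-7
  sample_size: 12
  ne_trajectory: [[12, 300], [6, 25], [null, 500]]  # bottleneck 12-18 gens ago
exclude_flagged_relatives: false
```

Real-data mode replaces the `simulate` block with `vcf`, `annotations`
(TSV: chrom, pos, impact, sift_score) and `outgroups` (TSV: chrom, pos,
out1, out2) paths.

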