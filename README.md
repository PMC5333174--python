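# qphylo

Quality-controlled Y-chromosome phylogeography: from heterogeneous per-sample
sequence evidence to a dated haplogroup tree, frequency maps and Y-STR branch
assignments.

## Who this is for

Population geneticists and genetic genealogists working with full
Y-chromosome sequences of a haplogroup of interest, where the samples come
from different sequencing platforms (different covered ranges, depths and
error profiles) and the goal is a single well-supported maximum-parsimony
tree with calibrated clade ages, plus the classical companion analyses:
haplogroup frequency surfaces and STR-based assignment of non-sequenced
samples to branches.

## What it does

1. **Site filtering** (`qphylo.filtering`) — converts per-sample read
   evidence (VCF or a simple TSV dialect) into a filtered matrix of variable
   positions: base quality ≥ 15, mapping quality ≥ 10, depth ≥ 2, false
   "heterozygous" haploid calls dropped only when the minor allele exceeds
   10%, STR-prone regions masked by dimeric (dinucleotide) entropy < 0.44,
   indel positions excluded, and a ≥ 60% call-rate rule with a whitelist for
   branch-naming SNPs. A "stringent" preset (depth ≥ 10, single allele) is
   available, and `sweep_configs` grades whole rule grids by phylogenetic
   quality.
2. **Maximum parsimony with QC** (`qphylo.parsimony`) — Hartigan/Fitch
   scoring with missing data, exact search to 9 taxa and stepwise addition +
   NNI/SPR hill-climbing beyond, outgroup rooting, Fitch-backtrace mutation
   mapping onto branches, Robinson–Foulds spread of co-optimal trees,
   homoplasy counts, root-leaf clock checks and parsimony bootstrap.
3. **Rho dating** (`qphylo.dating`) — clade ages from branch mutation
   counts: rho = Σ m_b·n_b/n, σ² = Σ m_b·n_b²/n², age = rho/(L·μ) with the
   pedigree-calibrated rate μ = 0.78 × 10⁻⁹ mutations/bp/year, including
   platform-consistent dating subsets.
4. **Frequency surfaces** (`qphylo.geomap`) — point samples (lat, lon, n, k)
   interpolated with the truncated-cone kernel ((R−d)/R)³ inside a 1,500 km
   radius of influence.
5. **STR branch prediction** (`qphylo.strpredict`) — mutation-step distance
   (multisets for multi-copy loci), nearest SNP-confirmed reference with
   panel-dependent thresholds (< 6 steps at 67/111 markers, ≤ 1 step at
   12/37), and a rule engine for haplogroup gating.
6. **Synthetic data** (`qphylo.simulate`, `qphylo.study`) — dated
   genealogies, Poisson SNP mutations, platform-heterogeneous coverage and
   noise, binomial geographic sampling and stepwise-mutation STR evolution,
   with full ground truth for parameter-recovery testing.

Everything is scriptable from Python or via the `qphylo` CLI
(`simulate | filter | tree | date | map | predict | run`).

## Worked example

A full study-scale replicate — 47 haplogroup carriers plus one outgroup on
three sequencing platforms across a 9.34 Mb region, with the 30
deep-platform samples used for dating:

```python
from qphylo.study import run_study

result = run_study(seed=0)
for key in ("n_variable_positions", "root_leaf_mean", "root_leaf_sd",
            "q3_age", "q3_age_se", "q3a1_age", "q3a1_age_se"):
    print(key, round(result[key], 1))
```

prints

```
n_variable_positions 1762
root_leaf_mean 107.3
root_leaf_sd 9.1
q3_age 15035.0
q3_age_se 1153.9
q3a1_age 1784.4
q3a1_age_se 189.5
```

Reading: filtering kept 1,762 variable positions across the 48 samples. The
root-to-tip mutation counts on the inferred tree are 107.3 ± 9.1 — the
near-constant counts expected from a clock-like haploid marker (the truth
expectation is 15,100 yr × 9.34 Mb × 0.78e-9 ≈ 110). The haplogroup TMRCA
estimated by the rho statistic from the 30-sample dating subset is
15,035 ± 1,154 years against a simulated truth of 15,100, and the young
nested subclade is dated 1,784 ± 190 years against a truth of 1,600 — both
within one standard error.

The same chain on your own data:

```bash
qphylo filter --tsv observations.tsv --ref chrY.fasta --preset relaxed --out run/
qphylo tree   --matrix run/matrix.vcf --outgroup OUTGROUP_ID --out run/
qphylo date   --tree run/tree.nwk --length 9340000 --out run/dating.tsv
qphylo map    --samples frequencies.csv --radius 1500 --power 3 --out run/surface.csv
qphylo predict --query strs.csv --panel confirmed.csv --out run/predicted.csv
```

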