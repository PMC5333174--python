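# Methods

`qphylo` implements the computational chain used to reconstruct the
phylogeography of a rare Y-chromosome haplogroup from heterogeneous
full-Y sequence data: haploid site filtering, maximum-parsimony tree
reconstruction with phylogenetic quality control, rho-statistic clade
dating under a fixed mutation-rate calibration, kernel-interpolated
haplogroup frequency surfaces, and Y-STR branch prediction. Because raw
genealogical sequence data of this kind is largely private, the package
ships a synthetic-data generator whose outputs carry full ground truth, so
every stage can be validated by parameter recovery.

## Synthetic data model

**Genealogy.** `simulate_genealogy` produces a dated rooted tree: either a
star (all tips attached to the root — the shape under which the rho
estimator is exactly unbiased and its variance has a closed form) or a
random sequential-coalescence ("yule"-style) topology whose node ages are
rescaled so the root age equals the requested TMRCA. Tips sit at age 0 and
ages decrease strictly from root to tips.

**Mutations.** Each branch of duration `t` years receives
`Poisson(t · L · μ)` SNPs (`L` = region length in bp, `μ` = per-bp per-year
rate, default 0.78e-9 from pedigree sequencing calibrations). Sites are
unique-event (infinite sites) by default: Y-SNPs at these time depths
essentially never recur, and recurrence on a tree is treated as an error
signal by the QC stage. `allow_recurrent` lifts the constraint to exercise
homoplasy counting.

**Sequencing evidence.** Tips are assigned platform profiles (covered
intervals, negative-binomial depth with optional floor, normal base/mapping
quality scores). Depth is negative binomial because the data the filters are
designed for is over-dispersed relative to Poisson; no published depth
distribution exists for the platforms emulated, so the defaults are stated
in `PlatformProfile`, not inferred. Sequencing error converts a binomial
share of reads at a site into uniformly chosen wrong bases, producing the
false "heterozygous" haploid sites the minor-allele rule must handle.
Observations are emitted only at mutated sites; coverage intervals carry the
information needed for call-rate denominators and the analysable length
`L`. The generator does not model read-level artefacts (FASTQ/BAM),
alignment error, recombination (absent on the MSY) or demography beyond
tree shape — so passing tests demonstrate correctness of the analysis
logic under the stated statistical model, not robustness to every artefact
of real sequencing.

**Ancestral states.** The ancestral allele at each site equals the
reference base; the derived allele is drawn uniformly from the other three.

**Geography and STRs.** Carrier counts at sampling sites are
`Binomial(n, f(lat, lon))` draws from a supplied frequency surface. Y-STR
haplotypes evolve under the stepwise mutation model: `Poisson(t · rate)`
events per marker per branch, each ±1 repeat (floored at 1).

**Determinism.** Every generator consumes a `numpy` `SeedSequence` derived
from the config seed plus a per-generator constant, so one seed fixes the
whole dataset byte-for-byte while the generators stay independent.

## Site filtering

Calls are made per sample per position from read counts with quality
metadata. The default ("relaxed") thresholds are the rule set this kind of
heterogeneous haploid data supports: base quality ≥ 15 and mapping quality
≥ 10 (failing read sets are discarded), remaining depth ≥ 2, and a sample's
call discarded only when the minor-allele fraction strictly exceeds 10%
(a 9:1 site is retained; 8:2 is not). The "stringent" preset (depth ≥ 10,
single allele only) trades resolution for per-call confidence. The
heterozygous-excess rule is applied per sample-site — the offending sample
becomes MISSING and the column may survive through other samples — because
systematically bad columns are then caught by the call-rate rule.

Indel positions are excluded; SNPs near indels are kept unless they fall in
repeat-prone regions. Those are detected by dimeric entropy: the Shannon
entropy (log2) of the overlapping-dinucleotide distribution in a window,
normalised by log2(16) = 4. A homopolymer scores 0, a perfect (AC)n tract
≈ 0.25, random sequence > 0.9; positions below the 0.44 threshold are
masked. The window is 30 bp centered on the position — no window size is
canonical for this statistic, so it is configurable, and the 0.44 threshold
must be interpreted relative to this normalisation.

Positions are retained when confidently called in ≥ 60% of samples
(call rate), with a user-supplied whitelist for branch-naming SNPs where a
lower rate is acceptable. Retained positions must be variable. The
analysable length `L` reported with the matrix counts reference positions
that are unmasked and covered by ≥ ceil(0.6·n) samples (interval sweep);
this is the denominator for dating. Coordinates are 0-based half-open
internally; VCF I/O converts at the boundary.

`sweep_configs` re-runs matrix construction and tree search over a config
grid and reports matrix size, mean pairwise RF among co-optimal trees and
homoplasy count, flagging configs whose mean normalised RF exceeds 0.15 —
the level at which tree instability indicates data errors rather than
genuine uncertainty.

## Parsimony reconstruction and QC

Scores use Hartigan's generalisation of the Fitch algorithm (exact on
multifurcations, identical to Fitch on binary trees), vectorised across
sites with state bitmasks; MISSING is the full state set and never forces a
change. The brute-force minimal-labeling enumeration in the tests is the
independent oracle.

Search is over unrooted topologies: exhaustive enumeration up to 9 taxa,
otherwise random-order stepwise addition followed by NNI hill-climbing with
restarts, escalating to SPR rearrangements when NNI stalls. Co-optimal
distinct topologies are collected (capped, with a truncation flag). Trees
are rooted afterwards on the declared outgroup.

Mutations are mapped to branches by refining the Hartigan state sets from
the root down: the root takes the ancestral allele when its state set
allows, and each node retains the parental state whenever its first-pass
set permits (changes are therefore placed as tipward as the sets allow),
remaining ties broken in fixed A<C<G<T order. For unique-event characters
the mapping is unique, so the tie-break only affects homoplastic sites; the
rule is deterministic and pinned by tests.

QC metrics: parsimony score; number of co-optimal trees and their mean
pairwise Robinson–Foulds distance (raw and normalised by 2(n−3); the 0.15
flag applies to the normalised value); homoplasy count (sites whose changes
exceed observed-alleles − 1); root-to-leaf mutation counts (mean ± sd — a
clock check: near-equal counts are expected for a haploid clock-like
marker); and parsimony bootstrap supports (site resampling, heuristic
search per replicate, percent of replicates containing each bipartition of
the best tree).

## Rho dating

For a clade, rho is the mean number of mutations on the paths from the
clade root to its tips, computed in the equivalent branch-weighted form
Σ m_b·n_b / n. Its standard error uses the Saillard variance
σ² = Σ m_b·n_b² / n². Ages are rho/(L·μ) with SE σ/(L·μ); no rate
uncertainty is propagated. Dating subsets (samples sequenced on one
platform, to avoid coverage bias) are handled by pruning the annotated tree
to the subset — mutations on suppressed branch chains are concatenated onto
the surviving branch, so path counts are preserved — and each clade is dated
from the MRCA of its subset tips; clades reduced below two subset tips are
reported undated. `L` defaults to the variant matrix's analysable length
and can be overridden per subset.

## Frequency surfaces

Point samples (lat, lon, n, k) are interpolated with a distance-decay
weight inside a radius of influence: w(d) = ((R−d)/R)^p with R = 1,500 km
and p = 3 by default, distances by haversine (Earth radius 6,371 km). The
"weight function 3" convention is implemented as the exponent of this
truncated-cone kernel; because kernel families differ between gene-geography
programs, an inverse-distance d^−p alternative is provided. The weighted
mean is exact at a sample's own coordinates, bounded by the contributing
frequencies, and NO-DATA where no sample lies within the radius.
Frequencies are always computed from (k, n), never from pre-rounded
percentages. Grid default 0.5°, bounding box = samples padded by the
radius.

## STR branch prediction

The mutation-step distance between haplotypes sums |repeat difference| over
shared markers; multi-copy loci are compared as multisets under minimal
assignment (sorted-order matching; for unequal copy numbers the shorter
multiset is matched optimally and extra copies are free) — whether real
panels count palindromic multi-copy loci is not standardised, so this
choice is explicit and configurable at the data level. Queries are assigned
the branch of the nearest SNP-confirmed reference when the distance is
below the panel-dependent threshold: strictly fewer than 6 steps for
67/111-marker panels, at most 1 step for 12/37-marker panels. Ties across
branches leave the query unassigned with a tie report. A generic rule
engine (per-marker allowed ranges, minimum matched markers) provides
haplogroup gating of the kind used to pre-screen likely carriers from
published repeat-count signatures.

## Study-scale demonstration (`qphylo.study`)

`study_genealogy` encodes a 48-tip dated genealogy shaped like a rare-
haplogroup study: one outgroup, five principal branches arising 5–7 ky ago
from a 15.1 ky root, a young (1.6 ky) expanding subclade, and singleton
deep branches. Within-clade structure is star-like so each named clade's
TMRCA is exactly its listed age. `study_config` adds three platforms
(deep full-range "bigy", a longer-range and a shorter-range alternative)
with 30 samples on the deep platform forming the dating subset, and a base
error rate of 0.002. `run_study` executes the full chain and returns the
headline statistics. At L = 9.34 Mb and μ = 0.78e-9 this produces
~1,600–1,800 variable positions, root-leaf counts of ~110 ± 10 and a root
age of ~15,100 ± ~1,200 (SE) years per replicate — the same scale as the
published analyses this design emulates.

The pipeline's large tree search uses NNI-only hill-climbing with 2
restarts: at this signal strength stepwise addition plus NNI recovers every
supported split, and the O(n²) SPR sweep would dominate the runtime. SPR
remains on by default for general use and for the optimality checks at
small n.

## Numerical and design notes

- Entropy windows are computed in bounded-memory chunks (1 Mb) so
  megabase references do not allocate gigabyte intermediates.
- Unique-event site positions are drawn by rejection sampling, then
  shuffled so the partition across branches is exchangeable.
- The heuristic search's co-optimal set is deduplicated by bipartition
  sets, so rootings/rotations of one topology count once.
- Matrix calling is vectorised (pandas group aggregation); the scalar
  `call_sample_site` is the reference implementation and the two are
  cross-checked in the tests. Majority-allele ties break toward the
  alphabetically first base in both paths.
- Degenerate inputs: empty matrices are returned with diagnostics rather
  than raised; zero-variable-site searches return all topologies with an
  "unresolved" flag; singleton clades raise for rho and are reported
  undated in tables.

## Known limitations

- The MP search is heuristic above 9 taxa; optimality is verified
  experimentally (exact-search equivalence at 7 taxa), not guaranteed.
- The mutation mapper produces one most-parsimonious reconstruction, not
  the full MPR set; alternative placements of homoplastic changes are not
  enumerated.
- The rho clock assumes a constant rate and complete, unbiased detection of
  mutations within `L`; platform-restricted subsets mitigate, but cannot
  remove, detection bias in real data.
- Surface interpolation ignores coastlines, projections and anisotropy;
  it is an analysis artefact, not cartography.
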