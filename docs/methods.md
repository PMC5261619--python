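# Methods

## Scope and assumptions

The pipeline starts from *annotated* inputs: a quartet VCF with
per-sample genotype, depth, genotype quality and supporting base
quality, plus an annotation sidecar carrying gene symbol, consequence
class, three population allele frequencies, a conservation score and a
deleteriousness category. Read alignment, variant calling, relationship
checking and annotation-database lookups are upstream of this package
and are modeled as input columns. Likewise the probe tables for CNV
calling are already normalized log2 ratios.

## CNV analysis

Segmentation is a deterministic threshold-run rule: maximal runs of at
least `min_probes` (default 3) consecutive probes on one chromosome all
above `gain_thr = +0.3` (strictly) or all below `loss_thr = −0.3`
become one segment spanning the first to last probe position.
Commercial aberration-detection algorithms used on these arrays are
proprietary; the run rule keeps the stated ±0.3 contract and is exactly
testable. Consequences: called boundaries snap to probe positions, and
a single discordant probe splits a segment — acceptable at the
simulated probe density (planted segments span ≥ 10 probes).

Inheritance is classified on copy-number evidence only: a child segment
is *inherited* when a same-state parental segment reciprocally overlaps
it by ≥ 0.5 (a common CNV-concordance convention; configurable),
otherwise *de novo*. Note that a parental **balanced** translocation is
copy-neutral and invisible to this rule, so segments transmitted as an
unbalanced derivative correctly classify as de novo gains/losses even
though the rearrangement is inherited.

The retention filter keeps segments that are de novo AND strictly
larger than 100 kb AND overlap at least one gene AND carry a
pathogenicity label in {uncertain, likely_pathogenic, pathogenic}.
Labels come from an input table (clinical-database lookup is out of
scope); a missing label reads as `unlabeled` and is filtered out.
Coordinates are 1-based inclusive internally; BED input is converted on
read. Segment length is `end − start`, which reproduces the printed
sizes of the two translocation-derived segments (4,601,791 bp → "4.6 Mb",
752,072 bp → "752 kb").

## Variant filter cascade

Four filters, each a pure function returning a subset:

| filter | rule | default |
|---|---|---|
| qc | all four members: depth ≥ 20 reads, GQ ≥ 20, base quality ≥ 30 | inclusive bounds |
| rarity | every *present* frequency ≤ maf_max; all-missing = novel, kept | 0.01 |
| consequence | keep nonsynonymous SNV, frameshift/non-frameshift indel, stop gain/loss, splicing | — |
| deleteriousness | conservation ≥ 2 (when present) AND damaging category (when present) | conjunctive |

Interpretation choices: the base-quality bar is stored per genotype
(`BQ`) because the phrasing of sequencing QC is ambiguous between
mapping and base quality; the depth rule is implemented as *require*
≥ 20× in all members; the conservation and category criteria are
conjunctive when both annotations are present (configurable); novel
variants pass rarity by design. The three annotation filters commute
(asserted by test); qc does not interact with them.

Inheritance per child: *de novo* iff the child carries the alternate
allele and both parents are homozygous reference; otherwise the class
follows which parent carries it. Male X genotypes outside the
pseudoautosomal regions (hg19 PAR coordinates in `quartet.py`) are
single-allele; an alt there with a carrier mother is *hemizygous_x*,
and a paternal-only X alt in the son is a Mendelian inconsistency.
The partition routes de novo and hemizygous-X variants to their own
lists; remaining child-carried variants split into shared (both
siblings) and exclusive (exactly one). The shared+exclusive total is
the "rare inherited heterozygous" count the report prints. (Published
summaries of this design disagree between 316/128/86 and 312/125/85
totals; the package reports its own computed counts.)

## Network prioritization

Per sibling, the gene universe is the union of CNV genes, shared-variant
genes and exclusive-variant genes (the male's exclusive set includes
de novo and hemizygous-X genes), each intersected with the
brain-expressed gene list when the filter is enabled. The interaction
graph is the induced subgraph on that universe keeping edges with
combined confidence ≥ 0.4; scores above 1 are assumed to be on the
0–1000 database export scale and divided by 1000. Isolated universe
genes remain as degree-0 nodes so the summary statistics (average
degree 2E/N, percent of nodes with ≥ 1 edge) are comparable with
database-reported values. Both ratios are *truncated* to two decimals
because the reference outputs they are compared against truncate
(32/61 connected prints as 52.45%, not 52.46%).

Centralities are computed on the biggest connected component only
(ties broken by lexicographically smallest node list): degree;
unnormalized betweenness over unordered pairs; closeness
`(n−1)/Σ distances`; local clustering. The two prioritization scores:

- brokering `(deg/(n−1))·(1−clustering)` — this closed form reproduces
  all fifteen published per-gene brokering values from their printed
  degree/clustering inputs at component sizes 82 and 68, which the test
  suite adopts as its primary worked-example contract;
- bridging `betweenness × bridging coefficient`, with
  `BC(v) = (1/deg v)/Σ_{u∈N(v)} 1/deg u`. Published bridging values
  cannot be re-derived without the original edge list, so validation is
  oracle-based: on two cliques joined by a single gene, that gene must
  attain the strict maximum.

Roles use the 95th percentile (numpy linear interpolation between order
statistics, boundary inclusive ≥) of each score within the component.
With all scores tied, every gene qualifies — the degenerate case is
defined rather than an error. Degree-0 universe genes are not in the
component and hence not in the percentile denominator.

## Enrichment

Edge enrichment supports two nulls. The closed-form *density* null puts
`expected = C(k,2)·E_bg/C(N_bg,2)` and takes the upper tail of a Poisson
count at that mean. The default *permutation* null draws equal-size
uniform gene sets from the background node set and reports the
pseudo-count p-value `(1+x)/(1+B)`, which is never exactly zero and is
exactly valid for any B. Because the edge-count statistic is discrete,
the permutation p-value is slightly conservative (superuniform) when
ties with the observed count are likely; the null-uniformity test uses
a background (120 nodes, density 0.35, sets of 25) dense enough that
the tie mass is negligible. Over-representation is the one-sided
hypergeometric upper tail per category with Benjamini–Hochberg
adjustment (statsmodels), categories intersected with the universe.
Published enrichment p-values from web services are not reproduction
targets: their contemporaneous background networks and nulls are not
available; only the statistical machinery is in scope.

## Synthetic generator

`QuartetSpec` defaults encode the study conditions: 2000 variants, mean
depth 35× (the reported on-target mean), GQ centered at 60, planted
partition 102/125/85, 3 hemizygous-X variants, de novo rate 5×10⁻⁴ per
child per variant (≈ one expected de novo across the sibship, matching
the single reported de novo), rarity bound 0.01, and a CNV plan placing
a terminal 4p gain (chr4:71552–4673343) plus terminal 8p loss
(chr8:176814–928886) in both children with copy-neutral parents — the
unbalanced-translocation pattern. Probe noise is Normal(0, 0.1) with
gains centered at +log2(3/2) and losses at −1; spacing 25 kb keeps
every planted segment above 10 probes so threshold-run recovery is
deterministic. Declared chromosome lengths are shortened desk-scale
stand-ins, not genome builds.

Each noise variant violates exactly one named filter (cycled through
depth, GQ, base quality, rarity, consequence, conservation, category),
giving every filter a single-cause fixture and making planted-truth
recovery exact rather than probabilistic. "Novel" is encoded as missing
frequency, never zero. The network generator defaults to a two-block
topology whose planted bridge is the only inter-block connection, with
real edges ≥ 0.4 and decoys below; network genes are strided across the
gene pool so both siblings' universes and the background all overlap it.

What the generator does *not* emulate: linkage disequilibrium, locus-
dependent coverage, annotation errors, multi-allelic sites (the reader
decomposes them, but the generator emits bi-allelic records), segmental
duplications and CNV breakpoint uncertainty, and the degree
distribution of a real interaction database. Passing tests therefore
demonstrate correctness of the *filtering and prioritization logic*
under separable signal, not robustness to real-data artifacts.

## Problem sizes and determinism

Unit tests run a scaled-down quartet (300 variants, 30/25/20 partition);
the acceptance-style checks run the study-scale defaults (2000 variants,
102/125/85), brute-force centrality enumeration on 200 random graphs of
≤ 12 nodes, 1,000 permutation-null replicates at B = 199, and exhaustive
hypergeometric enumeration for universes ≤ 20 — all chosen so the whole
suite completes in well under a minute. All randomness flows from
`numpy.random.default_rng` seeded by the spec/config seed; identical
seeds give byte-identical output files.

## Known limitations

- The run-based segmenter has no statistical aberration score; it is a
  transparent stand-in honoring the ±0.3 thresholds.
- Compound-heterozygote CNV/SNV logic and inherited-CNV analysis are
  out of scope (the latter deliberately excluded from the analysis
  design).
- The percentile rule can select slightly more than 5% of genes under
  ties; the tie handling of the original analysis is unknown, so the
  rule here is pinned (linear interpolation, inclusive boundary) and
  configurable rather than reverse-engineered.
- Identifier mapping between protein and gene namespaces is assumed
  done upstream of the edge list.
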