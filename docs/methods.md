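# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic data does and does not emulate,
and the design decisions taken where more than one reasonable reading
existed.

## Local alignment and E-values

Protein homology search is an exact affine-gap Smith–Waterman over
BLOSUM62, not a seeded heuristic: at the panel sizes this package targets
(hundreds to a few thousand proteins) exactness is affordable and removes
heuristic-sensitivity from every downstream count. A gap of length *k*
costs `open + k·extend` with defaults open 11 / extend 1, the standard
pairing for BLOSUM62. Hit significance uses the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with the published gapped-BLOSUM62 constants
λ = 0.267, K = 0.041 and threshold 10⁻⁴; both constants are configurable
since they are statistical calibrations, not laws.

Because the family rule judges *coverage over all HSPs*, the aligner
returns suboptimal HSPs as well: after the optimal local path is traced,
the residues it used are masked on both sequences and the DP re-run,
until the next optimum fails the E-value threshold (or `max_hsps` is
reached). Masked residues cannot align but can be skipped by gaps, so
successive HSPs are non-overlapping in their matched columns.

Identity and similarity fractions are computed over gap-free aligned
columns only — "similar" means a residue pair with a positive BLOSUM62
score, so identical residues are always similar and
`identity ≤ similarity` holds on every hit. Intervals are 0-based
half-open internally and 1-based inclusive in tabular reports. The
ambiguity code X is rescored to 0 against everything (unknown residues
neither help nor hurt); B and Z keep their BLOSUM62 values.

The test suite checks the kernels against Biopython's `PairwiseAligner`
(an independent exact-DP implementation) configured with identical
scoring: top local scores agree exactly on hundreds of random pairs, as do
global scores.

## Family construction

Two proteins enter the same family when (i) all their HSPs pass the
E-value gate, (ii) the union of HSP spans covers **at least 80%** of the
protein length on **both** sides, and (iii) the length-weighted mean
similarity fraction across HSPs is **strictly over 50%**. Decisions taken
where the rule left room:

* Coverage is required on both partners. Families are meant to group
  full-length homologs; the symmetric rule is the stricter, reproducible
  reading and prevents a short protein from chaining into a long one's
  family through a domain hit.
* Multi-HSP similarity is aggregated as the mean of per-HSP similarity
  fractions weighted by gap-free column counts — the natural "fraction of
  aligned residue pairs that are similar" over the whole pair.
* Families are single-linkage connected components of the edge graph.
  No tree reconciliation or family splitting is attempted; components are
  the family definition here.
* Self-hits never form edges; within-strain edges are allowed, so paralogs
  share a family (their copy number is visible in the presence matrix).

Boundary semantics are load-bearing and tested: coverage exactly 0.80
passes ("at least"), similarity exactly 0.50 fails ("over").

The all-vs-all driver optionally prescreens pairs with a shared-k-mer
filter (k = 5, sampled with stride 3, one shared word required) before
running the DP. For the divergences where family edges are possible at
all (pairwise identity well above 50%), homologous pairs share dozens of
5-mers and the screen is lossless in practice; pairs near the decision
boundary of the similarity rule could in principle be missed, so the
screen can be disabled (`prefilter_k=None`) for an exhaustive run. The
same screen is available to the paralog scan.

## Pangenome algebra

Presence means member count ≥ 1; copy number never affects the set
algebra. `core` is presence in every group strain, `pan` presence in at
least one, and the specific core of a focal group is its core minus the
pan of all other groups. Lost families between a retained and a reduced
phenotype group require presence in **every** retained strain and absence
from **every** reduced strain — the strict reading of "families found in
the retained genomes without orthologs in the reduced genomes". A
`min_retained_strains` switch relaxes the first condition for exploratory
use; the default keeps it at the group size. Outputs are ordered
lexicographically by family id so every artifact is byte-reproducible.

## Paralogy and copy-number classes

A paralog call between two proteins of the same genome requires the best
local hit to cover **more than 50%** of the query's full length with
**more than 30%** identity over its aligned columns (both strict; exact
50% coverage or exact 30% identity is rejected). Only the
similarity-based rule is implemented; pathway-co-membership evidence from
external databases is out of scope, which is why the packaged annotation
table carries its curated paralog column — the published statistics remain
reproducible from the labels without re-querying any service. When a lost
family has several retained-genome members, every member is queried and
the union of calls is used; a family is "several copies" as soon as any
member has a paralog.

The lost-family summary reports COG-letter percentages to one decimal and
the SP/TM and with-paralog shares to the nearest integer percent — the
precision these statistics are conventionally quoted at.

The >30%-identity bar sits in the alignment twilight zone: a short query
can reach ~33% identity over half its length against an unrelated protein
through a gapped local alignment that is nevertheless statistically
significant (E ≈ 10⁻⁵). On random decoys this happens at roughly one
event per 5×10⁴ scanned pairs, which is the order of comparisons a
full-panel paralog scan performs — so several-copies counts on synthetic
panels can occasionally exceed the planted number by one such chance
call. This is a property of the rule, not of the implementation, and the
calls it admits are exactly the weak-homology calls it is designed to
admit on real data.

## ANI and species delineation

ANI follows the classical fragment scheme: the source genome is cut into
consecutive non-overlapping 1020-bp fragments (remainder discarded), each
fragment is aligned to the target, and fragments are retained when the
best alignment reaches ≥ 30% identity over ≥ 70% of the fragment; the
direction's ANI is the mean identity of retained fragments. Nucleotide
scoring is match +2 / mismatch −3 / gap open 5 / extend 2. To avoid a
full fragment × genome DP, each fragment is first *placed* by 16-mer
diagonal voting (sampled every 8 bp) and then aligned exactly within a
±64 bp window around the winning diagonal; the seeding only chooses where
to align — identity always comes from the DP. A fragment with no shared
16-mer is dropped, which is also what makes unrelated genome pairs come
out "undefined" rather than spuriously low.

Two genomes are conspecific when the mean of their two directional ANI
values reaches 95%; species are connected components of that graph,
labelled by their smallest member id. Directional values are kept and
reported separately because real assemblies give asymmetric ANI.

## Identity matrices

The matrix stage replaces a multiple alignment with all-pairs global
(Needleman–Wunsch, end gaps penalized) percent identity; at the
within-family identity levels the analysis cares about (> 77%), pairwise
and MSA-projected identities agree closely. Percent identity is
identities over gap-free aligned columns, reported to two decimals; an
alternative denominator including gap columns is selectable by flag. The
packaged AgD matrix is consumed as printed values (lower triangle mirrored
to a full symmetric matrix), and its summary statistics — mean 85.35 over
the 66 distinct pairs, minimum 77.15 — are computed from the table, not
resimulated.

## GC read filter

Reads with G+C fraction ≤ 54% are removed (boundary removed), emulating
the pre-assembly sort that separates plant contamination from a ~71%-GC
actinobacterial genome. GC is (G+C)/(A+C+G+T) with N excluded from the
denominator; empty or all-N reads are removed with a warning rather than
an error.

## Synthetic pangenomes: what they emulate and what they don't

The generator's default panel is the study condition the pipeline is
validated under: a focal cluster of 12 strains split 6 Sp+ / 6 Sp−, plus
two 2-strain outgroup clusters; 9 focal-specific core families; 88
families present in every Sp− strain and absent from every Sp+ strain;
24/88 of each family class carrying a duplicated copy (the several-copies
share of the annotation table); 7 strain-specific proteins per strain.
Two quantities are not dictated by any reported condition and were fixed
once at desk-scale-realistic values: 40 universal families and protein
lengths uniform in 120–300 aa.

Each family descends from one uniform-random ancestor; every member is the
ancestor with exactly `round(d·L)` positions substituted (default
d = 0.05), each to a uniformly drawn different residue. Substitutions
only — no indels — so planted identity is analytically exact without any
alignment: a pair of members differs at most at `2·round(d·L)` positions.
Note the guaranteed per-pair identity bound is `1 − 2·round(d·L)/L`,
which rounding can place marginally (≤ 1/L) below the nominal `1 − 2d`.
Strain-specific decoys are i.i.d. random sequences whose expected identity
to anything (~5%) sits far below every threshold. Genome pairs for ANI
carry exactly `round(rate·length)` substituted positions.

Consequently the synthetic data does **not** emulate: indels and length
variation within families, domain shuffling or partial homology,
amino-acid composition bias, codon structure or GC content of proteins,
gene gain/loss along a phylogeny, or horizontal transfer. Passing the
planted-truth tests therefore demonstrates that the inference chain is
correct when homology is full-length and well separated from noise — it
does not certify behaviour on borderline domain-level homology, which is
exactly where the configurable thresholds matter on real data.

All generators are deterministic in their seed, and the pipeline contains
no other randomness, so a fixed configuration reproduces every artifact
byte for byte.

## Problem sizes and numerical notes

The validation suite runs the full pipeline on five independently seeded
default panels (~1400 proteins, ~250 families each), compares the aligner
with the exhaustive-DP oracle on 200 random pairs of length ≤ 30, and
measures ANI on 102-kb genome pairs at substitution rates 1–10%, where
recovered ANI lands within 0.06 points of 100·(1 − rate) — the residual
coming from local-alignment end trimming, not from the estimator.
Tie-breaks in the DP tracebacks prefer the match state, and hits sort by
(E-value, −score), so all outputs are deterministic. Degenerate inputs
(empty panels, empty sequences, all-zero matrix rows, overlapping strain
groups, duplicate ANI pairs) raise informative errors rather than
propagating silently.

## Known limitations

* Connected-component clustering chains families through any single
  qualifying edge; there is no family splitting step.
* Karlin–Altschul constants are fixed per scoring scheme, not estimated
  from the score distribution of the actual search.
* The ANI seeding step assumes enough shared 16-mers for placement, which
  holds below ~20% divergence but will drop diverged fragments before the
  retention rule ever sees them.
* COG letters, localization labels and curated paralog lists are consumed
  as given; the package never predicts them.
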