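# Methods

This note documents the models and procedures implemented in `motifrecruit`,
the parameters that matter, the design choices made where the problem was
genuinely open, and what the synthetic benchmark does and does not show.

## Recruitment model

Two species are compared through a 1:1 ortholog map. For each motif and each
ortholog pair, presence is called on the 3 kb of sequence upstream of the TSS
(clipped at chromosome edges, reverse-complemented for minus-strand genes);
"present" means at least one occurrence on either strand. The four per-pair
statuses are gained_in_C4, lost_in_C4, shared and absent; only gained_in_C4
motifs are recruitment candidates, since the question is what the C4 lineage
acquired. Donors are the path-length-1 neighbours of the C3 ortholog in the
C3 GRN whose promoter carries the motif; an event requires at least one.
Mode classification looks up each donor's C4 ortholog: any retention →
copy_paste, complete loss across mapped donors → cut_paste, unmapped donors
without retention → undetermined. Mode is an interpretation layered on the
presence data, not an independent measurement, and is labelled as such in the
output.

## Motif scanning

Consensus scanning supports the full IUPAC alphabet; `N` in a promoter
matches nothing. Forward and reverse-strand hits with the same footprint
(palindromes) are reported once, on the plus strand, because downstream logic
is presence/absence. PWM scanning scores log-odds against a background
(uniform by default, configurable) and reports windows reaching a fraction
`tau` of the maximum achievable score; `tau = 0.8` is the default, standard
for PWM practice. Offsets are 0-based within the promoter, with a recorded
mapping to genomic BED6 coordinates.

For degraded motif instances (the mutation benchmark below) the consensus is
converted to a soft PWM (consensus base 0.91, others 0.03) and scanned at
`tau = 0.7`, chosen so that one substitution in a ~10 bp motif is tolerated
but two are not; this is the package's operationalisation of
mutation-tolerant scanning.

De novo discovery ranks k-mers (k = 6..12 by default) by one-sided
hypergeometric enrichment of per-promoter presence in a foreground set versus
a background set, Bonferroni-corrected over the 4^k candidates per width. It
is a deliberately transparent enumerative stand-in for dedicated discovery
tools; it has no Markov background model and cannot find gapped motifs.

## GRN inference (PCA-CMI)

For jointly Gaussian variables, MI(X,Y) = ½·ln(|C(X)|·|C(Y)|/|C(X,Y)|) and
CMI(X,Y|Z) = ½·ln(|C(X,Z)|·|C(Y,Z)|/(|C(Z)|·|C(X,Y,Z)|)), with |C(·)| sample
covariance determinants; all values are in nats. Both estimators are
non-negative on non-degenerate inputs (Fischer's inequality) and raise a
distinct degenerate-signal error on singular covariances (constant genes,
exact affine dependence).

The skeleton search starts from the complete graph, removes edges with
MI < θ at order 0, and at order L ≥ 1 removes an edge when the maximum CMI
over all size-L subsets of the two endpoints' common neighbours stays below
θ. Defaults are θ = 0.03 nats and max order 1, both exposed. Two numerical
choices: adjacency is frozen within each sweep (removals take effect between
sweeps), so the outcome does not depend on edge enumeration order; and sweeps
repeat at each order until stable. Zero-variance genes are excluded with a
warning.

Known limitation, established with the exact population covariance rather
than samples: on dense-ish random networks (30 genes, edge density 0.1) with
±1 weights and unit noise, the procedure tops out around skeleton F1 ≈ 0.6
at the defaults and ≈ 0.78 over any (θ, order ≤ 3) setting. Two structural
causes: a direct edge can be masked at order 0 when a parallel indirect path
exactly cancels its correlation (±1 weights make exact cancellation common),
and gene pairs sharing two or more parents stay dependent given any single
conditioner, so order-1 conditioning cannot separate them. Sparser networks
and weight distributions without exact cancellation behave much better (the
three-gene chain is recovered exactly). This ceiling is a property of the
method under those generating conditions, not of the implementation — the
test suite pins the implementation to a brute-force transcription on small
graphs.

## Markov clustering

Standard MCL on the column-stochastic transition matrix with unit self-loops:
expansion (matrix squaring) alternating with inflation (elementwise power,
default 2.0, then column renormalisation), entries below 1e-6 pruned,
convergence when the largest elementwise change drops below 1e-8 (error after
100 iterations). Communities are the connected components of the converged
non-zero structure, which always partition the node set. The GRN's final
(C)MI scores are used as edge weights by default; a binarised mode exists.

## K-means with FOM

For each candidate k, every condition is held out in turn: genes are
clustered on the remaining conditions and the figure of merit is the root
mean squared deviation of the held-out condition around its cluster means,
summed over conditions and adjusted by √(n/(n−k)). The number of clusters is
chosen where the curve stops improving: a k = 1 baseline anchors the curve's
total range, and the chosen k is the smallest whose improvement at k+1 falls
below 10 % of that range (ties and flat curves resolve to the smallest k).
K-means uses k-means++ with 10 restarts and a fixed seed.

## TE evidence

The distance statistic is signed and dimensionless:
d = (donor start − acceptor start)/chromosome length, using annotated gene
start coordinates; |d| < 0.1 (strict) on the same chromosome is proximal,
different chromosomes are never proximal. Because only one species'
chromosome table is assumed, the acceptor is represented by its C3 ortholog's
coordinates, and this convention is recorded in the output.

TE-to-promoter alignment is iterated Smith–Waterman with affine gaps
(match +1, mismatch −2, first gap base −5, extension −2), both TE
orientations; after each reported alignment the promoter interval is masked
and the search repeats until the best remaining alignment fails the gates
(identity ≥ 80 %, ≥ 20 alignment columns). These gates replace an E-value
model; they are score-scheme-dependent and exposed as parameters. Whether a
TE "contains" a motif is decided by the same scanner used on promoters, for
consistency. An event is TE-supported when at least one donor shows a motif
occurrence entirely inside a TE–promoter alignment (the required count is
exposed through the evidence table).

## Binding affinity (MR / relative MR)

An element matches a TF's PWM when its best ungapped log-odds placement —
both strands, every offset of the shorter within the longer, scoring only
overlapped columns — reaches `tau` (default 0.8) of the best achievable score
on the same overlap. "Matched" therefore has one free parameter; the
statistic of interest is the contrast between the motif set and random
same-length elements, which is insensitive to reasonable `tau`. IUPAC codes
in elements score as the mean over their expansions; elements of length ≤ 5
are filtered out and reported, never silently dropped. The null pools, per
TF, 1,000 i.i.d. background sequences per motif (uniform by default); a null
MR of zero with a positive motif MR yields +inf (enriched), both zero is an
explicit undefined-result signal. Enrichment is strict (> 2). TRANSFAC count
matrices get a +0.01 pseudocount per cell before conversion to
probabilities. A per-motif (non-pooled) null is available, but pooling is
the default because MR is defined on a set.

## Synthetic data

The generator emulates the study's inputs at desk scale: two species, two
300 kb chromosomes, 20 genes each (40 ortholog pairs — the size of the
motivating analysis), 3 kb promoters, i.i.d. background sequence with
configurable composition (default mildly AT-rich, 0.3/0.2/0.2/0.3), 10
motifs of 10–14 bp (all above the length-5 filter), a TE library of 12
elements (150–400 bp; classes cycle retrotransposon / class II / MITE), a
planted GRN (Erdős–Rényi, density 0.08, ±1 weights) and linear-Gaussian
expression (200 samples, unit noise). Ten recruitment events are planted by
default, half TE-mediated and half bare-motif, half copy and half cut.
Orthology is simulated as identical gene indices and coordinates; gene
layout keeps neighbouring promoters disjoint so a planted insert can never
leak into another gene's promoter. Donors are drawn one-to-two gene slots
from the acceptor, so most planted donors are proximal under the 0.1 rule.
Inserts overwrite promoter background (coordinates never shift); TE-mediated
events insert the whole TE copy, with the motif embedded at least 20 bp from
either TE end, into both the donor C3 and acceptor C4 promoters. A per-base
mutation rate (default 0) degrades each planted motif instance
independently. Chance occurrences of an event motif in its acceptor's C3
promoter, or in a cut donor's C4 promoter, or in a non-designated TE, are
scrubbed by redrawing that sequence (bounded retries, then an error); other
chance occurrences are left in place, as they would be in real data.

What passing the benchmark shows: the detection logic, TE-overlap test and
enrichment statistic recover exactly what was planted under the model's own
assumptions. What it does not show: robustness to real promoter evolution —
indels and rearrangements (coordinates here never shift), paralogy and
imperfect orthology, TE decay, compositional heterogeneity, or GRNs whose
edges are not linear-Gaussian.

## Benchmark problem sizes

The shipped tests and the acceptance script use n = 10,000 samples for the
closed-form MI check, n = 5,000 for chain recovery, 30 genes × 500 samples
× 10 seeds for the planted-network sweep, 1,000 random (promoter, motif)
pairs for scanner-oracle equivalence, the default 40-pair dataset (10 seeds
for the mutation sweep), exhaustive 4^6 enumeration for the null match
probability, and 10 planted-TF replicates at 1,000 nulls per motif.
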