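# Methods

This note documents the models, rules and numerical choices behind
`generosion`, in the order the pipeline runs.

## Ortholog classification

Each ancestral ORF is paired with a derived locus — by shared gene id for
synthetic data (where pairing is known exactly), by best-scoring locus for
real assemblies — and aligned with an optimal local affine-gap aligner
(match +1, mismatch −2, a gap of length *L* costs 5 + *L*; implemented on
Bio.Align.PairwiseAligner). Classification follows a three-way rule:

- **intact** — alignment spans >99% of the ancestral ORF (>90% for ORFs
  shorter than 300 nt), and the alignment contains no frameshifting indel
  (length not a multiple of 3), no premature stop codon in the ancestral
  frame, and no IS-element insertion. An *in-frame* internal indel does not
  disqualify a gene: the rule is about reading-frame integrity and span.
- **absent** — no locus aligns above a coverage floor of 0.20 of the
  ancestral length. The floor separates vestigial fragments from true loss
  by large deletion; it is configurable because no principled universal
  value exists.
- **pseudogene** — everything else.

Score ties in the alignment are broken toward the path with the most matched
positions (a 1e-6 match bonus during the DP; reported scores are recomputed
exactly under the nominal integer scoring, which the bonus can never
reorder). This matters at disrupted gene termini: without it, an optimal
local alignment may "trim" a frameshifted end instead of opening the gap,
hiding the frameshift and, for short genes, leaving coverage just above the
90% threshold.

## Mutation-event extraction

Disrupting mutations fall in six categories: internal insertion, internal
deletion, 5′ deletion, 3′ deletion, nonsense substitution, IS-element
insertion.

- Unaligned ancestral termini and deletions touching the first/last
  ancestral codon are terminal (5′/3′) deletions; other deletions are
  internal.
- Nonsense calls project the derived sequence onto the ancestral codon
  frame, using only codons whose three reference positions align gap-free,
  and require a stop codon in the derived copy where the ancestral codon is
  not a stop. This makes the call independent of frameshifts elsewhere in
  the gene: a frameshifted downstream region still aligns base-for-base, so
  it contributes no spurious stops.
- A kilobase-scale IS insertion is never bridged by an optimal local
  alignment under this scoring (the gap would cost more than the flanking
  matches earn), so catalog IS copies are excised from the derived locus
  *before* alignment — located by infix edit distance ≤ 20% of the IS length
  (edlib) — and logged as is_element events. Insertions already inside an
  alignment are also checked against the catalog (≥80% identity over ≥80%
  of the catalog length).

Mutation densities divide a pseudogene's event count by its length in kb,
either the ancestral ORF length or the current (observed) locus length;
the contrast between the two measures how much large deletions have erased.
The Poisson diagnostic reports the variance-to-mean ratio of per-pseudogene
event counts with the dispersion statistic (n−1)·s²/x̄ ~ χ²(n−1).

## Composition and divergence

GC2 is the G+C percentage at second codon positions, GC4 at third positions
of the eight fourfold-degenerate codon families (CTN, GTN, TCN, CCN, ACN,
GCN, CGN, GGN — two-/three-fold families and stop codons never contribute),
GCI over intergenic positions. Degeneracy is assigned from the *ancestral*
codon only, since the ancestral genome is the fixed template both derived
genomes are compared against. Divergence is the uncorrected p-distance over
class sites projected through gap-free alignment columns, pooled across
genes, computed separately for intact genes and pseudogenes. p-distance is
used because at the few-percent divergences this method targets,
multiple-hit corrections change the third digit; a correction flag is the
natural extension point. Ambiguous bases are excluded from every G+C
denominator.

Divergence time is t = d₄ / (2 μₛ g): d₄ the pairwise fourfold-site
divergence, μₛ a synonymous rate per site per year, the factor 2 for the two
diverging lineages, and g an optional generations-per-year rescaling
(default 1) for clocks calibrated in other units. With the printed inputs
d₄ = 0.043 and μₛ = 2.2×10⁻⁷ the unscaled conversion gives ≈ 97,700 years.

## Synthetic genome-erosion generator

The generator is the test harness for every downstream stage; its defaults
describe the study conditions the pipeline targets.

Ancestral genome: 4,000 ORFs, lengths gamma(shape 2, mean 950 nt) rounded to
codons (right-skewed, like real bacterial gene inventories), each ATG… stop
with no internal stop, on random strands, separated by spacers
(gamma, mean 300 nt, G+C 45%). Codon composition is controlled by two
knobs: G+C at the first two codon positions (50%) and at third positions
(60%), the latter equal by construction to the realized GC4 because stop
rejection only touches non-fourfold families.

Erosion of a neutral class of 1,500 genes (defaults): first,
`deletion_fraction` (10%) of the class is removed wholly (the "absent"
class); then `mutation_budget` (3,000) disrupting events are placed one at a
time — category drawn from `category_mix`, host gene drawn with probability
proportional to its *current* length. The default mix is the observed
weevil-symbiont spectrum (19/34/7/11/19/10% across the six categories).
Category is drawn before the host gene and the gene redrawn on placement
collisions, so realized category counts are exactly multinomial. Event
realizations: small indels of 1–10 nt with length mod 3 ≠ 0 (frameshifting
by construction); nonsense as a single substitution creating an in-frame
stop; terminal deletions removing uniform 10–50% of the respective end
(capped so at least max(30 nt, 25%) of the gene stays alignable — full loss
belongs to the deletion channel, not the truncation channel); IS insertions
copying a catalog sequence (default: one synthetic ~1 kb element with 25-bp
inverted repeats, generated from the seed). Events live in ancestral
per-gene coordinates with a 12-bp separation, so ground truth and extraction
correspond one-to-one.

Background substitutions: fourfold-degenerate third positions mutate at
`point_sub_rate_gc4` (default 0.043, the realized pairwise divergence scale
of recently host-restricted symbionts) with probability `at_bias` (0.75) of
moving toward A/T; all other coding positions at `point_sub_rate_gc2`
(default 0.01), multiplied by `neutral_gc2_multiplier` (3.0) in neutral
genes — the minimal two-rate model that reproduces dGC4 > dGC2 and
dGC2_Ψ > dGC2. Background changes that would create an in-frame stop are
skipped: premature stops are exclusively the logged nonsense channel, and
genes under selection are assumed purified of them. Intergenic sequence
mutates at the degenerate-site rate. All randomness flows from one config
seed through named child streams, so runs are byte-reproducible.

What the generator does *not* emulate: rearrangements and inversions (hence
no perturbed G+C-skew structure), IS proliferation dynamics beyond simple
insertion, selection regimes between "fully constrained" and "fully
neutral", and real codon-usage bias. Passing closed-loop tests therefore
demonstrates correctness of the classification/estimation machinery under
the stated stochastic model, not robustness to assembly error or alignment
ambiguity in real data.

## Monte Carlo estimation of genes under relaxed selection

Model: from the ancestral length inventory, a neutral class of *n* genes is
drawn uniformly; each cycle one disrupting mutation lands on a neutral gene
with probability proportional to its length (one mutation per cycle — the
estimator depends only on cumulative counts). Tracked quantities: the
pseudogene count (neutral genes hit ≥1 time), the size difference Δ between
disrupted genes and *all* still-undisrupted genes (neutral-but-unhit plus
constrained — matching how Δ is measured from a classified genome), and the
cumulative density (cycles per kb of summed neutral-class length; repeat
hits count, since the density numerator is cumulative mutations).

Closed forms used as oracles: after M placements, gene *i* is disrupted with
p_i = 1 − (1 − L_i/ΣL)^M; expected count Σp_i, expected class means are the
p-weighted and (1−p)-weighted length means. These ignore the (small)
within-run length changes caused by indels, which is why the oracle tests
drive the generator with a nonsense-only mix where lengths are constant.

Estimation: for each candidate *n* on a grid (default P\* … 2P\*, step 10),
replicate runs (default 25) locate the cycle at which the pseudogene count
first reaches the observed P\*; the estimator accepts the smallest *n* whose
replicate-mean Δ at that cycle is within ±10 nt of the observed Δ\*. The
implementation records exact first-hit cycles, equivalent to recording every
cycle, so count-matching has no discretization error; `record_interval`
still controls trajectory output. Δ at count-match increases monotonically
with *n* (larger classes are less saturated when P\* is reached, so size
bias is stronger), which makes the match well defined and lets the grid scan
stop early once Δ overshoots. The matched cycle divided by the neutral-class
kb is the deletion-corrected mutation density; the spread of per-replicate
estimates is reported alongside.

Accuracy: closed-loop recovery of a known class size of 1,500 (4,000 genes,
3,000-event budget) is unbiased to ~1% with a between-realization SD of
~65 genes. That SD is dominated by the observables themselves: with ~76% of
the neutral class visibly disrupted, the observed Δ moves by tens of bases
depending on which tail-of-the-distribution giant genes fell into the
neutral class, and the estimator faithfully inverts whatever Δ it is given.
Rare erosion realizations (one of twenty seeds in the test suite) therefore
land just past a ±10% bound.

## Problem sizes and other fixed choices

Test and acceptance runs use the full 4,000-gene scale for closed-loop
classification, spectrum recovery, GC4-target recovery and class-size
recovery, 600 genes for substitution-rate recovery, 300–400 genes for
replicate-heavy property checks, and 200 replicates for simulator-vs-closed-
form comparisons; these sizes put every statistical tolerance (3 SE / 3 SD /
99% CI) well above numerical noise. The estimator caps runs at 200,000
cycles; grid points that cannot reach P\* within the cap are reported
unreached. Genes whose length is not a multiple of three are excluded from
codon-based site classes with a warning. Degenerate inputs (empty site
classes, zero-length current loci, empty ortholog classes) propagate as NaN
rather than raising, except where the input is a contract violation (empty
sequences, all-zero event counts).
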