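# Methods

`ecfmap` reconstructs the regulon of an extracytoplasmic-function (ECF)
sigma factor from three evidence streams: in-vivo binding (ChIP enrichment),
promoter sequence (a gapped two-block motif), and expression dependence
(wild-type vs deletion-mutant induction). The concrete system it is shaped
around is the sigma-E cell-envelope-stress regulon of *Streptomyces
coelicolor*: a −35 tetramer (consensus AAC**C**) and a −10 pentamer
(consensus **C**GTCT) separated by a weakly constrained 16–17 bp spacer,
planted 10–400 bp upstream of target start codons in a ~72% GC genome.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Coordinates and the distance convention

All internal coordinates are 0-based half-open; GFF3 is read and written in
its native 1-based inclusive dialect, BED-like tables stay 0-based.
Upstream regions are always reported on the gene's *sense* strand, 5′→3′
toward the start codon, so every downstream motif operation is a
forward-strand operation regardless of genomic strand.

"Distance to start codon" is defined as the number of bases between the 3′
end of the −10 element and the first base of the start codon. Published
promoter tables rarely state their measurement point; this is a convention,
fixed once and used consistently by the readers, the scanner, and the
synthetic-data planting arithmetic, and exposed where a user needs to
re-derive distances under a different convention.

## Peak calling

Coverage is compared in fixed windows (25 bp default, the resolution of the
reported summit). For each window the ChIP count is tested against the
input-control count with the exact conditional test for a ratio of two
Poisson intensities: given the window total *n* = chip + control, the ChIP
count is Binomial(*n*, ρ) under the null, with ρ the ChIP share of the
combined library size. We use this form rather than a plug-in Poisson test
with the scaled control treated as a known mean because the plug-in version
ignores control noise and is severely anticonservative (roughly 35× the
nominal type-I rate at the 10⁻⁴ threshold in our calibration runs); the
conditional test is exactly calibrated, which the test suite verifies by
Monte-Carlo on an exchangeable null.

Windows passing both the p-value threshold (10⁻⁴ raw by default; optional
Benjamini–Hochberg behind a flag) and a minimum library-normalised
enrichment (2× default, computed with 0.5 pseudocounts) are merged when at
most one merge-gap apart; the best window (lowest p, then highest
enrichment, then leftmost) is the summit. No multiple-testing correction is
applied by default because the screen it reproduces used a raw threshold.

Summit flanks fed to motif discovery are oriented to the sense strand of
the nearest in-range gene (start codon within 400 bp downstream of the
summit, either strand). A forward-strand-only motif search requires this:
without orientation, sites upstream of minus-strand genes appear
reverse-complemented and the sampler can lock onto the reverse-complement
motif.

## Two-block Gibbs sampler

The motif model is one occurrence per sequence (OOPS): each input sequence
carries exactly one site, consisting of a width-4 block, a gap of 16 or 17
bp, and a width-5 block, on the forward strand. OOPS is appropriate here
because each peak region is expected to hold one promoter.

The sampler is the classic collapsed scheme: hold one sequence out, rebuild
the two count matrices (pseudocount 0.5 per cell) and the gap-length
distribution from the rest, and resample the held-out sequence's (start,
gap) from the posterior proportional to the product of position-specific
odds against the background times the gap weight. The background defaults
to the empirical mononucleotide frequency of the input set — at 72% GC a
uniform background would reward spurious GC-rich blocks.

Each restart runs a bounded sampling phase (50 sweeps by default, stopping
early when the motif score has not improved for 10 sweeps or assignments
pass through a full sweep unchanged), then a deterministic argmax sweep
repeated to a fixed point, which makes the reported optimum reproducible.
Forty restarts are run by default and the best kept; restart *k* always
consumes random stream *k* derived from the seed, so the best-of-*n* score
is monotone in *n* at fixed seed, and the whole procedure is bit-for-bit
deterministic given the seed.

Motifs are ranked by relative entropy: the summed per-column
Kullback–Leibler divergence (bits) of the pseudocounted column frequencies
from the background; gap columns contribute nothing. BioProspector's
objective function is not published in detail, so no equivalence with that
tool's output is claimed; relative entropy is the standard
information-content score for this model class.

## Promoter PWMs, scoring and scanning

A two-block PWM carries probabilities only for the −35 and −10 columns;
spacer columns are score-neutral. This makes spacer normalisation exact: a
promoter with a 17-bp spacer contributes identical block counts to the
16-spacer matrix and vice versa, so the 16- and 17-spacer matrices built
from one promoter set differ only in the gap used during scanning, and the
otherwise arbitrary choice of *which* spacer base to drop or duplicate
never arises. (A full-width matrix including spacer columns would have to
make that choice; we judged the score-neutral form strictly cleaner.)

Scores are summed log₂ odds against a mononucleotide background (default
72% GC), with probabilities (count + 0.5)/(N + 2). A score is reported both
raw and min–max normalised to [0, 1] using the per-column extreme odds, so
1.0 is the best-scoring block pair and 0.0 the anti-consensus. N bases
score at background (zero contribution). The *core* is the six columns of
highest information content (KL from background), ties broken 5′-first; for
the packaged validated set these are −35 positions 1–3 and −10 positions
3–5, i.e. the AAC / TCT cores.

Scan thresholds are calibrated on the PWM's own training sites: sensitivity
*s* sets the full-score threshold at the score quantile that keeps a
fraction *s* of the training promoters detectable, and core sensitivity
does the same over core scores. At the defaults (both 1) the thresholds are
the minima over the training set, so every training promoter is recovered
by construction — the property a "sensitivity = 1" dial is meant to have.
An exact-consensus core rule was considered and rejected: six of the 19
validated promoters carry at least one core mismatch, so any rule that
demands a perfect core contradicts the validated data it was built from.
The measured cost of the calibrated thresholds is a ~5% chance of a spurious
hit in a random 190-bp window of 72% GC background (Monte-Carlo, frozen in
the test suite); tightening is available through the sensitivity dials.

A scan evaluates every offset of every supplied PWM (hence both spacer
lengths), keeps hits passing both thresholds, restricts them to the
10–200 bp upstream window by default, and sorts by normalised score then
proximity to the start codon.

## Candidate promoters from peaks

The candidate screen formalises "conservation of AAC and TC": within 400 bp
upstream of a peak-associated gene (sense strand), a block pair is a
candidate when its −35 matches AAC at positions 1–3 with at most one
mismatch and its −10 contains TC at positions (3,4) or (4,5) with at most
one mismatch, with a 16- or 17-bp spacer. These defaults admit all 91 rows
of the packaged predicted-promoter table (a stricter published-looking rule
such as requiring a C at −35 position 4 would reject the AACG promoters in
that table). When a discovered motif is supplied, candidates are rescored
by its log-odds tables and the best per peak–gene pair kept. Peaks with no
gene in range are reported as orphans, not errors; a peak between divergent
genes may produce one candidate per gene.

## Expression classification

Expression matrices are per-gene median-normalised (log₂), making
classification invariant to gene-wise constants. Induction is the maximum
rise over the time course relative to t = 0. The qualitative
promoter-dependence scheme is operationalised with explicit thresholds:

- a gene is classifiable when WT induction ≥ 1.0 log₂ (twofold);
- dependence is *complete* when mutant induction ≤ 0.5 log₂;
- *none* when mutant induction reaches the WT level within ε = 0.1 log₂;
- *partial* otherwise.

Class I = one promoter and complete dependence; Class II = one promoter,
partial; Class III = multiple promoters (an external annotation joined from
a TSV — promoter counts are experimental evidence, not inferred here) with
at least partial dependence. These cutoffs are decisions, exposed in
config; agreement with curated labels on real data is not asserted — the
recovery guarantees below are statements about synthetic data with planted
structure.

## Conservation across a genome panel

Orthologs are found by reciprocal best hit over protein sequences, using an
affine-gap local aligner (BLOSUM62, gap open −11, extend −1) — the
desk-scale stand-in for a BlastP search; a precomputed ortholog table can
be supplied instead for large panels. Identity is matches over aligned
columns, coverage is the aligned span of the shorter sequence over its
length; pairs must be mutual best (ties broken by identity then id) and
pass 30% identity / 50% coverage. These cut-offs are conventional defaults,
config-exposed.

Each (target, species) cell is then: *absent* when no ortholog passes;
otherwise the ortholog's 10–200 bp upstream window is scanned with both
PWMs and the cell is the best hit's normalised score, or *no_site*. A
target is "conserved" when its site cells reach a minimum number of genomes
(default: 9 of a 19-genome panel). Conservation counts are monotone
non-increasing in the identity, coverage and sensitivity thresholds.

## Synthetic data: what it emulates, and what it does not

The generators produce, under one mandatory seed (all streams are
decorrelated per stage, byte-identical across reruns):

- **Genome**: one contig of i.i.d. mononucleotide background at 72% GC,
  alternating-strand genes (300 bp, ATG start codons, translated to the
  proteome) separated by 900–1300 bp intergenic gaps — wide enough that
  neighbouring upstream windows can never collide. Target genes (planted
  class mix: 20% I, 20% II, 10% III by default) receive one site drawn from
  the emission PWM at a distance uniform on [10, 400].
- **Sites**: columns drawn independently from the validated-set count
  frequencies (no pseudocount), gap 16 vs 17 at the 17:2 training odds,
  rejection-sampled until detectable at default scan settings. A draw that
  scores below every validated promoter is not a site in any operational
  sense, and keeping such draws would make the truth table wrong by
  construction. For the same reason the upstream screen windows are scrubbed
  of *chance* consensus matches (spurious scan-hit frames are re-randomised
  until clean), so "site present" in the truth table and "site detectable"
  coincide exactly. Real genomes contain chance matches; the measured ~5%
  per-window rate above quantifies what the pipeline would report on them.
- **ChIP**: control Poisson at depth 5 per base; ChIP rate rising over a
  triangular profile of half-width 150 bp centred on each site, peaking at
  10× depth. The triangular shape mimics the unimodal fragment pile-up
  around a bound site and keeps the summit window at the site; profiles of
  nearby sites merge additively. No read-level artefacts (duplicates, GC
  bias, shearing structure) are modelled.
- **Expression**: Normal(0,1) baselines; induced genes gain a step delta
  after t = 0 (WT delta uniform on [2, 4] log₂; mutant delta 0 for Class I,
  scaled by a partial-dependence factor of 0.3–0.7 for Class II and 0.4–0.7
  for Class III). Reported values are means of 2 replicate draws with
  per-replicate noise σ = 0.3, mirroring the replicate-combination step of
  standard microarray processing — the matrices the pipeline consumes are
  replicate-combined coefficients, not single arrays.
- **Species family**: per-species amino-acid substitutions at the
  configured rate (0.05 default) for proteomes and DNA substitutions for
  genomes; with probability 0.2 a surviving target's site is randomised to
  background (re-drawn until it no longer scans as a site), with
  probability 0.1 the gene is deleted outright. Retained sites are excluded
  from substitution: site decay is modelled as the discrete loss event, not
  as gradual erosion, so the truth table stays binary. There are no indels,
  no rearrangements and no phylogenetic structure (species are independent
  draws from the reference, not a tree).

Because the generators guarantee site/truth coincidence, passing the
recovery benchmarks demonstrates that the *pipeline machinery* is correct
and calibrated — not that the thresholds would achieve the same accuracy
on real genomes, where promoter decay is gradual and chance matches exist.

## Benchmarks the test suite runs (fixed seeds, default parameters)

- peak caller: exact type-I calibration at 10⁻⁴ on a 10⁶ bp exchangeable
  null; ≥95% recovery of planted 10× regions at depth 5.
- Gibbs sampler: ≥90% of planted sites assigned within ±1 bp (30 sequences
  × 20 replicates, 40 restarts).
- PWM scoring: exact agreement with a full enumeration over all 4⁴ × 4⁵
  block pairs.
- classifier: ≥90% recovery of planted Class I/II/III labels and ≥95%
  non-target specificity at σ = 0.3 (200 genes × 20 seeds).
- conservation: ≥99% cell agreement with the family truth table at
  substitution rate 0.1 (8 species × 10 seeds).
- end to end: ≥90% precision and recall of planted promoters from raw
  coverage through the candidate table (3 seeded replicates).

Problem sizes (genome length ~50 kb, 14–200 genes, panels of 8–10 species)
were chosen so the full suite completes in minutes on one CPU while keeping
every proportion the analysis depends on (GC content, site spacing, depth,
noise) at the values the defaults are built around.

## Known limitations

- The scanning thresholds are calibrated on 19 promoters; with so small a
  training set the minimum-score threshold has high variance, and the
  PRODORIC/Virtual Footprint score it stands in for is not published, so
  numerical scores are not comparable across tools.
- The candidate rule and class thresholds formalise screens that are in
  practice partly manual curation; the packaged promoter table, not the
  rule, is the ground truth.
- The RBH aligner is quadratic per protein pair and meant for desk-scale
  panels; supply a precomputed ortholog table for real proteomes.
- Classes are assigned per gene, not per operon; polycistronic targets
  inherit the representative gene's series.
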