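# Methods

## The problem being modelled

A tumour/normal somatic-calling design sequences an affected tissue and a
reference tissue (blood) of the same person to medium depth (~10–40×) and
looks for positions where the reference matches the genome (VAF ≈ 0) while
the affected tissue shows an elevated VAF.  This works when a recent clonal
expansion puts the mutation into a large fraction of sampled cells.  In
polyclonal bulk material — airway brushings sample ~9 cm² of epithelium
containing clones that are presumably sub-millimetre — each clone-private
mutation is carried by a vanishing cell fraction, its expected VAF sits far
below the callers' working threshold, and the calling output consists
almost entirely of false positives.  The package makes that failure mode
(and the conditions under which the same strategy succeeds) reproducible
and quantifiable.

## Detection-limit model

For a mutation private to a clone occupying cell fraction *f* of a sample
with ploidy *p*, carried on *c* copies (*c* = 1 heterozygous, 2
homozygous), the expected VAF is *fc/p*.  A caller demanding a minimal VAF
*t* therefore needs *f* ≥ *tp/c* — 30% of cells at the typical *t* = 0.15
for a diploid het mutation.  At read depth *D*, detection requires the
sampled alt-read count X ~ Binomial(D, fc/p) to reach
max(*m*, ⌈*tD*⌉), where *m* is a minimal supporting-read count
(default 3; *m* = 0 recovers the pure-threshold model).  The tail is
evaluated exactly via the binomial survival function; no normal
approximation is used.  Two numerical details:

* ⌈*tD*⌉ is computed as `ceil(round(t*D, 9))` so products that are
  integers up to binary-float noise (0.15 × 20) are not rounded up.
* The model ignores copy-number alterations; samples are assumed screened
  for ploidy deviations before calling.

Consequences the tests verify: detection probability is monotone in *f*;
as *D* → ∞ it converges to a step function at *f* = *tp/c* (deeper
sequencing helps only above the limit — below it, noise-driven calls
*vanish* with depth); and the analytic tail agrees with Monte-Carlo read
sampling.

## Synthetic cohort generator

The generator produces every input the pipeline consumes.  Defaults encode
the sequencing design being emulated; each is configurable.

**Genome.** A slice of `genome_length` bp (default 1 Mb, 2 chromosomes).
Desk-scale runs use 1 Mb rather than 3 Gb; densities of simulated artifact
sites are scaled up correspondingly (below) so that call-set sizes remain
informative.

**Clone mixtures.** A sample is a set of clones with fractions summing to
1 − `infiltrate_fraction` (default infiltrate 0.1; brush samples are >90%
epithelial).  Each clone carries private heterozygous mutations; all
clones share a germline background (defaults: 500 het + 300 hom variants
per Mb, 70% of het variants placed on common-SNP track positions, as real
inherited variation overwhelmingly is).  Two regimes:

* *brushing* — 200 clones with symmetric-Dirichlet(1) fractions, 10
  private mutations each.  Typical clone fraction ~0.5% of cells, i.e.
  expected VAF ~0.25% — far below the 30%-of-cells limit, mirroring
  sub-millimetre clonal units sampled over square centimetres.  The true
  clone-size distribution of airway epithelium is unknown; the Dirichlet
  concentration and clone count are exposed as configuration, not claims.
* *cancer* — one clone at 90% of cells, the validation regime.

**Read sampling.** Depth is Poisson around the tissue mean (brush 20×,
blood 27×; a negative-binomial dispersion parameter is available but off
by default since only mean coverages are being emulated); alt counts are
Binomial(depth, expected VAF).  An optional per-base error rate adds alt
reads at non-variant sites; the default is 0 so that test oracles are
exact — passing tests therefore do not demonstrate robustness to
sequencing error, only to sampling noise.

**Annotation tracks.** Random interval sets covering fixed genome
fractions (exactly, by construction): repeats 55% (leaving 45%
non-repetitive), 50-mer-unique mappability 77%, all-SNPs 5% with
common-SNPs 0.5% as a strict subset, DNase clusters 3%.  Tracks are stored
as merged, sorted interval arrays; point membership is a binary search,
property-tested against a linear scan.

**Shared artifacts.** Real consensus call sets are not empty even when no
mutation is detectable, because some error modes are visible to *every*
caller.  Two channels reproduce this, both free parameters of the
generator rather than literature values:

* *mapping artifacts* (default 35/Mb): spurious target-tissue alt reads at
  VAF ~ U(0.20, 0.45), placed 60% inside repeat-or-non-unique regions.
  Amplicon re-sequencing shows nothing there (outcome "absent").
* *hidden germline* (default 15/Mb): heterozygous SNPs whose blood read
  draw is sampled from the low-depth conditional in which zero alt reads
  were seen (depth ~ Poisson(4), alt = 0) — the mechanism that turns a
  germline SNP into a spurious "somatic" call.  Amplicon re-sequencing
  reveals ~50% VAF in both tissues (outcome "germline polymorphism"),
  concentrated in the low tier because the positions sit on SNPs.

The combined 50/Mb density is a desk-scale choice: it gives a 1 Mb, 12
subject cohort a consensus set of a few hundred calls, enough to exercise
tier-stratified selection.  At the per-Mb consensus densities seen in
real whole genomes a 1 Mb slice would contain ~0 calls.

**Caller personalities.** A caller emits a site when the *shared* sampled
target VAF ≥ its threshold (default 0.15 for all three), with at least
`min_alt_reads` supporting reads (3; the restrictive caller demands 4) and
zero alt reads in the reference tissue, minus an `fn_rate` (2%) of random
misses.  On top, each caller fabricates *independent* false positives
(Poisson per Mb: 400 for the permissive pair, 40 for the restrictive
caller — the ~10:1 output-size contrast, scaled like the artifact
densities), placed on common-SNP positions with 10× enrichment.  Because
private false positives are independent across callers, intersection
removes them while union keeps them — the mechanism behind the
precision/recall ordering the tests assert.

**Amplicon pileups.** One observation per candidate × subject × tissue at
Poisson(27 000)× depth, alt counts binomial at the mixture-implied VAF of
the owning subject.

## Consensus and evaluation

Matching is by (normalized chromosome, position) only; alleles are ignored
(an optional strict mode exists).  Attributes of a consensus call (VAF,
depths) are taken from a configurable reporting caller, defaulting to the
most restrictive (smallest) call set.  Precision of an empty call set is
reported as 0 with a warning; Dice of two empty sets is NaN with a
warning.  Duplicate positions within one caller are resolved upstream
(keep first, log), so the set algebra is pure.

## Confidence tiers

High ⇔ ¬SNP ∧ ¬repeat ∧ unique; low ⇔ SNP ∨ (repeat ∧ ¬unique); medium ⇔
¬SNP ∧ exactly one of {repeat, ¬unique}.  The exactly-one-of reading of
"medium" is the only assignment consistent with the other two definitions
across the 8 flag combinations, which the tests enumerate exhaustively.
Rare/unknown-frequency SNPs (all-SNP minus common-SNP) never affect the
tier; they enter only the stringent re-assessment conjunction
(depth ≥ 20 in both tissues ∧ reference VAF = 0 ∧ no dbSNP entry).
Unknown depths or VAFs fail stringent flags conservatively, with a
warning, never silently.

## Verification

**Selection.** Per tier, up to `n_per_tier` (30) candidates: forced
inclusions first (nonsynonymous/splice-site calls, counted against their
own tier's quota), then greedy repair for subject coverage (subjects in
sorted order, one random eligible call each), then uniform sampling
without replacement.  chrY calls are excluded before anything else.  A
tier smaller than its quota is taken whole with a warning; a subject with
only chrY calls is warned about and skipped.  Deterministic under seed.

**Decision matrix.** Boundary inclusivity follows the stated wording:
reference is VAF < 1%; subclonal is 5% ≤ VAF < 20% *and* depth strictly
> 1000; heterozygous is 20% ≤ VAF ≤ 80%; homozygous is VAF > 80%;
everything else is indeterminate.  Depth 0 is a distinct no-data marker.
All boundaries are configurable.

**Adjudication.** The published procedure resolved indeterminate values by
manual comparison with the same position in other samples; here that
comparison principle is made explicit: with *b* the median VAF of the
other samples at the position, VAF ≤ max(2*b*, 1%) resolves to reference
(shared background), anything higher to subclonal (sample-elevated).  The
coefficients (2×, 1% floor) are configurable and every resolution is
logged with its evidence.  Single-sample positions stay flagged.

**Outcomes.** A precedence chain makes the categories total and mutually
exclusive: unclear (any undecided target-tissue class) → absent (reference
in both target tissues) → germline polymorphism (het/hom in both) →
confirmed somatic (subclonal in the sampled tissue, reference in blood,
and *no* other subject showing the variant — the strictest reading of
"clearly higher VAF in the target than in blood") → shared/other (variant
in both tissues, shared across subjects, or out-of-matrix patterns such as
heterozygous in one tissue only).  "Subject-specific" means no sample of
any other subject classifies as non-reference.  Note the deliberate
strictness: a fully clonal somatic mutation (brush VAF ≈ 0.5, blood 0)
classifies heterozygous-in-brush and lands in the shared/other row rather
than confirmed; confirmation is reserved for the subclonal signature.

**Extrapolation.** estimated_true(tier) = confirmed/tested × tier_total;
the overall false-positive fraction is 1 − Σ estimated_true / Σ totals.
A tier with calls but no tested candidates is an error, not a silent 0.
No uncertainty interval is attached — the estimate is a point scaling.

## Pipeline and reproducibility

One declarative config (YAML; CLI flags override) drives
simulate → call → consensus → annotate → burden/IMD → select → verify →
extrapolate.  All randomness derives from a single seed through
`numpy.random.SeedSequence` spawning, so a rerun with the same config is
byte-identical; the manifest records the effective config, per-stage
counts (validated for internal consistency: tier counts sum to the
consensus count, outcome-table columns sum to tested counts) and SHA-256
checksums of every output file.  Each stage is independently invokable on
the previous stage's files through the CLI.

## Known limitations

* No read-level simulation (FASTQ/BAM), no mutational-signature-aware
  substitution spectra, no spatial clone geometry: the area-to-cell-
  fraction mapping is deliberately excluded because no quantitative
  clone-size data exist for this tissue.
* The caller personalities are threshold caricatures; they reproduce the
  output-size contrast and intersection behaviour of real tools, not
  their internal statistical models.
* The artifact channels are phenomenological.  Their rates set the size of
  the consensus set directly, so absolute call counts from the simulator
  carry no biological meaning — only the contrasts between strategies,
  tiers and regimes do.
* Sequencing error defaults to 0; the adjudication rule is exercised by
  constructed fixtures rather than by emergent error in end-to-end runs.
* IMD output supports manual review of clustering only; no automated
  kataegis caller or outlier rule is included.
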