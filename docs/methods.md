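# Methods

This note documents the models implemented in attmut, the defaults they
ship with, and the choices made where the underlying biology or published
practice leaves the design open.

## The two-state mutation model

Lineages are modelled as switching between two states tied to the mobile
element's position:

* **element integrated** ("mutator"): the element supplies *mutS* with an
  alternative start and regulatory region; mismatch repair is partially
  effective. Default rate 0.3 mutations/generation — two orders of
  magnitude above the ~0.003/generation bacterial baseline, matching the
  elevated loads seen even in lineages that never lost the element.
  Default transition probability p_ti = 16.5/17.5 ≈ 0.943 (ts/tv 16.5).
* **element excised** ("hypermutator"): excision leaves a 2-bp frameshift
  scar in *mutS* and abolishes mismatch repair. Default rate 3.75
  mutations/generation (≈1,500 mutations over 400 generations) with
  p_ti = 24.6/25.6 ≈ 0.961 (ts/tv 24.6).

Switching is Bernoulli per selection round: P(excise) = 0.1,
P(reintegrate) = 0.5 by default. Published data constrain only the
steady-state excised fraction (~10⁻⁴ of genomes), not the per-round
switch rates, so these are free parameters chosen to produce the sporadic
burst pattern the experiment shows; both are exposed on `SimConfig`.

Per round, the number of new fixed mutations is Poisson(rate ×
generations); each is independently a transition with the state's p_ti;
positions are uniform without replacement; supporting-read fractions are
uniform on (0.8, 1.0]. An extra 5% of calls are "contaminants" with
fractions in (0.2, 0.8) — mapping noise that the fixed-SNP filter must
remove — with uniformly random substitution types. One selection round is
3 colony growths × 24 generations + 8 generations in liquid = 80
generations; five rounds give the 400-generation default design.

What the generator deliberately does **not** emulate: selection and
fitness effects of individual mutations, linkage/hitchhiking, raw reads
and alignment error beyond the two filtered artifact classes, horizontal
element transfer between strains, and indels other than the element's
footprint. Tests passing on this generator therefore certify the
*analysis* logic (filters, estimators, reconstructions), not robustness to
every failure mode of real short-read data.

## Variant filters

* Fixed-SNP rule: read fraction strictly greater than 0.80 ("more than
  80%" read literally; a call at exactly 0.80 is removed).
* Deletion rule: maximal runs of exactly zero coverage strictly longer
  than 100 bp.
* Contig-end margin: 50 bp by default. The margin is not dictated by the
  biology; it was chosen as roughly one read length (40-bp reads) on the
  draft assembly, and is configurable.
* Lineage continuity: every round's (filtered) cumulative SNP set must
  contain the previous round's; violations are reported per round.
* Coordinates are 0-based half-open internally; VCF/GFF (1-based) are
  converted only in `attmut.io`. Multi-allelic VCF records are split into
  biallelic records on read.

## Spectrum statistics

* The binomial MLE is the pooled fraction Σk/Σn (closed form; the
  product-binomial likelihood depends on the data only through the pooled
  counts). Tests cross-check it against a 10⁻⁴-step grid search. The
  likelihood curve is evaluated on 2,001 even grid points plus p̂ itself
  and normalised by its maximum, so the reported curve peaks at exactly 1.
* Dispersion: index = sample variance (n−1 denominator) / mean. No
  standard finite-sample null is assumed; significance is a parametric
  bootstrap under Poisson(mean) with the same number of rounds (default
  10,000 replicates, seeded; p = (1+#{index* ≥ index})/(B+1)). All-zero
  counts define index 0, p 1.
* Transition-bias χ²: each lineage contributes a two-cell goodness-of-fit
  term against the null transition probability, summed over lineages with
  df = L−1 (df = 1 for a single lineage, the usual one-proportion df).
  The construction behind the originally reported statistic of this form
  is not fully specified in the literature we follow; ours is documented
  here and may differ in detail. The null defaults to p = 0.70 (ts/tv
  ≈ 2.33, the midpoint of typical wild-type reports of 2.1–3).
* OLS of ts/tv ratio on per-round load pools rounds across lineages;
  rounds with zero transversions (infinite ratio) are excluded. A
  constant-response input returns slope 0 / F 0 explicitly rather than a
  0/0 R².

## Excision model

An integrated locus is `upstream | core+scar | element | core | downstream`;
the pre-insertion host gene is `upstream | core+scar | downstream`.
Recombination between the direct-repeat cores yields
attB = `upstream | core | downstream` (the scar bases leave with the
circle) and attP = `core | scar | element`, written linearly with its
origin fixed at the first base of the repeat core so amplicon coordinates
are reproducible. Base conservation (len attB + len attP = len integrated)
and the excision/integration round trip are exact identities and are
asserted over randomised loci.

Frameshift ⇔ scar length mod 3 ≠ 0. A stop is "premature" when it sits
strictly before the wild-type stop codon's scar-shifted position in attB
coordinates (for in-frame scars the wild-type stop simply moves
scar/3 codons forward and is not premature). Translation uses the
bacterial code (table 11). The synthetic gene builder plants the 9-mer
`ATAAGTAAC` at a codon boundary downstream of the scar: it encodes no stop
in frame 0 but a stop in both shifted frames, so every frame-shifting scar
deterministically exposes a premature stop; for in-frame scars the builder
re-draws the junction codons until the excised gene is stop-free. The real
att-core sequences and offset geometry of the motivating strain are not
public; the synthetic locus reproduces the 2-bp-transfer *behaviour*
without claiming the real coordinates.

In-silico PCR is exact-match only: the assay primers are designed against
known sequence, and a mismatch model would add ambiguity without changing
any conclusion; a 3'-anchored mismatch allowance is a documented extension
point, off by default. Circular templates are searched across the origin
(doubled-sequence scan, products capped at template length). The
four-amplicon assay derives all four pairs from two host-flank anchors and
two element-end primers; `design_assay_primers` verifies each pair on its
positive-control template and that the attB pair cannot bridge the
integrated element within `max_len`.

## qPCR quantification

The amplification model is the standard log-linear relation
Cq = intercept − log10(q)/log10(1+E). Each target (attB and the genomic
control locus) gets its own least-squares standard curve from the
100%-excision dilution series (≥3 distinct dilutions; efficiency
10^(−1/slope) − 1). A sample's excision frequency is
quantity(attB)/quantity(control); the undiluted standard self-normalises
to exactly 1, and any constant per-target Cq offset cancels. Technical
replicate wells are averaged first; mean ± SE is computed across
biological replicates (the published work does not state its replicate
structure; the plate format here carries explicit replicate indices).
Undetermined Cq is a below-detection sentinel, never a number. Growth
phases are compared with a paired two-sided t-test; zero-variance
differences return explicit 0/±∞ sentinels. Simulated plates default to
the study conditions: true frequencies 7.95×10⁻⁵ (exponential) and
1.27×10⁻⁴ (stationary), efficiency 0.95, Cq noise SD 0.1, 8 replicates,
six ten-fold dilutions.

## Problem sizes in the default runs

The test suite and `scripts/acceptance.py` run on scaled-down instances
chosen so the full suite executes in well under a minute of CPU while
keeping every statistical check adequately powered: genomes of 150–500 kb
(versus the ~5-Mb default chromosome), 2–8 lineages × 4–5 rounds, 100
replicates for CI coverage, 200 datasets × 2,000 bootstrap replicates for
dispersion calibration, 500 random templates for the PCR oracle, and 200
simulated plates for qPCR recovery. Coverage tracks default to mean depth
35× (the study's reported mean) with Poisson noise.

## Known limitations

* The coverage model is Poisson; real short-read depth is over-dispersed
  and mappability-structured, so the deletion detector's false-positive
  calibration on synthetic tracks is optimistic.
* `classify_snp` assumes single-exon CDS models and takes the first
  containing CDS when annotations overlap.
* The χ² construction and the OLS pooling are stated choices among several
  defensible ones (see above); both are configurable at the call site.
* Excision/reintegration rates per generation are not identifiable from a
  steady-state excision frequency alone; the simulator's switch
  probabilities are scenario parameters, not estimates.
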