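# Methods

## The statistic

Exon inclusion is quantified purely from junction-spanning reads.  For a
cassette exon *mid* with flanking exons *up* and *down*,

Ψ = (e(up,mid) + e(mid,down)) / (e(up,mid) + e(mid,down) + e(up,down)),

with e(i,j) the number of reads whose gapped alignment blocks abut exon
*i*'s end and exon *j*'s start with at least `min_overhang` aligned
nucleotides on each side.  The formula is implemented verbatim: an
inclusion transcript contributes reads to *two* junctions while an
exclusion transcript contributes to one, so the statistic is not the
isoform fraction.  We keep the printed form for fidelity and expose
`x_inclusion = e(up,mid) + e(mid,down)` and
`m_total = x_inclusion + e(up,down)` as the counts all downstream
inference uses.  No exon-body coverage model is attempted.

Because of the double counting, a two-isoform mixture at inclusion weight
w does not produce junction-Ψ = w.  `isoform_weights_for_psi` inverts the
expectation — using the exact per-junction placement counts, including
end-truncation — so simulations can be phrased directly in Ψ units.  The
inversion is exact in expectation and is property-tested against a
brute-force enumeration of every (isoform, start) placement.

## Posterior, Bayes factor, and event filters

Given x inclusion-supporting reads out of m informative reads, Ψ gets a
conjugate Beta posterior (default prior Beta(1,1)); the credible interval
is the central 95% of that posterior.  Clone-vs-parent calling uses the
closed-form Bayes factor of independent-Ψ (uniform priors) versus
shared-Ψ (uniform prior); the binomial coefficients cancel, leaving a
ratio of Beta normalizing constants.  This is a deliberate, documented
substitute for a full generative isoform-assignment model: it operates on
the same inclusion/exclusion counts the Ψ statistic uses, is symmetric in
the samples, and is consistent (evidence grows with depth under a true
difference).  The conventional stringent thresholds — |ΔΨ| ≥ 0.2,
total reads ≥ 10, BF ≥ 10 — are defaults, with ΔΨ taken between posterior
means so it stays defined at low counts, and the read filter applied per
sample (both m's must reach the cutoff; the stricter of the two possible
readings).  No multiple-testing correction is applied; event tables carry
raw BF so users can post-filter.

Calibration under the defaults, verified by the acceptance suite: the
null rate of BF ≥ 10 at 100 reads per sample is well under 5%; power at a
true ΔΨ of 0.5 with 100 reads exceeds 80% by a wide margin; 95% credible
intervals cover a uniform-drawn true Ψ at 0.95 ± 0.03 over 200
simulations at 2000 reads.

## Synthetic data

The generators are pure functions of their inputs and a seed.

* **Junction reads** — single-end reads of configurable length (default
  75 nt, substitution error 0.001/nt) placed uniformly along the spliced
  mRNA of an isoform drawn by weight; the emitted SAM uses skip (`N`)
  cigar records matching the genomic exon blocks.  There is no
  fragment-length, paired-end, or positional-bias model: junction
  counting is the only consumer, and uniform placement makes the expected
  junction counts available in closed form.  Truth tables record every
  read's isoform and both the analytic expectation and the exact realized
  junction counts under the counter's own overhang rule.
* **Amplicon reads** — full-length copies of the amplicon carrying one
  allele (reference, insertion, or deletion at the cut site) drawn from a
  stated spectrum, plus substitution errors.  Sequencing error is
  substitution-only by construction, so every indel the caller sees comes
  from the spectrum and the recovery denominator is unambiguous.  The cut
  position is the last reference base 5′ of the blunt cleavage (3 nt 5′
  of the PAM); insertions go in after it, a deletion of length d removes
  the d bases ending at it.
* **Deletion alleles** — removal of a closed genomic interval, with truth
  provided by the same `interpret_deletion` routine users call (length,
  removed exons, breakpoint contexts).
* **Gene-level counts** — negative binomial with variance
  μ + φμ², default dispersion φ = 0.01 (≈10% CV at high expression, a
  typical value for a well-expressed gene across cell-line replicates;
  no dispersion was available to copy, so this is the package's choice).

What passing recovery tests on these data do **not** show: robustness to
alignment artifacts, positional or GC bias, PCR chimeras and duplicates
(duplicates are only injected explicitly to exercise deduplication), or
mis-annotation of exon boundaries.  Real libraries need those properties
established separately.

## Counting and calling rules

* Junctions whose boundaries match no annotated exon edge are collected
  under novel keys (genomic donor-end/acceptor-start), never dropped —
  this is how an intron-retaining fusion transcript from a genomic
  deletion surfaces in the junction table.
* `min_overhang` defaults to 6 nt: small enough to keep power with 75-nt
  reads, large enough to suppress spurious single-block abutments.
* Deduplication keys on (chromosome, alignment start, cigar) and is
  **opt-in**.  At high per-gene depth, single-end reads collide on that
  key by chance (a short transcript has only a few hundred distinct
  placements), so deduplicating simulated data saturates the counts; the
  option exists for inputs that genuinely contain PCR duplicates, and
  counting is tested to be invariant to injected duplicates when it is on.
* Indels are taken from cigars and left-aligned (shifted to the lowest
  compatible coordinate; idempotent by construction), then aggregated by
  (position, type, allele).  Positions are 1-based at the leftmost
  affected base; insertions are anchored at the last reference base
  before the inserted sequence.  Alleles below 0.5% frequency are dropped
  from the table (configurable) but still count toward the edited
  fraction.  Substitutions can never create indel rows.
* A convenience global aligner (match +2, mismatch −3, gap open −5, gap
  extend −1) turns raw amplicon reads into cigars when no aligner output
  is available; scoring is pinned for reproducibility.
* Guide strength is a strict inequality: edited fraction > 20% is
  "strong".  Editing-vs-skipping association uses Spearman rank
  correlation, dropping incomplete pairs and reporting the n used.

## Consequence prediction

Frame phase is the mod-3 rule on the summed skipped-exon lengths; it is
cross-checked against a translation oracle (C-terminal peptide
preservation) in the tests.  After a frameshifting skip, the downstream
exons are scanned for the first ATG in the annotated frame (anchored at
the first base of the model's coding-start exon); no Kozak-context
scoring is attempted.  RT-PCR product sizes are exon-label arithmetic —
remainder of the forward-primer exon, fully included intervening exons
present in the isoform, reverse-primer exon up to the primer end — so the
same operation serves any isoform, including deletion-derived ones.
Deletion interpretation predicts the nearest surviving upstream exon
splicing to the nearest surviving downstream exon when both breakpoints
are intronic, and a fusion retaining the partial upstream segment when a
breakpoint interrupts an exon.  This is a stated simplification: splice
site strength is not modelled, and the package reports promiscuous
multi-exon junctions without attempting to explain them.

## Fixtures and coordinates

The four packaged gene models are toy loci on toy chromosomes.  Only the
published constraints are encoded: cassette lengths from RT-PCR band-size
differences (331 − 209 = 122 nt; 353 − 140 = 213 nt), the in-frame 228-nt
cassette whose multi-exon skips are all frameshifting except the single
skip, the cut site at nucleotide 97 of that cassette, and the 832-bp and
2268-bp deletion alleles placed so their breakpoint contexts match the
reported transcripts.  Flank splits inside the primer intervals are free
choices; only their sums are constrained.  All fixtures are +-strand;
minus-strand input is reflected into transcription order at load time and
covered by a reflection test.

## Problem sizes

Defaults used by the test and acceptance suites, chosen as the package's
standard operating points: junction simulations at depth 1200–10000 reads
(≈200–1700 informative junction reads), amplicon spectra at depth 5000,
calibration at 100–2000 count-level reads over 200–500 replicates,
expression recovery averaged over 100 simulated experiments at 2–3
replicates each.

## Known limitations

Single-end scope throughout (the pair-level view of duplicates and
junction support is approximated); no aligner is run, so alignment error
modes are out of scope; the Bayes factor is exon-local and ignores
isoform structure beyond inclusion/exclusion; deletion-transcript
prediction ignores splice-site strength; no NMD-efficiency or protein
mass prediction.
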