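# Methods

## The statistic and its assumptions

`poolscan` compares protein-coding sequence between population pairs using
the proportion-based p_N/p_S ratio. For a codon-aligned pair of ORFs, each
codon position contributes fractional *expected sites*: of the three possible
single-base changes at a position, the fraction that is synonymous counts
toward S, the remainder toward N (Nei & Gojobori's 1986 counting). Observed
differences are split the same way; codons differing at k > 1 positions are
resolved by averaging the synonymous/nonsynonymous step counts over all k!
orderings of single-base steps, excluding orderings that pass through a stop
codon (if every ordering does, all k steps are counted nonsynonymous — the
conservative reading for a pair of sense codons). Then

    p_N = N_d / N,   p_S = S_d / S,   ratio = p_N / p_S,

with N and S averaged over the two sequences of the pair. No multiple-hit
correction is applied: the statistic targets within-species comparisons where
per-site divergence is far below saturation, and at those distances the
Jukes–Cantor-style corrections are identity-level perturbations. A
maximum-likelihood codon model (GY94) could replace this estimator; for
distances this small the added machinery (codon-frequency and κ estimation
per gene on a handful of differences) is poorly identified, so the package
deliberately uses the NG86 proportion estimator and validates it by
simulation recovery instead.

Interpretation requires the two samples to come from reproductively isolated
populations, so that between-population differences are fixed substitutions
rather than shared segregating variation; with samples from a single panmictic
population the ratio does not measure positive selection.

Thresholds: ratio > 1.0 → `strong` candidate; 0.5 < ratio ≤ 1.0 → `moderate`
(a deliberately less conservative band, useful when truncated ORFs leave some
nonsynonymous changes unsampled); otherwise `below`. Genes are `filtered`,
with an explicit reason, when the pair has fewer than 3 differing sites
(ratio estimates from 1–2 differences are dominated by sampling noise), the
ORF is ≤ 150 nt, either sequence contains an in-frame stop, or S_d = 0
(excluded rather than reported as an infinite ratio, which would otherwise
flood the `strong` bin with zero-denominator artifacts).

## ORF prediction

Reading frames come from upstream protein-alignment hints when available
(strand + frame per contig); otherwise all six frames are scanned and the
longest qualifying ORF wins (ties prefer the + strand, then the smallest
start). An ORF is the first ATG in frame extended to the first in-frame stop
(excluded) or to the sequence end — truncated ORFs without a terminator are
accepted — and must be strictly longer than 150 nt. Coordinates are 0-based
half-open internally and 1-based inclusive in GFF3; because predicted ORFs
always begin at their ATG, the GFF3 phase column is 0 on both strands.

## SNP filtering and classification

Variant records are kept when they are biallelic single-nucleotide changes
with phred quality ≥ 20, alternate-allele occurrence ≥ 2, and coverage ≤ 200
— all three thresholds inclusive. Occurrence is read from INFO/AC
(alternate-allele observation count) and coverage from INFO/DP; multiallelic
records are split and each alternate filtered independently. Every rejected
record carries a reason code (`indel`, `low_qual`, `low_occurrence`,
`high_coverage`), checked in that fixed order so that counts partition the
input. The coverage cap is a paralog guard: collapsed duplicates inflate
apparent coverage and produce spurious "SNPs" between gene copies.

A kept SNP inside an ORF is localized to its codon; on − strand ORFs the
position maps through the reverse complement and both alleles are
complemented. The effect compares standard-genetic-code translations of the
reference and alternate codon. Changes to or from a stop codon are labeled
nonsynonymous; this matches the site-counting convention above, so observed
differences and expected sites stay on the same bookkeeping (every codon
contributes exactly 3 sites, N + S equals sequence length). SNPs outside any
ORF stay in the global SNP table but are excluded from codon analysis, as are
codons containing ambiguous bases.

## McDonald–Kreitman test and neutrality index

Within-species polymorphism counts (P_n, P_s) and between-species fixed
divergence counts (D_n, D_s) form a 2×2 table; under neutrality the
nonsynonymous fraction should be the same in both strata. The neutrality
index NI = (P_n/P_s)/(D_n/D_s) is computed from raw counts and reported as
undefined, with a reason, whenever P_s, D_n or D_s is zero. A site planted in
both strata counts once, as polymorphism: a site still segregating within a
species is not a fixed difference.

Significance uses a self-contained two-tailed Fisher's exact test: the
p-value sums hypergeometric probabilities of all tables with the observed
margins whose point probability is ≤ that of the observed table
(point-probability method, the convention of common MK implementations).
Probabilities are computed in log-space via `lgamma`, and the comparison uses
a relative tolerance factor 1 + 1e-7 so floating-point noise cannot exclude
exact ties. An all-zero table yields p = 1 by convention. The implementation
is verified against full rational-arithmetic enumeration (all tables with
margins ≤ 12, tolerance 1e-9) and against `scipy.stats.fisher_exact` as an
independent cross-check.

In the pipeline, divergence is obtained by comparing the in-group ORF with a
codon-aligned outgroup ortholog; in codons with several differences each site
is classified by substituting the outgroup base singly into the in-group
codon. This one-at-a-time reading keeps the MK counts integral (the 2×2 test
needs counts, not pathway-averaged fractions) and coincides with the pathway
average whenever at most one difference falls in a codon — the typical case
at the divergences simulated here.

## GO overrepresentation

For each term annotating the test set, the one-tailed (upper) hypergeometric
p-value is taken on the 2×2 table of term membership versus set membership,
with sequences (not annotation instances) as the counting unit. Raw p-values
are adjusted by Benjamini–Hochberg step-up; significance means adjusted
p ≤ α (default 0.05). Significant terms can be reduced to their most-specific
members by removing any term that is a transitive ancestor of another
significant term under a child → parent table (full OBO ontology parsing is
out of scope; the reduction only needs the parent relation). Pairwise tissue
comparisons report, per tissue, the intersection of terms significant against
each other tissue separately.

## The synthetic-data generator

The generator emulates the statistical structure the scan assumes, not the
sequencing process: no reads, no assembly, no expression levels.

* **Ancestral ORFs** — ATG plus uniform random sense codons, 51–200 codons by
  default (the lower bound is the smallest length passing the > 150 nt rule).
* **Fixed differences** — each substitution picks one of the two descendant
  branches uniformly, then a (site, alternate base) with probability
  proportional to κ^[transition] · ω^[nonsynonymous]; changes creating
  in-frame stops have weight zero (the scan excludes stop-containing ORFs, so
  they would only be discarded), and the start codon is never mutated so the
  emitted sequences keep satisfying the ORF invariants the predictor relies
  on. The number of substitutions per gene is Poisson with mean 4 (matching a
  reported per-contig SNP load of mean 4, median 2). Indels are never placed
  inside ORFs — the filtered dataset the scan sees contains none.
* **Polymorphism** — per population, Poisson(2) sites per gene drawn with the
  same weighting against that population's fixed sequence; emitted only as
  VCF records (they segregate in the pool, so the FASTA is unchanged), with
  quality uniform on [20, 60], coverage on [4, 200] and occurrence ≥ 2.
* **Outgroup divergence** — per gene, Poisson(15) nonsynonymous and
  Poisson(30) synonymous changes (the magnitude of published per-gene MK
  divergence counts), applied in random interleaved order with
  class-restricted draws.
* **Noise records** — configurable fractions of the VCF constructed to fail
  exactly one filter each: indels (0.2), quality < 20 (0.1), coverage > 200
  (0.1), occurrence 1 (0.05). The manifest records exact per-type counts, so
  filter bookkeeping is testable as an identity, not a tolerance.
* **Labels** — every planted variant is labeled by translating the affected
  codon before and after the change at the moment it is applied. The
  downstream classifier labels independently from the emitted files; their
  100% agreement is a cross-implementation oracle, exercised in the tests.
* **Defaults** — ω = 0.3 (the genome-wide mean p_N/p_S reported for this
  design is ≈ 0.28), κ = 2 (a typical mammalian transcriptome
  transition/transversion ratio). Contigs carry 5–30 nt UTRs free of ATG
  substrings so the planted start is the first in-frame ATG a hinted
  predictor sees.
* **Seeding** — one master seed; per-gene streams derived as
  `default_rng([seed, gene_index, stage_tag])`, so bundles are byte-identical
  across runs and stable under regeneration of any single gene.

What the generator does **not** emulate: read-level error profiles and
mapping artifacts (noise records are drawn from configured ranges, not from a
sequencer model), linkage between sites, codon-usage and GC bias,
indel variation, alternative splicing, and a real GO DAG (the parent table is
a flat set of chains). Passing tests therefore demonstrate correctness of the
statistical machinery on data satisfying the scan's own assumptions — not
robustness to assembly or alignment failure modes.

## Calibration and validation choices

* **ω recovery** is checked by simulating 500 genes of 300 codons with 30
  fixed differences at ω ∈ {0.5, 1, 2} and requiring the median estimated
  ratio within 15% of ω, with `strong` assigned to ≥ 80% of ω = 2 genes and
  ≤ 10% of ω = 0.5 genes. These simulations run at κ = 1: the NG86 estimator
  assumes no transition/transversion bias, so recovery is calibrated under
  the estimator's own model; κ = 2 remains the generator default elsewhere
  and functions as a stress parameter, since transition bias inflates the
  synonymous fraction at third positions and biases the ratio conservatively
  (downward).
* **Null calibration**: with polymorphism and divergence drawn from identical
  class probabilities, the MK Fisher test's rejection rate at α = 0.05 stays
  ≤ 0.05 over 2,000 replicates (exact conditional tests are conservative);
  null GO annotation simulations keep the FDR-significant proportion ≤ 0.05.
* **Problem sizes** in the test suite (60-gene bundles, 500-gene recovery
  runs, 1,000 random codon pairs for path-oracle checks) were chosen as the
  smallest sizes at which the checked quantities are statistically stable;
  they are the package's own validation conditions, and all tolerance bands
  were fixed with the study design, before execution, and are not revisited.

## Known limitations

* Population ORFs are matched by shared reference-contig identifier, which is
  exact when both populations are assembled against one reference; the
  package does not cluster or align sequences, so shared genes with
  unequal-length ORFs are skipped (reported, not silently dropped) rather
  than gap-aligned.
* The MK divergence classifier's one-substitution-at-a-time reading
  undercounts pathway effects in codons carrying 2–3 differences.
* The neutrality index from pooled data carries an ascertainment bias toward
  high within-species P_n/P_s (allele frequencies are unobservable, so rare
  amino-acid variants are not down-weighted); NI values should be compared
  among genes, not read as absolute selection coefficients.
* `fisher_exact_2x2` enumerates the support of one margin; it is exact and
  fast for the count magnitudes of per-gene tables (hundreds), not intended
  for genome-wide contingency tables with margins in the millions.
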