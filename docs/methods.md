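# Methods

This note documents the models implemented in `secmut`, the assumptions behind
them, the defaults that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Genotype-pair calling

Sites require ≥8 non-duplicate reads of mapping quality ≥20 in both tumor and
normal; otherwise the site is skipped (returned as `None`, not an error).
Per-sample log-likelihoods over the 10 diploid genotypes use the
quality-derived error rate ε = 10^(−min(base Q, mapping Q)/10), with qualities
clamped to [Q2, Q60] (the floor avoids log 0, the cap reflects that
quality calibration above Q60 is not meaningful). A genotype {a₁, a₂} assigns
each read ½·p(b|a₁) + ½·p(b|a₂), p = 1−ε on match, ε/3 otherwise.

The joint model over 10×10 tumor/normal pairs multiplies a normal-genotype
prior, a tumor-given-normal transition prior, and both likelihoods. Priors
(all configurable on `PairPriors`):

| parameter | default | meaning |
|---|---|---|
| `het_rate` | 1e-3 | genome fraction heterozygous; split over the 3 ref-containing hets |
| `somatic_rate` | 1e-4 | P(tumor genotype ≠ normal genotype), split over the 9 alternatives |
| `nonref_rate` | `het_rate`/100 | total prior mass on the 6 genotypes without the reference allele |

These values are declared, not fitted: the cited calling method names the
prior structure but no numbers. Sites with fewer than two non-reference reads
short-circuit to homozygous-reference. Categories: identical pair → germline;
normal het + tumor hom → LOH; otherwise somatic with
SS = −10·log₁₀ P(G_t = G_n | data), capped at 255. Argmax ties break toward
ref-containing genotypes (conservative). The posterior normalizes over the
100 pairs, which makes SS invariant to any constant shift of the
log-likelihoods; as `somatic_rate → 0` no site can be called somatic.

## Site filters

Ten named filters; a record passes only if all pass, and a missing metric
fails closed. `conf`: genotype quality **or** SS ≥ 15 (either suffices).
`dp`: combined depth ≥ 4. `mq0`: < 5 MQ0 reads. `sb`: two-sided exact
binomial test of the forward/reverse alt-read split against 0.5, fail at
p ≤ 0.005. `mmqs` ≤ 20, `amm` ≤ 1.5. `detp`: mean fractional distance to the
3′ read end outside [0.2, 0.8] is rejected — end-of-read clustering is a
classical artifact signal, so the bare inequality is interpreted as a
rejection region (polarity configurable in principle; the same applies to
`ma`, where ≥2 reads supporting ≥2 distinct alternate alleles reject the
site). `ad`: tumor alt depth ≥ 4; `gad`: normal alt depth ≤ 3.

## Signature decomposition

Spectra are tallied in the conventional 96-channel order (C>A, C>G, C>T, T>A,
T>C, T>G × 5′ base × 3′ base), purine-reference SNVs reverse-complemented onto
the pyrimidine strand; `secmut.channels` is the single ordering authority.
With the signature basis fixed and known, per-sample non-negative matrix
factorization reduces to non-negative least squares, solved exactly by
`scipy.optimize.nnls`; this is deterministic and verifiable against a
brute-force simplex scan, which the tests do. Exposures are reported as
fractions of the spectrum total; a signature is *active* at ≥100 attributed
mutations or >25% of the total. Prevalence is mutations divided by the
captured megabases (62.52 Mb default), reported to 3 significant figures.

## Microsatellite instability

Per locus, distinct repeat lengths with read support strictly above 5% of the
best-supported length are counted; loci under 30 reads are excluded. A locus
is unstable when the count strictly exceeds μ + 3σ of its background panel
(here an input table; the simulator fabricates it). Sample score = percent of
evaluable loci unstable; with a matched normal, the normal's percentage is
subtracted, each sample using its own denominator (loci evaluable only in the
tumor still count for the tumor). MSI-high at a relative percentage ≥ 15
(inclusive, following the method description; the flag threshold is a
parameter).

## Copy number, purity and ploidy

Exon statistics: exons with mean depth < 5 in both samples are dropped; het
SNPs require DP_t ≥ 10, DP_n ≥ 20 and a normal allele fraction in
[0.25, 0.75]; the majority allele fraction is the better-supported allele's
read fraction, per sample. Segmentation runs exactly three agglomerative
rounds; in each, one left-to-right pass merges neighbors whose RC (and tumor
AF, when both carry het SNPs) are *not* distinguishable by a Welch t-test
from summary statistics at p > 0.95, each unit merging at most once per
round. That merge rule is implemented literally; note that under continuous
noise it requires |t| < 0.063, so near-identical neighbors merge rarely and
segmentation stays close to exon resolution — the downstream fit is designed
to tolerate that (it weights segments by length and maximizes over states
per segment). RC is then rescaled so the length-weighted genome-wide median
is exactly 1.0, which presumes the median of the genome is at (or near) the
normal copy state.

AF skew correction: `AF_corr = AF_t − (AF_n − 0.5)·exp(−½((AF_t − AF_n)/0.05)²)`,
clamped to [0.5, 1] — the Gaussian gate confines the subtraction to regions
where tumor and normal fractions agree (balanced copy number).

Purity/ploidy likelihood: for candidate (α, τ), each segment is explained by
its best allelic state from {(1,1), (2,1), (1,0), (2,0), (2,2)} plus 50/50
subclonal mixtures of each altered state with (1,1), under Gaussian
likelihoods of observed RC and corrected AF around

    RC(A,B) = (a(A+B) + 2(1−a)) / (aτ + 2(1−a)),
    AF(A,B) = (aA + (1−a)) / (a(A+B) + 2(1−a)),   a = α·clonal_fraction,

the standard two-population tumor/normal mixture. Segment standard deviations
are floored at 0.02 (RC and AF) to keep degenerate zero-variance segments
from dominating. The joint log-likelihood is the segment-length-weighted sum
over autosomes.

Three additions make this identifiable in practice, all package design
choices:

1. **Observation-model AF expectations.** Observed majority fractions are
   folded at 0.5 (they are maxima of two allele fractions), which biases them
   upward by an amount the matched normal shares; the skew correction then
   removes that bias through its gate. Comparing *raw* expectations against
   *corrected* observations would systematically eat weak true imbalance
   (e.g. a 2:1 state at α = 0.3 has a signal of 0.065, inside the 0.05-wide
   gate) and bias purity downward. The expected AF of every state is therefore
   pushed through the same folding (half-normal mean, with the per-SNP noise
   scale recovered from the normal's fold bias via σ = b·√(π/2)) and the same
   correction formula before entering the likelihood: like is compared with
   like.
2. **Parsimony penalties.** A per-segment log-likelihood penalty of 1.0 on any
   non-(1,1) state and an extra 0.5 on subclonal states. Two exact
   degeneracies force this: a whole-genome doubling ((1,1)→(2,2),
   (1,0)→(2,0) at doubled ploidy) reproduces every expectation, as does
   replacing clonal states at purity α with 50/50 subclonal states at 2α.
   The penalties resolve both toward the explanation that aberrates the least
   genome, and also stop the densely packed state expectations at low purity
   from chasing per-segment noise.
3. **Degeneracy detection.** A fit is flagged degenerate when near-tied
   restarts disagree on α by more than 0.2, or when the best fit improves on
   a forced all-(1,1) diploid null (RC 1, AF ½) by less than 1.0 weighted
   log-likelihood unit — an all-normal genome carries no purity information.
   Genomes with no AF-bearing segment (≥3 het SNPs) raise an error advising
   coverage-only analysis instead of silently fitting.

Optimization is projected numerical-gradient ascent (central differences,
step halving on failure, growth on success) with box constraints
α ∈ [0.05, 1], τ ∈ [1, 8], convergence at |Δll| < 1e-6 or 300 iterations, and
≥10 random restarts from a seeded generator (deterministic given the seed).
Final ploidy is recomputed by inverting the RC model into continuous tumor
copy number and taking the length-weighted mean. State assignment excludes
normal (1,1) segments and segments deviating from every integral state
(t-test p < 0.05, from summary statistics; one-sample z-fallback for
single-exon segments); segments above 2.5 Mb form the detailed report.

Known limitation: when a single aberrant state covers the majority of the
genome, median-centering anchors the RC scale on that state and a
"mostly diploid at lower purity" explanation can genuinely dominate the
likelihood at α ≲ 0.3 — that configuration violates the centering
assumption and is not recoverable by this method. The purity benchmark
genomes therefore keep every aberrant state below half the genome
(1.8: 20% (1,0); 2.0: 12% (2,1) + 12% (1,0); 3.0: 35% (2,2) + 30% (2,1)).

## Classification

Rules in precedence order (all thresholds on `ClassThresholds`): **MSI** when
signatures 6+15 exceed 0.30, or the indel fraction is ≥ 0.30, or the sample
is MSI-high; **UV** when signatures 7+11 exceed 0.30 on a tumor with ≥10
mutations/Mb; **PAUCI** below the 10/Mb ceiling. The ceiling sits inside the
burden gap observed between low- and high-burden tumors (5.2 vs 15.4 per Mb)
and is echoed in every report. MSI outranks UV (mixed-signature flag raised
when both fire). A profile satisfying no rule receives its nearest rule by
normalized distance to the firing boundary with a low-confidence flag — no
profile is left unclassified. A purity sanity check (2 × median somatic VAF)
is reported alongside the copy-number-derived α without reconciliation.
Mismatch-repair screening reports exactly: nonsense SNVs and frameshifting
indels (somatic or germline) and somatic gene losses, on MLH1/MSH2/MSH6/PMS2
by default.

## Neoepitopes

All distinct 9-mers of the mutant protein overlapping a mutated residue: up
to nine for an internal missense, fewer near termini; for frameshifts, every
window touching the novel C-terminal sequence through its new stop (stop-loss
is treated frameshift-like). Synonymous changes yield nothing. Expression
filtering keeps peptides whose gene reaches `min_tpm` (default 1 TPM) and
passes everything through when no expression table exists. Clonality uses
CCF = VAF·(purity·CN + 2(1−purity))/(purity·multiplicity), multiplicity 1 by
default, clonal at CCF ≥ 0.75 — an explicit interpretation, since no
clonality computation is defined upstream; MHC binding prediction and HLA
typing are external hand-offs by design.

## Expression

log2(1+TPM); genes ranked by post-transform variance (consistent with
computing correlations on transformed values), zero-variance genes dropped
first, ties at the top-n boundary broken by gene id; Pearson correlation over
samples; complete-linkage clustering on Euclidean distances between
correlation rows (the cited plotting tool's defaults; both configurable).
Robustness sets — genes above a variance cutoff, or the full transcriptome —
are selectable.

## Synthetic data

The generators emulate the statistical shape of each input, not its physical
provenance: multinomial channel draws for spectra (trinucleotide contexts are
emitted with each SNV; no reference genome is involved), constructed
repeat-length count tables whose polymorphism counts sit deterministically on
the correct side of the μ + 3σ boundary, Gaussian noise (sd 0.05) for
relative coverage and folded Gaussian noise (sd 0.03) for per-SNP majority
fractions around the mixture-model expectations, Poisson depths (mean 100)
and Poisson het-SNP counts (mean 2/exon), and per-record filter metrics
constructed to pass or fail specific filters. Noise magnitudes are not
reported upstream and are configurable; the defaults above are typical of
moderately covered FFPE exomes. Two physical couplings are honored in the
filter fixtures: total depth < 4 forces tumor alt depth < 4 (so a `dp`
corruption necessarily co-fails `ad`), and it also caps the normal alt depth
and the strand counts (so `dp`/`ad` suppress a drawn `gad`/`sb` corruption).

What passing tests on this data do **not** show: robustness to alignment and
FFPE artifacts, GC and capture-efficiency coverage waves, subclonal
heterogeneity beyond 50/50 mixtures, indel realignment effects at
microsatellites, or real inter-locus background correlation — all upstream of
the summary statistics this pipeline consumes. Problem sizes used in the
test suite and acceptance script (catalogs of ~1000 SNVs, 500-locus MSI
panels, 200-exon genomes, 20 or fewer replicates per condition) were chosen
as the smallest sizes at which the statistical tolerances above are
meaningful.
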