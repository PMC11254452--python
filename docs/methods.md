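# Methods

This note records the statistical definitions the package implements, the
generative model behind the synthetic communities, the numerical choices
that were genuinely open, and what the validation studies do and do not
demonstrate.

## Statistics on read alignments

**Coordinates and counts.** Everything internal is 0-based half-open; GFF,
SAM and VCF convert at the boundary. The atom of all downstream statistics
is the per-position A/C/G/T read count for one sample. Read filters follow
standard profiling practice: percent identity = matches / aligned columns
(indels count as non-matches, from the NM tag) with a 0.95 floor, and
aligned fraction of the full read with a 0.75 floor. When both mates of a
fragment cover a position the first mate seen wins, so coverage and allele
support are never double-counted; N calls never count at all. How real
profilers resolve mate overlap is tool-specific; first-mate-wins is this
package's convention.

**Nucleotide diversity.** Site π = 1 − Σ_b f_b², the probability two reads
drawn with replacement differ; gene and genome π are means of site π over
positions with coverage ≥ 5. A widely circulated shorthand writes this
statistic as Σ f_b² alone; that form is a typographical truncation — it
equals 1 for a monomorphic site — and is inconsistent with the 10⁻³–10⁻²
per-site values reported for diverse sediment populations, so the
complemented form is implemented and no strict-shorthand mode is provided.

**SNV calling.** A site is a variant iff coverage ≥ 5 and at least one
non-consensus allele has frequency ≥ 5% and a read count exceeding the
99.999th percentile of Binomial(coverage, ε) with ε = 10⁻⁵ (the binomial
null is our reading of "above the expected sequencing error rate"; at
desk-scale coverages it amounts to requiring ≥ 2 supporting reads, so the
frequency clause dominates). The phrase "at least 5× the coverage and 5% of
the SNP frequency" is read as coverage ≥ 5 AND frequency ≥ 5%; the
alternative reading (≥ 5 supporting reads) is noted but not adopted.
Consensus ties break toward the reference base, else alphabetically.
Multi-allelic sites stay one record; mixed-class sites are labelled
`mixed`.

**π is computed on error-screened counts, not on SNV-filtered counts.**
Before averaging π, alleles whose counts are consistent with the binomial
error null are zeroed (the consensus always survives), but the 5% frequency
cutoff is *not* applied. Raw counts would add a ~2ε error floor (+20–40% at
π = 0.005–0.01 with ε = 10⁻³ reads); applying the full SNV cutoff would
truncate every real minor allele near 5% and bias π down by ~30%. The
error-screen-only estimator recovers analytic truth within ~−12% at 50×
(the residual bias is the loss of minor alleles drawn fewer than twice).
This coverage dependence is intrinsic: at 15× the same estimator recovers
only about half of true π, so π comparisons should be made at matched or
high (≥50×) coverage.

**conANI / popANI.** Over positions with coverage ≥ 5 (the same floor as
SNV calling, since both derive from the 5× rule): conANI counts positions
whose consensus differs from the reference; popANI counts positions where
*no* called allele (filter-passing or consensus) equals the reference.
popANI ≥ conANI by construction.

**Trimmed coverage.** Mean coverage discards the top and bottom ⌈10%⌉ of
per-position coverages, mirroring the 0.10/0.90 trim convention of coverage
profilers.

## Linkage disequilibrium

Haplotypes are observed only within single sequenced fragments (a read or
its mate pair) — the only phase a metagenome exposes; nothing is imputed
across fragments. Each SNV pair yields a 2×2 gamete table over the two most
frequent called alleles per site; fragments carrying any other allele at
either site are dropped. With p_A, p_B, p_AB the table frequencies:
D = p_AB − p_A p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)), D′ = |D|/D_max with the
usual sign-dependent D_max; both are clamped to [0,1] against float
round-off. Pairs need ≥ 5 fragments by default (mirroring the site-coverage
floor; no pair-depth rule is standard) and must be polymorphic within the
table. The distance filter drops pairs beyond mean + 2.5 SD of the pair
distances, computed per profiling run.

**LD-decay study design.** Two estimator artifacts matter when measuring
decay. First, geometry: with L-bp reads and F-bp fragments, observable pair
distances are 0..L (within a read) and roughly F−2L..F (across mates); the
decay study uses 150-bp reads with 1000-bp fragments so mate pairs span the
1/ρ = 1 kb recombination scale — with 300-bp fragments every observable
pair sits inside one recombination segment and no decay is measurable at
ρ = 10⁻³. Second, small-sample bias: E[r̂²] inflates by roughly 1/depth, and
pair depth falls with distance, which fabricates a spurious *positive*
trend at low depths; a pair-depth floor of 20 keeps the differential bias
below the decay signal. Binned mean r² (100-bp bins, pairs pooled over
replicates) then shows a strongly negative Spearman trend under
recombination (≈ −0.7 to −0.9 at ρ = 10⁻³) and none without it.

## Depth-layer differentiation

Samples are stratified into the upper (0–20 cm) and lower (20–100 cm)
layers — a fixed function of the ten depth intervals — and read counts are
pooled per layer before frequencies are computed (pooling versus averaging
per-sample frequencies is not dictated by the layer definition; pooling
treats each layer as one population, consistent with computing a single
F_ST between two units). At each SNV position covered ≥ 5× in both pools,
restricted to the two most frequent alleles across pools:

H_w = [2p₁(1−p₁) + 2p₂(1−p₂)]/2, H_b = p₁(1−p₂) + p₂(1−p₁),
F_ST = (H_b − H_w)/H_b.

Plug-in frequencies are used exactly as the estimator is written; the
sample-size-corrected variant is deliberately not the default. Negative
values are reported raw. Gene-level F_ST is the ratio of sums
Σ(H_b − H_w)/ΣH_b over the gene's defined sites — the recommended
combination for Hudson-type estimators, which weights sites by their
information content instead of averaging unstable per-site ratios.

**Screens and contrasts.** HND genes: gene π ≥ mean + 2.5 SD, with the mean
and SD pooled over all (gene, sample) values of the population — a pooled
baseline across depths; a per-depth baseline is a noted alternative. HD
genes: gene F_ST ≥ genomic mean + 2.5 SD. With zero SD nothing is flagged.
Layer contrasts use Welch's t (two-tailed, unequal variance) or the
Wilcoxon rank-sum (exact for small samples); two identical zero-variance
groups report statistic 0, p = 1. The MAF contrast conditions on SNVs that
participate in at least one pair with D′ strictly below 1 — our reading of
the near-tautological "when D′ ≤ 1" condition, i.e. sites with direct
evidence of recombination. Environmental correlations are plain Pearson r
with two-tailed p; Benjamini–Hochberg q-values are emitted alongside, never
replacing, the raw p-values on which the screens operate.

## Dereplication

ANI between two genomes is estimated by cutting one into 1-kb fragments,
computing each fragment's 16-mer containment c in the other genome, mapping
c to a fragment identity c^(1/16) (the expected intact-k-mer fraction at
per-site divergence d is (1−d)^k), and averaging over matched fragments in
both directions; alignment coverage is the matched-fragment fraction. The
estimator is exact on identical genomes and accurate to < 0.005 at 1–5%
divergence — well inside the 1% the clustering decision needs. Populations
are single-linkage components at ANI ≥ 0.97 with an alignment-coverage gate
(default 0.5; the coverage cutoff used alongside the published 97% ANI
decision is not stated and is configurable). Representatives maximise
completeness − 5 × contamination (the common dereplication default weight,
since only "highest completeness and lowest contamination" is specified),
ties to the smallest genome id. The high-frequency filter demands members
from ≥ 5 *distinct* depth samples.

## The synthetic community

The generative model is a finite pool of H haplotypes of one ancestor —
chosen for closed-form expectations, not as a claim about sediment biology.

- **Ancestor**: random genome at a target GC, with non-overlapping genes
  (ATG start, stop end, no internal stops, alternating strands) placed on a
  regular grid.
- **Mutation**: each site of each haplotype independently substitutes with
  probability µ to a uniform other base. Nonsynonymous candidates in a gene
  with suppression s ∈ [0,1] are discarded with probability s; the
  acceptance uniform is always drawn so realized counts are monotone in s
  at fixed seed. µ for a target π inverts E[π] ≈ 2µ(1 − 1/H); defaults aim
  at π ≈ 0.01, mid-range for diverse sediment populations, with 20
  haplotypes weighted by a Dirichlet(5) draw.
- **Recombination**: each output haplotype is a mosaic of the pool,
  switching source with probability ρ per bp (starting from itself, so
  ρ = 0 is the identity); the mutation ledger is rebuilt from the mosaic.
- **Layer differentiation**: differentiated genes carry ecotype-structured
  biallelic sites — every engineered site's derived allele is shared by one
  per-gene carrier subset of half the haplotypes — so reweighting that
  subset's total frequency by +δ (upper layer) / −δ (lower layer), clipped
  to [0,1] with a warning, shifts every engineered site's derived-allele
  frequency by exactly δ and the truth table stays exact. Independent
  per-haplotype mutations would give carrier sets uncorrelated with any
  single reweightable subset, and no weight change could realise a uniform
  ±δ shift; the ecotype design is what makes the reweighting mechanism
  well-defined. The engineered-site rate defaults to 4µ so a differentiated
  gene's expected heterozygosity matches the neutral background (an
  ecotype site contributes ~0.5 per site versus ~2µ for a neutral site).
  Combining ρ > 0 with differentiated genes erodes the ecotype structure;
  the recombination and differentiation studies therefore use one
  mechanism at a time.
- **Reads**: paired-end fragments sample a haplotype from the sample's
  frequency vector (per-gene vectors when the fragment overlaps a
  differentiated gene), uniform positions, uniform substitution errors at
  rate ε (default 10⁻³, Illumina-like), constant quality strings, no
  indels. Reads are emitted pre-aligned against the ancestor with true
  coordinates — read mapping is out of scope and desk-scale validation
  must not depend on an external aligner.
- **Truth table**: per-layer expected allele frequencies are
  haplotype-frequency-weighted indicators on the realized pool; expected
  site π = 1 − Σf²; expected gene F_ST applies the same Hudson
  ratio-of-sums as the estimator to the layer frequencies; syn/nonsyn
  counts come from the mutation ledger. All outputs are pure functions of
  (config, seed).

**What passing the simulation studies shows — and what it does not.** The
simulator has independent-site mutations, uniform errors, uniform fragment
positions, no indels, no strand or quality artifacts, and exact alignments.
Recovery under these conditions validates the estimators and filters as
implemented; it says nothing about mapping bias, indel noise,
quality-correlated errors or reference chimerism in real sediment data.

## Validation study designs

Problem sizes are desk-scale by design. π recovery: 200-kb genome, 40
genes, H = 20, one 50× sample, ε = 10⁻³, targets π ∈ {0.01, 0.005};
tolerance ±15% of the truth table. Selection: 40 genes (20 suppressed at
s = 0.8, 20 neutral), 50×, 5 replicates, one-sided Mann–Whitney per
replicate. LD decay: 40-kb genome, 100×, 150-bp reads/1-kb fragments,
pair depth ≥ 20, ρ ∈ {0, 10⁻³}, 5 replicates pooled. Differentiation: 50
genes with 5 differentiated at δ = 0.3; the flagging study runs at 150×
pooled per layer — the 2.5-SD threshold necessarily sits at ≈0.85 of the
engineered F_ST once 10% of genes are outliers (they inflate the genomic SD
themselves), and per-gene estimation noise is fragment-sampling-dominated
(~0.04–0.05 at 50× pooled, shared across a gene's sites), so a reliable
screen needs the ~0.02 noise that deeper pooling provides — while the
F_ST-accuracy comparison (±0.05 against truth) is evaluated at 50× pooled.
Dereplication: 12 genomes of 20 kb in 3 planted clusters at ~1% within- and
~5% between-cluster divergence.

## Known limitations

- π estimates are coverage-dependent below ~30× (minor-allele censoring).
- Read-pair LD is bounded by the fragment length; r² carries a 1/depth
  upward bias that must be depth-controlled in decay analyses.
- dN/dS is informative only when the consensus diverges from the reference
  (e.g. a dominant non-reference haplotype); under near-even haplotype
  mixtures consensus substitutions are rare and dN/dS is mostly undefined.
- The ANI estimator assumes mostly-unique 16-mers; heavy repeats would
  inflate containment.
- The two-layer F_ST treats layers as fixed pools; no correction for
  unequal sample sizes is applied by default (the corrected estimator is
  available behind a flag).
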