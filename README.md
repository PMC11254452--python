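# microdiv

Strain-level microdiversity profiling for metagenome-assembled populations.

Environmental microbial populations — here, the populations recovered from
vertically stratified sediment metagenomes — are not clonal: reads mapped
back to a representative genome reveal within-population polymorphism whose
structure records mutation, recombination, selection and differentiation.
`microdiv` computes the standard population-genomic statistics of that
polymorphism directly from read alignments, plus the outlier screens used to
find genes under unusual diversity or depth-stratified selection, and ships
a ground-truthed within-species community simulator so every estimator can
be validated against analytic expectations.

## What it computes

Given a representative genome (FASTA), gene models (GFF3) and per-sample
read alignments (SAM/BAM, filtered at ≥95% read identity and ≥75% aligned
fraction):

- **Nucleotide diversity** per site, π = 1 − (f_A² + f_C² + f_G² + f_T²)
  — the probability that two reads drawn with replacement differ — averaged
  over covered positions per gene and per genome.
- **SNV calls** at sites with coverage ≥ 5 where a non-consensus allele
  reaches 5% frequency and its read count exceeds a Binomial(coverage,
  10⁻⁵) sequencing-error null; each SNV carries its major-allele frequency
  (MAF) and synonymous/nonsynonymous class.
- **conANI / popANI** per genome × sample: identity of the consensus (resp.
  any called allele) to the reference over compared positions.
- **Linkage disequilibrium** from read-pair haplotypes: r² and D′ per SNV
  pair on a 2×2 gamete table, the 2.5-SD pair-distance filter, distance-
  binned LD decay, the D′ < 1 fraction, and the rN²/rS² contrast between
  nonsynonymous and synonymous pairs.
- **pN/pS and dN/dS** with Nei–Gojobori-style opportunity counting
  (N + S = 3 × codons), plus the raw N/S count ratio.
- **Hudson F_ST** between the 0–20 cm and 20–100 cm depth layers,
  F_ST = (H_b − H_w)/H_b with plug-in layer allele frequencies, aggregated
  per gene by ratio of sums.
- **Outlier screens**: HND genes (gene π ≥ mean + 2.5 SD within the
  population) and HD genes (gene F_ST ≥ genomic mean + 2.5 SD), layer
  contrasts (Welch t / Wilcoxon rank-sum) and Pearson correlations of π
  with environmental factors.
- **Dereplication**: pairwise genome ANI by fragment k-mer containment,
  single-linkage clustering at 97% ANI into species-like populations,
  representative selection by completeness − 5 × contamination, and the
  ≥5-distinct-depths high-frequency filter.

The simulator (`microdiv.simulate`) draws a pool of haplotypes around a
random ancestor with tunable mean π, per-gene nonsynonymous suppression,
per-bp recombination rate and a per-gene depth-layer frequency shift δ, then
emits pre-aligned paired-end reads together with a truth table of expected
per-site frequencies, π and F_ST.

## Worked example

Simulate a 50-kb, 20-gene community of 20 haplotypes at target mean
π ≈ 0.01 sequenced at 50×, then profile it:

```python
from microdiv import simulate as msim, io as mio
from microdiv.profiling import pileup, call_snvs, genome_profile

cfg = msim.SimulationConfig(seed=42, genome_length=50_000, n_genes=20,
                            samples=(msim.SampleSpec("s01", "0-5", 50.0),))
res = msim.run_simulation(cfg, "community")

reads = mio.iter_alignments(res.sam_paths["s01"])
counts = pileup(reads, res.reference)
snvs = call_snvs(counts, res.reference, res.genes)
prof = genome_profile(counts, snvs, res.reference, sample_id="s01")
print(f"sample {prof.sample_id}: coverage {prof.mean_coverage:.1f}x, breadth {prof.breadth:.3f}")
print(f"SNVs: {prof.snv_count} ({prof.snv_per_mbp:.0f}/Mbp), "
      f"mean pi {prof.mean_pi:.4f} (truth {res.truth.genome_mean_pi['s01']:.4f})")
print(f"conANI {prof.con_ani:.4f}, popANI {prof.pop_ani:.4f}, mean MAF {prof.mean_maf:.3f}")
```

prints

```
sample s01: coverage 50.1x, breadth 1.000
SNVs: 2396 (47973/Mbp), mean pi 0.0093 (truth 0.0102)
conANI 1.0000, popANI 1.0000, mean MAF 0.912
```

Reading the output: the whole genome is covered (breadth 1.0) at the
targeted depth; roughly 2.4 thousand sites carry a second allele past the
filters (≈48k SNV/Mbp at this diversity); the estimated genome mean π
(0.0093) sits within ~10% of the analytic truth-table value (0.0102); and
because no haplotype's alleles ever replace the ancestral consensus, both
ANI measures are 1 — the sample is the same "species" as its reference.

The same steps are available from the shell:

```bash
microdiv simulate --outdir community --seed 42
microdiv profile  --ref community/reference.fasta --genes community/genes.gff \
                  --bam community/s01.sam --sample-id s01 --out profiles/
microdiv fst      --ref community/reference.fasta --genes community/genes.gff \
                  --sample-sheet community/samples.tsv --out fst/
```

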