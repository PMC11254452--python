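"""Per-gene diversity statistics and selection metrics.

Nucleotide diversity at a site is the probability that two reads drawn with
replacement carry different bases, pi = 1 - sum_b f_b^2; a gene's pi is the
mean over its covered positions.  Synonymous/nonsynonymous classification
uses the standard genetic code; mutational opportunity (N and S sites) is
counted Nei-Gojobori style, with each codon contributing fractional sites
over its nine possible single-base changes.  pN/pS normalises polymorphism
counts, dN/dS consensus-substitution counts, by those opportunities.  Genes
whose pi stands >= k standard deviations above the population mean are
flagged as high-nucleotide-diversity (HND) outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from microdiv.io import BASES, GeneModel, ReferenceSet, revcomp

logger = logging.getLogger(__name__)

# Standard genetic code (codon -> amino acid; '*' = stop).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


def site_pi(counts: Sequence[int] | np.ndarray) -> float | None:
    """Per-site nucleotide diversity 1 - (f_A^2 + f_C^2 + f_G^2 + f_T^2).

    Equals the probability that two reads drawn with replacement differ.
    Returns None at zero coverage.
    """
    c = np.asarray(counts, dtype=float)
    cov = c.sum()
    if cov <= 0:
        return None
    f = c / cov
    return float(1.0 - np.dot(f, f))


def site_pi_array(counts: np.ndarray, min_coverage: int = 1) -> np.ndarray:
    """Vectorised site pi over an (L, 4) count matrix; NaN below min coverage."""
    cov = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counts / cov[:, None]
        pi = 1.0 - np.einsum("ij,ij->i", f, f)
    pi[cov < max(min_coverage, 1)] = np.nan
    return pi


def gene_pi(counts: np.ndarray, min_coverage: int = 5) -> float | None:
    """Mean site pi over a gene's positions with coverage >= min_coverage.

    ``counts`` is the (gene_length, 4) slice of the pileup (allele-filtered
    upstream if desired).  Missing (None) when no position reaches coverage.
    """
    pi = site_pi_array(counts, min_coverage=min_coverage)
    ok = ~np.isnan(pi)
    if not ok.any():
        return None
    return float(pi[ok].mean())


def coding_sequence(gene: GeneModel, reference: ReferenceSet) -> str:
    """The gene's CDS on its coding strand."""
    seg = reference.contigs[gene.contig][gene.start : gene.end]
    return revcomp(seg) if gene.strand == "-" else seg


def codon_index(gene: GeneModel, position: int) -> tuple[int, int]:
    """(codon number, offset within codon) of a genomic position in the CDS."""
    if not gene.start <= position < gene.end:
        raise ValueError(f"position {position} outside gene {gene.gene_id}")
    cds_pos = (position - gene.start) if gene.strand == "+" else (gene.end - 1 - position)
    return divmod(cds_pos, 3)


def classify_mutation(
    gene: GeneModel,
    position: int,
    ref_base: str,
    alt_base: str,
    reference: ReferenceSet,
) -> str:
    """Classify a single-base change as 'synonymous' or 'nonsynonymous'.

    The codon containing *position* is built on the coding strand
    (reverse-complemented for - strand genes), the alternate base is
    substituted, and amino acids compared under the standard code; any
    stop<->sense change is nonsynonymous.  Positions in genes that are not
    frame-complete are returned as 'intergenic' (excluded from selection
    statistics) and logged.
    """
    if not gene.frame_complete:
        logger.debug("gene %s not frame-complete; SNV treated as intergenic", gene.gene_id)
        return "intergenic"
    cds = coding_sequence(gene, reference)
    codon_no, offset = codon_index(gene, position)
    codon = cds[codon_no * 3 : codon_no * 3 + 3]
    if gene.strand == "-":
        ref_cds = revcomp(ref_base)
        alt_cds = revcomp(alt_base)
    else:
        ref_cds, alt_cds = ref_base, alt_base
    if codon[offset] != ref_cds:
        raise ValueError(
            f"reference mismatch at {gene.gene_id}:{position} "
            f"(codon has {codon[offset]}, expected {ref_cds})"
        )
    mutant = codon[:offset] + alt_cds + codon[offset + 1 :]
    return "synonymous" if GENETIC_CODE[codon] == GENETIC_CODE[mutant] else "nonsynonymous"


def opportunity_sites(gene: GeneModel, reference: ReferenceSet) -> tuple[float, float]:
    """Nei-Gojobori mutational opportunity: (N, S) fractional site counts.

    Per codon each of the nine single-base changes is classified; every codon
    position contributes (nonsyn changes)/3 to N and (syn changes)/3 to S, so
    N + S = 3 x codon count for stop-free frame-complete genes.  Reference
    codons that are themselves stops are skipped with a warning.
    """
    if not gene.frame_complete:
        raise ValueError(f"gene {gene.gene_id} is not frame-complete")
    cds = coding_sequence(gene, reference)
    n_sites = 0.0
    s_sites = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            if i + 3 < len(cds):  # internal stop: skip, terminal stop is normal
                logger.warning("internal stop codon in %s at codon %d", gene.gene_id, i // 3)
            continue
        aa = GENETIC_CODE[codon]
        for off in range(3):
            for b in BASES:
                if b == codon[off]:
                    continue
                mutant = codon[:off] + b + codon[off + 1 :]
                if GENETIC_CODE[mutant] == aa:
                    s_sites += 1 / 3
                else:
                    n_sites += 1 / 3
    return n_sites, s_sites


def gene_pnps(nd: int, sd: int, n_sites: float, s_sites: float) -> float | None:
    """pN/pS = (Nd/N) / (Sd/S); None when Sd = 0 or S = 0 (not infinity)."""
    if s_sites <= 0 or n_sites <= 0 or sd == 0:
        return None
    return (nd / n_sites) / (sd / s_sites)


def gene_dnds(nonsyn_subs: int, syn_subs: int, n_sites: float, s_sites: float) -> float | None:
    """dN/dS on consensus substitutions, raw proportion ratio.

    No multiple-hit correction: within-population divergence here is tiny
    (ANI >= 97%), so corrections are negligible.  None when syn_subs = 0.
    """
    if s_sites <= 0 or n_sites <= 0 or syn_subs == 0:
        return None
    return (nonsyn_subs / n_sites) / (syn_subs / s_sites)


def ns_ratio(nd: int, sd: int) -> float | None:
    """Unnormalised nonsynonymous:synonymous SNV count ratio; None when Sd=0."""
    if sd == 0:
        return None
    return nd / sd


@dataclass
class HndScreenResult:
    """Outcome of the high-nucleotide-diversity gene screen."""

    population_id: str
    mean_pi: float
    sd_pi: float
    threshold: float
    flagged_genes: list[str] = field(default_factory=list)


def screen_hnd(
    gene_pi_table: pd.DataFrame,
    k: float = 2.5,
    population_id: str = "population",
) -> HndScreenResult:
    """Flag genes whose pi is >= mean + k*SD of the population's gene-pi pool.

    ``gene_pi_table`` needs columns gene_id and pi (one row per gene x
    sample); mean and SD are pooled over all non-missing values across
    samples, and a gene is flagged if it reaches the threshold in any sample.
    With SD = 0 the flag requires strict excess over the mean, so a flat
    table flags nothing.
    """
    vals = gene_pi_table["pi"].dropna()
    if len(vals) < 2:
        raise ValueError("need >= 2 non-missing gene-pi values to screen")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    threshold = mean + k * sd
    tab = gene_pi_table.dropna(subset=["pi"])
    if sd == 0:
        hits = tab.loc[tab["pi"] > threshold, "gene_id"]
    else:
        hits = tab.loc[tab["pi"] >= threshold, "gene_id"]
    return HndScreenResult(
        population_id=population_id,
        mean_pi=mean,
        sd_pi=sd,
        threshold=threshold,
        flagged_genes=sorted(set(hits)),
    )


@dataclass
class GeneStats:
    """Per-gene, per-sample diversity and selection statistics."""

    gene_id: str
    sample_id: str
    covered_positions: int
    pi: float | None
    snv_count: int
    syn_snvs: int
    nonsyn_snvs: int
    syn_sites: float
    nonsyn_sites: float
    pnps: float | None
    syn_subs: int
    nonsyn_subs: int
    dnds: float | None
    hnd: bool = False

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "sample_id": self.sample_id,
            "covered_positions": self.covered_positions,
            "pi": self.pi,
            "snv_count": self.snv_count,
            "syn_snvs": self.syn_snvs,
            "nonsyn_snvs": self.nonsyn_snvs,
            "syn_sites": self.syn_sites,
            "nonsyn_sites": self.nonsyn_sites,
            "pnps": self.pnps,
            "syn_subs": self.syn_subs,
            "nonsyn_subs": self.nonsyn_subs,
            "dnds": self.dnds,
            "hnd": self.hnd,
        }


def gene_stats_table(
    counts_by_contig: Mapping[str, np.ndarray],
    snvs: Iterable,
    genes: Sequence[GeneModel],
    reference: ReferenceSet,
    sample_id: str,
    min_coverage: int = 5,
    pi_min_freq: float = 0.0,
    error_rate: float = 1e-5,
) -> list[GeneStats]:
    """Assemble :class:`GeneStats` for every frame-complete gene of one sample.

    ``counts_by_contig`` is the raw pileup; gene pi is computed on counts
    screened by the sequencing-error null (the SNV frequency cutoff is not
    applied to pi).  Consensus substitutions are positions with coverage >=
    min_coverage whose consensus differs from the reference, classified like
    SNVs.
    """
    from microdiv.profiling import consensus_codes, filtered_counts

    snv_by_gene: dict[str, list] = {}
    for s in snvs:
        if s.gene_id is not None:
            snv_by_gene.setdefault(s.gene_id, []).append(s)

    out: list[GeneStats] = []
    for gene in genes:
        if not gene.frame_complete:
            continue
        counts = counts_by_contig[gene.contig][gene.start : gene.end]
        cov = counts.sum(axis=1)
        covered = int((cov >= min_coverage).sum())
        filt = filtered_counts(counts, min_freq=pi_min_freq, error_rate=error_rate)
        pi = gene_pi(filt, min_coverage=min_coverage)
        n_sites, s_sites = opportunity_sites(gene, reference)

        nd = sd = 0
        gene_snvs = snv_by_gene.get(gene.gene_id, [])
        for s in gene_snvs:
            if s.mutation_class == "nonsynonymous":
                nd += 1
            elif s.mutation_class == "synonymous":
                sd += 1

        ref_codes = reference.codes(gene.contig)[gene.start : gene.end]
        cons = consensus_codes(counts, ref_codes)
        sub_pos = np.nonzero((cov >= min_coverage) & (cons != ref_codes) & (ref_codes < 4))[0]
        syn_subs = nonsyn_subs = 0
        for p in sub_pos:
            cls = classify_mutation(
                gene, gene.start + int(p), BASES[ref_codes[p]], BASES[cons[p]], reference
            )
            if cls == "synonymous":
                syn_subs += 1
            elif cls == "nonsynonymous":
                nonsyn_subs += 1

        out.append(
            GeneStats(
                gene_id=gene.gene_id,
                sample_id=sample_id,
                covered_positions=covered,
                pi=pi,
                snv_count=len(gene_snvs),
                syn_snvs=sd,
                nonsyn_snvs=nd,
                syn_sites=s_sites,
                nonsyn_sites=n_sites,
                pnps=gene_pnps(nd, sd, n_sites, s_sites),
                syn_subs=syn_subs,
                nonsyn_subs=nonsyn_subs,
                dnds=gene_dnds(nonsyn_subs, syn_subs, n_sites, s_sites),
            )
        )
    return out
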