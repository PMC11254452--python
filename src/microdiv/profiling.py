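"""Pileups, SNV calling and per genome x sample profiles.

SNV calling follows the coverage/frequency reading of the profiling filters:
a site is a variant iff its coverage is >= 5, at least one non-consensus
allele reaches 5% frequency, and that allele's read count exceeds what a
sequencing-error null (Binomial(coverage, 1e-5)) would plausibly produce.
conANI counts positions whose consensus differs from the reference; popANI
counts only positions where *no* called allele matches the reference, so
popANI >= conANI always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from microdiv.io import BASES, AlignedRead, GeneModel, ReferenceSet

#: Quantile of the binomial error null an allele count must exceed.
ERROR_NULL_QUANTILE = 0.99999


@dataclass
class SiteCounts:
    """Per-position A/C/G/T read counts for one sample (the atom of it all)."""

    contig: str
    position: int
    counts: np.ndarray  # shape (4,), order A,C,G,T

    @property
    def coverage(self) -> int:
        return int(self.counts.sum())


@dataclass
class SnvRecord:
    """A called variant site.

    ``alleles`` holds (base, count, frequency) for every called allele
    (consensus first, then passing minors by descending count); frequencies
    are over called alleles only.
    """

    contig: str
    position: int
    ref_base: str
    alleles: list[tuple[str, int, float]]
    maf: float
    minor_freq: float
    gene_id: str | None
    mutation_class: str  # synonymous | nonsynonymous | intergenic | mixed

    def as_row(self) -> dict:
        return {
            "contig": self.contig,
            "position": self.position,
            "ref_base": self.ref_base,
            "alleles": ",".join(b for b, _, _ in self.alleles),
            "counts": ",".join(str(c) for _, c, _ in self.alleles),
            "frequencies": ",".join(f"{f:.6g}" for _, _, f in self.alleles),
            "maf": self.maf,
            "minor_freq": self.minor_freq,
            "gene_id": self.gene_id,
            "mutation_class": self.mutation_class,
        }


@dataclass
class GenomeProfile:
    """Summary of one genome in one sample."""

    genome_id: str
    sample_id: str
    mean_coverage: float
    breadth: float
    covered_length: int
    snv_count: int
    snv_per_mbp: float | None
    mean_pi: float | None
    con_ani: float | None
    pop_ani: float | None
    mean_maf: float | None

    def as_row(self) -> dict:
        return vars(self).copy()


# ---------------------------------------------------------------------------
# Pileup

def pileup(
    reads: Iterable[AlignedRead],
    reference: ReferenceSet,
) -> dict[str, np.ndarray]:
    """Accumulate per-position base counts, deduplicating mate overlaps.

    Returns contig -> (length, 4) int32 count matrix.  When both mates of a
    fragment cover a position, the first mate seen wins and the position is
    counted once.
    """
    counts = {
        cid: np.zeros((length, 4), dtype=np.int32)
        for cid, length in reference.lengths.items()
    }
    seen: dict[tuple[str, str], np.ndarray] = {}
    for read in reads:
        if read.contig not in counts:
            raise ValueError(f"read {read.read_id} on unknown contig {read.contig!r}")
        mat = counts[read.contig]
        pos = read.ref_positions
        codes = read.base_codes
        if len(pos) and (pos[0] < 0 or pos[-1] >= mat.shape[0]):
            raise ValueError(f"read {read.read_id} outside contig bounds (corrupt input)")
        key = (read.mate_id, read.contig)
        prev = seen.get(key)
        if prev is None:
            seen[key] = pos
        else:
            keep = ~np.isin(pos, prev)
            pos, codes = pos[keep], codes[keep]
        np.add.at(mat, (pos, codes), 1)
    return counts


# ---------------------------------------------------------------------------
# Allele filtering and consensus

def _error_thresholds(coverages: np.ndarray, error_rate: float) -> np.ndarray:
    """Per-coverage allele-count threshold from the binomial error null."""
    uniq, inv = np.unique(coverages, return_inverse=True)
    thr = stats.binom.ppf(ERROR_NULL_QUANTILE, uniq, error_rate)
    return thr[inv]


def allele_pass_mask(
    counts: np.ndarray,
    min_freq: float = 0.05,
    error_rate: float = 1e-5,
) -> np.ndarray:
    """Boolean (L, 4) mask of alleles passing the frequency and error tests.

    An allele passes iff its frequency is >= min_freq and its count exceeds
    the 99.999th percentile of Binomial(coverage, error_rate).  The
    consensus allele is not special-cased here; callers add it explicitly.
    """
    cov = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / cov[:, None]
    thr = _error_thresholds(cov, error_rate)
    mask = (freq >= min_freq) & (counts > thr[:, None]) & (counts > 0)
    mask[cov == 0] = False
    return mask


def consensus_codes(counts: np.ndarray, ref_codes: np.ndarray | None = None) -> np.ndarray:
    """Consensus base code per position.

    Ties break toward the reference base when it is among the top counts,
    else to the lexicographically smallest base (A<C<G<T); argmax already
    returns the lowest index on ties.
    """
    cons = counts.argmax(axis=1).astype(np.uint8)
    if ref_codes is not None:
        valid = ref_codes < 4
        ref_idx = np.where(valid, ref_codes, 0).astype(np.intp)
        ref_count = np.take_along_axis(counts, ref_idx[:, None], axis=1)[:, 0]
        top = counts.max(axis=1)
        tie_with_ref = valid & (ref_count == top)
        cons = np.where(tie_with_ref, ref_codes, cons).astype(np.uint8)
    return cons


def filtered_counts(
    counts: np.ndarray,
    min_freq: float = 0.05,
    error_rate: float = 1e-5,
    ref_codes: np.ndarray | None = None,
) -> np.ndarray:
    """Counts with non-called alleles zeroed (consensus always retained).

    This is the count matrix pi statistics are computed on, so that a
    sequencing-error floor does not masquerade as diversity.
    """
    mask = allele_pass_mask(counts, min_freq=min_freq, error_rate=error_rate)
    cons = consensus_codes(counts, ref_codes)
    mask[np.arange(len(counts)), cons] = counts[np.arange(len(counts)), cons] > 0
    return np.where(mask, counts, 0)


# ---------------------------------------------------------------------------
# SNV calling

def _gene_lookup(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]]:
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    out = {}
    for cid, gs in by_contig.items():
        gs = sorted(gs, key=lambda g: g.start)
        starts = np.array([g.start for g in gs])
        ends = np.array([g.end for g in gs])
        out[cid] = (starts, ends, gs)
    return out


def gene_at(
    lookup: Mapping[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]],
    contig: str,
    position: int,
) -> GeneModel | None:
    """The (non-overlapping) gene containing a position, if any."""
    if contig not in lookup:
        return None
    starts, ends, gs = lookup[contig]
    i = int(np.searchsorted(starts, position, side="right")) - 1
    if i >= 0 and position < ends[i]:
        return gs[i]
    return None


def call_snvs(
    counts_by_contig: Mapping[str, np.ndarray],
    reference: ReferenceSet,
    genes: Sequence[GeneModel] = (),
    min_coverage: int = 5,
    min_freq: float = 0.05,
    error_rate: float = 1e-5,
) -> list[SnvRecord]:
    """Call SNVs from pileup counts under the coverage/frequency/error filters.

    A site is an SNV iff coverage >= min_coverage and at least one
    non-consensus allele passes the per-allele tests (frequency >= min_freq
    and count above the binomial error null).  Failing alleles are dropped
    from the record; frequencies are renormalised over called alleles.  Gene
    context and mutation class are attached; multi-allelic sites whose
    passing alleles imply different classes are 'mixed'.
    """
    from microdiv.genes import classify_mutation

    lookup = _gene_lookup(genes)
    out: list[SnvRecord] = []
    for contig, counts in counts_by_contig.items():
        cov = counts.sum(axis=1)
        ref_codes = reference.codes(contig)
        mask = allele_pass_mask(counts, min_freq=min_freq, error_rate=error_rate)
        cons = consensus_codes(counts, ref_codes)
        rows = np.arange(len(counts))
        mask_noncons = mask.copy()
        mask_noncons[rows, cons] = False
        candidate = (cov >= min_coverage) & mask_noncons.any(axis=1)
        for p in np.nonzero(candidate)[0]:
            p = int(p)
            called = [cons[p]] + [
                b for b in np.argsort(-counts[p]) if b != cons[p] and mask[p, b]
            ]
            called_counts = counts[p, called].astype(int)
            total = called_counts.sum()
            freqs = called_counts / total
            alleles = [
                (BASES[int(b)], int(c), float(f))
                for b, c, f in zip(called, called_counts, freqs)
            ]
            maf = float(freqs.max())
            gene = gene_at(lookup, contig, p)
            ref_base = BASES[ref_codes[p]] if ref_codes[p] < 4 else "N"
            if gene is None or not gene.frame_complete or ref_codes[p] >= 4:
                gene_id, mclass = (gene.gene_id if gene else None), "intergenic"
            else:
                gene_id = gene.gene_id
                classes = {
                    classify_mutation(gene, p, ref_base, BASES[int(b)], reference)
                    for b in called
                    if BASES[int(b)] != ref_base
                }
                mclass = classes.pop() if len(classes) == 1 else "mixed"
            out.append(
                SnvRecord(
                    contig=contig,
                    position=p,
                    ref_base=ref_base,
                    alleles=alleles,
                    maf=maf,
                    minor_freq=float(freqs.min()),
                    gene_id=gene_id,
                    mutation_class=mclass,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Genome profile and ANI

def trimmed_mean_coverage(coverages: np.ndarray, trim: float = 0.10) -> float:
    """Mean coverage after discarding the top and bottom *trim* deciles.

    ceil(trim * n) positions are dropped from each end of the sorted vector.
    """
    n = len(coverages)
    if n == 0:
        return float("nan")
    k = math.ceil(trim * n)
    mid = np.sort(coverages)[k : n - k]
    if len(mid) == 0:
        return float(np.mean(coverages))
    return float(mid.mean())


def consensus_and_population_ani(
    counts_by_contig: Mapping[str, np.ndarray],
    reference: ReferenceSet,
    min_coverage: int = 5,
    min_freq: float = 0.05,
    error_rate: float = 1e-5,
) -> tuple[float | None, float | None]:
    """(conANI, popANI) over positions with coverage >= min_coverage.

    conANI = 1 - (consensus != reference)/compared; popANI = 1 - (no called
    allele equals reference)/compared.  Called alleles are the filter-passing
    ones plus the consensus, so popANI >= conANI by construction.  Both are
    None when no position is compared.
    """
    compared = 0
    con_diff = 0
    pop_diff = 0
    for contig, counts in counts_by_contig.items():
        cov = counts.sum(axis=1)
        ref_codes = reference.codes(contig)
        ok = (cov >= min_coverage) & (ref_codes < 4)
        if not ok.any():
            continue
        compared += int(ok.sum())
        mask = allele_pass_mask(counts, min_freq=min_freq, error_rate=error_rate)
        cons = consensus_codes(counts, ref_codes)
        rows = np.arange(len(counts))
        mask[rows, cons] = True
        ref_idx = np.where(ref_codes < 4, ref_codes, 0).astype(np.intp)
        ref_called = np.take_along_axis(mask, ref_idx[:, None], axis=1)[:, 0]
        con_diff += int((ok & (cons != ref_codes)).sum())
        pop_diff += int((ok & ~ref_called).sum())
    if compared == 0:
        return None, None
    return 1 - con_diff / compared, 1 - pop_diff / compared


def genome_profile(
    counts_by_contig: Mapping[str, np.ndarray],
    snvs: Sequence[SnvRecord],
    reference: ReferenceSet,
    sample_id: str = "sample",
    min_coverage: int = 5,
    min_freq: float = 0.05,
    error_rate: float = 1e-5,
    trim: float = 0.10,
    pi_min_freq: float = 0.0,
) -> GenomeProfile:
    """Per genome x sample summary statistics.

    Mean coverage is decile-trimmed; SNV/Mbp normalises by the length with
    coverage >= min_coverage; mean pi averages site pi over those positions
    (None when nothing is covered).  pi uses counts screened only by the
    sequencing-error null (``pi_min_freq`` defaults to 0): the 5% frequency
    cutoff defines SNV *calls*, and applying it to pi would truncate real
    minor alleles near the cutoff.
    """
    cov_all = np.concatenate(
        [counts_by_contig[cid].sum(axis=1) for cid in reference.contigs]
    )
    covered_length = int((cov_all >= min_coverage).sum())
    breadth = float((cov_all >= 1).mean())

    pis = []
    for cid in reference.contigs:
        counts = counts_by_contig[cid]
        filt = filtered_counts(
            counts, min_freq=pi_min_freq, error_rate=error_rate,
            ref_codes=reference.codes(cid),
        )
        from microdiv.genes import site_pi_array

        pi = site_pi_array(filt, min_coverage=min_coverage)
        pis.append(pi[~np.isnan(pi)])
    pi_vals = np.concatenate(pis) if pis else np.array([])
    mean_pi = float(pi_vals.mean()) if len(pi_vals) else None

    snv_count = len(snvs)
    snv_per_mbp = snv_count / (covered_length / 1e6) if covered_length else None
    con_ani, pop_ani = consensus_and_population_ani(
        counts_by_contig, reference, min_coverage, min_freq, error_rate
    )
    mean_maf = float(np.mean([s.maf for s in snvs])) if snvs else None
    return GenomeProfile(
        genome_id=reference.genome_id,
        sample_id=sample_id,
        mean_coverage=trimmed_mean_coverage(cov_all, trim=trim),
        breadth=breadth,
        covered_length=covered_length,
        snv_count=snv_count,
        snv_per_mbp=snv_per_mbp,
        mean_pi=mean_pi,
        con_ani=con_ani,
        pop_ani=pop_ani,
        mean_maf=mean_maf,
    )
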