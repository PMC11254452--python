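"""Ground-truthed within-species community simulator.

The model is a mixture of H haplotypes of one ancestral genome.  Each
haplotype carries independent per-site substitutions (probability mu per
site, tuning the target nucleotide diversity), with nonsynonymous candidates
in genes under purifying selection discarded with probability s.
Recombination turns each haplotype into a mosaic of the pool (source-switch
probability rho per bp).  Two depth layers (0-20 vs 20-100 cm) differ by a
per-gene reweighting of the haplotype mixture that shifts the derived-allele
frequency of designated "differentiated" genes by +/-delta.  Paired-end
reads are emitted pre-aligned against the ancestor (true coordinates, no
aligner), with uniform per-base substitution errors.

Differentiated genes carry ecotype-structured polymorphism: every
engineered site's derived allele is shared by one per-gene carrier subset of
haplotypes, so reweighting that subset moves every such site's frequency by
exactly delta and the analytic truth table stays closed-form.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from microdiv.io import (
    BASES,
    DEPTH_INTERVALS,
    GeneModel,
    ReferenceSet,
    SampleSheet,
    decode_sequence,
    layer_of_interval,
    revcomp,
    write_fasta,
    write_genes,
)
from microdiv.genes import GENETIC_CODE, STOP_CODONS

CONTIG_ID = "contig_1"


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing sample: id, depth interval and target mean coverage."""

    sample_id: str
    depth_interval: str
    coverage: float = 15.0

    @property
    def layer(self) -> str:
        return layer_of_interval(self.depth_interval)


def default_samples(coverage: float = 15.0) -> tuple[SampleSpec, ...]:
    """One sample per core depth interval, like a 0-100 cm sediment column."""
    return tuple(
        SampleSpec(f"s{i + 1:02d}", interval, coverage)
        for i, interval in enumerate(DEPTH_INTERVALS)
    )


def mu_for_pi(target_pi: float, n_haplotypes: int) -> float:
    """Per-site mutation probability that yields a target mean site pi.

    With equal haplotype weights, E[pi] ~= (1 - 1/H) * 2 mu (1 - mu) plus an
    O(mu^2) term; inverting the linear part is accurate in the 0.004-0.02
    regime of interest.
    """
    return target_pi / (2.0 * (1.0 - 1.0 / n_haplotypes))


@dataclass
class SimulationConfig:
    """Parameters of one simulated community.

    Defaults emulate a 0-100 cm sediment column profiled at 10 depths:
    a 100-kb genome with 40 900-bp genes, 20 haplotypes at mean pi ~0.01
    (the middle of the 0.0045-0.0195 range typical of sediment
    populations), 15x coverage per sample, 2x100 bp pairs with 300 bp
    fragments and a 1e-3 per-base error rate.
    """

    seed: int = 0
    genome_length: int = 100_000
    gc: float = 0.5
    n_genes: int = 40
    gene_length: int = 900
    n_haplotypes: int = 20
    mu: float = mu_for_pi(0.01, 20)
    rho: float = 0.0
    selection: dict[str, float] = field(default_factory=dict)
    differentiated_genes: tuple[str, ...] = ()
    delta: float = 0.3
    differentiated_site_rate: float | None = None  # default: 2 * mu
    samples: tuple[SampleSpec, ...] = field(default_factory=default_samples)
    read_length: int = 100
    fragment_length: int = 300
    error_rate: float = 1e-3
    dirichlet_alpha: float = 5.0

    def __post_init__(self) -> None:
        for name in ("gc", "mu", "rho", "delta", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for gid, s in self.selection.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"selection factor for {gid} must be in [0, 1]")
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.gene_length % 3 != 0 or self.gene_length < 9:
            raise ValueError("gene_length must be a multiple of 3 and >= 9")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")

    @property
    def site_rate_differentiated(self) -> float:
        """Per-site probability of an engineered site in differentiated genes.

        Defaults to 4 mu: an ecotype site split ~50/50 contributes ~0.5 to
        site heterozygosity versus ~2 mu for a neutral site, so 4 mu gives
        differentiated genes roughly the same expected diversity as the
        neutral background.
        """
        if self.differentiated_site_rate is not None:
            return self.differentiated_site_rate
        return 4 * self.mu


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Ancestor

def build_ancestor(config: SimulationConfig) -> tuple[ReferenceSet, list[GeneModel]]:
    """A random genome with non-overlapping valid ORFs, deterministic per seed.

    Genes start ATG, end in a stop codon, contain no internal stop on the
    coding strand, and alternate between + and - strands.  Intergenic and
    codon bases follow the configured GC fraction.
    """
    rng = _rng(config, 0)
    L = config.genome_length
    slot = L // config.n_genes if config.n_genes else L
    if config.n_genes and config.gene_length + 2 > slot:
        raise ValueError(
            f"cannot place {config.n_genes} genes of {config.gene_length} bp "
            f"in a {L} bp genome"
        )
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    codes = rng.choice(4, size=L, p=p).astype(np.uint8)
    seq = list(decode_sequence(codes))

    genes: list[GeneModel] = []
    stops = sorted(STOP_CODONS)
    for i in range(config.n_genes):
        start = i * slot + (slot - config.gene_length) // 2
        n_internal = config.gene_length // 3 - 2
        codons = ["ATG"]
        for _ in range(n_internal):
            while True:
                codon = "".join(BASES[c] for c in rng.choice(4, size=3, p=p))
                if codon not in STOP_CODONS:
                    break
            codons.append(codon)
        codons.append(stops[rng.integers(len(stops))])
        cds = "".join(codons)
        strand = "+" if i % 2 == 0 else "-"
        segment = cds if strand == "+" else revcomp(cds)
        seq[start : start + config.gene_length] = segment
        genes.append(
            GeneModel(
                gene_id=f"gene_{i + 1:04d}",
                contig=CONTIG_ID,
                start=start,
                end=start + config.gene_length,
                strand=strand,
                frame_complete=True,
            )
        )
    reference = ReferenceSet({CONTIG_ID: "".join(seq)}, genome_id="simulated")
    return reference, genes


# ---------------------------------------------------------------------------
# Haplotypes

@dataclass
class HaplotypePool:
    """H haplotypes plus the mutation ledger and ecotype carrier sets."""

    reference: ReferenceSet
    genes: list[GeneModel]
    haplotypes: np.ndarray  # (H, L) uint8 base codes
    ledger: pd.DataFrame    # columns: position, haplotype, ref, alt, cls, gene_id
    carriers: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def length(self) -> int:
        return self.haplotypes.shape[1]


class _Classifier:
    """Cached syn/nonsyn classification against the ancestral genome."""

    def __init__(self, reference: ReferenceSet, genes: Sequence[GeneModel]):
        self.gene_index = np.full(reference.lengths[CONTIG_ID], -1, dtype=np.int32)
        self.genes = list(genes)
        self.cds = []
        for i, g in enumerate(self.genes):
            self.gene_index[g.start : g.end] = i
            seg = reference.contigs[g.contig][g.start : g.end]
            self.cds.append(revcomp(seg) if g.strand == "-" else seg)
        self._comp = {0: 3, 1: 2, 2: 1, 3: 0}

    def gene_of(self, pos: int) -> GeneModel | None:
        i = self.gene_index[pos]
        return self.genes[i] if i >= 0 else None

    def classify(self, pos: int, alt_code: int) -> tuple[str, str | None]:
        """(class, gene_id) of a substitution at *pos* to *alt_code*."""
        i = self.gene_index[pos]
        if i < 0:
            return "intergenic", None
        g = self.genes[i]
        if not g.frame_complete:
            return "intergenic", g.gene_id
        cds = self.cds[i]
        cds_pos = (pos - g.start) if g.strand == "+" else (g.end - 1 - pos)
        codon_no, off = divmod(cds_pos, 3)
        codon = cds[codon_no * 3 : codon_no * 3 + 3]
        alt = BASES[self._comp[alt_code]] if g.strand == "-" else BASES[alt_code]
        mutant = codon[:off] + alt + codon[off + 1 :]
        cls = "synonymous" if GENETIC_CODE[codon] == GENETIC_CODE[mutant] else "nonsynonymous"
        return cls, g.gene_id


def simulate_haplotypes(
    reference: ReferenceSet,
    genes: Sequence[GeneModel],
    config: SimulationConfig,
) -> HaplotypePool:
    """Draw the haplotype pool with mutation, selection and ecotype structure.

    Outside differentiated genes, each site of each haplotype mutates
    independently with probability mu to a uniform other base; nonsynonymous
    candidates in a gene with suppression s are discarded with probability s
    (the acceptance uniform is always drawn, so realized nonsynonymous
    counts are monotone in s at fixed seed).  Differentiated genes instead
    receive shared biallelic sites split along a per-gene carrier subset of
    half the haplotypes.  Every accepted mutation is recorded in the ledger.
    """
    rng = _rng(config, 1)
    anc = reference.codes(CONTIG_ID)
    L = len(anc)
    H = config.n_haplotypes
    pool = np.tile(anc, (H, 1))
    clf = _Classifier(reference, genes)
    diff_set = set(config.differentiated_genes)
    known = {g.gene_id for g in genes}
    if diff_set - known:
        raise ValueError(f"unknown differentiated genes: {sorted(diff_set - known)}")

    neutral = np.ones(L, dtype=bool)
    for g in genes:
        if g.gene_id in diff_set:
            neutral[g.start : g.end] = False

    rows: list[tuple[int, int, str, str, str, str | None]] = []
    for h in range(H):
        sites = np.nonzero((rng.random(L) < config.mu) & neutral)[0]
        jumps = rng.integers(1, 4, size=len(sites))
        accepts = rng.random(len(sites))
        for pos, jump, u in zip(sites, jumps, accepts):
            pos = int(pos)
            ref_code = int(anc[pos])
            alt_code = (ref_code + int(jump)) % 4
            cls, gene_id = clf.classify(pos, alt_code)
            if cls == "nonsynonymous" and gene_id is not None:
                s = config.selection.get(gene_id, 0.0)
                if u < s:
                    continue
            pool[h, pos] = alt_code
            rows.append((pos, h, BASES[ref_code], BASES[alt_code], cls, gene_id))

    carriers: dict[str, np.ndarray] = {}
    q = config.site_rate_differentiated
    for g in genes:
        if g.gene_id not in diff_set:
            continue
        carr = np.sort(rng.choice(H, size=H // 2, replace=False))
        carriers[g.gene_id] = carr
        sites = g.start + np.nonzero(rng.random(g.length) < q)[0]
        jumps = rng.integers(1, 4, size=len(sites))
        accepts = rng.random(len(sites))
        for pos, jump, u in zip(sites, jumps, accepts):
            pos = int(pos)
            ref_code = int(anc[pos])
            alt_code = (ref_code + int(jump)) % 4
            cls, gene_id = clf.classify(pos, alt_code)
            if cls == "nonsynonymous":
                s = config.selection.get(g.gene_id, 0.0)
                if u < s:
                    continue
            pool[carr, pos] = alt_code
            for h in carr:
                rows.append((pos, int(h), BASES[ref_code], BASES[alt_code], cls, gene_id))

    ledger = pd.DataFrame(
        rows, columns=["position", "haplotype", "ref", "alt", "cls", "gene_id"]
    ).sort_values(["position", "haplotype"], ignore_index=True)
    return HaplotypePool(
        reference=ReferenceSet(dict(reference.contigs), genome_id=reference.genome_id),
        genes=list(genes),
        haplotypes=pool,
        ledger=ledger,
        carriers=carriers,
    )


def _rebuild_ledger(pool_mat: np.ndarray, reference: ReferenceSet, genes: Sequence[GeneModel]) -> pd.DataFrame:
    anc = reference.codes(CONTIG_ID)
    clf = _Classifier(reference, genes)
    rows = []
    hs, ps = np.nonzero(pool_mat != anc[None, :])
    cache: dict[tuple[int, int], tuple[str, str | None]] = {}
    for h, pos in zip(hs, ps):
        pos = int(pos)
        alt_code = int(pool_mat[h, pos])
        key = (pos, alt_code)
        if key not in cache:
            cache[key] = clf.classify(pos, alt_code)
        cls, gene_id = cache[key]
        rows.append((pos, int(h), BASES[int(anc[pos])], BASES[alt_code], cls, gene_id))
    return pd.DataFrame(
        rows, columns=["position", "haplotype", "ref", "alt", "cls", "gene_id"]
    ).sort_values(["position", "haplotype"], ignore_index=True)


def apply_recombination(
    pool: HaplotypePool,
    config: SimulationConfig,
    return_switch_counts: bool = False,
):
    """Replace each haplotype by a mosaic of the pool.

    Walking the genome, the source haplotype switches with probability rho
    per bp (to a uniform draw from the pool, possibly itself); haplotype h
    starts from source h, so rho = 0 returns the pool unchanged.  The
    mutation ledger is rebuilt from the mosaic alleles.
    """
    if config.rho == 0:
        return (pool, np.zeros(pool.n_haplotypes, dtype=int)) if return_switch_counts else pool
    rng = _rng(config, 2)
    H, L = pool.haplotypes.shape
    new = np.empty_like(pool.haplotypes)
    switch_counts = np.zeros(H, dtype=int)
    cols = np.arange(L)
    for h in range(H):
        switch = rng.random(L) < config.rho
        switch[0] = False
        switch_counts[h] = int(switch.sum())
        seg = np.cumsum(switch)
        sources = np.empty(seg[-1] + 1, dtype=np.intp)
        sources[0] = h
        if len(sources) > 1:
            sources[1:] = rng.integers(0, H, size=len(sources) - 1)
        new[h] = pool.haplotypes[sources[seg], cols]
    out = HaplotypePool(
        reference=pool.reference,
        genes=pool.genes,
        haplotypes=new,
        ledger=_rebuild_ledger(new, pool.reference, pool.genes),
        carriers=dict(pool.carriers),
    )
    return (out, switch_counts) if return_switch_counts else out


# ---------------------------------------------------------------------------
# Layer mixtures

@dataclass
class SampleMix:
    """Haplotype frequencies for one sample: genome-wide plus per-gene overrides."""

    sample_id: str
    layer: str
    weights: np.ndarray                      # (H,), sums to 1
    gene_weights: dict[str, np.ndarray] = field(default_factory=dict)

    def weights_for(self, gene_id: str | None) -> np.ndarray:
        if gene_id is not None and gene_id in self.gene_weights:
            return self.gene_weights[gene_id]
        return self.weights


def _reweight(base: np.ndarray, carriers: np.ndarray, target: float) -> np.ndarray:
    w = base.copy()
    w0 = base[carriers].sum()
    mask = np.zeros(len(base), dtype=bool)
    mask[carriers] = True
    if target <= 0:
        w[mask] = 0.0
        w[~mask] = base[~mask] / (1 - w0)
    elif target >= 1:
        w[mask] = base[mask] / w0
        w[~mask] = 0.0
    else:
        w[mask] = base[mask] * target / w0
        w[~mask] = base[~mask] * (1 - target) / (1 - w0)
    return w


def mix_layers(pool: HaplotypePool, config: SimulationConfig) -> dict[str, SampleMix]:
    """Per-sample haplotype frequency vectors with layer differentiation.

    One baseline frequency vector is drawn (Dirichlet, concentration
    ``dirichlet_alpha``); for each differentiated gene, the carrier subset's
    total weight is shifted by +delta in upper-layer samples and -delta in
    lower-layer samples (clipped to [0, 1] with a warning when the clip
    removes all carriers or all non-carriers).
    """
    rng = _rng(config, 3)
    H = pool.n_haplotypes
    base = rng.dirichlet(np.full(H, config.dirichlet_alpha))
    layer_gene_weights: dict[str, dict[str, np.ndarray]] = {"upper": {}, "lower": {}}
    for gene_id, carr in pool.carriers.items():
        w0 = base[carr].sum()
        for layer, sign in (("upper", +1), ("lower", -1)):
            target = w0 + sign * config.delta
            if target <= 0 or target >= 1:
                warnings.warn(
                    f"delta={config.delta} clips the {layer}-layer carrier weight "
                    f"of {gene_id} (baseline {w0:.3f}); clipping to [0, 1]",
                    stacklevel=2,
                )
            layer_gene_weights[layer][gene_id] = _reweight(base, carr, target)
    return {
        spec.sample_id: SampleMix(
            sample_id=spec.sample_id,
            layer=spec.layer,
            weights=base.copy(),
            gene_weights={g: w.copy() for g, w in layer_gene_weights[spec.layer].items()},
        )
        for spec in config.samples
    }


# ---------------------------------------------------------------------------
# Reads

def generate_reads(
    pool: HaplotypePool,
    mixes: Mapping[str, SampleMix],
    config: SimulationConfig,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Emit per-sample SAM files of paired-end reads with true coordinates.

    Each fragment samples a haplotype from the sample's frequency vector
    (per-gene vectors for fragments overlapping a differentiated gene),
    a uniform start position, and per-base substitution errors at rate
    ``error_rate``.  Reads are recorded pre-aligned against the ancestor;
    byte-identical output under the same seed.
    """
    L = pool.length
    rl, flen = config.read_length, config.fragment_length
    if rl > L or flen > L:
        raise ValueError("read/fragment length exceeds genome length")
    anc = pool.reference.codes(CONTIG_ID)
    os.makedirs(outdir, exist_ok=True)
    diff_genes = [g for g in pool.genes if g.gene_id in pool.carriers]
    paths: dict[str, str] = {}
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    qual = "I" * rl

    for si, spec in enumerate(config.samples):
        rng = _rng(config, 100 + si)
        mix = mixes[spec.sample_id]
        n_frag = int(round(spec.coverage * L / (2 * rl)))
        pos = rng.integers(0, L - flen + 1, size=n_frag)

        group = np.full(n_frag, -1, dtype=np.int32)
        for gi, g in enumerate(diff_genes):
            group[(pos < g.end) & (pos + flen > g.start)] = gi
        hap = np.empty(n_frag, dtype=np.intp)
        H = pool.n_haplotypes
        sel = group == -1
        if sel.any():
            hap[sel] = rng.choice(H, size=int(sel.sum()), p=mix.weights)
        for gi, g in enumerate(diff_genes):
            sel = group == gi
            if sel.any():
                hap[sel] = rng.choice(H, size=int(sel.sum()), p=mix.weights_for(g.gene_id))

        off1 = pos[:, None] + np.arange(rl)[None, :]
        off2 = (pos + flen - rl)[:, None] + np.arange(rl)[None, :]
        reads1 = pool.haplotypes[hap[:, None], off1]
        reads2 = pool.haplotypes[hap[:, None], off2]
        for reads in (reads1, reads2):
            err = rng.random(reads.shape) < config.error_rate
            jump = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
            reads[err] = (reads[err] + jump[err]) % 4
        nm1 = (reads1 != anc[off1]).sum(axis=1)
        nm2 = (reads2 != anc[off2]).sum(axis=1)

        path = os.path.join(str(outdir), f"{spec.sample_id}.sam")
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{CONTIG_ID}\tLN:{L}\n")
            for i in range(n_frag):
                p1 = int(pos[i]) + 1
                p2 = int(pos[i]) + flen - rl + 1
                qname = f"{spec.sample_id}.frag{i:07d}"
                s1 = base_lut[reads1[i]].tobytes().decode("ascii")
                s2 = base_lut[reads2[i]].tobytes().decode("ascii")
                fh.write(
                    f"{qname}\t99\t{CONTIG_ID}\t{p1}\t60\t{rl}M\t=\t{p2}\t{flen}\t"
                    f"{s1}\t{qual}\tNM:i:{int(nm1[i])}\n"
                )
                fh.write(
                    f"{qname}\t147\t{CONTIG_ID}\t{p2}\t60\t{rl}M\t=\t{p1}\t{-flen}\t"
                    f"{s2}\t{qual}\tNM:i:{int(nm2[i])}\n"
                )
        paths[spec.sample_id] = path
    return paths


# ---------------------------------------------------------------------------
# Truth table

@dataclass
class TruthTable:
    """Analytic expectations evaluated on the realized pool and mixtures."""

    contig: str
    layer_freqs: dict[str, np.ndarray]       # layer -> (L, 4) allele frequencies
    pooled_site_pi: np.ndarray               # (L,) expected pi at pooled weights
    gene_pi: pd.DataFrame                    # gene_id, sample_id, expected_pi
    genome_mean_pi: dict[str, float]         # sample -> mean expected site pi
    site_fst: np.ndarray                     # (L,) Hudson F_ST, NaN where undefined
    gene_fst: pd.DataFrame                   # gene_id, expected_fst, n_sites
    mutation_counts: pd.DataFrame            # gene_id, syn, nonsyn
    pool_polymorphic: np.ndarray             # (L,) bool: >= 2 alleles in the pool


def site_frequencies(
    pool: HaplotypePool,
    weights: np.ndarray,
    gene_weights: Mapping[str, np.ndarray] | None = None,
    start: int = 0,
    end: int | None = None,
) -> np.ndarray:
    """Haplotype-frequency-weighted allele frequencies over [start, end)."""
    end = pool.length if end is None else end
    L = end - start
    freqs = np.zeros((L, 4))
    rows = np.arange(L)
    region_weights = weights
    for h in range(pool.n_haplotypes):
        np.add.at(freqs, (rows, pool.haplotypes[h, start:end]), region_weights[h])
    if gene_weights:
        for g in pool.genes:
            w = gene_weights.get(g.gene_id)
            if w is None:
                continue
            gs, ge = max(g.start, start), min(g.end, end)
            if gs >= ge:
                continue
            sub = np.zeros((ge - gs, 4))
            r = np.arange(ge - gs)
            for h in range(pool.n_haplotypes):
                np.add.at(sub, (r, pool.haplotypes[h, gs:ge]), w[h])
            freqs[gs - start : ge - start] = sub
    return freqs


def expected_statistics(
    pool: HaplotypePool,
    mixes: Mapping[str, SampleMix],
    config: SimulationConfig,
) -> TruthTable:
    """Evaluate the analytic truth table on the known pool and mixtures.

    Expected site pi = 1 - sum_b f_b^2 at the relevant haplotype weights;
    expected gene pi averages over gene positions; site F_ST applies the
    Hudson estimator to the two layer frequency vectors (top-two alleles);
    gene F_ST combines sites by ratio of sums, mirroring the estimator.
    """
    L = pool.length
    by_layer: dict[str, list[SampleMix]] = {"upper": [], "lower": []}
    for m in mixes.values():
        by_layer[m.layer].append(m)

    layer_freqs: dict[str, np.ndarray] = {}
    for layer, ms in by_layer.items():
        if not ms:
            continue
        acc = np.zeros((L, 4))
        for m in ms:
            acc += site_frequencies(pool, m.weights, m.gene_weights)
        layer_freqs[layer] = acc / len(ms)

    gene_rows = []
    genome_mean = {}
    pooled = np.zeros((L, 4))
    for m in mixes.values():
        f = site_frequencies(pool, m.weights, m.gene_weights)
        pooled += f
        pi = 1.0 - np.einsum("ij,ij->i", f, f)
        genome_mean[m.sample_id] = float(pi.mean())
        for g in pool.genes:
            gene_rows.append(
                {
                    "gene_id": g.gene_id,
                    "sample_id": m.sample_id,
                    "expected_pi": float(pi[g.start : g.end].mean()),
                }
            )
    pooled /= max(len(mixes), 1)
    pooled_pi = 1.0 - np.einsum("ij,ij->i", pooled, pooled)

    site_fst = np.full(L, np.nan)
    hb_arr = np.zeros(L)
    hw_arr = np.zeros(L)
    if "upper" in layer_freqs and "lower" in layer_freqs:
        fu, fl = layer_freqs["upper"], layer_freqs["lower"]
        comb = fu + fl
        order = np.argsort(-comb, axis=1, kind="stable")
        a = order[:, 0]
        b = order[:, 1]
        rows = np.arange(L)
        nu = fu[rows, a] + fu[rows, b]
        nl = fl[rows, a] + fl[rows, b]
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(nu > 0, fu[rows, a] / nu, np.nan)
            p2 = np.where(nl > 0, fl[rows, a] / nl, np.nan)
        hw_arr = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        hb_arr = p1 * (1 - p2) + p2 * (1 - p1)
        defined = np.isfinite(hb_arr) & (hb_arr > 0)
        site_fst[defined] = (hb_arr[defined] - hw_arr[defined]) / hb_arr[defined]

    gene_fst_rows = []
    for g in pool.genes:
        sl = slice(g.start, g.end)
        hb = hb_arr[sl]
        hw = hw_arr[sl]
        ok = np.isfinite(hb) & (hb > 0)
        den = hb[ok].sum()
        gene_fst_rows.append(
            {
                "gene_id": g.gene_id,
                "expected_fst": float((hb[ok] - hw[ok]).sum() / den) if den > 0 else np.nan,
                "n_sites": int(ok.sum()),
            }
        )

    led = pool.ledger.drop_duplicates(subset=["position", "alt"])
    mut_rows = []
    for g in pool.genes:
        sub = led[led["gene_id"] == g.gene_id]
        mut_rows.append(
            {
                "gene_id": g.gene_id,
                "syn": int((sub["cls"] == "synonymous").sum()),
                "nonsyn": int((sub["cls"] == "nonsynonymous").sum()),
            }
        )

    poly = (pool.haplotypes != pool.haplotypes[0][None, :]).any(axis=0)

    return TruthTable(
        contig=CONTIG_ID,
        layer_freqs=layer_freqs,
        pooled_site_pi=pooled_pi,
        gene_pi=pd.DataFrame(gene_rows),
        genome_mean_pi=genome_mean,
        site_fst=site_fst,
        gene_fst=pd.DataFrame(gene_fst_rows),
        mutation_counts=pd.DataFrame(mut_rows),
        pool_polymorphic=poly,
    )


# ---------------------------------------------------------------------------
# End-to-end convenience

@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: ReferenceSet
    genes: list[GeneModel]
    pool: HaplotypePool
    mixes: dict[str, SampleMix]
    truth: TruthTable
    sample_sheet: SampleSheet
    sam_paths: dict[str, str]
    outdir: str


def run_simulation(config: SimulationConfig, outdir: str | os.PathLike) -> SimulationResult:
    """Run the full simulator and write all artifacts to *outdir*.

    Emits reference FASTA, genes GFF3, per-sample SAM, a sample sheet TSV
    and gene-level truth tables (expected pi and F_ST).
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    reference, genes = build_ancestor(config)
    pool = simulate_haplotypes(reference, genes, config)
    pool = apply_recombination(pool, config)
    mixes = mix_layers(pool, config)
    sam_paths = generate_reads(pool, mixes, config, outdir)
    truth = expected_statistics(pool, mixes, config)

    write_fasta(reference, os.path.join(outdir, "reference.fasta"))
    write_genes(genes, os.path.join(outdir, "genes.gff"))
    sheet = SampleSheet.from_rows(
        (s.sample_id, s.depth_interval, sam_paths[s.sample_id]) for s in config.samples
    )
    sheet.write(os.path.join(outdir, "samples.tsv"))
    truth.gene_pi.to_csv(os.path.join(outdir, "truth_gene_pi.tsv"), sep="\t", index=False)
    truth.gene_fst.to_csv(os.path.join(outdir, "truth_gene_fst.tsv"), sep="\t", index=False)
    truth.mutation_counts.to_csv(
        os.path.join(outdir, "truth_mutations.tsv"), sep="\t", index=False
    )
    return SimulationResult(
        config=config,
        reference=reference,
        genes=genes,
        pool=pool,
        mixes=mixes,
        truth=truth,
        sample_sheet=sheet,
        sam_paths=sam_paths,
        outdir=outdir,
    )
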