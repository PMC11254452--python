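"""The synthetic community generator and its analytic truth tables."""

from __future__ import annotations

import os

import numpy as np
import pytest
from scipy import stats

from microdiv import io as mio
from microdiv import simulate as msim


def _cfg(**kw):
    defaults = dict(
        seed=1,
        genome_length=12_000,
        n_genes=5,
        samples=(
            msim.SampleSpec("u1", "0-5", 20.0),
            msim.SampleSpec("l1", "80-100", 20.0),
        ),
    )
    defaults.update(kw)
    return msim.SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# ancestor


def test_ancestor_genes_are_valid_orfs():
    ref, genes = msim.build_ancestor(_cfg())
    assert len(genes) == 5
    from microdiv.genes import GENETIC_CODE, STOP_CODONS, coding_sequence

    spans = sorted((g.start, g.end) for g in genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2  # non-overlapping
    for g in genes:
        cds = coding_sequence(g, ref)
        assert cds.startswith("ATG")
        assert cds[-3:] in STOP_CODONS
        internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        assert not any(c in STOP_CODONS for c in internal)
        assert g.frame_complete


def test_ancestor_deterministic_under_seed(tmp_path):
    cfg = _cfg(seed=33)
    for d in ("a", "b"):
        ref, genes = msim.build_ancestor(cfg)
        mio.write_fasta(ref, tmp_path / f"{d}.fa")
        mio.write_genes(genes, tmp_path / f"{d}.gff")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.gff").read_bytes() == (tmp_path / "b.gff").read_bytes()


def test_ancestor_gc_content_within_binomial_bound():
    cfg = _cfg(genome_length=100_000, n_genes=10, gc=0.5)
    ref, _ = msim.build_ancestor(cfg)
    seq = ref.contigs[msim.CONTIG_ID]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert gc == pytest.approx(0.5, abs=0.02)


def test_ancestor_rejects_impossible_gene_packing():
    with pytest.raises(ValueError, match="cannot place"):
        msim.build_ancestor(_cfg(genome_length=3000, n_genes=5, gene_length=900))


# ---------------------------------------------------------------------------
# haplotypes


def test_mu_zero_gives_clonal_pool():
    cfg = _cfg(mu=0.0)
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    anc = ref.codes(msim.CONTIG_ID)
    assert (pool.haplotypes == anc[None, :]).all()
    assert len(pool.ledger) == 0
    truth = msim.expected_statistics(pool, msim.mix_layers(pool, cfg), cfg)
    assert np.allclose(truth.pooled_site_pi, 0.0)


def test_full_suppression_blocks_nonsynonymous_mutations():
    cfg = _cfg(mu=0.01)
    ref, genes = msim.build_ancestor(cfg)
    target = genes[0].gene_id
    cfg_s = _cfg(mu=0.01, selection={target: 1.0})
    pool = msim.simulate_haplotypes(ref, genes, cfg_s)
    in_gene = pool.ledger[pool.ledger["gene_id"] == target]
    assert (in_gene["cls"] != "nonsynonymous").all()
    assert (in_gene["cls"] == "synonymous").any()


def test_suppression_monotone_in_s():
    cfg = _cfg(mu=0.02)
    ref, genes = msim.build_ancestor(cfg)
    target = genes[1].gene_id
    counts = []
    for s in (0.0, 0.4, 0.8, 1.0):
        c = _cfg(mu=0.02, selection={target: s})
        pool = msim.simulate_haplotypes(ref, genes, c)
        led = pool.ledger
        counts.append(
            int(((led["gene_id"] == target) & (led["cls"] == "nonsynonymous")).sum())
        )
    assert counts == sorted(counts, reverse=True)


def test_expected_pi_of_pool_matches_direct_enumeration():
    """Truth-table pi at a site equals 1 - sum f^2 over realized alleles."""
    cfg = _cfg(mu=0.01, seed=4)
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    mixes = msim.mix_layers(pool, cfg)
    truth = msim.expected_statistics(pool, mixes, cfg)
    w = np.zeros(pool.n_haplotypes)
    for m in mixes.values():
        w += m.weights
    w /= len(mixes)
    rng = np.random.default_rng(0)
    for pos in rng.integers(0, pool.length, size=200):
        in_diff = any(
            g.start <= pos < g.end
            for g in pool.genes
            if g.gene_id in pool.carriers
        )
        if in_diff:
            continue  # pooled weights differ per layer inside those genes
        f = np.zeros(4)
        np.add.at(f, pool.haplotypes[:, pos], w)
        assert truth.pooled_site_pi[pos] == pytest.approx(1 - np.dot(f, f), abs=1e-9)


# ---------------------------------------------------------------------------
# recombination


def test_rho_zero_is_identity():
    cfg = _cfg(mu=0.01, rho=0.0)
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    out = msim.apply_recombination(pool, cfg)
    assert out.haplotypes is pool.haplotypes


def test_recombination_switch_count_within_poisson_bounds():
    cfg = _cfg(genome_length=10_000, rho=1e-3, mu=0.005)
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    _, switches = msim.apply_recombination(pool, cfg, return_switch_counts=True)
    lam = 1e-3 * 10_000
    lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
    mean = switches.mean()
    assert lo <= mean <= hi


def test_recombination_rebuilds_ledger_consistently():
    cfg = _cfg(mu=0.01, rho=5e-4, seed=8)
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    out = msim.apply_recombination(pool, cfg)
    anc = ref.codes(msim.CONTIG_ID)
    n_diff = int((out.haplotypes != anc[None, :]).sum())
    assert len(out.ledger) == n_diff


# ---------------------------------------------------------------------------
# layer mixtures


def test_mix_layers_frequencies_sum_to_one():
    cfg = _cfg(mu=0.01, differentiated_genes=("gene_0002",), delta=0.3)
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    mixes = msim.mix_layers(pool, cfg)
    for m in mixes.values():
        assert m.weights.sum() == pytest.approx(1.0)
        for w in m.gene_weights.values():
            assert w.sum() == pytest.approx(1.0)


def test_delta_zero_gives_equal_layers_and_zero_fst():
    cfg = _cfg(mu=0.01, differentiated_genes=("gene_0002",), delta=0.0)
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    mixes = msim.mix_layers(pool, cfg)
    up = [m for m in mixes.values() if m.layer == "upper"][0]
    lo = [m for m in mixes.values() if m.layer == "lower"][0]
    assert np.allclose(up.weights_for("gene_0002"), lo.weights_for("gene_0002"))
    truth = msim.expected_statistics(pool, mixes, cfg)
    defined = ~np.isnan(truth.site_fst)
    assert np.allclose(truth.site_fst[defined], 0.0, atol=1e-9)


def test_delta_shifts_engineered_site_frequency_exactly():
    cfg = _cfg(mu=0.005, differentiated_genes=("gene_0003",), delta=0.3, seed=13)
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    mixes = msim.mix_layers(pool, cfg)
    gene = next(g for g in genes if g.gene_id == "gene_0003")
    carriers = pool.carriers["gene_0003"]
    up = [m for m in mixes.values() if m.layer == "upper"][0]
    lo = [m for m in mixes.values() if m.layer == "lower"][0]
    w_up = up.weights_for("gene_0003")[carriers].sum()
    w_lo = lo.weights_for("gene_0003")[carriers].sum()
    base = up.weights[carriers].sum()
    assert w_up == pytest.approx(min(base + 0.3, 1.0))
    assert w_lo == pytest.approx(max(base - 0.3, 0.0))
    # engineered sites inside the gene then differ by exactly delta + delta
    led = pool.ledger
    eng = led[(led["gene_id"] == "gene_0003")]["position"].unique()
    assert len(eng) > 0
    truth = msim.expected_statistics(pool, mixes, cfg)
    fu = truth.layer_freqs["upper"]
    fl = truth.layer_freqs["lower"]
    for pos in eng:
        alt = mio.BASE_TO_CODE[led[led["position"] == pos]["alt"].iloc[0]]
        assert fu[pos, alt] - fl[pos, alt] == pytest.approx(w_up - w_lo, abs=1e-9)


def test_expected_fst_example_values():
    """Hudson formula on engineered frequencies: (0.8, 0.2) -> ~0.529."""
    from microdiv.differentiation import hudson_fst

    _, _, fst = hudson_fst(0.8, 0.2)
    assert fst == pytest.approx(0.36 / 0.68)
    _, _, fst_fixed = hudson_fst(1.0, 0.0)
    assert fst_fixed == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# reads


def test_reads_deterministic_and_coverage_on_target(tmp_path):
    cfg = _cfg(seed=21, genome_length=10_000, n_genes=4,
               samples=(msim.SampleSpec("s01", "0-5", 50.0),))
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    mixes = msim.mix_layers(pool, cfg)
    p1 = msim.generate_reads(pool, mixes, cfg, tmp_path / "a")
    p2 = msim.generate_reads(pool, mixes, cfg, tmp_path / "b")
    b1 = open(p1["s01"], "rb").read()
    b2 = open(p2["s01"], "rb").read()
    assert b1 == b2  # byte-identical under the same seed
    emitted = sum(
        len(line.split("\t")[9])
        for line in b1.decode().splitlines()
        if not line.startswith("@")
    )
    assert emitted == pytest.approx(50.0 * 10_000, rel=0.05)


def test_error_free_single_haplotype_reads_match_it(tmp_path):
    cfg = _cfg(
        seed=22,
        genome_length=8_000,
        n_genes=3,
        n_haplotypes=2,
        mu=0.005,
        error_rate=0.0,
        dirichlet_alpha=1e9,  # effectively equal weights; read check below
        samples=(msim.SampleSpec("s01", "0-5", 10.0),),
    )
    ref, genes = msim.build_ancestor(cfg)
    pool = msim.simulate_haplotypes(ref, genes, cfg)
    mixes = msim.mix_layers(pool, cfg)
    paths = msim.generate_reads(pool, mixes, cfg, tmp_path)
    for read in mio.iter_alignments(paths["s01"], 0.0, 0.0):
        calls = read.base_codes
        matches = [
            (calls == pool.haplotypes[h, read.ref_positions]).all()
            for h in range(pool.n_haplotypes)
        ]
        assert any(matches)  # every read is an exact copy of one haplotype


def test_run_simulation_writes_all_artifacts(small_sim):
    out = small_sim.outdir
    for name in (
        "reference.fasta",
        "genes.gff",
        "samples.tsv",
        "s01.sam",
        "truth_gene_pi.tsv",
        "truth_gene_fst.tsv",
        "truth_mutations.tsv",
    ):
        assert os.path.exists(os.path.join(out, name)), name
    ref_back = mio.read_fasta(os.path.join(out, "reference.fasta"))
    assert ref_back.contigs == small_sim.reference.contigs
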