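"""Gene-level diversity statistics, codon machinery and the HND screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from microdiv.genes import (
    classify_mutation,
    gene_dnds,
    gene_pi,
    gene_pnps,
    ns_ratio,
    opportunity_sites,
    screen_hnd,
    site_pi,
)
from microdiv.io import BASES, GeneModel, ReferenceSet
from tests.conftest import make_counts


# ---------------------------------------------------------------------------
# site pi


@pytest.mark.parametrize(
    "counts,expected",
    [
        ({"A": 10}, 0.0),
        ({"A": 5, "C": 5}, 0.5),
        ({"A": 8, "G": 2}, 0.32),
    ],
)
def test_site_pi_examples(counts, expected):
    row = make_counts(1, {0: counts})[0]
    assert site_pi(row) == pytest.approx(expected)


def test_site_pi_zero_coverage_is_missing():
    assert site_pi([0, 0, 0, 0]) is None


@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=4).filter(
        lambda c: sum(c) > 0
    )
)
@settings(max_examples=200, deadline=None)
def test_site_pi_equals_pairwise_mismatch_probability(counts):
    """pi must equal P(two reads drawn with replacement differ), enumerated."""
    n = sum(counts)
    mismatch = sum(
        (counts[i] / n) * (counts[j] / n)
        for i in range(4)
        for j in range(4)
        if i != j
    )
    assert site_pi(counts) == pytest.approx(mismatch, abs=1e-12)


def test_gene_pi_is_mean_over_covered_positions():
    counts = make_counts(100, {i: {"A": 10} for i in range(100)})
    counts[7] = make_counts(1, {0: {"A": 8, "G": 2}})[0]
    assert gene_pi(counts, min_coverage=5) == pytest.approx(0.32 / 100)


def test_gene_pi_missing_when_nothing_covered():
    counts = make_counts(30, {i: {"A": 2} for i in range(30)})
    assert gene_pi(counts, min_coverage=5) is None


# ---------------------------------------------------------------------------
# mutation classification


def test_classify_synonymous_third_position(tiny_reference, tiny_gene):
    # codon TTT at positions 9-11; TTT->TTC is Phe->Phe
    assert (
        classify_mutation(tiny_gene, 11, "T", "C", tiny_reference) == "synonymous"
    )


def test_classify_nonsynonymous_first_position(tiny_reference, tiny_gene):
    # TTT->ATT is Phe->Ile
    assert (
        classify_mutation(tiny_gene, 9, "T", "A", tiny_reference) == "nonsynonymous"
    )


def test_classify_minus_strand_uses_reverse_complement(minus_reference, minus_gene):
    # CDS is ATG GGG TAA; genomic position 7 holds C (complement of CDS G).
    # Genomic C->T means CDS G->A: GGG->GAG (Gly->Glu), nonsynonymous;
    # genomic C->A means CDS G->T: GGG->GTG? position maps to codon offset 1.
    assert (
        classify_mutation(minus_gene, 6, "C", "T", minus_reference) == "nonsynonymous"
    )


def test_classify_stop_gain_is_nonsynonymous():
    # gene ATG TGG TAA: TGG (Trp) -> TGA (stop) at CDS position 5
    ref = ReferenceSet({"c1": "ATGTGGTAA"})
    gene = GeneModel("g", "c1", 0, 9, "+")
    assert classify_mutation(gene, 5, "G", "A", ref) == "nonsynonymous"


def test_classify_against_full_cds_translation_oracle():
    """Per-codon lookup must agree with translating the whole mutant CDS."""
    rng = np.random.default_rng(42)
    n_checked = 0
    while n_checked < 1000:
        n_codons = int(rng.integers(3, 30))
        cds = "ATG" + "".join(
            BASES[b]
            for b in rng.integers(0, 4, size=3 * (n_codons - 2))
        ) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        from microdiv.io import revcomp

        segment = cds if strand == "+" else revcomp(cds)
        pad = "".join(BASES[b] for b in rng.integers(0, 4, size=5))
        ref = ReferenceSet({"c1": pad + segment + pad})
        gene = GeneModel("g", "c1", 5, 5 + len(cds), strand)
        pos = int(rng.integers(gene.start, gene.end))
        ref_base = ref.contigs["c1"][pos]
        alt_base = BASES[int((BASES.index(ref_base) + rng.integers(1, 4)) % 4)]
        got = classify_mutation(gene, pos, ref_base, alt_base, ref)

        cds_pos = (pos - gene.start) if strand == "+" else (gene.end - 1 - pos)
        alt_cds = alt_base if strand == "+" else revcomp(alt_base)
        mutant = cds[:cds_pos] + alt_cds + cds[cds_pos + 1 :]
        before = str(Seq(cds).translate())
        after = str(Seq(mutant).translate())
        expected = "synonymous" if before == after else "nonsynonymous"
        assert got == expected, (cds, strand, pos, ref_base, alt_base)
        n_checked += 1


# ---------------------------------------------------------------------------
# opportunity sites


def test_opportunity_single_codon_ttt():
    # only TTT->TTC is synonymous among the 9 changes
    ref = ReferenceSet({"c1": "TTT"})
    gene = GeneModel("g", "c1", 0, 3, "+")
    n, s = opportunity_sites(gene, ref)
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_opportunity_tryptophan_has_no_synonymous_change():
    ref = ReferenceSet({"c1": "TGG"})
    gene = GeneModel("g", "c1", 0, 3, "+")
    n, s = opportunity_sites(gene, ref)
    assert s == 0.0 and n == pytest.approx(3.0)


def test_opportunity_conservation_over_random_orfs():
    """N + S = 3 x codons for stop-free frame-complete genes, any strand."""
    rng = np.random.default_rng(7)
    from microdiv.io import revcomp
    from microdiv.genes import STOP_CODONS

    for _ in range(50):
        n_codons = int(rng.integers(2, 40))
        codons = ["ATG"]
        while len(codons) < n_codons:
            c = "".join(BASES[b] for b in rng.integers(0, 4, size=3))
            if c not in STOP_CODONS:
                codons.append(c)
        cds = "".join(codons)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = cds if strand == "+" else revcomp(cds)
        ref = ReferenceSet({"c1": seq})
        gene = GeneModel("g", "c1", 0, len(cds), strand)
        n, s = opportunity_sites(gene, ref)
        assert n + s == pytest.approx(3 * n_codons, abs=1e-9)


# ---------------------------------------------------------------------------
# ratio statistics


@pytest.mark.parametrize(
    "fn,args,expected",
    [
        (gene_pnps, (3, 3, 600, 200), 1 / 3),
        (gene_pnps, (0, 5, 600, 200), 0.0),
        (gene_pnps, (3, 0, 600, 200), None),  # Sd=0 -> missing, not infinity
        (gene_dnds, (2, 2, 600, 200), 1 / 3),
        (gene_dnds, (0, 3, 600, 200), 0.0),
        (gene_dnds, (2, 0, 600, 200), None),
        (ns_ratio, (4, 8), 0.5),
        (ns_ratio, (4, 0), None),
    ],
)
def test_selection_ratios(fn, args, expected):
    got = fn(*args)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


# ---------------------------------------------------------------------------
# HND screen


def test_screen_hnd_flags_single_outlier():
    rows = [{"gene_id": f"g{i}", "sample_id": "s", "pi": 0.001} for i in range(100)]
    rows.append({"gene_id": "gX", "sample_id": "s", "pi": 0.05})
    res = screen_hnd(pd.DataFrame(rows))
    assert res.flagged_genes == ["gX"]
    assert res.threshold == pytest.approx(
        res.mean_pi + 2.5 * res.sd_pi
    )


def test_screen_hnd_flat_table_flags_nothing():
    rows = [{"gene_id": f"g{i}", "sample_id": "s", "pi": 0.01} for i in range(10)]
    assert screen_hnd(pd.DataFrame(rows)).flagged_genes == []


def test_screen_hnd_k0_flags_everything_at_or_above_mean():
    rows = [
        {"gene_id": "a", "sample_id": "s", "pi": 0.01},
        {"gene_id": "b", "sample_id": "s", "pi": 0.02},
        {"gene_id": "c", "sample_id": "s", "pi": 0.03},
    ]
    assert screen_hnd(pd.DataFrame(rows), k=0.0).flagged_genes == ["b", "c"]


def test_dnds_below_one_under_nonsynonymous_suppression():
    """A dominant-haplotype population with suppressed nonsynonymous mutations
    accumulates consensus substitutions with dN/dS well below 1, while
    neutral genes sit near the ~3:1 mutational opportunity ratio."""
    from microdiv import io as mio
    from microdiv import simulate as msim
    from microdiv.genes import gene_stats_table
    from microdiv.profiling import call_snvs, pileup

    kwargs = dict(
        genome_length=24_000,
        n_genes=16,
        mu=0.01,
        n_haplotypes=4,
        dirichlet_alpha=0.15,  # uneven weights -> one haplotype dominates
        error_rate=0.0,
        samples=(msim.SampleSpec("s01", "0-5", 50.0),),
    )
    cfg0 = msim.SimulationConfig(seed=4, **kwargs)
    _, genes = msim.build_ancestor(cfg0)
    suppressed = {g.gene_id for g in genes[:8]}
    cfg = msim.SimulationConfig(
        seed=4, selection={g: 0.9 for g in suppressed}, **kwargs
    )
    res = msim.run_simulation(cfg, "scratch/test_dnds_sim")
    counts = pileup(mio.iter_alignments(res.sam_paths["s01"]), res.reference)
    snvs = call_snvs(counts, res.reference, res.genes)
    rows = gene_stats_table(counts, snvs, res.genes, res.reference, "s01")

    def pooled_dnds(gene_ids):
        n_sub = sum(r.nonsyn_subs for r in rows if r.gene_id in gene_ids)
        s_sub = sum(r.syn_subs for r in rows if r.gene_id in gene_ids)
        n_opp = sum(r.nonsyn_sites for r in rows if r.gene_id in gene_ids)
        s_opp = sum(r.syn_sites for r in rows if r.gene_id in gene_ids)
        return (n_sub / n_opp) / (s_sub / s_opp)

    neutral = {r.gene_id for r in rows} - suppressed
    assert pooled_dnds(suppressed) < 0.5
    assert pooled_dnds(neutral) > 0.5
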