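"""Reproducibility studies: exact oracles and simulation-based recovery.

Each function runs one self-contained study on synthetic data and returns
plain numbers, so the same code backs the test suite and the acceptance
script.  Problem sizes are desk-scale: genomes of 40-200 kb, 5 replicates
per stochastic study, coverages of 50-100x.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from microdiv import io as mio
from microdiv import simulate as msim
from microdiv.differentiation import (
    fst_table,
    gene_fst_table,
    hudson_fst,
    layer_pooled_counts,
    screen_hd,
)
from microdiv.dereplicate import (
    cluster_populations,
    pairwise_ani,
    select_representative,
    PopulationCluster,
)
from microdiv.genes import gene_stats_table, site_pi
from microdiv.linkage import (
    LinkagePair,
    collect_pairs,
    compute_ld,
    distance_filter,
    ld_decay,
)
from microdiv.profiling import call_snvs, genome_profile, pileup


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31)


# ---------------------------------------------------------------------------
# exact oracles


def site_pi_oracle_error(seed: int, n: int = 1000) -> float:
    """Max |site_pi - with-replacement pairwise-mismatch probability|."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        counts = rng.integers(0, 60, size=4)
        if counts.sum() == 0:
            counts[0] = 1
        total = counts.sum()
        mismatch = sum(
            (counts[i] / total) * (counts[j] / total)
            for i in range(4)
            for j in range(4)
            if i != j
        )
        worst = max(worst, abs(site_pi(counts) - mismatch))
    return worst


def ld_oracle_error(seed: int, n: int = 1000) -> float:
    """Max |(r2, D') - brute-force 2x2 definition| over random tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n:
        t = tuple(int(x) for x in rng.integers(0, 50, size=4))
        total = sum(t)
        if total == 0:
            continue
        p_a = (t[0] + t[1]) / total
        p_b = (t[0] + t[2]) / total
        got = compute_ld(t)
        if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
            assert got is None
            done += 1
            continue
        d = t[0] / total - p_a * p_b
        r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
        if d == 0:
            dprime = 0.0
        else:
            d_max = (
                min(p_a * (1 - p_b), (1 - p_a) * p_b)
                if d > 0
                else min(p_a * p_b, (1 - p_a) * (1 - p_b))
            )
            dprime = abs(d) / d_max
        worst = max(worst, abs(got[0] - min(r2, 1.0)), abs(got[1] - min(dprime, 1.0)))
        done += 1
    return worst


def fst_oracle_error(seed: int, n: int = 1000) -> float:
    """Max |hudson_fst - direct heterozygosity evaluation| over random (p1, p2)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        p1, p2 = rng.random(2)
        h_w = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        h_b = p1 * (1 - p2) + p2 * (1 - p1)
        got_hw, got_hb, got_fst = hudson_fst(p1, p2)
        worst = max(worst, abs(got_hw - h_w), abs(got_hb - h_b))
        if h_b > 0:
            worst = max(worst, abs(got_fst - (h_b - h_w) / h_b))
    return worst


# ---------------------------------------------------------------------------
# filter behaviour


def snv_filter_cases() -> int:
    """How many of the three documented call/no-call cases behave as stated."""
    ref = mio.ReferenceSet({"c1": "A"})
    ok = 0
    calls = call_snvs({"c1": np.array([[17, 0, 3, 0]], dtype=np.int32)}, ref)
    ok += len(calls) == 1 and calls[0].maf == 0.85
    ok += call_snvs({"c1": np.array([[3, 0, 1, 0]], dtype=np.int32)}, ref) == []
    ok += call_snvs({"c1": np.array([[199, 0, 1, 0]], dtype=np.int32)}, ref) == []
    return ok


def gaussian_distance_retention(seed: int, n: int = 5000) -> float:
    """Retained fraction of Gaussian pair distances under the 2.5-SD filter."""
    rng = np.random.default_rng(seed)
    d = np.clip(rng.normal(200, 40, size=n).astype(int), 1, None)
    pairs = [
        LinkagePair("c1", 0, int(x), 5, 0, 0, 5, 1.0, 1.0) for x in d
    ]
    _, report = distance_filter(pairs)
    return report["retained_fraction"]


# ---------------------------------------------------------------------------
# parameter recovery


def _profile_sample(res, sample_id):
    reads = mio.iter_alignments(res.sam_paths[sample_id])
    counts = pileup(reads, res.reference)
    snvs = call_snvs(counts, res.reference, res.genes)
    prof = genome_profile(counts, snvs, res.reference, sample_id)
    return counts, snvs, prof


def pi_recovery_study(
    seed: int,
    target_pi: float,
    genome_length: int = 200_000,
    n_genes: int = 40,
    coverage: float = 50.0,
    workdir: str = "scratch/eval_pi",
) -> dict:
    """Estimate genome mean pi from reads and compare with the truth table.

    One sample at *coverage*, sequencing error 1e-3.  Returns truth,
    estimate and the relative error (%).  popANI - conANI is reported as a
    sanity margin (non-negative by construction).
    """
    cfg = msim.SimulationConfig(
        seed=_sub_seed(seed, int(target_pi * 1e4)),
        genome_length=genome_length,
        n_genes=n_genes,
        mu=msim.mu_for_pi(target_pi, 20),
        error_rate=1e-3,
        samples=(msim.SampleSpec("s01", "0-5", coverage),),
    )
    res = msim.run_simulation(cfg, workdir)
    _, _, prof = _profile_sample(res, "s01")
    truth = res.truth.genome_mean_pi["s01"]
    return {
        "truth": truth,
        "estimate": prof.mean_pi,
        "rel_err_pct": 100.0 * (prof.mean_pi - truth) / truth,
        "pop_minus_con_ani": prof.pop_ani - prof.con_ani,
        "snv_per_mbp": prof.snv_per_mbp,
        "n_sites": genome_length,
    }


# ---------------------------------------------------------------------------
# selection recovery


def selection_study(
    seed: int,
    replicates: int = 5,
    n_genes: int = 40,
    coverage: float = 50.0,
    suppression: float = 0.8,
    workdir: str = "scratch/eval_sel",
) -> dict:
    """pN/pS contrast between suppressed (s=0.8) and neutral (s=0) genes.

    Half the genes carry nonsynonymous suppression; per replicate a
    one-sided Mann-Whitney test asks whether suppressed genes have lower
    pN/pS.  Returns the per-replicate p-values and pooled medians.
    """
    pvals = []
    med_supp, med_neut = [], []
    for r in range(replicates):
        cfg0 = msim.SimulationConfig(
            seed=_sub_seed(seed, 10 + r),
            genome_length=n_genes * 1200,
            n_genes=n_genes,
            samples=(msim.SampleSpec("s01", "0-5", coverage),),
        )
        _, genes = msim.build_ancestor(cfg0)
        suppressed = [g.gene_id for g in genes[: n_genes // 2]]
        cfg = msim.SimulationConfig(
            seed=cfg0.seed,
            genome_length=cfg0.genome_length,
            n_genes=n_genes,
            selection={g: suppression for g in suppressed},
            samples=cfg0.samples,
        )
        res = msim.run_simulation(cfg, f"{workdir}_{r}")
        counts, snvs, _ = _profile_sample(res, "s01")
        stats_rows = gene_stats_table(
            counts, snvs, res.genes, res.reference, "s01"
        )
        by_arm = {"supp": [], "neut": []}
        for row in stats_rows:
            if row.pnps is None:
                continue
            arm = "supp" if row.gene_id in suppressed else "neut"
            by_arm[arm].append(row.pnps)
        mw = stats.mannwhitneyu(
            by_arm["supp"], by_arm["neut"], alternative="less"
        )
        pvals.append(float(mw.pvalue))
        med_supp.append(float(np.median(by_arm["supp"])))
        med_neut.append(float(np.median(by_arm["neut"])))
    return {
        "pvalues": pvals,
        "max_p": max(pvals),
        "median_pnps_suppressed": float(np.mean(med_supp)),
        "median_pnps_neutral": float(np.mean(med_neut)),
        "n_genes_per_arm": n_genes // 2,
    }


# ---------------------------------------------------------------------------
# recombination signature


def ld_decay_study(
    seed: int,
    replicates: int = 5,
    genome_length: int = 40_000,
    coverage: float = 100.0,
    min_pair_depth: int = 20,
    bin_width: int = 100,
    workdir: str = "scratch/eval_ld",
) -> dict:
    """Binned r2-vs-distance trend with and without recombination.

    Reads are 150 bp with 1 kb fragments so mate pairs span the 1/rho
    recombination scale; pairs from all replicates are pooled per condition
    before binning.  Returns the pooled Spearman trend for rho=0 and
    rho=1e-3 plus the D' < 1 fraction under strong recombination.
    """
    trends = {}
    for rho in (0.0, 1e-3):
        pooled = []
        for r in range(replicates):
            cfg = msim.SimulationConfig(
                seed=_sub_seed(seed, 20 + r),
                genome_length=genome_length,
                n_genes=16,
                rho=rho,
                read_length=150,
                fragment_length=1000,
                samples=(msim.SampleSpec("s01", "0-5", coverage),),
            )
            res = msim.run_simulation(cfg, f"{workdir}_{rho}_{r}")
            reads = mio.iter_alignments(res.sam_paths["s01"])
            counts = pileup(reads, res.reference)
            snvs = call_snvs(counts, res.reference, res.genes)
            reads = mio.iter_alignments(res.sam_paths["s01"])
            pairs = collect_pairs(reads, snvs, min_pair_depth=min_pair_depth)
            pairs, _ = distance_filter(pairs)
            pooled.extend(pairs)
        _, trend = ld_decay(pooled, bin_width)
        trends[rho] = trend

    # strong recombination -> all four gametes at most pairs
    cfg = msim.SimulationConfig(
        seed=_sub_seed(seed, 30),
        genome_length=20_000,
        n_genes=8,
        rho=0.05,
        samples=(msim.SampleSpec("s01", "0-5", 100.0),),
    )
    res = msim.run_simulation(cfg, f"{workdir}_strong")
    reads = mio.iter_alignments(res.sam_paths["s01"])
    counts = pileup(reads, res.reference)
    snvs = call_snvs(counts, res.reference, res.genes)
    reads = mio.iter_alignments(res.sam_paths["s01"])
    strong_pairs = collect_pairs(reads, snvs, min_pair_depth=20)
    from microdiv.linkage import dprime_lt1_fraction

    frac = dprime_lt1_fraction(strong_pairs) if strong_pairs else float("nan")
    return {
        "trend_rho0": trends[0.0],
        "trend_rho1e3": trends[1e-3],
        "dprime_lt1_fraction_recombining": frac,
        "n_replicates": replicates,
    }


# ---------------------------------------------------------------------------
# differentiation recovery


def _fst_replicate(seed, n_genes, n_differentiated, delta, layer_coverage, workdir):
    """One two-layer simulation; returns (screen, gene table, truth, engineered)."""
    uppers = ("0-5", "5-10", "10-15", "15-20")
    lowers = ("20-30", "30-40", "40-50", "50-60", "60-80", "80-100")
    diff_genes = tuple(
        f"gene_{i:04d}"
        for i in np.linspace(5, n_genes - 2, n_differentiated).astype(int)
    )
    samples = tuple(
        msim.SampleSpec(f"u{i}", iv, layer_coverage / len(uppers))
        for i, iv in enumerate(uppers)
    ) + tuple(
        msim.SampleSpec(f"l{i}", iv, layer_coverage / len(lowers))
        for i, iv in enumerate(lowers)
    )
    cfg = msim.SimulationConfig(
        seed=seed,
        genome_length=n_genes * 1250,
        n_genes=n_genes,
        differentiated_genes=diff_genes,
        delta=delta,
        samples=samples,
    )
    res = msim.run_simulation(cfg, workdir)
    counts_by_sample, layer = {}, {}
    for rec in res.sample_sheet:
        reads = mio.iter_alignments(rec.path)
        counts_by_sample[rec.sample_id] = pileup(reads, res.reference)
        layer[rec.sample_id] = rec.layer
    pools = layer_pooled_counts(counts_by_sample, layer)
    pooled_all = {
        c: pools["upper"][c] + pools["lower"][c] for c in res.reference.contigs
    }
    snvs = call_snvs(pooled_all, res.reference, res.genes)
    records = fst_table(pools["upper"], pools["lower"], snvs)
    gene_tab = gene_fst_table(records)
    screen = screen_hd(gene_tab)
    truth = res.truth.gene_fst.set_index("gene_id")["expected_fst"]
    return screen, gene_tab, truth, diff_genes


def differentiation_study(
    seed: int,
    replicates: int = 5,
    n_genes: int = 50,
    n_differentiated: int = 5,
    delta: float = 0.3,
    screen_coverage: float = 150.0,
    accuracy_coverage: float = 50.0,
    workdir: str = "scratch/eval_fst",
) -> dict:
    """HD-screen recovery of engineered layer-differentiated genes.

    Two sub-studies: the flagging study runs at *screen_coverage* pooled
    reads per layer, where per-gene F_ST sampling noise (~0.02) is small
    against the screen margin (the 2.5-SD threshold sits at ~85% of the
    engineered F_ST because the outliers inflate the genomic SD themselves);
    the accuracy study compares estimated gene F_ST with the analytic truth
    at *accuracy_coverage* pooled per layer.
    """
    tp = fp = 0
    for r in range(replicates):
        screen, gene_tab, truth, diff_genes = _fst_replicate(
            _sub_seed(seed, 40 + r), n_genes, n_differentiated, delta,
            screen_coverage, f"{workdir}_screen_{r}",
        )
        flagged = set(screen.flagged_genes)
        tp += len(flagged & set(diff_genes))
        fp += len(flagged - set(diff_genes))

    fst_errors = []
    for r in range(replicates):
        _, gene_tab, truth, diff_genes = _fst_replicate(
            _sub_seed(seed, 60 + r), n_genes, n_differentiated, delta,
            accuracy_coverage, f"{workdir}_acc_{r}",
        )
        est = gene_tab.set_index("gene_id")["fst"]
        for g in diff_genes:
            if g in est.index and np.isfinite(truth[g]):
                fst_errors.append(abs(float(est[g]) - float(truth[g])))
    return {
        "true_positives": tp,
        "n_engineered": replicates * n_differentiated,
        "false_positives": fp,
        "mean_abs_gene_fst_error": float(np.mean(fst_errors)),
        "n_replicates": replicates,
    }


# ---------------------------------------------------------------------------
# dereplication


def dereplication_study(seed: int, genome_length: int = 20_000, workdir=None) -> dict:
    """Planted-partition recovery at the 97% cutoff + representative choice."""
    rng = np.random.default_rng(seed)

    def random_genome(r, gid):
        seq = "".join(mio.BASES[b] for b in r.integers(0, 4, size=genome_length))
        return mio.ReferenceSet({"c1": seq}, genome_id=gid)

    def mutate(ref, rate, gid):
        seq = list(ref.contigs["c1"])
        for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
            seq[i] = mio.BASES[(mio.BASES.index(seq[i]) + int(rng.integers(1, 4))) % 4]
        return mio.ReferenceSet({"c1": "".join(seq)}, genome_id=gid)

    root = random_genome(np.random.default_rng(seed + 1), "root")
    genomes = {}
    for k in range(3):
        anc = mutate(root, 0.025, f"anc{k}")  # ~5% between clusters
        for j in range(4):
            gid = f"c{k}_g{j}"
            genomes[gid] = mutate(anc, 0.005, gid)  # ~1% within
    ids = sorted(genomes)
    pairs = [
        pairwise_ani(genomes[a], genomes[b])
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    ]
    clusters = cluster_populations(ids, pairs)
    got = sorted(tuple(c.members) for c in clusters)
    expected = sorted(tuple(sorted(f"c{k}_g{j}" for j in range(4))) for k in range(3))
    exact = int(got == expected)

    quality = {"a": (95.0, 2.0), "b": (90.0, 0.0)}
    rep_ok = int(
        select_representative(PopulationCluster("a", ["a", "b"]), quality) == "b"
    )
    tie_ok = int(
        select_representative(
            PopulationCluster("a", ["a", "b"]), {"a": (90.0, 0.0), "b": (90.0, 0.0)}
        )
        == "a"
    )
    within = [p.ani for p in pairs if p.genome_i.split("_")[0] == p.genome_j.split("_")[0]]
    return {
        "exact_recovery": exact,
        "representative_correct": rep_ok,
        "tie_break_correct": tie_ok,
        "mean_within_cluster_ani": float(np.mean(within)),
        "n_genomes": len(ids),
    }
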