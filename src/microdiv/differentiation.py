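"""Depth-layer differentiation: Hudson F_ST, outlier screens and contrasts.

Reads from the 0-20 cm (upper) and 20-100 cm (lower) samples are pooled at
the count level per layer; at each site covered >= 5x in both pools the
Hudson estimator F_ST = (H_b - H_w)/H_b is evaluated on plug-in allele
frequencies, where H_w is the mean within-layer heterozygosity and H_b the
between-layer heterozygosity.  Gene-level F_ST combines sites by ratio of
sums, the recommended aggregation for Hudson-type estimators.  Genes whose
F_ST stands >= 2.5 SD above the genomic mean are flagged as highly
differentiated (HD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class FstRecord:
    """Hudson F_ST at one site (or one gene) between the two layers."""

    contig: str
    position: int | None
    gene_id: str | None
    p_upper: float
    p_lower: float
    n_upper: int
    n_lower: int
    h_w: float
    h_b: float
    fst: float | None

    def as_row(self) -> dict:
        return vars(self).copy()


@dataclass
class HdScreenResult:
    """Outcome of the highly-differentiated gene screen."""

    population_id: str
    mean_fst: float
    sd_fst: float
    threshold: float
    flagged_genes: list[str] = field(default_factory=list)
    flagged_table: pd.DataFrame | None = None


@dataclass
class LayerContrast:
    """A two-layer comparison of one metric across samples."""

    metric: str
    test: str
    statistic: float
    pvalue: float
    mean_upper: float
    mean_lower: float
    n_upper: int
    n_lower: int


def hudson_fst(p1: float, p2: float) -> tuple[float, float, float | None]:
    """(H_w, H_b, F_ST) for one biallelic site from layer frequencies p1, p2.

    H_w = [2 p1(1-p1) + 2 p2(1-p2)]/2, H_b = p1(1-p2) + p2(1-p1),
    F_ST = (H_b - H_w)/H_b; None when H_b = 0.  Negative values are
    reported raw, never clamped.
    """
    h_w = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    h_b = p1 * (1 - p2) + p2 * (1 - p1)
    if h_b == 0:
        return h_w, h_b, None
    return h_w, h_b, (h_b - h_w) / h_b


def site_fst(
    counts_upper: np.ndarray,
    counts_lower: np.ndarray,
    contig: str = "",
    position: int | None = None,
    gene_id: str | None = None,
    min_coverage: int = 5,
    corrected: bool = False,
) -> FstRecord | None:
    """F_ST at one site from pooled per-layer base counts (length-4 each).

    The site is restricted to the two most frequent alleles across both
    pools; frequencies are renormalised over those two.  None when either
    pool is below *min_coverage* (site skipped).

    With ``corrected=True`` the sample-size-corrected Hudson numerator
    (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) replaces H_b - H_w;
    the plug-in form is the default, matching the estimator as written.
    """
    cu = np.asarray(counts_upper, dtype=float)
    cl = np.asarray(counts_lower, dtype=float)
    if cu.sum() < min_coverage or cl.sum() < min_coverage:
        return None
    combined = cu + cl
    top2 = np.argsort(-combined, kind="stable")[:2]
    a = top2[0]
    nu = cu[top2].sum()
    nl = cl[top2].sum()
    if nu == 0 or nl == 0:
        return None
    p1 = cu[a] / nu
    p2 = cl[a] / nl
    h_w, h_b, fst = hudson_fst(p1, p2)
    if corrected and h_b > 0 and nu > 1 and nl > 1:
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (nu - 1)
            - p2 * (1 - p2) / (nl - 1)
        )
        h_w = h_b - num  # keep (h_b - h_w) carrying the corrected numerator
        fst = num / h_b
    return FstRecord(
        contig=contig, position=position, gene_id=gene_id,
        p_upper=p1, p_lower=p2, n_upper=int(nu), n_lower=int(nl),
        h_w=h_w, h_b=h_b, fst=fst,
    )


def layer_pooled_counts(
    counts_by_sample: Mapping[str, Mapping[str, np.ndarray]],
    layer_of_sample: Mapping[str, str],
) -> dict[str, dict[str, np.ndarray]]:
    """Sum per-sample pileup counts into per-layer pools (upper/lower)."""
    pools: dict[str, dict[str, np.ndarray]] = {"upper": {}, "lower": {}}
    for sample_id, per_contig in counts_by_sample.items():
        layer = layer_of_sample[sample_id]
        for contig, mat in per_contig.items():
            if contig not in pools[layer]:
                pools[layer][contig] = np.zeros_like(mat)
            pools[layer][contig] += mat
    return pools


def fst_table(
    pool_upper: Mapping[str, np.ndarray],
    pool_lower: Mapping[str, np.ndarray],
    snvs: Sequence,
    min_coverage: int = 5,
    corrected: bool = False,
) -> list[FstRecord]:
    """Site F_ST at every SNV position (differentia positions, coverage >= 5).

    SNV sites come from calls on the pooled data or the union of per-sample
    calls; each must reach *min_coverage* in both layer pools.
    """
    records = []
    for s in snvs:
        rec = site_fst(
            pool_upper[s.contig][s.position],
            pool_lower[s.contig][s.position],
            contig=s.contig, position=s.position, gene_id=s.gene_id,
            min_coverage=min_coverage, corrected=corrected,
        )
        if rec is not None:
            records.append(rec)
    return records


def gene_fst(site_records: Sequence[FstRecord]) -> float | None:
    """Gene-level F_ST as ratio of sums: sum(H_b - H_w) / sum(H_b).

    None when the gene has no defined site or sum(H_b) = 0.
    """
    recs = [r for r in site_records if r.fst is not None]
    if not recs:
        return None
    num = sum(r.h_b - r.h_w for r in recs)
    den = sum(r.h_b for r in recs)
    if den == 0:
        return None
    return num / den


def gene_fst_table(site_records: Sequence[FstRecord]) -> pd.DataFrame:
    """Per-gene ratio-of-sums F_ST from a site-level record list."""
    by_gene: dict[str, list[FstRecord]] = {}
    for r in site_records:
        if r.gene_id is not None:
            by_gene.setdefault(r.gene_id, []).append(r)
    rows = [
        {"gene_id": g, "fst": gene_fst(recs), "n_sites": len(recs)}
        for g, recs in sorted(by_gene.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "fst", "n_sites"])


def screen_hd(
    gene_fst_tab: pd.DataFrame,
    k: float = 2.5,
    population_id: str = "population",
    gene_annotations: pd.DataFrame | None = None,
) -> HdScreenResult:
    """Flag genes with F_ST >= genomic mean + k*SD.

    ``gene_fst_tab`` needs columns gene_id and fst.  With SD = 0 nothing is
    flagged.  When *gene_annotations* (gene_id plus e.g. pi, pnps columns)
    is given, the flagged table joins them for the diversity comparison.
    """
    tab = gene_fst_tab.dropna(subset=["fst"])
    if len(tab) < 2:
        raise ValueError("need >= 2 genes with defined F_ST to screen")
    mean = float(tab["fst"].mean())
    sd = float(tab["fst"].std(ddof=1))
    threshold = mean + k * sd
    if sd == 0:
        flagged = tab.iloc[0:0]
    else:
        flagged = tab[tab["fst"] >= threshold]
    flagged = flagged.sort_values("gene_id")
    if gene_annotations is not None and len(flagged):
        flagged = flagged.merge(gene_annotations, on="gene_id", how="left")
    return HdScreenResult(
        population_id=population_id,
        mean_fst=mean,
        sd_fst=sd,
        threshold=threshold,
        flagged_genes=sorted(flagged["gene_id"]),
        flagged_table=flagged.reset_index(drop=True),
    )


def layer_contrast(
    values_upper: Sequence[float],
    values_lower: Sequence[float],
    metric: str = "metric",
    test: str = "welch",
) -> LayerContrast | None:
    """Compare a per-sample metric between layers.

    ``test`` is 'welch' (two-sample t, unequal variance, two-tailed) or
    'wilcoxon' (rank-sum, exact for small samples).  Identical zero-variance
    groups are reported as statistic 0, p = 1.  None when a layer has fewer
    than 2 non-missing values.
    """
    u = np.asarray([v for v in values_upper if v is not None and np.isfinite(v)], float)
    l = np.asarray([v for v in values_lower if v is not None and np.isfinite(v)], float)
    if len(u) < 2 or len(l) < 2:
        return None
    degenerate = u.std() == 0 and l.std() == 0 and len(u) and len(l) and u[0] == l[0]
    if degenerate:
        stat, p = 0.0, 1.0
    elif test == "welch":
        res = stats.ttest_ind(u, l, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        method = "exact" if max(len(u), len(l)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(u, l, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return LayerContrast(
        metric=metric, test=test, statistic=stat, pvalue=p,
        mean_upper=float(u.mean()), mean_lower=float(l.mean()),
        n_upper=len(u), n_lower=len(l),
    )


def maf_contrast(
    snvs_by_sample: Mapping[str, Sequence],
    pairs_by_sample: Mapping[str, Sequence],
    layer_of_sample: Mapping[str, str],
    tolerance: float = 1e-9,
) -> LayerContrast | None:
    """Layer contrast of mean major-allele frequency at recombining sites.

    Qualifying SNVs are those participating in at least one linkage pair
    with D' strictly below 1 (all four gametes seen); per-sample mean MAF is
    computed over them, then compared between layers by Welch t.  Samples
    with no qualifying SNV are skipped; None when the condition empties a
    layer.
    """
    upper_means, lower_means = [], []
    for sample_id, snvs in snvs_by_sample.items():
        pairs = pairs_by_sample.get(sample_id, [])
        qual_sites = set()
        for p in pairs:
            if p.dprime < 1 - tolerance:
                qual_sites.add((p.contig, p.position_i))
                qual_sites.add((p.contig, p.position_j))
        mafs = [s.maf for s in snvs if (s.contig, s.position) in qual_sites]
        if not mafs:
            continue
        (upper_means if layer_of_sample[sample_id] == "upper" else lower_means).append(
            float(np.mean(mafs))
        )
    return layer_contrast(upper_means, lower_means, metric="maf", test="welch")


def env_correlation(
    pi_by_depth: pd.DataFrame,
    env_by_depth: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of per-depth population pi with each factor.

    Inputs are depth-indexed tables (populations and environmental factors
    as columns); rows are matched on the index.  Returns one row per
    (population, factor) with r, two-tailed p and a Benjamini-Hochberg q
    column reported alongside (not replacing) raw p.  Combinations with
    fewer than 3 shared depths or zero variance are skipped.
    """
    rows = []
    for pop in pi_by_depth.columns:
        for factor in env_by_depth.columns:
            joined = pd.concat(
                [pi_by_depth[pop], env_by_depth[factor]], axis=1, join="inner"
            ).dropna()
            if len(joined) < 3:
                continue
            x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                {"population": pop, "factor": factor, "n": len(joined),
                 "r": float(r), "p": float(p)}
            )
    df = pd.DataFrame(rows, columns=["population", "factor", "n", "r", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df
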