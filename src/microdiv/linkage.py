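"""Read-pair linkage disequilibrium between SNV sites.

Haplotype observations come from single sequenced fragments only (a read or
its mate) -- the only phase observable in a metagenome.  Each SNV pair on a
contig yields a 2x2 gamete table over the two most frequent called alleles
per site, from which r2 and D' are computed by their textbook definitions.
Pairs separated by more than mean + 2.5 SD of the pair-distance distribution
are discarded as unreliable before decay and summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from microdiv.io import BASE_TO_CODE, AlignedRead
from microdiv.profiling import SnvRecord


@dataclass
class LinkagePair:
    """Two SNVs on one contig with fragment-haplotype counts and LD values.

    A/a are the major/minor alleles at site i, B/b at site j; counts are
    fragments covering both sites.  pair_class is NN/NS/SS from the two
    SNVs' mutation classes (None when either class is not syn/nonsyn).
    """

    contig: str
    position_i: int
    position_j: int
    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int
    r2: float
    dprime: float
    pair_class: str | None = None

    @property
    def distance(self) -> int:
        return self.position_j - self.position_i

    @property
    def total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    def as_row(self) -> dict:
        return {
            "contig": self.contig,
            "position_i": self.position_i,
            "position_j": self.position_j,
            "distance": self.distance,
            "n_AB": self.n_AB,
            "n_Ab": self.n_Ab,
            "n_aB": self.n_aB,
            "n_ab": self.n_ab,
            "r2": self.r2,
            "dprime": self.dprime,
            "pair_class": self.pair_class,
        }


def compute_ld(counts: tuple[int, int, int, int]) -> tuple[float, float] | None:
    """(r2, D') from a 2x2 gamete count table (n_AB, n_Ab, n_aB, n_ab).

    D = p_AB - p_A p_B; r2 = D^2 / (p_A(1-p_A) p_B(1-p_B)); D' = |D|/D_max
    with D_max = min(p_A(1-p_B), (1-p_A)p_B) for D > 0 and
    min(p_A p_B, (1-p_A)(1-p_B)) for D < 0; D = 0 gives D' = 0.  None when
    either site is monomorphic within the table (undefined).
    """
    n_ab_, n_aB_, n_Ab_, n_AB_ = counts[3], counts[2], counts[1], counts[0]
    n = n_AB_ + n_Ab_ + n_aB_ + n_ab_
    if n == 0:
        return None
    p_a = (n_AB_ + n_Ab_) / n
    p_b = (n_AB_ + n_aB_) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    p_ab = n_AB_ / n
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return min(r2, 1.0), 0.0
    # clamp float round-off: both quantities are <= 1 algebraically
    return min(r2, 1.0), min(abs(d) / d_max, 1.0)


def _fragment_calls(
    reads: Iterable[AlignedRead],
    snv_positions: Mapping[str, np.ndarray],
) -> dict[tuple[str, str], dict[int, int]]:
    """(fragment, contig) -> {snv position -> base code}; first call wins."""
    frags: dict[tuple[str, str], dict[int, int]] = {}
    for read in reads:
        pos_arr = snv_positions.get(read.contig)
        if pos_arr is None or len(pos_arr) == 0:
            continue
        hit = np.isin(read.ref_positions, pos_arr)
        if not hit.any():
            continue
        calls = frags.setdefault((read.mate_id, read.contig), {})
        for p, c in zip(read.ref_positions[hit], read.base_codes[hit]):
            calls.setdefault(int(p), int(c))
    return frags


def pair_haplotype_counts(
    reads: Iterable[AlignedRead],
    snv_i: SnvRecord,
    snv_j: SnvRecord,
) -> tuple[int, int, int, int]:
    """Gamete counts for one SNV pair from fragments covering both sites.

    Each qualifying fragment contributes exactly one observation; fragments
    carrying an allele outside the two most frequent called alleles at
    either site are discarded.
    """
    if snv_i.contig != snv_j.contig:
        raise ValueError("SNVs must share a contig")
    pos = {snv_i.contig: np.array([snv_i.position, snv_j.position])}
    frags = _fragment_calls(reads, pos)
    maj_i, min_i = _top_two_alleles(snv_i)
    maj_j, min_j = _top_two_alleles(snv_j)
    table = [0, 0, 0, 0]
    for calls in frags.values():
        bi = calls.get(snv_i.position)
        bj = calls.get(snv_j.position)
        if bi is None or bj is None:
            continue
        if bi not in (maj_i, min_i) or bj not in (maj_j, min_j):
            continue
        idx = (0 if bi == maj_i else 2) + (0 if bj == maj_j else 1)
        table[idx] += 1
    return tuple(table)


def _top_two_alleles(snv: SnvRecord) -> tuple[int, int]:
    """Base codes of the two most frequent called alleles (major, minor)."""
    ordered = sorted(snv.alleles, key=lambda a: -a[1])[:2]
    if len(ordered) < 2:
        raise ValueError(f"SNV at {snv.contig}:{snv.position} is not polymorphic")
    return BASE_TO_CODE[ordered[0][0]], BASE_TO_CODE[ordered[1][0]]


_PAIR_CLASS = {
    frozenset({"nonsynonymous"}): "NN",
    frozenset({"synonymous"}): "SS",
    frozenset({"nonsynonymous", "synonymous"}): "NS",
}


def collect_pairs(
    reads: Iterable[AlignedRead],
    snvs: Sequence[SnvRecord],
    min_pair_depth: int = 5,
) -> list[LinkagePair]:
    """All SNV pairs co-covered by fragments, with LD computed.

    Fragments carrying non-called alleles at a site are dropped from that
    pair's table; pairs with fewer than *min_pair_depth* fragments or
    monomorphic within the table are omitted (undefined LD).
    """
    snv_by_site: dict[tuple[str, int], SnvRecord] = {
        (s.contig, s.position): s for s in snvs
    }
    pos_by_contig: dict[str, np.ndarray] = {}
    for s in snvs:
        pos_by_contig.setdefault(s.contig, [])
    for s in snvs:
        pos_by_contig[s.contig].append(s.position)
    pos_by_contig = {c: np.array(sorted(p)) for c, p in pos_by_contig.items()}

    alleles: dict[tuple[str, int], tuple[int, int]] = {}
    for s in snvs:
        if len(s.alleles) >= 2:
            alleles[(s.contig, s.position)] = _top_two_alleles(s)

    frags = _fragment_calls(reads, pos_by_contig)
    tables: dict[tuple[str, int, int], list[int]] = {}
    for (_, contig), calls in frags.items():
        sites = sorted(calls)
        for a in range(len(sites)):
            ka = (contig, sites[a])
            if ka not in alleles:
                continue
            maj_a, min_a = alleles[ka]
            ba = calls[sites[a]]
            if ba not in (maj_a, min_a):
                continue
            for b in range(a + 1, len(sites)):
                kb = (contig, sites[b])
                if kb not in alleles:
                    continue
                maj_b, min_b = alleles[kb]
                bb = calls[sites[b]]
                if bb not in (maj_b, min_b):
                    continue
                idx = (0 if ba == maj_a else 2) + (0 if bb == maj_b else 1)
                tables.setdefault((contig, sites[a], sites[b]), [0, 0, 0, 0])[idx] += 1

    pairs: list[LinkagePair] = []
    for (contig, pi, pj), table in sorted(tables.items()):
        if sum(table) < min_pair_depth:
            continue
        ld = compute_ld(tuple(table))
        if ld is None:
            continue
        r2, dprime = ld
        ci = snv_by_site[(contig, pi)].mutation_class
        cj = snv_by_site[(contig, pj)].mutation_class
        pair_class = None
        if ci in ("synonymous", "nonsynonymous") and cj in ("synonymous", "nonsynonymous"):
            pair_class = _PAIR_CLASS[frozenset({ci, cj})]
        pairs.append(
            LinkagePair(
                contig=contig, position_i=pi, position_j=pj,
                n_AB=table[0], n_Ab=table[1], n_aB=table[2], n_ab=table[3],
                r2=r2, dprime=dprime, pair_class=pair_class,
            )
        )
    return pairs


def distance_filter(
    pairs: Sequence[LinkagePair],
    k: float = 2.5,
) -> tuple[list[LinkagePair], dict]:
    """Drop pairs whose distance is >= mean + k*SD of all pair distances.

    Returns (retained pairs, report) where the report carries the cutoff and
    retained fraction.  With SD = 0 nothing is dropped.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs for the distance filter")
    d = np.array([p.distance for p in pairs], dtype=float)
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    if sd == 0:
        retained = list(pairs)
    else:
        cutoff = mean + k * sd
        retained = [p for p in pairs if p.distance < cutoff]
    report = {
        "mean_distance": mean,
        "sd_distance": sd,
        "cutoff": mean + k * sd,
        "n_input": len(pairs),
        "n_retained": len(retained),
        "retained_fraction": len(retained) / len(pairs),
    }
    return retained, report


def ld_decay(
    pairs: Sequence[LinkagePair],
    bin_width_bp: int = 50,
) -> tuple[pd.DataFrame, float | None]:
    """Distance-binned mean r2 and the Spearman trend across bins.

    Returns (bins table, Spearman rho of bin midpoint vs mean r2); the trend
    is None with fewer than 3 occupied bins.
    """
    if not pairs:
        return pd.DataFrame(columns=["bin_mid", "mean_r2", "n_pairs"]), None
    d = np.array([p.distance for p in pairs])
    r2 = np.array([p.r2 for p in pairs])
    bins = d // bin_width_bp
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append(
            {
                "bin_mid": (b + 0.5) * bin_width_bp,
                "mean_r2": float(r2[sel].mean()),
                "n_pairs": int(sel.sum()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        return table, None
    rho = stats.spearmanr(table["bin_mid"], table["mean_r2"]).statistic
    return table, float(rho)


def rn2_rs2(pairs: Sequence[LinkagePair]) -> float | None:
    """Mean r2 over NN pairs / mean r2 over SS pairs (NS excluded).

    None when either class is empty.
    """
    nn = [p.r2 for p in pairs if p.pair_class == "NN"]
    ss = [p.r2 for p in pairs if p.pair_class == "SS"]
    if not nn or not ss:
        return None
    return float(np.mean(nn) / np.mean(ss))


def dprime_lt1_fraction(pairs: Sequence[LinkagePair], tolerance: float = 1e-9) -> float:
    """Fraction of pairs with D' < 1 (all four gametes observed)."""
    if not pairs:
        raise ValueError("no pairs")
    return float(np.mean([p.dprime < 1 - tolerance for p in pairs]))
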