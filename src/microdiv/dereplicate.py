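"""Clustering genome assemblies into species-like populations at 97% ANI.

Pairwise ANI is estimated by a fragment + k-mer containment method: one
genome is cut into non-overlapping fragments, each fragment's k-mer
containment c in the other genome is converted to a per-fragment identity
c^(1/k), and ANI is the mean identity over matched fragments (computed in
both directions and averaged).  Populations are single-linkage components of
the graph whose edges are pairs with ANI >= 0.97 and alignment coverage
above a gate; representatives maximise completeness - 5 x contamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from microdiv.io import ReferenceSet


@dataclass(frozen=True)
class GenomePair:
    """A pairwise genome comparison (symmetric by construction)."""

    genome_i: str
    genome_j: str
    ani: float
    coverage: float  # fraction of fragments with a k-mer match, averaged


@dataclass
class PopulationCluster:
    """One species-like population (a single-linkage ANI cluster)."""

    cluster_id: str
    members: list[str]
    representative: str | None = None
    high_frequency: bool = False

    @property
    def member_count(self) -> int:
        return len(self.members)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def _directional(
    a: ReferenceSet, b: ReferenceSet, fragment: int, k: int, min_containment: float
) -> tuple[float, float]:
    """(mean fragment identity, matched-fragment fraction) of a against b."""
    b_kmers: set[str] = set()
    for seq in b.contigs.values():
        b_kmers |= _kmers(seq, k)
    identities = []
    total = 0
    for seq in a.contigs.values():
        starts = range(0, len(seq), fragment)
        for s in starts:
            frag = seq[s : s + fragment]
            if len(frag) < k:
                continue
            total += 1
            fk = _kmers(frag, k)
            if not fk:
                continue
            c = len(fk & b_kmers) / len(fk)
            if c >= min_containment:
                identities.append(c ** (1.0 / k))
    if total == 0 or not identities:
        return 0.0, 0.0
    return sum(identities) / len(identities), len(identities) / total


def pairwise_ani(
    genome_a: ReferenceSet,
    genome_b: ReferenceSet,
    fragment: int = 1000,
    k: int = 16,
    min_containment: float = 0.02,
) -> GenomePair:
    """Estimate ANI and alignment coverage between two genomes.

    Genomes shorter than one fragment fall back to single-fragment mode
    (the whole contig is the fragment).  Values are averaged over both
    comparison directions.  Identical genomes give ANI = coverage = 1.
    """
    ani_ab, cov_ab = _directional(genome_a, genome_b, fragment, k, min_containment)
    ani_ba, cov_ba = _directional(genome_b, genome_a, fragment, k, min_containment)
    if cov_ab == 0 and cov_ba == 0:
        ani = 0.0
    elif cov_ab == 0 or cov_ba == 0:
        ani = ani_ab if cov_ab else ani_ba
    else:
        ani = (ani_ab + ani_ba) / 2
    return GenomePair(
        genome_i=genome_a.genome_id,
        genome_j=genome_b.genome_id,
        ani=ani,
        coverage=(cov_ab + cov_ba) / 2,
    )


def cluster_populations(
    genome_ids: Sequence[str],
    pairs: Sequence[GenomePair],
    ani_cutoff: float = 0.97,
    coverage_cutoff: float = 0.5,
) -> list[PopulationCluster]:
    """Single-linkage clustering of genomes on the thresholded ANI graph.

    An edge joins two genomes when ANI >= ani_cutoff and coverage >=
    coverage_cutoff; clusters are connected components, so membership is
    independent of input order.  Cluster ids come from the lexicographically
    smallest member.
    """
    parent = {g: g for g in genome_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        if p.ani >= ani_cutoff and p.coverage >= coverage_cutoff:
            ra, rb = find(p.genome_i), find(p.genome_j)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for g in genome_ids:
        groups.setdefault(find(g), []).append(g)
    clusters = [
        PopulationCluster(cluster_id=min(members), members=sorted(members))
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def select_representative(
    cluster: PopulationCluster,
    quality_table: Mapping[str, tuple[float, float]],
) -> str:
    """Pick the member maximising completeness - 5 x contamination.

    Quality values are percentages (CheckM-style).  Exact score ties go to
    the lexicographically smallest genome id.  A member missing from the
    quality table is an error naming the genome.
    """
    best_id: str | None = None
    best_score = -float("inf")
    for g in sorted(cluster.members):
        if g not in quality_table:
            raise KeyError(f"no quality metrics for genome {g!r}")
        completeness, contamination = quality_table[g]
        score = completeness - 5.0 * contamination
        if score > best_score:
            best_id, best_score = g, score
    assert best_id is not None
    return best_id


def high_frequency_filter(
    clusters: Sequence[PopulationCluster],
    source_depth: Mapping[str, str],
    min_members: int = 5,
) -> list[PopulationCluster]:
    """Flag clusters whose members come from >= min_members DISTINCT depths.

    Five genomes binned from four depth samples do not qualify; the rule
    counts distinct source depths, not genomes.  Flags are set in place and
    the flagged clusters returned.
    """
    flagged = []
    for c in clusters:
        depths = {source_depth[m] for m in c.members}
        c.high_frequency = len(depths) >= min_members
        if c.high_frequency:
            flagged.append(c)
    return flagged
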