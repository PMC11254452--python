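"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: everything internal is 0-based half-open; GFF, SAM
and VCF interfaces convert at the boundary (GFF/VCF are 1-based inclusive).
A single convention prevents off-by-one drift across modules.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Base encoding shared by all modules: A=0, C=1, G=2, T=3, N/other=4.
BASES = "ACGT"
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The ten core depth intervals (cm) and the two-way layer stratification.
DEPTH_INTERVALS = (
    "0-5", "5-10", "10-15", "15-20", "20-30",
    "30-40", "40-50", "50-60", "60-80", "80-100",
)
UPPER_INTERVALS = frozenset({"0-5", "5-10", "10-15", "15-20"})


def layer_of_interval(interval: str) -> str:
    """Map a depth interval to its layer: 0-20 cm -> 'upper', deeper -> 'lower'."""
    if interval not in DEPTH_INTERVALS:
        raise ValueError(f"unknown depth interval: {interval!r}")
    return "upper" if interval in UPPER_INTERVALS else "lower"


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return CODE_TO_BASE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class ReferenceSet:
    """A set of contigs (one genome), uppercase A/C/G/T/N sequences."""

    contigs: dict[str, str]
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if len(seq) < 1:
                raise FormatError(f"contig {cid!r} is empty")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"contig {cid!r} contains non-ACGTN characters: {sorted(bad)}"
                )
        self._codes: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def codes(self, contig: str) -> np.ndarray:
        """Encoded (uint8) sequence of one contig, cached."""
        if contig not in self._codes:
            self._codes[contig] = encode_sequence(self.contigs[contig])
        return self._codes[contig]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene; start/end are internal 0-based half-open."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    frame_complete: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id}: end <= start")
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignedRead:
    """One aligned read reduced to its per-reference-position base calls.

    ``ref_positions``/``base_codes`` are parallel arrays holding only aligned,
    non-N calls (codes 0-3).  ``mate_id`` (the query name) is the fragment
    pairing key used for mate-overlap deduplication and read-pair linkage.
    """

    read_id: str
    contig: str
    pos: int                      # 0-based leftmost reference position
    ref_positions: np.ndarray
    base_codes: np.ndarray
    mate_id: str
    identity: float = 1.0
    aligned_fraction: float = 1.0

    @property
    def aligned_length(self) -> int:
        return len(self.ref_positions)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    depth_interval: str
    layer: str
    path: str


@dataclass
class SampleSheet:
    """Sample metadata: sample -> depth interval, layer, alignment path.

    The layer is always (re)derived from the depth interval so the two can
    never disagree.
    """

    samples: list[SampleRecord] = field(default_factory=list)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "SampleSheet":
        """Build from (sample_id, depth_interval, path) rows."""
        recs = [
            SampleRecord(sid, interval, layer_of_interval(interval), path)
            for sid, interval, path in rows
        ]
        return cls(recs)

    @classmethod
    def read(cls, path: str | os.PathLike) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "depth_interval", "path"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        return cls.from_rows(
            df[["sample_id", "depth_interval", "path"]].itertuples(index=False)
        )

    def write(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            [
                (s.sample_id, s.depth_interval, s.layer, s.path)
                for s in self.samples
            ],
            columns=["sample_id", "depth_interval", "layer", "path"],
        ).to_csv(path, sep="\t", index=False)

    def by_layer(self) -> dict[str, list[SampleRecord]]:
        out: dict[str, list[SampleRecord]] = {"upper": [], "lower": []}
        for s in self.samples:
            out[s.layer].append(s)
        return out

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike, genome_id: str | None = None) -> ReferenceSet:
    """Read a FASTA file into a :class:`ReferenceSet` (sequences uppercased)."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig id: {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ReferenceSet(contigs, genome_id=genome_id)


def write_fasta(reference: ReferenceSet, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in reference.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF (Prodigal-style CDS rows, 1-based inclusive)

def read_genes(path: str | os.PathLike, reference: ReferenceSet) -> list[GeneModel]:
    """Read gene models from a GFF3 file and validate them against *reference*.

    ``frame_complete`` is set from length divisibility by 3.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            contig, _source, _type, start_s, end_s, _score, strand, _frame, attrs = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if contig not in reference.contigs:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            if end1 > len(reference.contigs[contig]):
                raise FormatError(f"{path}:{lineno}: gene beyond contig end")
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:].strip()
                    break
            if gene_id is None:
                gene_id = f"{contig}_{start1}_{end1}"
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            length = end1 - start1 + 1
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in "+-" else "+",
                    frame_complete=length % 3 == 0,
                )
            )
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 CDS rows (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tmicrodiv\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# SAM/BAM

_ALIGNED_OPS = frozenset({0, 7, 8})          # M, =, X
_QUERY_ALIGNED_OPS = frozenset({0, 1, 7, 8})  # M, I, =, X


def iter_alignments(
    path: str | os.PathLike,
    min_identity: float = 0.95,
    min_aligned_fraction: float = 0.75,
) -> Iterator[AlignedRead]:
    """Stream filtered reads from a SAM/BAM file.

    Percent identity = matches / aligned columns, where aligned columns count
    M/=/X plus insertions and deletions (indels are non-matches); mismatch+
    indel count comes from the NM tag.  Aligned fraction is the share of the
    full query (including soft clips) in aligned columns.  Unmapped,
    secondary and supplementary records are skipped (count logged).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    mode = "rb" if str(path).endswith(".bam") else "r"
    skipped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            cigar = rec.cigartuples or []
            aligned_cols = sum(n for op, n in cigar if op in (0, 1, 2, 7, 8))
            if aligned_cols == 0:
                skipped += 1
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            identity = (aligned_cols - nm) / aligned_cols
            query_len = rec.infer_read_length() or len(rec.query_sequence or "")
            query_aligned = sum(n for op, n in cigar if op in _QUERY_ALIGNED_OPS)
            fraction = query_aligned / query_len if query_len else 0.0
            if identity < min_identity or fraction < min_aligned_fraction:
                continue
            seq = rec.query_sequence or ""
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.fromiter((q for q, _ in pairs), dtype=np.int64)
            rpos = np.fromiter((r for _, r in pairs), dtype=np.int64)
            codes = encode_sequence(seq)[qpos]
            keep = codes < 4  # N bases never count as alleles or coverage
            suffix = "/2" if rec.is_read2 else "/1"
            yield AlignedRead(
                read_id=(rec.query_name or "") + suffix,
                contig=rec.reference_name or "",
                pos=rec.reference_start,
                ref_positions=rpos[keep],
                base_codes=codes[keep],
                mate_id=rec.query_name or "",
                identity=identity,
                aligned_fraction=fraction,
            )
    if skipped:
        logger.info("iter_alignments(%s): skipped %d unusable records", path, skipped)


# ---------------------------------------------------------------------------
# Statistics tables and VCF

#: Deterministic column orders per table kind.
TABLE_COLUMNS = {
    "snv": [
        "contig", "position", "ref_base", "alleles", "counts", "frequencies",
        "maf", "minor_freq", "gene_id", "mutation_class",
    ],
    "gene_stats": [
        "gene_id", "sample_id", "covered_positions", "pi", "snv_count",
        "syn_snvs", "nonsyn_snvs", "syn_sites", "nonsyn_sites",
        "pnps", "syn_subs", "nonsyn_subs", "dnds", "hnd",
    ],
    "linkage": [
        "contig", "position_i", "position_j", "distance",
        "n_AB", "n_Ab", "n_aB", "n_ab", "r2", "dprime", "pair_class",
    ],
    "profile": [
        "genome_id", "sample_id", "mean_coverage", "breadth", "covered_length",
        "snv_count", "snv_per_mbp", "mean_pi", "con_ani", "pop_ani", "mean_maf",
    ],
    "fst": [
        "contig", "position", "gene_id", "p_upper", "p_lower",
        "n_upper", "n_lower", "h_w", "h_b", "fst",
    ],
}

_SORT_KEYS = ["contig", "position", "position_i", "gene_id", "sample_id"]


def write_tables(records, path: str | os.PathLike, kind: str, reference: ReferenceSet | None = None) -> None:
    """Write a statistics table as TSV (or VCF for kind='snv_vcf').

    Column order and row sort (contig, position, gene-id) are deterministic.
    ``records`` is a DataFrame or an iterable of dicts/dataclasses with the
    kind's fields.
    """
    if kind == "snv_vcf":
        _write_snv_vcf(records, path, reference)
        return
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind: {kind!r}")
    cols = TABLE_COLUMNS[kind]
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if hasattr(r, "as_row"):
                rows.append(r.as_row())
            elif isinstance(r, dict):
                rows.append(r)
            else:
                rows.append(vars(r))
        df = pd.DataFrame(rows, columns=cols if not rows else None)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df = df[cols]
    sort_by = [c for c in _SORT_KEYS if c in df.columns]
    if len(df) and sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def _write_snv_vcf(snvs, path, reference: ReferenceSet | None) -> None:
    """Write SNV records as a minimal VCF v4.2 (1-based positions, AF INFO)."""
    recs = sorted(snvs, key=lambda s: (s.contig, s.position))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        if reference is not None:
            for cid, length in reference.lengths.items():
                fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in recs:
            alts = [(b, f) for b, _c, f in s.alleles if b != s.ref_base]
            if not alts:
                continue
            alt_s = ",".join(b for b, _ in alts)
            af_s = ",".join(f"{f:.6g}" for _, f in alts)
            fh.write(
                f"{s.contig}\t{s.position + 1}\t.\t{s.ref_base}\t{alt_s}\t.\tPASS\tAF={af_s}\n"
            )
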