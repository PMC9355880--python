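"""Repeat-subfamily expression quantification from read alignments.

To estimate subfamily expression without bias from genic transcription,
reads are filtered before counting: a read is discarded if any of its
alignments overlaps a gene body (strand-agnostic), if any alignment is
spliced or spans an annotated splice-junction coordinate, or if its polyA
content exceeds a threshold. Surviving reads are counted once per subfamily
group, and only if all their alignments fall on elements of a single group
(multi-mappers within one subfamily count once; cross-subfamily multi-mappers
are left unassigned). Counts are normalized per million by library size or
by reads aligning to genes and repeats, and fold changes are reported
against a control sample.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .catalog import RepeatFeature

__all__ = [
    "GeneModel",
    "Alignment",
    "AlignedRead",
    "SubfamilyCountTable",
    "FoldChangeTable",
    "GeneIndex",
    "ElementIndex",
    "filter_reads",
    "assign_subfamily",
    "count_subfamilies",
    "normalize_counts",
    "fold_change",
    "read_alignments_tsv",
    "write_alignments_tsv",
    "read_alignments_sam",
    "read_gene_models_bed12",
    "read_gene_models_gtf",
    "write_gene_models_bed12",
    "polya_fraction",
]

LIBRARY_SIZE = "library_size"
GENES_PLUS_REPEATS = "genes_plus_repeats"


@dataclass(frozen=True)
class GeneModel:
    chrom: str
    strand: str
    start: int
    end: int
    exons: Tuple[Tuple[int, int], ...]
    gene_id: str = ""

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id!r}: invalid exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: exons overlap or are unsorted")
            prev_end = e

    @property
    def junctions(self) -> Tuple[Tuple[int, int], ...]:
        """(donor, acceptor) coordinate pairs between consecutive exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class Alignment:
    chrom: str
    blocks: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment requires >=1 block")
        prev_end = None
        for s, e in self.blocks:
            if s >= e:
                raise ValueError(f"invalid alignment block ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("alignment blocks overlap or are unsorted")
            prev_end = e

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1

    @property
    def span(self) -> Tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    polyA_frac: float
    alignments: Tuple[Alignment, ...]

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValueError(f"read {self.read_id!r} has no alignments")
        if not 0.0 <= self.polyA_frac <= 1.0:
            raise ValueError(f"read {self.read_id!r}: polyA_frac outside [0, 1]")


class GeneIndex:
    """Interval lookup over gene bodies plus a per-chrom splice-junction set."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._bodies: Dict[str, IntervalTree] = {}
        self._junctions: Dict[str, np.ndarray] = {}
        junc: Dict[str, Set[int]] = {}
        for g in genes:
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
            for donor, acceptor in g.junctions:
                junc.setdefault(g.chrom, set()).update((donor, acceptor))
        for chrom, coords in junc.items():
            self._junctions[chrom] = np.array(sorted(coords), dtype=np.int64)

    def overlaps_gene(self, aln: Alignment) -> bool:
        tree = self._bodies.get(aln.chrom)
        if tree is None:
            return False
        return any(tree.overlap(s, e) for s, e in aln.blocks)

    def covers_junction(self, aln: Alignment) -> bool:
        """True iff a single-block alignment strictly contains a junction coordinate."""
        coords = self._junctions.get(aln.chrom)
        if coords is None or aln.spliced:
            return False
        s, e = aln.blocks[0]
        i = np.searchsorted(coords, s, side="right")
        return bool(i < len(coords) and coords[i] < e)


class ElementIndex:
    """Interval lookup mapping genomic positions to repeat group labels.

    Built from the raw repeat annotation (every annotated element of a
    subfamily, independent of the assembled full-length catalog).
    """

    def __init__(self, features: Iterable[RepeatFeature]):
        self._trees: Dict[str, IntervalTree] = {}
        for f in features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f.group)

    def groups_at(self, aln: Alignment) -> Set[str]:
        tree = self._trees.get(aln.chrom)
        if tree is None:
            return set()
        groups: Set[str] = set()
        for s, e in aln.blocks:
            for iv in tree.overlap(s, e):
                groups.add(iv.data)
        return groups


def filter_reads(
    reads: Sequence[AlignedRead],
    genes: Sequence[GeneModel] | GeneIndex,
    polyA_max: float = 0.8,
) -> List[AlignedRead]:
    """Drop reads overlapping genes or splice sites, or with high polyA content.

    A read is tainted (removed) if ANY of its alignments trips a filter.
    Gene overlap is strand-agnostic. The three predicates are independent,
    so filter order cannot change the surviving set.
    """
    if not 0.0 <= polyA_max <= 1.0:
        raise ValueError(f"polyA_max must be in [0, 1], got {polyA_max}")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    kept = []
    for read in reads:
        if read.polyA_frac > polyA_max:
            continue
        if any(a.spliced or index.covers_junction(a) for a in read.alignments):
            continue
        if any(index.overlaps_gene(a) for a in read.alignments):
            continue
        kept.append(read)
    return kept


def assign_subfamily(read: AlignedRead, element_index: ElementIndex) -> Optional[str]:
    """The unique group all alignments of the read fall on, else None.

    Returns the group label when every alignment overlaps elements of exactly
    one common group; a read with any off-repeat alignment or alignments on
    mixed groups is unassigned. A multi-mapped read therefore contributes a
    single count to a single group.
    """
    union: Set[str] = set()
    for aln in read.alignments:
        groups = element_index.groups_at(aln)
        if not groups:
            return None
        union |= groups
        if len(union) > 1:
            return None
    return next(iter(union)) if len(union) == 1 else None


@dataclass
class SubfamilyCountTable:
    sample_id: str
    counts: Dict[str, int]
    reads_total: int
    denominator: Optional[int] = None
    normalized: Dict[str, float] = field(default_factory=dict)
    fractions: Dict[str, float] = field(default_factory=dict)
    mode: Optional[str] = None

    @property
    def assigned_total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self):
        import pandas as pd

        groups = sorted(self.counts)
        return pd.DataFrame(
            {
                "group": groups,
                "count": [self.counts[g] for g in groups],
                "normalized": [self.normalized.get(g, math.nan) for g in groups],
                "fraction": [self.fractions.get(g, math.nan) for g in groups],
            }
        )


def count_subfamilies(
    reads: Sequence[AlignedRead],
    element_index: ElementIndex,
    sample_id: str = "sample",
) -> SubfamilyCountTable:
    """Count filtered reads per group; unassigned reads are excluded.

    Order-invariant: each read is classified independently.
    """
    counts: Dict[str, int] = {}
    for read in reads:
        group = assign_subfamily(read, element_index)
        if group is not None:
            counts[group] = counts.get(group, 0) + 1
    return SubfamilyCountTable(sample_id=sample_id, counts=counts, reads_total=len(reads))


def normalize_counts(
    table: SubfamilyCountTable, mode: str, denominator: int
) -> SubfamilyCountTable:
    """Populate per-million normalized values and the fraction-of-reads view."""
    if mode not in (LIBRARY_SIZE, GENES_PLUS_REPEATS):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denominator <= 0:
        raise ValueError(f"denominator must be > 0, got {denominator} (unusable sample)")
    normalized = {g: c * 1e6 / denominator for g, c in table.counts.items()}
    fractions = {g: c / denominator for g, c in table.counts.items()}
    return SubfamilyCountTable(
        sample_id=table.sample_id,
        counts=dict(table.counts),
        reads_total=table.reads_total,
        denominator=denominator,
        normalized=normalized,
        fractions=fractions,
        mode=mode,
    )


@dataclass
class FoldChangeTable:
    fc: Dict[str, float]
    undefined: Set[str]

    def to_frame(self):
        import pandas as pd

        groups = sorted(self.fc)
        return pd.DataFrame(
            {
                "group": groups,
                "fold_change": [self.fc[g] for g in groups],
                "undefined": [g in self.undefined for g in groups],
            }
        )


def fold_change(treated: SubfamilyCountTable, control: SubfamilyCountTable) -> FoldChangeTable:
    """Per-group ratio of normalized treated over control values.

    Groups absent or zero in the control are flagged undefined (NaN); no
    pseudocount is applied.
    """
    if treated.mode is None or control.mode is None:
        raise ValueError("both tables must be normalized before fold_change")
    if treated.mode != control.mode:
        raise ValueError(
            f"normalization mode mismatch: {treated.mode!r} vs {control.mode!r}"
        )
    fc: Dict[str, float] = {}
    undefined: Set[str] = set()
    for g in sorted(set(treated.normalized) | set(control.normalized)):
        c = control.normalized.get(g, 0.0)
        t = treated.normalized.get(g, 0.0)
        if c == 0.0:
            fc[g] = math.nan
            undefined.add(g)
        else:
            fc[g] = t / c
    return FoldChangeTable(fc=fc, undefined=undefined)


# ---------------------------------------------------------------------------
# I/O


def polya_fraction(sequence: str) -> float:
    """Fraction of the read that is polyA-like: max of A and T content.

    The T branch covers reads aligned on the reverse strand, where a polyA
    tail reads as polyT.
    """
    if not sequence:
        return 0.0
    seq = sequence.upper()
    n = len(seq)
    return max(seq.count("A"), seq.count("T")) / n


def _format_blocks(blocks: Sequence[Tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def _parse_blocks(text: str) -> Tuple[Tuple[int, int], ...]:
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_alignments_tsv(reads: Sequence[AlignedRead], path: str) -> None:
    """Plain-TSV alignment dialect: one row per alignment.

    Columns: read_id, chrom, blocks ("start-end[,start-end...]"), polyA_frac.
    """
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tblocks\tpolyA_frac\n")
        for read in reads:
            for aln in read.alignments:
                fh.write(
                    f"{read.read_id}\t{aln.chrom}\t{_format_blocks(aln.blocks)}"
                    f"\t{read.polyA_frac:.6g}\n"
                )


def read_alignments_tsv(path: str) -> List[AlignedRead]:
    order: List[str] = []
    rows: Dict[str, List[Tuple[Alignment, float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["read_id", "chrom", "blocks", "polyA_frac"]:
            raise ValueError(f"{path}: not an alignment TSV (bad header)")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            rid, chrom, blocks, frac = fields[:4]
            if rid not in rows:
                rows[rid] = []
                order.append(rid)
            rows[rid].append((Alignment(chrom=chrom, blocks=_parse_blocks(blocks)), float(frac)))
    return [
        AlignedRead(
            read_id=rid,
            polyA_frac=rows[rid][0][1],
            alignments=tuple(a for a, _ in rows[rid]),
        )
        for rid in order
    ]


def _blocks_from_cigar(pos: int, cigartuples) -> Tuple[Tuple[int, int], ...]:
    """Reference blocks split only on N (introns); M/=/X/D extend the block."""
    blocks: List[Tuple[int, int]] = []
    start = pos
    cur = pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            cur += length
        elif op == 3:  # N: splice gap
            if cur > start:
                blocks.append((start, cur))
            cur += length
            start = cur
        # I, S, H, P consume no reference
    if cur > start:
        blocks.append((start, cur))
    return tuple(blocks)


def read_alignments_sam(path: str) -> List[AlignedRead]:
    """Read all mapped alignments (primary and secondary) grouped per read.

    polyA content is computed from the primary record's sequence; secondary
    records routinely omit the sequence.
    """
    import pysam

    order: List[str] = []
    alns: Dict[str, List[Alignment]] = {}
    fracs: Dict[str, float] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            rid = rec.query_name
            if rid not in alns:
                alns[rid] = []
                order.append(rid)
            alns[rid].append(
                Alignment(
                    chrom=rec.reference_name,
                    blocks=_blocks_from_cigar(rec.reference_start, rec.cigartuples),
                )
            )
            if not rec.is_secondary and rec.query_sequence:
                fracs[rid] = polya_fraction(rec.query_sequence)
    return [
        AlignedRead(read_id=rid, polyA_frac=fracs.get(rid, 0.0), alignments=tuple(alns[rid]))
        for rid in order
    ]


def read_gene_models_bed12(path: str) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + off, start + off + sz) for off, sz in zip(starts, sizes))
            genes.append(
                GeneModel(
                    chrom=chrom,
                    strand=strand,
                    start=int(f[1]),
                    end=int(f[2]),
                    exons=exons,
                    gene_id=name,
                )
            )
    return genes


def write_gene_models_bed12(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id or "gene",
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_models_gtf(path: str) -> List[GeneModel]:
    """One GeneModel per transcript, from the exon lines of a GTF."""
    exons: Dict[Tuple[str, str, str], List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            tid = attrs.get("transcript_id") or attrs.get("gene_id") or "tx"
            key = (f[0], f[6], tid)
            # GTF is 1-based inclusive
            exons.setdefault(key, []).append((int(f[3]) - 1, int(f[4])))
    genes = []
    for (chrom, strand, tid), ex in sorted(exons.items()):
        ex.sort()
        genes.append(
            GeneModel(
                chrom=chrom,
                strand=strand,
                start=ex[0][0],
                end=ex[-1][1],
                exons=tuple(ex),
                gene_id=tid,
            )
        )
    return genes
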