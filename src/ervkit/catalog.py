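"""Assembly and classification of full-length retrotransposon elements.

ERV proviruses are annotated by RepeatMasker/Repbase as separate records:
internal ("-int") segments and long terminal repeats (LTRs). This module
re-assembles those records into elements:

* inner parts of the same subfamily lying within ``max_gap`` bp of each other
  are chain-merged;
* a merged inner flanked by an admissible LTR within ``max_ltr_dist`` bp on
  both sides is a *full-length* element, with one flank a *half-length*
  element, and an LTR never attached to any inner is a *solo LTR*;
* an inner with no admissible flank is kept as *inner_only* so that no
  annotated record is silently dropped.

Coordinates are 0-based half-open throughout; RepeatMasker ``.out`` records
(1-based inclusive) are converted on read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "RepeatFeature",
    "MergedInner",
    "AssembledElement",
    "LtrCompatibilityTable",
    "DEFAULT_GROUP_PATTERNS",
    "DEFAULT_INNER_KEYWORD",
    "derive_group",
    "load_repeat_annotation",
    "merge_inner_parts",
    "assemble_elements",
    "classify_solo_ltrs",
    "select_long_lines",
    "build_catalog",
    "CatalogResult",
    "write_catalog_bed",
    "write_catalog_summary",
]

#: Ordered (regex, group) rules mapping Repbase subfamily names to the broad
#: taxa counted in this package. Editable because Repbase label sets vary by
#: release.
DEFAULT_GROUP_PATTERNS: Tuple[Tuple[str, str], ...] = (
    (r"^IAP", "IAP"),
    (r"^MMERVK", "MMERVK"),
    (r"^MMETn", "MMETn"),
    (r"^RLTRETN", "MMETn"),
    (r"^L1", "L1"),
    (r"^L2", "L2"),
)

DEFAULT_INNER_KEYWORD = "int"

FULL_LENGTH = "full_length"
HALF_LENGTH = "half_length"
SOLO_LTR = "solo_ltr"
INNER_ONLY = "inner_only"

_CATEGORY_COLORS = {
    FULL_LENGTH: "31,119,180",
    HALF_LENGTH: "255,127,14",
    SOLO_LTR: "44,160,44",
    INNER_ONLY: "127,127,127",
}


def derive_group(name: str, patterns: Sequence[Tuple[str, str]] = DEFAULT_GROUP_PATTERNS) -> str:
    """Map a repeat subfamily name to its broad group via the pattern table."""
    for pat, group in patterns:
        if re.match(pat, name):
            return group
    return "other"


@dataclass(frozen=True)
class RepeatFeature:
    """One annotated repeat interval (0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    repclass: str
    group: str
    is_inner: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"repeat feature {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"repeat feature {self.id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MergedInner:
    """A chain of same-subfamily inner parts merged across gaps <= max_gap."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    group: str
    member_ids: Tuple[str, ...]


@dataclass(frozen=True)
class AssembledElement:
    """An assembled retrotransposon element with its structural category."""

    chrom: str
    start: int
    end: int
    strand: str
    group: str
    subfamily: str
    category: str
    inner: Optional[MergedInner] = None
    ltr5_id: Optional[str] = None
    ltr3_id: Optional[str] = None

    @property
    def n_ltrs(self) -> int:
        return int(self.ltr5_id is not None) + int(self.ltr3_id is not None)


@dataclass
class LtrCompatibilityTable:
    """Admissible LTR groups per inner group.

    IAP inner parts admit only IAP LTRs; by default every group admits only
    LTRs of its own group, which generalizes that rule symmetrically.
    """

    table: Dict[str, Set[str]] = field(default_factory=dict)

    @classmethod
    def same_group(cls, groups: Iterable[str]) -> "LtrCompatibilityTable":
        return cls({g: {g} for g in set(groups)})

    def admits(self, inner_group: str, ltr_group: str) -> bool:
        if inner_group not in self.table:
            raise KeyError(f"no LTR compatibility entry for inner group {inner_group!r}")
        return ltr_group in self.table[inner_group]

    @classmethod
    def from_yaml(cls, path: str) -> "LtrCompatibilityTable":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({k: set(v) for k, v in raw.items()})


def _infer_repclass(name: str, group: str) -> str:
    if group in ("L1", "L2"):
        return "LINE"
    if re.match(r"^(Alu|B[124]|MIR)", name):
        return "SINE"
    return "LTR"


_RM_CLASS = {"LTR": "LTR", "LINE": "LINE", "SINE": "SINE"}


def load_repeat_annotation(
    path: str,
    dialect: str = "bed",
    pattern_table: Sequence[Tuple[str, str]] = DEFAULT_GROUP_PATTERNS,
    inner_keyword: str = DEFAULT_INNER_KEYWORD,
) -> List[RepeatFeature]:
    """Read a repeat annotation into RepeatFeature records sorted by (chrom, start).

    Parameters
    ----------
    path:
        BED6 (optionally with a 7th repclass column) or RepeatMasker ``.out``.
    dialect:
        ``"bed"`` or ``"repeatmasker_out"``.
    pattern_table:
        Ordered (regex, group) rules; first match wins, fallback ``"other"``.
    inner_keyword:
        A feature is an inner part iff its name contains this keyword.
    """
    if dialect not in ("bed", "repeatmasker_out"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    records: List[Tuple[str, int, int, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if dialect == "bed":
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
                name, strand = fields[3], fields[5]
                repclass = fields[6] if len(fields) > 6 else ""
            else:
                fields = line.split()
                if fields and fields[0] in ("SW", "score"):  # .out header lines
                    continue
                if len(fields) < 11:
                    raise ValueError(f"{path}:{lineno}: expected >=11 RepeatMasker columns")
                chrom = fields[4]
                try:
                    # 1-based inclusive -> 0-based half-open
                    start, end = int(fields[5]) - 1, int(fields[6])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
                strand = "-" if fields[8] in ("C", "-") else "+"
                name = fields[9]
                repclass = _RM_CLASS.get(fields[10].split("/")[0], "other")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start ({start}) must be < end ({end})")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            records.append((chrom, start, end, name, strand, repclass))

    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    features = []
    for i, (chrom, start, end, name, strand, repclass) in enumerate(records):
        group = derive_group(name, pattern_table)
        features.append(
            RepeatFeature(
                id=f"r{i:06d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                name=name,
                repclass=repclass or _infer_repclass(name, group),
                group=group,
                is_inner=inner_keyword in name,
            )
        )
    return features


def merge_inner_parts(features: Sequence[RepeatFeature], max_gap: int = 200) -> List[MergedInner]:
    """Chain-merge same-subfamily inner parts separated by at most ``max_gap`` bp.

    The gap between consecutive parts is ``next.start - prev.end`` (bases
    strictly between them); touching or overlapping parts always merge.
    Merging is restricted to the same (chrom, strand, subfamily) and is
    transitively closed.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    for f in features:
        if not f.is_inner:
            raise ValueError(f"merge_inner_parts expects inner parts only; {f.id!r} is not")

    by_key: Dict[Tuple[str, str, str], List[RepeatFeature]] = {}
    for f in features:
        by_key.setdefault((f.chrom, f.strand, f.name), []).append(f)

    merged: List[MergedInner] = []
    for (chrom, strand, name), group_feats in by_key.items():
        group_feats.sort(key=lambda f: (f.start, f.end, f.id))
        chain: List[RepeatFeature] = []
        chain_end = None
        for f in group_feats:
            if chain and f.start - chain_end > max_gap:
                merged.append(_close_chain(chain))
                chain = []
            chain.append(f)
            chain_end = f.end if chain_end is None or len(chain) == 1 else max(chain_end, f.end)
        if chain:
            merged.append(_close_chain(chain))
    merged.sort(key=lambda m: (m.chrom, m.start, m.end, m.strand, m.subfamily))
    return merged


def _close_chain(chain: List[RepeatFeature]) -> MergedInner:
    return MergedInner(
        chrom=chain[0].chrom,
        start=min(f.start for f in chain),
        end=max(f.end for f in chain),
        strand=chain[0].strand,
        subfamily=chain[0].name,
        group=chain[0].group,
        member_ids=tuple(f.id for f in chain),
    )


def assemble_elements(
    inners: Sequence[MergedInner],
    ltrs: Sequence[RepeatFeature],
    max_ltr_dist: int = 50,
    compat: Optional[LtrCompatibilityTable] = None,
) -> List[AssembledElement]:
    """Attach flanking LTRs to merged inner parts and categorize the elements.

    An LTR is a candidate flank for an inner if it lies on the same chromosome
    and strand, its group is admissible for the inner's group, and its
    edge-to-edge gap to the inner is at most ``max_ltr_dist`` bp (overlapping
    LTRs count as gap <= 0). Each LTR attaches to at most one element: the
    contention is resolved globally, nearest inner first, ties broken by the
    smaller inner start, then smaller LTR start. Both flanks attached gives a
    full-length element, exactly one a half-length element, none an
    ``inner_only`` record. No length filter is applied to inners or LTRs.
    """
    if max_ltr_dist < 0:
        raise ValueError(f"max_ltr_dist must be >= 0, got {max_ltr_dist}")
    if compat is None:
        compat = LtrCompatibilityTable.same_group([m.group for m in inners])
    for f in ltrs:
        if f.is_inner:
            raise ValueError(f"assemble_elements expects non-inner LTRs; {f.id!r} is inner")

    # candidate (distance, inner_idx, ltr, side) triples; side 'up'/'down' in
    # genomic orientation, mapped to 5'/3' by strand afterwards
    candidates: List[Tuple[int, int, int, str, RepeatFeature]] = []
    for ii, inner in enumerate(inners):
        if inner.group not in compat.table:
            raise KeyError(f"no LTR compatibility entry for inner group {inner.group!r}")
        for ltr in ltrs:
            if ltr.chrom != inner.chrom or ltr.strand != inner.strand:
                continue
            if not compat.admits(inner.group, ltr.group):
                continue
            if ltr.start < inner.start and inner.start - ltr.end <= max_ltr_dist:
                gap = inner.start - ltr.end
                candidates.append((max(0, gap), ii, ltr.start, "up", ltr))
            elif ltr.end > inner.end and ltr.start - inner.end <= max_ltr_dist:
                gap = ltr.start - inner.end
                candidates.append((max(0, gap), ii, ltr.start, "down", ltr))

    candidates.sort(key=lambda c: (c[0], inners[c[1]].start, c[2], c[3]))
    up_flank: Dict[int, RepeatFeature] = {}
    down_flank: Dict[int, RepeatFeature] = {}
    used_ltrs: Set[str] = set()
    for _dist, ii, _ltr_start, side, ltr in candidates:
        slot = up_flank if side == "up" else down_flank
        if ii in slot or ltr.id in used_ltrs:
            continue
        slot[ii] = ltr
        used_ltrs.add(ltr.id)

    elements: List[AssembledElement] = []
    for ii, inner in enumerate(inners):
        up = up_flank.get(ii)
        down = down_flank.get(ii)
        n = int(up is not None) + int(down is not None)
        category = FULL_LENGTH if n == 2 else HALF_LENGTH if n == 1 else INNER_ONLY
        start = min([inner.start] + [l.start for l in (up, down) if l is not None])
        end = max([inner.end] + [l.end for l in (up, down) if l is not None])
        if inner.strand == "+":
            ltr5, ltr3 = up, down
        else:
            ltr5, ltr3 = down, up
        elements.append(
            AssembledElement(
                chrom=inner.chrom,
                start=start,
                end=end,
                strand=inner.strand,
                group=inner.group,
                subfamily=inner.subfamily,
                category=category,
                inner=inner,
                ltr5_id=ltr5.id if ltr5 is not None else None,
                ltr3_id=ltr3.id if ltr3 is not None else None,
            )
        )
    elements.sort(key=lambda e: (e.chrom, e.start, e.end))
    return elements


def attached_ltr_ids(elements: Iterable[AssembledElement]) -> Set[str]:
    """The ids of all LTRs used as flanks in an assembled element list."""
    ids: Set[str] = set()
    for e in elements:
        for lid in (e.ltr5_id, e.ltr3_id):
            if lid is not None:
                ids.add(lid)
    return ids


def classify_solo_ltrs(
    ltrs: Sequence[RepeatFeature], attached_ids: Set[str]
) -> List[AssembledElement]:
    """Every LTR never attached as a flank becomes a solo-LTR element."""
    solos = [
        AssembledElement(
            chrom=f.chrom,
            start=f.start,
            end=f.end,
            strand=f.strand,
            group=f.group,
            subfamily=f.name,
            category=SOLO_LTR,
            ltr5_id=f.id,
        )
        for f in ltrs
        if f.id not in attached_ids
    ]
    solos.sort(key=lambda e: (e.chrom, e.start, e.end))
    return solos


def select_long_lines(
    features: Sequence[RepeatFeature], min_len_exclusive: int = 6000
) -> List[RepeatFeature]:
    """Keep L1 elements strictly longer than ``min_len_exclusive`` bp (default >6 kb)."""
    return [f for f in features if f.group == "L1" and f.length > min_len_exclusive]


@dataclass
class CatalogResult:
    """Assembled element catalog plus its per-group category summary."""

    elements: List[AssembledElement]

    def by_category(self, category: str) -> List[AssembledElement]:
        return [e for e in self.elements if e.category == category]

    def summary(self) -> Dict[str, Dict[str, int]]:
        out: Dict[str, Dict[str, int]] = {}
        for e in self.elements:
            per = out.setdefault(
                e.group, {FULL_LENGTH: 0, HALF_LENGTH: 0, SOLO_LTR: 0, INNER_ONLY: 0}
            )
            per[e.category] += 1
        return out


def build_catalog(
    features: Sequence[RepeatFeature],
    max_gap: int = 200,
    max_ltr_dist: int = 50,
    compat: Optional[LtrCompatibilityTable] = None,
) -> CatalogResult:
    """Run the full assembly: merge inners, attach LTRs, classify solos."""
    inners = [f for f in features if f.is_inner]
    ltrs = [f for f in features if f.repclass == "LTR" and not f.is_inner]
    merged = merge_inner_parts(inners, max_gap=max_gap)
    if compat is None and merged:
        compat = LtrCompatibilityTable.same_group(
            [m.group for m in merged] + [l.group for l in ltrs]
        )
    assembled = assemble_elements(merged, ltrs, max_ltr_dist=max_ltr_dist, compat=compat)
    solos = classify_solo_ltrs(ltrs, attached_ltr_ids(assembled))
    elements = sorted(assembled + solos, key=lambda e: (e.chrom, e.start, e.end, e.category))
    return CatalogResult(elements=elements)


def write_catalog_bed(result: CatalogResult, path: str) -> None:
    """Write the catalog as BED9 with the category in the name and itemRgb colors."""
    with open(path, "w") as fh:
        for e in result.elements:
            name = f"{e.subfamily}|{e.group}|{e.category}"
            fh.write(
                "\t".join(
                    [
                        e.chrom,
                        str(e.start),
                        str(e.end),
                        name,
                        "0",
                        e.strand,
                        str(e.start),
                        str(e.end),
                        _CATEGORY_COLORS[e.category],
                    ]
                )
                + "\n"
            )


def write_catalog_summary(result: CatalogResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
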