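"""Independent reference implementations used as oracles in tests.

These deliberately avoid the package's algorithms: merging is done by
transitive closure over an exhaustive O(n^2) pairwise scan, LTR attachment
by brute-force candidate enumeration, and read classification by scanning
every annotated feature per read. They share only the rule definitions
(gap <= max_gap merges; edge-to-edge LTR distance <= max_ltr_dist attaches;
nearest inner wins, ties to the smaller start).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from ervkit.catalog import RepeatFeature, derive_group

GROUP_NAME_POOL = [
    ("IAPEz-int", "LTR"),
    ("IAPLTR1_Mm", "LTR"),
    ("IAPLTR2_Mm", "LTR"),
    ("MMERVK10C-int", "LTR"),
    ("MMERVK10C", "LTR"),
    ("MMETn-int", "LTR"),
    ("MMETn_Mm", "LTR"),
    ("L1Md_A", "LINE"),
    ("B2_Mm2", "SINE"),
]


def random_annotation(seed: int, n_features: int = 300, span: int = 60_000) -> List[RepeatFeature]:
    """Messy random annotation: arbitrary overlaps, strands and subfamilies."""
    rng = np.random.default_rng(seed)
    feats = []
    for i in range(n_features):
        name, repclass = GROUP_NAME_POOL[int(rng.integers(0, len(GROUP_NAME_POOL)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(80, 2500))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{int(rng.integers(1, 3))}"
        feats.append(
            RepeatFeature(
                id=f"q{i:05d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                name=name,
                repclass=repclass,
                group=derive_group(name),
                is_inner="int" in name,
            )
        )
    feats.sort(key=lambda f: (f.chrom, f.start, f.end, f.name))
    return feats


def _pairwise_gap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Edge-to-edge separation; <= 0 for touching or overlapping intervals."""
    return max(a[0], b[0]) - min(a[1], b[1])


def oracle_merge(features: Sequence[RepeatFeature], max_gap: int) -> List[dict]:
    """Transitive closure over all pairs with separation <= max_gap."""
    groups: Dict[Tuple[str, str, str], List[RepeatFeature]] = {}
    for f in features:
        groups.setdefault((f.chrom, f.strand, f.name), []).append(f)
    merged = []
    for key, members in groups.items():
        n = len(members)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                gi = (members[i].start, members[i].end)
                gj = (members[j].start, members[j].end)
                if _pairwise_gap(gi, gj) <= max_gap:
                    parent[find(i)] = find(j)
        clusters: Dict[int, List[RepeatFeature]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(members[i])
        for cluster in clusters.values():
            merged.append(
                {
                    "chrom": key[0],
                    "strand": key[1],
                    "subfamily": key[2],
                    "group": cluster[0].group,
                    "start": min(f.start for f in cluster),
                    "end": max(f.end for f in cluster),
                    "member_ids": tuple(sorted(f.id for f in cluster)),
                }
            )
    merged.sort(key=lambda m: (m["chrom"], m["start"], m["end"], m["strand"], m["subfamily"]))
    return merged


def oracle_catalog(
    features: Sequence[RepeatFeature],
    max_gap: int = 200,
    max_ltr_dist: int = 50,
) -> Set[Tuple]:
    """Full brute-force catalog; same-group LTR compatibility.

    Returns a set of (chrom, start, end, strand, group, category) tuples,
    directly comparable with the package's assembled catalog.
    """
    inners = [f for f in features if f.is_inner]
    ltrs = [f for f in features if f.repclass == "LTR" and not f.is_inner]
    merged = oracle_merge(inners, max_gap)

    candidates = []
    for mi, m in enumerate(merged):
        for ltr in ltrs:
            if ltr.chrom != m["chrom"] or ltr.strand != m["strand"]:
                continue
            if ltr.group != m["group"]:
                continue
            if ltr.start < m["start"] and m["start"] - ltr.end <= max_ltr_dist:
                candidates.append((max(0, m["start"] - ltr.end), mi, ltr.start, "up", ltr))
            elif ltr.end > m["end"] and ltr.start - m["end"] <= max_ltr_dist:
                candidates.append((max(0, ltr.start - m["end"]), mi, ltr.start, "down", ltr))
    candidates.sort(key=lambda c: (c[0], merged[c[1]]["start"], c[2], c[3]))

    flanks: Dict[Tuple[int, str], RepeatFeature] = {}
    used: Set[str] = set()
    for dist, mi, _ls, side, ltr in candidates:
        if (mi, side) in flanks or ltr.id in used:
            continue
        flanks[(mi, side)] = ltr
        used.add(ltr.id)

    out: Set[Tuple] = set()
    counted: Dict[Tuple, int] = {}
    for mi, m in enumerate(merged):
        attached = [flanks.get((mi, "up")), flanks.get((mi, "down"))]
        attached = [a for a in attached if a is not None]
        category = {2: "full_length", 1: "half_length", 0: "inner_only"}[len(attached)]
        start = min([m["start"]] + [a.start for a in attached])
        end = max([m["end"]] + [a.end for a in attached])
        key = (m["chrom"], start, end, m["strand"], m["group"], category)
        counted[key] = counted.get(key, 0) + 1
        out.add(key + (counted[key],))
    for ltr in ltrs:
        if ltr.id not in used:
            key = (ltr.chrom, ltr.start, ltr.end, ltr.strand, ltr.group, "solo_ltr")
            counted[key] = counted.get(key, 0) + 1
            out.add(key + (counted[key],))
    return out


def catalog_key_set(elements) -> Set[Tuple]:
    """The package catalog rendered in the oracle's comparable key form."""
    out: Set[Tuple] = set()
    counted: Dict[Tuple, int] = {}
    for e in elements:
        key = (e.chrom, e.start, e.end, e.strand, e.group, e.category)
        counted[key] = counted.get(key, 0) + 1
        out.add(key + (counted[key],))
    return out


def brute_force_read_group(read, features: Sequence[RepeatFeature]):
    """Per-read classifier scanning every feature for block overlap."""
    union = set()
    for aln in read.alignments:
        groups = set()
        for f in features:
            if f.chrom != aln.chrom:
                continue
            for s, e in aln.blocks:
                if s < f.end and f.start < e:
                    groups.add(f.group)
                    break
        if not groups:
            return None
        union |= groups
    return next(iter(union)) if len(union) == 1 else None
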