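"""Ground-truthed synthetic inputs for every analysis module.

Each generator is a pure function of its seed and parameters and returns the
planted ground truth alongside the data, so the catalog assembly, repeat
quantification, imaging and PALM pipelines can be validated end-to-end
without any external download. A global seed is expanded into per-component
substreams, so adding a generator never perturbs the output of another.

The generators emulate structure, not realism: annotations are laid out on a
short synthetic contig with generous spacing, reads are placed to trip
exactly one filter each (contaminants) or none (planted subfamily reads),
image stacks contain Gaussian spots over flat background noise, and PALM
point patterns are Gaussian clusters over uniform background.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .catalog import (
    FULL_LENGTH,
    HALF_LENGTH,
    INNER_ONLY,
    SOLO_LTR,
    RepeatFeature,
    derive_group,
)
from .imaging import ImageStack, _panel_side
from .palm import LocalizationSet, SiteAnchor
from .quant import AlignedRead, Alignment, GeneModel

__all__ = [
    "TruthCatalog",
    "TruthElement",
    "TruthReads",
    "TruthImage",
    "TruthPalm",
    "simulate_repeat_annotation",
    "simulate_reads",
    "simulate_two_channel_stack",
    "simulate_palm",
    "simulate_droplet_image",
    "features_to_bed",
    "write_stack_tiff",
    "write_truth_json",
]

# substream tags: one per generator, so streams never collide
_TAG_ANNOTATION = 1
_TAG_READS = 2
_TAG_STACK = 3
_TAG_PALM = 4
_TAG_DROPLET = 5

_GROUP_NAMES = {
    "IAP": {"inner": "IAPEz-int", "ltr": "IAPLTR1_Mm"},
    "MMERVK": {"inner": "MMERVK10C-int", "ltr": "MMERVK10C"},
    "MMETn": {"inner": "MMETn-int", "ltr": "MMETn_Mm"},
}
_GROUP_CYCLE = ("IAP", "MMERVK", "MMETn")

_LTR_LEN = 350
_INNER_LEN = 1200


@dataclass(frozen=True)
class TruthElement:
    label: str
    category: str
    group: str
    chrom: str
    start: int
    end: int


@dataclass
class TruthCatalog:
    elements: List[TruthElement]

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for e in self.elements:
            out[e.category] = out.get(e.category, 0) + 1
        return out


@dataclass
class SimulatedAnnotation:
    features: List[RepeatFeature]
    truth: TruthCatalog
    chrom: str


def _feature(fid, chrom, start, end, name, strand, repclass="LTR") -> RepeatFeature:
    return RepeatFeature(
        id=fid,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        name=name,
        repclass=repclass,
        group=derive_group(name),
        is_inner="int" in name,
    )


def simulate_repeat_annotation(
    seed: int,
    n_full: int = 5,
    n_half: int = 3,
    n_solo: int = 7,
    n_inner_only: int = 0,
    gap_range: Tuple[int, int] = (50, 200),
    ltr_dist_range: Tuple[int, int] = (0, 50),
    boundary_cases: bool = False,
    max_gap: int = 200,
    max_ltr_dist: int = 50,
    chrom: str = "chrS",
    spacing: int = 1000,
) -> SimulatedAnnotation:
    """Plant full-length / half-length / solo-LTR structures on one contig.

    Elements are separated by at least ``spacing`` bp so they cannot
    interfere; with ``boundary_cases`` four deterministic constructs probe
    the merge-gap (200/201 bp) and LTR-distance (50/51 bp) decision
    boundaries exactly.
    """
    if not (0 <= gap_range[0] <= gap_range[1] <= max_gap):
        raise ValueError(f"gap_range {gap_range} inconsistent with max_gap {max_gap}")
    if not (0 <= ltr_dist_range[0] <= ltr_dist_range[1] <= max_ltr_dist):
        raise ValueError(
            f"ltr_dist_range {ltr_dist_range} inconsistent with max_ltr_dist {max_ltr_dist}"
        )
    rng = np.random.default_rng([seed, _TAG_ANNOTATION])
    features: List[RepeatFeature] = []
    truth: List[TruthElement] = []
    cursor = 1000
    serial = 0

    def nid() -> str:
        nonlocal serial
        serial += 1
        return f"s{serial:05d}"

    def draw(lo_hi: Tuple[int, int]) -> int:
        return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    def plant_full(group: str, label: str) -> None:
        nonlocal cursor
        names = _GROUP_NAMES[group]
        strand = str(rng.choice(["+", "-"]))
        d5, d3, gap = draw(ltr_dist_range), draw(ltr_dist_range), draw(gap_range)
        s = cursor
        ltr_a = _feature(nid(), chrom, s, s + _LTR_LEN, names["ltr"], strand)
        i1s = ltr_a.end + d5
        inner1 = _feature(nid(), chrom, i1s, i1s + _INNER_LEN, names["inner"], strand)
        i2s = inner1.end + gap
        inner2 = _feature(nid(), chrom, i2s, i2s + _INNER_LEN, names["inner"], strand)
        lbs = inner2.end + d3
        ltr_b = _feature(nid(), chrom, lbs, lbs + _LTR_LEN, names["ltr"], strand)
        features.extend([ltr_a, inner1, inner2, ltr_b])
        truth.append(TruthElement(label, FULL_LENGTH, group, chrom, ltr_a.start, ltr_b.end))
        cursor = ltr_b.end + spacing

    def plant_half(group: str, label: str) -> None:
        nonlocal cursor
        names = _GROUP_NAMES[group]
        strand = str(rng.choice(["+", "-"]))
        d = draw(ltr_dist_range)
        upstream = bool(rng.integers(0, 2))
        s = cursor
        if upstream:
            ltr = _feature(nid(), chrom, s, s + _LTR_LEN, names["ltr"], strand)
            istart = ltr.end + d
            inner = _feature(nid(), chrom, istart, istart + 1800, names["inner"], strand)
            span = (ltr.start, inner.end)
        else:
            inner = _feature(nid(), chrom, s, s + 1800, names["inner"], strand)
            lstart = inner.end + d
            ltr = _feature(nid(), chrom, lstart, lstart + _LTR_LEN, names["ltr"], strand)
            span = (inner.start, ltr.end)
        features.extend([ltr, inner])
        truth.append(TruthElement(label, HALF_LENGTH, group, chrom, span[0], span[1]))
        cursor = span[1] + spacing

    def plant_solo(group: str, label: str) -> None:
        nonlocal cursor
        strand = str(rng.choice(["+", "-"]))
        ltr = _feature(nid(), chrom, cursor, cursor + _LTR_LEN, _GROUP_NAMES[group]["ltr"], strand)
        features.append(ltr)
        truth.append(TruthElement(label, SOLO_LTR, group, chrom, ltr.start, ltr.end))
        cursor = ltr.end + spacing

    def plant_inner_only(group: str, label: str) -> None:
        nonlocal cursor
        strand = str(rng.choice(["+", "-"]))
        inner = _feature(
            nid(), chrom, cursor, cursor + 1500, _GROUP_NAMES[group]["inner"], strand
        )
        features.append(inner)
        truth.append(TruthElement(label, INNER_ONLY, group, chrom, inner.start, inner.end))
        cursor = inner.end + spacing

    for i in range(n_full):
        plant_full(_GROUP_CYCLE[i % 3], f"full{i}")
    for i in range(n_half):
        plant_half(_GROUP_CYCLE[i % 3], f"half{i}")
    for i in range(n_solo):
        plant_solo(_GROUP_CYCLE[i % 3], f"solo{i}")
    for i in range(n_inner_only):
        plant_inner_only(_GROUP_CYCLE[i % 3], f"inneronly{i}")

    if boundary_cases:
        names = _GROUP_NAMES["IAP"]

        # gap exactly max_gap between inner parts: still one merged inner -> full
        s = cursor
        la = _feature(nid(), chrom, s, s + _LTR_LEN, names["ltr"], "+")
        i1 = _feature(nid(), chrom, la.end + 10, la.end + 10 + _INNER_LEN, names["inner"], "+")
        i2 = _feature(
            nid(), chrom, i1.end + max_gap, i1.end + max_gap + _INNER_LEN, names["inner"], "+"
        )
        lb = _feature(nid(), chrom, i2.end + 10, i2.end + 10 + _LTR_LEN, names["ltr"], "+")
        features.extend([la, i1, i2, lb])
        truth.append(TruthElement("b_gap_eq", FULL_LENGTH, "IAP", chrom, la.start, lb.end))
        cursor = lb.end + spacing

        # gap max_gap + 1: two merged inners, each with one outer LTR -> two halves
        s = cursor
        la = _feature(nid(), chrom, s, s + _LTR_LEN, names["ltr"], "+")
        i1 = _feature(nid(), chrom, la.end + 10, la.end + 10 + _INNER_LEN, names["inner"], "+")
        i2 = _feature(
            nid(),
            chrom,
            i1.end + max_gap + 1,
            i1.end + max_gap + 1 + _INNER_LEN,
            names["inner"],
            "+",
        )
        lb = _feature(nid(), chrom, i2.end + 10, i2.end + 10 + _LTR_LEN, names["ltr"], "+")
        features.extend([la, i1, i2, lb])
        truth.append(TruthElement("b_gap_over_a", HALF_LENGTH, "IAP", chrom, la.start, i1.end))
        truth.append(TruthElement("b_gap_over_b", HALF_LENGTH, "IAP", chrom, i2.start, lb.end))
        cursor = lb.end + spacing

        # LTR distance exactly max_ltr_dist on both sides -> full
        s = cursor
        la = _feature(nid(), chrom, s, s + _LTR_LEN, names["ltr"], "+")
        i1 = _feature(
            nid(), chrom, la.end + max_ltr_dist, la.end + max_ltr_dist + 1800, names["inner"], "+"
        )
        lb = _feature(
            nid(), chrom, i1.end + max_ltr_dist, i1.end + max_ltr_dist + _LTR_LEN, names["ltr"], "+"
        )
        features.extend([la, i1, lb])
        truth.append(TruthElement("b_dist_eq", FULL_LENGTH, "IAP", chrom, la.start, lb.end))
        cursor = lb.end + spacing

        # LTR distance max_ltr_dist + 1, single LTR -> unattached inner + solo LTR
        s = cursor
        la = _feature(nid(), chrom, s, s + _LTR_LEN, names["ltr"], "+")
        i1 = _feature(
            nid(),
            chrom,
            la.end + max_ltr_dist + 1,
            la.end + max_ltr_dist + 1 + 1800,
            names["inner"],
            "+",
        )
        features.extend([la, i1])
        truth.append(TruthElement("b_dist_over_inner", INNER_ONLY, "IAP", chrom, i1.start, i1.end))
        truth.append(TruthElement("b_dist_over_ltr", SOLO_LTR, "IAP", chrom, la.start, la.end))
        cursor = i1.end + spacing

    return SimulatedAnnotation(features=features, truth=TruthCatalog(truth), chrom=chrom)


@dataclass
class TruthReads:
    planted_counts: Dict[str, int]
    labels: Dict[str, str]  # read_id -> {group | gene | spliced | polyA | ambiguous}
    n_contaminants: int
    n_ambiguous: int


@dataclass
class SimulatedReads:
    reads: List[AlignedRead]
    genes: List[GeneModel]
    truth: TruthReads
    chrom: str
    contig_length: int


def simulate_reads(
    seed: int,
    planted_counts: Mapping[str, int],
    n_gene: int = 100,
    n_spliced: int = 50,
    n_polyA: int = 50,
    n_ambiguous: int = 50,
    features: Sequence[RepeatFeature] = (),
    genes: Optional[Sequence[GeneModel]] = None,
    n_gene_models: int = 5,
    read_len: int = 100,
    multi_frac: float = 0.3,
    polyA_contaminant_frac: float = 0.95,
) -> SimulatedReads:
    """Plant subfamily reads inside annotated elements plus contaminants.

    Subfamily reads fall entirely within elements of a single group (a
    ``multi_frac`` share of them gets 1-2 extra alignments on other elements
    of the same group). Each contaminant class trips exactly one filter:
    gene reads lie inside an exon, spliced reads are gapped in intergenic
    space, polyA reads are intergenic with high A content, and ambiguous
    reads align to elements of two different groups (surviving all filters
    but left unassigned).
    """
    if not features:
        raise ValueError("simulate_reads requires a repeat annotation")
    rng = np.random.default_rng([seed, _TAG_READS])
    chrom = features[0].chrom
    by_group: Dict[str, List[RepeatFeature]] = {}
    for f in features:
        if f.length >= read_len:
            by_group.setdefault(f.group, []).append(f)
    for g in planted_counts:
        if g not in by_group:
            raise ValueError(f"group {g!r} missing from the annotation")
    if n_ambiguous > 0 and len(by_group) < 2:
        raise ValueError("ambiguous reads require elements of >=2 groups")

    max_end = max(f.end for f in features)
    if genes is None:
        gene_zone = max_end + 10_000
        genes = [
            GeneModel(
                chrom=chrom,
                strand="+",
                start=gene_zone + i * 2000,
                end=gene_zone + i * 2000 + 1000,
                exons=(
                    (gene_zone + i * 2000, gene_zone + i * 2000 + 300),
                    (gene_zone + i * 2000 + 700, gene_zone + i * 2000 + 1000),
                ),
                gene_id=f"gene{i}",
            )
            for i in range(max(n_gene_models, 1))
        ]
    genes = list(genes)
    intergenic = max(max_end, max(g.end for g in genes)) + 10_000

    reads: List[AlignedRead] = []
    labels: Dict[str, str] = {}
    serial = 0

    def rid(label: str) -> str:
        nonlocal serial
        serial += 1
        labels_key = f"{label}_{serial:06d}"
        labels[labels_key] = label if label in planted_counts else label
        return labels_key

    def element_read(elements: List[RepeatFeature]) -> Alignment:
        e = elements[int(rng.integers(0, len(elements)))]
        off = int(rng.integers(0, e.length - read_len + 1))
        return Alignment(chrom=chrom, blocks=((e.start + off, e.start + off + read_len),))

    for group in sorted(planted_counts):
        elements = by_group[group]
        for _ in range(planted_counts[group]):
            alns = [element_read(elements)]
            if len(elements) >= 2 and rng.random() < multi_frac:
                for _extra in range(int(rng.integers(1, 3))):
                    alns.append(element_read(elements))
            reads.append(
                AlignedRead(read_id=rid(group), polyA_frac=0.2, alignments=tuple(alns))
            )

    for _ in range(n_gene):
        g = genes[int(rng.integers(0, len(genes)))]
        es, ee = g.exons[0]
        off = int(rng.integers(0, max(ee - es - read_len, 0) + 1))
        reads.append(
            AlignedRead(
                read_id=rid("gene"),
                polyA_frac=0.2,
                alignments=(Alignment(chrom=chrom, blocks=((es + off, es + off + read_len),)),),
            )
        )

    cursor = intergenic
    for _ in range(n_spliced):
        half = read_len // 2
        blocks = ((cursor, cursor + half), (cursor + half + 200, cursor + half + 200 + half))
        reads.append(
            AlignedRead(
                read_id=rid("spliced"),
                polyA_frac=0.2,
                alignments=(Alignment(chrom=chrom, blocks=blocks),),
            )
        )
        cursor += 1000
    for _ in range(n_polyA):
        reads.append(
            AlignedRead(
                read_id=rid("polyA"),
                polyA_frac=polyA_contaminant_frac,
                alignments=(Alignment(chrom=chrom, blocks=((cursor, cursor + read_len),)),),
            )
        )
        cursor += 1000

    group_list = sorted(by_group)
    for i in range(n_ambiguous):
        g1 = group_list[i % len(group_list)]
        g2 = group_list[(i + 1) % len(group_list)]
        reads.append(
            AlignedRead(
                read_id=rid("ambiguous"),
                polyA_frac=0.2,
                alignments=(element_read(by_group[g1]), element_read(by_group[g2])),
            )
        )

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = TruthReads(
        planted_counts=dict(planted_counts),
        labels=labels,
        n_contaminants=n_gene + n_spliced + n_polyA,
        n_ambiguous=n_ambiguous,
    )
    return SimulatedReads(
        reads=reads,
        genes=genes,
        truth=truth,
        chrom=chrom,
        contig_length=cursor + 10_000,
    )


def write_reads_sam(sim: SimulatedReads, path: str) -> None:
    """Emit the simulated alignments as SAM with proper multimapper records.

    The first alignment of each read is the primary record and carries a
    sequence whose A content matches the planted polyA fraction; extra
    alignments are secondary (flag 0x100, sequence omitted).
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": sim.chrom, "LN": int(sim.contig_length)}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in sim.reads:
            for i, aln in enumerate(read.alignments):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read.read_id
                rec.flag = 0 if i == 0 else 256
                rec.reference_id = 0
                rec.reference_start = aln.blocks[0][0]
                rec.mapping_quality = 255
                cigar = []
                prev_end = None
                for s, e in aln.blocks:
                    if prev_end is not None:
                        cigar.append((3, s - prev_end))  # N
                    cigar.append((0, e - s))  # M
                    prev_end = e
                rec.cigartuples = cigar
                if i == 0:
                    n = sum(e - s for s, e in aln.blocks)
                    n_a = int(round(read.polyA_frac * n))
                    rec.query_sequence = "A" * n_a + ("CG" * n)[: n - n_a]
                out.write(rec)


@dataclass
class TruthImage:
    fish_centers: np.ndarray  # (n, 3) x, y (px), z (slice), sub-pixel
    if_centers: np.ndarray
    colocalized: np.ndarray  # (n,) bool, aligned with fish_centers
    offset_nm: float
    coloc_fraction: float


@dataclass
class SimulatedStack:
    fish: ImageStack
    if_channel: ImageStack
    nucleus_mask: np.ndarray
    truth: TruthImage


def _render_spots(
    shape: Tuple[int, int, int],
    centers: np.ndarray,
    amplitude: float,
    sigma_xy_px: float,
    sigma_z_px: float,
) -> np.ndarray:
    data = np.zeros(shape, dtype=float)
    nz, ny, nx = shape
    rx = int(math.ceil(4 * sigma_xy_px))
    rz = int(math.ceil(4 * max(sigma_z_px, 0.5)))
    for cx, cy, cz in centers:
        x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 1)
        y0, y1 = max(0, int(cy) - rx), min(ny, int(cy) + rx + 1)
        z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 1)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        data[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(
            -(
                ((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_xy_px**2)
                + ((zz - cz) ** 2) / (2 * sigma_z_px**2)
            )
        )
    return data


def simulate_two_channel_stack(
    seed: int,
    n_foci: int = 200,
    coloc_fraction: float = 1.0,
    offset_nm: float = 0.0,
    psf_sigma_nm: float = 100.0,
    psf_sigma_z_nm: float = 300.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    noise_sd: float = 10.0,
    pixel_size_nm: float = 65.0,
    z_step_nm: float = 300.0,
    dims: Tuple[int, int, int] = (15, 448, 448),
    l_um: float = 1.5,
) -> SimulatedStack:
    """Two-channel z-stack with planted foci and a controlled coloc fraction.

    FISH spots are 3D Gaussians placed inside an elliptical nucleus mask with
    enough border margin for complete average-image patches. A
    ``coloc_fraction`` share of IF spots sits at ``offset_nm`` from its FISH
    partner (0 = perfectly coincident); the rest are placed uniformly at
    random inside the nucleus. Gaussian read noise is added on a flat
    background.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    nz, ny, nx = dims
    rng = np.random.default_rng([seed, _TAG_STACK])
    margin = _panel_side(l_um, pixel_size_nm) // 2 + 3
    a, b = nx / 2 - margin, ny / 2 - margin
    if a <= 2 or b <= 2 or nz < 5:
        raise ValueError(f"dims {dims} too small for the panel margin {margin}")
    cx0, cy0 = (nx - 1) / 2, (ny - 1) / 2

    def sample_xy(n: int) -> np.ndarray:
        pts = np.empty((n, 2))
        got = 0
        while got < n:
            cand = rng.uniform(-1, 1, size=(2 * (n - got) + 8, 2))
            ok = cand[:, 0] ** 2 + cand[:, 1] ** 2 <= 1.0
            take = cand[ok][: n - got]
            pts[got : got + take.shape[0]] = take
            got += take.shape[0]
        return np.column_stack([cx0 + a * pts[:, 0], cy0 + b * pts[:, 1]])

    zmargin = 2
    if n_foci > int(math.pi * a * b):
        raise ValueError(f"n_foci={n_foci} too large for the nucleus mask")
    fish_xy = sample_xy(n_foci)
    fish_z = rng.uniform(zmargin, nz - 1 - zmargin, size=n_foci)
    fish_centers = np.column_stack([fish_xy, fish_z])

    n_coloc = int(round(coloc_fraction * n_foci))
    coloc = np.zeros(n_foci, dtype=bool)
    coloc[:n_coloc] = True
    theta = rng.uniform(0, 2 * math.pi, size=n_coloc)
    off_px = offset_nm / pixel_size_nm
    if_coloc = fish_centers[:n_coloc].copy()
    if_coloc[:, 0] += off_px * np.cos(theta)
    if_coloc[:, 1] += off_px * np.sin(theta)
    n_bg = n_foci - n_coloc
    if_bg = np.column_stack(
        [sample_xy(n_bg), rng.uniform(zmargin, nz - 1 - zmargin, size=n_bg)]
    )
    if_centers = np.vstack([if_coloc, if_bg])

    sxy = psf_sigma_nm / pixel_size_nm
    sz = psf_sigma_z_nm / z_step_nm
    fish_data = background + _render_spots(dims, fish_centers, amplitude, sxy, sz)
    if_data = background + _render_spots(dims, if_centers, amplitude, sxy, sz)
    if noise_sd > 0:
        fish_data = fish_data + rng.normal(0, noise_sd, size=dims)
        if_data = if_data + rng.normal(0, noise_sd, size=dims)
    fish_data = np.clip(fish_data, 0, None)
    if_data = np.clip(if_data, 0, None)

    yy, xx = np.mgrid[0:ny, 0:nx]
    ellipse = ((xx - cx0) / a) ** 2 + ((yy - cy0) / b) ** 2 <= 1.0
    mask = np.broadcast_to(ellipse, dims).copy()

    truth = TruthImage(
        fish_centers=fish_centers,
        if_centers=if_centers,
        colocalized=coloc,
        offset_nm=offset_nm,
        coloc_fraction=coloc_fraction,
    )
    return SimulatedStack(
        fish=ImageStack(fish_data, pixel_size_nm, z_step_nm, channel="fish"),
        if_channel=ImageStack(if_data, pixel_size_nm, z_step_nm, channel="if"),
        nucleus_mask=mask,
        truth=truth,
    )


@dataclass
class TruthPalm:
    cluster_centers: np.ndarray  # (k, 2) nm
    cluster_sizes: np.ndarray  # (k,)
    site: Tuple[float, float]
    nearest_site_distance_nm: float
    n_background: int


@dataclass
class SimulatedPalm:
    locs: LocalizationSet
    truth: TruthPalm


DEFAULT_PALM_CLUSTERS: Tuple[Tuple[Tuple[float, float], float, int], ...] = (
    ((2000.0, 2000.0), 30.0, 200),
    ((3000.0, 2000.0), 30.0, 200),
    ((2500.0, 2866.0), 30.0, 200),
)


def simulate_palm(
    seed: int,
    clusters: Sequence[Tuple[Tuple[float, float], float, int]] = DEFAULT_PALM_CLUSTERS,
    background_density: float = 1.0,  # points per um^2
    site: Optional[Tuple[float, float]] = None,
    field_um: Tuple[float, float] = (6.0, 6.0),
    acquisition_span: float = 100.0,
    cell_id: object = 0,
) -> SimulatedPalm:
    """Gaussian-scattered clusters plus uniform background localizations.

    Timestamps are uniform over the acquisition window. Truth records the
    planted centers and sizes and the planted nearest-to-site distance.
    """
    rng = np.random.default_rng([seed, _TAG_PALM])
    fx, fy = field_um[0] * 1000.0, field_um[1] * 1000.0
    pts = []
    centers = []
    sizes = []
    for (cx, cy), sigma, n in clusters:
        if not (0 <= cx <= fx and 0 <= cy <= fy):
            raise ValueError(f"cluster center ({cx}, {cy}) outside field")
        xy = rng.normal([cx, cy], sigma, size=(n, 2))
        pts.append(xy)
        centers.append((cx, cy))
        sizes.append(n)
    n_bg = rng.poisson(background_density * field_um[0] * field_um[1])
    if n_bg:
        pts.append(rng.uniform([0, 0], [fx, fy], size=(n_bg, 2)))
    xy = np.vstack(pts) if pts else np.empty((0, 2))
    t = rng.uniform(0, acquisition_span, size=xy.shape[0])
    locs = LocalizationSet(
        points=np.column_stack([xy, t]), acquisition_span=acquisition_span, cell_id=cell_id
    )
    if site is None:
        site = centers[0] if centers else (fx / 2, fy / 2)
    d = (
        min(math.hypot(cx - site[0], cy - site[1]) for cx, cy in centers)
        if centers
        else math.nan
    )
    truth = TruthPalm(
        cluster_centers=np.array(centers),
        cluster_sizes=np.array(sizes),
        site=(float(site[0]), float(site[1])),
        nearest_site_distance_nm=float(d),
        n_background=int(n_bg),
    )
    return SimulatedPalm(locs=locs, truth=truth)


def simulate_droplet_image(
    seed: int,
    ratios: Sequence[float] = (2.0, 5.0, 20.0),
    radius_px: int = 12,
    background: float = 100.0,
    droplet_marker: float = 1000.0,
    noise_sd: float = 0.0,
    dims: Tuple[int, int] = (256, 256),
) -> Tuple[np.ndarray, np.ndarray, Dict[str, object]]:
    """A droplet-channel / client-channel image pair with planted ratios.

    Droplets are disks on a grid; inside droplet i the client channel is
    ``ratios[i] * background`` so the planted partition ratio is exact in
    the noiseless case. Returns (client image, droplet image, truth dict).
    """
    rng = np.random.default_rng([seed, _TAG_DROPLET])
    ny, nx = dims
    spacing = 4 * radius_px + 8
    per_row = max((nx - spacing) // spacing, 1)
    measure = np.full(dims, background, dtype=float)
    droplet = np.full(dims, background / 10.0, dtype=float)
    yy, xx = np.mgrid[0:ny, 0:nx]
    centers = []
    for i, ratio in enumerate(ratios):
        cx = spacing + (i % per_row) * spacing
        cy = spacing + (i // per_row) * spacing
        if cy + radius_px >= ny or cx + radius_px >= nx:
            raise ValueError("too many droplets for the image dimensions")
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
        measure[disk] = ratio * background
        droplet[disk] = droplet_marker
        centers.append((cx, cy))
    if noise_sd > 0:
        measure = np.clip(measure + rng.normal(0, noise_sd, size=dims), 0, None)
        droplet = np.clip(droplet + rng.normal(0, noise_sd, size=dims), 0, None)
    truth = {"ratios": list(ratios), "centers": centers, "radius_px": radius_px}
    return measure, droplet, truth


# ---------------------------------------------------------------------------
# writers


def features_to_bed(features: Sequence[RepeatFeature], path: str) -> None:
    """BED6 + repclass column, the native annotation format of this package."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                "\t".join(
                    [f.chrom, str(f.start), str(f.end), f.name, "0", f.strand, f.repclass]
                )
                + "\n"
            )


def write_stack_tiff(stack: ImageStack, path: str) -> None:
    import tifffile

    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        metadata={"pixel_size_nm": stack.pixel_size_xy, "z_step_nm": stack.z_step},
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def write_truth_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
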