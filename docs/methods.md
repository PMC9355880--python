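# Methods

This note documents the models and procedures implemented in `ervkit`, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Retrotransposon element assembly (`ervkit.catalog`)

Repeat annotations describe ERV proviruses as fragments: internal segments
whose subfamily name carries the keyword `int`, and LTR records. The
assembly reconstructs elements in three deterministic steps.

**Merging.** Inner parts are grouped by (chromosome, strand, subfamily) and
chain-merged when the edge-to-edge gap `next.start − prev.end` is at most
`max_gap` (default 200 bp). The gap is the number of bases strictly between
the two features, so touching or overlapping parts (gap ≤ 0) always merge;
merging is transitively closed and, for sorted inputs with a running
maximum end, equivalent to the transitive closure of the pairwise
separation relation (the property the exhaustive test oracle exploits).

**LTR attachment.** An LTR is a candidate flank for a merged inner when it
lies on the same chromosome and strand, its group is admissible for the
inner's group, and its edge-to-edge distance is at most `max_ltr_dist`
(default 50 bp). Distances are measured edge to edge; an overlapping LTR
counts as distance 0. Candidates are resolved globally and greedily: sort
by (distance, inner start, LTR start, side) and attach while both the
inner's side and the LTR are free. This makes contention ("one LTR between
two inners") deterministic — the nearer inner wins, ties go to the smaller
start — and guarantees every LTR attaches to at most one element. Both
flanks ⇒ `full_length`; one ⇒ `half_length`; none ⇒ `inner_only` (kept so
that every annotated inner is conserved in the output, but counted as
neither full nor half in summaries). LTRs never attached anywhere become
`solo_ltr` records. The element's subfamily is that of its inner part; the
5′/3′ identity of the flanks follows the strand. No length restriction is
applied to inners or LTRs.

**Compatibility.** IAP inners admit only IAP LTRs. The shipped default
generalizes this symmetrically — every group admits only LTRs of its own
group — because the broad groups used here (IAP, MMERVK, MMETn) are exactly
the taxa being separated; a YAML table can relax this (e.g. to let any ERVK
LTR flank a non-IAP ERVK inner).

**Coordinates.** 0-based half-open everywhere; RepeatMasker `.out` records
(1-based inclusive) are converted on read. Strand agreement between inner
and LTR is required: the merge is per-strand anyway, and a provirus's LTRs
are co-oriented with its body. Candidate full-length L1 elements are
reported by a strict length gate (> 6 kb).

## Repeat expression quantification (`ervkit.quant`)

Reads are filtered before counting, with *any-alignment* semantics (one
tainted alignment removes the whole read):

* **gene overlap** — any alignment block overlapping any gene body by ≥ 1 bp,
  strand-agnostic (the conservative reading, removing more reads);
* **splice sites** — any gapped (N-containing) alignment, or a single-block
  alignment strictly containing an annotated exon–intron boundary
  coordinate in its interior;
* **polyA** — polyA fraction above `polyA_max` (default 0.8), where the
  fraction is max(A content, T content) of the read so that reverse-strand
  tails are caught.

The three predicates are independent, so filter order cannot change the
result. A surviving read is assigned to group *g* iff the union of groups
overlapped by its alignments is exactly {*g*} and no alignment is
off-repeat; it then contributes exactly one count, regardless of how many
alignments or elements it touched. Assignment uses the raw annotation
(every element of a subfamily), not the assembled full-length catalog.
Normalization reports counts ×10⁶/denominator (library size, or reads
aligning to genes and repeats) plus a fraction-of-reads view; fold change
is the ratio of normalized values against the control, with zero-control
groups flagged undefined rather than pseudocounted. "Library size" is
taken as total aligned reads.

Alignments are read from SAM/BAM (pysam; all records of a multi-mapper,
with polyA content computed from the primary record's sequence) or from a
plain-TSV dialect (`read_id, chrom, blocks, polyA_frac`) that makes small
text fixtures explicit. Reference blocks are split only at N cigar
operations; deletions do not create spurious "spliced" blocks.

## RNA-FISH / IF quantification (`ervkit.imaging`)

**Foci.** Voxels at or above the threshold are labeled as 3D
26-connected components; components smaller than `min_voxels` (default 4)
are dropped; centroids are intensity-weighted and sub-pixel. The same
threshold should be used for image sets that will be compared.

**Average panels.** The panel side is `round(l / pixel_size)` forced odd so
a unique center pixel exists (l = 1.5 µm default). Each focus contributes
the patch at its nearest z-slice; a config flag can average a z-window
instead. Foci whose patch would cross the image border are skipped and
counted (`n_skipped`) because partial patches bias the mean. The null panel
draws centers uniformly from nucleus-mask voxels (interior-eroded so all
patches are complete) with an explicit seed. Panel averaging is linear in
the input image, a property the tests exploit.

**Radial profile.** Annular means on equal-width bins from r = 0 to l/2
(the center of the edge pixel); corner pixels beyond l/2 are excluded so
annuli are complete. Bin counts are limited to side/2; in validation
against a closed-form Gaussian, bin widths of ~1.4 px keep the discrete
pixel radii within each annulus representative of the bin center (1-px
bins make the first annulus degenerate — only the exact center pixel —
and bias the comparison).

**Colocalization statistics.** Spearman's r is computed pixelwise between
the FISH-centered FISH and IF panels (profile-wise comparison is available
by correlating the two radial profiles); constant panels yield NaN.
Per-nucleus Manders overlap is M_OC = Σ R'G'/√(Σ R'²·Σ G'²) on
threshold-masked intensities, with split coefficients M1, M2 also emitted;
Pearson uses all in-mask voxels. For nearest-cluster distances, "±4.5
slices" around a focus is realized as a 9-slice window (center ± 4) — a
fractional slice count cannot index discrete planes — maximum-projected,
thresholded, 8-connected-labeled with a minimum area, and the Euclidean
xy distance to the nearest intensity-weighted center of mass is reported
in nm; absence of any component is flagged, not silently zero. The
colocalized fraction is the share of non-flagged foci with distance below
the cutoff (200 nm default).

**Droplets.** The droplet channel is segmented by Otsu's threshold (or an
explicit one); per component of at least `min_area` pixels, the partition
ratio is mean client intensity inside over mean client intensity in the
non-droplet background.

Nuclear masks are accepted as images or derived from a nuclear-stain
channel by Otsu threshold plus hole filling.

## PALM metrics (`ervkit.palm`)

Localizations accumulated over the acquisition window (100 s) are
clustered in xy by DBSCAN with neighborhood radius 50 nm and a 10-point
minimum — declared defaults, since density-based clustering parameters for
this kind of data are a free choice, and exposed everywhere. Time is
ignored: cluster size is the total localization count in the window.
Derived metrics: distance from the MS2 site anchor to the nearest cluster
center (plus that cluster's size), and per-cell cluster counts and mean
sizes (mean flagged NaN for cluster-free cells). Core-point membership is
order-independent; planted-recovery tests operate in the regime where
border-point ambiguity is immaterial (inter-cluster spacing ≫ radius).

## Synthetic data (`ervkit.simulate`)

Each generator is a pure function of (seed, parameters); the global seed is
expanded into fixed per-generator substreams so adding one generator never
perturbs another's output, and all emitted files are byte-reproducible.

* **Annotations** plant full/half/solo structures with ≥ 1 kb spacing
  (inner parts 1.2–1.8 kb, LTRs 350 bp, gaps and flank distances drawn
  inside the legal ranges); `boundary_cases` adds four constructs sitting
  exactly at gap 200/201 and distance 50/51 with their known outcomes.
* **Reads** are placed entirely inside elements of one group (a 30% share
  get 1–2 extra same-group alignments, emitted as SAM secondaries);
  contaminants each trip exactly one filter (exonic, gapped-intergenic,
  polyA-rich intergenic), and "ambiguous" reads align to two groups so
  they survive filtering but stay unassigned. Counts are therefore
  recovered *exactly* — the filters are deterministic — and stochasticity
  enters only if the planted counts themselves are drawn (as the
  fold-change validation does, Poisson per group at 50,000 reads/sample).
* **Image stacks** (default 15×448×448 voxels, 65 nm pixels, 300 nm steps)
  place 3D Gaussian spots (σ_xy 100 nm — a diffraction-limited PSF
  convolved with the finite extent of a nascent-RNA focus — σ_z 300 nm,
  peak 10× the background of 100 counts) inside an elliptical nucleus mask
  with enough margin for complete panels; a configured fraction of IF
  spots sits at a controlled offset from its FISH partner and the rest are
  uniform in the nucleus; Gaussian noise of sd 10 (shot noise at
  background level) is added. The field size keeps the chance rate of a
  *random* IF punctum within 200 nm of a focus at a few percent, which is
  the floor visible in the recovered fraction for planted fraction 0.
* **PALM** patterns scatter Gaussian clusters (default three of 200 points,
  σ 30 nm, 1 µm apart) over a uniform background (1 point/µm², far below
  the DBSCAN density threshold of min_points/(π·radius²)).
* **Droplets** are uniform disks with exact planted partition ratios.

What the generators do *not* emulate: real sequence content and aligner
error, nucleus morphology and structured nuclear background, optical
aberrations and depth-dependent PSFs, photophysics (blinking,
photoconversion) and localization drift. Passing tests therefore
demonstrate that the computations implement their rules correctly and
recover planted truth under controlled conditions — not that those rules
are robust to every artifact of real data.

## Problem sizes and validation design

Validation runs use desk-scale inputs chosen to make the statistical
assertions meaningful: 50 random annotations of 300 features for exhaustive
O(n²)-oracle comparison, 50,000 reads per sample for fold-change recovery
(asserted within 3 Poisson standard deviations), 20 stacks of 200 foci for
colocalization recovery (fractions asserted within ±0.05 of the planted
value, Spearman ≥ 0.9 at full colocalization and |r| ≤ 0.2 for independent
channels), and single-construct stacks for sub-pixel assertions (centroid
within 0.5 px; a planted 300 nm offset within one 65 nm pixel). The
acceptance script reports the same quantities from freshly generated data
at a user-supplied seed.

## Known limitations

* The assembly resolves LTR contention greedily (nearest inner first);
  a provirus nested inside another element can in principle claim an LTR
  that a globally optimal matching would assign differently.
* DBSCAN border points can attach to either adjacent cluster when two
  clusters nearly touch; cluster *counts* are unaffected.
* Spearman on panels is sensitive to the fraction of structure-free
  background pixels: with very small spots or very high camera noise the
  flat tail of the panel dilutes the correlation even at full
  colocalization.
* The TSV alignment dialect carries polyA fractions verbatim, while the
  SAM path recomputes them from the primary sequence; synthetic SAM
  sequences are constructed so both agree, but real SAM input with omitted
  primary sequences falls back to polyA 0.
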