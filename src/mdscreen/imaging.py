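"""Per-cell quantification of two-channel high-content fields.

The DNA channel (PicoGreen-like) carries both nuclei and mtDNA nucleoid
puncta; the two object classes are separated purely by size, as in
high-content protocols for live fibroblasts.  The membrane-potential
channel (TMRM/CMXRos-like) traces the polarised mitochondrial reticulum.

The module segments nuclei, partitions the field into per-nucleus cell
territories, detects nucleoid puncta, skeletonises the mitochondrial
network, and emits one :class:`CellRecord` row per cell with the
integrated-density metrics used by the screen statistics:

* nucleoid count and summed punctum area (µm²),
* nucleoid / nuclear / mitochondrial integrated density
  (object area × mean background-subtracted intensity, AU·µm²),
* summed reticulum length (µm),
* Rho-0 flag (cell void of detectable mtDNA) and ploidy class
  (G1 vs S/G2 by nuclear DNA content).

All thresholds are relative (Otsu, MAD multiples), so segmentation is
invariant to global multiplicative intensity rescaling and every
integrated density is homogeneous of degree one in the
background-subtracted image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.stats import gaussian_kde
from skimage.feature import peak_local_max
from skimage.filters import gaussian as sk_gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import dilation, disk, skeletonize
from skimage.segmentation import clear_border, watershed

logger = logging.getLogger("mdscreen")

G1 = "G1"
S_G2 = "S_G2"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FieldImage:
    """One imaged field: two intensity rasters plus acquisition metadata.

    Parameters
    ----------
    dna : ndarray
        DNA-dye channel (nuclei + nucleoid puncta), arbitrary units.
    mmp : ndarray
        Membrane-potential-dye channel, arbitrary units.
    pixel_size : float
        Lateral pixel size in µm/pixel.
    """

    dna: np.ndarray
    mmp: np.ndarray
    pixel_size: float
    well_id: str = ""
    field_index: int = 0
    run_id: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.dna = np.asarray(self.dna, dtype=float)
        self.mmp = np.asarray(self.mmp, dtype=float)
        if self.dna.shape != self.mmp.shape:
            raise ValueError(
                f"channel shapes differ: {self.dna.shape} vs {self.mmp.shape}"
            )
        if self.dna.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dna.shape

    def to_tiff(self, path) -> None:
        """Write as a two-page 16-bit TIFF (page 1 = DNA, page 2 = MMP)."""
        stack = np.stack([self.dna, self.mmp])
        stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
        tifffile.imwrite(
            path,
            stack,
            metadata={
                "pixel_size_um": self.pixel_size,
                "well_id": self.well_id,
                "field_index": self.field_index,
                "run_id": self.run_id,
                "cell_line": self.cell_line,
            },
        )

    @classmethod
    def from_tiff(cls, path) -> "FieldImage":
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if stack.ndim != 3 or stack.shape[0] != 2:
            raise ValueError(f"{path}: expected a two-page TIFF")
        return cls(
            dna=stack[0].astype(float),
            mmp=stack[1].astype(float),
            pixel_size=float(meta.get("pixel_size_um", 1.0)),
            well_id=str(meta.get("well_id", "")),
            field_index=int(meta.get("field_index", 0)),
            run_id=str(meta.get("run_id", "")),
            cell_line=str(meta.get("cell_line", "")),
        )


@dataclass
class QuantParams:
    """Tunable segmentation and classification parameters.

    Size cut-offs implement segmentation-on-size: objects in the DNA
    channel at least ``nucleus_min_area_um2`` are nuclei, punctate
    band-pass maxima of at most ``nucleoid_max_area_um2`` are nucleoids.
    """

    nucleus_smooth_sigma_px: float = 3.0   # washes out puncta before Otsu
    nucleus_min_area_um2: float = 30.0
    puncta_sigma_um: float = 0.5          # expected spot width (PSF-scale)
    puncta_threshold_k: float = 5.0       # MAD multiples above DoG median
    nucleoid_max_area_um2: float = 2.0
    nucleus_exclusion_dilation_px: int = 2
    mito_threshold_k: float = 4.0         # MAD multiples above MMP background
    rho0_max_count: int = 2
    rho0_max_area_um2: float = 3.0    # ~2 spurious diffraction-limited spots
    ploidy_threshold_factor: float = 1.5  # × G1 mode of nuclear DNA content
    shapiro_alpha: float = 0.05


@dataclass
class SegmentationResult:
    """Label rasters produced by the segmentation stages."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    nucleoid_labels: np.ndarray
    mito_mask: np.ndarray
    reticulum_length_um: dict = dc_field(default_factory=dict)
    background_dna: float = 0.0
    background_mmp: float = 0.0


CELL_RECORD_COLUMNS = [
    "cell_id",
    "nucleoid_count",
    "puncta_summed_area",
    "puncta_integrated_density",
    "nuclear_integrated_density",
    "mmp_integrated_density",
    "reticulum_length",
    "is_rho0",
    "ploidy_class",
    "well_id",
    "field_index",
    "run_id",
    "cell_line",
]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(field: FieldImage, params: QuantParams | None = None) -> np.ndarray:
    """Segment nuclei in the DNA channel by size.

    The channel is Gaussian-smoothed, thresholded with Otsu's relative
    criterion, and connected components smaller than
    ``nucleus_min_area_um2`` are dropped (they are left for nucleoid
    detection).  Nuclei touching the field border are removed so that
    partially imaged cells never enter the statistics.
    """
    params = params or QuantParams()
    img = field.dna
    if img.size == 0:
        raise ValueError("empty DNA channel")
    smoothed = sk_gaussian(img, sigma=params.nucleus_smooth_sigma_px,
                           preserve_range=True)
    if smoothed.max() <= smoothed.min():
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    labels = sk_label(mask)
    min_area_px = params.nucleus_min_area_um2 / field.pixel_size**2
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area_px)
    mask &= ~np.isin(labels, small)
    mask = clear_border(mask)
    labels, _ = ndi.label(mask)
    return labels.astype(np.int32)


def assign_cell_territories(nucleus_labels: np.ndarray,
                            field: FieldImage | None = None) -> np.ndarray:
    """Partition the field into one territory per nucleus.

    Nearest-nucleus growth: every pixel joins the territory of the
    nucleus with the closest centroid (Euclidean distance transform
    from centroid seeds), so two symmetric nuclei split the field along
    their perpendicular bisector regardless of nuclear size.
    Deterministic and parameter-free; with no nuclei the whole raster
    is unassigned (0).
    """
    if nucleus_labels.max() == 0:
        return np.zeros_like(nucleus_labels, dtype=np.int32)
    n = int(nucleus_labels.max())
    seeds = np.zeros_like(nucleus_labels, dtype=np.int32)
    for lab, (r, c) in zip(range(1, n + 1),
                           ndi.center_of_mass(nucleus_labels > 0,
                                              nucleus_labels,
                                              range(1, n + 1))):
        seeds[int(round(r)), int(round(c))] = lab
    _, (ri, ci) = ndi.distance_transform_edt(seeds == 0,
                                             return_indices=True)
    return seeds[ri, ci].astype(np.int32)


def _robust_scale(values: np.ndarray) -> float:
    mad = np.median(np.abs(values - np.median(values)))
    return 1.4826 * float(mad)


def detect_nucleoids(field: FieldImage, nucleus_labels: np.ndarray,
                     params: QuantParams | None = None) -> np.ndarray:
    """Detect punctate mtDNA nucleoids in the DNA channel.

    A difference-of-Gaussians band-pass tuned to ``puncta_sigma_um``
    suppresses both background and the smooth nuclear signal; pixels
    exceeding ``puncta_threshold_k`` robust standard deviations above
    the band-pass median are candidate puncta.  Local maxima seed a
    watershed so that spots separated by more than roughly one spot
    width are counted individually; closer pairs merge (the documented
    resolution limit).  Candidates overlapping the (slightly dilated)
    nuclear footprint or exceeding ``nucleoid_max_area_um2`` are
    rejected.
    """
    params = params or QuantParams()
    img = field.dna
    sigma_px = max(params.puncta_sigma_um / field.pixel_size, 0.5)
    dog = (sk_gaussian(img, sigma=sigma_px, preserve_range=True)
           - sk_gaussian(img, sigma=2.0 * sigma_px, preserve_range=True))
    scale = _robust_scale(dog.ravel())
    if scale == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thr = float(np.median(dog)) + params.puncta_threshold_k * scale
    mask = dog > thr
    if nucleus_labels.max() > 0:
        nuc = dilation(nucleus_labels > 0,
                       disk(params.nucleus_exclusion_dilation_px))
        mask &= ~nuc
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    # seed from a slightly sharper band-pass: the matched filter decides
    # what is a punctum, the sharper scale splits close pairs down to
    # ~2 spot widths instead of ~3
    dog_seed = (sk_gaussian(img, sigma=0.7 * sigma_px, preserve_range=True)
                - sk_gaussian(img, sigma=1.4 * sigma_px, preserve_range=True))
    seed_thr = (float(np.median(dog_seed))
                + params.puncta_threshold_k * _robust_scale(dog_seed.ravel()))
    peaks = peak_local_max(
        dog_seed,
        min_distance=1,
        threshold_abs=seed_thr,
        exclude_border=False,
    )
    seeds = np.zeros(img.shape, dtype=np.int32)
    keep = mask[peaks[:, 0], peaks[:, 1]]
    peaks = peaks[keep]
    seeds[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dog, seeds, mask=mask).astype(np.int32)
    # reject extended (non-punctate) objects by their core footprint
    # (pixels above 70 % of the object peak).  The core area is
    # brightness-independent, and the 70 % level is calibrated so that
    # an unresolved pair of diffraction-limited spots — which merges
    # into a single object below the resolution limit — still passes
    # the size gate and is counted as one punctum.
    max_area_px = params.nucleoid_max_area_um2 / field.pixel_size**2
    big = []
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        vals = dog[sl][labels[sl] == lab]
        core_area = int((vals >= 0.7 * vals.max()).sum())
        if core_area > max_area_px:
            big.append(lab)
    if big:
        labels[np.isin(labels, big)] = 0
    return labels


def segment_mito_network(field: FieldImage, cell_labels: np.ndarray,
                         params: QuantParams | None = None
                         ) -> tuple[np.ndarray, dict]:
    """Threshold and skeletonise the membrane-potential channel.

    Returns the binary mitochondrial mask and the summed skeleton
    length (µm) per cell territory.  The threshold is the field median
    plus ``mito_threshold_k`` robust standard deviations, so the mask
    is invariant to multiplicative intensity rescaling up to the
    additive background.
    """
    params = params or QuantParams()
    img = field.mmp
    bg = float(np.median(img))
    scale = _robust_scale(img.ravel())
    # a zero MAD means a noise-free background: anything above it is signal
    mask = img > bg + params.mito_threshold_k * scale
    skel = skeletonize(mask) if mask.any() else mask
    lengths: dict[int, float] = {}
    for lab in range(1, int(cell_labels.max()) + 1):
        lengths[lab] = _skeleton_length_px(skel & (cell_labels == lab)) \
            * field.pixel_size
    return mask, lengths


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Polyline length of a skeleton: half the summed link lengths.

    Each 4-neighbour link contributes 1 px, each diagonal link √2 px;
    every link is seen from both ends, hence the factor ½.
    """
    if not skel.any():
        return 0.0
    s = skel.astype(np.int8)
    ortho = (s[:-1, :] & s[1:, :]).sum() + (s[:, :-1] & s[:, 1:]).sum()
    diag = (s[:-1, :-1] & s[1:, 1:]).sum() + (s[:-1, 1:] & s[1:, :-1]).sum()
    return float(ortho + np.sqrt(2.0) * diag)


# ---------------------------------------------------------------------------
# per-cell metrics
# ---------------------------------------------------------------------------

def segment_field(field: FieldImage,
                  params: QuantParams | None = None) -> SegmentationResult:
    """Run all segmentation stages on one field."""
    params = params or QuantParams()
    nuclei = segment_nuclei(field, params)
    cells = assign_cell_territories(nuclei, field)
    nucleoids = detect_nucleoids(field, nuclei, params)
    mito_mask, lengths = segment_mito_network(field, cells, params)
    obj_dna = (nuclei > 0) | (nucleoids > 0)
    bg_dna = float(np.median(field.dna[~obj_dna])) if (~obj_dna).any() else 0.0
    bg_mmp = float(np.median(field.mmp[~mito_mask])) if (~mito_mask).any() else 0.0
    return SegmentationResult(
        nucleus_labels=nuclei,
        cell_labels=cells,
        nucleoid_labels=nucleoids,
        mito_mask=mito_mask,
        reticulum_length_um=lengths,
        background_dna=bg_dna,
        background_mmp=bg_mmp,
    )


def _punctum_area_and_density(img: np.ndarray, region: np.ndarray,
                              bg: float, pixel_size: float
                              ) -> tuple[float, float]:
    """Half-max footprint area (µm²) and integrated density of one punctum.

    The footprint is the set of pixels, within the punctum's watershed
    support, whose background-subtracted intensity exceeds half the
    punctum peak — an adaptive per-spot level that makes the area
    estimate independent of spot brightness.
    """
    vals = img[region] - bg
    peak = float(vals.max())
    if peak <= 0:
        return 0.0, 0.0
    above = vals >= 0.5 * peak
    area = float(above.sum()) * pixel_size**2
    mean_excess = float(vals[above].mean())
    return area, area * mean_excess


def compute_cell_records(seg: SegmentationResult, field: FieldImage,
                         params: QuantParams | None = None) -> pd.DataFrame:
    """Assemble one metrics row per cell.

    Integrated densities follow the high-content convention: object
    area (µm²) × mean object intensity above the field background,
    summed over the object class belonging to the cell.  The
    background is the per-channel median outside all detected objects.
    """
    params = params or QuantParams()
    ps2 = field.pixel_size**2
    n_cells = int(seg.nucleus_labels.max())

    # one pass over puncta: measure each and assign it to the territory
    # holding most of its pixels (ties break towards the lower cell id,
    # deterministically), so every punctum is counted exactly once
    per_cell = {cid: {"count": 0, "area": 0.0, "density": 0.0}
                for cid in range(1, n_cells + 1)}
    for lab, sl in enumerate(ndi.find_objects(seg.nucleoid_labels), start=1):
        if sl is None:
            continue
        region_local = seg.nucleoid_labels[sl] == lab
        owners = seg.cell_labels[sl][region_local]
        owner = int(np.bincount(owners, minlength=n_cells + 1)[1:].argmax()) + 1
        if owner not in per_cell or (owners == owner).sum() == 0:
            continue
        area, dens = _punctum_area_and_density(
            field.dna[sl], region_local, seg.background_dna,
            field.pixel_size)
        per_cell[owner]["count"] += 1
        per_cell[owner]["area"] += area
        per_cell[owner]["density"] += dens

    rows = []
    for cid in range(1, n_cells + 1):
        territory = seg.cell_labels == cid
        if not territory.any():
            logger.warning("cell %d has no territory pixels; excluded", cid)
            continue
        nuc = seg.nucleus_labels == cid
        nuc_vals = field.dna[nuc] - seg.background_dna
        nuclear_id = float(np.clip(nuc_vals, 0, None).sum()) * ps2

        count = per_cell[cid]["count"]
        summed_area = per_cell[cid]["area"]
        puncta_id = per_cell[cid]["density"]

        mito = seg.mito_mask & territory
        mmp_vals = field.mmp[mito] - seg.background_mmp
        mmp_id = float(np.clip(mmp_vals, 0, None).sum()) * ps2

        rows.append({
            "cell_id": cid,
            "nucleoid_count": count,
            "puncta_summed_area": summed_area,
            "puncta_integrated_density": puncta_id,
            "nuclear_integrated_density": nuclear_id,
            "mmp_integrated_density": mmp_id,
            "reticulum_length": seg.reticulum_length_um.get(cid, 0.0),
            "is_rho0": False,
            "ploidy_class": G1,
            "well_id": field.well_id,
            "field_index": field.field_index,
            "run_id": field.run_id,
            "cell_line": field.cell_line,
        })
    return pd.DataFrame(rows, columns=CELL_RECORD_COLUMNS)


def classify_rho0(records: pd.DataFrame,
                  params: QuantParams | None = None) -> pd.DataFrame:
    """Flag cells void of detectable mtDNA (Rho-0).

    A cell is Rho-0 when its nucleoid count is at most ``rho0_max_count``
    AND its summed punctum area is at most ``rho0_max_area_um2``; the
    area guard tolerates rare sub-resolution false spots.
    """
    params = params or QuantParams()
    records = records.copy()
    records["is_rho0"] = (
        (records["nucleoid_count"] <= params.rho0_max_count)
        & (records["puncta_summed_area"] <= params.rho0_max_area_um2)
    )
    return records


def classify_ploidy(records: pd.DataFrame,
                    params: QuantParams | None = None) -> pd.DataFrame:
    """Assign G1 vs S/G2 by nuclear DNA content.

    The G1 mode of nuclear integrated density is located with a kernel
    density estimate; cells above ``ploidy_threshold_factor`` × the mode
    are called S/G2 (nuclear DNA content near 2× the G1 mode).  Fewer
    than 10 cells is degenerate: all cells are called G1 with a warning.
    """
    params = params or QuantParams()
    records = records.copy()
    vals = records["nuclear_integrated_density"].to_numpy(float)
    if len(vals) < 10 or np.ptp(vals) == 0:
        if len(vals) < 10:
            warnings.warn("fewer than 10 cells: ploidy classification "
                          "degenerate, all cells called G1", stacklevel=2)
        records["ploidy_class"] = G1
        return records
    kde = gaussian_kde(vals)
    grid = np.linspace(vals.min(), vals.max(), 512)
    g1_mode = float(grid[np.argmax(kde(grid))])
    thr = params.ploidy_threshold_factor * g1_mode
    records["ploidy_class"] = np.where(vals > thr, S_G2, G1)
    return records


def quantify_field(field: FieldImage,
                   params: QuantParams | None = None,
                   classify: bool = True) -> pd.DataFrame:
    """Full per-field pipeline: segment, measure, classify."""
    params = params or QuantParams()
    seg = segment_field(field, params)
    records = compute_cell_records(seg, field, params)
    if classify and len(records):
        records = classify_rho0(records, params)
        records = classify_ploidy(records, params)
    return records


def quantify_fields(fields, params: QuantParams | None = None,
                    ploidy_per_culture: bool = True) -> pd.DataFrame:
    """Quantify many fields; ploidy is classified per culture (cell line).

    The per-culture grouping matters because absolute nuclear
    integrated density varies between cultures and runs, while the
    G1/S-G2 ratio is internal to each.
    """
    params = params or QuantParams()
    frames = [quantify_field(f, params, classify=False) for f in fields]
    records = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=CELL_RECORD_COLUMNS)
    if not len(records):
        return records
    records = classify_rho0(records, params)
    if ploidy_per_culture and records["cell_line"].nunique() > 1:
        parts = [classify_ploidy(g, params)
                 for _, g in records.groupby("cell_line", sort=False)]
        records = pd.concat(parts, ignore_index=True)
    else:
        records = classify_ploidy(records, params)
    return records
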