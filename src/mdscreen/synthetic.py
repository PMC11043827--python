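"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the data-generating process of a high-content
nucleoside-supplementation screen in primary fibroblasts:

* two-channel fields of mononucleated cells — Gaussian-profile nuclei
  and point-like mtDNA nucleoid puncta in the DNA channel, a
  filamentous mitochondrial reticulum in the membrane-potential
  channel — with additive Gaussian read noise;
* a configurable fraction of Rho-0 cells (zero nucleoids) and of S/G2
  cells (nuclear DNA content drawn from a mode at ~2× the G1 mode);
* plate screens in which supplement conditions act multiplicatively on
  nucleoid content, cell number and polarised mitochondrial mass, with
  log-normal run-level intercepts (differences within a run are more
  reproducible than between runs);
* exponential mtDNA depletion–recovery time courses read out as qPCR
  Ct pairs;
* heavy-isotope labelling tables in which a 10 %-heavy nucleoside
  supplement is diluted through finite endogenous pools.

Every generator is a pure function of its spec and seed: identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep
from scipy.ndimage import gaussian_filter

from .imaging import G1, S_G2, FieldImage
from .recovery import NUCLEOSIDES, IsotopeTable, QpcrMeasurement

# canonical nucleoside order used for subset labels (A, T, G, C)
NUCLEOSIDE_ORDER = ("A", "T", "G", "C")
DMSO = "DMSO"


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """One supplementation condition and its true multiplicative effects.

    The DMSO baseline is the condition with an empty supplement set; it
    must carry unit effects on all three readouts.
    """

    supplements: frozenset
    concentration: float        # µM
    serum: float = 10.0         # % dialysed FCS
    effect_mtdna: float = 1.0   # × nucleoid content
    effect_cells: float = 1.0   # × cell number
    effect_mmp: float = 1.0     # × polarised mitochondrial mass

    def __post_init__(self):
        object.__setattr__(self, "supplements", frozenset(self.supplements))
        bad = self.supplements - set(NUCLEOSIDE_ORDER)
        if bad:
            raise ValueError(f"unknown nucleosides: {sorted(bad)}")
        if self.is_baseline and not (
            self.effect_mtdna == self.effect_cells == self.effect_mmp == 1.0
        ):
            raise ValueError("DMSO baseline must have all effect factors = 1")

    @property
    def is_baseline(self) -> bool:
        return len(self.supplements) == 0

    @property
    def label(self) -> str:
        if self.is_baseline:
            return DMSO
        return "".join(n for n in NUCLEOSIDE_ORDER if n in self.supplements)


@dataclass(frozen=True)
class FieldSpec:
    """Geometry, intensity and noise parameters of one synthetic field.

    ``noise_sd`` is the additive Gaussian read noise; the puncta
    signal-to-noise ratio is ``puncta_intensity / noise_sd`` (default
    10).  Defaults emulate a 20× high-content acquisition of a
    quiescent fibroblast monolayer.
    """

    field_size: tuple = (512, 512)     # pixels (rows, cols)
    pixel_size: float = 0.5            # µm / pixel
    n_cells: int = 20
    rho0_fraction: float = 0.0
    nucleoid_count_mean: float = 50.0  # per-cell mean (placeholder, config)
    puncta_sigma: float = 0.5          # µm, spot PSF width
    nucleus_intensity_mean: float = 1500.0   # peak AU of a G1 nucleus
    puncta_intensity: float = 1000.0   # peak AU of one nucleoid spot
    background: float = 200.0          # AU
    noise_sd: float = 100.0            # AU
    s_phase_fraction: float = 0.0
    seed: int = 0
    # geometry details (not readouts; fixed realistic defaults)
    nucleus_area_mean: float = 170.0   # µm², lognormal mean
    nucleus_area_cv: float = 0.2
    min_separation: float = 22.0       # µm between nucleus centres
    mito_mass_mean: float = 8.0e5      # AU, total polarised mass per cell
    mito_mass_cv: float = 0.3
    mito_curves: tuple = (2, 6)        # curves per cell (inclusive range)

    def __post_init__(self):
        if not (0.0 <= self.rho0_fraction <= 1.0):
            raise ValueError("rho0_fraction must be in [0, 1]")
        if not (0.0 <= self.s_phase_fraction <= 1.0):
            raise ValueError("s_phase_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass(frozen=True)
class RecoverySpec:
    """Exponential mtDNA depletion–recovery course parameters.

    After ddC depletion the true relative copy number follows
    ``C(t) = C0 · (d + (1 − d)(1 − e^{−rt}))`` with depletion fraction
    ``d`` remaining at day 0 and rate ``r`` per day.
    """

    baseline_copies: float = 500.0        # copies per cell pre-depletion
    depletion_fraction: float = 0.5       # remaining at day 0 (~50 % post-ddC)
    recovery_rate_untreated: float = 0.08   # day⁻¹
    recovery_rate_treated: float = 0.33     # day⁻¹ (reaches baseline ~day 14)
    timepoints: tuple = (0.0, 7.0, 14.0, 21.0)
    ct_noise_sd: float = 0.05             # cycles
    replicates: int = 2
    ct_b2m: float = 24.0                  # reference Ct, fixed

    def __post_init__(self):
        if not (0.0 < self.depletion_fraction <= 1.0):
            raise ValueError("depletion_fraction must be in (0, 1]")
        if self.recovery_rate_untreated < 0 or self.recovery_rate_treated < 0:
            raise ValueError("recovery rates must be >= 0")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("negative timepoints not allowed")


@dataclass(frozen=True)
class PoolSpec:
    """Heavy-isotope label-dilution parameters.

    The supplement is ``heavy_fraction_supplement`` heavy-labelled
    (0.10 in the standard design); label entering new DNA is diluted by
    the endogenous pool of each nucleoside.
    """

    endogenous_pools: dict = dc_field(
        default_factory=lambda: {"dA": 4.0, "dC": 2.0, "dG": 1.2, "dT": 1.0})
    supplement_flux: dict = dc_field(
        default_factory=lambda: {n: 1.0 for n in NUCLEOSIDES})
    heavy_fraction_supplement: float = 0.10
    new_dna_fraction: float = 0.5
    measurement_cv: float = 0.1
    total_area: float = 1.0e6          # AU, arbitrary peak-area scale

    def __post_init__(self):
        if not (0.0 <= self.heavy_fraction_supplement <= 1.0):
            raise ValueError("heavy_fraction_supplement must be in [0, 1]")
        if any(p <= 0 for p in self.endogenous_pools.values()):
            raise ValueError("all endogenous pools must be > 0")
        if not (0.0 <= self.new_dna_fraction <= 1.0):
            raise ValueError("new_dna_fraction must be in [0, 1]")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be >= 0")


@dataclass
class CellGroundTruth:
    """Per-cell ground truth recorded during rendering."""

    cell_id: int
    nucleus_center: tuple           # (x, y) = (col, row) pixels
    nucleus_area: float             # µm²
    ploidy_class: str
    nucleoid_count: int
    nucleoid_positions: list        # [(x, y) pixels]
    mito_polarized_mass: float      # AU
    is_rho0: bool


# ---------------------------------------------------------------------------
# screen enumeration
# ---------------------------------------------------------------------------

def subset_label(subset) -> str:
    """Canonical label of a supplement subset (letters in A,T,G,C order)."""
    s = frozenset(subset)
    return "".join(n for n in NUCLEOSIDE_ORDER if n in s) or DMSO


def enumerate_supplement_conditions(nucleosides,
                                    concentrations,
                                    serum: float = 10.0,
                                    effects: dict | None = None
                                    ) -> list[ScreenSpec]:
    """All non-empty supplement subsets crossed with each concentration.

    One DMSO baseline per concentration context is prepended.  Ordering
    is canonical and deterministic: by concentration, then subset size,
    then alphabetical label.  ``effects`` optionally maps a subset
    label to ``(effect_mtdna, effect_cells, effect_mmp)``.

    The four-nucleoside, one-concentration case gives the standard 15
    conditions (A, T, G, C, AT, AG, AC, TG, TC, GC, ATG, ATC, AGC,
    TGC, ATGC) plus baseline.
    """
    nucleosides = sorted(set(nucleosides),
                         key=lambda n: NUCLEOSIDE_ORDER.index(n))
    if not nucleosides:
        raise ValueError("empty nucleoside set")
    bad = set(nucleosides) - set(NUCLEOSIDE_ORDER)
    if bad:
        raise ValueError(f"unknown nucleosides: {sorted(bad)}")
    effects = effects or {}

    subsets = []
    for k in range(1, len(nucleosides) + 1):
        subsets.extend(frozenset(c)
                       for c in itertools.combinations(nucleosides, k))
    subsets.sort(key=lambda s: (len(s), sorted(subset_label(s))))

    out: list[ScreenSpec] = []
    for conc in sorted(concentrations):
        out.append(ScreenSpec(frozenset(), concentration=conc, serum=serum))
        for s in subsets:
            e = effects.get(subset_label(s), (1.0, 1.0, 1.0))
            out.append(ScreenSpec(s, concentration=conc, serum=serum,
                                  effect_mtdna=e[0], effect_cells=e[1],
                                  effect_mmp=e[2]))
    return out


# ---------------------------------------------------------------------------
# field rendering
# ---------------------------------------------------------------------------

def _add_gaussian(img: np.ndarray, row: float, col: float,
                  sigma: float, amplitude: float) -> None:
    """Accumulate an isotropic Gaussian of given peak amplitude in place."""
    h, w = img.shape
    half = max(2, int(math.ceil(4.0 * sigma)))
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    img[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def _place_centers(spec: FieldSpec, rng: np.random.Generator,
                   n_cells: int, margin_px: float) -> np.ndarray:
    """Seeded random centres with minimum separation (rejection sampling)."""
    h, w = spec.field_size
    min_sep_px = spec.min_separation / spec.pixel_size
    usable = max(h - 2 * margin_px, 0) * max(w - 2 * margin_px, 0)
    # each centre excludes a disc of radius min_sep/2
    if n_cells * math.pi * (min_sep_px / 2.0) ** 2 > 0.75 * usable:
        raise ValueError(
            f"field {spec.field_size} too small for {n_cells} cells at "
            f"min_separation {spec.min_separation} µm")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 500 * max(n_cells, 1):
            raise ValueError("could not place all cells; field too crowded")
        r = rng.uniform(margin_px, h - margin_px)
        c = rng.uniform(margin_px, w - margin_px)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep_px**2
               for rr, cc in centers):
            centers.append((r, c))
    return np.array(centers).reshape(n_cells, 2)


def _truncated_poisson_ge1(rng: np.random.Generator, mean: float) -> int:
    """Poisson draw conditioned on being >= 1 (non-Rho-0 cells carry mtDNA)."""
    for _ in range(1000):
        k = int(rng.poisson(mean))
        if k >= 1:
            return k
    return 1


def _render_reticulum(spec: FieldSpec, rng: np.random.Generator,
                      center: np.ndarray, radius_px: float,
                      mass: float, shape: tuple) -> np.ndarray:
    """Smooth random curves around a cell centre, normalised to ``mass``.

    2–6 cubic splines through short random walks emulate a filamentous
    mitochondrial reticulum; the per-cell image is smoothed and scaled
    so its summed intensity equals the cell's polarised mass exactly.
    """
    lo, hi = spec.mito_curves
    n_curves = int(rng.integers(lo, hi + 1))
    canvas = np.zeros(shape)
    h, w = shape
    for _ in range(n_curves):
        n_ctrl = 5
        start = center + rng.uniform(-0.4, 0.4, size=2) * radius_px
        steps = rng.normal(0.0, radius_px * 0.35, size=(n_ctrl - 1, 2))
        pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
        # keep control points inside the cell's disc
        d = pts - center
        r = np.hypot(d[:, 0], d[:, 1])
        over = r > radius_px
        pts[over] = center + d[over] / r[over, None] * radius_px
        try:
            tck, _ = splprep([pts[:, 0], pts[:, 1]], s=radius_px, k=3)
        except Exception:
            continue
        u = np.linspace(0, 1, 200)
        ry, cx = splev(u, tck)
        ry = np.clip(np.round(ry).astype(int), 0, h - 1)
        cx = np.clip(np.round(cx).astype(int), 0, w - 1)
        np.add.at(canvas, (ry, cx), 1.0)
    canvas = gaussian_filter(canvas, sigma=1.2)
    total = canvas.sum()
    if total > 0:
        canvas *= mass / total
    return canvas


def render_field(spec: FieldSpec) -> tuple[FieldImage, list[CellGroundTruth]]:
    """Render one two-channel field and its per-cell ground truth.

    Channel 1: Gaussian-profile nuclei plus isotropic nucleoid spots of
    width ``puncta_sigma``; channel 2: per-cell filamentous reticulum
    whose total intensity equals the cell's polarised mass before
    noise.  Additive Gaussian read noise of sd ``noise_sd`` is applied
    to both channels.  Identical spec (including seed) gives
    bit-identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    ch1 = np.full((h, w), float(spec.background))
    ch2 = np.full((h, w), float(spec.background))
    truth: list[CellGroundTruth] = []

    if spec.n_cells > 0:
        # margin keeps nuclei off the border so no cell is excluded downstream
        r_nuc_mean = math.sqrt(spec.nucleus_area_mean / math.pi) / spec.pixel_size
        margin = 1.8 * r_nuc_mean + 4.0
        centers = _place_centers(spec, rng, spec.n_cells, margin)

        sigma_ln = math.sqrt(math.log(1.0 + spec.nucleus_area_cv**2))
        mito_sigma_ln = math.sqrt(math.log(1.0 + spec.mito_mass_cv**2))

        for cid in range(spec.n_cells):
            row, col = centers[cid]
            area = spec.nucleus_area_mean * math.exp(
                rng.normal(-0.5 * sigma_ln**2, sigma_ln))
            r_nuc_px = math.sqrt(area / math.pi) / spec.pixel_size
            sigma_nuc = r_nuc_px / 1.5

            is_s = rng.random() < spec.s_phase_fraction
            # the ploidy readout is integrated density (total nuclear
            # intensity), so the 2x S/G2 mode acts on the blob total, not
            # the peak; jitter is clipped so S/G2 targets strictly exceed
            # every G1 target in the field
            jitter = float(np.clip(math.exp(rng.normal(0.0, 0.1)), 0.7, 1.4))
            ploidy_factor = 2.0 * max(jitter, 0.8) if is_s else jitter
            sigma_ref = (math.sqrt(spec.nucleus_area_mean / math.pi)
                         / spec.pixel_size / 1.5)
            total_ref = spec.nucleus_intensity_mean * 2.0 * math.pi * sigma_ref**2
            amp = total_ref * ploidy_factor / (2.0 * math.pi * sigma_nuc**2)
            _add_gaussian(ch1, row, col, sigma_nuc, amp)

            is_rho0 = rng.random() < spec.rho0_fraction
            count = 0 if is_rho0 else _truncated_poisson_ge1(
                rng, spec.nucleoid_count_mean)

            # nucleoids: uniform over this cell's Voronoi territory
            # (nearest-centre rule), outside the nuclear footprint
            d2 = ((centers[:, 0] - row) ** 2 + (centers[:, 1] - col) ** 2)
            d2[cid] = np.inf
            r_terr = 0.5 * math.sqrt(float(d2.min())) if spec.n_cells > 1 \
                else 0.45 * min(h, w)
            r_terr = max(r_terr, r_nuc_px * 1.6 + 4.0)
            r_excl = 1.3 * r_nuc_px + 2.0
            positions: list[tuple[float, float]] = []
            sigma_sp = spec.puncta_sigma / spec.pixel_size
            guard = 0
            while len(positions) < count and guard < 2000 * max(count, 1):
                guard += 1
                pr = rng.uniform(3.0, h - 3.0)
                pc = rng.uniform(3.0, w - 3.0)
                if (pr - row) ** 2 + (pc - col) ** 2 < r_excl**2:
                    continue
                # stay inside this cell's territory (nearest-centre rule)
                dd = (centers[:, 0] - pr) ** 2 + (centers[:, 1] - pc) ** 2
                if np.argmin(dd) != cid:
                    continue
                positions.append((pc, pr))  # (x, y)
                spot_amp = spec.puncta_intensity * math.exp(
                    rng.normal(0.0, 0.15))
                _add_gaussian(ch1, pr, pc, sigma_sp, spot_amp)
            count = len(positions)
            is_rho0 = count == 0

            mass = spec.mito_mass_mean * math.exp(
                rng.normal(-0.5 * mito_sigma_ln**2, mito_sigma_ln))
            ch2 += _render_reticulum(spec, rng, centers[cid],
                                     min(r_terr, 0.9 * r_terr), mass, (h, w))

            truth.append(CellGroundTruth(
                cell_id=cid + 1,
                nucleus_center=(float(col), float(row)),
                nucleus_area=float(area),
                ploidy_class=S_G2 if is_s else G1,
                nucleoid_count=count,
                nucleoid_positions=positions,
                mito_polarized_mass=float(mass),
                is_rho0=is_rho0,
            ))

    if spec.noise_sd > 0:
        ch1 += rng.normal(0.0, spec.noise_sd, size=(h, w))
        ch2 += rng.normal(0.0, spec.noise_sd, size=(h, w))

    image = FieldImage(dna=ch1, mmp=ch2, pixel_size=spec.pixel_size)
    return image, truth


def truth_to_frame(truth: list[CellGroundTruth], **meta) -> pd.DataFrame:
    """Flatten ground truth to one row per cell (positions dropped)."""
    rows = [{
        "cell_id": t.cell_id,
        "nucleus_area": t.nucleus_area,
        "ploidy_class": t.ploidy_class,
        "nucleoid_count": t.nucleoid_count,
        "mito_polarized_mass": t.mito_polarized_mass,
        "is_rho0": t.is_rho0,
        **meta,
    } for t in truth]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screen dataset
# ---------------------------------------------------------------------------

@dataclass
class ScreenDataset:
    """Rendered screen: fields, per-cell ground truth and the plate map."""

    fields: list
    truth: pd.DataFrame
    platemap: pd.DataFrame


def generate_screen_dataset(screen: list[ScreenSpec],
                            base: FieldSpec,
                            fields_per_well: int = 9,
                            runs: int = 2,
                            seed: int = 0,
                            run_sigma: float = 0.1,
                            cell_line: str = "CTRL1") -> ScreenDataset:
    """Render a plate screen with known condition and run effects.

    Each condition occupies one well per run with ``fields_per_well``
    fields (nine in the standard acquisition).  Condition effects act
    multiplicatively on the base spec; a log-normal run intercept of sd
    ``run_sigma`` (log scale) multiplies nucleoid content, so
    between-run differences exceed within-run ones.
    """
    if fields_per_well < 1:
        raise ValueError("fields_per_well must be >= 1")
    rng = np.random.default_rng(seed)
    run_intercepts = np.exp(rng.normal(0.0, run_sigma, size=runs)) \
        if run_sigma > 0 else np.ones(runs)

    fields: list[FieldImage] = []
    truth_frames: list[pd.DataFrame] = []
    plate_rows: list[dict] = []
    well_counter = 0
    for run in range(runs):
        run_id = f"run{run + 1}"
        for cond in screen:
            well_counter += 1
            well_id = f"W{well_counter:03d}"
            n_cells = max(0, int(round(base.n_cells * cond.effect_cells)))
            mean_eff = (base.nucleoid_count_mean * cond.effect_mtdna
                        * run_intercepts[run])
            plate_rows.append({
                "well_id": well_id,
                "cell_line": cell_line,
                "run": run_id,
                "serum": cond.serum,
                "supplements": cond.label,
                "concentration_um": cond.concentration,
                "day": 7,
                "treated": not cond.is_baseline,
            })
            for fi in range(fields_per_well):
                fseed = int(rng.integers(0, 2**31 - 1))
                fspec = replace(base,
                                n_cells=n_cells,
                                nucleoid_count_mean=mean_eff,
                                mito_mass_mean=base.mito_mass_mean
                                * cond.effect_mmp,
                                seed=fseed)
                img, truth = render_field(fspec)
                img.well_id = well_id
                img.field_index = fi
                img.run_id = run_id
                img.cell_line = cell_line
                fields.append(img)
                truth_frames.append(truth_to_frame(
                    truth, well_id=well_id, field_index=fi, run_id=run_id,
                    cell_line=cell_line, condition=cond.label,
                    concentration_um=cond.concentration, serum=cond.serum,
                    effect_mtdna=cond.effect_mtdna,
                    effect_cells=cond.effect_cells,
                    effect_mmp=cond.effect_mmp,
                    run_intercept=run_intercepts[run]))
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else \
        pd.DataFrame()
    return ScreenDataset(fields=fields, truth=truth,
                         platemap=pd.DataFrame(plate_rows))


# ---------------------------------------------------------------------------
# recovery courses
# ---------------------------------------------------------------------------

def true_copy_fraction(spec: RecoverySpec, t: float, treated: bool) -> float:
    """C(t)/C0 = d + (1 − d)(1 − e^{−rt})."""
    r = spec.recovery_rate_treated if treated else spec.recovery_rate_untreated
    d = spec.depletion_fraction
    return d + (1.0 - d) * (1.0 - math.exp(-r * t))


def rate_for_target(depletion_fraction: float, day: float,
                    target: float = 0.95) -> float:
    """Closed-form rate such that the course reaches ``target``·C0 at ``day``.

    The exponential approaches baseline asymptotically, so ``target``
    must lie strictly between the depletion fraction and 1.  The
    default of 0.95 encodes "reaches baseline" as recovery to within a
    5 % equivalence margin — roughly the 95 % CI half-width of a
    two-replicate day mean at the standard 0.05-cycle Ct noise.
    """
    d = depletion_fraction
    if not (d < target < 1.0):
        raise ValueError("target must satisfy depletion_fraction < target < 1")
    return -math.log(1.0 - (target - d) / (1.0 - d)) / day


def generate_recovery_course(spec: RecoverySpec, treated: bool,
                             seed: int = 0,
                             line: str = "CTRL",
                             include_reference: bool = True
                             ) -> list[QpcrMeasurement]:
    """Simulate qPCR Ct pairs along a depletion–recovery course.

    Copy numbers follow the exponential recovery model; Ct values are
    the exact inversion of the copy-number formula at 100 % efficiency
    (Ct noise added to the mtDNA Ct only, keeping the noise scale a
    single dial).  A pre-depletion reference sample is included so
    courses can be normalised to baseline.
    """
    rng = np.random.default_rng(seed)
    out: list[QpcrMeasurement] = []

    def ct_mt_for(copies: float) -> float:
        # copies per diploid genome = 2^(ct_b2m - ct_mt) * 2
        return spec.ct_b2m - math.log2(copies / 2.0)

    if include_reference:
        for rep in range(spec.replicates):
            noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 \
                else 0.0
            out.append(QpcrMeasurement(
                sample=f"{line}_ref_r{rep}", line=line, treated=treated,
                day=0.0, ct_mt=ct_mt_for(spec.baseline_copies) + noise,
                ct_b2m=spec.ct_b2m, replicate=rep, is_reference=True))
    for t in spec.timepoints:
        copies = spec.baseline_copies * true_copy_fraction(spec, t, treated)
        for rep in range(spec.replicates):
            noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 \
                else 0.0
            out.append(QpcrMeasurement(
                sample=f"{line}_d{t:g}_r{rep}", line=line, treated=treated,
                day=float(t), ct_mt=ct_mt_for(copies) + noise,
                ct_b2m=spec.ct_b2m, replicate=rep))
    return out


def generate_recovery_experiment(spec: RecoverySpec, seed: int = 0,
                                 line: str = "CTRL"
                                 ) -> tuple[list, list]:
    """Treated and untreated arms sharing one pre-depletion reference.

    Both arms of a depletion–recovery experiment derive from the same
    culture, so they are normalised to a single pre-depletion sample;
    the reference is carried in the untreated arm's measurement list.
    """
    untreated = generate_recovery_course(spec, treated=False, seed=seed,
                                         line=line, include_reference=True)
    treated = generate_recovery_course(spec, treated=True, seed=seed + 1,
                                       line=line, include_reference=False)
    return treated, untreated


# ---------------------------------------------------------------------------
# isotope tables
# ---------------------------------------------------------------------------

def true_specific_activity(spec: PoolSpec, nucleoside: str) -> float:
    """Label dilution: h · f / (f + p), scaled by the new-DNA fraction."""
    f = spec.supplement_flux[nucleoside]
    p = spec.endogenous_pools[nucleoside]
    if f + p <= 0:
        raise ValueError(f"zero total supply for {nucleoside}")
    frac_new = spec.heavy_fraction_supplement * f / (f + p)
    return frac_new * spec.new_dna_fraction


def generate_isotope_table(spec: PoolSpec, seed: int = 0) -> IsotopeTable:
    """Simulate heavy/light peak areas under label dilution.

    For each nucleoside the heavy fraction of newly synthesised DNA is
    ``h·f/(f+p)``; the observed specific activity is that fraction
    times the new-DNA fraction.  Peak areas carry log-normal
    measurement noise of CV ``measurement_cv`` (unit mean).  The true
    activities are recorded as ground truth.
    """
    rng = np.random.default_rng(seed)
    if spec.measurement_cv > 0:
        s = math.sqrt(math.log(1.0 + spec.measurement_cv**2))
    else:
        s = 0.0
    rows = []
    truth = {}
    for n in NUCLEOSIDES:
        sa = true_specific_activity(spec, n)
        truth[n] = sa
        e_h = math.exp(rng.normal(-0.5 * s**2, s)) if s > 0 else 1.0
        e_l = math.exp(rng.normal(-0.5 * s**2, s)) if s > 0 else 1.0
        rows.append({
            "nucleoside": n,
            "heavy_area": spec.total_area * sa * e_h,
            "light_area": spec.total_area * (1.0 - sa) * e_l,
        })
    return IsotopeTable(areas=pd.DataFrame(rows), truth=truth)
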