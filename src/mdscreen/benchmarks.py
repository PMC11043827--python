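"""Ground-truth recovery benchmarks for the whole pipeline.

Each function simulates data under known study conditions, runs the
corresponding analysis stage, and reports how well the known truth is
recovered.  They power the acceptance checks and are also useful for
re-validating the pipeline after parameter changes.

All randomness is controlled by an explicit seed; problem sizes are
chosen so a full sweep runs in a few minutes on one CPU.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imaging import (FieldImage, quantify_field, quantify_fields,
                      segment_field)
from .recovery import (NUCLEOSIDES, infer_pools, normalize_course,
                       specific_activity, treatment_effect_anova)
from .screen import compare_to_baseline, fit_group_effect, summarize_screen
from .synthetic import (FieldSpec, PoolSpec, RecoverySpec, ScreenSpec,
                        generate_isotope_table, generate_recovery_experiment,
                        generate_screen_dataset, rate_for_target,
                        render_field)


def match_cells_to_truth(seg, truth) -> dict:
    """Segmentation label -> truth index, by nearest nucleus centroid."""
    n = int(seg.nucleus_labels.max())
    cents = ndi.center_of_mass(seg.nucleus_labels > 0, seg.nucleus_labels,
                               range(1, n + 1))
    centers = [(t.nucleus_center[1], t.nucleus_center[0]) for t in truth]
    return {
        lab: int(np.argmin([(r - tr) ** 2 + (c - tc) ** 2
                            for tr, tc in centers]))
        for lab, (r, c) in enumerate(cents, start=1)
    }


def nucleoid_recovery(n_fields: int = 9, n_cells: int = 20,
                      count_mean: float = 40.0, seed: int = 0) -> dict:
    """Per-cell nucleoid-count recovery on standard SNR-10 fields."""
    truths, measured = [], []
    for i in range(n_fields):
        spec = FieldSpec(n_cells=n_cells, nucleoid_count_mean=count_mean,
                         seed=seed + i)
        image, truth = render_field(spec)
        seg = segment_field(image)
        rec = quantify_field(image)
        match = match_cells_to_truth(seg, truth)
        truths += [truth[match[cid]].nucleoid_count for cid in rec.cell_id]
        measured += rec.nucleoid_count.tolist()
    t = np.asarray(truths, float)
    m = np.asarray(measured, float)
    return {
        "mean_rel_err_pct": float(100.0 * np.mean(np.abs(m - t) / t)),
        "correlation": float(np.corrcoef(t, m)[0, 1]),
        "bias_pct": float(100.0 * (m.mean() - t.mean()) / t.mean()),
        "n_cells": int(len(t)),
    }


def rho0_recovery(fraction: float, n_cells_total: int = 500,
                  seed: int = 0) -> dict:
    """Recovered Rho-0 proportion for a culture of known composition."""
    per_field = 20
    n_fields = int(np.ceil(n_cells_total / per_field))
    fields, flags = [], []
    for i in range(n_fields):
        spec = FieldSpec(n_cells=per_field, nucleoid_count_mean=40.0,
                         rho0_fraction=fraction, seed=seed + i)
        image, truth = render_field(spec)
        fields.append(image)
        flags += [t.is_rho0 for t in truth]
    rec = quantify_fields(fields)
    return {
        "true_fraction": float(np.mean(flags)),
        "estimated_fraction": float(rec.is_rho0.mean()),
        "n_cells": int(len(rec)),
    }


def intensity_linearity(k: float = 2.0, seed: int = 42) -> dict:
    """Maximum relative deviation from exact ×k scaling (noise-free)."""
    spec = FieldSpec(n_cells=10, nucleoid_count_mean=30, seed=seed,
                     noise_sd=0)
    image, _ = render_field(spec)
    r1 = quantify_field(image, classify=False)
    scaled = FieldImage(dna=image.dna * k, mmp=image.mmp * k,
                        pixel_size=image.pixel_size)
    r2 = quantify_field(scaled, classify=False)
    dev = 0.0
    for col in ("nuclear_integrated_density", "puncta_integrated_density",
                "mmp_integrated_density"):
        a = r1[col].to_numpy()
        b = r2[col].to_numpy()
        dev = max(dev, float(np.max(np.abs(b - k * a) / np.abs(k * a))))
    return {"max_rel_deviation": dev, "n_cells": int(len(r1))}


def effect_recovery(n_screens: int = 20, seed: int = 0,
                    effect_mtdna: float = 2.0,
                    effect_cells: float = 0.5) -> dict:
    """End-to-end recovery of multiplicative screen effects vs DMSO."""
    pct_mtdna, pct_cells, dlog = [], [], []
    for s in range(n_screens):
        conds = [ScreenSpec(frozenset(), 200.0),
                 ScreenSpec(frozenset("ATGC"), 200.0,
                            effect_mtdna=effect_mtdna,
                            effect_cells=effect_cells)]
        base = FieldSpec(n_cells=12, nucleoid_count_mean=40.0, seed=0)
        ds = generate_screen_dataset(conds, base, fields_per_well=4,
                                     runs=1, seed=seed + s, run_sigma=0.1)
        cells = quantify_fields(ds.fields)
        meta = ds.platemap.set_index("well_id")
        for col, src in (("condition", "supplements"),
                         ("concentration_um", "concentration_um"),
                         ("serum", "serum")):
            cells[col] = cells["well_id"].map(meta[src])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = summarize_screen(cells)
        pct_mtdna.append(float(summary.pct_change_mtdna.iloc[0]))
        pct_cells.append(float(summary.pct_change_cells.iloc[0]))
        base_cells = cells[cells.condition == "DMSO"]
        treated = cells[cells.condition == "ATGC"]
        dlog.append(float(
            np.log10(treated.loc[treated.puncta_summed_area > 0,
                                 "puncta_summed_area"]).mean()
            - np.log10(base_cells.loc[base_cells.puncta_summed_area > 0,
                                      "puncta_summed_area"]).mean()))
    return {
        "pct_change_mtdna": float(np.mean(pct_mtdna)),
        "pct_change_cells": float(np.mean(pct_cells)),
        "log10_area_difference": float(np.mean(dlog)),
        "n_screens": n_screens,
    }


def gated_test_null_calibration(n_sims: int = 3000, n: int = 50,
                                seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the normality-gated two-sample test."""
    rng = np.random.default_rng(seed)
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sims):
            _, p = compare_to_baseline(rng.normal(0, 1, n),
                                       rng.normal(0, 1, n))
            rejections += p < alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}


def lmm_null_calibration(n_sims: int = 100, seed: int = 0,
                         alpha: float = 0.05) -> dict:
    """Type-I error of the mixed-model treatment test under the
    generator null (no effect, log-normal run intercepts)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        rows = []
        for run in range(3):
            intercept = rng.normal(0.0, 0.1)
            for arm in (0, 1):
                vals = rng.normal(1.0 + intercept, 0.2, 100)
                rows += [{"log10_area": v, "treatment": arm,
                          "run_id": f"r{run}", "cell_line": "L1"}
                         for v in vals]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_group_effect(pd.DataFrame(rows))
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}


def recovery_anova_power(n_sims: int = 100, seed: int = 0,
                         alpha: float = 0.01) -> dict:
    """Detection rate for the standard treated-vs-untreated course:
    treated reaches baseline (95 % equivalence) by day 14, untreated
    recovers at half that rate, Ct noise 0.05 cycles."""
    r = rate_for_target(0.5, 14.0, target=0.95)
    spec = RecoverySpec(recovery_rate_treated=r,
                        recovery_rate_untreated=r / 2, ct_noise_sd=0.05)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_sims):
            t, u = generate_recovery_experiment(spec, seed=seed + 2 * i)
            res = treatment_effect_anova(normalize_course(t, reference=u),
                                         normalize_course(u))
            hits += res["treatment_p"] < alpha
    return {"power": hits / n_sims, "n_sims": n_sims}


def recovery_anova_null(n_sims: int = 1000, seed: int = 0,
                        alpha: float = 0.05) -> dict:
    """Type-I error of the treatment ANOVA with equal recovery rates."""
    spec = RecoverySpec(recovery_rate_treated=0.1,
                        recovery_rate_untreated=0.1, ct_noise_sd=0.05)
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_sims):
            t, u = generate_recovery_experiment(spec, seed=seed + 2 * i)
            res = treatment_effect_anova(normalize_course(t, reference=u),
                                         normalize_course(u))
            rejections += res["treatment_p"] < alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}


def pool_ordering_sweep(seed: int = 0) -> dict:
    """Limiting-nucleoside calls over all 24 orderings of 4 pool sizes
    (noise-free) and over noisy replicates with a distinct smallest pool."""
    hits = 0
    for perm in itertools.permutations([1.0, 2.0, 3.0, 4.0]):
        pools = dict(zip(NUCLEOSIDES, perm))
        pat = generate_isotope_table(
            PoolSpec(endogenous_pools=pools, measurement_cv=0), seed=seed)
        ctrl = [generate_isotope_table(PoolSpec(measurement_cv=0),
                                       seed=seed + 1)]
        inf = infer_pools(pat, ctrl)
        hits += inf.limiting[0] == min(pools, key=pools.get)

    noisy_pools = {"dA": 4.0, "dC": 2.0, "dG": 2.0, "dT": 1.0}
    noisy_hits = 0
    n_rep = 400
    for i in range(n_rep):
        pat = generate_isotope_table(
            PoolSpec(endogenous_pools=noisy_pools, measurement_cv=0.1),
            seed=seed + 10 + i)
        ctrl = [generate_isotope_table(PoolSpec(measurement_cv=0.1),
                                       seed=seed + 5000 + 3 * i + j)
                for j in range(3)]
        inf = infer_pools(pat, ctrl)
        noisy_hits += inf.limiting[0] == "dT"

    example = PoolSpec(endogenous_pools={"dA": 9, "dC": 1, "dG": 1, "dT": 1},
                       new_dna_fraction=1.0, measurement_cv=0)
    sa = specific_activity(generate_isotope_table(example, seed=seed))
    by = dict(zip(sa.nucleoside, sa.specific_activity))
    return {
        "noise_free_hits": hits,
        "noise_free_total": 24,
        "noisy_accuracy": noisy_hits / n_rep,
        "example_activity_dA": float(by["dA"]),
        "example_activity_dT": float(by["dT"]),
    }
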