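"""Generator unit and property tests: enumeration, rendering, courses,
isotope tables — all against closed forms or the generator's own logs."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdscreen.recovery import NUCLEOSIDES, copy_number_from_ct, normalize_course
from mdscreen.synthetic import (FieldSpec, PoolSpec, RecoverySpec, ScreenSpec,
                                enumerate_supplement_conditions,
                                generate_isotope_table,
                                generate_recovery_course,
                                generate_screen_dataset, render_field,
                                rate_for_target, true_copy_fraction,
                                true_specific_activity)

FIFTEEN_COMBINATIONS = ["A", "T", "G", "C", "AT", "AC", "AG", "CT", "CG", "GT",
            "ATC", "ATG", "AGC", "TGC", "ATGC"]


class TestEnumeration:
    def test_four_nucleosides_give_fifteen_conditions_plus_baseline(self):
        conds = enumerate_supplement_conditions("ATGC", [200])
        non_base = [c for c in conds if not c.is_baseline]
        assert len(non_base) == 15
        assert sum(c.is_baseline for c in conds) == 1
        # the 15 subsets are exactly the non-empty subsets of {A,T,G,C}
        assert {c.supplements for c in non_base} == \
            {frozenset(s) for s in FIFTEEN_COMBINATIONS}

    def test_canonical_ordering_is_deterministic(self):
        a = enumerate_supplement_conditions("ATGC", [50, 200])
        b = enumerate_supplement_conditions("CGTA", [200, 50])
        assert [c.label for c in a] == [c.label for c in b]
        sizes = [len(c.supplements) for c in a if c.concentration == 50]
        assert sizes == sorted(sizes)

    def test_singleton_set(self):
        conds = enumerate_supplement_conditions({"T"}, [50])
        assert [c.label for c in conds] == ["DMSO", "T"]

    def test_three_nucleosides_two_concentrations(self):
        conds = enumerate_supplement_conditions({"A", "T", "G"}, [50, 200])
        assert sum(not c.is_baseline for c in conds) == 14  # 7 subsets x 2
        assert sum(c.is_baseline for c in conds) == 2

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_supplement_conditions(set(), [50])

    @given(st.sets(st.sampled_from("ATGC"), min_size=1),
           st.lists(st.sampled_from([50.0, 200.0]), min_size=1, max_size=2,
                    unique=True))
    @settings(max_examples=30, deadline=None)
    def test_powerset_count(self, nucleosides, concentrations):
        conds = enumerate_supplement_conditions(nucleosides, concentrations)
        expected = (2 ** len(nucleosides) - 1) * len(concentrations)
        assert sum(not c.is_baseline for c in conds) == expected

    def test_baseline_must_have_unit_effects(self):
        with pytest.raises(ValueError):
            ScreenSpec(frozenset(), 200.0, effect_mtdna=2.0)


class TestRenderField:
    def test_empty_field_is_background_plus_noise(self):
        spec = FieldSpec(n_cells=0, noise_sd=0, seed=1)
        image, truth = render_field(spec)
        assert truth == []
        assert np.allclose(image.dna, spec.background)
        assert np.allclose(image.mmp, spec.background)

    def test_determinism_bit_identical(self):
        spec = FieldSpec(n_cells=8, seed=7)
        a, _ = render_field(spec)
        b, _ = render_field(spec)
        assert np.array_equal(a.dna, b.dna)
        assert np.array_equal(a.mmp, b.mmp)

    def test_rho0_iff_zero_nucleoids(self):
        spec = FieldSpec(n_cells=20, rho0_fraction=0.5, seed=3)
        _, truth = render_field(spec)
        for t in truth:
            assert t.is_rho0 == (t.nucleoid_count == 0)
        assert any(t.is_rho0 for t in truth)

    def test_nucleoids_outside_nucleus_inside_territory(self):
        spec = FieldSpec(n_cells=12, nucleoid_count_mean=30, seed=5)
        _, truth = render_field(spec)
        centers = np.array([[t.nucleus_center[1], t.nucleus_center[0]]
                            for t in truth])
        for i, t in enumerate(truth):
            r_nuc = math.sqrt(t.nucleus_area / math.pi) / spec.pixel_size
            for (x, y) in t.nucleoid_positions:
                d_own = math.hypot(y - centers[i, 0], x - centers[i, 1])
                assert d_own > r_nuc  # outside the nuclear footprint
                d_all = np.hypot(centers[:, 0] - y, centers[:, 1] - x)
                assert np.argmin(d_all) == i  # inside own territory

    def test_mmp_intensity_conservation(self):
        spec = FieldSpec(n_cells=10, seed=3, noise_sd=0)
        image, truth = render_field(spec)
        total = (image.mmp - spec.background).sum()
        expected = sum(t.mito_polarized_mass for t in truth)
        assert total == pytest.approx(expected, rel=1e-9)

    def test_field_too_small_raises(self):
        with pytest.raises(ValueError):
            render_field(FieldSpec(field_size=(64, 64), n_cells=50))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            FieldSpec(rho0_fraction=1.5)
        with pytest.raises(ValueError):
            FieldSpec(noise_sd=-1)

    def test_sg2_nuclear_targets_exceed_g1(self):
        # the jitter clipping makes every S/G2 integrated-density target
        # strictly exceed every G1 target within a field; with zero
        # noise the rendered totals preserve that ordering
        spec = FieldSpec(n_cells=20, s_phase_fraction=0.5, seed=9,
                         noise_sd=0, nucleoid_count_mean=1.0)
        image, truth = render_field(spec)
        from mdscreen.benchmarks import match_cells_to_truth
        from mdscreen.imaging import quantify_field, segment_field
        seg = segment_field(image)
        rec = quantify_field(image, classify=False)
        match = match_cells_to_truth(seg, truth)
        g1 = [rec.nuclear_integrated_density[i] for i, cid in
              enumerate(rec.cell_id) if truth[match[cid]].ploidy_class == "G1"]
        sg2 = [rec.nuclear_integrated_density[i] for i, cid in
               enumerate(rec.cell_id) if truth[match[cid]].ploidy_class == "S_G2"]
        assert g1 and sg2
        assert min(sg2) > max(g1)


class TestScreenDataset:
    def test_baseline_screen_shape(self):
        base = FieldSpec(field_size=(256, 256), n_cells=4,
                         nucleoid_count_mean=20, min_separation=20.0)
        ds = generate_screen_dataset([ScreenSpec(frozenset(), 200.0)], base,
                                     fields_per_well=9, runs=1, seed=0)
        assert len(ds.fields) == 9
        assert (ds.truth["effect_mtdna"] == 1.0).all()
        assert ds.platemap.shape[0] == 1

    def test_mtdna_effect_doubles_truth_mean(self):
        base = FieldSpec(field_size=(384, 384), n_cells=8,
                         nucleoid_count_mean=30, seed=0)
        conds = [ScreenSpec(frozenset(), 200.0),
                 ScreenSpec(frozenset("ATGC"), 200.0, effect_mtdna=2.0)]
        ds = generate_screen_dataset(conds, base, fields_per_well=6, runs=1,
                                     seed=4, run_sigma=0.0)
        means = ds.truth.groupby("condition")["nucleoid_count"].mean()
        ratio = means["ATGC"] / means["DMSO"]
        assert ratio == pytest.approx(2.0, rel=0.08)  # binomial sampling

    def test_run_intercepts_multiply_nucleoid_content(self):
        base = FieldSpec(field_size=(384, 384), n_cells=8,
                         nucleoid_count_mean=30, seed=0)
        ds = generate_screen_dataset([ScreenSpec(frozenset(), 200.0)], base,
                                     fields_per_well=8, runs=2, seed=11,
                                     run_sigma=0.4)
        g = ds.truth.groupby("run_id").agg(
            mean_count=("nucleoid_count", "mean"),
            intercept=("run_intercept", "first"))
        implied = g["mean_count"] / (30.0 * g["intercept"])
        assert np.allclose(implied, 1.0, rtol=0.1)

    def test_fields_per_well_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_screen_dataset([ScreenSpec(frozenset(), 200.0)],
                                    FieldSpec(), fields_per_well=0)


class TestRecoveryCourse:
    def test_day0_equals_depletion_fraction_exactly(self):
        spec = RecoverySpec(ct_noise_sd=0)
        course = normalize_course(
            generate_recovery_course(spec, treated=False, seed=0))
        day0 = course.data.loc[course.data.day == 0, "rel_copy"]
        assert np.allclose(day0, spec.depletion_fraction)

    def test_zero_rate_course_is_flat(self):
        spec = RecoverySpec(ct_noise_sd=0, recovery_rate_untreated=0.0)
        course = normalize_course(
            generate_recovery_course(spec, treated=False, seed=0))
        assert np.allclose(course.data["rel_copy"], spec.depletion_fraction)

    def test_rate_for_target_closed_form(self):
        r = rate_for_target(0.5, 14.0, target=0.95)
        spec = RecoverySpec(recovery_rate_treated=r)
        assert true_copy_fraction(spec, 14.0, treated=True) == \
            pytest.approx(0.95, abs=1e-12)
        with pytest.raises(ValueError):
            rate_for_target(0.5, 14.0, target=1.0)

    def test_negative_timepoints_rejected(self):
        with pytest.raises(ValueError):
            RecoverySpec(timepoints=(-1.0, 7.0))

    def test_ct_values_invert_copy_number_formula(self):
        spec = RecoverySpec(ct_noise_sd=0)
        for m in generate_recovery_course(spec, treated=True, seed=0):
            t = 0.0 if m.is_reference else m.day
            expected = spec.baseline_copies * (
                1.0 if m.is_reference else true_copy_fraction(spec, t, True))
            assert copy_number_from_ct(m) == pytest.approx(expected)


class TestIsotopeTable:
    def test_no_dilution_limit_gives_supplement_fraction(self):
        spec = PoolSpec(endogenous_pools={n: 1e-9 for n in NUCLEOSIDES},
                        new_dna_fraction=1.0, measurement_cv=0)
        table = generate_isotope_table(spec, seed=0)
        sa = table.areas["heavy_area"] / (table.areas["heavy_area"]
                                          + table.areas["light_area"])
        assert np.allclose(sa, 0.10, atol=1e-6)

    def test_vanishing_flux_gives_zero_activity(self):
        flux = {n: 1.0 for n in NUCLEOSIDES}
        flux["dT"] = 1e-12
        spec = PoolSpec(supplement_flux=flux, measurement_cv=0)
        assert true_specific_activity(spec, "dT") < 1e-10

    def test_hand_computed_dilution_example(self):
        spec = PoolSpec(endogenous_pools={"dA": 9, "dC": 1, "dG": 1, "dT": 1},
                        new_dna_fraction=1.0, measurement_cv=0)
        truth = generate_isotope_table(spec, seed=0).truth
        assert truth["dA"] == pytest.approx(0.01)
        for n in ("dC", "dG", "dT"):
            assert truth[n] == pytest.approx(0.05)

    def test_determinism(self):
        a = generate_isotope_table(PoolSpec(), seed=5).areas
        b = generate_isotope_table(PoolSpec(), seed=5).areas
        assert a.equals(b)

    def test_zero_pool_rejected(self):
        with pytest.raises(ValueError):
            PoolSpec(endogenous_pools={n: 0.0 for n in NUCLEOSIDES})

    @given(st.floats(0.01, 0.5), st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_dilution_formula_scalar_recomputation(self, heavy, pool):
        pools = {n: pool for n in NUCLEOSIDES}
        spec = PoolSpec(endogenous_pools=pools,
                        heavy_fraction_supplement=heavy,
                        new_dna_fraction=0.7, measurement_cv=0)
        sa = true_specific_activity(spec, "dA")
        assert sa == pytest.approx(heavy * 1.0 / (1.0 + pool) * 0.7)
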