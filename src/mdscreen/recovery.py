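"""Depletion–recovery copy-number analysis and heavy-isotope pool inference.

Two downstream assays complement the imaging screen:

1. **qPCR relative mtDNA copy number.**  A mitochondrial target and the
   single-copy nuclear reference gene B2M are assayed together; assuming
   100 % amplification efficiency, mtDNA copies per diploid genome are
   ``2^(Ct_B2M − Ct_mt) × 2`` (B2M is present at two copies per diploid
   nucleus).  Recovery time courses after dideoxycytidine (ddC)
   depletion are normalised to the pre-depletion reference and compared
   between supplemented and unsupplemented arms with a two-way ANOVA
   blocking time, plus per-day Welch t-tests.

2. **Stable-isotope label dilution.**  Cells fed a nucleoside mix that
   is 10 % heavy-labelled incorporate the label into new DNA diluted by
   the endogenous nucleoside pools.  The specific activity of each
   nucleoside — heavy / (heavy + light) peak area — therefore falls
   with pool size; its reciprocal, after normalisation to the control
   median, indexes the pool, and the nucleoside with the *highest*
   specific activity is the limiting one for DNA replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

NUCLEOSIDES = ("dA", "dC", "dG", "dT")

CT_RANGE = (0.0, 45.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class QpcrMeasurement:
    """One qPCR Ct pair (mtDNA target and B2M reference) for a sample."""

    sample: str
    line: str
    treated: bool
    day: float
    ct_mt: float
    ct_b2m: float
    replicate: int = 0
    is_reference: bool = False

    def __post_init__(self) -> None:
        for name in ("ct_mt", "ct_b2m"):
            ct = getattr(self, name)
            if np.isfinite(ct) and not (CT_RANGE[0] < ct < CT_RANGE[1]):
                raise ValueError(f"{name}={ct} outside plausible range {CT_RANGE}")

    @property
    def missing(self) -> bool:
        return not (np.isfinite(self.ct_mt) and np.isfinite(self.ct_b2m))


@dataclass
class RecoveryCourse:
    """Per-day relative copy numbers, normalised so the pre-depletion
    reference equals 1; replicate values retained."""

    data: pd.DataFrame          # columns: day, treated, replicate, rel_copy
    reference_mean: float

    def day_means(self) -> pd.DataFrame:
        return (self.data.groupby(["treated", "day"], as_index=False)
                ["rel_copy"].mean())


@dataclass
class IsotopeTable:
    """Heavy/light peak areas per nucleoside, optionally with generator
    ground truth of the underlying specific activities."""

    areas: pd.DataFrame         # columns: nucleoside, heavy_area, light_area
    truth: dict | None = None

    def __post_init__(self) -> None:
        required = {"nucleoside", "heavy_area", "light_area"}
        missing = required - set(self.areas.columns)
        if missing:
            raise ValueError(f"isotope table missing columns: {sorted(missing)}")


@dataclass
class PoolInference:
    """Control-normalised activities and derived pool indices."""

    specific_activity: dict
    normalized_activity: dict
    pool_index: dict
    limiting: tuple                  # nucleosides tied as limiting
    limiting_label: str              # e.g. "dT" or "dT/dG"
    synthesis_rate_proxy: float


# ---------------------------------------------------------------------------
# qPCR copy number
# ---------------------------------------------------------------------------

def copy_number_from_ct(m: QpcrMeasurement) -> float:
    """Relative mtDNA copies per diploid genome from one Ct pair.

    Assumes 100 % efficiency for both targets; B2M contributes the ×2
    diploid factor.  Missing Ct values give NaN (flagged upstream).
    """
    if m.missing:
        return float("nan")
    return float(2.0 ** (m.ct_b2m - m.ct_mt) * 2.0)


def normalize_course(measurements: list[QpcrMeasurement],
                     reference: list[QpcrMeasurement] | None = None
                     ) -> RecoveryCourse:
    """Normalise a recovery time course to its pre-depletion reference.

    The reference is the mean copy number over the pre-depletion
    untreated measurements — passed explicitly via ``reference`` or
    taken from the measurements flagged ``is_reference``.  Treated and
    untreated arms of one experiment must be normalised to the *same*
    reference, otherwise independent reference noise masquerades as a
    treatment effect.  The reference itself maps to 1 by construction.
    """
    ref_pool = reference if reference is not None else measurements
    ref = [copy_number_from_ct(m) for m in ref_pool
           if m.is_reference and not m.missing]
    if not ref:
        raise ValueError("no pre-depletion reference measurement present")
    ref_mean = float(np.mean(ref))
    rows = []
    n_missing = 0
    for m in measurements:
        if m.is_reference:
            continue
        if m.missing:
            n_missing += 1
            continue
        if m.day < 0:
            raise ValueError(f"negative timepoint: {m.day}")
        rows.append({
            "day": m.day,
            "treated": bool(m.treated),
            "replicate": m.replicate,
            "rel_copy": copy_number_from_ct(m) / ref_mean,
        })
    if n_missing:
        warnings.warn(f"{n_missing} measurements with missing Ct excluded",
                      stacklevel=2)
    return RecoveryCourse(data=pd.DataFrame(rows), reference_mean=ref_mean)


def treatment_effect_anova(course_treated: RecoveryCourse | pd.DataFrame,
                           course_untreated: RecoveryCourse | pd.DataFrame
                           ) -> dict:
    """Two-way ANOVA (treatment + time, no interaction) on a recovery course.

    With only two replicates per cell an interaction term is not
    estimable, so the additive model blocks time and tests treatment;
    per-day Welch t-tests are reported alongside.  Day 0 (the end of
    depletion) precedes the divergence of the arms — both are the same
    culture before supplementation starts — so it is excluded from the
    treatment ANOVA, though it is kept in the per-day comparisons.
    Identical arms give a treatment F of ~0 and p of 1.
    """
    t = course_treated.data if isinstance(course_treated, RecoveryCourse) \
        else course_treated
    u = course_untreated.data if isinstance(course_untreated, RecoveryCourse) \
        else course_untreated
    df = pd.concat([t.assign(arm="treated"), u.assign(arm="untreated")],
                   ignore_index=True)
    post = df[df["day"] > 0] if (df["day"] > 0).any() else df
    n_days = post["day"].nunique()
    reps = post.groupby(["arm", "day"]).size()
    if n_days < 2 or (reps < 2).all():
        raise ValueError("need >= 2 timepoints with >= 2 replicates")

    model = smf.ols("rel_copy ~ C(arm) + C(day)", data=post).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-SS edge cases emit RuntimeWarnings
        table = anova_lm(model, typ=2)
    trt_ss = float(table.loc["C(arm)", "sum_sq"])
    resid_ss = float(table.loc["Residual", "sum_sq"])
    if resid_ss <= 0 or trt_ss <= 1e-12 * max(resid_ss, 1.0):
        treatment_p = 1.0
    else:
        treatment_p = float(table.loc["C(arm)", "PR(>F)"])
    time_p = float(table.loc["C(day)", "PR(>F)"])

    per_day = []
    skipped = False
    for day, g in df.groupby("day"):
        x = g.loc[g["arm"] == "treated", "rel_copy"].to_numpy()
        y = g.loc[g["arm"] == "untreated", "rel_copy"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            skipped = True
            continue
        res = stats.ttest_ind(x, y, equal_var=False)
        per_day.append({"day": day, "t": float(res.statistic),
                        "p": float(res.pvalue)})
    if skipped:
        warnings.warn("single replicate at some timepoints: per-day tests "
                      "skipped there", stacklevel=2)
    return {
        "treatment_p": treatment_p,
        "time_p": time_p,
        "per_day_tests": pd.DataFrame(per_day),
        "anova_table": table,
    }


# ---------------------------------------------------------------------------
# isotope pools
# ---------------------------------------------------------------------------

def specific_activity(table: IsotopeTable | pd.DataFrame) -> pd.DataFrame:
    """Specific activity per nucleoside: heavy / (heavy + light).

    Scale-invariant to joint rescaling of both peak areas; a zero total
    area leaves that nucleoside's activity undefined (NaN, flagged).
    """
    df = table.areas if isinstance(table, IsotopeTable) else table
    df = df.copy()
    total = df["heavy_area"] + df["light_area"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["specific_activity"] = np.where(total > 0,
                                           df["heavy_area"] / total,
                                           np.nan)
    if (total <= 0).any():
        bad = df.loc[total <= 0, "nucleoside"].tolist()
        warnings.warn(f"zero total peak area for {bad}: activity undefined",
                      stacklevel=2)
    return df


def infer_pools(patient: IsotopeTable | pd.DataFrame,
                controls: list,
                tie_rel_tol: float = 0.05) -> PoolInference:
    """Infer relative nucleoside pool sizes and the limiting nucleoside.

    Patient activities are normalised to the control median per
    nucleoside; the reciprocal of the normalised activity indexes the
    available pool.  The limiting nucleoside is the argmax of the
    patient specific activity (smallest pool); activities within
    ``tie_rel_tol`` of the maximum are reported jointly (e.g. "dT/dG").
    The synthesis-rate proxy is the reciprocal normalised activity of
    the (top) limiting nucleoside.
    """
    pat = specific_activity(patient).set_index("nucleoside")
    ctrl_frames = [specific_activity(c) for c in controls]
    ctrl = pd.concat(ctrl_frames, ignore_index=True)
    ctrl_median = ctrl.groupby("nucleoside")["specific_activity"].median()
    if (ctrl_median <= 0).any() or ctrl_median.isna().any():
        bad = ctrl_median.index[(ctrl_median <= 0) | ctrl_median.isna()].tolist()
        raise ValueError(f"control median activity not positive for {bad}")

    sa = pat["specific_activity"]
    normalized = (sa / ctrl_median.reindex(sa.index)).to_dict()
    with np.errstate(divide="ignore"):
        pool_index = {n: (1.0 / v if v > 0 else np.inf)
                      for n, v in normalized.items()}

    order = sa.sort_values(ascending=False)
    top = float(order.iloc[0])
    limiting = tuple(n for n, v in order.items()
                     if top > 0 and v >= (1.0 - tie_rel_tol) * top)
    if not limiting:
        limiting = (order.index[0],)
    label = "/".join(limiting)
    proxy = 1.0 / normalized[limiting[0]]
    return PoolInference(
        specific_activity=sa.to_dict(),
        normalized_activity=normalized,
        pool_index=pool_index,
        limiting=limiting,
        limiting_label=label,
        synthesis_rate_proxy=float(proxy),
    )
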