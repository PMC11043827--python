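"""Screen statistics: condition summaries, baseline-normalised effects,
normality-gated tests, mixed-model group effects, galactose viability.

Per-cell summed nucleoid area is approximately log-normal across cells,
so mtDNA content is summarised and tested on the log10 scale (Rho-0
cells, whose summed area is zero, are excluded from the log but kept in
cell counts and the Rho-0 proportion).  Percentage changes versus the
DMSO baseline — the headline screen readout — are computed on the raw
scale for all three readouts (mean summed area, cell count, mean MMP
integrated density).

Test selection follows the normality-gated convention: Shapiro–Wilk on
each sample at α = 0.05; if either sample departs from normality the
two-sided Mann–Whitney U test is used, otherwise a two-sample t-test.
Group effects across runs (and cell lines) are estimated with a linear
mixed model with random intercepts per run (and per line), reflecting
that within-run comparisons are more robust than between-run ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass
class ConditionSummary:
    """Per-condition readouts for one run/line/serum context."""

    condition: str
    concentration_um: float
    serum: float
    cell_count: int
    rho0_proportion: float
    mean_log10_area: float          # NaN when no cell has puncta
    median_log10_area: float
    mean_raw_area: float            # raw µm², all cells (Rho-0 at 0)
    mean_mmp: float
    mtdna_undefined: bool = False   # every cell Rho-0 / zero area


@dataclass
class MixedModelResult:
    """Fixed treatment effect on log10 summed area with run/line intercepts."""

    estimate: float
    se: float
    p_value: float
    var_run: float
    var_line: float
    fallback: bool = False          # run-level fixed effects used instead


# ---------------------------------------------------------------------------
# summaries and percent change
# ---------------------------------------------------------------------------

def summarize_condition(records: pd.DataFrame,
                        condition: str = "",
                        concentration_um: float = float("nan"),
                        serum: float = float("nan")) -> ConditionSummary:
    """Summarise the per-cell records of one condition.

    mtDNA content statistics are computed on log10 summed punctum area
    over cells with positive area; Rho-0 cells count towards
    ``cell_count`` and ``rho0_proportion`` only.
    """
    n = len(records)
    if n == 0:
        warnings.warn("zero cells in condition; empty summary", stacklevel=2)
        return ConditionSummary(condition, concentration_um, serum, 0,
                                float("nan"), float("nan"), float("nan"),
                                float("nan"), float("nan"),
                                mtdna_undefined=True)
    areas = records["puncta_summed_area"].to_numpy(float)
    positive = areas[areas > 0]
    undefined = positive.size == 0
    log_areas = np.log10(positive) if not undefined else np.array([])
    return ConditionSummary(
        condition=condition,
        concentration_um=concentration_um,
        serum=serum,
        cell_count=n,
        rho0_proportion=float(records["is_rho0"].mean()),
        mean_log10_area=float(log_areas.mean()) if not undefined else float("nan"),
        median_log10_area=float(np.median(log_areas)) if not undefined else float("nan"),
        mean_raw_area=float(areas.mean()),
        mean_mmp=float(records["mmp_integrated_density"].mean()),
        mtdna_undefined=undefined,
    )


def percent_change_vs_baseline(treated: ConditionSummary,
                               baseline: ConditionSummary) -> dict:
    """Percentage change of the three screen readouts vs the DMSO baseline.

    100 × (treated − baseline) / baseline on raw-scale mean summed area
    (mtDNA), cell count, and mean MMP integrated density.  A zero
    baseline leaves that readout undefined (NaN).
    """
    def pct(t: float, b: float) -> float:
        if not np.isfinite(b) or b == 0:
            warnings.warn("baseline mean is zero/undefined; percent change "
                          "flagged NaN", stacklevel=3)
            return float("nan")
        return 100.0 * (t - b) / b

    return {
        "pct_change_mtdna": pct(treated.mean_raw_area, baseline.mean_raw_area),
        "pct_change_cells": pct(float(treated.cell_count),
                                float(baseline.cell_count)),
        "pct_change_mmp": pct(treated.mean_mmp, baseline.mean_mmp),
    }


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def compare_to_baseline(treated: np.ndarray, baseline: np.ndarray,
                        alpha: float = DEFAULT_ALPHA) -> tuple[str, float]:
    """Normality-gated two-sample test.

    Shapiro–Wilk on each sample; if either rejects at ``alpha`` (or is
    degenerate/constant) the two-sided Mann–Whitney U test is run
    (exact for small tie-free samples, otherwise normal approximation
    with tie and continuity correction), else a two-sided two-sample
    t-test.  Returns ``(test_used, p_value)`` with test_used in
    {"MW", "t"}.
    """
    x = np.asarray(treated, float)
    y = np.asarray(baseline, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")

    def is_normalish(v: np.ndarray) -> bool:
        if np.ptp(v) == 0:
            return False  # constant sample: no evidence of normality
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(v).pvalue >= alpha

    if is_normalish(x) and is_normalish(y):
        res = stats.ttest_ind(x, y)
        return "t", float(res.pvalue)

    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return "MW", 1.0  # all observations tied: no evidence of a shift
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(x), len(y)) <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return "MW", float(res.pvalue)


def fit_group_effect(records: pd.DataFrame,
                     value_col: str = "log10_area",
                     treatment_col: str = "treatment",
                     run_col: str = "run_id",
                     line_col: str = "cell_line") -> MixedModelResult:
    """Linear mixed model for the treatment effect on log10 summed area.

    ``value ~ treatment`` with a random intercept per run, plus a
    variance component per cell line when several lines are present.
    On a singular/non-converging fit, falls back to run-level (and
    line-level) fixed effects with a warning.
    """
    df = records.dropna(subset=[value_col]).copy()
    if df[run_col].nunique() < 2:
        raise ValueError("mixed model requires >= 2 runs")
    multi_line = line_col in df.columns and df[line_col].nunique() > 1

    vc = {"line": f"0 + C({line_col})"} if multi_line else None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(f"{value_col} ~ {treatment_col}", data=df,
                                groups=df[run_col], vc_formula=vc)
            fit = model.fit(reml=True)
        est = float(fit.params[treatment_col])
        se = float(fit.bse[treatment_col])
        p = float(fit.pvalues[treatment_col])
        var_run = float(fit.cov_re.iloc[0, 0])
        var_line = float(fit.vcomp[0]) if multi_line and len(fit.vcomp) else 0.0
        if not (np.isfinite(est) and np.isfinite(p) and np.isfinite(se)):
            raise ValueError("non-finite mixed-model estimates")
        return MixedModelResult(est, se, p, max(var_run, 0.0),
                                max(var_line, 0.0))
    except Exception:
        warnings.warn("singular mixed-model fit; falling back to run-level "
                      "fixed effects", stacklevel=2)
        formula = f"{value_col} ~ {treatment_col} + C({run_col})"
        if multi_line:
            formula += f" + C({line_col})"
        fit = smf.ols(formula, data=df).fit()
        return MixedModelResult(
            estimate=float(fit.params[treatment_col]),
            se=float(fit.bse[treatment_col]),
            p_value=float(fit.pvalues[treatment_col]),
            var_run=0.0, var_line=0.0, fallback=True)


def galactose_viability(count_galactose: int, count_glucose: int) -> float:
    """Viability in galactose as % of the matched high-glucose count.

    Cells unable to respire die in galactose; the ratio collapses
    towards 0 for severely mtDNA-depleted cultures.
    """
    if count_glucose <= 0:
        raise ValueError("glucose-media cell count must be > 0")
    if count_galactose < 0:
        raise ValueError("cell counts must be >= 0")
    return 100.0 * count_galactose / count_glucose


# ---------------------------------------------------------------------------
# screen-level table
# ---------------------------------------------------------------------------

CONDITION_KEYS = ["condition", "concentration_um", "serum"]
CONTEXT_KEYS = ["run_id", "cell_line", "concentration_um", "serum"]


def summarize_screen(records: pd.DataFrame,
                     alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Condition-level screen table with baseline-normalised effects.

    For every (run, line, serum, concentration) context with a DMSO
    baseline, each supplemented condition gets: summary statistics,
    percentage changes of the three readouts vs baseline, the
    normality-gated test on log10 summed area, and a
    Benjamini–Hochberg adjusted p-value column (reported alongside the
    raw per-condition p-values, which remain the headline flags).

    ``records`` must carry a ``condition`` column ("DMSO" for the
    baseline) in addition to the per-cell metrics.
    """
    records = records.copy()
    with np.errstate(divide="ignore"):
        records["log10_area"] = np.where(
            records["puncta_summed_area"] > 0,
            np.log10(records["puncta_summed_area"].clip(lower=1e-300)),
            np.nan)
    rows = []
    for ctx, group in records.groupby(CONTEXT_KEYS, sort=True):
        base = group[group["condition"] == "DMSO"]
        if not len(base):
            warnings.warn(f"context {ctx} has no DMSO baseline; skipped",
                          stacklevel=2)
            continue
        base_summary = summarize_condition(base, "DMSO", ctx[2], ctx[3])
        base_log = base["log10_area"].dropna().to_numpy()
        for cond, sub in group.groupby("condition", sort=True):
            if cond == "DMSO":
                continue
            summary = summarize_condition(sub, cond, ctx[2], ctx[3])
            pct = percent_change_vs_baseline(summary, base_summary)
            sub_log = sub["log10_area"].dropna().to_numpy()
            if len(sub_log) >= 3 and len(base_log) >= 3:
                test_used, p = compare_to_baseline(sub_log, base_log, alpha)
            else:
                test_used, p = "NA", float("nan")
            rows.append({
                "run_id": ctx[0], "cell_line": ctx[1],
                "concentration_um": ctx[2], "serum": ctx[3],
                "condition": cond,
                "cell_count": summary.cell_count,
                "rho0_proportion": summary.rho0_proportion,
                "mean_log10_area": summary.mean_log10_area,
                "median_log10_area": summary.median_log10_area,
                "mean_raw_area": summary.mean_raw_area,
                "mean_mmp": summary.mean_mmp,
                **pct,
                "test_used": test_used,
                "p_value": p,
            })
    table = pd.DataFrame(rows)
    if len(table):
        mask = table["p_value"].notna()
        adj = np.full(len(table), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                table.loc[mask, "p_value"], method="fdr_bh")[1]
        table["p_value_bh"] = adj
    return table
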