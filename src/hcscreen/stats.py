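"""γH2AX normalization, growth-rate estimation and treatment inference.

γH2AX (total nuclear intensity of the phospho-H2AX stain, a double-strand
break marker) is normalized in two steps: (1) row-wise subtraction of the
mean per-cell signal of the row's secondary-only control well, removing
nonspecific background per technical replicate; (2) a robust linear model
(Huber M-estimation) of the time-zero signal on plate and column factors,
whose estimated effects are subtracted from every well of every plate —
removing plate- and position-dependent acquisition offsets without letting
genuine treatment responses (absent at time zero) leak into the correction.

Growth is summarised by least squares on log2 cell counts,
log2(count(t)) = a + b·t, giving the doubling time 1/b hours (the
dimensionless quantity 2^b is reported alongside as a legacy convention).
Treatment effects on subpopulation trajectories are tested by a split-plot
ANOVA: treatment is applied per plate (whole plot, fully confounded with
plate), wells are subplots and time is continuous, so the reportable test
is the time x treatment interaction against the within-plate residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .gating import MissingControlError


class DesignError(ValueError):
    """The data do not support the requested analysis design."""


# --------------------------------------------------------------------------
# gamma-H2AX normalization
# --------------------------------------------------------------------------

def row_normalize_gamma(cells: pd.DataFrame, layout,
                        value_column: str = "total_gH2AX") -> pd.DataFrame:
    """Subtract the secondary-only control's mean signal row by row.

    Returns the cells with added columns ``replicate_row``, ``is_control``
    and ``gamma_row_norm`` (value minus the mean per-cell total of the
    row's control well).  Exactly invariant to any additive offset applied
    to a whole row, controls and experimental wells alike.
    """
    wells = layout.wells
    merged = cells.merge(
        wells[["plate", "well", "replicate_row", "is_control", "column",
               "dose_gy", "time_h"]],
        on=["plate", "well"], how="left", validate="many_to_one",
    )
    if merged["replicate_row"].isna().any():
        raise ValueError("some cells reference wells absent from the layout")
    out = []
    for row_id, grp in merged.groupby("replicate_row"):
        ctrl = grp[grp["is_control"]]
        if ctrl.empty:
            raise MissingControlError(
                f"replicate row {row_id!r} has no secondary-only control well"
            )
        ctrl_mean = float(ctrl[value_column].mean())
        g = grp.copy()
        g["gamma_row_norm"] = g[value_column] - ctrl_mean
        out.append(g)
    return pd.concat(out, ignore_index=True)


def plate_column_adjust(normed: pd.DataFrame,
                        value_column: str = "gamma_row_norm",
                        huber_t: float = 1.345) -> pd.DataFrame:
    """Remove plate and column effects estimated robustly at time zero.

    A Huber M-estimated linear model with sum-to-zero factor coding is
    fitted to the time-zero values on plate and column; an interaction term
    is included only when every plate x column cell at time zero holds at
    least two wells.  The estimated effects (relative to the grand level)
    are then subtracted from all wells on all plates, preserving the
    within-well ordering of cells.  Adds the column ``gamma_adjusted``.
    """
    t0 = normed[normed["time_h"] == 0.0]
    plates = normed["plate"].unique()
    missing = [p for p in plates if p not in set(t0["plate"])]
    if missing:
        raise DesignError(
            f"plate(s) {missing} contribute no time-zero wells; the "
            "plate/column model cannot be anchored"
        )
    t0 = t0.copy()
    t0["_col"] = t0["column"].astype(int).astype(str)
    cell_wells = t0.groupby(["plate", "_col"])["well"].nunique()
    full_grid = len(cell_wells) == t0["plate"].nunique() * t0["_col"].nunique()
    with_interaction = full_grid and (cell_wells >= 2).all()
    formula = f"{value_column} ~ C(plate, Sum) + C(_col, Sum)"
    if with_interaction:
        formula += " + C(plate, Sum):C(_col, Sum)"
    rlm = smf.rlm(formula, data=t0, M=sm.robust.norms.HuberT(t=huber_t)).fit()

    all_rows = normed.copy()
    all_rows["_col"] = all_rows["column"].astype(int).astype(str)
    # effect = fitted value minus the intercept (grand level); unseen factor
    # levels cannot occur because every plate/column appears at time zero
    design = all_rows[["plate", "_col"]].copy()
    design[value_column] = 0.0
    effects = rlm.predict(design) - rlm.params["Intercept"]
    all_rows["gamma_adjusted"] = all_rows[value_column] - effects.to_numpy()
    return all_rows.drop(columns=["_col"])


# --------------------------------------------------------------------------
# growth
# --------------------------------------------------------------------------

@dataclass
class GrowthFit:
    """Least-squares fit of log2 counts against time (hours)."""

    a: float                 # intercept, log2 count units
    b: float                 # slope, per hour
    doubling_time_h: float   # 1/b when b > 0, else NaN
    doubling_time_legacy_convention: float  # the dimensionless 2^b
    residual_se: float
    n_points: int

    def predict_count(self, t) -> np.ndarray:
        """count(t) = 2^a · 2^(t·b), the exact inverse of the linear fit."""
        return 2.0 ** (self.a + self.b * np.asarray(t, dtype=float))


def fit_growth(counts, times) -> GrowthFit:
    """Fit log2(count) = a + b·t by ordinary least squares.

    Zero counts cannot be log-transformed and are excluded with a warning;
    at least three usable time points are required.  The doubling time is
    1/b hours (missing when b <= 0).
    """
    counts = np.asarray(counts, dtype=float)
    times = np.asarray(times, dtype=float)
    if counts.shape != times.shape:
        raise ValueError("counts and times must have the same length")
    usable = counts > 0
    if (~usable).any():
        warnings.warn(f"excluding {int((~usable).sum())} zero/negative counts")
    counts, times = counts[usable], times[usable]
    if len(counts) < 3:
        raise DesignError("need at least 3 usable time points")
    y = np.log2(counts)
    X = np.column_stack([np.ones_like(times), times])
    coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    dof = len(y) - 2
    rss = float(((y - X @ coef) ** 2).sum())
    resid_se = float(np.sqrt(rss / dof)) if dof > 0 else np.nan
    return GrowthFit(
        a=a, b=b,
        doubling_time_h=(1.0 / b) if b > 1e-12 else np.nan,
        doubling_time_legacy_convention=2.0**b,
        residual_se=resid_se, n_points=len(y),
    )


# --------------------------------------------------------------------------
# split-plot and one-way ANOVA
# --------------------------------------------------------------------------

@dataclass
class SplitPlotResult:
    """Time x treatment interaction test from the split-plot design."""

    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    phenotype: str | None = None


def split_plot_interaction(data: pd.DataFrame,
                           value_column: str = "proportion",
                           time_column: str = "time_h",
                           plate_column: str = "plate",
                           phenotype_column: str | None = None):
    """Test whether trajectories over time differ between treatments.

    ``data`` holds one row per well per time point.  Treatment is applied
    at the plate level (one treatment per plate, fully confounded), so the
    treatment main effect has no valid error term and is not reported; the
    time x plate interaction — time continuous — is tested against the
    within-plate well residual, which is exactly the hypothesis that the
    change in proportion over time is equivalent across treatments.

    With ``phenotype_column`` the test is run per phenotype and a list of
    results is returned; otherwise a single :class:`SplitPlotResult`.
    """
    if phenotype_column is not None:
        return [
            _split_plot_single(grp, value_column, time_column, plate_column,
                               phenotype=str(ph))
            for ph, grp in data.groupby(phenotype_column)
        ]
    return _split_plot_single(data, value_column, time_column, plate_column)


def _split_plot_single(data, value_column, time_column, plate_column,
                       phenotype=None) -> SplitPlotResult:
    plates = data[plate_column].unique()
    if len(plates) < 2:
        raise DesignError("split-plot needs >= 2 treatments/plates")
    if data[time_column].nunique() < 2:
        raise DesignError("split-plot needs >= 2 time points")
    counts = data.groupby([plate_column, time_column]).size()
    if (counts < 2).any():
        raise DesignError("need >= 2 wells per plate-time combination")

    d = data.rename(columns={value_column: "_y", time_column: "_t",
                             plate_column: "_plate"})
    full = smf.ols("_y ~ _t + C(_plate) + _t:C(_plate)", data=d).fit()
    reduced = smf.ols("_y ~ _t + C(_plate)", data=d).fit()
    df_num = int(reduced.df_resid - full.df_resid)
    df_den = int(full.df_resid)
    if full.ssr <= 0 or df_den == 0:
        raise DesignError("residual degrees of freedom exhausted")
    f = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    return SplitPlotResult(f_statistic=float(f), p_value=p,
                           df_num=df_num, df_den=df_den, phenotype=phenotype)


def one_way_anova_and_sem(groups: dict[str, np.ndarray]):
    """Classical one-way ANOVA plus per-group mean ± SEM.

    ``groups`` maps group labels to value arrays (>= 2 groups, >= 2 values
    each).  Returns (F, p, summary DataFrame with mean, sem, n).
    """
    if len(groups) < 2:
        raise DesignError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise DesignError(f"group {k!r} has fewer than 2 values")
    f, p = sps.f_oneway(*arrays.values())
    summary = pd.DataFrame([
        {"group": k, "mean": float(v.mean()),
         "sem": float(v.std(ddof=1) / np.sqrt(len(v))), "n": len(v)}
        for k, v in arrays.items()
    ])
    return float(f), float(p), summary


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (optional; no correction is applied by
    default to the per-donor ANOVAs)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
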