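"""Marker-positivity gating by control-anchored mixture-model thresholds.

For each marker and each technical-replicate row, the natural log of
per-cell mean intensity (experimental wells pooled with the row's
secondary-only control well) is modelled as a mixture of normal components.
The secondary-only control identifies the null: the threshold is the first
crossing of two weighted component densities beyond the point where the
control density has effectively vanished, and every component with mean
below the threshold belongs to the null.  Cells whose log intensity exceeds
the threshold are called positive.  Thresholds are always derived per
replicate row, never pooled across plates: staining and acquisition vary
enough between rows and plates that one global threshold misclassifies.

Positivity booleans combine into phenotype classes; for the K14/K19 panel
these are the four quadrants DN, K14+, K19+, DP.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gaussian_kde, norm

QUADRANT_PANEL = ("K14", "K19")

#: column schemas of the gate/frequency CSV outputs
GATES_COLUMNS = ["marker", "replicate_row", "threshold", "n_components",
                 "weights", "means", "sds", "null_components"]


class InsufficientDataError(ValueError):
    """Too few finite values to fit a gate."""


class DegenerateFitError(ValueError):
    """All values identical; mixture fit undefined."""


class MissingControlError(ValueError):
    """A secondary-only control well is required but absent."""


@dataclass
class MixtureFit:
    """A 1-D normal mixture on the natural-log intensity scale."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n: int

    @property
    def k(self) -> int:
        return len(self.weights)

    def bic(self) -> float:
        n_params = 3 * self.k - 1
        return n_params * np.log(self.n) - 2.0 * self.loglik

    def component_density(self, i: int, x: np.ndarray) -> np.ndarray:
        return self.weights[i] * norm.pdf(x, self.means[i], self.sds[i])


@dataclass
class MarkerGate:
    """Fitted mixture plus positivity threshold for one marker in one row."""

    marker: str
    replicate_row: str
    fit: MixtureFit
    threshold: float | None = None
    null_component_ids: list[int] = dfield(default_factory=list)
    used_fallback: bool = False


def fit_normal_mixture(x: np.ndarray, k: int, tol: float = 1e-8,
                       max_iter: int = 500) -> MixtureFit:
    """EM fit of a k-component 1-D normal mixture.

    Initialisation is deterministic (component means at sample quantiles,
    equal weights), so the fit depends only on the data.  Component scales
    are floored at 1e-3 times the sample SD to avoid variance collapse onto
    single points.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 50:
        raise InsufficientDataError(f"need >= 50 finite values, got {n}")
    sd = x.std()
    if sd == 0:
        raise DegenerateFitError("all values identical")

    q = (np.arange(k) + 0.5) / k
    means = np.quantile(x, q)
    sds = np.full(k, sd / k + 1e-12)
    weights = np.full(k, 1.0 / k)
    floor = 1e-3 * sd
    loglik = -np.inf
    for _ in range(max_iter):
        comp = weights * norm.pdf(x[:, None], means, sds)
        tot = comp.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        new_loglik = float(np.log(tot).sum())
        r = comp / tot[:, None]
        nk = r.sum(axis=0)
        weights = nk / n
        means = (r * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        var = (r * (x[:, None] - means) ** 2).sum(axis=0) / np.maximum(nk, 1e-12)
        sds = np.sqrt(np.maximum(var, floor**2))
        if abs(new_loglik - loglik) < tol * (1 + abs(new_loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    order = np.argsort(means)
    return MixtureFit(weights[order], means[order], sds[order],
                      loglik=loglik, n=n)


def fit_log_intensity_mixture(log_values, k: int | str = 2,
                              marker: str = "", replicate_row: str = "",
                              max_k: int = 4) -> MarkerGate:
    """Fit the row-wise log-intensity mixture for one marker.

    ``log_values`` are natural-log mean intensities of all cells in one
    replicate row pooled with its control well.  ``k`` is the component
    count (default two: negative and positive); ``k="bic"`` selects
    2..``max_k`` components by BIC, accommodating skewed null populations.
    """
    if k == "bic":
        fits = [fit_normal_mixture(log_values, kk) for kk in range(2, max_k + 1)]
        fit = min(fits, key=lambda f: f.bic())
    else:
        fit = fit_normal_mixture(log_values, int(k))
    return MarkerGate(marker=marker, replicate_row=replicate_row, fit=fit)


def two_normal_crossing(w1, m1, s1, w2, m2, s2) -> float:
    """Analytic crossing of two weighted normal densities between their means.

    Solves the log-density equality (a quadratic in x) and returns the root
    inside (min(m1,m2), max(m1,m2)); used both by the threshold search and
    as an independent oracle in validation.
    """
    if m1 > m2:
        w1, m1, s1, w2, m2, s2 = w2, m2, s2, w1, m1, s1
    a = 0.5 * (1.0 / s1**2 - 1.0 / s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = 0.5 * (m1**2 / s1**2 - m2**2 / s2**2) \
        + np.log((w2 / s2) / (w1 / s1))
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            raise ValueError("densities do not cross")
        roots = np.array([-c / b])
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("densities do not cross")
        roots = np.array([(-b - np.sqrt(disc)) / (2 * a),
                          (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    if len(inside) == 0:
        raise ValueError("no crossing between the component means")
    return float(inside.min())


def derive_threshold(gate: MarkerGate, control_log_values,
                     epsilon_frac: float = 1e-3,
                     fallback_quantile: float = 0.999,
                     grid_points: int = 512) -> float:
    """Anchor the positivity threshold to the secondary-only control.

    The control's kernel density (512-point grid spanning its data range
    ± 3 bandwidths) identifies x0, the control mode: beyond it the control
    density only decays toward zero.  The threshold is the first crossing
    of two weighted component densities at x > x0 — equivalently the first
    point past x0 where the locally dominant component changes — which for
    a negative/positive pair is their density intersection.  If no crossing
    exists beyond x0 (positive population absent, or its density everywhere
    below the control's by the ``epsilon_frac`` vanishing check) the
    control's upper quantile is the conservative fallback.  Components with
    mean below the threshold form the null.
    """
    ctrl = np.asarray(control_log_values, dtype=float)
    ctrl = ctrl[np.isfinite(ctrl)]
    if len(ctrl) < 50:
        raise MissingControlError(
            "a secondary-only control well with >= 50 cells is required "
            "for every replicate row"
        )
    if ctrl.std() == 0:
        x0 = float(ctrl[0])
    else:
        kde = gaussian_kde(ctrl)
        bw = kde.factor * ctrl.std()
        grid = np.linspace(ctrl.min() - 3 * bw, ctrl.max() + 3 * bw,
                           grid_points)
        dens = kde(grid)
        # past the mode the control population only approaches zero;
        # crossings below/inside its bulk are not candidate thresholds
        x0 = float(grid[int(np.argmax(dens))])

    fit = gate.fit
    hi = float(np.max(fit.means + 4 * fit.sds))
    tau = None
    if hi > x0:
        xs = np.linspace(x0, hi, 4096)
        dens_c = np.stack([fit.component_density(i, xs)
                           for i in range(fit.k)])
        dominant = np.argmax(dens_c, axis=0)
        switches = np.nonzero(np.diff(dominant) != 0)[0]
        for s in switches:
            i, j = int(dominant[s]), int(dominant[s + 1])
            # a crossing between collapsed (heavily overlapping) components
            # is a fitting artefact of unimodal data, not a null/positive
            # boundary; genuine marker gates sit >= 2.5 pooled SDs apart
            if abs(fit.means[j] - fit.means[i]) \
                    < 1.5 * max(fit.sds[i], fit.sds[j]):
                continue
            f = lambda x: fit.component_density(i, np.array([x]))[0] \
                - fit.component_density(j, np.array([x]))[0]
            try:
                tau = brentq(f, xs[s], xs[s + 1])
            except ValueError:
                tau = float(xs[s])
            break  # ties broken by smallest x

    used_fallback = tau is None
    if used_fallback:
        tau = float(np.quantile(ctrl, fallback_quantile))
    gate.threshold = float(tau)
    gate.used_fallback = used_fallback
    gate.null_component_ids = [i for i in range(fit.k)
                               if fit.means[i] < tau]
    if not gate.null_component_ids:
        # at least the lowest component is null by construction
        gate.null_component_ids = [int(np.argmin(fit.means))]
    return gate.threshold


# --------------------------------------------------------------------------
# classification and tables
# --------------------------------------------------------------------------

def quadrant_label(k14_pos: bool, k19_pos: bool) -> str:
    if k14_pos and k19_pos:
        return "DP"
    if k14_pos:
        return "K14+"
    if k19_pos:
        return "K19+"
    return "DN"


def safe_log(values: np.ndarray) -> np.ndarray:
    """Natural log with zero/negative protection: non-positive entries are
    offset by half the smallest positive observed value so every cell stays
    classifiable."""
    v = np.asarray(values, dtype=float)
    pos = v[v > 0]
    if len(pos) == 0:
        raise ValueError("no positive intensities to take logs of")
    offset = 0.5 * pos.min()
    return np.log(np.where(v > 0, v, offset))


def classify_cells(cells: pd.DataFrame,
                   gates: dict[tuple[str, str], MarkerGate],
                   panel: tuple[str, ...] = QUADRANT_PANEL,
                   marker_columns: dict[str, str] | None = None
                   ) -> pd.DataFrame:
    """Call per-marker positivity and phenotype class for every cell.

    ``cells`` must carry a ``replicate_row`` column; ``gates`` maps
    (replicate_row, marker) to a fitted+thresholded :class:`MarkerGate`.
    ``marker_columns`` maps marker names to intensity columns (default
    ``mean_Cy3``/``mean_Cy5`` for K14/K19).
    """
    if "replicate_row" not in cells.columns:
        raise ValueError("cells need a replicate_row column")
    marker_columns = marker_columns or {"K14": "mean_Cy3", "K19": "mean_Cy5"}
    out = cells[["plate", "well", "cell_id", "replicate_row"]].copy() \
        if "plate" in cells.columns else cells.copy()
    for marker in panel:
        col = marker_columns[marker]
        if col not in cells.columns:
            raise ValueError(f"marker column {col!r} missing from records")
        logs = safe_log(cells[col].to_numpy())
        pos = np.zeros(len(cells), dtype=bool)
        for row_id, idx in cells.groupby("replicate_row").indices.items():
            key = (str(row_id), marker)
            if key not in gates:
                raise ValueError(f"no gate for marker {marker!r} in "
                                 f"replicate row {row_id!r}")
            gate = gates[key]
            if gate.threshold is None:
                raise ValueError("gate threshold not derived")
            pos[idx] = logs[idx] > gate.threshold
        out[f"{marker}_pos"] = pos
    if set(panel) == set(QUADRANT_PANEL):
        out["phenotype"] = [
            quadrant_label(a, b)
            for a, b in zip(out["K14_pos"], out["K19_pos"])
        ]
    else:
        out["phenotype"] = [
            "/".join(f"{m}{'+' if row[f'{m}_pos'] else '-'}" for m in panel)
            for _, row in out.iterrows()
        ]
    return out


def fit_row_gates(cells: pd.DataFrame, layout,
                  panel: tuple[str, ...] = QUADRANT_PANEL,
                  marker_columns: dict[str, str] | None = None,
                  k: int | str = 2) -> dict[tuple[str, str], MarkerGate]:
    """Fit and threshold a gate for every (replicate row, marker).

    Experimental cells of the row are pooled with the row's control-well
    cells for the mixture fit; the control cells alone anchor the threshold.
    """
    marker_columns = marker_columns or {"K14": "mean_Cy3", "K19": "mean_Cy5"}
    wells = layout.wells
    cells = cells.merge(
        wells[["plate", "well", "replicate_row", "is_control"]],
        on=["plate", "well"], how="left", validate="many_to_one",
    )
    if cells["replicate_row"].isna().any():
        raise ValueError("some cells reference wells absent from the layout")
    gates: dict[tuple[str, str], MarkerGate] = {}
    for row_id, grp in cells.groupby("replicate_row"):
        ctrl = grp[grp["is_control"]]
        if ctrl.empty:
            raise MissingControlError(
                f"replicate row {row_id!r} has no secondary-only control well"
            )
        for marker in panel:
            col = marker_columns[marker]
            pooled = safe_log(grp[col].to_numpy())
            ctrl_log = safe_log(ctrl[col].to_numpy())
            gate = fit_log_intensity_mixture(pooled, k=k, marker=marker,
                                             replicate_row=str(row_id))
            derive_threshold(gate, ctrl_log)
            gates[(str(row_id), marker)] = gate
    return gates


def frequency_table(calls: pd.DataFrame, layout,
                    grouping: list[str] | None = None,
                    class_column: str = "phenotype") -> pd.DataFrame:
    """Mean subpopulation percentages ± SEM over technical-replicate wells.

    Percentages are computed per well first (each class as a percentage of
    the well's total cells, so they sum to 100 per well), then averaged over
    the wells of each group.  SEM is sd/sqrt(n) and reported missing for
    groups with a single well.  Control wells are excluded; empty wells are
    excluded with a warning.
    """
    grouping = grouping or ["donor", "dose_gy", "time_h"]
    wells = layout.wells
    cols = list(dict.fromkeys(["plate", "well", "is_control"] + grouping))
    merged = calls.merge(
        wells[cols], on=["plate", "well"], how="left",
        validate="many_to_one",
    )
    merged = merged[~merged["is_control"]]
    classes = sorted(merged[class_column].unique())
    per_well = []
    for (plate, well), grp in merged.groupby(["plate", "well"]):
        n = len(grp)
        if n == 0:
            warnings.warn(f"well {well} on {plate} is empty; excluded")
            continue
        pct = grp[class_column].value_counts(normalize=True) * 100.0
        rec = {"plate": plate, "well": well}
        rec.update(grp.iloc[0][grouping].to_dict())
        for cls in classes:
            rec[cls] = float(pct.get(cls, 0.0))
        per_well.append(rec)
    pw = pd.DataFrame(per_well)
    rows = []
    for keys, grp in pw.groupby(grouping):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rec = dict(zip(grouping, keys))
        rec["n_wells"] = len(grp)
        for cls in classes:
            vals = grp[cls].to_numpy()
            rec[f"{cls}_mean_pct"] = float(vals.mean())
            rec[f"{cls}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1 else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def overlap_table(calls: pd.DataFrame,
                  markers: tuple[str, ...]) -> pd.DataFrame:
    """Counts and percentages of every marker-combination region.

    For n markers all 2^n disjoint regions are reported (region counts sum
    to the total cell count) together with per-marker marginal positives.
    """
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    flags = {m: calls[f"{m}_pos"].to_numpy(dtype=bool) for m in markers}
    n_total = len(calls)
    rows = []
    for combo in itertools.product([True, False], repeat=len(markers)):
        mask = np.ones(n_total, dtype=bool)
        for m, want in zip(markers, combo):
            mask &= flags[m] == want
        label = "/".join(f"{m}{'+' if w else '-'}"
                         for m, w in zip(markers, combo))
        count = int(mask.sum())
        rows.append({"region": label, "count": count,
                     "percent": 100.0 * count / n_total if n_total else 0.0})
    for m in markers:
        count = int(flags[m].sum())
        rows.append({"region": f"{m}+ (marginal)", "count": count,
                     "percent": 100.0 * count / n_total if n_total else 0.0})
    rows.append({"region": "total", "count": n_total, "percent": 100.0})
    return pd.DataFrame(rows)


def gates_to_frame(gates: dict[tuple[str, str], MarkerGate]) -> pd.DataFrame:
    """Serialize gates for gates.csv."""
    rows = []
    for (row_id, marker), g in sorted(gates.items()):
        rows.append({
            "marker": marker,
            "replicate_row": row_id,
            "threshold": g.threshold,
            "n_components": g.fit.k,
            "weights": ";".join(f"{w:.6g}" for w in g.fit.weights),
            "means": ";".join(f"{m:.6g}" for m in g.fit.means),
            "sds": ";".join(f"{s:.6g}" for s in g.fit.sds),
            "null_components": ";".join(map(str, g.null_component_ids)),
        })
    return pd.DataFrame(rows, columns=GATES_COLUMNS)
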