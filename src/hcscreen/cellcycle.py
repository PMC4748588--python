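"""Cell-cycle phase assignment from DNA content (integrated nuclear DAPI).

Per well, the distribution of per-cell total DAPI intensity shows a 2n (G1)
peak and a 4n (G2/M) peak at roughly twice its location.  A two-component
t-distribution mixture is fitted by EM (degrees of freedom selected from a
fixed grid for stability on small wells), and four cut-points delimit the
five compartments sub-G1 | G1 | S | G2/M | post-G2:

    c0 = mu1 - z*s1,  c1 = mu1 + z*s1,  c2 = mu2 - z*s2,  c3 = mu2 + z*s2

with multiplier z = 2 by default.  An alternative "crossing" mode places
c1/c2 at the weighted-density intersection of the two peaks instead.
EdU incorporation, when imaged, is gated by the same control-anchored
mixture-threshold procedure used for phenotype markers and cross-tabulated
against the DNA-content phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import t as t_dist

from .gating import (InsufficientDataError, MarkerGate, MissingControlError,
                     derive_threshold, fit_log_intensity_mixture, safe_log)

PHASE_ORDER = ("subG1", "G1", "S", "G2M", "postG2")
DF_GRID = (3.0, 5.0, 8.0, 12.0, 20.0, 30.0)

FITS_COLUMNS = ["plate", "well", "mu1", "s1", "nu1", "mu2", "s2", "nu2",
                "w1", "w2", "c0", "c1", "c2", "c3", "z", "flags"]


@dataclass
class CellCycleFit:
    """Two-peak t-mixture with the four phase cut-points for one well."""

    mu1: float
    s1: float
    nu1: float
    mu2: float
    s2: float
    nu2: float
    w1: float
    w2: float
    c0: float
    c1: float
    c2: float
    c3: float
    z: float = 2.0
    flags: list[str] = field(default_factory=list)

    @property
    def cutpoints(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2, self.c3])

    @property
    def ratio(self) -> float:
        return self.mu2 / self.mu1


def _t_mixture_em(x: np.ndarray, nu: float, mu_init, s_init, w_init,
                  scale_cap_frac: float = 0.09,
                  ratio_box: tuple[float, float] = (1.6, 2.4),
                  tol: float = 1e-8, max_iter: int = 300):
    """Constrained EM for two t peaks plus a fixed uniform background.

    Three stabilizers keep the components on the 2n and 4n peaks instead of
    the S-phase plateau and debris between/beyond them: a uniform
    background component (density 1/range, weight estimated) that absorbs
    non-peak cells; a cap on each peak's coefficient of variation
    (``scale_cap_frac``, default 9 % — DNA-content peaks of usable imaging
    quality are tighter than this, while an uncapped second component
    happily widens to swallow the S band); and projection of the second
    location into ``ratio_box`` times the first (the 2n/4n prior, matching
    the accepted-fit invariant).  Returns the two t components' weights
    (renormalized), locations and scales plus the log-likelihood.
    """
    mu = np.asarray(mu_init, dtype=float).copy()
    s = np.asarray(s_init, dtype=float).copy()
    w = np.concatenate([0.9 * np.asarray(w_init, dtype=float), [0.1]])
    n = len(x)
    floor = 1e-3 * x.std()
    u_dens = 1.0 / max(x.max() - x.min(), 1e-12)
    loglik = -np.inf
    for _ in range(max_iter):
        dens_t = w[:2] * t_dist.pdf((x[:, None] - mu) / s, df=nu) / s
        dens = np.column_stack([dens_t, np.full(n, w[2] * u_dens)])
        tot = np.maximum(dens.sum(axis=1), 1e-300)
        new_loglik = float(np.log(tot).sum())
        r = dens / tot[:, None]
        delta2 = ((x[:, None] - mu) / s) ** 2
        u = (nu + 1.0) / (nu + delta2)
        ru = r[:, :2] * u
        nk = r.sum(axis=0)
        w = nk / n
        mu = (ru * x[:, None]).sum(axis=0) / np.maximum(ru.sum(axis=0), 1e-12)
        mu[1] = np.clip(mu[1], ratio_box[0] * mu[0], ratio_box[1] * mu[0])
        var = (ru * (x[:, None] - mu) ** 2).sum(axis=0) \
            / np.maximum(nk[:2], 1e-12)
        s = np.sqrt(np.maximum(var, floor**2))
        s = np.minimum(s, scale_cap_frac * mu)
        if abs(new_loglik - loglik) < tol * (1 + abs(new_loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    w_t = w[:2] / max(w[:2].sum(), 1e-12)
    return w_t, mu, s, loglik


def fit_dna_content(masses, z: float = 2.0,
                    df_grid: tuple[float, ...] = DF_GRID,
                    cutpoint_method: str = "multiplier",
                    g2_ratio_hint: float = 2.0) -> CellCycleFit:
    """Fit the two-peak DNA-content model for one well.

    Requires at least 200 cells.  The EM is initialised at the dominant
    histogram peak and ``g2_ratio_hint`` times it (the 4n prior), and the
    common df is chosen from ``df_grid`` by likelihood.  If the fitted
    second peak carries < 5 % of the mass or collapses onto the first, the
    fit is flagged ``unimodal``; if the G1/S and S/G2 cut-points cross,
    both are replaced by the midpoint of the peaks and ``peaks_merged`` is
    flagged.  Accepted two-peak fits with a location ratio outside
    [1.6, 2.4] are flagged ``ratio_out_of_range``.
    """
    x = np.asarray(masses, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < 200:
        raise InsufficientDataError(
            f"need >= 200 cells to fit DNA content, got {len(x)}"
        )
    # deterministic init: dominant mode from a coarse histogram
    hist, edges = np.histogram(x, bins=64)
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    med = np.median(x)
    mu1_init = min(mode, med)
    mu_init = np.array([mu1_init, g2_ratio_hint * mu1_init])
    s_init = np.full(2, 0.06 * mu1_init)
    w_init = np.array([0.7, 0.3])

    best = None
    for nu in df_grid:
        w, mu, s, ll = _t_mixture_em(x, nu, mu_init, s_init, w_init)
        if best is None or ll > best[-1]:
            best = (nu, w, mu, s, ll)
    nu, w, mu, s, _ = best
    order = np.argsort(mu)
    w, mu, s = w[order], mu[order], s[order]

    flags: list[str] = []
    if w[1] < 0.05 or (mu[1] - mu[0]) < 2.0 * max(s[0], s[1]):
        flags.append("unimodal")
    elif not (1.6 <= mu[1] / mu[0] <= 2.4):
        flags.append("ratio_out_of_range")

    c0 = mu[0] - z * s[0]
    c3 = mu[1] + z * s[1]
    if cutpoint_method == "multiplier":
        c1 = mu[0] + z * s[0]
        c2 = mu[1] - z * s[1]
    elif cutpoint_method == "crossing":
        c1 = c2 = _weighted_t_crossing(w, mu, s, nu)
    else:
        raise ValueError(f"unknown cutpoint_method {cutpoint_method!r}")
    if c1 >= c2:
        mid = 0.5 * (mu[0] + mu[1])
        c1 = c2 = mid
        if cutpoint_method == "multiplier":
            flags.append("peaks_merged")

    return CellCycleFit(mu1=float(mu[0]), s1=float(s[0]), nu1=float(nu),
                        mu2=float(mu[1]), s2=float(s[1]), nu2=float(nu),
                        w1=float(w[0]), w2=float(w[1]),
                        c0=float(c0), c1=float(c1), c2=float(c2),
                        c3=float(c3), z=z, flags=flags)


def _weighted_t_crossing(w, mu, s, nu) -> float:
    """Crossing of the two weighted t densities between the peak locations."""
    f = lambda x: (w[0] * t_dist.pdf((x - mu[0]) / s[0], nu) / s[0]
                   - w[1] * t_dist.pdf((x - mu[1]) / s[1], nu) / s[1])
    lo, hi = mu[0], mu[1]
    if f(lo) * f(hi) > 0:
        return 0.5 * (lo + hi)
    return float(brentq(f, lo, hi))


def assign_phase(masses, fit: CellCycleFit) -> np.ndarray:
    """Phase per cell from DNA mass and the fit's cut-points.

    Intervals are half-open, lower-inclusive: mass < c0 is sub-G1, [c0, c1)
    G1, [c1, c2) S, [c2, c3) G2/M and >= c3 post-G2 (so a mass exactly at
    c1 is S).
    """
    m = np.asarray(masses, dtype=float)
    idx = np.searchsorted(fit.cutpoints, m, side="right")
    return np.asarray(PHASE_ORDER)[idx]


def phase_fractions(phases) -> dict[str, float]:
    """Fraction of cells in each compartment; sums to 1 exactly."""
    s = pd.Series(phases)
    frac = s.value_counts(normalize=True)
    return {p: float(frac.get(p, 0.0)) for p in PHASE_ORDER}


def edu_gate(edu_totals, control_edu_totals) -> tuple[np.ndarray, MarkerGate]:
    """EdU positivity by the control-anchored mixture-threshold procedure.

    Applies the phenotype-gating machinery to log total EdU intensity:
    experimental cells pooled with the EdU-negative control population for
    the mixture fit, the control anchoring the threshold.  Returns the
    per-cell boolean flags and the fitted gate.
    """
    edu = np.asarray(edu_totals, dtype=float)
    if control_edu_totals is None or len(np.asarray(control_edu_totals)) == 0:
        raise MissingControlError("edu_gate requires a control population")
    ctrl = np.asarray(control_edu_totals, dtype=float)
    pooled = safe_log(np.concatenate([edu, ctrl]))
    gate = fit_log_intensity_mixture(pooled, k=2, marker="EdU")
    derive_threshold(gate, safe_log(ctrl))
    return safe_log(edu) > gate.threshold, gate


def fit_wells(cells: pd.DataFrame, z: float = 2.0,
              min_cells: int = 200,
              cutpoint_method: str = "multiplier"):
    """Fit DNA content and assign phases for every well of a cell table.

    Returns (fits DataFrame in the cellcycle_fits.csv schema, phases
    DataFrame with cell_id and phase).  Wells below ``min_cells`` are
    skipped with a flag row.
    """
    fit_rows = []
    phase_frames = []
    for (plate, well), grp in cells.groupby(["plate", "well"]):
        try:
            fit = fit_dna_content(grp["dapi_mass"].to_numpy(), z=z,
                                  cutpoint_method=cutpoint_method)
        except InsufficientDataError:
            fit_rows.append({"plate": plate, "well": well,
                             "flags": "insufficient_data"})
            continue
        fit_rows.append({
            "plate": plate, "well": well,
            "mu1": fit.mu1, "s1": fit.s1, "nu1": fit.nu1,
            "mu2": fit.mu2, "s2": fit.s2, "nu2": fit.nu2,
            "w1": fit.w1, "w2": fit.w2,
            "c0": fit.c0, "c1": fit.c1, "c2": fit.c2, "c3": fit.c3,
            "z": fit.z, "flags": ";".join(fit.flags),
        })
        phase_frames.append(pd.DataFrame({
            "plate": plate, "well": well,
            "cell_id": grp["cell_id"].to_numpy(),
            "phase": assign_phase(grp["dapi_mass"].to_numpy(), fit),
        }))
    fits = pd.DataFrame(fit_rows, columns=FITS_COLUMNS)
    phases = (pd.concat(phase_frames, ignore_index=True)
              if phase_frames else
              pd.DataFrame(columns=["plate", "well", "cell_id", "phase"]))
    phases["edu_positive"] = pd.NA
    return fits, phases
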