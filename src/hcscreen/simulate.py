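"""Seeded synthetic-plate simulator.

Generates multi-channel fluorescence field images of mixed mammary
epithelial cultures together with the ground-truth cell table and plate
layout that the downstream analysis stages assume:

* four phenotype classes (DN, K14+, K19+, DP) drawn from configurable
  proportions, with per-marker log-normal positive/negative intensity
  components so pooled log-intensity histograms are bimodal;
* secondary-antibody-only control wells whose marker channels show only the
  shared background (negative) component;
* a 2n/4n DNA-content model (t-distributed G1/G2 peaks, uniform S and
  sub-G1/post-G2 bands) driving integrated nuclear DAPI intensity;
* dose- and time-dependent γH2AX induction with "resolver" and
  "non-resolver" donor archetypes;
* exponential growth with per-class doubling times, slowed by ionising
  radiation in a dose-dependent way.

Nuclei are rendered as anti-aliased filled ellipses (eccentricity ≤ 0.6 so
true circularity stays above the segmentation pass band), blurred slightly
and overlaid with Gaussian read noise.  Each well draws from its own random
stream derived from (master seed, well id), so outputs are byte-identical
for a given seed regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .layout import FieldGrid, PlateLayout, make_row_layout

CHANNEL_NAMES = ["DAPI", "FITC", "Cy3", "Cy5"]
CLASSES = ("DN", "K14+", "K19+", "DP")
PHASES = ("subG1", "G1", "S", "G2M", "postG2")
GAMMA_TIMES = (0.0, 1.0, 2.0, 6.0, 24.0, 48.0)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class CapacityError(RuntimeError):
    """Requested cell count does not fit in the field at the allowed overlap."""


# --------------------------------------------------------------------------
# configuration blocks
# --------------------------------------------------------------------------

@dataclass
class MarkerModel:
    """Log-normal intensity model of one marker.

    Locations/scales are on the natural-log intensity scale.  The negative
    (background) component is shared between marker-negative cells and
    secondary-only control wells, which is what makes the control-anchored
    gating threshold well defined.
    """

    channel: str
    positive_classes: tuple[str, ...]
    #: defaults give ~5.3 pooled-SD separation between the components —
    #: the regime where the quadrant classifier's Bayes error is < 2 %,
    #: matching well-stained cytokeratin panels
    pos_loc: float = 5.0
    pos_scale: float = 0.40
    neg_loc: float = 3.0
    neg_scale: float = 0.35

    def validate(self, name: str) -> None:
        if self.pos_scale <= 0 or self.neg_scale <= 0:
            raise ConfigurationError(f"marker {name}: scales must be > 0")
        if self.channel not in CHANNEL_NAMES[1:]:
            raise ConfigurationError(f"marker {name}: unknown channel")


@dataclass
class DnaContentModel:
    """DNA-content (integrated DAPI) model.

    G1 and G2/M peaks are t-distributed around ``g1_mass`` and
    ``g2_ratio * g1_mass``; S, sub-G1 and post-G2 cells fill uniform bands
    between/beyond the peaks, delimited at ``z_band`` peak scales.  A
    near-normal default df keeps band leakage at the downstream z = 2
    cut-points small relative to the assay's phase-fraction tolerance.
    """

    g1_mass: float = 20000.0
    g2_ratio: float = 2.0
    phase_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "subG1": 0.05, "G1": 0.55, "S": 0.15, "G2M": 0.20, "postG2": 0.05,
        }
    )
    t_scale_frac: float = 0.05   # peak scale as a fraction of peak location
    t_df: float = 12.0
    z_band: float = 2.0

    def validate(self) -> None:
        tot = sum(self.phase_fractions.get(p, 0.0) for p in PHASES)
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError("phase fractions must sum to 1")
        if self.g2_ratio <= 1.0:
            raise ConfigurationError("G2/G1 ratio must exceed 1")
        if self.g1_mass <= 0 or self.t_scale_frac <= 0:
            raise ConfigurationError("DNA-content scales must be > 0")


@dataclass
class GammaKinetics:
    """Dose/time course of mean specific nuclear γH2AX intensity (a.u.).

    Mean level at dose d and time t is ``baseline + amp_per_gy * d *
    shape[t]`` where the shape profile depends on the donor archetype:
    resolvers peak at 1 h and return close to baseline by 24 h,
    non-resolvers keep ≥ 80 % of the 1-h peak through 24–48 h.
    """

    archetype: str = "resolver"
    baseline: float = 30.0
    amp_per_gy: float = 40.0
    secondary_background: float = 25.0
    noise_sigma_log: float = 0.30
    doses: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0)
    shapes: dict[str, dict[float, float]] = field(
        default_factory=lambda: {
            "resolver": {0.0: 0.0, 1.0: 1.0, 2.0: 0.75, 6.0: 0.45,
                         24.0: 0.08, 48.0: 0.04},
            "non_resolver": {0.0: 0.0, 1.0: 1.0, 2.0: 0.95, 6.0: 0.90,
                             24.0: 0.85, 48.0: 0.82},
        }
    )

    def mean_level(self, dose: float, time_h: float) -> float:
        """Mean specific γH2AX at (dose, time); excludes secondary background."""
        if dose not in self.doses:
            raise ConfigurationError(f"dose {dose} Gy not in configured set")
        if time_h not in self.shapes[self.archetype]:
            raise ConfigurationError(f"time {time_h} h not in configured set")
        return self.baseline + self.amp_per_gy * dose * \
            self.shapes[self.archetype][time_h]

    def validate(self) -> None:
        if self.archetype not in self.shapes:
            raise ConfigurationError(f"unknown archetype {self.archetype!r}")
        if self.noise_sigma_log <= 0:
            raise ConfigurationError("gamma noise sigma must be > 0")


@dataclass
class GrowthModel:
    """Exponential growth: per-class doubling times (h) and a multiplicative
    dose-dependent inhibition factor on the growth slope."""

    doubling_time_h: dict[str, float] = field(
        default_factory=lambda: {"DN": 60.0, "K14+": 30.0, "K19+": 28.0,
                                 "DP": 24.0}
    )
    dose_inhibition: dict[float, float] = field(
        default_factory=lambda: {0.0: 1.0, 1.0: 0.8, 2.0: 0.6, 5.0: 0.3}
    )

    def validate(self) -> None:
        for c, dt in self.doubling_time_h.items():
            if dt <= 0:
                raise ConfigurationError(f"doubling time for {c} must be > 0")


@dataclass
class Geometry:
    """Acquisition geometry: a fixed grid of fields per well."""

    fields_per_well: int = 25
    grid: tuple[int, int] = (5, 5)
    field_spacing_um: float = 100.0
    image_size_px: int = 512
    pixel_size_um: float = 0.65

    def validate(self) -> None:
        if self.grid[0] * self.grid[1] != self.fields_per_well:
            raise ConfigurationError("field grid does not match fields_per_well")
        if self.image_size_px < 32 or self.pixel_size_um <= 0:
            raise ConfigurationError("invalid image geometry")


@dataclass
class SimulationConfig:
    """Full configuration of one simulated plate experiment."""

    phenotype_proportions: dict[str, float] = field(
        default_factory=lambda: {"K19+": 0.406, "K14+": 0.252,
                                 "DP": 0.229, "DN": 0.113}
    )
    cells_per_well: int = 2000
    wells_per_condition: int = 5
    markers: dict[str, MarkerModel] = field(
        default_factory=lambda: {
            "K14": MarkerModel(channel="Cy3",
                               positive_classes=("K14+", "DP")),
            "K19": MarkerModel(channel="Cy5",
                               positive_classes=("K19+", "DP")),
        }
    )
    dna_content: DnaContentModel = field(default_factory=DnaContentModel)
    gamma_h2ax: GammaKinetics = field(default_factory=GammaKinetics)
    growth: GrowthModel = field(default_factory=GrowthModel)
    geometry: Geometry = field(default_factory=Geometry)
    #: what the FITC channel carries: "gamma" (γH2AX), "edu", or "marker"
    fitc_content: str = "gamma"
    edu_positive_log_shift: float = math.log(10.0)
    nucleus_area_um2: float = 110.0
    nucleus_area_sd_um2: float = 20.0
    max_eccentricity: float = 0.6
    max_overlap_fraction: float = 0.0
    #: extra centre-to-centre clearance (px) beyond the touching distance,
    #: so "non-overlapping" nuclei remain resolvable after the blur
    placement_buffer_px: float = 5.0
    noise_sigma: float = 2.0
    blur_sigma: float = 1.0
    apply_growth: bool = True
    seed: int = 0

    def validate(self) -> None:
        tot = sum(self.phenotype_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phenotype proportions sum to {tot}, not 1"
            )
        for cls in self.phenotype_proportions:
            if cls not in CLASSES:
                raise ConfigurationError(f"unknown phenotype class {cls!r}")
        for name, m in self.markers.items():
            m.validate(name)
        if self.fitc_content not in ("gamma", "edu", "marker"):
            raise ConfigurationError("fitc_content must be gamma/edu/marker")
        self.dna_content.validate()
        self.gamma_h2ax.validate()
        self.growth.validate()
        self.geometry.validate()
        if not (0 <= self.max_overlap_fraction < 1):
            raise ConfigurationError("max_overlap_fraction must be in [0, 1)")


# --------------------------------------------------------------------------
# per-well random streams
# --------------------------------------------------------------------------

def well_rng(seed: int, plate: str, well: str) -> np.random.Generator:
    """Independent stream for one well, derived from (master seed, well id)."""
    plate_code = sum(ord(c) * 31**i for i, c in enumerate(str(plate))) % 2**31
    well_code = sum(ord(c) * 131**i for i, c in enumerate(str(well))) % 2**31
    return np.random.default_rng([int(seed) % 2**31, plate_code, well_code])


# --------------------------------------------------------------------------
# growth
# --------------------------------------------------------------------------

def class_counts_at_time(config: SimulationConfig, dose: float, time_h: float,
                         count0: float | None = None) -> dict[str, float]:
    """Expected per-class cell counts at a (dose, time) condition."""
    if dose not in config.growth.dose_inhibition:
        raise ConfigurationError(f"dose {dose} Gy not configured for growth")
    inh = config.growth.dose_inhibition[dose]
    n0 = config.cells_per_well if count0 is None else count0
    out = {}
    for cls, p in config.phenotype_proportions.items():
        b = inh / config.growth.doubling_time_h[cls]
        out[cls] = n0 * p * 2.0 ** (time_h * b)
    return out


def growth_series(config: SimulationConfig, dose: float, times,
                  phenotype: str | None = None,
                  count0: float | None = None) -> np.ndarray:
    """Expected cell counts over ``times`` for one dose.

    With ``phenotype`` the series is that class alone (started from its share
    of ``count0``); otherwise the total over classes.  Inhibition acts
    multiplicatively on the growth slope, so for any positive inhibition the
    treated series never exceeds the untreated one at positive times.
    """
    times = np.asarray(list(times), dtype=float)
    bad = [t for t in times if t not in GAMMA_TIMES]
    if bad:
        raise ConfigurationError(f"times {bad} outside the design set")
    counts = []
    for t in times:
        per_class = class_counts_at_time(config, dose, float(t), count0)
        if phenotype is not None:
            if phenotype not in per_class:
                raise ConfigurationError(f"unknown phenotype {phenotype!r}")
            counts.append(per_class[phenotype])
        else:
            counts.append(sum(per_class.values()))
    return np.asarray(counts)


# --------------------------------------------------------------------------
# per-cell draws (tabular ground truth)
# --------------------------------------------------------------------------

def _truncated_t(rng: np.random.Generator, df: float, z: float) -> float:
    # rejection sampling; acceptance ~0.93 even at df 3, z 2
    while True:
        v = rng.standard_t(df)
        if abs(v) <= z:
            return v


def _draw_dna_mass(rng: np.random.Generator, phase: str,
                   dna: DnaContentModel) -> float:
    """DNA mass given phase: disjoint bands delimited at z_band peak scales.

    Peaks are t-distributed *truncated* to their band, S/sub-G1/post-G2
    uniform between/beyond, so a cell's phase label and its DNA-content
    band agree by construction — the idealisation the band-cut phase
    caller targets.
    """
    mu1 = dna.g1_mass
    mu2 = dna.g1_mass * dna.g2_ratio
    s1 = dna.t_scale_frac * mu1
    s2 = dna.t_scale_frac * mu2
    z = dna.z_band
    if phase == "G1":
        return mu1 + s1 * _truncated_t(rng, dna.t_df, z)
    if phase == "G2M":
        return mu2 + s2 * _truncated_t(rng, dna.t_df, z)
    if phase == "S":
        return rng.uniform(mu1 + z * s1, mu2 - z * s2)
    if phase == "subG1":
        return rng.uniform(0.35 * mu1, mu1 - z * s1)
    if phase == "postG2":
        return rng.uniform(mu2 + z * s2, 1.55 * mu2)
    raise ConfigurationError(f"unknown phase {phase!r}")


def draw_well_cells(config: SimulationConfig, well_meta: dict,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw the ground-truth cell table for one well (no rendering).

    ``well_meta`` is one layout row as a dict (needs plate, well, dose_gy,
    time_h, is_control).  Marker values of secondary-only control wells are
    drawn from the shared negative component regardless of true class.
    """
    dose = float(well_meta["dose_gy"])
    time_h = float(well_meta["time_h"])
    is_control = bool(well_meta["is_control"])

    classes = list(config.phenotype_proportions)
    probs = np.array([config.phenotype_proportions[c] for c in classes])
    if config.apply_growth:
        per_class = class_counts_at_time(config, dose, time_h)
        expected = np.array([per_class[c] for c in classes])
        n = int(round(expected.sum()))
        probs = expected / expected.sum()
    else:
        n = config.cells_per_well
    draw = rng.multinomial(n, probs)
    cls = np.repeat(classes, draw)
    rng.shuffle(cls)

    phases = list(config.dna_content.phase_fractions)
    pfrac = np.array([config.dna_content.phase_fractions[p] for p in phases])
    phase = np.asarray(phases)[rng.choice(len(phases), size=n, p=pfrac)]
    mass = np.array([_draw_dna_mass(rng, p, config.dna_content) for p in phase])

    area = np.clip(
        rng.normal(config.nucleus_area_um2, config.nucleus_area_sd_um2, n),
        0.55 * config.nucleus_area_um2, 2.2 * config.nucleus_area_um2,
    )
    ecc = rng.uniform(0.0, config.max_eccentricity, n)
    theta = rng.uniform(0.0, math.pi, n)

    df = pd.DataFrame({
        "plate": well_meta["plate"],
        "well": well_meta["well"],
        "cell_index": np.arange(1, n + 1),
        "true_class": cls,
        "true_phase": phase,
        "dapi_mass_true": mass,
        "area_um2_true": area,
        "eccentricity": ecc,
        "orientation": theta,
    })

    for name, m in config.markers.items():
        pos = np.isin(cls, m.positive_classes) & (not is_control)
        logv = np.where(pos, rng.normal(m.pos_loc, m.pos_scale, n),
                        rng.normal(m.neg_loc, m.neg_scale, n))
        df[f"true_{name}_pos"] = pos
        df[f"value_{name}"] = np.exp(logv)

    g = config.gamma_h2ax
    lam = g.mean_level(dose, time_h) if not is_control else 0.0
    lognoise = np.exp(rng.normal(-g.noise_sigma_log**2 / 2.0,
                                 g.noise_sigma_log, n))
    df["true_gamma_mean"] = lam
    df["value_gamma"] = (g.secondary_background + lam) * lognoise

    s_phase = phase == "S"
    edu_pos = s_phase & (not is_control)
    edu_shift = np.where(edu_pos, config.edu_positive_log_shift, 0.0)
    df["true_edu_pos"] = edu_pos
    df["value_edu"] = np.exp(rng.normal(3.0 + edu_shift, 0.35, n))
    return df


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _ellipse_coverage(a: float, b: float, theta: float, cx: float, cy: float,
                      shape: tuple[int, int], supersample: int = 3):
    """Anti-aliased coverage of an ellipse; returns (slice_y, slice_x, cov)."""
    pad = int(math.ceil(a)) + 2
    x0, x1 = int(cx) - pad, int(cx) + pad + 1
    y0, y1 = int(cy) - pad, int(cy) + pad + 1
    x0c, x1c = max(x0, 0), min(x1, shape[1])
    y0c, y1c = max(y0, 0), min(y1, shape[0])
    if x0c >= x1c or y0c >= y1c:
        return None
    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    xs = np.add.outer(np.arange(x0c, x1c, dtype=float), offs).ravel()
    ys = np.add.outer(np.arange(y0c, y1c, dtype=float), offs).ravel()
    dx = xs[None, :] - cx
    dy = ys[:, None] - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = (u * u + v * v) <= 1.0
    cov = inside.reshape(y1c - y0c, ss, x1c - x0c, ss).mean(axis=(1, 3))
    return slice(y0c, y1c), slice(x0c, x1c), cov


def _place_cells(truth: pd.DataFrame, config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Assign cells to fields and non-overlapping positions within fields."""
    geo = config.geometry
    px = geo.pixel_size_um
    n = len(truth)
    fields = rng.integers(1, geo.fields_per_well + 1, size=n)
    a_px = np.sqrt(
        (truth["area_um2_true"].to_numpy() / px**2)
        / (math.pi * np.sqrt(1.0 - truth["eccentricity"].to_numpy() ** 2))
    )
    xs = np.zeros(n)
    ys = np.zeros(n)
    size = geo.image_size_px
    order = np.arange(n)
    for f in np.unique(fields):
        idx = order[fields == f]
        placed_x, placed_y, placed_r = [], [], []
        for i in idx:
            margin = a_px[i] + 3.0
            if 2 * margin >= size:
                raise CapacityError("image too small for the nucleus size")
            ok = False
            for _ in range(400):
                x = rng.uniform(margin, size - margin)
                y = rng.uniform(margin, size - margin)
                if placed_x:
                    d = np.hypot(np.array(placed_x) - x,
                                 np.array(placed_y) - y)
                    lim = (np.array(placed_r) + a_px[i]) \
                        * (1.0 - config.max_overlap_fraction) \
                        + config.placement_buffer_px \
                        * (1.0 - config.max_overlap_fraction)
                    if np.any(d < lim):
                        continue
                ok = True
                break
            if not ok:
                raise CapacityError(
                    f"cannot place {len(idx)} cells in a {size} px field at "
                    f"max overlap {config.max_overlap_fraction}"
                )
            placed_x.append(x)
            placed_y.append(y)
            placed_r.append(a_px[i])
            xs[i], ys[i] = x, y
    out = truth.copy()
    out["field"] = fields
    out["x"] = xs
    out["y"] = ys
    out["semi_major_px"] = a_px
    return out


def render_field(truth_field: pd.DataFrame,
                 config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Render one field as a (4, H, W) float32 stack (DAPI, FITC, Cy3, Cy5).

    DAPI is rendered so the integrated nuclear intensity equals the cell's
    true DNA mass; marker channels carry the cell's mean intensity; the
    FITC channel carries γH2AX (or EdU) as an integrated total.  A small
    Gaussian blur and read noise are applied after rendering.
    """
    geo = config.geometry
    size = geo.image_size_px
    stack = np.zeros((len(CHANNEL_NAMES), size, size), dtype=np.float64)
    chan_idx = {c: i for i, c in enumerate(CHANNEL_NAMES)}

    for _, cell in truth_field.iterrows():
        a = cell["semi_major_px"]
        b = a * math.sqrt(1.0 - cell["eccentricity"] ** 2)
        patch = _ellipse_coverage(a, b, cell["orientation"], cell["x"],
                                  cell["y"], (size, size))
        if patch is None:
            continue
        sy, sx, cov = patch
        total_cov = cov.sum()
        if total_cov <= 0:
            continue
        stack[chan_idx["DAPI"], sy, sx] += \
            cov * (cell["dapi_mass_true"] / total_cov)
        for name, m in config.markers.items():
            stack[chan_idx[m.channel], sy, sx] += cov * cell[f"value_{name}"]
        if config.fitc_content == "gamma":
            stack[chan_idx["FITC"], sy, sx] += \
                cov * (cell["value_gamma"] / total_cov)
        elif config.fitc_content == "edu":
            stack[chan_idx["FITC"], sy, sx] += \
                cov * (cell["value_edu"] / total_cov)

    if config.blur_sigma > 0:
        for c in range(stack.shape[0]):
            stack[c] = ndi.gaussian_filter(stack[c], config.blur_sigma)
    if config.noise_sigma > 0:
        stack += rng.normal(0.0, config.noise_sigma, stack.shape)
    return stack.astype(np.float32)


def generate_well(config: SimulationConfig, well_meta: dict,
                  seed: int | None = None):
    """Simulate one well: returns (truth table, iterator of (field, stack)).

    The iterator renders fields lazily so a full well never needs to be held
    in memory; the truth table already includes field assignments and
    positions.
    """
    rng = well_rng(seed if seed is not None else config.seed,
                   well_meta["plate"], well_meta["well"])
    truth = draw_well_cells(config, well_meta, rng)
    truth = _place_cells(truth, config, rng)
    # one child stream per field so rendering order cannot matter
    field_seeds = rng.integers(0, 2**31 - 1, size=config.geometry.fields_per_well)

    def fields():
        for f in range(1, config.geometry.fields_per_well + 1):
            frng = np.random.default_rng(field_seeds[f - 1])
            yield f, render_field(truth[truth["field"] == f], config, frng)

    return truth, fields()


@dataclass
class SimulationResult:
    layout: PlateLayout
    truth: pd.DataFrame
    images: dict | None  # {(plate, well): {field: stack}} when kept


def generate_plate(config: SimulationConfig,
                   layout: PlateLayout | None = None,
                   seed: int | None = None,
                   out_dir=None,
                   keep_images: bool = False) -> SimulationResult:
    """Simulate a whole plate.

    With ``out_dir`` every field is written as a multi-channel TIFF under
    ``fields/<well>/f<NN>.tif`` and ``truth.csv``/``layout.csv`` are emitted
    alongside; with ``keep_images`` the stacks are also returned in memory
    (only sensible for small configurations).
    """
    config.validate()
    if layout is None:
        layout = make_row_layout(
            n_replicates=config.wells_per_condition,
            grid=FieldGrid(config.geometry.grid[0], config.geometry.grid[1],
                           config.geometry.field_spacing_um),
        )
    truths = []
    images: dict = {}
    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        (out_dir / "fields").mkdir(parents=True, exist_ok=True)
    for _, wmeta in layout.wells.iterrows():
        meta = wmeta.to_dict()
        truth, fields = generate_well(config, meta, seed)
        truths.append(truth)
        well_key = (meta["plate"], meta["well"])
        if keep_images:
            images[well_key] = {}
        for f, stack in fields:
            if out_dir is not None:
                wdir = out_dir / "fields" / str(meta["well"])
                wdir.mkdir(exist_ok=True)
                tifffile.imwrite(wdir / f"f{f:02d}.tif", stack,
                                 photometric="minisblack")
            if keep_images:
                images[well_key][f] = stack
    truth_all = pd.concat(truths, ignore_index=True)
    if out_dir is not None:
        truth_all.to_csv(out_dir / "truth.csv", index=False)
        layout.save(out_dir / "layout.csv")
    return SimulationResult(layout=layout, truth=truth_all,
                            images=images if keep_images else None)


def sorted_culture_config(config: SimulationConfig,
                          proportions: dict[str, float]) -> SimulationConfig:
    """A FACS-sorted culture emulated simply as altered class proportions."""
    return replace(config, phenotype_proportions=dict(proportions))
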