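"""Synthetic study generator: phantoms and raw data with known truth.

No public dataset accompanies the rabbit study this package emulates, so
every analysis input is generated here with the statistical structure the
pipeline assumes, around a preset table whose *true* values are the study's
reported group means.  The generator therefore defines the recovery targets:
run the measurement pipeline on its noisy output and you should get the
preset truths back.

Generated modalities
--------------------
* paired inferior/superior endplate point clouds with zone-wise gap
  narrowing (micro-CT surrogate),
* lateral-radiograph height triplets (Ha, Hm, Hp) with a 10-mm calibration
  marker, on the biweekly schedule,
* multi-echo spin-echo stacks with known per-region T2 (20 echoes,
  20-400 ms, TR 2500 ms),
* seven-category histology score tables, and
* NP cell censuses (alive counts in three fields of view, clone flags).

Endplate pairs share lateral sample positions between the two plates (as if
exported from a common segmentation lattice); this makes the directed
least-distance height equal the local vertical gap exactly in the noiseless
limit.  Zone gap scales are blended smoothly across zone boundaries over a
configurable physical width (default 0.5 mm).

Everything is deterministic given a seed; ``generate_study`` spawns
independent child streams per animal and modality from one master seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .disc3d import ZONES, EndplateCloud
from .histology import CENSUS_FIELDS, SCORE_CATEGORIES, CellCensus, HistologyScore
from .study_design import StudyDesign, default_design
from .t2map import EchoStack, default_te_list

__all__ = [
    "DegenerationPreset",
    "PhantomGeometry",
    "PresetTable",
    "load_presets",
    "generate_endplate_pair",
    "generate_radiograph_series",
    "generate_radiograph_table",
    "generate_echo_stack",
    "disc_t2_phantom",
    "generate_histology_and_cells",
    "generate_study",
    "StudyData",
]

_QUADRANT_CENTER_DEG = {"anterior": 0.0, "l_lateral": 90.0, "posterior": 180.0, "r_lateral": -90.0}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# preset table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegenerationPreset:
    """True degeneration state of one (treatment, week) cell."""

    treatment: str
    week: int
    zone_gap_scale: dict[str, float]
    severity: float
    cell_survival_fraction: float
    clone_probability: float
    t2_scale: float
    histology_score_means: dict[str, float]

    def __post_init__(self) -> None:
        for z in ZONES:
            s = self.zone_gap_scale.get(z)
            if s is None or not 0.0 < s <= 1.0:
                raise ValueError(f"zone scale {z!r} must lie in (0, 1], got {s}")
        for name in ("cell_survival_fraction", "clone_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.t2_scale <= 1.0:
            raise ValueError(f"t2_scale must lie in (0, 1], got {self.t2_scale}")


@dataclass(frozen=True)
class PhantomGeometry:
    """Elliptical disc footprint and sampling parameters for phantoms."""

    a_mm: float = 7.5
    b_mm: float = 5.0
    base_gap_mm: float = 1.2
    points_per_endplate: int = 2000
    surface_roughness_sd_mm: float = 0.05
    np_fraction: float = 0.5
    blend_mm: float = 0.5

    def __post_init__(self) -> None:
        if not (self.a_mm >= self.b_mm > 0):
            raise ValueError("footprint requires a_mm >= b_mm > 0")
        if self.base_gap_mm <= 0:
            raise ValueError("base_gap_mm must be positive")
        if self.points_per_endplate <= 0:
            raise ValueError("points_per_endplate must be positive")
        if self.surface_roughness_sd_mm < 0:
            raise ValueError("surface roughness sd must be nonnegative")
        if not 0.0 < self.np_fraction < 1.0:
            raise ValueError("np_fraction must lie in (0, 1)")


@dataclass
class PresetTable:
    """The full calibration: presets per (treatment, week), radiographic
    trajectories, phantom geometry, noise levels and baselines."""

    presets: dict[tuple[str, int], DegenerationPreset]
    dhi_trajectory_pct: dict[str, dict[int, float]]
    geometry: PhantomGeometry
    noise: dict[str, float | str]
    baseline: dict[str, float]
    histology_score_range: tuple[int, int] = (0, 2)

    def preset(self, treatment: str, week: int) -> DegenerationPreset:
        try:
            return self.presets[(treatment, week)]
        except KeyError:
            raise KeyError(f"no preset for treatment {treatment!r} at week {week}") from None

    def trajectory(self, treatment: str) -> dict[int, float]:
        return self.dhi_trajectory_pct[treatment]


def _validate_monotone(presets: dict[tuple[str, int], DegenerationPreset]) -> None:
    """Degeneration must progress with time; dose ordering is checked at
    the early/mid weeks (the calibrated week-12 posterior values are
    non-monotone in dose, matching the reported data)."""
    mia = sorted({t for t, _ in presets if t.startswith("MIA")}, key=lambda s: float(s.split("_")[1]))
    weeks = sorted({w for _, w in presets})
    for t in mia:
        for z in ZONES:
            vals = [presets[(t, w)].zone_gap_scale[z] for w in weeks if (t, w) in presets]
            if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValueError(f"zone scale {z!r} for {t} must be non-increasing in week")
    for w in weeks:
        if w > 8:
            continue
        for z in ZONES:
            vals = [presets[(t, w)].zone_gap_scale[z] for t in mia if (t, w) in presets]
            if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValueError(f"zone scale {z!r} at week {w} must be non-increasing in dose")


def load_presets(path=None) -> PresetTable:
    """Load a preset YAML; default is the calibrated table shipped with the
    package."""
    if path is None:
        ref = importlib.resources.files("discdegen").joinpath("data/default_presets.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    geom = PhantomGeometry(**raw["geometry"])
    weights = raw["histology_category_weights"]
    lo, hi = raw["histology_score_range"]
    presets: dict[tuple[str, int], DegenerationPreset] = {}
    for treatment, per_week in raw["presets"].items():
        for week, cell in per_week.items():
            sev = float(cell["severity"])
            means = {c: min(float(hi), max(float(lo), weights[c] * sev)) for c in SCORE_CATEGORIES}
            presets[(treatment, int(week))] = DegenerationPreset(
                treatment=treatment,
                week=int(week),
                zone_gap_scale={z: float(v) for z, v in cell["zone_gap_scale"].items()},
                severity=sev,
                cell_survival_fraction=float(cell["cell_survival_fraction"]),
                clone_probability=float(cell["clone_probability"]),
                t2_scale=1.0 - 0.5 * sev,
                histology_score_means=means,
            )
    _validate_monotone(presets)
    traj = {
        t: {int(w): float(p) for w, p in d.items()}
        for t, d in raw["dhi_trajectory_pct"].items()
    }
    return PresetTable(
        presets=presets,
        dhi_trajectory_pct=traj,
        geometry=geom,
        noise=raw["noise"],
        baseline=raw["baseline"],
        histology_score_range=(int(lo), int(hi)),
    )


def uniform_preset_table(table: PresetTable) -> PresetTable:
    """Copy of a preset table whose gap fields are spatially uniform: every
    zone of a preset gets that cell's radiographic trajectory scale.

    With uniform gaps (and noise off) the directed least-distance height
    equals the true gap exactly, which makes this the configuration for
    machine-precision generator/pipeline consistency checks.
    """
    presets = {}
    for (t, w), p in table.presets.items():
        s = table.dhi_trajectory_pct[t][w] / 100.0
        presets[(t, w)] = DegenerationPreset(
            treatment=t, week=w, zone_gap_scale={z: s for z in ZONES},
            severity=p.severity, cell_survival_fraction=p.cell_survival_fraction,
            clone_probability=p.clone_probability, t2_scale=p.t2_scale,
            histology_score_means=dict(p.histology_score_means),
        )
    import dataclasses

    return dataclasses.replace(table, presets=presets)


# ---------------------------------------------------------------------------
# endplate phantoms
# ---------------------------------------------------------------------------


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _zone_of(rho: np.ndarray, theta_deg: np.ndarray, np_fraction: float) -> np.ndarray:
    """Sharp zone label per point (same rule as the analysis partition)."""
    labels = np.empty(rho.shape, dtype=object)
    labels[np.abs(theta_deg) <= 45.0] = "anterior"
    labels[np.abs(theta_deg) >= 135.0] = "posterior"
    lat = (np.abs(theta_deg) > 45.0) & (np.abs(theta_deg) < 135.0)
    labels[lat & (theta_deg > 0)] = "l_lateral"
    labels[lat & (theta_deg <= 0)] = "r_lateral"
    labels[rho <= np_fraction] = "np"
    return labels.astype(str)


def _gap_scale_field(
    x: np.ndarray,
    y: np.ndarray,
    preset: DegenerationPreset,
    geom: PhantomGeometry,
) -> np.ndarray:
    """Smoothly blended zone-scale field evaluated at footprint positions.

    Radial blend (NP vs annulus) and angular blend (between annulus
    quadrants) both act over ``blend_mm`` of physical distance; with
    ``blend_mm -> 0`` the field degenerates to the sharp zone map.
    """
    a, b, f, w = geom.a_mm, geom.b_mm, geom.np_fraction, geom.blend_mm
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
    theta = np.degrees(np.arctan2(y, x))
    # physical radius of the footprint boundary along each point's ray
    with np.errstate(divide="ignore", invalid="ignore"):
        r_edge = 1.0 / np.sqrt((np.cos(np.radians(theta)) / a) ** 2 + (np.sin(np.radians(theta)) / b) ** 2)
    # annulus scale: smooth partition of unity over the four quadrants
    arc_radius = np.maximum(rho, f) * r_edge  # arc length per radian at the point
    weights = np.zeros((len(x), 4))
    scales = np.zeros(4)
    for i, (zone, c) in enumerate(_QUADRANT_CENTER_DEG.items()):
        d = np.abs((theta - c + 180.0) % 360.0 - 180.0)  # wrapped angular distance
        arc = np.radians(45.0 - d) * arc_radius  # signed physical distance to sector edge
        weights[:, i] = _smoothstep(arc / max(w, 1e-9) + 0.5) if w > 0 else (d < 45.0) + 0.5 * (d == 45.0)
        scales[i] = preset.zone_gap_scale[zone]
    wsum = weights.sum(axis=1, keepdims=True)
    annulus = (weights / np.where(wsum > 0, wsum, 1.0)) @ scales
    # radial blend NP <-> annulus over physical distance from the NP edge
    radial = (rho - f) * r_edge
    t_r = _smoothstep(radial / max(w, 1e-9) + 0.5) if w > 0 else (radial > 0).astype(float)
    return (1.0 - t_r) * preset.zone_gap_scale["np"] + t_r * annulus


def generate_endplate_pair(
    preset: DegenerationPreset,
    geom: PhantomGeometry,
    seed,
    n_superior: int | None = None,
    level: str | None = None,
    animal: int | None = None,
) -> tuple[EndplateCloud, EndplateCloud, dict[str, float]]:
    """Sample a paired endplate phantom.

    Points are uniform over the elliptical footprint.  The local gap above
    each position equals ``base_gap_mm * zone_gap_scale[zone]``, blended
    smoothly across zone boundaries, plus independent Gaussian surface
    roughness on each plate.  By default the superior plate reuses the
    inferior lateral positions (congruent sampling); ``n_superior`` samples
    that many independent positions instead (density studies).

    Returns the inferior cloud, the superior cloud and the exact per-zone
    mean true gaps actually realised (sharp zone assignment, no roughness).
    """
    rng = _rng(seed)
    n = geom.points_per_endplate
    if n <= 0:
        raise ValueError("points_per_endplate must be positive")

    def sample_footprint(m: int) -> tuple[np.ndarray, np.ndarray]:
        r = np.sqrt(rng.uniform(0.0, 1.0, m))
        th = rng.uniform(0.0, 2.0 * np.pi, m)
        return geom.a_mm * r * np.cos(th), geom.b_mm * r * np.sin(th)

    x, y = sample_footprint(n)
    scale = _gap_scale_field(x, y, preset, geom)
    gap = geom.base_gap_mm * scale
    rough = geom.surface_roughness_sd_mm
    z_inf = rng.normal(0.0, rough, n) if rough > 0 else np.zeros(n)

    if n_superior is None:
        xs, ys, gs = x, y, gap
    else:
        xs, ys = sample_footprint(int(n_superior))
        gs = geom.base_gap_mm * _gap_scale_field(xs, ys, preset, geom)
    z_sup = gs + (rng.normal(0.0, rough, len(xs)) if rough > 0 else 0.0)

    inferior = EndplateCloud(np.column_stack([x, y, z_inf]), "inferior", level=level, animal=animal, week=preset.week)
    superior = EndplateCloud(np.column_stack([xs, ys, z_sup]), "superior", level=level, animal=animal, week=preset.week)

    rho = np.sqrt((x / geom.a_mm) ** 2 + (y / geom.b_mm) ** 2)
    theta = np.degrees(np.arctan2(y, x))
    zone = _zone_of(rho, theta, geom.np_fraction)
    true_gaps = {z: float(np.mean(gap[zone == z])) if (zone == z).any() else float("nan") for z in ZONES}
    return inferior, superior, true_gaps


# ---------------------------------------------------------------------------
# radiographs
# ---------------------------------------------------------------------------


def generate_radiograph_series(
    trajectory_pct: dict[int, float],
    noise_sd_mm: float,
    seed,
    baseline_heights_mm: tuple[float, float, float] = (3.8, 4.2, 3.6),
    marker_px: float = 200.0,
    marker_mm: float = 10.0,
) -> tuple[list[dict], float]:
    """Noisy radiographic height triplets for one disc across timepoints.

    ``trajectory_pct`` maps week -> true percent of baseline height and
    must include the week-0 baseline.  All three heights scale together
    with the trajectory; i.i.d. Gaussian measurement noise (mm) is added to
    each height, and readings are returned in *pixels* against a marker
    that encodes the mm-per-pixel scale exactly.

    Returns ``(rows, marker_px)`` with one dict per week holding the pixel
    triplet.
    """
    if not trajectory_pct:
        raise ValueError("empty trajectory")
    if 0 not in trajectory_pct:
        raise ValueError("trajectory must include the week-0 baseline")
    if noise_sd_mm < 0:
        raise ValueError("noise sd must be nonnegative")
    rng = _rng(seed)
    px_per_mm = marker_px / marker_mm
    ha0, hm0, hp0 = baseline_heights_mm
    rows = []
    for week in sorted(trajectory_pct):
        s = trajectory_pct[week] / 100.0
        mm = np.array([ha0, hm0, hp0]) * s
        if noise_sd_mm > 0:
            mm = mm + rng.normal(0.0, noise_sd_mm, 3)
        rows.append(
            {
                "week": int(week),
                "Ha_px": float(mm[0] * px_per_mm),
                "Hm_px": float(mm[1] * px_per_mm),
                "Hp_px": float(mm[2] * px_per_mm),
                "marker_px": float(marker_px),
            }
        )
    return rows, float(marker_px)


def generate_radiograph_table(
    design: StudyDesign,
    table: PresetTable,
    seed,
    animals=None,
    noise_sd_mm: float | None = None,
) -> pd.DataFrame:
    """Tidy pixel-space measurement table for a set of animals.

    Each animal contributes all five levels on its biweekly schedule up to
    its sacrifice week (every level follows its treatment's %DHI
    trajectory; the reference level is flat by calibration).
    """
    rng = _rng(seed)
    if animals is None:
        animals = design.animals()
    if noise_sd_mm is None:
        noise_sd_mm = float(table.noise["radiograph_sd_mm"])
    bl = table.baseline
    base_heights = (bl["anterior_height_mm"], bl["middle_height_mm"], bl["posterior_height_mm"])
    records = []
    for animal in animals:
        last = design.week_of_animal(animal)
        weeks = [w for w in design.radiograph_weeks if w <= last]
        for level in design.levels:
            treatment = design.level_map[level].label
            traj = {w: table.trajectory(treatment)[w] for w in weeks}
            rows, _ = generate_radiograph_series(
                traj,
                noise_sd_mm,
                rng,
                baseline_heights_mm=base_heights,
                marker_px=float(bl["marker_px"]),
                marker_mm=float(bl["marker_mm"]),
            )
            for r in rows:
                records.append({"animal": animal, "level": level, **r})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# MR echo stacks
# ---------------------------------------------------------------------------


def generate_echo_stack(
    t2_field: np.ndarray,
    s0_field: np.ndarray,
    te_list_ms: np.ndarray | None = None,
    noise_model: str = "gaussian",
    noise_sd: float = 0.0,
    seed=None,
) -> EchoStack:
    """Simulate a multi-echo stack ``S = S0 exp(-TE/T2)`` plus noise.

    ``noise_model`` is 'gaussian' (additive, clipped at zero to keep the
    stack physical) or 'rician' (magnitude of the complex signal with
    independent Gaussian noise on both channels).  ``noise_sd`` is in
    signal units.  Where ``s0_field`` is 0 the voxel is pure noise
    background.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    t2 = np.asarray(t2_field, float)
    s0 = np.asarray(s0_field, float)
    if np.any(t2[s0 > 0] <= 0):
        raise ValueError("T2 must be positive wherever S0 > 0")
    te = default_te_list() if te_list_ms is None else np.asarray(te_list_ms, float)
    rng = _rng(seed)
    with np.errstate(divide="ignore"):
        decay = np.exp(-te / np.where(t2 > 0, t2, np.inf)[..., None])
    clean = s0[..., None] * decay
    if noise_sd == 0:
        sig = clean
    elif noise_model == "gaussian":
        sig = np.clip(clean + rng.normal(0.0, noise_sd, clean.shape), 0.0, None)
    elif noise_model == "rician":
        re = clean + rng.normal(0.0, noise_sd, clean.shape)
        im = rng.normal(0.0, noise_sd, clean.shape)
        sig = np.hypot(re, im)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return EchoStack(signal=sig, te_list_ms=te)


def disc_t2_phantom(
    np_t2_ms: float,
    af_t2_ms: float,
    shape: tuple[int, int] = (32, 32),
    s0: float = 100.0,
    np_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-compartment sagittal disc phantom.

    An elliptical disc (outer AF border) fills most of the image; the inner
    co-axial ellipse scaled by ``np_fraction`` is NP at ``np_t2_ms``, the
    ring is AF at ``af_t2_ms``, the background has no signal.  Returns
    ``(t2_field, s0_field, disc_mask, np_mask)``; ``disc_mask`` is the
    ROI a reader would trace around the outer AF border.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    a, b = 0.45 * nx, 0.30 * ny  # footprint semi-axes in voxels
    r = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    disc = r <= 1.0
    np_mask = r <= np_fraction
    t2 = np.zeros(shape)
    t2[disc] = af_t2_ms
    t2[np_mask] = np_t2_ms
    s0_field = np.where(disc, s0, 0.0)
    return t2, s0_field, disc, np_mask


# ---------------------------------------------------------------------------
# histology and cells
# ---------------------------------------------------------------------------


def generate_histology_and_cells(
    preset: DegenerationPreset,
    seed,
    control_alive_per_field: float = 120.0,
    score_range: tuple[int, int] = (0, 2),
) -> tuple[HistologyScore, CellCensus]:
    """Draw one disc's histology grades and NP cell census.

    Category scores are binomial on the score range with the preset mean
    (a truncated discrete distribution centred on the mean); alive counts
    per field are Poisson around ``control mean x survival fraction``; the
    clone flag is Bernoulli with the preset probability.
    """
    rng = _rng(seed)
    lo, hi = score_range
    span = hi - lo
    scores = {}
    for cat in SCORE_CATEGORIES:
        m = preset.histology_score_means[cat]
        if not lo <= m <= hi:
            raise ValueError(f"mean for {cat!r} outside score range [{lo}, {hi}]")
        scores[cat] = int(lo + rng.binomial(span, (m - lo) / span))
    alive = {
        f: int(rng.poisson(control_alive_per_field * preset.cell_survival_fraction))
        for f in CENSUS_FIELDS
    }
    clone = bool(rng.random() < preset.clone_probability)
    return (
        HistologyScore(scores=scores, score_range=(lo, hi)),
        CellCensus(alive=alive, clone_present=clone),
    )


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """One full synthetic study plus its truth table."""

    design: StudyDesign
    radiographs: pd.DataFrame
    endplates: dict[tuple[int, str], tuple[EndplateCloud, EndplateCloud, dict[str, float]]]
    echo_stacks: dict[tuple[int, str], dict]
    histology: pd.DataFrame
    cells: pd.DataFrame
    truth: pd.DataFrame
    master_seed: int


def generate_study(
    design: StudyDesign | None = None,
    master_seed: int = 0,
    presets: PresetTable | None = None,
    modalities: tuple[str, ...] = ("radiograph", "microct", "mri", "histology"),
) -> StudyData:
    """Generate every animal, level and modality of the emulated study.

    Deterministic given ``master_seed``: each (animal, modality) gets its
    own child stream spawned from one seed sequence, so regenerating with
    the same seed is bit-identical and different seeds share structure but
    not noise.  The truth table records every generator parameter for
    recovery reporting.
    """
    design = design or default_design()
    table = presets or load_presets()
    missing = [
        (t.label, w)
        for w in design.timepoints_weeks
        for t in design.level_map.values()
        if (t.label, w) not in table.presets
    ]
    if missing:
        raise KeyError(f"preset cells missing for {missing}")

    root = np.random.SeedSequence(master_seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("radiograph", "microct", "mri", "histology"), root.spawn(4)
        )
    }

    geom = table.geometry
    bl = table.baseline
    truth_rows = []

    radiographs = pd.DataFrame()
    if "radiograph" in modalities:
        radiographs = generate_radiograph_table(design, table, streams["radiograph"])

    endplates: dict[tuple[int, str], tuple] = {}
    echo_stacks: dict[tuple[int, str], dict] = {}
    hist_rows, cell_rows = [], []
    te = default_te_list(bl["te_first_ms"], bl["te_last_ms"], int(bl["n_echoes"]))

    for animal in design.animals():
        week = design.week_of_animal(animal)
        arm = design.arm_of_animal(animal)
        for level in design.levels:
            treatment = design.level_map[level].label
            preset = table.preset(treatment, week)
            row = {
                "animal": animal,
                "level": level,
                "treatment": treatment,
                "week": week,
                "arm": arm,
                "severity": preset.severity,
                "cell_survival_fraction": preset.cell_survival_fraction,
                "clone_probability": preset.clone_probability,
                "t2_scale": preset.t2_scale,
                "dhi_pct_final": table.trajectory(treatment)[week],
            }
            for z in ZONES:
                row[f"true_scale_{z}"] = preset.zone_gap_scale[z]

            if "microct" in modalities and arm == "microct":
                inf, sup, gaps = generate_endplate_pair(
                    preset, geom, streams["microct"], level=level, animal=animal
                )
                endplates[(animal, level)] = (inf, sup, gaps)
                for z in ZONES:
                    row[f"true_gap_{z}_mm"] = gaps[z]

            if "mri" in modalities and arm == "mri":
                rng = streams["mri"]
                jitter = float(table.noise.get("t2_disc_jitter_frac", 0.0))
                np_t2 = bl["np_t2_ms"] * preset.t2_scale
                if jitter > 0:
                    np_t2 *= max(1.0 + rng.normal(0.0, jitter), 0.1)
                t2f, s0f, disc_mask, np_mask = disc_t2_phantom(np_t2, bl["af_t2_ms"])
                noise_sd = float(table.noise["mr_noise_frac"]) * 100.0
                stack = generate_echo_stack(
                    t2f, s0f, te, str(table.noise.get("mr_noise_model", "gaussian")), noise_sd, rng
                )
                echo_stacks[(animal, level)] = {
                    "stack": stack,
                    "disc_mask": disc_mask,
                    "np_mask": np_mask,
                    "true_np_t2_ms": float(np_t2),
                    "true_af_t2_ms": float(bl["af_t2_ms"]),
                }
                row["true_np_t2_ms"] = float(np_t2)

            if "histology" in modalities:
                score, census = generate_histology_and_cells(
                    preset,
                    streams["histology"],
                    control_alive_per_field=float(bl["control_alive_per_field"]),
                    score_range=table.histology_score_range,
                )
                hist_rows.append(
                    {"animal": animal, "level": level, "treatment": treatment, "week": week,
                     **score.scores, "total": score.total}
                )
                cell_rows.append(
                    {"animal": animal, "level": level, "treatment": treatment, "week": week,
                     **{f"alive_{f}": census.alive[f] for f in CENSUS_FIELDS},
                     "total_alive": census.total_alive, "clone_present": census.clone_present}
                )
            truth_rows.append(row)

    return StudyData(
        design=design,
        radiographs=radiographs,
        endplates=endplates,
        echo_stacks=echo_stacks,
        histology=pd.DataFrame(hist_rows),
        cells=pd.DataFrame(cell_rows),
        truth=pd.DataFrame(truth_rows),
        master_seed=master_seed,
    )
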