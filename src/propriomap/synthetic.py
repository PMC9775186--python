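"""Synthetic study generator.

Everything the downstream pipeline consumes is produced here with known,
planted effects: arm position matching (APM) exams for healthy controls and
stroke participants, control white-matter tract masks on a shared voxel
grid, stroke lesion masks, per-tract diffusion metrics (FA/MD/volume), and
directed streamline-count connectomes over an 8-region cortical network.

The generator is the ground truth for every test: deficit profiles, lesion
damage fractions and metric couplings are all recorded in
:class:`GroundTruth` so that expected group differences can be computed
independently of the pipeline under test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

TRACTS = ("SLF_I", "SLF_II", "SLF_III", "AF", "MdLF")
HEMISPHERES = ("L", "R")
ROI_LABELS = ("S1", "SMG", "AG", "SPL", "SMA", "dPMC", "vPMC", "STG")

#: which ROI pairs each association tract principally serves; used to couple
#: streamline loss to tract damage.  Parietal-frontal for the SLF branches,
#: temporal-frontal for the AF, temporal-parietal for the MdLF.
TRACT_ROI_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "SLF_I": (("SPL", "SMA"), ("SPL", "dPMC")),
    "SLF_II": (("AG", "dPMC"), ("SPL", "SMG"), ("AG", "SPL")),
    "SLF_III": (("SMG", "vPMC"), ("S1", "vPMC"), ("S1", "SMG")),
    "AF": (("STG", "vPMC"), ("STG", "dPMC")),
    "MdLF": (("STG", "AG"), ("STG", "SPL")),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetLayout:
    """Nine APM targets on a 3x3 square grid in workspace coordinates (cm).

    x is lateral (positive rightward), y anterior; the central target sits at
    the origin, standing in for the posture-defined workspace centre.
    """

    positions: np.ndarray  # (9, 2) cm
    center_index: int
    spacing_cm: float

    def outer_indices(self) -> np.ndarray:
        return np.array([i for i in range(9) if i != self.center_index])


@dataclass(frozen=True)
class DeficitProfile:
    """Parameterizes the matching behaviours the APM parameters measure.

    noise_sd_cm inflates trial-to-trial variability, contraction_factor
    shrinks (<1) or enlarges (>1) the matched workspace about its centroid,
    shift_cm displaces it systematically, and lapse_rate is the probability
    of an off-target trial.
    """

    noise_sd_cm: tuple[float, float] = (0.0, 0.0)
    contraction_factor: tuple[float, float] = (1.0, 1.0)
    shift_cm: tuple[float, float] = (0.0, 0.0)
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.noise_sd_cm) < 0:
            raise ValueError("noise_sd_cm must be non-negative")
        if min(self.contraction_factor) <= 0:
            raise ValueError("contraction_factor must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")


IDENTITY_PROFILE = DeficitProfile()


@dataclass(frozen=True)
class Demographics:
    age: float
    sex: str  # {M, F}
    handedness: str  # {L, A, R}
    group: str = "control"  # {stroke, control}
    lesioned_hemisphere: str = "none"  # {L, R, none}

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.handedness not in ("L", "A", "R"):
            raise ValueError(f"unknown handedness {self.handedness!r}")
        if self.group == "stroke" and self.lesioned_hemisphere == "none":
            raise ValueError("stroke participants must have a lesioned hemisphere")


@dataclass(frozen=True)
class ApmExam:
    """One participant's 54 matching trials plus demographics.

    Trial table columns: block, target_index, target_x, target_y (passive
    arm, cm), matched_x, matched_y (active arm, cm), peak_speed (m/s).
    The midline (x = midline_x) is the mirror axis between the two arms.
    """

    participant_id: str
    demographics: Demographics
    trials: pd.DataFrame
    midline_x: float = 0.0

    def __post_init__(self) -> None:
        counts = self.trials["target_index"].value_counts()
        if len(counts) != 9 or counts.nunique() != 1:
            raise ValueError("exam must probe 9 targets equally often")


@dataclass
class CovariateModel:
    """Normative covariate structure for deficit-free matching behaviour.

    Matching noise grows linearly with age (cm of SD per year past
    ``age_ref``); males get a small additive offset; handedness contributes
    nothing by default but has a slot so the design stays identifiable.
    Between-subject spread enters through ``between_sd`` plus lognormal
    contraction jitter and Gaussian shift jitter.
    """

    age_range: tuple[float, float] = (45.0, 85.0)
    age_ref: float = 65.0
    base_noise_sd: float = 0.9  # cm, both axes
    age_noise_slope: float = 0.012  # cm SD per year
    sex_noise_delta: float = 0.08  # added for M
    hand_noise_delta: float = 0.0  # added for non-right handers
    between_sd: float = 0.15  # cm, participant-level noise-SD spread
    contraction_log_sd: float = 0.04
    shift_sd: float = 0.45  # cm
    lapse_rate: float = 0.01
    prop_male: float = 0.5
    prop_right_handed: float = 0.95

    def draw_demographics(self, rng: np.random.Generator, **kw) -> Demographics:
        age = float(rng.uniform(*self.age_range))
        sex = "M" if rng.random() < self.prop_male else "F"
        if rng.random() < self.prop_right_handed:
            hand = "R"
        else:
            hand = "L" if rng.random() < 0.7 else "A"
        return Demographics(age=age, sex=sex, handedness=hand, **kw)

    def noise_sd(self, demo: Demographics, rng: np.random.Generator) -> float:
        sd = (
            self.base_noise_sd
            + self.age_noise_slope * (demo.age - self.age_ref)
            + (self.sex_noise_delta if demo.sex == "M" else 0.0)
            + (self.hand_noise_delta if demo.handedness != "R" else 0.0)
            + rng.normal(0.0, self.between_sd)
        )
        return max(sd, 0.15)

    def draw_profile(self, demo: Demographics, rng: np.random.Generator) -> DeficitProfile:
        sd = self.noise_sd(demo, rng)
        contract = tuple(np.exp(rng.normal(0.0, self.contraction_log_sd, 2)))
        shift = tuple(rng.normal(0.0, self.shift_sd, 2))
        return DeficitProfile(
            noise_sd_cm=(sd, sd),
            contraction_factor=contract,
            shift_cm=shift,
            lapse_rate=self.lapse_rate,
        )


# ---------------------------------------------------------------------------
# APM exam generation
# ---------------------------------------------------------------------------

def gen_target_layout(spacing_cm: float = 10.0) -> TargetLayout:
    """Nine targets: eight outer targets in a square ring around the centre.

    Horizontally/vertically adjacent outer targets are ``spacing_cm`` apart,
    so corners sit at (+-spacing, +-spacing) and the centre at the origin.
    """
    if spacing_cm <= 0:
        raise ValueError("spacing_cm must be positive")
    s = float(spacing_cm)
    grid = [(x, y) for y in (s, 0.0, -s) for x in (-s, 0.0, s)]
    positions = np.array(grid, dtype=float)
    center_index = int(np.flatnonzero((positions == 0).all(axis=1))[0])
    return TargetLayout(positions=positions, center_index=center_index, spacing_cm=s)


def simulate_exam(
    layout: TargetLayout,
    profile: DeficitProfile,
    demographics: Demographics,
    rng: np.random.Generator,
    participant_id: str = "P000",
    n_blocks: int = 6,
    midline_x: float = 0.0,
) -> ApmExam:
    """Simulate one APM exam: 6 blocks x 9 targets in shuffled order.

    The robot places the passive arm on a target; the matched (active-arm)
    position is the mirror image of the target about the midline, contracted
    about the matched-workspace centroid, shifted, and jittered with
    Gaussian noise.  Lapses replace the noise with a broad uniform miss.
    Passive-movement peak speed is drawn uniform on [0.3, 0.5] m/s and kept
    only for format fidelity.
    """
    cx, cy = profile.contraction_factor
    sx, sy = profile.shift_cm
    nx, ny = profile.noise_sd_cm
    mirrored = layout.positions.copy()
    mirrored[:, 0] = 2.0 * midline_x - mirrored[:, 0]
    centroid = mirrored.mean(axis=0)

    rows = []
    for block in range(n_blocks):
        for ti in rng.permutation(9):
            tx, ty = layout.positions[ti]
            mx, my = mirrored[ti]
            mx = centroid[0] + cx * (mx - centroid[0]) + sx
            my = centroid[1] + cy * (my - centroid[1]) + sy
            if profile.lapse_rate and rng.random() < profile.lapse_rate:
                span = 1.5 * layout.spacing_cm
                mx += rng.uniform(-span, span)
                my += rng.uniform(-span, span)
            else:
                mx += rng.normal(0.0, nx)
                my += rng.normal(0.0, ny)
            rows.append(
                (block, int(ti), tx, ty, mx, my, rng.uniform(0.3, 0.5))
            )
    trials = pd.DataFrame(
        rows,
        columns=[
            "block", "target_index", "target_x", "target_y",
            "matched_x", "matched_y", "peak_speed",
        ],
    )
    return ApmExam(
        participant_id=participant_id,
        demographics=demographics,
        trials=trials,
        midline_x=midline_x,
    )


def simulate_normative_cohort(
    n: int,
    covariate_model: CovariateModel | None = None,
    rng: np.random.Generator | None = None,
    layout: TargetLayout | None = None,
    min_n: int = 50,
    id_prefix: str = "N",
) -> tuple[list[ApmExam], list[Demographics]]:
    """Deficit-free cohort with age/sex covariate effects on matching noise.

    ``n`` must reach ``min_n`` so the downstream normative regression has
    enough participants to fit stably.
    """
    if n < min_n:
        raise ValueError(f"normative cohort needs n >= {min_n}, got {n}")
    covariate_model = covariate_model or CovariateModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    layout = layout or gen_target_layout()
    exams, demos = [], []
    for i in range(n):
        demo = covariate_model.draw_demographics(rng)
        profile = covariate_model.draw_profile(demo, rng)
        exams.append(
            simulate_exam(layout, profile, demo, rng, participant_id=f"{id_prefix}{i:04d}")
        )
        demos.append(demo)
    return exams, demos


# ---------------------------------------------------------------------------
# voxel grids, tract tubes, lesions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0


@dataclass(frozen=True)
class TractSpec:
    """Parametric tract: a tube of given radius around a smooth centerline.

    The centerline runs anterior-posterior (along the grid's y axis) with a
    gentle sinusoidal bow; ``x_offset``/``z_offset`` place the tube in the
    hemisphere cross-section (voxel units relative to the hemisphere
    centre).
    """

    name: str
    hemisphere: str
    x_offset: float
    z_offset: float
    radius_vox: float = 2.0
    bow_vox: float = 1.5

    def centerline(self, grid: GridSpec, wobble: np.ndarray | None = None) -> np.ndarray:
        nx, ny, nz = grid.shape
        hemi_cx = nx * (0.25 if self.hemisphere == "L" else 0.75)
        y = np.linspace(ny * 0.15, ny * 0.85, 121)
        t = (y - y[0]) / (y[-1] - y[0])
        x = np.full_like(y, hemi_cx + self.x_offset)
        z = nz * 0.5 + self.z_offset + self.bow_vox * np.sin(np.pi * t)
        pts = np.column_stack([x, y, z])
        if wobble is not None:
            # smooth per-control perturbation in the (x, z) cross-section
            a = wobble  # (4,) coefficients
            pts[:, 0] += a[0] + a[1] * np.sin(np.pi * t)
            pts[:, 2] += a[2] + a[3] * np.sin(np.pi * t)
        return pts


#: cross-section placement per tract (voxel offsets from hemisphere centre).
#: Pairwise separations stay >= ~6 voxels so lesion components sized for one
#: tube cannot clip a neighbouring tube.
DEFAULT_TRACT_OFFSETS: dict[str, tuple[float, float]] = {
    "SLF_I": (0.0, 9.0),
    "SLF_II": (0.0, 3.0),
    "SLF_III": (0.0, -3.0),
    "AF": (6.0, 0.0),
    "MdLF": (6.0, -8.0),
}


def default_tract_specs(grid: GridSpec | None = None) -> list[TractSpec]:
    specs = []
    for hemi in HEMISPHERES:
        sign = -1.0 if hemi == "L" else 1.0
        for tract in TRACTS:
            dx, dz = DEFAULT_TRACT_OFFSETS[tract]
            specs.append(
                TractSpec(name=tract, hemisphere=hemi, x_offset=sign * dx, z_offset=dz)
            )
    return specs


def _voxel_centers(grid: GridSpec) -> np.ndarray:
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)


def rasterize_tube(centerline: np.ndarray, radius_vox: float, grid: GridSpec) -> np.ndarray:
    """Binary mask of voxels whose centre lies within radius of the polyline.

    A KD-tree over a densely resampled centerline prefilters the grid; the
    borderline shell is then re-tested with the exact point-to-segment
    distance, so membership is exact even for voxels on the boundary.
    """
    seg = np.diff(centerline, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    n_dense = max(int(lengths.sum() / 0.25), len(centerline))
    t = np.linspace(0, 1, n_dense)
    cum = np.concatenate([[0], np.cumsum(lengths)]) / lengths.sum()
    dense = np.column_stack(
        [np.interp(t, cum, centerline[:, d]) for d in range(3)]
    )
    if (dense.min(axis=0) < -0.5).any() or (
        dense.max(axis=0) > np.array(grid.shape) - 0.5
    ).any():
        raise ValueError("tube centerline leaves the grid bounds")
    coords = _voxel_centers(grid)
    tree = cKDTree(dense)
    d, _ = tree.query(coords, k=1)
    inside = d <= radius_vox - 0.25
    border = (~inside) & (d <= radius_vox + 0.25)
    if border.any():
        pts = coords[border]  # exact min distance over all segments
        a, b = centerline[:-1], centerline[1:]
        ab = b - a
        denom = (ab**2).sum(axis=1)
        best = np.full(len(pts), np.inf)
        for j in range(len(a)):
            ap = pts - a[j]
            tt = np.clip(ap @ ab[j] / denom[j], 0.0, 1.0)
            proj = a[j] + tt[:, None] * ab[j]
            best = np.minimum(best, np.linalg.norm(pts - proj, axis=1))
        inside[border] = best <= radius_vox
    return inside.reshape(grid.shape)


def simulate_tract_masks(
    grid: GridSpec,
    tract_specs: list[TractSpec],
    n_controls: int,
    jitter_vox: float,
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str], list[np.ndarray]], dict[tuple[str, str], np.ndarray]]:
    """Per-control binary tract masks plus voxelwise agreement maps.

    Each control's tract is the spec tube under a smooth random perturbation
    of amplitude ``jitter_vox``; the pseudo-probability map is the voxelwise
    fraction of controls whose mask contains the voxel.
    """
    masks: dict[tuple[str, str], list[np.ndarray]] = {}
    prob_maps: dict[tuple[str, str], np.ndarray] = {}
    for spec in tract_specs:
        key = (spec.name, spec.hemisphere)
        per_control = []
        for _ in range(n_controls):
            wobble = rng.normal(0.0, jitter_vox, 4) if jitter_vox > 0 else None
            line = spec.centerline(grid, wobble)
            per_control.append(rasterize_tube(line, spec.radius_vox, grid))
        masks[key] = per_control
        prob_maps[key] = np.mean(per_control, axis=0)
    return masks, prob_maps


def ellipsoid_mask(
    center: np.ndarray, radii: np.ndarray, grid: GridSpec
) -> np.ndarray:
    """Axis-aligned ellipsoid rasterized on the grid (voxel-centre test)."""
    coords = _voxel_centers(grid)
    u = (coords - center[None, :]) / radii[None, :]
    return ((u**2).sum(axis=1) <= 1.0).reshape(grid.shape)


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class LesionAssignment:
    """One stroke participant's lesion plan: which hemisphere, which tracts.

    ``targets`` maps tract name -> intended damage fraction of the tube's
    length; an empty mapping yields a small lesion away from every tract.
    """

    hemisphere: str
    targets: dict[str, float] = field(default_factory=dict)


def default_lesion_assignments() -> list[LesionAssignment]:
    """26 stroke participants with per-tract lesion counts {3, 6, 8, 20, 9}.

    Mirrors the emulated study scenario: AF lesions dominate, SLF I lesions
    are rare, six participants have no lesion on any tract of interest, and
    single participants frequently belong to several lesion groups.
    Hemispheres follow the 19 right / 7 left split of the emulated cohort.
    """
    plans: list[dict[str, float]] = [
        {"AF": 0.45, "SLF_III": 0.30, "SLF_II": 0.15},
        {"AF": 0.30, "SLF_III": 0.20},
        {"AF": 0.55, "MdLF": 0.35, "SLF_III": 0.25},
        {"AF": 0.25},
        {"AF": 0.40, "MdLF": 0.30},
        {"AF": 0.15, "SLF_III": 0.10, "SLF_II": 0.20, "SLF_I": 0.10},
        {"AF": 0.50, "MdLF": 0.45},
        {"AF": 0.20},
        {"AF": 0.35, "SLF_III": 0.30, "SLF_II": 0.25, "SLF_I": 0.15},
        {"AF": 0.30, "MdLF": 0.25},
        {"AF": 0.45, "SLF_III": 0.15},
        {"AF": 0.10},
        {"AF": 0.55, "MdLF": 0.40, "SLF_II": 0.30, "SLF_I": 0.20},
        {"AF": 0.25, "MdLF": 0.20},
        {"AF": 0.35, "SLF_III": 0.25, "SLF_II": 0.15},
        {"AF": 0.15},
        {"AF": 0.50, "MdLF": 0.30},
        {"AF": 0.30, "SLF_III": 0.20, "SLF_II": 0.10},
        {"AF": 0.40, "MdLF": 0.35},
        {"AF": 0.20, "MdLF": 0.15},
        {},
        {},
        {},
        {},
        {},
        {},
    ]
    hemis = ["R"] * 19 + ["L"] * 7
    return [
        LesionAssignment(hemisphere=h, targets=dict(p))
        for h, p in zip(hemis, plans)
    ]


@dataclass
class StudyConfig:
    """Conditions of the emulated study.

    Couplings express, per unit mean damage fraction (0..1 averaged over the
    five tracts of the lesioned hemisphere), how much matching noise SD
    (cm), workspace contraction, and lateral shift (cm) a lesion adds, and
    how strongly FA drops, MD rises, tract volume shrinks, and streamlines
    are lost on tract-served ROI pairs.
    """

    n_stroke: int = 26
    n_control: int = 7
    grid: GridSpec = field(default_factory=GridSpec)
    agreement_k: int = 6
    control_jitter_vox: float = 0.6
    lesion_assignments: list[LesionAssignment] | None = None
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    # lesion -> behaviour couplings
    noise_per_damage: float = 5.0  # cm SD per unit mean damage
    contract_per_damage: float = 0.8  # fractional shrink per unit mean damage
    shift_per_damage: float = 5.0  # cm per unit mean damage
    # lesion -> anatomy couplings
    fa_slope: float = 0.10  # FA drop per unit tract damage
    md_slope: float = 1.5e-4  # mm^2/s rise per unit tract damage
    vol_slope: float = 0.35  # fractional tract-volume loss per unit damage
    streamline_loss: float = 0.6  # fractional loss on served pairs per unit damage
    # baselines
    fa_base: dict[str, float] = field(
        default_factory=lambda: {
            "SLF_I": 0.44, "SLF_II": 0.46, "SLF_III": 0.45, "AF": 0.48, "MdLF": 0.42,
        }
    )
    md_base: float = 7.5e-4  # mm^2/s
    fa_noise: float = 0.015
    md_noise: float = 2.5e-5

    def __post_init__(self) -> None:
        if self.lesion_assignments is None and self.n_stroke == 26:
            self.lesion_assignments = default_lesion_assignments()
        if self.lesion_assignments is not None and len(self.lesion_assignments) != self.n_stroke:
            raise ValueError("one lesion assignment per stroke participant required")
        if not 1 <= self.agreement_k <= self.n_control:
            raise ValueError("agreement_k must lie in [1, n_control]")


@dataclass
class GroundTruth:
    """Planted effects: what the pipeline *should* recover."""

    config: StudyConfig
    damage_fraction: pd.DataFrame  # stroke participants x tracts (planned)
    profiles: dict[str, DeficitProfile]
    mean_damage: dict[str, float]


@dataclass
class StudyDataset:
    """Complete synthetic study on one shared voxel grid."""

    config: StudyConfig
    exams: dict[str, ApmExam]
    demographics: dict[str, Demographics]
    control_tract_masks: dict[tuple[str, str], list[np.ndarray]]
    tract_prob_maps: dict[tuple[str, str], np.ndarray]
    lesion_masks: dict[str, np.ndarray]
    tract_metrics: pd.DataFrame  # participant, tract, hemisphere, FA, MD, volume_mm3
    connectomes: dict[tuple[str, str], pd.DataFrame]  # (participant, hemi) -> edge list
    seed_volumes: dict[str, dict[str, float]]  # participant -> roi -> mm3
    ground_truth: GroundTruth

    @property
    def stroke_ids(self) -> list[str]:
        return [p for p, d in self.demographics.items() if d.group == "stroke"]

    @property
    def control_ids(self) -> list[str]:
        return [p for p, d in self.demographics.items() if d.group == "control"]


def _lesion_mask_for(
    assignment: LesionAssignment,
    templates: dict[tuple[str, str], np.ndarray],
    specs: dict[tuple[str, str], TractSpec],
    grid: GridSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multifocal lesion: one axis-aligned ellipsoid per targeted tract.

    Each component is centred on a voxel of the targeted tract's realized
    group template, with the long axis along the tube so the intended
    damage fraction sets the anterior-posterior extent.  Voxels falling on
    the templates of *non*-targeted tracts in the same hemisphere are then
    carved out, so lesion-group membership matches the assignment exactly.
    """
    hemi = assignment.hemisphere
    protected = np.zeros(grid.shape, dtype=bool)
    for (tract, h), tpl in templates.items():
        if h == hemi and tract not in assignment.targets:
            protected |= tpl
    if not assignment.targets:
        # small deep lesion clear of every tube (near the grid floor)
        hemi_cx = grid.shape[0] * (0.25 if hemi == "L" else 0.75)
        center = np.array([
            hemi_cx + rng.normal(0, 0.5),
            grid.shape[1] * rng.uniform(0.3, 0.7),
            grid.shape[2] * 0.5 - 15.0,
        ])
        radii = np.array([2.0, rng.uniform(2.0, 4.0), 2.0])
        return ellipsoid_mask(center, radii, grid) & ~protected
    mask = np.zeros(grid.shape, dtype=bool)
    for tract, frac in assignment.targets.items():
        spec = specs[(tract, hemi)]
        tpl_vox = np.argwhere(templates[(tract, hemi)])
        # pick a seed voxel from the middle half of the tube's extent
        ys = tpl_vox[:, 1]
        lo, hi = np.quantile(ys, [0.25, 0.75])
        middle = tpl_vox[(ys >= lo) & (ys <= hi)]
        center = middle[rng.integers(len(middle))].astype(float)
        line = spec.centerline(grid)
        half_len = max(frac, 0.05) * (line[-1, 1] - line[0, 1]) / 2.0 + spec.radius_vox
        radii = np.array([2.8, half_len, 2.8])
        mask |= ellipsoid_mask(center, radii, grid)
    return mask & ~protected


def simulate_study(
    config: StudyConfig | None = None, rng: np.random.Generator | None = None
) -> StudyDataset:
    """Generate the full synthetic study with lesion-coupled deficits.

    Deficit profiles, FA/MD/volume decrements (lesioned hemisphere only) and
    streamline losses all scale with the planted per-tract damage fractions,
    so increasing a coupling strengthens every downstream group difference.
    """
    config = config or StudyConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    grid = config.grid
    if config.lesion_assignments is None:
        raise ValueError("config must provide lesion assignments for n_stroke != 26")

    specs = {(s.name, s.hemisphere): s for s in default_tract_specs(grid)}
    control_masks, prob_maps = simulate_tract_masks(
        grid, list(specs.values()), config.n_control, config.control_jitter_vox, rng
    )
    templates = {
        key: np.sum(m, axis=0) >= config.agreement_k
        for key, m in control_masks.items()
    }

    layout = gen_target_layout()
    exams: dict[str, ApmExam] = {}
    demographics: dict[str, Demographics] = {}
    lesion_masks: dict[str, np.ndarray] = {}
    profiles: dict[str, DeficitProfile] = {}
    mean_damage: dict[str, float] = {}
    damage_rows = []

    cov = config.covariate_model
    for i, assignment in enumerate(config.lesion_assignments):
        pid = f"S{i:03d}"
        demo = cov.draw_demographics(
            rng, group="stroke", lesioned_hemisphere=assignment.hemisphere
        )
        lesion_masks[pid] = _lesion_mask_for(assignment, templates, specs, grid, rng)
        dmg = {t: float(assignment.targets.get(t, 0.0)) for t in TRACTS}
        damage_rows.append({"participant": pid, **dmg})
        md = float(np.mean(list(dmg.values())))
        mean_damage[pid] = md

        base = cov.draw_profile(demo, rng)
        sd = base.noise_sd_cm[0] + config.noise_per_damage * md
        contract = tuple(
            c * max(1.0 - config.contract_per_damage * md, 0.2)
            for c in base.contraction_factor
        )
        shift = (
            base.shift_cm[0] + config.shift_per_damage * md * rng.choice([-1.0, 1.0]),
            base.shift_cm[1],
        )
        profile = DeficitProfile(
            noise_sd_cm=(sd, sd),
            contraction_factor=contract,
            shift_cm=shift,
            lapse_rate=min(base.lapse_rate + 0.1 * md, 1.0),
        )
        profiles[pid] = profile
        demographics[pid] = demo
        exams[pid] = simulate_exam(layout, profile, demo, rng, participant_id=pid)

    for i in range(config.n_control):
        pid = f"C{i:03d}"
        demo = cov.draw_demographics(rng, group="control")
        profile = cov.draw_profile(demo, rng)
        demographics[pid] = demo
        profiles[pid] = profile
        exams[pid] = simulate_exam(layout, profile, demo, rng, participant_id=pid)

    damage = pd.DataFrame(damage_rows).set_index("participant")

    # ---- diffusion metrics --------------------------------------------
    vox_mm3 = grid.voxel_size_mm**3
    template_vox = {key: int(tpl.sum()) for key, tpl in templates.items()}
    rows = []
    for pid, demo in demographics.items():
        for tract in TRACTS:
            for hemi in HEMISPHERES:
                dmg = 0.0
                if demo.group == "stroke" and hemi == demo.lesioned_hemisphere:
                    dmg = damage.loc[pid, tract]
                fa = (
                    config.fa_base[tract]
                    - config.fa_slope * dmg
                    + rng.normal(0, config.fa_noise)
                )
                md_val = (
                    config.md_base + config.md_slope * dmg + rng.normal(0, config.md_noise)
                )
                vol = template_vox[(tract, hemi)] * vox_mm3 * (
                    1.0 - config.vol_slope * dmg
                ) * np.exp(rng.normal(0, 0.08))
                rows.append(
                    {
                        "participant": pid,
                        "tract": tract,
                        "hemisphere": hemi,
                        "FA": fa,
                        "MD": md_val,
                        "volume_mm3": vol,
                    }
                )
    tract_metrics = pd.DataFrame(rows)

    # ---- connectomes --------------------------------------------------
    pair_loss = {}  # (roi_a, roi_b) -> tract list serving the pair
    for tract, pairs in TRACT_ROI_PAIRS.items():
        for a, b in pairs:
            pair_loss.setdefault(frozenset((a, b)), []).append(tract)

    base_volume = {
        roi: v
        for roi, v in zip(
            ROI_LABELS, (5200.0, 6800.0, 7400.0, 9100.0, 6100.0, 7800.0, 5600.0, 10400.0)
        )
    }
    base_rate = 0.35  # streamlines per mm^3 of seed at zero damage
    connectomes: dict[tuple[str, str], pd.DataFrame] = {}
    seed_volumes: dict[str, dict[str, float]] = {}
    for pid, demo in demographics.items():
        vols = {
            roi: base_volume[roi] * np.exp(rng.normal(0, 0.07)) for roi in ROI_LABELS
        }
        seed_volumes[pid] = vols
        for hemi in HEMISPHERES:
            edges = []
            for a in ROI_LABELS:
                for b in ROI_LABELS:
                    if a == b:
                        continue
                    loss = 0.0
                    if demo.group == "stroke" and hemi == demo.lesioned_hemisphere:
                        for tract in pair_loss.get(frozenset((a, b)), []):
                            loss += config.streamline_loss * damage.loc[pid, tract]
                    mean_count = (
                        base_rate * vols[a] * max(1.0 - loss, 0.02)
                        * np.exp(rng.normal(0, 0.10))
                    )
                    edges.append(
                        {
                            "roi_from": a,
                            "roi_to": b,
                            "streamlines": float(rng.poisson(mean_count)),
                            "seed_volume_mm3": vols[a],
                        }
                    )
            connectomes[(pid, hemi)] = pd.DataFrame(edges)

    gt = GroundTruth(
        config=config, damage_fraction=damage, profiles=profiles, mean_damage=mean_damage
    )
    return StudyDataset(
        config=config,
        exams=exams,
        demographics=demographics,
        control_tract_masks=control_masks,
        tract_prob_maps=prob_maps,
        lesion_masks=lesion_masks,
        tract_metrics=tract_metrics,
        connectomes=connectomes,
        seed_volumes=seed_volumes,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def exam_to_frame(exam: ApmExam) -> pd.DataFrame:
    df = exam.trials.copy()
    df.insert(0, "participant", exam.participant_id)
    return df


def exams_to_csv(exams: list[ApmExam] | dict[str, ApmExam], path) -> None:
    if isinstance(exams, dict):
        exams = list(exams.values())
    pd.concat([exam_to_frame(e) for e in exams], ignore_index=True).to_csv(
        path, index=False
    )


def exams_from_csv(path, demographics: dict[str, Demographics]) -> dict[str, ApmExam]:
    """Round-trip loader for the trial-table CSV written by exams_to_csv."""
    df = pd.read_csv(path)
    exams = {}
    for pid, sub in df.groupby("participant", sort=False):
        exams[pid] = ApmExam(
            participant_id=pid,
            demographics=demographics[pid],
            trials=sub.drop(columns="participant").reset_index(drop=True),
        )
    return exams


def demographics_from_csv(path) -> dict[str, Demographics]:
    df = pd.read_csv(path).set_index("participant")
    return {
        pid: Demographics(
            age=float(r["age"]), sex=r["sex"], handedness=r["handedness"],
            group=r["group"], lesioned_hemisphere=r["lesioned_hemisphere"],
        )
        for pid, r in df.iterrows()
    }


def demographics_to_frame(demos: dict[str, Demographics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"participant": pid, **dataclasses.asdict(d)}
            for pid, d in demos.items()
        ]
    ).set_index("participant")


def connectomes_to_csv(
    connectomes: dict[tuple[str, str], pd.DataFrame], path
) -> None:
    """Directed edge lists for all (participant, hemisphere) connectomes."""
    frames = []
    for (pid, hemi), edges in connectomes.items():
        df = edges.copy()
        df.insert(0, "participant", pid)
        df.insert(1, "hemisphere", hemi)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def connectomes_from_csv(path) -> tuple[dict[tuple[str, str], pd.DataFrame], dict[str, dict[str, float]]]:
    """Inverse of connectomes_to_csv; also recovers per-ROI seed volumes."""
    df = pd.read_csv(path)
    connectomes = {}
    seed_volumes: dict[str, dict[str, float]] = {}
    for (pid, hemi), sub in df.groupby(["participant", "hemisphere"], sort=False):
        connectomes[(pid, hemi)] = sub.drop(
            columns=["participant", "hemisphere"]
        ).reset_index(drop=True)
        vols = sub.groupby("roi_from")["seed_volume_mm3"].first()
        seed_volumes.setdefault(pid, {}).update(vols.to_dict())
    return connectomes, seed_volumes
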