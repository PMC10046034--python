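"""Synthetic cerebrovascular phantoms and blood-pressure cohorts.

Real angiographic cohorts with per-subject blood pressure are rarely
shareable, so every downstream stage here (preprocessing, segmentation,
feature extraction, classification experiments) is exercised against
phantoms generated by this module:

* **Vessel trees** — branching polyline centerlines with per-point radii.
  Branches are straight runs perturbed by smooth sinusoidal displacement
  whose amplitude is the tortuosity knob; child radii decay geometrically.
* **Volumes** — tubes are rasterized into a two-population intensity volume
  (bright vessel voxels around a mean ``mu_b``, darker tissue around
  ``mu_o``), with optional Gaussian noise and a smooth multiplicative bias
  field, as in bright-blood time-of-flight angiography.
* **Cohorts** — subjects carry four noisy (SBP, DBP) reading pairs drawn
  around class-conditional true pressures; vessel geometry is coupled to the
  subject's mean arterial pressure so hypertensive vasculature has smaller
  radii and higher tortuosity, with ``effect_size`` scaling the coupling.

Everything is deterministic given the spec seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import bp_labels
from .bp_labels import BPCategoryRules, DEFAULT_RULES


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RadiusLaw:
    """Root radius distribution and geometric child decay.

    Root radii are lognormal around ``root_mean`` voxels with log-scale SD
    ``root_sigma`` (0 gives fixed radii); each branching level multiplies
    the radius by ``decay`` ∈ (0, 1].
    """

    root_mean: float = 4.0
    root_sigma: float = 0.01
    decay: float = 0.8

    def __post_init__(self) -> None:
        if self.root_mean <= 0:
            raise ValueError("root radius must be positive")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay factor must be in (0, 1]")
        if self.root_sigma < 0:
            raise ValueError("root_sigma must be >= 0")


@dataclass(frozen=True)
class VesselTreeSpec:
    n_root_branches: int = 2
    branch_levels: int = 3
    radius_law: RadiusLaw = field(default_factory=RadiusLaw)
    tortuosity_amplitude: float = 1.0
    volume_shape: Tuple[int, int, int] = (64, 64, 64)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_root_branches < 1 or self.branch_levels < 1:
            raise ValueError("need at least one root branch and one level")
        if any(s < 32 for s in self.volume_shape):
            raise ValueError("volume_shape must be >= 32 per axis")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be >= 0")


@dataclass
class Branch:
    points: np.ndarray  # (n, 3) float voxel coordinates
    radii: np.ndarray  # (n,) voxels
    level: int


@dataclass
class VesselTree:
    branches: List[Branch]
    spec: VesselTreeSpec

    @property
    def centerline(self) -> List[np.ndarray]:
        return [b.points for b in self.branches]

    @property
    def point_radii(self) -> np.ndarray:
        """All per-centerline-point radii, concatenated across branches."""
        return np.concatenate([b.radii for b in self.branches])

    def max_radius(self) -> float:
        return float(max(b.radii.max() for b in self.branches))


@dataclass
class PhantomVolume:
    intensities: np.ndarray  # 3-D float
    truth_mask: np.ndarray  # 3-D bool
    centerline: List[np.ndarray]
    point_radii: np.ndarray
    voxel_size: float = 1.0  # mm, metadata only


# --------------------------------------------------------------------------
# vessel tree generation
# --------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction")
    return v / n


def _perp_basis(d: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to d and to each other."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, ref))
    return u, np.cross(d, u)


def _trace_branch(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    radius: float,
    amplitude: float,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Walk a sinusoidally perturbed straight run, reflecting at the safe box."""
    n = max(int(round(length)), 2)
    d = _unit(direction.copy())
    u, w = _perp_basis(d)
    phase_u, phase_w = rng.uniform(0, 2 * np.pi, size=2)
    # one to two full wiggle periods along the branch
    freq = 2 * np.pi * rng.uniform(1.0, 2.0) / n
    pts = np.empty((n, 3))
    pos = start.astype(float).copy()
    base = pos.copy()
    for i in range(n):
        off = amplitude * (
            math.sin(freq * i + phase_u) * u + math.sin(freq * i + phase_w) * w
        )
        p = base + off
        # reflect the base direction off the walls of the safe box
        for ax in range(3):
            if p[ax] < lo[ax] or p[ax] > hi[ax]:
                d[ax] = -d[ax]
                p[ax] = min(max(p[ax], lo[ax]), hi[ax])
        pts[i] = p
        base = base + d
        base = np.clip(base, lo, hi)
    return pts


def generate_vessel_tree(spec: VesselTreeSpec, rng: Optional[np.random.Generator] = None) -> VesselTree:
    """Grow a branching vessel tree inside ``spec.volume_shape``.

    Root branches start near one face and run across the volume; each level
    spawns two children per parent tip with geometrically decayed radii.
    The whole tree is kept inside the volume with a margin of at least the
    maximum radius (plus wiggle amplitude), so rasterized tubes never touch
    the boundary.  Raises ``ValueError`` when the requested radii cannot fit.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    shape = np.asarray(spec.volume_shape, dtype=float)
    law = spec.radius_law
    if law.root_sigma > 0:
        root_radii = law.root_mean * np.exp(
            rng.normal(0.0, law.root_sigma, size=spec.n_root_branches)
        )
    else:
        root_radii = np.full(spec.n_root_branches, law.root_mean)
    max_r = float(root_radii.max())
    margin = max_r + spec.tortuosity_amplitude + 1.0
    lo = np.full(3, margin)
    hi = shape - 1.0 - margin
    if np.any(hi - lo < 4):
        raise ValueError(
            f"tree with max radius {max_r:.1f} and amplitude "
            f"{spec.tortuosity_amplitude:.1f} cannot fit in volume {spec.volume_shape}"
        )

    branches: List[Branch] = []
    span = float((hi - lo).min())

    def grow(start: np.ndarray, direction: np.ndarray, radius: float, level: int) -> None:
        length = span * (0.7 if level == 1 else 0.45) * (0.75 ** (level - 1))
        pts = _trace_branch(
            start, direction, length, radius, spec.tortuosity_amplitude, lo, hi, rng
        )
        branches.append(Branch(points=pts, radii=np.full(len(pts), radius), level=level))
        if level < spec.branch_levels:
            tip = pts[-1]
            tangent = _unit(pts[-1] - pts[-2]) if len(pts) > 1 else direction
            u, w = _perp_basis(tangent)
            for sign in (1.0, -1.0):
                ang = rng.uniform(np.pi / 6, np.pi / 3)
                azim = rng.uniform(0, 2 * np.pi)
                lateral = math.cos(azim) * u + math.sin(azim) * w
                child_dir = _unit(
                    math.cos(ang) * tangent + sign * math.sin(ang) * lateral
                )
                grow(tip, child_dir, radius * law.decay, level + 1)

    for i in range(spec.n_root_branches):
        # stagger root starts along one face of the safe box
        frac = (i + 1) / (spec.n_root_branches + 1)
        start = np.array(
            [lo[0], lo[1] + frac * (hi[1] - lo[1]), lo[2] + 0.5 * (hi[2] - lo[2])]
        )
        jitter = rng.uniform(-0.1, 0.1, size=3) * (hi - lo)
        start = np.clip(start + jitter, lo, hi)
        direction = _unit(np.array([1.0, rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3)]))
        grow(start, direction, float(root_radii[i]), 1)

    return VesselTree(branches=branches, spec=spec)


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def rasterize_mask(tree: VesselTree) -> np.ndarray:
    """Voxelize the tree: a voxel is foreground iff its center lies within
    the local radius of some centerline point (exact Euclidean criterion,
    evaluated on the branch bounding box)."""
    shape = np.asarray(tree.spec.volume_shape)
    mask = np.zeros(tuple(shape), dtype=bool)
    for br in tree.branches:
        r = float(br.radii.max())
        lo = np.maximum(np.floor(br.points.min(axis=0) - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(br.points.max(axis=0) + r + 1).astype(int) + 1, shape)
        grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
        vox = np.stack([g.ravel() for g in grids], axis=1).astype(float)  # (n, 3)
        hit = np.zeros(len(vox), dtype=bool)
        for start in range(0, len(br.points), 64):  # chunk to bound memory
            pts = br.points[start : start + 64]
            rr = br.radii[start : start + 64]
            d2 = ((vox[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            hit |= (d2 <= (rr**2)[None, :]).any(axis=1)
        sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub | hit.reshape(sub.shape)
    return mask


def bias_field(shape: Sequence[int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude·f with f a product of
    half-period cosines (|f| ≤ 1), random phases; max/min ratio is bounded
    by (1+a)/(1−a)."""
    if not (0.0 <= amplitude < 1.0):
        raise ValueError("bias amplitude must be in [0, 1)")
    grids = np.meshgrid(*[np.linspace(0, np.pi, s) for s in shape], indexing="ij")
    f = np.ones(tuple(shape))
    for g in grids:
        f = f * np.cos(g + rng.uniform(0, 2 * np.pi))
    return 1.0 + amplitude * f


def rasterize(
    tree: VesselTree,
    spec: Optional[VesselTreeSpec] = None,
    noise_sd: float = 10.0,
    bias_amplitude: float = 0.0,
    mu_b: float = 200.0,
    mu_o: float = 100.0,
    rng: Optional[np.random.Generator] = None,
) -> PhantomVolume:
    """Render a vessel tree into an intensity volume.

    Vessel voxels are drawn from N(mu_b, noise_sd²), tissue voxels from
    N(mu_o, noise_sd²) — bright-vessel angiography convention requires
    mu_b > mu_o.  A smooth multiplicative bias field of the given amplitude
    is applied last.
    """
    if mu_b <= mu_o:
        raise ValueError("vessel mean mu_b must exceed tissue mean mu_o")
    if spec is None:
        spec = tree.spec
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1]))
    mask = rasterize_mask(tree)
    vol = np.full(spec.volume_shape, float(mu_o))
    vol[mask] = mu_b
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    if bias_amplitude > 0:
        vol = vol * bias_field(spec.volume_shape, bias_amplitude, rng)
    centers = [br.points for br in tree.branches]
    return PhantomVolume(
        intensities=vol,
        truth_mask=mask,
        centerline=centers,
        point_radii=tree.point_radii,
    )


# --------------------------------------------------------------------------
# analytic tube features (volume-free path)
# --------------------------------------------------------------------------

def centerline_curvature(points: np.ndarray) -> np.ndarray:
    """Unsigned curvature |r''| of a ~unit-speed polyline, per point."""
    if len(points) < 3:
        return np.zeros(len(points))
    t = np.gradient(points, axis=0)
    speed = np.linalg.norm(t, axis=1)
    speed[speed == 0] = 1.0
    tangent = t / speed[:, None]
    dt = np.gradient(tangent, axis=0) / speed[:, None]
    return np.linalg.norm(dt, axis=1)


def tube_curvature_samples(tree: VesselTree, n_theta: int = 12) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic principal-curvature samples on the tube surface.

    For a tube of radius r around a centerline with local curvature κ, the
    principal curvatures at circumferential angle θ are k1 = 1/r and
    k2 = κ·cosθ / (1 − r·κ·cosθ); sampling θ uniformly reproduces the
    circumference-averaged surface statistics without rasterization.
    Returns (mean curvature samples, Gaussian curvature samples).
    """
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    cos_t = np.cos(theta)
    mean_c, gauss_c = [], []
    for br in tree.branches:
        kappa = centerline_curvature(br.points)
        r = br.radii
        denom = 1.0 - r[:, None] * kappa[:, None] * cos_t[None, :]
        denom = np.clip(denom, 0.2, None)  # avoid the degenerate inner fold
        k2 = kappa[:, None] * cos_t[None, :] / denom
        k1 = (1.0 / r)[:, None] * np.ones_like(k2)
        mean_c.append(((k1 + k2) / 2.0).ravel())
        gauss_c.append((k1 * k2).ravel())
    return np.concatenate(mean_c), np.concatenate(gauss_c)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassBP:
    """Class-conditional resting-BP distribution (mmHg)."""

    sbp_mean: float
    sbp_sd: float
    dbp_mean: float
    dbp_sd: float

    def __post_init__(self) -> None:
        if self.sbp_sd <= 0 or self.dbp_sd <= 0:
            raise ValueError("BP SDs must be positive")


# defaults follow the systolic-rule cohort demographics: normotensive
# 114.6 ± 5.7 / 78.4 ± 6.0, hypertensive 136.6 ± 7.2 / 85.4 ± 6.4 mmHg
NORMOTENSIVE_BP = ClassBP(114.6, 5.7, 78.4, 6.0)
HYPERTENSIVE_BP = ClassBP(136.6, 7.2, 85.4, 6.4)


@dataclass(frozen=True)
class CohortSpec:
    class_bp_params: Tuple[ClassBP, ClassBP] = (NORMOTENSIVE_BP, HYPERTENSIVE_BP)
    effect_size: float = 0.8
    n_per_class: Tuple[int, int] = (68, 48)
    reading_sd: float = 3.0  # within-subject repeat-measurement SD, mmHg
    base_tree: VesselTreeSpec = field(default_factory=VesselTreeSpec)
    rng_seed: int = 0
    # coupling strengths at full severity (effect_size = 1, MAP at the top
    # of the mild-hypertension band): radii shrink 30%, tortuosity doubles
    radius_shrink: float = 0.3
    tortuosity_gain: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect_size must be in [0, 1]")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be non-negative")


@dataclass
class Subject:
    subject_id: str
    bp_readings: List[Tuple[float, float]]
    resting_sbp: float
    resting_dbp: float
    map_value: float
    labels: dict  # rule -> label
    source: str = "original"
    true_class: str = bp_labels.NORMOTENSIVE
    tree_spec: Optional[VesselTreeSpec] = None


def severity_from_map(map_value: float, effect_size: float) -> float:
    """Vascular remodeling severity in [0, effect_size] as a function of the
    subject's resting MAP.

    Remodeling onsets once MAP leaves the normal band (above the
    normal/high-normal boundary, 99.00 mmHg) and grows linearly until it
    saturates at the grade-1/grade-2 boundary (119.00 mmHg); subjects whose
    chronic pressure load stays in or below the normal band carry no
    pressure-driven remodeling.
    """
    z = (map_value - 99.00) / (119.00 - 99.00)
    return effect_size * float(np.clip(z, 0.0, 1.0))


def subject_tree_spec(cohort: CohortSpec, map_value: float, seed: int) -> VesselTreeSpec:
    """Vessel-tree spec for one subject, coupled to their MAP severity."""
    s = severity_from_map(map_value, cohort.effect_size)
    base = cohort.base_tree
    law = replace(base.radius_law, root_mean=base.radius_law.root_mean * (1.0 - cohort.radius_shrink * s))
    return replace(
        base,
        radius_law=law,
        tortuosity_amplitude=base.tortuosity_amplitude * (1.0 + cohort.tortuosity_gain * s),
        rng_seed=seed,
    )


def generate_subject_bp(
    cls: ClassBP, reading_sd: float, rng: np.random.Generator
) -> Tuple[List[Tuple[float, float]], float, float, float]:
    true_sbp = rng.normal(cls.sbp_mean, cls.sbp_sd)
    true_dbp = rng.normal(cls.dbp_mean, cls.dbp_sd)
    readings = [
        (
            float(max(true_sbp + rng.normal(0, reading_sd), 40.0)),
            float(max(true_dbp + rng.normal(0, reading_sd), 20.0)),
        )
        for _ in range(4)
    ]
    sbp, dbp = bp_labels.resting_bp(readings)
    return readings, sbp, dbp, bp_labels.compute_map(sbp, dbp)


def generate_cohort(
    cohort: CohortSpec,
    mode: str = "trees",
    rules: BPCategoryRules = DEFAULT_RULES,
) -> List[Subject]:
    """Draw a cohort of subjects with class-conditional blood pressure.

    ``mode`` controls how much geometry is attached: ``"bp"`` gives labels
    only, ``"trees"`` (default) attaches the MAP-coupled per-subject
    ``VesselTreeSpec`` (volumes or features can be materialized later).
    Deterministic for a fixed ``cohort.rng_seed``.
    """
    if mode not in ("bp", "trees"):
        raise ValueError("mode must be 'bp' or 'trees'")
    rng = np.random.default_rng(cohort.rng_seed)
    subjects: List[Subject] = []
    class_names = (bp_labels.NORMOTENSIVE, bp_labels.HYPERTENSIVE)
    for cls_params, n, cls_name in zip(cohort.class_bp_params, cohort.n_per_class, class_names):
        for i in range(n):
            readings, sbp, dbp, map_value = generate_subject_bp(
                cls_params, cohort.reading_sd, rng
            )
            labels = {
                "systolic": bp_labels.label_systolic(sbp, dbp, rules),
                "diastolic": bp_labels.label_diastolic(sbp, dbp, rules),
                "map": bp_labels.collapse(bp_labels.map_category(map_value, rules)),
            }
            seed = int(rng.integers(0, 2**31 - 1))
            tree_spec = (
                subject_tree_spec(cohort, map_value, seed) if mode == "trees" else None
            )
            subjects.append(
                Subject(
                    subject_id=f"{cls_name[:4]}-{i:04d}",
                    bp_readings=readings,
                    resting_sbp=sbp,
                    resting_dbp=dbp,
                    map_value=map_value,
                    labels=labels,
                    true_class=cls_name,
                    tree_spec=tree_spec,
                )
            )
    return subjects


def subject_volume(subject: Subject, **rasterize_kwargs) -> PhantomVolume:
    """Materialize a subject's phantom volume from its tree spec."""
    if subject.tree_spec is None:
        raise ValueError("subject has no tree spec (generate cohort with mode='trees')")
    tree = generate_vessel_tree(subject.tree_spec)
    return rasterize(tree, **rasterize_kwargs)
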