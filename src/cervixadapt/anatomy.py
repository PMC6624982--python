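"""Synthetic deformable pelvic anatomy.

A seeded parametric patient model stands in for the (unavailable) weekly MRI
anatomies.  The cervix-uterus is a bent elliptical capsule whose fundus is
pushed in the anterior-superior direction by bladder filling; the bladder is
a volume-matched superellipsoid; the rectum a posterior tube; the nodal
target (CTV_LN_Pelvic) a pair of bony-fixed lateral tubes; and the bowel bag
a pelvic envelope minus the other organs.  Because the organ model is
parametric, the correspondence between any two bladder-fill states is known
exactly, which supplies the ground-truth deformation field that replaces
image registration.

Population defaults are calibrated so that the 10-minute displacement of the
uterine fundus over a large cohort has median ~3.1 mm and 90th percentile
~7.8 mm, the intrafraction cervix-uterus motion statistics reported for
comparable scan intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.special import gamma as _gamma

from .geometry import DeformationField
from .grid import Mask, VoxelGrid, default_grid

__all__ = [
    "PatientTemplate",
    "AnatomyInstance",
    "FractionPair",
    "make_patient",
    "render_anatomy",
    "sample_fraction_pair",
    "ground_truth_dvf",
    "STRUCTURES",
]

STRUCTURES = ("CTV_T_HR", "CTV_T_LR", "CTV_LN_Pelvic", "bladder", "rectum", "bowel_bag")

# fixed skeletal landmarks of the model (mm, cervix-centred frame)
_CERVIX_BASE = np.array([0.0, 0.0, -30.0])
_UTERUS_DIR0 = np.array([0.0, np.sin(np.deg2rad(25.0)), np.cos(np.deg2rad(25.0))])
_FILL_PUSH_DIR = np.array([0.0, np.sin(np.deg2rad(45.0)), np.cos(np.deg2rad(45.0))])
_VAGINA_LENGTH = 20.0  # upper vagina included in the low-risk CTV
_CORPUS_EXTRA_RADIUS = 7.0  # corpus is wider than the cervix
_AP_MARGIN = 5.0  # AP margin of the high-risk CTV folded into the low-risk CTV
_BLADDER_CENTER = np.array([0.0, 45.0, -15.0])
_BLADDER_ASPECT = np.array([0.95, 1.10, 0.95])
_BLADDER_P = 2.5
_RECTUM_RADIUS = 14.0
_LN_RADIUS = 12.0
_LN_X = 55.0
_BOWEL_CENTER_Z = 110.0
_BOWEL_SEMI = np.array([75.0, 65.0, 85.0])
_BOWEL_P = 3.0
_BOWEL_CENTER_Y = 15.0


@dataclass(frozen=True)
class PatientTemplate:
    """Per-patient parameters of the deformable anatomy model.

    ``anteversion_response`` is the fundus displacement (mm) per 100 ml of
    bladder filling; together with the fill-rate law it sets the
    intrafraction motion scale.  ``regression_rate`` is the fractional
    weekly shrinkage of the high-risk CTV (0 disables regression).
    """

    patient_id: str
    uterus_length: float = 75.0
    cervix_radius: float = 16.0
    anteversion_response: float = 13.1
    bladder_base_volume: float = 60.0
    fill_rate_mean: float = 2.5
    fill_rate_sd: float = 0.5
    setup_rotation_sd: float = 1.5
    regression_rate: float = 0.0
    bowel_caudal_shift: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("uterus_length", "cervix_radius", "fill_rate_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("anteversion_response", "fill_rate_sd", "setup_rotation_sd", "regression_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# population distributions (documented in docs/methods.md); the motion block
# is calibrated so 10-min fundus displacement has p50/p90 = 3.1/7.8 mm
_POP = dict(
    uterus_length=("normal_clip", 75.0, 10.0, 55.0, 95.0),
    cervix_radius=("normal_clip", 16.0, 2.0, 12.0, 21.0),
    anteversion_response=("lognormal", 13.086, 0.6211),
    bladder_base_volume=("normal_clip", 60.0, 20.0, 15.0, 120.0),
    fill_rate_mean=("normal_clip", 2.5, 0.8, 0.8, 5.0),
    fill_rate_sd=("const", 0.5),
    setup_rotation_sd=("const", 1.5),
    regression_rate=("const", 0.0),
    bowel_caudal_shift=("normal_clip", 0.0, 10.0, -22.0, 22.0),
)


def make_patient(seed: int, overrides: Optional[Dict[str, float]] = None) -> PatientTemplate:
    """Draw one patient template from the population distributions.

    Deterministic for a given seed; any field may be overridden by name.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    overrides = dict(overrides or {})
    valid = set(PatientTemplate.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown override keys: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    params: Dict[str, float] = {}
    for name, spec in _POP.items():
        kind = spec[0]
        if kind == "normal_clip":
            _, mu, sd, lo, hi = spec
            params[name] = float(np.clip(rng.normal(mu, sd), lo, hi))
        elif kind == "lognormal":
            _, med, sigma = spec
            params[name] = float(np.exp(rng.normal(np.log(med), sigma)))
        else:  # const
            params[name] = float(spec[1])
    params.update({k: v for k, v in overrides.items() if k not in ("patient_id", "rng_seed")})
    pid = overrides.get("patient_id", f"P{seed:04d}")
    return PatientTemplate(patient_id=str(pid), rng_seed=int(seed), **params)


# --------------------------------------------------------------------------
# capsule model of the cervix-uterus


def _bezier(p0, p1, p2, s):
    s = np.asarray(s, dtype=float)[:, None]
    return (1 - s) ** 2 * p0 + 2 * s * (1 - s) * p1 + s**2 * p2


def _bezier_tangent(p0, p1, p2, s):
    s = np.asarray(s, dtype=float)[:, None]
    return 2 * (1 - s) * (p1 - p0) + 2 * s * (p2 - p1)


def fundus_center(template: PatientTemplate, bladder_fill: float) -> np.ndarray:
    """Physical position (mm) of the uterine fundus centre at a given fill."""
    fundus0 = _CERVIX_BASE + template.uterus_length * _UTERUS_DIR0
    return fundus0 + template.anteversion_response * bladder_fill / 100.0 * _FILL_PUSH_DIR


def _control_points(template: PatientTemplate, fill: float):
    p0 = _CERVIX_BASE
    p1 = p0 + 0.45 * template.uterus_length * _UTERUS_DIR0 + np.array([0.0, 8.0, 0.0])
    p2 = fundus_center(template, fill)
    return p0, p1, p2


def _regression_shrink(template: PatientTemplate, week: int) -> float:
    return max(0.5, 1.0 - template.regression_rate * week)


def _radius_profiles(template: PatientTemplate, s: np.ndarray, week: int):
    """(r_x, r_n) semi-axes along the capsule; AP extra over the cervix part.

    Tumour regression (if enabled) shrinks the cervix radius with treatment
    week, which both target volumes share."""
    rc = template.cervix_radius * _regression_shrink(template, week)
    r_x = rc + _CORPUS_EXTRA_RADIUS * np.clip((s - 0.35) / 0.40, 0.0, 1.0)
    ap = _AP_MARGIN * np.clip((0.45 - s) / 0.15, 0.0, 1.0)
    return r_x, r_x + ap


_CAPSULE_BLEND_RADIUS = 2.5  # mm tangential blending of the row ellipsoids


def _capsule_rows(template: PatientTemplate, fill: float, week: int,
                  n_uterus: int = 140, n_vagina: int = 24, n_cap: int = 16):
    """Sampled cross-section rows of the cervix-uterus capsule.

    Returns (centers, tang, n_hat, r_x, r_n): row centres, local frames and
    per-row semi-axes (LR and AP-ish).  End caps are encoded as extra rows of
    shrinking radius so the rasterizer and the surface mesh describe the
    same continuous shape.  Row order and count are identical for every
    bladder fill, giving exact cross-fill correspondence; the vaginal rows
    are static.
    """
    p0, p1, p2 = _control_points(template, fill)
    s = np.linspace(0.0, 1.0, n_uterus)
    centers = _bezier(p0, p1, p2, s)
    tang = _bezier_tangent(p0, p1, p2, s)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    # vagina: straight continuation below the cervix, static across fills
    t0 = tang[0]
    sv = np.linspace(1.0, 1.0 / n_vagina, n_vagina)
    v_centers = p0 - np.outer(sv * _VAGINA_LENGTH, t0)
    v_tang = np.tile(t0, (n_vagina, 1))
    centers = np.vstack([v_centers, centers])
    tang = np.vstack([v_tang, tang])
    r_x_u, r_n_u = _radius_profiles(template, s, week)
    r_vag = 0.8 * template.cervix_radius * _regression_shrink(template, week)
    r_x = np.concatenate([np.full(n_vagina, r_vag), r_x_u])
    r_n = np.concatenate([np.full(n_vagina, r_vag), r_n_u])
    # end caps: rows at axial offsets a with cross radii scaled by
    # sqrt(1 - (a/r)^2); the outermost row sits one blend radius short of the
    # pole so the blended union ends exactly at the pole
    rt = _CAPSULE_BLEND_RADIUS
    rows_b, rows_t = [], []
    for end, sign, store in ((0, -1.0, rows_b), (-1, +1.0, rows_t)):
        r_end = r_x[end]
        a = np.linspace(r_end - rt, (r_end - rt) / n_cap, n_cap)
        f = np.sqrt(np.clip(1.0 - (a / r_end) ** 2, 0.0, 1.0))
        for am, fm in zip(a, f):
            store.append((centers[end] + sign * am * tang[end], tang[end],
                          fm * r_x[end], fm * r_n[end]))
    if rows_t:
        rows_t = rows_t[::-1]  # equator-most first
    centers = np.vstack([[r[0] for r in rows_b], centers, [r[0] for r in rows_t]])
    tang = np.vstack([[r[1] for r in rows_b], tang, [r[1] for r in rows_t]])
    r_x = np.concatenate([[r[2] for r in rows_b], r_x, [r[2] for r in rows_t]])
    r_n = np.concatenate([[r[3] for r in rows_b], r_n, [r[3] for r in rows_t]])
    # frames: x_hat is global LR; n_hat completes a right-handed frame in AP/SI
    n_hat = np.stack([np.zeros(len(tang)), tang[:, 2], -tang[:, 1]], axis=1)
    n_hat /= np.linalg.norm(n_hat, axis=1, keepdims=True)
    return centers, tang, n_hat, r_x, r_n


def _rasterize_capsule(grid: VoxelGrid, centers, tang, n_hat, r_x, r_n) -> np.ndarray:
    """Union of per-row ellipsoids (axes x_hat/n_hat = r_x/r_n, tangential =
    the blend radius); dense rows make the union a smooth capped tube."""
    pad = float(np.max(r_n)) + 2 * max(grid.spacing)
    lo_mm = centers.min(axis=0) - pad
    hi_mm = centers.max(axis=0) + pad
    lo = np.maximum(np.floor(grid.mm_to_indices(lo_mm)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.mm_to_indices(hi_mm)).astype(int) + 1, np.asarray(grid.shape))
    if np.any(hi <= lo):
        raise RuntimeError("structure lies outside the voxel grid")
    axes = [grid.axis_coords(ax)[lo[ax]:hi[ax]] for ax in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    inside = np.zeros(len(pts), dtype=bool)
    rt = _CAPSULE_BLEND_RADIUS
    for i in range(len(centers)):
        o = pts - centers[i]
        ox = o[:, 0]
        on = o @ n_hat[i]
        ot = o @ tang[i]
        q = (ox / r_x[i]) ** 2 + (on / r_n[i]) ** 2 + (ot / rt) ** 2
        inside |= q <= 1.0
    data = np.zeros(grid.shape, dtype=bool)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside.reshape(tuple(hi - lo))
    return data


def _superellipsoid(grid: VoxelGrid, center, semi, p, clip: bool = False) -> np.ndarray:
    """Rasterize |x/a|^p + |y/b|^p + |z/c|^p <= 1.  With ``clip`` the shape
    may extend beyond the grid and is truncated (used for the bowel
    envelope, which continues cranially past the simulated volume);
    otherwise an out-of-grid shape is a generation error."""
    center = np.asarray(center, float)
    semi = np.asarray(semi, float)
    lo_mm, hi_mm = center - semi, center + semi
    if not clip and (
        np.any(lo_mm < np.asarray(grid.origin) - 0.5 * np.asarray(grid.spacing))
        or np.any(hi_mm > np.asarray(grid.indices_to_mm(np.asarray(grid.shape) - 1))
                  + 0.5 * np.asarray(grid.spacing))
    ):
        raise RuntimeError(
            f"superellipsoid (center={center}, semi={semi}) extends outside the grid"
        )
    lo = np.maximum(np.floor(grid.mm_to_indices(lo_mm)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.mm_to_indices(hi_mm)).astype(int) + 1, np.asarray(grid.shape))
    axes = [grid.axis_coords(ax)[lo[ax]:hi[ax]] for ax in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    q = (
        np.abs((xx - center[0]) / semi[0]) ** p
        + np.abs((yy - center[1]) / semi[1]) ** p
        + np.abs((zz - center[2]) / semi[2]) ** p
    )
    data = np.zeros(grid.shape, dtype=bool)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = q <= 1.0
    return data


def _superellipsoid_volume_const(p: float) -> float:
    return 8.0 * _gamma(1 + 1 / p) ** 3 / _gamma(1 + 3 / p)


def _bladder_mask(grid: VoxelGrid, fill_ml: float, exclude: np.ndarray) -> np.ndarray:
    """Superellipsoid bladder matched to the target volume after carving."""
    if fill_ml <= 0:
        return np.zeros(grid.shape, dtype=bool)
    target_mm3 = fill_ml * 1000.0
    c = _superellipsoid_volume_const(_BLADDER_P) * float(np.prod(_BLADDER_ASPECT))
    u = (target_mm3 / c) ** (1.0 / 3.0)
    vox = grid.voxel_volume_mm3
    data = None
    for _ in range(3):
        data = _superellipsoid(grid, _BLADDER_CENTER, u * _BLADDER_ASPECT, _BLADDER_P) & ~exclude
        got = data.sum() * vox
        if got <= 0:
            u *= 1.3
            continue
        u *= (target_mm3 / got) ** (1.0 / 3.0)
    return data


def _tube_mask(grid: VoxelGrid, centers: np.ndarray, radius: float) -> np.ndarray:
    pad = radius + 2 * max(grid.spacing)
    lo = np.maximum(np.floor(grid.mm_to_indices(centers.min(axis=0) - pad)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.mm_to_indices(centers.max(axis=0) + pad)).astype(int) + 1,
                    np.asarray(grid.shape))
    axes = [grid.axis_coords(ax)[lo[ax]:hi[ax]] for ax in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    best = np.full(len(pts), np.inf)
    for cpt in centers:
        d2 = ((pts - cpt) ** 2).sum(axis=1)
        np.minimum(best, d2, out=best)
    data = np.zeros(grid.shape, dtype=bool)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = (best <= radius**2).reshape(tuple(hi - lo))
    return data


def _rectum_centers() -> np.ndarray:
    z = np.linspace(-60.0, 30.0, 40)
    y = -45.0 + 8.0 * ((z + 20.0) / 60.0) ** 2
    return np.stack([np.zeros_like(z), y, z], axis=1)


def _ln_centers() -> np.ndarray:
    z = np.linspace(-10.0, 95.0, 45)
    y = -20.0 + 0.25 * (z + 10.0)
    left = np.stack([np.full_like(z, _LN_X), y, z], axis=1)
    right = np.stack([np.full_like(z, -_LN_X), y, z], axis=1)
    return np.vstack([left, right])


def _rotate_about(points: np.ndarray, angle_deg: float, center: np.ndarray) -> np.ndarray:
    """Rotate points about the LR axis through ``center`` (sagittal rotation)."""
    if angle_deg == 0.0:
        return points
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    rel = points - center
    out = rel.copy()
    out[:, 1] = c * rel[:, 1] - s * rel[:, 2]
    out[:, 2] = s * rel[:, 1] + c * rel[:, 2]
    return out + center


@dataclass
class AnatomyInstance:
    """One voxelized anatomical state (all structures + landmarks).

    Masks are rendered lazily on first access and cached; landmark positions
    are analytic and always available.
    """

    template: PatientTemplate
    grid: VoxelGrid
    bladder_fill: float
    week_index: int = 0
    setup_rotation: float = 0.0
    _masks: Optional[Dict[str, Mask]] = field(default=None, repr=False)

    @property
    def landmarks(self) -> Dict[str, np.ndarray]:
        return {"top_of_uterus": fundus_center(self.template, self.bladder_fill)}

    @property
    def masks(self) -> Dict[str, Mask]:
        if self._masks is None:
            self._masks = _render_masks(self)
        return self._masks

    def mask(self, name: str) -> Mask:
        return self.masks[name]

    def validate(self) -> None:
        """Check the structural invariants of a rendered instance."""
        m = self.masks
        if not m["CTV_T_LR"].contains(m["CTV_T_HR"]):
            raise AssertionError("CTV_T_HR not contained in CTV_T_LR")
        if not m["bladder"].intersect(m["CTV_T_LR"]).is_empty():
            raise AssertionError("bladder overlaps the low-risk CTV core")
        for other in ("bladder", "rectum", "CTV_T_LR"):
            if not m["bowel_bag"].intersect(m[other]).is_empty():
                raise AssertionError(f"bowel bag overlaps {other}")


def _render_masks(inst: AnatomyInstance) -> Dict[str, Mask]:
    t, g = inst.template, inst.grid
    rows = _capsule_rows(t, inst.bladder_fill, inst.week_index)
    lr_data = _rasterize_capsule(g, *rows)
    # high-risk CTV: cervix portion of the same capsule (isotropic radius),
    # optionally shrinking with treatment week
    p0, p1, p2 = _control_points(t, inst.bladder_fill)
    s_hr = np.linspace(0.0, 0.30, 28)
    c_hr = _bezier(p0, p1, p2, s_hr)
    shrink = _regression_shrink(t, inst.week_index)
    hr_data = _tube_mask(g, c_hr, t.cervix_radius * shrink)
    hr_data &= lr_data
    bladder = _bladder_mask(g, inst.bladder_fill, lr_data)
    rectum = _tube_mask(g, _rectum_centers(), _RECTUM_RADIUS) & ~lr_data & ~bladder
    ln_centers = _rotate_about(_ln_centers(), inst.setup_rotation,
                               inst.landmarks["top_of_uterus"])
    ln = _tube_mask(g, ln_centers, _LN_RADIUS)
    bowel_center = np.array([0.0, _BOWEL_CENTER_Y,
                             _BOWEL_CENTER_Z + t.bowel_caudal_shift])
    bowel = _superellipsoid(g, bowel_center, _BOWEL_SEMI, _BOWEL_P, clip=True)
    bowel &= ~(bladder | rectum | lr_data)
    return {
        "CTV_T_HR": Mask(g, hr_data),
        "CTV_T_LR": Mask(g, lr_data),
        "CTV_LN_Pelvic": Mask(g, ln),
        "bladder": Mask(g, bladder),
        "rectum": Mask(g, rectum),
        "bowel_bag": Mask(g, bowel),
    }


def render_anatomy(
    template: PatientTemplate,
    bladder_fill: float,
    week: int = 0,
    grid: Optional[VoxelGrid] = None,
    setup_rotation: float = 0.0,
) -> AnatomyInstance:
    """Voxelized anatomy of one patient at a given bladder fill (ml)."""
    if bladder_fill < 0:
        raise ValueError("bladder_fill must be >= 0")
    return AnatomyInstance(
        template=template,
        grid=grid if grid is not None else default_grid(),
        bladder_fill=float(bladder_fill),
        week_index=int(week),
        setup_rotation=float(setup_rotation),
    )


@dataclass
class FractionPair:
    """Pre-delivery (t0) and post-interval (t1) anatomies of one fraction.

    t0 plays the role of the plan-selection / replanning scan, t1 the
    evaluation scan acquired ``delta_t`` minutes later.  Translations between
    t0 and t1 are not modelled; the setup rotation (about the top of the
    uterus, LR axis) displaces the bony frame and is shared by both states.
    """

    t0: AnatomyInstance
    t1: AnatomyInstance
    delta_t: float
    setup_rotation: float

    def __post_init__(self) -> None:
        if self.t1.bladder_fill < self.t0.bladder_fill:
            raise ValueError("t1 bladder fill must be >= t0 bladder fill")

    @property
    def landmark_displacement(self) -> float:
        """Euclidean top-of-uterus displacement between t0 and t1 (mm)."""
        a = self.t0.landmarks["top_of_uterus"]
        b = self.t1.landmarks["top_of_uterus"]
        return float(np.linalg.norm(b - a))


def sample_fraction_pair(
    template: PatientTemplate,
    week: int,
    delta_t: float = 10.0,
    seed: int = 0,
    grid: Optional[VoxelGrid] = None,
) -> FractionPair:
    """Draw one fraction's paired anatomies separated by ``delta_t`` minutes.

    The t0 fill comes from the patient's fill distribution; the t1 fill adds
    ``rate * delta_t`` with the rate drawn from the patient's fill-rate law
    (truncated at a small positive floor).
    """
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    rng = np.random.default_rng([int(seed), int(template.rng_seed), int(week)])
    # daily fills stay bracketed by the empty/full planning-scan states, as
    # the drinking protocol intends
    extra = float(np.clip(rng.normal(90.0, 50.0), 0.0, 220.0))
    fill0 = float(np.clip(template.bladder_base_volume + extra, 40.0, 290.0))
    rate = float(np.clip(rng.normal(template.fill_rate_mean, template.fill_rate_sd), 0.2, None))
    fill1 = fill0 + rate * delta_t
    rot = float(rng.normal(0.0, template.setup_rotation_sd)) if template.setup_rotation_sd > 0 else 0.0
    g = grid if grid is not None else default_grid()
    t0 = render_anatomy(template, fill0, week=week, grid=g, setup_rotation=rot)
    t1 = render_anatomy(template, fill1, week=week, grid=g, setup_rotation=rot)
    return FractionPair(t0=t0, t1=t1, delta_t=float(delta_t), setup_rotation=rot)


# --------------------------------------------------------------------------
# ground-truth deformation field


def _surface_param_grid(template: PatientTemplate, fill: float, week: int,
                        n_phi: int = 40):
    """Parametric surface vertices of the low-risk CTV capsule.

    One vertex ring per capsule row (caps included) plus the two poles.  The
    row and angle indexing is identical for every fill, so equal indices
    correspond across anatomical states.
    """
    centers, tang, n_hat, r_x, r_n = _capsule_rows(template, fill, week)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    cphi, sphi = np.cos(phi), np.sin(phi)
    x_hat = np.array([1.0, 0.0, 0.0])
    rings = [
        centers[i] + np.outer(r_x[i] * cphi, x_hat) + np.outer(r_n[i] * sphi, n_hat[i])
        for i in range(len(centers))
    ]
    verts = np.vstack(rings)
    pole_bot = centers[0] - _CAPSULE_BLEND_RADIUS * tang[0]
    pole_top = centers[-1] + _CAPSULE_BLEND_RADIUS * tang[-1]
    verts = np.vstack([verts, pole_bot, pole_top])
    n_rings = len(rings)
    faces = []
    for r in range(n_rings - 1):
        a0, b0 = r * n_phi, (r + 1) * n_phi
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            faces.append([a0 + j, b0 + jn, b0 + j])
            faces.append([a0 + j, a0 + jn, b0 + jn])
    ib, it = len(verts) - 2, len(verts) - 1
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        faces.append([ib, jn, j])
        top0 = (n_rings - 1) * n_phi
        faces.append([it, top0 + j, top0 + jn])
    return verts, np.asarray(faces, dtype=int)


def ground_truth_dvf(
    template: PatientTemplate,
    fill_full: float,
    fill_empty: float,
    week: int = 0,
) -> DeformationField:
    """Exact full-to-empty correspondence field of the low-risk CTV surface.

    The parametric capsule provides the correspondence directly: equal
    surface parameters at the two fills are corresponding material points,
    which is the role the biomechanical contour registration plays on real
    scans.
    """
    if not fill_full >= fill_empty >= 0:
        raise ValueError("need fill_full >= fill_empty >= 0")
    v_full, faces = _surface_param_grid(template, fill_full, week)
    v_empty, _ = _surface_param_grid(template, fill_empty, week)
    return DeformationField(
        vertices=v_full,
        displacements=v_empty - v_full,
        faces=faces,
        source_label=f"fill_{fill_full:g}",
        target_label=f"fill_{fill_empty:g}",
    )
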