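"""Margin-expansion, interpolation-count and surface-distance oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervixadapt import (DeformationField, MarginSpec, Mask, VoxelGrid, expand,
                         interpolate_structure, max_surface_distance,
                         min_interpolation_count)

from conftest import random_mask, small_grid


# ---------------------------------------------------------------------------
# independent Minkowski-dilation oracle: explicit shift-union


def octant_offsets(spec: MarginSpec, spacing):
    """All integer offsets inside the octant-ellipsoid structuring element,
    enumerated in pure python."""
    m = {(+1,): None}
    margins = np.array([[spec.right, spec.left],
                        [spec.posterior, spec.anterior],
                        [spec.inferior, spec.superior]])
    half = [int(np.ceil(margins[ax].max() / spacing[ax])) for ax in range(3)]
    out = []
    for i in range(-half[0], half[0] + 1):
        for j in range(-half[1], half[1] + 1):
            for k in range(-half[2], half[2] + 1):
                q = 0.0
                ok = True
                for ax, off in enumerate((i, j, k)):
                    d = off * spacing[ax]
                    semi = margins[ax][1] if d >= 0 else margins[ax][0]
                    if d == 0:
                        continue
                    if semi == 0:
                        ok = False
                        break
                    q += (d / semi) ** 2
                if ok and q <= 1.0 + 1e-12:
                    out.append((i, j, k))
    return out


def minkowski_oracle(mask: Mask, spec: MarginSpec) -> np.ndarray:
    """Dilation as an explicit union of shifted copies (no scipy, no FFT)."""
    g = mask.grid
    seeds = mask.data
    if spec.zero_margin_si_plane is not None:
        z = g.axis_coords(2)
        seeds = seeds & (z >= spec.zero_margin_si_plane)[None, None, :]
    out = mask.data.copy()
    n = np.array(g.shape)
    for off in octant_offsets(spec, g.spacing):
        src = [slice(max(0, -o), min(n[ax], n[ax] - o)) for ax, o in enumerate(off)]
        dst = [slice(max(0, o), min(n[ax], n[ax] + o)) for ax, o in enumerate(off)]
        out[tuple(dst)] |= seeds[tuple(src)]
    return out


@pytest.mark.parametrize("case", range(12))
def test_expand_matches_minkowski_oracle(case, rng):
    """Anisotropic/asymmetric margins equal brute-force Minkowski dilation."""
    r = np.random.default_rng(case)
    n = int(r.integers(12, 32))
    sp = float(r.choice([1.0, 1.5, 2.5]))
    g = VoxelGrid((n, n, n), (sp, sp, sp))
    mask = random_mask(r, g, p=float(r.uniform(0.01, 0.15)))
    margins = r.uniform(0.0, 6.0, size=6)
    margins[margins < sp / 2] = 0.0  # avoid the sub-voxel quantization warning
    plane = None if case % 3 else float(g.axis_coords(2)[n // 3])
    spec = MarginSpec(*margins, zero_margin_si_plane=plane)
    got = expand(mask, spec)
    np.testing.assert_array_equal(got.data, minkowski_oracle(mask, spec))


def test_expand_isotropic_ball_volume():
    """5 mm isotropic expansion of a point is a digital ball of radius 5."""
    g = small_grid(n=16, spacing=1.0)
    data = np.zeros(g.shape, bool)
    data[8, 8, 8] = True
    ball = expand(Mask(g, data), MarginSpec.isotropic(5.0))
    expected = 4.0 / 3.0 * np.pi * 5.0**3
    assert ball.voxel_count() == pytest.approx(expected, rel=0.05)


def test_expand_anisotropic_extents():
    """10 mm AP / 5 mm LR+SI margins give 21- and 11-voxel extents."""
    g = small_grid(n=25, spacing=1.0)
    data = np.zeros(g.shape, bool)
    data[12, 12, 12] = True
    spec = MarginSpec(left=5, right=5, anterior=10, posterior=10,
                      inferior=5, superior=5)
    out = expand(Mask(g, data), spec)
    idx = np.argwhere(out.data)
    extents = idx.max(axis=0) - idx.min(axis=0) + 1
    assert tuple(extents) == (11, 21, 11)


def test_expand_zero_margin_is_identity(rng):
    g = small_grid()
    m = random_mask(rng, g, 0.1)
    np.testing.assert_array_equal(expand(m, MarginSpec()).data, m.data)


def test_expand_zero_margin_region_keeps_but_does_not_seed():
    g = small_grid(n=20, spacing=1.0)
    data = np.zeros(g.shape, bool)
    data[10, 10, 3] = True   # below the plane: kept, no expansion seeded
    data[10, 10, 14] = True  # above: expands normally
    spec = MarginSpec.isotropic(3.0, zero_margin_si_plane=8.0)
    out = expand(Mask(g, data), spec)
    assert out.data[10, 10, 3]
    assert not out.data[10, 13, 3]
    assert out.data[10, 13, 14]


def test_expand_subvoxel_margin_warns():
    g = small_grid(n=10, spacing=2.5)
    data = np.zeros(g.shape, bool)
    data[5, 5, 5] = True
    with pytest.warns(UserWarning, match="quantized"):
        expand(Mask(g, data), MarginSpec.isotropic(1.0))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(p=st.floats(0.02, 0.3), m1=st.floats(0, 4), m2=st.floats(0, 4),
       seed=st.integers(0, 10**6))
def test_expand_extensive_and_monotone(p, m1, m2, seed):
    """Dilation contains its input and is monotone in the margins."""
    r = np.random.default_rng(seed)
    g = small_grid(n=14, spacing=1.0)
    mask = random_mask(r, g, p)
    lo, hi = sorted([m1, m2])
    lo = 0.0 if lo < 0.5 else lo
    hi = 0.0 if hi < 0.5 else hi
    small = expand(mask, MarginSpec.isotropic(lo))
    big = expand(mask, MarginSpec.isotropic(hi))
    assert small.contains(mask)
    assert big.contains(small)


# ---------------------------------------------------------------------------
# deformation fields


def _translation_field(mask: Mask, shift):
    verts = mask.surface_points_mm()
    disp = np.tile(np.asarray(shift, float), (len(verts), 1))
    return DeformationField(verts, disp)


def brute_force_min_count(field, max_gap, k_max=50):
    """Exhaustive search: smallest k whose consecutive-shape gaps fit."""
    for k in range(k_max + 1):
        alphas = np.linspace(0.0, 1.0, k + 2)
        gaps = [
            max_surface_distance(field.moved_vertices(a0), field.moved_vertices(a1),
                                 mode="correspondence")
            for a0, a1 in zip(alphas[:-1], alphas[1:])
        ]
        if max(gaps) <= max_gap:
            return k
    raise AssertionError("no k found")


@pytest.mark.parametrize("seed", range(20))
def test_min_interpolation_count_matches_exhaustive_search(seed):
    r = np.random.default_rng(seed)
    verts = r.normal(0, 30, (60, 3))
    disp = r.normal(0, r.uniform(1, 20), (60, 3))
    field = DeformationField(verts, disp)
    gap = float(r.uniform(2, 15))
    assert min_interpolation_count(field, gap) == brute_force_min_count(field, gap)


@pytest.mark.parametrize("maxdisp,expected", [(9.0, 0), (25.0, 2), (40.0, 3)])
def test_min_interpolation_count_known_values(maxdisp, expected):
    verts = np.zeros((4, 3))
    disp = np.zeros((4, 3))
    disp[0, 2] = maxdisp
    assert min_interpolation_count(DeformationField(verts, disp), 10.0) == expected


def test_interpolation_pure_translation_centroid():
    """A 20 mm translation field at alpha = 0.5 moves the centroid 10 mm."""
    g = small_grid(n=40, spacing=1.0)
    x, y, z = np.meshgrid(*[g.axis_coords(a) for a in range(3)], indexing="ij")
    sphere = Mask(g, (x - 10) ** 2 + (y - 20) ** 2 + (z - 10) ** 2 <= 6.0**2)
    ctr = sphere.centroid_mm()
    # parametric sphere mesh (the field needs faces for normals)
    n_th, n_ph = 24, 24
    th = np.linspace(0, np.pi, n_th)
    ph = np.linspace(0, 2 * np.pi, n_ph, endpoint=False)
    tt, pp = np.meshgrid(th, ph, indexing="ij")
    pts = np.stack([6 * np.sin(tt) * np.cos(pp) + 10,
                    6 * np.sin(tt) * np.sin(pp) + 20,
                    6 * np.cos(tt) + 10], axis=-1).reshape(-1, 3)
    faces = []
    for i in range(n_th - 1):
        for j in range(n_ph):
            jn = (j + 1) % n_ph
            a, b = i * n_ph + j, (i + 1) * n_ph + j
            c, d = (i + 1) * n_ph + jn, i * n_ph + jn
            faces.append([a, d, c])
            faces.append([a, c, b])
    field = DeformationField(pts, np.tile([0.0, -20.0, 0.0], (len(pts), 1)),
                             faces=np.asarray(faces))
    m_half = interpolate_structure(field, 0.5, g)
    got = m_half.centroid_mm()
    np.testing.assert_allclose(got, ctr + [0, -10, 0], atol=1.0)
    with pytest.raises(ValueError):
        interpolate_structure(field, 1.5, g)


def test_max_surface_distance_translation(rng):
    g = small_grid(n=30, spacing=1.0)
    data = np.zeros(g.shape, bool)
    data[5:12, 5:12, 5:12] = True
    a = Mask(g, data)
    b = Mask(g, np.roll(data, 7, axis=0))
    assert max_surface_distance(a, b, mode="hausdorff") == pytest.approx(7.0)
    assert max_surface_distance(a, a, mode="hausdorff") == 0.0
    verts = a.surface_points_mm()
    moved = verts + [7.0, 0, 0]
    assert max_surface_distance(verts, moved, mode="correspondence") == pytest.approx(7.0)
    with pytest.raises(ValueError):
        max_surface_distance(a, b, mode="correspondence")
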