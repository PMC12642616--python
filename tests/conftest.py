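"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the implementation's code paths:
lumen areas are checked by Monte-Carlo point sampling with shapely
containment tests, and SASA by rejection sampling with a seeded RNG
instead of the deterministic golden-spiral quadrature.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from bltpgeom import GrooveSpec, make_groove
from bltpgeom.axis import SliceSlab


# ---------------------------------------------------------------------------
# hand-written PDB fixture helpers
# ---------------------------------------------------------------------------

def pdb_atom_line(serial, name, resname, chain, resnum, xyz,
                  occ=1.0, altloc=" ", element="C", record="ATOM"):
    """One fixed-column PDB ATOM/HETATM record."""
    x, y, z = xyz
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}"
        f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


# ---------------------------------------------------------------------------
# synthetic structure fixtures (session-scoped: generation is deterministic)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def halfpipe():
    """Jitter-free half-pipe groove, constant 10 A radius, axis +z."""
    spec = GrooveSpec(length=100.0, inner_radius_profile=10.0,
                      opening_angle=180.0, atom_radius=1.7)
    model, truth = make_groove(spec)
    return spec, model, truth


@pytest.fixture(scope="session")
def twolayer():
    """Two-layer groove: Leu lining at r=10, Asp exterior at r=13."""
    spec = GrooveSpec(length=100.0, inner_radius_profile=10.0,
                      opening_angle=180.0, wall_layers=2, layer_spacing=3.0,
                      atom_radius=1.7)
    model, truth = make_groove(spec)
    return spec, model, truth


def semicircle_slab(radius=10.0, n=721, atom_radius=0.0, closed=False):
    """A SliceSlab whose projected atoms lie on a (semi)circular arc."""
    if closed:
        theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    else:
        theta = np.linspace(-math.pi / 2.0, math.pi / 2.0, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    return SliceSlab(index=0, s_lo=0.0, s_hi=5.0,
                     atom_indices=np.arange(len(pts)), projected=pts,
                     radii=np.full(len(pts), atom_radius))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mc_lumen_area(points, radii, n_samples=1_000_000, seed=42):
    """Monte-Carlo lumen area: uniform samples in the hull bounding box,
    counted when inside the convex hull (shapely) and outside every wall
    disk (KD-tree)."""
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    minx, miny, maxx, maxy = hull.bounds
    rng = np.random.default_rng(seed)
    xs = rng.uniform(minx, maxx, n_samples)
    ys = rng.uniform(miny, maxy, n_samples)
    inside = shapely.contains_xy(hull, xs, ys)
    radii = np.asarray(radii, dtype=float)
    if radii.max() > 0:
        tree = cKDTree(points)
        samples = np.column_stack([xs, ys])
        dist, idx = tree.query(samples, k=min(8, len(points)))
        in_wall = (dist < radii[idx]).any(axis=1)
        inside &= ~in_wall
    box_area = (maxx - minx) * (maxy - miny)
    return inside.mean() * box_area


def rejection_sasa(coords, radii, probe=1.4, n_samples=10_000, seed=7):
    """Brute-force SASA: random (seeded) directions on each inflated sphere,
    accessible when outside all other inflated spheres."""
    coords = np.asarray(coords, dtype=float)
    inflated = np.asarray(radii, dtype=float) + probe
    rng = np.random.default_rng(seed)
    total = 0.0
    per_atom = []
    for i in range(len(coords)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + inflated[i] * v
        accessible = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= inflated[j] ** 2
        area = accessible.mean() * 4.0 * math.pi * inflated[i] ** 2
        per_atom.append(area)
        total += area
    return total, np.array(per_atom)


def spherical_cap_sasa(r, probe, d):
    """Closed-form SASA of one of two equal spheres at center distance d:
    4*pi*R^2 minus the buried cap 2*pi*R*h with R = r + probe, h = R - d/2."""
    R = r + probe
    h = R - d / 2.0
    return 4.0 * math.pi * R * R - 2.0 * math.pi * R * h
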