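"""Synthetic structures with known ground-truth geometry.

The generator builds "taco shell" groove lattices — pseudo-atom walls on a
(possibly flaring) cylindrical surface with a missing arc (the mouth) —
plus simple sphere systems with analytically known surface areas.  Every
downstream stage (axis fitting, slicing, lumen metrics, SASA, lining
classification) can therefore be validated against exact ground truth
without downloading any deposited model.

Pseudo-atoms are written as single-atom residues (atom name CA, element C)
so that residue-level hydropathy profiling works on synthetic data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io import (
    AtomRecord,
    BltpGeomError,
    DEFAULT_VDW_RADIUS,
    StructureModel,
    write_pdb,
)

RadiusProfile = Callable[[float], float]


class SpecError(BltpGeomError):
    """Invalid synthetic-structure specification."""


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise SpecError("axis direction must be non-zero")
    return v / n


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane normal to ``direction``."""
    d = _unit(direction)
    # seed with the global axis least aligned with d
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(d)))] = 1.0
    u = seed - np.dot(seed, d) * d
    u /= np.linalg.norm(u)
    w = np.cross(d, u)
    return u, w


@dataclass
class GrooveSpec:
    """Parameters of a synthetic open-groove wall lattice.

    ``opening_angle`` is the missing arc in degrees: 0 gives a closed tube,
    180 a half-pipe.  ``inner_radius_profile`` may be a constant (Angstrom)
    or a callable of the axial coordinate s in [0, length].  Wall layers
    stack outward every ``layer_spacing`` Angstrom; pseudo-atoms are spaced
    ``lattice_spacing`` Angstrom apart both along the arc and axially.
    Identical spec + seed reproduce bitwise-identical coordinates.
    """

    length: float = 100.0
    inner_radius_profile: float | RadiusProfile = 10.0
    opening_angle: float = 180.0
    wall_layers: int = 1
    layer_spacing: float = 3.0
    lattice_spacing: float = 1.5
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    inner_residue: str = "LEU"
    outer_residue: str = "ASP"
    atom_radius: float = DEFAULT_VDW_RADIUS
    seed: int = 0
    jitter_sd: float = 0.0

    def radius_at(self, s: float) -> float:
        if callable(self.inner_radius_profile):
            return float(self.inner_radius_profile(s))
        return float(self.inner_radius_profile)

    def validate(self) -> None:
        if self.length <= 0:
            raise SpecError("length must be positive")
        if self.lattice_spacing <= 0:
            raise SpecError("lattice_spacing must be positive")
        if self.wall_layers < 1:
            raise SpecError("wall_layers must be >= 1")
        if not 0 <= self.opening_angle < 360:
            raise SpecError("opening_angle must be in [0, 360)")
        if self.atom_radius < 0 or self.jitter_sd < 0:
            raise SpecError("atom_radius and jitter_sd must be non-negative")
        n_check = max(2, int(math.ceil(self.length / self.lattice_spacing)) + 1)
        for s in np.linspace(0.0, self.length, n_check):
            if self.radius_at(float(s)) <= self.atom_radius:
                raise SpecError(
                    f"inner radius {self.radius_at(float(s)):.3g} A at s={s:.3g} "
                    f"does not exceed atom_radius {self.atom_radius:.3g} A"
                )

    def describe(self) -> str:
        r = ("callable" if callable(self.inner_radius_profile)
             else f"{self.inner_radius_profile:g}")
        return (
            f"groove length={self.length:g}A radius={r} opening={self.opening_angle:g}deg "
            f"layers={self.wall_layers} layer_spacing={self.layer_spacing:g} "
            f"lattice={self.lattice_spacing:g} jitter_sd={self.jitter_sd:g} seed={self.seed}"
        )


@dataclass
class GroundTruth:
    """Exact geometry of a generated groove, for parameter-recovery tests."""

    lining_label: list[str]            # per-atom: "interior" or "exterior"
    axial_position: np.ndarray         # per-atom true s (pre-jitter), A
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    length: float
    opening_angle: float

    def inner_radius(self, s: float) -> float:
        return self._radius_fn(s)

    def lumen_area(self, s: float) -> float:
        """True cross-section area under the convex mouth-closure rule.

        The lumen is bounded by the wall arc (angular span beta = 2*pi minus
        the opening) and the chord closing the mouth: a circular segment of
        area R^2 * (beta - sin beta) / 2.  For a closed tube this is the full
        disc; for a half-pipe, half the disc.
        """
        beta = math.radians(360.0 - self.opening_angle)
        r = self.inner_radius(s)
        return 0.5 * r * r * (beta - math.sin(beta))

    _radius_fn: RadiusProfile = field(default=lambda s: 10.0, repr=False)


def make_groove(spec: GrooveSpec) -> tuple[StructureModel, GroundTruth]:
    """Generate a groove wall lattice and its ground truth.

    Wall atoms cover azimuths ``[opening/2, 360 - opening/2]`` (the mouth is
    centred on azimuth 0, the +u direction of the deterministic plane
    basis).  Layer 0 sits on the inner radius; each further layer is
    ``layer_spacing`` farther out.  Inner-layer atoms get ``inner_residue``
    and the label "interior"; the outermost layer gets ``outer_residue`` and
    "exterior"; intermediate layers (if any) get the inner residue and the
    "interior" label.
    """
    spec.validate()
    d = _unit(spec.axis_direction)
    u, w = _plane_basis(d)
    origin = np.asarray(spec.axis_origin, dtype=float)
    rng = np.random.default_rng(spec.seed)

    half_open = math.radians(spec.opening_angle) / 2.0
    arc_span = 2.0 * math.pi - 2.0 * half_open

    n_axial = max(2, int(round(spec.length / spec.lattice_spacing)) + 1)
    s_values = np.linspace(0.0, spec.length, n_axial)

    atoms: list[AtomRecord] = []
    labels: list[str] = []
    axial: list[float] = []
    serial = 0
    for s in s_values:
        base_r = spec.radius_at(float(s))
        for layer in range(spec.wall_layers):
            r = base_r + layer * spec.layer_spacing
            # arc length r*arc_span sampled every lattice_spacing
            n_arc = max(2, int(round(r * arc_span / spec.lattice_spacing)) + 1)
            thetas = half_open + np.linspace(0.0, arc_span, n_arc)
            is_outer = (layer == spec.wall_layers - 1) and spec.wall_layers > 1
            resname = spec.outer_residue if is_outer else spec.inner_residue
            label = "exterior" if is_outer else "interior"
            for th in thetas:
                serial += 1
                pos = (origin + s * d
                       + r * math.cos(th) * u + r * math.sin(th) * w)
                if spec.jitter_sd > 0:
                    pos = pos + rng.normal(0.0, spec.jitter_sd, size=3)
                atoms.append(AtomRecord(
                    serial=serial,
                    name="CA",
                    element="C",
                    residue_name=resname,
                    chain_id="A",
                    residue_number=serial,
                    position=(float(pos[0]), float(pos[1]), float(pos[2])),
                    vdw_radius=spec.atom_radius,
                    occupancy=1.0,
                ))
                labels.append(label)
                axial.append(float(s))

    model = StructureModel(atoms=atoms, source_id="synthetic-groove",
                           title=spec.describe())
    truth = GroundTruth(
        lining_label=labels,
        axial_position=np.array(axial),
        axis_origin=origin,
        axis_direction=d,
        length=spec.length,
        opening_angle=spec.opening_angle,
        _radius_fn=spec.radius_at,
    )
    return model, truth


def make_sphere_system(
    centers: Sequence[Sequence[float]],
    radii: Sequence[float],
    group_labels: Sequence[str] | None = None,
) -> StructureModel:
    """Build a model of isolated spheres (one single-atom residue each).

    ``group_labels`` become chain identifiers, so sphere systems double as
    interface (buried-surface) fixtures with analytically known answers.
    """
    centers = [np.asarray(c, dtype=float) for c in centers]
    radii = list(radii)
    if group_labels is None:
        group_labels = ["A"] * len(centers)
    if not (len(centers) == len(radii) == len(group_labels)):
        raise SpecError("centers, radii and group_labels must have equal length")
    atoms = [
        AtomRecord(
            serial=i + 1, name="CA", element="C", residue_name="SPH",
            chain_id=str(group_labels[i]), residue_number=i + 1,
            position=(float(c[0]), float(c[1]), float(c[2])),
            vdw_radius=float(radii[i]),
        )
        for i, c in enumerate(centers)
    ]
    return StructureModel(atoms=atoms, source_id="synthetic-spheres")


def write_groove(
    spec: GrooveSpec,
    pdb_path: str | Path,
    truth_csv_path: str | Path | None = None,
) -> tuple[StructureModel, GroundTruth]:
    """Generate a groove, write the PDB fixture and a ground-truth sidecar."""
    model, truth = make_groove(spec)
    write_pdb(model, pdb_path, remarks=[
        "SYNTHETIC GROOVE FIXTURE (bltpgeom)",
        spec.describe(),
    ])
    if truth_csv_path is not None:
        with open(truth_csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["serial", "lining_label", "axial_position_A"])
            for atom, label, s in zip(model.atoms, truth.lining_label,
                                      truth.axial_position):
                writer.writerow([atom.serial, label, f"{s:.3f}"])
    return model, truth
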