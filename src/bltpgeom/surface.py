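"""Solvent-accessible surface area, interface burial, and cavity lining.

The SASA engine is a from-scratch Shrake-Rupley implementation with a
deterministic golden-spiral quadrature: for each atom, ``n_points``
quasi-uniform points are placed on the probe-inflated sphere and a point
counts as accessible when it lies outside every neighbour's inflated
sphere.  There is no randomness anywhere in the main path, so SASA totals
are bit-reproducible.

Buried (interface) surface area between two atom groups is the two-sided
difference SASA(A) + SASA(B) - SASA(A union B), matching the "total buried
surface" convention; divide by two for a one-sided interface area.

Channel-lining classification is geometric: within each slab, an atom
"lines" the lumen when the 2-D segment from the lumen centroid to the
atom's projected center is not blocked by any other atom's disk.  Disks
that overlap the target's own center (contiguous wall neighbours) do not
count as blockers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .axis import AxisFrame, SliceSlab
from .io import (
    BltpGeomError,
    KYTE_DOOLITTLE,
    Selection,
    StructureModel,
    apply_selection,
    hydropathy,
)
from .lumen import LumenCrossSection


class SasaStateError(BltpGeomError):
    """SASA requested on atoms without assigned radii."""


class OverlappingGroupsError(BltpGeomError):
    """Interface groups share atoms."""


def golden_spiral_points(n: int) -> np.ndarray:
    """(n, 3) deterministic quasi-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.maximum(0.0, 1.0 - cos_theta ** 2))
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([
        sin_theta * np.cos(phi),
        sin_theta * np.sin(phi),
        cos_theta,
    ])


@dataclass
class SASAResult:
    """Per-atom and total solvent-accessible surface area (A^2)."""

    per_atom: np.ndarray
    probe_radius: float
    n_sphere_points: int
    radii_set: str = "bondi"

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def shrake_rupley_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SASAResult:
    """Shrake-Rupley SASA with a golden-spiral point set.

    Each atom's sphere of radius ``r + probe`` carries ``n_points`` test
    points; the accessible fraction times the sphere area gives the
    per-atom SASA.  Neighbour lookup uses a KD-tree over atom centers.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64 for a usable quadrature")
    coords = model.coords
    radii = model.radii
    if np.any(~np.isfinite(radii)) or np.any(radii < 0):
        raise SasaStateError("all atoms need finite non-negative radii")
    inflated = radii + probe_radius
    unit = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    max_inflated = float(inflated.max())
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        ri = inflated[i]
        pts = coords[i] + ri * unit
        neighbours = tree.query_ball_point(coords[i], ri + max_inflated)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            rj = inflated[j]
            if np.linalg.norm(coords[j] - coords[i]) >= ri + rj:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= rj * rj
            if not accessible.any():
                break
        per_atom[i] = accessible.mean() * 4.0 * math.pi * ri * ri
    return SASAResult(per_atom=per_atom, probe_radius=probe_radius,
                      n_sphere_points=n_points)


@dataclass
class InterfaceReport:
    """SASA of two groups alone and combined, and their buried surface."""

    sasa_a_alone: float
    sasa_b_alone: float
    sasa_ab_combined: float
    bsa_total: float                 # two-sided: A + B - AB
    per_residue: pd.DataFrame        # chain, residue, dSASA on each side
    probe_radius: float
    n_sphere_points: int

    @property
    def bsa_one_sided(self) -> float:
        return 0.5 * self.bsa_total


def _atom_key(atom) -> tuple:
    return (atom.chain_id, atom.residue_number, atom.name, atom.serial)


def interface_bsa(
    model: StructureModel,
    group_a: Selection,
    group_b: Selection,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> InterfaceReport:
    """Buried surface area between two disjoint atom groups.

    Runs three SASA evaluations (A alone, B alone, A and B together) and
    reports ``bsa_total = SASA(A) + SASA(B) - SASA(AB)`` plus a per-residue
    breakdown of the SASA each residue loses on complex formation.
    """
    sub_a = apply_selection(model, group_a)
    sub_b = apply_selection(model, group_b)
    keys_a = {_atom_key(a) for a in sub_a.atoms}
    keys_b = {_atom_key(a) for a in sub_b.atoms}
    if keys_a & keys_b:
        raise OverlappingGroupsError(
            f"groups share {len(keys_a & keys_b)} atoms; selections must be disjoint"
        )
    combined = StructureModel(
        atoms=list(sub_a.atoms) + list(sub_b.atoms),
        source_id=model.source_id, title=model.title,
    )
    res_a = shrake_rupley_sasa(sub_a, probe_radius, n_points)
    res_b = shrake_rupley_sasa(sub_b, probe_radius, n_points)
    res_ab = shrake_rupley_sasa(combined, probe_radius, n_points)

    alone = np.concatenate([res_a.per_atom, res_b.per_atom])
    delta = alone - res_ab.per_atom
    rows: dict[tuple, dict] = {}
    for atom, d, side in zip(
        combined.atoms, delta,
        ["A"] * len(sub_a.atoms) + ["B"] * len(sub_b.atoms),
    ):
        key = (side, atom.chain_id, atom.residue_number, atom.residue_name)
        row = rows.setdefault(key, {
            "group": side, "chain_id": atom.chain_id,
            "residue_number": atom.residue_number,
            "residue_name": atom.residue_name, "delta_sasa_A2": 0.0,
        })
        row["delta_sasa_A2"] += float(d)
    per_residue = pd.DataFrame(list(rows.values()))

    bsa = res_a.total + res_b.total - res_ab.total
    if bsa < 0:                      # quadrature noise on contact-free groups
        bsa = 0.0
    return InterfaceReport(
        sasa_a_alone=res_a.total,
        sasa_b_alone=res_b.total,
        sasa_ab_combined=res_ab.total,
        bsa_total=bsa,
        per_residue=per_residue,
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )


@dataclass
class LiningLabels:
    """Per-atom lining/exterior/unassigned labels plus slab assignment."""

    labels: np.ndarray               # str per selected atom
    slab_of_atom: np.ndarray         # int per atom, -1 if unassigned

    def fraction(self, label: str) -> float:
        return float((self.labels == label).mean())


def _segment_blocked(
    target: np.ndarray,
    centroid: np.ndarray,
    others: np.ndarray,
    other_radii: np.ndarray,
) -> bool:
    """Does any disk intersect the segment centroid -> target?

    Disks that already cover the target point are treated as part of the
    same wall surface and do not block.
    """
    if len(others) == 0:
        return False
    seg = target - centroid
    seg_len2 = float(seg @ seg)
    rel = others - centroid
    if seg_len2 == 0:
        dist = np.linalg.norm(rel, axis=1)
    else:
        t = np.clip((rel @ seg) / seg_len2, 0.0, 1.0)
        closest = centroid + t[:, None] * seg
        dist = np.linalg.norm(others - closest, axis=1)
    covers_target = np.linalg.norm(others - target, axis=1) < other_radii
    blocked = (dist < other_radii) & ~covers_target
    return bool(blocked.any())


def classify_lining(
    model: StructureModel,
    slabs: list[SliceSlab],
    sections: list[LumenCrossSection],
) -> LiningLabels:
    """Label each atom as lumen-lining or exterior by 2-D line of sight.

    Within a slab, an atom is "lining" when the segment from the slab's
    lumen centroid to the atom's projected center clears every other
    member's disk; otherwise "exterior".  Atoms of empty slabs are
    "unassigned".
    """
    n = len(model.atoms)
    labels = np.full(n, "unassigned", dtype=object)
    slab_of_atom = np.full(n, -1, dtype=int)
    for slab, sec in zip(slabs, sections):
        slab_of_atom[slab.atom_indices] = slab.index
        if sec.is_empty or not np.isfinite(sec.centroid[0]):
            continue
        centroid = np.asarray(sec.centroid)
        pts = slab.projected
        radii = slab.radii
        for local, global_idx in enumerate(slab.atom_indices):
            mask = np.arange(len(pts)) != local
            blocked = _segment_blocked(
                pts[local], centroid, pts[mask], radii[mask]
            )
            labels[global_idx] = "exterior" if blocked else "lining"
    return LiningLabels(labels=labels.astype(str), slab_of_atom=slab_of_atom)


def hydropathy_profile(
    model: StructureModel,
    labels: LiningLabels,
    n_slabs: int,
    table: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slab mean hydropathy of lining and exterior residue sets.

    Each residue contributes once per slab regardless of its atom count;
    residues outside the hydropathy table are excluded.  Slabs with no
    standard residues in a class yield NaN (missing), not zero.
    """
    tab = KYTE_DOOLITTLE if table is None else table
    lining_means = np.full(n_slabs, np.nan)
    exterior_means = np.full(n_slabs, np.nan)
    per_class: dict[str, dict[int, set[tuple]]] = {
        "lining": {}, "exterior": {},
    }
    residue_value: dict[tuple, float] = {}
    for atom, label, slab_idx in zip(model.atoms, labels.labels,
                                     labels.slab_of_atom):
        if label not in per_class or slab_idx < 0:
            continue
        h = hydropathy(atom.residue_name, tab)
        if math.isnan(h):
            continue
        rkey = (atom.chain_id, atom.residue_number, atom.residue_name)
        residue_value[rkey] = h
        per_class[label].setdefault(int(slab_idx), set()).add(rkey)
    for cls, target in (("lining", lining_means), ("exterior", exterior_means)):
        for slab_idx, residues in per_class[cls].items():
            if residues:
                target[slab_idx] = float(
                    np.mean([residue_value[r] for r in residues])
                )
    return lining_means, exterior_means
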