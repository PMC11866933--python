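"""Coarse-grained chain topology: bonds, angles, elastic network, exposure.

The per-residue interaction strength xi is derived once from the solvent
accessibility of the reference structure (Shrake-Rupley on the one-bead
spheres) and frozen; disordered residues always carry xi = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .params import ForceFieldParams, ResidueType, default_params
from .structure_io import (
    DomainDefinition,
    ReferenceStructure,
    make_ideal_helix,
    normalize_sequence,
)

SASA_PROBE_RADIUS = 0.14   # nm, water-probe radius
SASA_N_POINTS = 960        # sphere sample points per bead


@dataclass
class SurfaceExposure:
    """Per-residue solvent-accessible surface areas and exposure ratios."""

    s_residue: np.ndarray   # nm^2
    s_ratio: np.ndarray     # S_residue / S_ref; may exceed 1, stored unclamped


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = SASA_PROBE_RADIUS,
                  n_points: int = SASA_N_POINTS) -> np.ndarray:
    """Per-sphere solvent-accessible surface area (nm^2).

    Classic point-sampling: each sphere of radius r_i + probe is covered
    with a quasi-uniform point set; a point is accessible iff it lies
    outside every other expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n = len(coords)
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    rmax = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii[i] + rmax):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return areas


def compute_sasa(
    structure: ReferenceStructure,
    residue_table: Mapping[str, ResidueType],
    probe_radius: float = SASA_PROBE_RADIUS,
) -> SurfaceExposure:
    """Per-residue SASA of the one-bead spheres and exposure ratio.

    ``s_ratio = S_residue / S_ref`` uses the amino-acid-specific reference
    areas stored in the residue table (computed with the same algorithm and
    probe, so the ratio is internally consistent).
    """
    if len(structure) == 0:
        raise ValueError("structure must be nonempty")
    radii = np.array([residue_table[c].radius for c in structure.residue_codes])
    s_residue = shrake_rupley(structure.coords, radii, probe_radius)
    s_ref = np.array([residue_table[c].s_ref for c in structure.residue_codes])
    with np.errstate(invalid="ignore"):
        s_ratio = s_residue / s_ref
    return SurfaceExposure(s_residue=s_residue, s_ratio=s_ratio)


def make_reference_areas(
    residue_table: Mapping[str, ResidueType],
    probe_radius: float = SASA_PROBE_RADIUS,
) -> dict[str, float]:
    """Reference surface area per amino acid: central residue of an
    A7-X-A7 ideal helix, computed with the runtime SASA algorithm.

    The 15-residue alanine host buries the central residue's helix context
    so the ratio S_residue/S_ref reports burial by tertiary packing, not by
    the helix itself. Deterministic.
    """
    out = {}
    for code in sorted(c for c in residue_table if c.isupper()):
        helix = make_ideal_helix("A" * 7 + code + "A" * 7)
        radii = np.array([residue_table[c].radius for c in helix.residue_codes])
        areas = shrake_rupley(helix.coords, radii, probe_radius)
        out[code] = float(areas[7])
    return out


def xi_from_sratio(s_ratio: float, lambda_threshold: float, is_folded: bool) -> float:
    """Surface-exposure interaction strength.

    Disordered residues always interact at full strength. In folded
    domains the strength is 1 above the exposure threshold lambda and
    decreases linearly with exposure below it, reaching zero for fully
    buried residues.
    """
    if not is_folded:
        return 1.0
    if s_ratio >= lambda_threshold:
        return 1.0
    return max(0.0, s_ratio / lambda_threshold)


# ---------------------------------------------------------------------------
# Chain topology
# ---------------------------------------------------------------------------


@dataclass
class ChainTopology:
    """All per-chain terms of the energy model for one molecule."""

    bead_codes: str
    bead_sigma: np.ndarray        # nm
    bead_charge: np.ndarray       # e
    bead_xi: np.ndarray           # [0, 1]
    is_folded: np.ndarray         # bool per bead
    bonds: np.ndarray             # (B, 2) int, consecutive pairs
    bond_l0: np.ndarray           # (B,) nm
    angles: np.ndarray            # (A, 3) int, consecutive triples
    angle_k: np.ndarray           # (A,) kJ/(mol rad^2)
    enm_pairs: np.ndarray         # (E, 2) int
    enm_r0: np.ndarray            # (E,) nm
    exclusions: frozenset[tuple[int, int]]
    kind: str = "protein"         # protein | rna

    @property
    def n_beads(self) -> int:
        return len(self.bead_codes)


def build_chain_topology(
    sequence: str,
    domains: DomainDefinition | None = None,
    reference: ReferenceStructure | None = None,
    params: ForceFieldParams | None = None,
    residue_table: Mapping[str, ResidueType] | None = None,
    kind: str = "protein",
) -> ChainTopology:
    """Build the coarse-grained topology for one chain.

    Bonds connect all consecutive pairs at the polymer-type rest length;
    angles span all consecutive triples with a 180 deg target. For folded
    domains an elastic network adds a harmonic pair for every intradomain
    (i, j) with |i - j| >= 2 whose reference distance is at or below the
    network cutoff, with the reference distance as rest length; no network
    pair crosses between domains. xi is computed once from the reference
    structure and frozen. Nonbonded exclusions cover exactly the bonded
    (i, i+1) pairs (optionally also the network pairs, per the params flag).
    """
    from .params import residue_table as default_table

    params = params or default_params()
    sequence = normalize_sequence(sequence, kind)
    table = residue_table or default_table(params)
    domains = domains or DomainDefinition(())
    n = len(sequence)
    if n == 0:
        raise ValueError("sequence must be nonempty")

    if domains.ranges and kind == "rna":
        raise ValueError("folded domains are not supported for nucleotide chains")
    if domains.ranges:
        if reference is None:
            raise ValueError("domains require a reference structure")
        if domains.max_residue > len(reference):
            raise ValueError(
                f"domain range extends to residue {domains.max_residue} but the "
                f"reference has only {len(reference)} residues"
            )
        if len(reference) != n:
            raise ValueError("reference structure must cover the full sequence")

    types = [table[c] for c in sequence]
    sigma = np.array([t.sigma for t in types])
    charge = np.array([t.charge for t in types])

    is_folded = np.zeros(n, dtype=bool)
    for s, e in domains.zero_based():
        is_folded[s:e] = True

    xi = np.ones(n)
    if domains.ranges:
        exposure = compute_sasa(reference, table)
        for i in range(n):
            xi[i] = xi_from_sratio(
                float(exposure.s_ratio[i]), params.lambda_threshold, bool(is_folded[i])
            )

    l0 = params.l0_nucleotide if kind == "rna" else params.l0_protein
    k_angle = params.k_angle_nucleotide if kind == "rna" else params.k_angle_protein
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]) if n > 1 else np.empty((0, 2), int)
    bond_l0 = np.full(len(bonds), l0)
    angles = (
        np.column_stack([np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)])
        if n > 2 else np.empty((0, 3), int)
    )
    angle_ks = np.full(len(angles), k_angle)

    enm_pairs, enm_r0 = [], []
    for s, e in domains.zero_based():
        idx = np.arange(s, e)
        sub = reference.coords[idx]
        d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        ii, jj = np.nonzero((d <= params.enm_cutoff) & (np.triu(np.ones_like(d, dtype=bool), k=2)))
        for a, b in zip(ii, jj):
            enm_pairs.append((idx[a], idx[b]))
            enm_r0.append(d[a, b])
    enm_pairs = np.array(enm_pairs, int) if enm_pairs else np.empty((0, 2), int)
    enm_r0 = np.array(enm_r0, float)

    exclusions = {(int(i), int(j)) for i, j in bonds}
    if params.enm_excludes_nonbonded:
        exclusions |= {(int(i), int(j)) for i, j in enm_pairs}

    return ChainTopology(
        bead_codes=sequence,
        bead_sigma=sigma,
        bead_charge=charge,
        bead_xi=xi,
        is_folded=is_folded,
        bonds=bonds,
        bond_l0=bond_l0,
        angles=angles,
        angle_k=angle_ks,
        enm_pairs=enm_pairs,
        enm_r0=enm_r0,
        exclusions=frozenset(exclusions),
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Serialization (sidecar CSVs next to a bead PDB)
# ---------------------------------------------------------------------------


def write_topology_sidecar(topology: ChainTopology, path) -> None:
    """Write bead table and elastic-network pair list as sidecar CSVs.

    ``<path>.beads.csv`` holds (index, code, sigma, charge, xi, folded) and
    ``<path>.enm.csv`` holds (i, j, r0_nm).
    """
    path = Path(path)
    lines = ["index,code,sigma_nm,charge_e,xi,folded"]
    for i in range(topology.n_beads):
        lines.append(
            f"{i},{topology.bead_codes[i]},{topology.bead_sigma[i]:.6f},"
            f"{topology.bead_charge[i]},{topology.bead_xi[i]:.6f},"
            f"{int(topology.is_folded[i])}"
        )
    path.with_suffix(".beads.csv").write_text("\n".join(lines) + "\n")
    lines = ["i,j,r0_nm"]
    for (i, j), r0 in zip(topology.enm_pairs, topology.enm_r0):
        lines.append(f"{i},{j},{r0:.6f}")
    path.with_suffix(".enm.csv").write_text("\n".join(lines) + "\n")
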