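"""Energy model evaluation: all terms of the total potential plus forces.

The total energy is the sum of harmonic bonds, the elastic network over
folded domains, harmonic angles, the 10-5 short-range pair potential with
surface-exposure-scaled well depths, and screened (Debye-Hueckel)
electrostatics with an effective solvation repulsion. The 10-5 term uses
the Mie(10,5) normalization U = 4 eps [(sigma/r)^10 - (sigma/r)^5], which
is zero at r = sigma_ij and reaches its minimum -eps at r = 2^(1/5)
sigma_ij. Electrostatic amplitudes are A_i = q_i sqrt(ke / eps_r) so that
A_i A_j exp(-r/kappa)/r is the Debye-Hueckel energy in kJ/mol; the
solvation amplitudes A0 add a weak always-repulsive term of the same
screened form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .params import (
    AROMATIC_CODES,
    CATIONIC_CODES,
    HYDROPHOBIC_CODES,
    KE,
    MASS_AMINO_ACID,
    MASS_NUCLEOTIDE,
    ForceFieldParams,
    default_params,
)
from .topology import ChainTopology


@dataclass
class SystemState:
    """Coordinates and periodic box for all chains of a system.

    ``chain_index`` maps each bead to its chain; ``topologies`` holds one
    ChainTopology per chain in chain order. Beads of chain c occupy the
    contiguous index block given by the chain's position.
    """

    coords: np.ndarray            # (M, 3) nm
    box: np.ndarray               # (3,) nm, orthorhombic
    chain_index: np.ndarray      # (M,) int
    topologies: list[ChainTopology]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.chain_index = np.asarray(self.chain_index, dtype=np.int64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        n_top = sum(t.n_beads for t in self.topologies)
        if n_top != len(self.coords) or len(self.chain_index) != len(self.coords):
            raise ValueError("coords, chain_index and topologies are inconsistent")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_chains(self) -> int:
        return len(self.topologies)

    def wrapped_coords(self) -> np.ndarray:
        return np.mod(self.coords, self.box)

    def copy(self) -> "SystemState":
        return SystemState(
            self.coords.copy(), self.box.copy(), self.chain_index.copy(),
            list(self.topologies),
        )

    def chain_slices(self) -> list[slice]:
        offsets = np.cumsum([0] + [t.n_beads for t in self.topologies])
        return [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]


@dataclass
class EnergyReport:
    """Per-term decomposition of the total potential energy (kJ/mol)."""

    u_bond: float
    u_enm: float
    u_angle: float
    u_short_range: float
    u_electrostatic: float

    @property
    def u_total(self) -> float:
        return (self.u_bond + self.u_enm + self.u_angle
                + self.u_short_range + self.u_electrostatic)

    def per_bead(self, n_beads: int) -> float:
        return self.u_total / n_beads


# ---------------------------------------------------------------------------
# Flattened system arrays for the kernels
# ---------------------------------------------------------------------------


@dataclass
class FlatSystem:
    """Per-bead and per-term arrays consumed by the compiled kernels."""

    sigma: np.ndarray
    eps_base: np.ndarray
    xi: np.ndarray
    amp_q: np.ndarray
    amp_a0: np.ndarray
    is_cat: np.ndarray
    is_arom: np.ndarray
    is_nuc: np.ndarray
    masses: np.ndarray
    bond_pairs: np.ndarray
    bond_r0: np.ndarray
    angle_triples: np.ndarray
    angle_k: np.ndarray
    enm_pairs: np.ndarray
    enm_r0: np.ndarray
    exclusion_keys: np.ndarray    # sorted i * M + j with i < j


def flatten_system(state: SystemState, params: ForceFieldParams) -> FlatSystem:
    m = state.n_beads
    sigma = np.empty(m)
    eps_base = np.empty(m)
    xi = np.empty(m)
    amp_q = np.empty(m)
    amp_a0 = np.empty(m)
    is_cat = np.zeros(m, dtype=np.uint8)
    is_arom = np.zeros(m, dtype=np.uint8)
    is_nuc = np.zeros(m, dtype=np.uint8)
    masses = np.empty(m)
    bond_pairs, bond_r0 = [], []
    angle_triples, angle_k = [], []
    enm_pairs, enm_r0 = [], []
    excl = []

    sqrt_ke = math.sqrt(KE / params.dielectric)
    offset = 0
    for top in state.topologies:
        n = top.n_beads
        sl = slice(offset, offset + n)
        sigma[sl] = top.bead_sigma
        xi[sl] = top.bead_xi
        amp_q[sl] = top.bead_charge * sqrt_ke
        for k, code in enumerate(top.bead_codes):
            i = offset + k
            if code.islower():
                is_nuc[i] = 1
                eps_base[i] = params.epsilon_polar
                amp_a0[i] = params.A0_polar
                masses[i] = MASS_NUCLEOTIDE
            else:
                hydro = code in HYDROPHOBIC_CODES
                eps_base[i] = params.epsilon_hydrophobic if hydro else params.epsilon_polar
                amp_a0[i] = params.A0_hydrophobic if hydro else params.A0_polar
                masses[i] = MASS_AMINO_ACID
                if code in CATIONIC_CODES:
                    is_cat[i] = 1
                if code in AROMATIC_CODES:
                    is_arom[i] = 1
        if len(top.bonds):
            bond_pairs.append(top.bonds + offset)
            bond_r0.append(top.bond_l0)
        if len(top.angles):
            angle_triples.append(top.angles + offset)
            angle_k.append(top.angle_k)
        if len(top.enm_pairs):
            enm_pairs.append(top.enm_pairs + offset)
            enm_r0.append(top.enm_r0)
        for i, j in top.exclusions:
            a, b = sorted((i + offset, j + offset))
            excl.append(a * m + b)
        offset += n

    def _stack(parts, width, dtype=np.int64):
        if parts:
            return np.ascontiguousarray(np.concatenate(parts).astype(dtype))
        return np.empty((0, width), dtype=dtype) if width > 1 else np.empty(0, dtype=dtype)

    return FlatSystem(
        sigma=sigma, eps_base=eps_base, xi=xi, amp_q=amp_q, amp_a0=amp_a0,
        is_cat=is_cat, is_arom=is_arom, is_nuc=is_nuc, masses=masses,
        bond_pairs=_stack(bond_pairs, 2),
        bond_r0=_stack(bond_r0, 1, float),
        angle_triples=_stack(angle_triples, 3),
        angle_k=_stack(angle_k, 1, float),
        enm_pairs=_stack(enm_pairs, 2),
        enm_r0=_stack(enm_r0, 1, float),
        exclusion_keys=np.sort(np.asarray(excl, dtype=np.int64)),
    )


def neighbor_pairs(
    coords: np.ndarray,
    box: np.ndarray,
    cutoff: float,
    exclusion_keys: np.ndarray,
    method: str = "kdtree",
) -> np.ndarray:
    """Unique nonbonded pair list (i < j) within cutoff, exclusions removed.

    ``method='kdtree'`` uses a periodic cKDTree (the production cell list);
    ``method='all'`` enumerates every pair regardless of distance, which the
    kernel then cuts off itself -- the two must give identical energies.
    """
    m = len(coords)
    if method == "all":
        ii, jj = np.triu_indices(m, k=1)
        pairs = np.column_stack([ii, jj]).astype(np.int64)
    else:
        wrapped = np.mod(coords, box)
        tree = cKDTree(wrapped, boxsize=np.asarray(box, dtype=float))
        pairs = tree.query_pairs(cutoff, output_type="ndarray").astype(np.int64)
        if len(pairs) == 0:
            return np.empty((0, 2), dtype=np.int64)
        pairs.sort(axis=1)
    keys = pairs[:, 0] * m + pairs[:, 1]
    if len(exclusion_keys):
        pos = np.searchsorted(exclusion_keys, keys)
        pos = np.clip(pos, 0, len(exclusion_keys) - 1)
        keep = exclusion_keys[pos] != keys
        pairs = pairs[keep]
    return np.ascontiguousarray(pairs)


def _check_box(state: SystemState, params: ForceFieldParams) -> None:
    if np.min(state.box) <= 2.0 * params.nonbonded_cutoff:
        raise ValueError(
            f"box edges must exceed twice the nonbonded cutoff "
            f"({2 * params.nonbonded_cutoff} nm); got {state.box}"
        )


def pair_tables_for(flat: FlatSystem, params: ForceFieldParams, pairs: np.ndarray):
    """Per-pair constants (sigma_ij, well depth, amplitude) for a pair list."""
    return _kernels.pair_tables(
        pairs, flat.sigma, flat.eps_base, flat.xi, flat.amp_q, flat.amp_a0,
        flat.is_cat, flat.is_arom, flat.is_nuc,
        params.eps_mod_cation_aromatic, params.eps_mod_cation_nucleic,
        params.eps_mod_aromatic_aromatic,
        params.combine_rule == "geometric",
        params.xi_scales_electrostatics,
    )


def _kernel_args(flat: FlatSystem, params: ForceFieldParams, pairs: np.ndarray):
    """Positional nonbonded arguments for the compiled kernels."""
    p_sig, p_eps, p_amp = pair_tables_for(flat, params, pairs)
    return (
        p_sig, p_eps, p_amp,
        params.shift_short_range, params.debye_length, params.nonbonded_cutoff,
    )


# ---------------------------------------------------------------------------
# Energy terms
# ---------------------------------------------------------------------------


def bond_energy(state: SystemState, params: ForceFieldParams | None = None) -> float:
    """Sum of 0.5 k_bond (l - l0)^2 over consecutive bonded pairs."""
    params = params or default_params()
    flat = flatten_system(state, params)
    f = np.zeros_like(state.coords)
    return float(_kernels.harmonic_pairs(
        state.wrapped_coords(), state.box, flat.bond_pairs, flat.bond_r0,
        params.k_bond, f
    ))


def enm_energy(state: SystemState, params: ForceFieldParams | None = None) -> float:
    """Elastic-network energy over intradomain pairs (rest = reference)."""
    params = params or default_params()
    flat = flatten_system(state, params)
    f = np.zeros_like(state.coords)
    return float(_kernels.harmonic_pairs(
        state.wrapped_coords(), state.box, flat.enm_pairs, flat.enm_r0,
        params.k_enm, f
    ))


def angle_energy(state: SystemState, params: ForceFieldParams | None = None) -> float:
    """Harmonic angle energy with a straight (180 deg) target."""
    params = params or default_params()
    flat = flatten_system(state, params)
    f = np.zeros_like(state.coords)
    return float(_kernels.harmonic_angles(
        state.wrapped_coords(), state.box, flat.angle_triples, flat.angle_k,
        params.theta0_rad, f
    ))


def _nonbonded(state, params, method):
    _check_box(state, params)
    flat = flatten_system(state, params)
    wrapped = state.wrapped_coords()
    pairs = neighbor_pairs(
        wrapped, state.box, params.nonbonded_cutoff,
        flat.exclusion_keys, method=method,
    )
    f = np.zeros_like(state.coords)
    u_sr, u_el = _kernels.nonbonded(
        wrapped, state.box, pairs, *_kernel_args(flat, params, pairs), f
    )
    return float(u_sr), float(u_el)


def short_range_energy(
    state: SystemState, params: ForceFieldParams | None = None,
    method: str = "kdtree",
) -> float:
    """10-5 pair energy with exposure-scaled well depths, 3 nm truncation."""
    return _nonbonded(state, params or default_params(), method)[0]


def electrostatic_energy(
    state: SystemState, params: ForceFieldParams | None = None,
    method: str = "kdtree",
) -> float:
    """Screened electrostatics plus effective solvation repulsion."""
    return _nonbonded(state, params or default_params(), method)[1]


def total_energy(
    state: SystemState, params: ForceFieldParams | None = None,
    method: str = "kdtree",
) -> EnergyReport:
    """All five energy terms of the model for an arbitrary state."""
    params = params or default_params()
    _check_box(state, params)
    flat = flatten_system(state, params)
    wrapped = state.wrapped_coords()
    pairs = neighbor_pairs(
        wrapped, state.box, params.nonbonded_cutoff,
        flat.exclusion_keys, method=method,
    )
    f = np.zeros_like(state.coords)
    u_bond, u_enm, u_angle, u_sr, u_el = _kernels.compute_forces(
        wrapped, state.box, pairs, *_kernel_args(flat, params, pairs),
        flat.bond_pairs, flat.bond_r0, params.k_bond,
        flat.enm_pairs, flat.enm_r0, params.k_enm,
        flat.angle_triples, flat.angle_k, params.theta0_rad,
        f,
    )
    return EnergyReport(
        u_bond=float(u_bond), u_enm=float(u_enm), u_angle=float(u_angle),
        u_short_range=float(u_sr), u_electrostatic=float(u_el),
    )


def forces(
    state: SystemState, params: ForceFieldParams | None = None,
    method: str = "kdtree",
) -> np.ndarray:
    """Analytic negative gradient of the total energy, (M, 3) kJ/(mol nm)."""
    params = params or default_params()
    _check_box(state, params)
    flat = flatten_system(state, params)
    wrapped = state.wrapped_coords()
    pairs = neighbor_pairs(
        wrapped, state.box, params.nonbonded_cutoff,
        flat.exclusion_keys, method=method,
    )
    f = np.zeros_like(state.coords)
    _kernels.compute_forces(
        wrapped, state.box, pairs, *_kernel_args(flat, params, pairs),
        flat.bond_pairs, flat.bond_r0, params.k_bond,
        flat.enm_pairs, flat.enm_r0, params.k_enm,
        flat.angle_triples, flat.angle_k, params.theta0_rad,
        f,
    )
    return f
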