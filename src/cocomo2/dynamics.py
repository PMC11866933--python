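"""Langevin NVT dynamics on the coarse-grained energy model.

The integrator is the BAOAB splitting of Langevin dynamics, which stays
accurate for configurational averages at the 10-20 fs steps used here.
Bead masses are uniform per polymer class (110 amu amino acids, 330 amu
nucleotides); with a Langevin thermostat at fixed friction the masses set
kinetics only, not configurational ensembles. Neighbor lists are periodic
kd-trees rebuilt on a fixed interval with a Verlet skin chosen so thermal
displacement between rebuilds stays far below half the skin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import _kernels
from .energetics import (
    EnergyReport,
    SystemState,
    _check_box,
    _kernel_args,
    flatten_system,
    neighbor_pairs,
)
from .params import KB, ForceFieldParams, default_params
from .assembly import minimize_energy


@dataclass
class RunSettings:
    """Integration settings for a Langevin run."""

    dt: float = 0.02                 # ps (20 fs production; 10 fs equilibration)
    n_steps: int = 10000
    temperature: float = 298.0       # K
    friction: float = 0.01           # ps^-1
    seed: int = 0
    report_interval: int = 1000      # steps between stored frames
    minimize_first: bool = False
    neighbor_skin: float = 0.6       # nm added to cutoff for the pair list
    rebuild_interval: int = 20       # steps between neighbor-list rebuilds

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.report_interval <= 0:
            raise ValueError("report_interval must be > 0")


@dataclass
class Trajectory:
    """Stored frames of a Langevin run (coordinates, velocities, energies)."""

    frames: np.ndarray            # (F, M, 3) nm
    velocities: np.ndarray        # (F, M, 3) nm/ps
    box: np.ndarray               # (3,) nm
    steps: np.ndarray             # (F,) step index of each frame
    energies: list[EnergyReport]
    masses: np.ndarray            # (M,) amu

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def state_at(self, frame: int, template: SystemState) -> SystemState:
        return SystemState(
            self.frames[frame].copy(), self.box.copy(),
            template.chain_index.copy(), list(template.topologies),
        )


def run_langevin(
    state: SystemState,
    params: ForceFieldParams | None = None,
    settings: RunSettings | None = None,
    callback: Callable[[int, np.ndarray], bool] | None = None,
) -> Trajectory:
    """Integrate Langevin dynamics; returns the reported frames.

    Frames (coordinates and velocities) are stored every
    ``report_interval`` steps, the initial frame included. ``callback``,
    if given, is invoked at every report with (step, coords) and may
    return True to stop the run early (used e.g. to stop once a condensate
    has formed). Runs are bit-reproducible for a fixed seed. Non-finite
    coordinates abort with the failing frame index.
    """
    params = params or default_params()
    settings = settings or RunSettings()
    _check_box(state, params)

    if settings.minimize_first:
        state = minimize_energy(state, params)

    flat = flatten_system(state, params)
    coords = state.coords.copy()
    rng = np.random.default_rng(settings.seed)
    kT = KB * settings.temperature
    vels = rng.normal(size=coords.shape) * np.sqrt(kT / flat.masses)[:, None]

    c1 = math.exp(-settings.friction * settings.dt)
    noise_scale = np.sqrt(kT * (1.0 - c1 * c1) / flat.masses)
    inv_mass = 1.0 / flat.masses
    forces_buf = np.zeros_like(coords)

    list_cutoff = params.nonbonded_cutoff + settings.neighbor_skin
    frames, velocities, steps, energies = [], [], [], []

    def report(step):
        frames.append(np.mod(coords, state.box))
        velocities.append(vels.copy())
        steps.append(step)
        pairs = neighbor_pairs(coords, state.box, params.nonbonded_cutoff,
                               flat.exclusion_keys)
        terms = _kernels.compute_forces(
            coords, state.box, pairs, *_kernel_args(flat, params, pairs),
            flat.bond_pairs, flat.bond_r0, params.k_bond,
            flat.enm_pairs, flat.enm_r0, params.k_enm,
            flat.angle_triples, flat.angle_k, params.theta0_rad, forces_buf,
        )
        energies.append(EnergyReport(*[float(t) for t in terms]))

    report(0)
    step = 0
    chunk_id = 0
    while step < settings.n_steps:
        next_report = min(step + settings.report_interval, settings.n_steps)
        while step < next_report:
            n_sub = min(settings.rebuild_interval, next_report - step)
            np.mod(coords, state.box, out=coords)
            pairs = neighbor_pairs(coords, state.box, list_cutoff,
                                   flat.exclusion_keys)
            ok = _kernels.baoab_chunk(
                coords, vels, state.box, pairs, *_kernel_args(flat, params, pairs),
                flat.bond_pairs, flat.bond_r0, params.k_bond,
                flat.enm_pairs, flat.enm_r0, params.k_enm,
                flat.angle_triples, flat.angle_k, params.theta0_rad,
                inv_mass, noise_scale, c1, settings.dt, n_sub,
                (settings.seed + 0x9E3779B1 * chunk_id) % (2**31), forces_buf,
            )
            chunk_id += 1
            step += n_sub
            if not ok:
                raise FloatingPointError(
                    f"non-finite coordinates at step {step} "
                    f"(last good frame index {len(frames) - 1})"
                )
        report(step)
        if callback is not None and callback(step, coords):
            break

    return Trajectory(
        frames=np.array(frames), velocities=np.array(velocities),
        box=state.box.copy(), steps=np.array(steps), energies=energies,
        masses=flat.masses,
    )


def kinetic_temperature(traj: Trajectory) -> tuple[np.ndarray, float]:
    """Instantaneous kinetic temperature per frame (K) and its mean.

    Equipartition: T = sum_i m_i |v_i|^2 / (3 N kB).
    """
    v2 = np.einsum("fid,fid->fi", traj.velocities, traj.velocities)
    ke = 0.5 * (traj.masses[None, :] * v2).sum(axis=1)
    n_dof = 3 * traj.velocities.shape[1]
    t_inst = 2.0 * ke / (n_dof * KB)
    return t_inst, float(t_inst.mean())


# ---------------------------------------------------------------------------
# Engine export: complete self-contained system serialization
# ---------------------------------------------------------------------------

ENGINE_FORMAT_VERSION = 1


def export_engine_system(state: SystemState, params: ForceFieldParams, path) -> None:
    """Write a complete, documented JSON description of the system.

    The file contains every bead (code, sigma, charge, xi, mass, chain),
    all bonded terms with their constants, the elastic-network pairs, the
    nonbonded exclusions and the global nonbonded constants, in the
    package's MD units (nm, kJ/mol, ps, amu, e). A re-imported system
    reproduces single-point energies exactly; the file is also the handoff
    format for production-scale engines. Deterministic for a given input.
    """
    flat = flatten_system(state, params)
    codes = "".join(t.bead_codes for t in state.topologies)
    doc = {
        "format": "cocomo2-engine-system",
        "version": ENGINE_FORMAT_VERSION,
        "units": {"length": "nm", "energy": "kJ/mol", "time": "ps",
                  "mass": "amu", "charge": "e"},
        "box_nm": state.box.tolist(),
        "beads": {
            "code": list(codes),
            "chain": state.chain_index.tolist(),
            "sigma_nm": flat.sigma.tolist(),
            "epsilon_base_kJmol": flat.eps_base.tolist(),
            "xi": flat.xi.tolist(),
            "charge_amplitude": flat.amp_q.tolist(),
            "a0_amplitude": flat.amp_a0.tolist(),
            "is_cationic": flat.is_cat.tolist(),
            "is_aromatic": flat.is_arom.tolist(),
            "is_nucleotide": flat.is_nuc.tolist(),
            "mass_amu": flat.masses.tolist(),
        },
        "bonds": {"pairs": flat.bond_pairs.tolist(),
                  "r0_nm": flat.bond_r0.tolist(),
                  "k_kJmolnm2": params.k_bond},
        "angles": {"triples": flat.angle_triples.tolist(),
                   "k_kJmolrad2": flat.angle_k.tolist(),
                   "theta0_deg": params.theta0},
        "elastic_network": {"pairs": flat.enm_pairs.tolist(),
                            "r0_nm": flat.enm_r0.tolist(),
                            "k_kJmolnm2": params.k_enm},
        "exclusions": flat.exclusion_keys.tolist(),
        "nonbonded": {
            "cutoff_nm": params.nonbonded_cutoff,
            "debye_length_nm": params.debye_length,
            "eps_mod_cation_aromatic": params.eps_mod_cation_aromatic,
            "eps_mod_cation_nucleic": params.eps_mod_cation_nucleic,
            "eps_mod_aromatic_aromatic": params.eps_mod_aromatic_aromatic,
            "combine_rule": params.combine_rule,
            "xi_scales_electrostatics": params.xi_scales_electrostatics,
            "shift_short_range": params.shift_short_range,
        },
        "coordinates_nm": state.coords.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def import_engine_system(path) -> dict:
    """Read an exported engine description back into flat arrays."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "cocomo2-engine-system":
        raise ValueError(f"{path} is not an engine system file")
    b = doc["beads"]
    return {
        "box": np.array(doc["box_nm"]),
        "coords": np.array(doc["coordinates_nm"]),
        "n_beads": len(b["code"]),
        "flat": dict(
            sigma=np.array(b["sigma_nm"]),
            eps_base=np.array(b["epsilon_base_kJmol"]),
            xi=np.array(b["xi"]),
            amp_q=np.array(b["charge_amplitude"]),
            amp_a0=np.array(b["a0_amplitude"]),
            is_cat=np.array(b["is_cationic"], dtype=np.uint8),
            is_arom=np.array(b["is_aromatic"], dtype=np.uint8),
            is_nuc=np.array(b["is_nucleotide"], dtype=np.uint8),
            masses=np.array(b["mass_amu"]),
        ),
        "bonds": (np.array(doc["bonds"]["pairs"], dtype=np.int64).reshape(-1, 2),
                  np.array(doc["bonds"]["r0_nm"]), doc["bonds"]["k_kJmolnm2"]),
        "angles": (np.array(doc["angles"]["triples"], dtype=np.int64).reshape(-1, 3),
                   np.array(doc["angles"]["k_kJmolrad2"]),
                   math.radians(doc["angles"]["theta0_deg"])),
        "enm": (np.array(doc["elastic_network"]["pairs"], dtype=np.int64).reshape(-1, 2),
                np.array(doc["elastic_network"]["r0_nm"]),
                doc["elastic_network"]["k_kJmolnm2"]),
        "exclusion_keys": np.array(doc["exclusions"], dtype=np.int64),
        "nonbonded": doc["nonbonded"],
    }


def engine_single_point_energy(system: dict) -> float:
    """Total potential energy of an imported engine system (kJ/mol)."""
    nb = system["nonbonded"]
    f = system["flat"]
    box = system["box"]
    coords = np.mod(system["coords"], box)
    forces_buf = np.zeros_like(coords)
    pairs = neighbor_pairs(coords, box, nb["cutoff_nm"], system["exclusion_keys"])
    bonds, bond_r0, k_bond = system["bonds"]
    enm, enm_r0, k_enm = system["enm"]
    angles, angle_k, theta0 = system["angles"]
    p_sig, p_eps, p_amp = _kernels.pair_tables(
        pairs, f["sigma"], f["eps_base"], f["xi"], f["amp_q"], f["amp_a0"],
        f["is_cat"], f["is_arom"], f["is_nuc"],
        nb["eps_mod_cation_aromatic"], nb["eps_mod_cation_nucleic"],
        nb["eps_mod_aromatic_aromatic"],
        nb["combine_rule"] == "geometric", nb["xi_scales_electrostatics"],
    )
    terms = _kernels.compute_forces(
        coords, box, pairs, p_sig, p_eps, p_amp,
        nb["shift_short_range"], nb["debye_length_nm"], nb["cutoff_nm"],
        bonds, bond_r0, k_bond, enm, enm_r0, k_enm, angles, angle_k, theta0,
        forces_buf,
    )
    return float(sum(terms))
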