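"""Multi-chain system assembly: random dispersion, preformed droplet, mixed.

The mixed-phase start (droplet plus dispersed monomers) is the preferred
initial condition for saturation-concentration runs: it lets the dilute
phase relax toward coexistence from either side, avoiding the nucleation /
melting hysteresis of the two extreme starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .energetics import (
    FlatSystem,
    SystemState,
    flatten_system,
    neighbor_pairs,
    total_energy,
)
from . import _kernels
from .params import N_AVOGADRO, ForceFieldParams, default_params
from .structure_io import DomainDefinition, ReferenceStructure, make_random_coil
from .topology import ChainTopology, build_chain_topology

#: target bead density of a freshly packed droplet, beads/nm^3 (relaxes
#: toward its own equilibrium during equilibration)
CONDENSATE_BEAD_DENSITY = 0.4
#: minimum inter-chain bead distance enforced at placement, nm
MIN_PLACEMENT_DISTANCE = 0.35


@dataclass
class ChainSpec:
    """One molecular species: sequence, optional folded domains, copy count."""

    sequence: str
    copies: int = 1
    domains: DomainDefinition | None = None
    reference: ReferenceStructure | None = None
    kind: str = "protein"

    def __post_init__(self) -> None:
        if self.copies <= 0:
            raise ValueError("copies must be > 0")


@dataclass
class AssemblySpec:
    """Recipe for a multi-chain starting configuration."""

    chain_specs: list[ChainSpec]
    box: np.ndarray
    mode: str = "random"            # random | condensate | mixed
    n_condensate: int = 0           # chains placed as droplet in mixed mode
    seed: int = 0
    condensate_density: float = CONDENSATE_BEAD_DENSITY  # beads/nm^3

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.mode not in ("random", "condensate", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        total = sum(c.copies for c in self.chain_specs)
        if self.mode == "mixed" and self.n_condensate > total:
            raise ValueError("n_condensate exceeds total copies")


# ---------------------------------------------------------------------------
# Concentration bookkeeping
# ---------------------------------------------------------------------------


def concentration(n_chains: int, box: np.ndarray) -> float:
    """Molar concentration (uM) of n chains in an orthorhombic box (nm)."""
    box = np.asarray(box, dtype=float).reshape(3)
    volume_l = float(np.prod(box)) * 1e-24  # nm^3 -> L
    if volume_l <= 0:
        raise ValueError("box volume must be > 0")
    return n_chains / (N_AVOGADRO * volume_l) * 1e6


def chains_for(concentration_um: float, box: np.ndarray) -> int:
    """Copy count whose concentration in the box is closest to the target."""
    box = np.asarray(box, dtype=float).reshape(3)
    volume_l = float(np.prod(box)) * 1e-24
    if volume_l <= 0:
        raise ValueError("box volume must be > 0")
    return int(round(concentration_um * 1e-6 * N_AVOGADRO * volume_l))


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


def _conformations(spec: AssemblySpec, params, rng) -> tuple[list[ChainTopology], list[np.ndarray]]:
    """Per-chain topology and centered template coordinates, in chain order."""
    topologies, templates = [], []
    for cs in spec.chain_specs:
        top = build_chain_topology(
            cs.sequence, cs.domains, cs.reference, params, kind=cs.kind
        )
        for c in range(cs.copies):
            if cs.reference is not None:
                coords = cs.reference.coords.copy()
            else:
                coords = make_random_coil(
                    cs.sequence, seed=int(rng.integers(2**31)),
                ).coords
            topologies.append(top)
            templates.append(coords - coords.mean(axis=0))
    return topologies, templates


def _random_rotation(rng) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()


def _try_place(
    placed_tree, placed_coords, template, center, rng, box
) -> np.ndarray | None:
    coords = template @ _random_rotation(rng).T + center
    if placed_tree is not None:
        d, _ = placed_tree.query(np.mod(coords, box), k=1)
        if np.min(d) < MIN_PLACEMENT_DISTANCE:
            return None
    return coords


def _place_chains(templates, centers_fn, spec, rng, max_retries=200):
    """Place each template at a center proposed by centers_fn, clash-checked."""
    box = spec.box
    placed: list[np.ndarray] = []
    all_coords = None
    tree = None
    for k, template in enumerate(templates):
        for attempt in range(max_retries):
            center = centers_fn(k, attempt)
            coords = _try_place(tree, all_coords, template, center, rng, box)
            if coords is not None:
                placed.append(coords)
                all_coords = np.concatenate(placed)
                tree = cKDTree(np.mod(all_coords, box), boxsize=box)
                break
        else:
            raise RuntimeError(
                f"could not place chain {k} without clashes after {max_retries} "
                "attempts; consider a larger box"
            )
    return placed


def place_random(spec: AssemblySpec, params: ForceFieldParams | None = None) -> SystemState:
    """All chains at random positions and orientations; seed-reproducible."""
    params = params or default_params()
    rng = np.random.default_rng(spec.seed)
    topologies, templates = _conformations(spec, params, rng)

    def centers(_k, _attempt):
        return rng.random(3) * spec.box

    placed = _place_chains(templates, centers, spec, rng)
    return _finish(placed, topologies, spec)


def droplet_radius(n_beads: int, density: float = CONDENSATE_BEAD_DENSITY) -> float:
    """Radius (nm) of a sphere holding n beads at the packing density."""
    return (3.0 * n_beads / (4.0 * math.pi * density)) ** (1.0 / 3.0)


def _droplet_centers(n_chains, beads_per_chain, box, rng,
                     density=CONDENSATE_BEAD_DENSITY):
    """Jittered lattice sites inside a central sphere at the target density."""
    radius = droplet_radius(n_chains * beads_per_chain, density)
    spacing = (4.0 / 3.0 * math.pi * radius**3 / max(n_chains, 1)) ** (1.0 / 3.0)
    center = box / 2.0
    sites = []
    grow = 1.0
    while len(sites) < n_chains:
        sites = []
        r = radius * grow
        half = int(math.ceil(r / spacing))
        for ix in range(-half, half + 1):
            for iy in range(-half, half + 1):
                for iz in range(-half, half + 1):
                    p = np.array([ix, iy, iz], dtype=float) * spacing
                    if np.linalg.norm(p) <= r:
                        sites.append(center + p)
        grow *= 1.15
    sites = np.array(sites)
    order = rng.permutation(len(sites))[:n_chains]
    jitter = rng.normal(scale=0.15 * spacing, size=(n_chains, 3))
    return sites[order] + jitter, radius


def place_condensate(
    spec: AssemblySpec, params: ForceFieldParams | None = None,
    minimize: bool = True,
) -> SystemState:
    """All chains packed as a central droplet, then relaxed to remove clashes."""
    params = params or default_params()
    rng = np.random.default_rng(spec.seed)
    topologies, templates = _conformations(spec, params, rng)
    n = len(templates)
    beads_per_chain = int(np.mean([len(t) for t in templates]))
    centers, _ = _droplet_centers(n, beads_per_chain, spec.box, rng,
                                  spec.condensate_density)

    def center_fn(k, attempt):
        if attempt == 0:
            return centers[k]
        return centers[k] + rng.normal(scale=0.3 * (1 + attempt / 20), size=3)

    placed = _place_chains(templates, center_fn, spec, rng)
    state = _finish(placed, topologies, spec)
    if minimize:
        state = minimize_energy(state, params)
    return state


def place_mixed(
    spec: AssemblySpec, params: ForceFieldParams | None = None,
    minimize: bool = True,
) -> SystemState:
    """Preformed droplet of ``n_condensate`` chains plus a dispersed remainder.

    Degenerate cases reduce to the pure modes: n_condensate equal to the
    total copy count gives a droplet-only start, zero gives a random start.
    """
    params = params or default_params()
    total = sum(c.copies for c in spec.chain_specs)
    if spec.n_condensate >= total:
        return place_condensate(spec, params, minimize=minimize)
    if spec.n_condensate <= 0:
        return place_random(spec, params)

    rng = np.random.default_rng(spec.seed)
    topologies, templates = _conformations(spec, params, rng)
    beads_per_chain = int(np.mean([len(t) for t in templates]))
    centers, radius = _droplet_centers(spec.n_condensate, beads_per_chain,
                                       spec.box, rng, spec.condensate_density)
    box_center = spec.box / 2.0
    margin = radius + 1.0

    def center_fn(k, attempt):
        if k < spec.n_condensate:
            if attempt == 0:
                return centers[k]
            return centers[k] + rng.normal(scale=0.3 * (1 + attempt / 20), size=3)
        while True:  # dilute chains stay outside the droplet
            p = rng.random(3) * spec.box
            delta = p - box_center
            delta -= spec.box * np.round(delta / spec.box)
            if np.linalg.norm(delta) > margin:
                return p

    placed = _place_chains(templates, center_fn, spec, rng)
    state = _finish(placed, topologies, spec)
    if minimize:
        state = minimize_energy(state, params)
    return state


def _finish(placed, topologies, spec) -> SystemState:
    coords = np.concatenate(placed)
    chain_index = np.concatenate(
        [np.full(len(p), c, dtype=np.int64) for c, p in enumerate(placed)]
    )
    return SystemState(np.mod(coords, spec.box), spec.box, chain_index, topologies)


# ---------------------------------------------------------------------------
# Energy minimization (steepest descent with step halving)
# ---------------------------------------------------------------------------


def minimize_energy(
    state: SystemState,
    params: ForceFieldParams | None = None,
    max_steps: int = 5000,
    force_tolerance: float = 100.0,   # kJ/(mol nm)
    initial_step: float = 0.01,       # nm
) -> SystemState:
    """Relax a state by steepest descent until forces fall below tolerance.

    The step length adapts: it grows after accepted moves and halves after
    rejected (energy-increasing) ones. Intended for clash removal after
    packing, not for locating precise minima.
    """
    from .energetics import _check_box, _kernel_args

    params = params or default_params()
    _check_box(state, params)
    flat = flatten_system(state, params)
    coords = np.mod(state.coords, state.box)
    f = np.zeros_like(coords)

    def eval_at(x, pairs):
        terms = _kernels.compute_forces(
            x, state.box, pairs, *_kernel_args(flat, params, pairs),
            flat.bond_pairs, flat.bond_r0, params.k_bond,
            flat.enm_pairs, flat.enm_r0, params.k_enm,
            flat.angle_triples, flat.angle_k, params.theta0_rad, f,
        )
        return float(sum(terms)), f

    step = initial_step
    pairs = neighbor_pairs(coords, state.box, params.nonbonded_cutoff + 0.5,
                           flat.exclusion_keys)
    u, grad = eval_at(coords, pairs)
    grad = grad.copy()
    for it in range(max_steps):
        fmax = float(np.abs(grad).max()) if len(grad) else 0.0
        if fmax < force_tolerance:
            break
        direction = grad / max(fmax, 1e-12)
        accepted = False
        for _ in range(20):
            trial = coords + step * direction
            u_new, grad_new = eval_at(trial, pairs)
            if np.isfinite(u_new) and u_new < u:
                coords, u = trial, u_new
                grad = grad_new.copy()
                step = min(step * 1.2, 0.1)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        if it % 25 == 24:
            coords = np.mod(coords, state.box)
            pairs = neighbor_pairs(coords, state.box,
                                   params.nonbonded_cutoff + 0.5,
                                   flat.exclusion_keys)
            u, g = eval_at(coords, pairs)
            grad = g.copy()
    return SystemState(coords, state.box.copy(), state.chain_index.copy(),
                       list(state.topologies))
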