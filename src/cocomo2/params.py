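"""Force-field parameter sets and per-residue property tables.

This module is the single source of truth for every numeric constant of the
residue-level coarse-grained model: the two published parameter generations
("cocomo" and "cocomo2"), the bonded constants shared by both, and the
per-residue radii, charges and interaction categories.

Units follow the standard MD convention used throughout the package:
energies in kJ/mol, lengths in nm, time in ps, masses in g/mol (amu),
charges in elementary charges, temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

# ---------------------------------------------------------------------------
# Physical constants (MD unit system)
# ---------------------------------------------------------------------------

#: Boltzmann constant, kJ/(mol K)
KB = 0.00831446261815324
#: Coulomb constant e^2 * N_A / (4 pi eps_0), kJ nm / mol
KE = 138.935456
#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

POLAR_CODES = frozenset("RNDCQEHKST")
HYDROPHOBIC_CODES = frozenset("AGILMFPWYV")
NUCLEOTIDE_CODES = frozenset("ACGU")
CATIONIC_CODES = frozenset("RK")
AROMATIC_CODES = frozenset("FYW")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGU"

# Amino-acid residue volumes (A^3), Zamyatnin (1972) partial volumes.
# The bead radius is that of the sphere of equivalent volume; the table is
# user-overridable through residue_table(volume_overrides=...).
_AA_VOLUME_A3 = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# RNA nucleotide residue volumes (A^3), approximate published residue
# volumes (Voss & Gerstein); one bead per nucleotide.
_NT_VOLUME_A3 = {"A": 315.0, "G": 341.0, "C": 288.0, "U": 280.0}

# Residue charges in elementary charges: Arg/Lys +1, Asp/Glu -1, His and
# termini neutral, one -1 per nucleotide (backbone phosphate).
_AA_CHARGE = {"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0}

#: Per-bead masses used by the dynamics engine (uniform within each polymer
#: class; with Langevin NVT at fixed friction they rescale kinetics only).
MASS_AMINO_ACID = 110.0
MASS_NUCLEOTIDE = 330.0


def radius_from_volume_a3(volume_a3: float) -> float:
    """Radius (nm) of the sphere with the given volume (A^3)."""
    return (3.0 * volume_a3 / (4.0 * math.pi)) ** (1.0 / 3.0) / 10.0


def sigma_from_radius(radius_nm: float) -> float:
    """Effective bead diameter: sigma = 2 r * 2^(-1/6)."""
    return 2.0 * radius_nm * 2.0 ** (-1.0 / 6.0)


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForceFieldParams:
    """Complete constant set of the coarse-grained energy model.

    The short-range well depths (``epsilon_*``), solvation repulsion
    amplitudes (``A0_*``) and the surface-exposure threshold
    ``lambda_threshold`` are the generation-specific, optimizable
    parameters; everything else is fixed across model versions.
    """

    # optimizable, generation-specific
    epsilon_polar: float = 0.176          # kJ/mol
    epsilon_hydrophobic: float = 0.295    # kJ/mol
    A0_polar: float = 0.0                 # sqrt(kJ nm / mol), effective
    A0_hydrophobic: float = 0.0002
    lambda_threshold: float = 0.7         # surface-exposure threshold in (0, 1]

    # bonded terms
    k_bond: float = 4184.0                # kJ/(mol nm^2)
    l0_protein: float = 0.38              # nm, mean Calpha-Calpha distance
    l0_nucleotide: float = 0.5            # nm, ssRNA backbone spacing
    k_enm: float = 500.0                  # kJ/(mol nm^2)
    enm_cutoff: float = 0.9               # nm, max rest length for network pairs
    k_angle_protein: float = 4.184        # kJ/(mol rad^2)
    k_angle_nucleotide: float = 5.021     # kJ/(mol rad^2)
    theta0: float = 180.0                 # degrees

    # short-range well-depth increments (added on top of the combined epsilon)
    eps_mod_cation_aromatic: float = 0.3  # kJ/mol, {R,K} x {F,Y,W}
    eps_mod_cation_nucleic: float = 0.2   # kJ/mol, {R,K} x nucleotide
    eps_mod_aromatic_aromatic: float = 0.1  # kJ/mol, {F,Y,W} x {F,Y,W}

    # electrostatics
    debye_length: float = 1.0             # nm (~100 mM ionic strength)
    dielectric: float = 80.0              # relative permittivity of water

    # nonbonded bookkeeping
    nonbonded_cutoff: float = 3.0         # nm, plain truncation

    # thermodynamic state
    temperature: float = 298.0            # K
    friction: float = 0.01                # ps^-1, Langevin collision rate

    # model-composition switches (see docs/methods.md)
    combine_rule: str = "geometric"       # geometric | arithmetic epsilon mixing
    xi_scales_electrostatics: bool = True
    enm_excludes_nonbonded: bool = False
    shift_short_range: bool = False       # energy-shift the 10-5 term at cutoff

    def __post_init__(self) -> None:
        nonneg = (
            "epsilon_polar", "epsilon_hydrophobic", "A0_polar",
            "A0_hydrophobic", "k_bond", "l0_protein", "l0_nucleotide",
            "k_enm", "enm_cutoff", "k_angle_protein", "k_angle_nucleotide",
            "eps_mod_cation_aromatic", "eps_mod_cation_nucleic",
            "eps_mod_aromatic_aromatic",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 < self.lambda_threshold <= 1.0:
            raise ValueError("lambda_threshold must be in (0, 1]")
        if self.debye_length <= 0:
            raise ValueError("debye_length must be > 0")
        if self.nonbonded_cutoff <= 0:
            raise ValueError("nonbonded_cutoff must be > 0")
        if self.combine_rule not in ("geometric", "arithmetic"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")

    @property
    def theta0_rad(self) -> float:
        return math.radians(self.theta0)

    def replace(self, **changes) -> "ForceFieldParams":
        return replace(self, **changes)

    # -- flat key=value serialization -------------------------------------

    def to_file(self, path) -> None:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise ValueError(f"unknown parameter {key!r} in {path}")
            if casts[key] == "bool" or casts[key] is bool:
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif casts[key] == "str" or casts[key] is str:
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def default_params(version: str = "cocomo2") -> ForceFieldParams:
    """Published parameter set for the requested model generation.

    The second generation differs from the first only in the optimizable
    constants (polar/hydrophobic well depths, solvation repulsion
    amplitudes), the presence of the surface-exposure threshold lambda and
    the aromatic-aromatic well-depth increment.
    """
    version = version.lower()
    if version == "cocomo2":
        return ForceFieldParams()
    if version == "cocomo":
        return ForceFieldParams(
            epsilon_polar=0.40,
            epsilon_hydrophobic=0.41,
            A0_polar=0.05,
            A0_hydrophobic=0.0,
            lambda_threshold=1.0,       # no surface scaling in generation 1
            eps_mod_aromatic_aromatic=0.0,
        )
    raise ValueError(f"unknown force-field version {version!r}; expected 'cocomo' or 'cocomo2'")


def scale_interactions(params: ForceFieldParams, factor: float) -> ForceFieldParams:
    """Uniformly scale every short-range well depth by ``factor``.

    Scales the polar/hydrophobic category depths and the three
    chemistry-specific increments together, leaving bonded terms and
    electrostatics untouched; used for interaction-strength scans.
    """
    return params.replace(
        epsilon_polar=params.epsilon_polar * factor,
        epsilon_hydrophobic=params.epsilon_hydrophobic * factor,
        eps_mod_cation_aromatic=params.eps_mod_cation_aromatic * factor,
        eps_mod_cation_nucleic=params.eps_mod_cation_nucleic * factor,
        eps_mod_aromatic_aromatic=params.eps_mod_aromatic_aromatic * factor,
    )


# ---------------------------------------------------------------------------
# Residue table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueType:
    """Per-residue bead properties.

    ``radius`` is the radius (nm) of the sphere with the residue's partial
    volume; ``sigma`` the derived zero-crossing diameter; ``charge`` in
    elementary charges; ``category`` one of polar / hydrophobic /
    nucleotide; ``s_ref`` the reference solvent-accessible surface area
    (nm^2) of the residue embedded in an alanine alpha-helix (NaN until
    computed or loaded).
    """

    code: str
    radius: float
    sigma: float
    charge: float
    category: str
    s_ref: float = float("nan")

    def __post_init__(self) -> None:
        expected = sigma_from_radius(self.radius)
        if abs(self.sigma - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValueError(f"sigma inconsistent with radius for {self.code!r}")


def _category(code: str, is_nucleotide: bool) -> str:
    if is_nucleotide:
        return "nucleotide"
    if code in POLAR_CODES:
        return "polar"
    if code in HYDROPHOBIC_CODES:
        return "hydrophobic"
    raise ValueError(f"unknown residue code {code!r}")


_SREF_CACHE: dict[tuple, dict[str, float]] = {}


def residue_table(
    params: ForceFieldParams | None = None,
    *,
    s_ref: Mapping[str, float] | None = None,
    charge_overrides: Mapping[str, float] | None = None,
    volume_overrides: Mapping[str, float] | None = None,
    compute_s_ref: bool = True,
) -> dict[str, ResidueType]:
    """Full per-residue property table: 20 amino acids + 4 nucleotides.

    Amino-acid codes use the standard one-letter alphabet; nucleotide codes
    are lowercase a/c/g/u so that RNA adenosine never collides with alanine.
    ``s_ref`` values are generated procedurally (helix-host reference areas,
    see :func:`cocomo2.topology.make_reference_areas`) unless a table is
    supplied; charges and volumes are user-overridable.
    """
    params = params or default_params()
    charges = dict(_AA_CHARGE)
    volumes = dict(_AA_VOLUME_A3)
    nt_volumes = dict(_NT_VOLUME_A3)
    if charge_overrides:
        charges.update(charge_overrides)
    if volume_overrides:
        for k, v in volume_overrides.items():
            if k.islower():
                nt_volumes[k.upper()] = v
            else:
                volumes[k] = v

    if s_ref is None and compute_s_ref:
        key = (tuple(sorted(volumes.items())),)
        if key not in _SREF_CACHE:
            from .topology import make_reference_areas  # deferred: avoids cycle

            _SREF_CACHE[key] = make_reference_areas(
                residue_table(params, compute_s_ref=False)
            )
        s_ref = _SREF_CACHE[key]

    table: dict[str, ResidueType] = {}
    for code in AMINO_ACIDS:
        r = radius_from_volume_a3(volumes[code])
        table[code] = ResidueType(
            code=code,
            radius=r,
            sigma=sigma_from_radius(r),
            charge=charges.get(code, 0.0),
            category=_category(code, is_nucleotide=False),
            s_ref=float(s_ref[code]) if s_ref and code in s_ref else float("nan"),
        )
    for nt in NUCLEOTIDES:
        code = nt.lower()
        r = radius_from_volume_a3(nt_volumes[nt])
        table[code] = ResidueType(
            code=code,
            radius=r,
            sigma=sigma_from_radius(r),
            charge=charges.get(code, -1.0),
            category="nucleotide",
            s_ref=4.0 * math.pi * (r + 0.14) ** 2,  # isolated-sphere area
        )
    return table


def residue_table_to_csv(table: Mapping[str, ResidueType], path) -> None:
    lines = ["code,radius_nm,charge_e,category,s_ref_nm2"]
    for code in sorted(table):
        t = table[code]
        lines.append(f"{t.code},{t.radius:.6f},{t.charge},{t.category},{t.s_ref:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def residue_table_from_csv(path) -> dict[str, ResidueType]:
    import pandas as pd

    df = pd.read_csv(path)
    table = {}
    for row in df.itertuples(index=False):
        r = float(row.radius_nm)
        table[row.code] = ResidueType(
            code=row.code, radius=r, sigma=sigma_from_radius(r),
            charge=float(row.charge_e), category=row.category,
            s_ref=float(row.s_ref_nm2),
        )
    return table


# ---------------------------------------------------------------------------
# Pair well depth
# ---------------------------------------------------------------------------


def _is_cationic(t: ResidueType) -> bool:
    return t.code in CATIONIC_CODES


def _is_aromatic(t: ResidueType) -> bool:
    return t.code in AROMATIC_CODES


def _base_epsilon(t: ResidueType, params: ForceFieldParams) -> float:
    # Nucleotides reuse the polar well depth (generation tables print only
    # polar/hydrophobic values); override via a custom residue table if needed.
    if t.category == "hydrophobic":
        return params.epsilon_hydrophobic
    return params.epsilon_polar


def epsilon_mod(t_i: ResidueType, t_j: ResidueType, params: ForceFieldParams) -> float:
    """Well-depth increment for chemistry-specific pairings.

    Cation-aromatic and cation-nucleotide increments carry over from the
    first model generation; the aromatic-aromatic increment is specific to
    the second generation (it is zero in the generation-1 parameter set).
    """
    ci, cj = _is_cationic(t_i), _is_cationic(t_j)
    ai, aj = _is_aromatic(t_i), _is_aromatic(t_j)
    ni, nj = t_i.category == "nucleotide", t_j.category == "nucleotide"
    if (ci and aj) or (ai and cj):
        return params.eps_mod_cation_aromatic
    if (ci and nj) or (ni and cj):
        return params.eps_mod_cation_nucleic
    if ai and aj:
        return params.eps_mod_aromatic_aromatic
    return 0.0


def pair_epsilon(
    t_i: ResidueType,
    t_j: ResidueType,
    xi_i: float = 1.0,
    xi_j: float = 1.0,
    params: ForceFieldParams | None = None,
) -> float:
    """Well depth (kJ/mol) of the short-range 10-5 potential for a bead pair.

    The category well depths are mixed by the configured combination rule
    (geometric mean by default), the chemistry-specific increment is added,
    and the whole depth is scaled bilinearly by the two surface-exposure
    interaction strengths xi in [0, 1].
    """
    params = params or default_params()
    if not (0.0 <= xi_i <= 1.0 and 0.0 <= xi_j <= 1.0):
        raise ValueError("xi values must lie in [0, 1]")
    e_i, e_j = _base_epsilon(t_i, params), _base_epsilon(t_j, params)
    if params.combine_rule == "geometric":
        base = math.sqrt(e_i * e_j)
    else:
        base = 0.5 * (e_i + e_j)
    return xi_i * xi_j * (base + epsilon_mod(t_i, t_j, params))
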