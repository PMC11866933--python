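"""Sequence, structure and trajectory I/O plus synthetic-fixture generators.

Internal length unit is nm everywhere; PDB files are converted A <-> nm at
the boundary. Protein residues use uppercase one-letter codes, RNA
nucleotides lowercase a/c/g/u (so adenosine never collides with alanine).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .params import AMINO_ACIDS, NUCLEOTIDES

# ideal alpha-helix Calpha-trace parameters
HELIX_RISE = 0.15       # nm per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 0.23     # nm

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA1 = {v: k for k, v in _AA3.items()}
_NT_RESNAMES = {"A": "a", "C": "c", "G": "g", "U": "u",
                "RA": "a", "RC": "c", "RG": "g", "RU": "u"}


def normalize_sequence(sequence: str, kind: str = "protein") -> str:
    """Canonical internal residue string for a raw sequence.

    Proteins map to uppercase one-letter codes, RNA to lowercase a/c/g/u.
    """
    seq = sequence.strip().replace("\n", "").replace(" ", "")
    if kind == "protein":
        seq = seq.upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown amino-acid code(s) {sorted(bad)}")
        return seq
    if kind == "rna":
        seq = seq.upper().replace("T", "U")
        bad = set(seq) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"unknown nucleotide code(s) {sorted(bad)}")
        return seq.lower()
    raise ValueError(f"unknown sequence kind {kind!r}")


def read_fasta(path, kind: str = "protein") -> dict[str, str]:
    """Sequences from a FASTA file, normalized to internal codes."""
    from Bio import SeqIO

    return {
        rec.id: normalize_sequence(str(rec.seq), kind)
        for rec in SeqIO.parse(str(path), "fasta")
    }


# ---------------------------------------------------------------------------
# Reference structures and folded-domain definitions
# ---------------------------------------------------------------------------


@dataclass
class ReferenceStructure:
    """One-bead-per-residue reference conformation (Calpha trace, nm)."""

    residue_codes: str
    coords: np.ndarray          # (N, 3) nm
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.residue_codes) != len(self.coords):
            raise ValueError("residue_codes and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    def __len__(self) -> int:
        return len(self.residue_codes)


@dataclass(frozen=True)
class DomainDefinition:
    """Folded-domain residue ranges, 1-based inclusive (biology convention)."""

    ranges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.ranges:
            if start < 1 or end < start:
                raise ValueError(f"invalid domain range {start}-{end}")
            if start <= prev_end:
                raise ValueError("domain ranges must be sorted and non-overlapping")
            prev_end = end

    @classmethod
    def parse(cls, text: str) -> "DomainDefinition":
        """Parse config syntax like ``"1-10,20-30"`` (empty -> no domains)."""
        text = text.strip()
        if not text:
            return cls(())
        ranges = []
        for part in text.split(","):
            start, _, end = part.partition("-")
            ranges.append((int(start), int(end)))
        return cls(tuple(ranges))

    def zero_based(self) -> list[tuple[int, int]]:
        """Ranges as half-open 0-based (start, stop) python slices."""
        return [(s - 1, e) for s, e in self.ranges]

    def contains(self, index0: int) -> bool:
        return any(s <= index0 < e for s, e in self.zero_based())

    @property
    def max_residue(self) -> int:
        return max((e for _, e in self.ranges), default=0)


# ---------------------------------------------------------------------------
# PDB I/O (Calpha / one-bead representation)
# ---------------------------------------------------------------------------


def write_pdb(
    structures: ReferenceStructure | Sequence[ReferenceStructure],
    path,
    *,
    remarks: Iterable[str] = (),
) -> None:
    """Write Calpha-trace PDB (one CA atom per bead, coordinates nm -> A)."""
    if isinstance(structures, ReferenceStructure):
        structures = [structures]
    lines = [f"REMARK   {r}" for r in remarks]
    serial = 1
    for s in structures:
        for i, code in enumerate(s.residue_codes):
            if code.islower():
                resname = code.upper().rjust(3)
            else:
                resname = _AA3[code]
            x, y, z = s.coords[i] * 10.0
            lines.append(
                f"ATOM  {serial % 100000:5d}  CA  {resname:>3s} {s.chain_id[:1]}"
                f"{(i + 1) % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference_pdb(path) -> list[ReferenceStructure]:
    """Calpha traces from a PDB file, one ReferenceStructure per chain.

    Coordinates are converted A -> nm. A residue without a CA atom (C1' is
    accepted for nucleotides) or with an unknown residue name raises an
    error naming the offending residue.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(parser.get_structure("ref", str(path)).get_models())

    out = []
    for chain in model:
        codes = []
        coords = []
        for residue in chain:
            resname = residue.get_resname().strip()
            if residue.id[0].strip():  # skip waters/hetero records
                continue
            if resname in _AA1:
                code = _AA1[resname]
            elif resname in _NT_RESNAMES:
                code = _NT_RESNAMES[resname]
            else:
                raise ValueError(
                    f"unknown residue name {resname!r} at {chain.id}:{residue.id[1]}"
                )
            atom = None
            for name in ("CA", "C1'", "P"):
                if name in residue:
                    atom = residue[name]
                    break
            if atom is None:
                raise ValueError(
                    f"residue {resname} {chain.id}:{residue.id[1]} has no CA atom"
                )
            codes.append(code)
            coords.append(atom.coord / 10.0)  # A -> nm
        if codes:
            out.append(
                ReferenceStructure("".join(codes), np.array(coords), chain_id=chain.id)
            )
    if not out:
        raise ValueError(f"no parsable chains in {path}")
    return out


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def make_ideal_helix(sequence: str, chain_id: str = "A") -> ReferenceStructure:
    """Calpha trace of an ideal alpha-helix.

    Rise 0.15 nm/residue, 100 deg/residue rotation, helix radius 0.23 nm,
    giving the canonical ~0.38 nm consecutive Calpha spacing. Deterministic.
    """
    if not sequence:
        raise ValueError("sequence must be nonempty")
    n = len(sequence)
    i = np.arange(n)
    omega = np.deg2rad(HELIX_TWIST) * i
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(omega), HELIX_RADIUS * np.sin(omega), HELIX_RISE * i]
    )
    coords -= coords[0]
    return ReferenceStructure(sequence, coords, chain_id=chain_id)


def make_random_coil(
    sequence: str,
    bond_length: float = 0.38,
    seed: int = 0,
    min_separation: float = 0.35,
    chain_id: str = "A",
) -> ReferenceStructure:
    """Self-avoiding-ish random walk with fixed bond length; seed-reproducible.

    Each new bead direction is resampled (bounded retries) until it clears
    ``min_separation`` from all previous beads; after the retry budget the
    best candidate seen is accepted, so construction never fails.
    """
    if bond_length <= 0:
        raise ValueError("bond_length must be > 0")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    coords = np.zeros((n, 3))
    for i in range(1, n):
        best = None
        best_min = -np.inf
        for _ in range(30):
            v = rng.normal(size=3)
            v *= bond_length / np.linalg.norm(v)
            cand = coords[i - 1] + v
            if i == 1:
                best = cand
                break
            d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
            dmin = d.min()
            if dmin > best_min:
                best, best_min = cand, dmin
            if dmin >= min_separation:
                break
        coords[i] = best
    return ReferenceStructure(sequence, coords, chain_id=chain_id)


# ---------------------------------------------------------------------------
# Trajectory I/O (DCD frames + PDB topology sidecar)
# ---------------------------------------------------------------------------


def write_trajectory(frames: np.ndarray, box: np.ndarray, path, topology=None) -> None:
    """Write frames (F, M, 3) nm with an orthorhombic box to a DCD file.

    ``topology``, if given, is a ReferenceStructure (or list of them) written
    as a matching PDB next to the trajectory (same stem, .pdb suffix).
    """
    import mdtraj.formats as mdfmt

    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0 or frames.shape[2] != 3:
        raise ValueError("frames must be a nonempty (F, M, 3) array")
    box = np.asarray(box, dtype=float).reshape(3)
    path = Path(path)
    with mdfmt.DCDTrajectoryFile(str(path), "w") as f:
        for frame in frames:
            f.write(
                xyz=(frame * 10.0).astype(np.float32),
                cell_lengths=(box * 10.0).astype(np.float64),
                cell_angles=np.array([90.0, 90.0, 90.0]),
            )
    if topology is not None:
        write_pdb(topology, path.with_suffix(".pdb"))


def read_trajectory(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a DCD trajectory back as (frames (F, M, 3) nm, box (3,) nm)."""
    import mdtraj.formats as mdfmt

    with mdfmt.DCDTrajectoryFile(str(path), "r") as f:
        xyz, cell_lengths, _ = f.read()
    if xyz is None or len(xyz) == 0:
        raise ValueError(f"no frames in {path}")
    frames = np.asarray(xyz, dtype=float) / 10.0
    box = np.asarray(cell_lengths[0], dtype=float) / 10.0
    return frames, box
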