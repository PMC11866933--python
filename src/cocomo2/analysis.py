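"""Condensate analysis: chain clustering, monomer counting, c_sat, R_g.

Chains are grouped by single-linkage hierarchical clustering of their
centers: two chains join when their center-center distance (minimum image)
is below ``factor`` times the mean of their radii of gyration. Chains in
clusters smaller than the monomer threshold form the dilute phase; the
dilute concentration over a trailing window of frames estimates the
saturation concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .assembly import concentration
from .energetics import SystemState

DEFAULT_CLUSTER_FACTOR = 2.4
DEFAULT_MONOMER_THRESHOLD = 5     # raise to 10 for high-concentration systems


@dataclass
class ClusterResult:
    """Chain-level clustering of one frame."""

    labels: np.ndarray            # per-chain cluster id (0-based)
    sizes: np.ndarray             # chains per cluster, indexed by cluster id
    monomer_threshold: int
    n_dilute: int                 # chains in clusters below the threshold
    dilute_concentration: float   # uM (full box volume; see estimate_csat)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def largest_cluster(self) -> int:
        return int(self.sizes.max()) if len(self.sizes) else 0


@dataclass
class CsatEstimate:
    """Dilute-phase concentration averaged over a trailing frame window."""

    value: float                  # uM
    window: tuple[int, int]       # frame range [start, stop) averaged
    per_frame: np.ndarray         # dilute concentration per analyzed frame


def unwrap_chain(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a chain whole across periodic boundaries by walking its bonds."""
    out = coords.copy()
    for i in range(1, len(out)):
        delta = out[i] - out[i - 1]
        delta -= box * np.round(delta / box)
        out[i] = out[i - 1] + delta
    return out


def chain_centers_and_rg(state: SystemState) -> tuple[np.ndarray, np.ndarray]:
    """Equal-mass center and radius of gyration per chain (nm).

    Each chain is first unwrapped with minimum-image steps along its bonds
    so a chain straddling the periodic boundary is measured whole.
    """
    centers, rgs = [], []
    for sl in state.chain_slices():
        whole = unwrap_chain(state.coords[sl], state.box)
        c = whole.mean(axis=0)
        rgs.append(float(np.sqrt(np.mean(np.sum((whole - c) ** 2, axis=1)))))
        centers.append(np.mod(c, state.box))
    return np.array(centers), np.array(rgs)


def cluster_chains(
    centers: np.ndarray,
    rg_values: np.ndarray,
    box: np.ndarray | None = None,
    factor: float = DEFAULT_CLUSTER_FACTOR,
    monomer_threshold: int = DEFAULT_MONOMER_THRESHOLD,
    rg_mode: str = "pairwise",
) -> ClusterResult:
    """Single-linkage clustering with an R_g-scaled distance cutoff.

    The pair (i, j) is linked when d(i, j) < factor * (Rg_i + Rg_j)/2
    (minimum image if a box is given). ``rg_mode='global'`` replaces the
    per-pair mean by the global mean R_g. Dilute chains are those in
    clusters of size below ``monomer_threshold``.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    n = len(centers)
    if n == 1:
        labels = np.zeros(1, dtype=int)
        sizes = np.array([1])
    else:
        delta = centers[:, None, :] - centers[None, :, :]
        if box is not None:
            box = np.asarray(box, dtype=float).reshape(3)
            delta -= box * np.round(delta / box)
        d = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
        if rg_mode == "global":
            avg = np.full((n, n), max(float(np.mean(rg_values)), 1e-12))
        else:
            avg = np.maximum((rg_values[:, None] + rg_values[None, :]) / 2.0, 1e-12)
        normalized = d / avg
        z = linkage(squareform(normalized, checks=False), method="single")
        # fcluster merges at <= t; shrink t marginally so the criterion is strict <
        labels = fcluster(z, t=factor * (1 - 1e-12), criterion="distance") - 1
        sizes = np.bincount(labels)
    n_dilute = int(sizes[labels][sizes[labels] < monomer_threshold].size)
    conc = concentration(n_dilute, box) if box is not None else float("nan")
    return ClusterResult(
        labels=labels, sizes=sizes, monomer_threshold=monomer_threshold,
        n_dilute=n_dilute, dilute_concentration=conc,
    )


def cluster_frame(
    state: SystemState,
    factor: float = DEFAULT_CLUSTER_FACTOR,
    monomer_threshold: int = DEFAULT_MONOMER_THRESHOLD,
    rg_mode: str = "pairwise",
) -> ClusterResult:
    centers, rgs = chain_centers_and_rg(state)
    return cluster_chains(centers, rgs, box=state.box, factor=factor,
                          monomer_threshold=monomer_threshold, rg_mode=rg_mode)


def estimate_csat(
    frames: Sequence[SystemState],
    window: tuple[int, int] | None = None,
    factor: float = DEFAULT_CLUSTER_FACTOR,
    monomer_threshold: int = DEFAULT_MONOMER_THRESHOLD,
    volume_mode: str = "full_box",
    rg_mode: str = "pairwise",
) -> CsatEstimate:
    """Saturation concentration as the windowed mean dilute concentration.

    The dilute (free monomer) count per frame is converted to a molar
    concentration over the full box volume by default -- the droplet volume
    is not subtracted, biasing the estimate by at most the droplet/box
    volume ratio; ``volume_mode='exclude_condensate'`` subtracts the dense
    phase volume estimated from the condensed chains' R_g spheres.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("no frames")
    if window is None:
        window = (0, n)
    start, stop = window
    if not (0 <= start < stop <= n):
        raise ValueError(f"window {window} outside trajectory of {n} frames")

    per_frame = []
    for state in frames[start:stop]:
        centers, rgs = chain_centers_and_rg(state)
        res = cluster_chains(centers, rgs, box=state.box, factor=factor,
                             monomer_threshold=monomer_threshold, rg_mode=rg_mode)
        c = res.dilute_concentration
        if volume_mode == "exclude_condensate":
            dense = res.sizes[res.labels] >= monomer_threshold
            v_dense = float(np.sum(4.0 / 3.0 * np.pi * rgs[dense] ** 3))
            v_box = float(np.prod(state.box))
            frac = max(1.0 - v_dense / v_box, 1e-9)
            c = c / frac
        per_frame.append(c)
    per_frame = np.array(per_frame)
    return CsatEstimate(value=float(per_frame.mean()), window=(start, stop),
                        per_frame=per_frame)


def detect_coexistence(
    results: Sequence[ClusterResult],
    condensate_size: int = 150,
) -> str:
    """Classify a run: 'dissolved', 'coexisting' or 'fully_condensed'.

    ``condensate_size`` is the minimum largest-cluster size that counts as
    a condensate; the conventional reference scale is ~150 chains and
    should be scaled with the total chain count for small systems.
    A window with no condensate in any frame is dissolved; a window where
    no chain ever leaves the dense phase is fully condensed; anything else
    is coexistence.
    """
    if not results:
        raise ValueError("no cluster results")
    has_condensate = any(r.largest_cluster >= condensate_size for r in results)
    if not has_condensate:
        return "dissolved"
    if all(r.n_dilute == 0 for r in results):
        return "fully_condensed"
    return "coexisting"
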