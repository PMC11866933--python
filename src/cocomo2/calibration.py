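"""Calibration machinery: the energy / saturation-concentration relation.

Condensation theory predicts an exponential relationship between the
per-residue potential energy of the condensed phase and the saturation
concentration, i.e. log10(c_sat) is linear in U_total/N_beads. Condensate
ensembles are scored once, a robust (RANSAC) linear fit maps energies to
log10(c_sat), and force-field parameters are then optimized against
experimental concentrations through that map with a bounded quasi-Newton
search -- avoiding a fresh multi-microsecond simulation per candidate
parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .energetics import SystemState, total_energy
from .params import ForceFieldParams

RANSAC_RESIDUAL_THRESHOLD = 0.3   # log10 units
RANSAC_MAX_TRIALS = 1000
DEFAULT_N_LAST_FRAMES = 10


@dataclass
class EnergyCsatPoint:
    """One system's condensate energy and measured saturation concentration."""

    per_bead_energy: float        # kJ/mol, U_total / N_beads over condensate frames
    log10_csat: float             # log10 of c_sat in mM
    system_label: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.per_bead_energy):
            raise ValueError(f"non-finite energy for {self.system_label!r}")


@dataclass
class EnergyCsatFit:
    """Robust linear fit log10(c_sat) = a * U + b with its inlier mask."""

    a: float                      # slope per (kJ/mol)
    b: float                      # intercept, log10 mM
    inlier_mask: np.ndarray
    rmsd_inliers: float           # log10 units, inliers only


def condensate_energy_points(
    frame_sets: Sequence[Sequence[SystemState]],
    params: ForceFieldParams,
    n_last_frames: int = DEFAULT_N_LAST_FRAMES,
    labels: Sequence[str] | None = None,
) -> list[float]:
    """Mean per-bead total energy over the final frames of each system.

    Scoring the tail of an existing condensate trajectory under (possibly
    different) parameters is the cheap proxy that makes optimization
    feasible; it assumes the candidate parameters do not reshape the
    condensate ensemble.
    """
    if n_last_frames < 1:
        raise ValueError("n_last_frames must be >= 1")
    out = []
    for k, frames in enumerate(frame_sets):
        if len(frames) < n_last_frames:
            label = labels[k] if labels else str(k)
            raise ValueError(
                f"system {label!r}: trajectory has {len(frames)} frames, "
                f"needs {n_last_frames}"
            )
        tail = frames[-n_last_frames:]
        u = [total_energy(s, params).u_total / s.n_beads for s in tail]
        out.append(float(np.mean(u)))
    return out


def fit_energy_csat(
    points: Sequence[EnergyCsatPoint],
    residual_threshold: float = RANSAC_RESIDUAL_THRESHOLD,
    max_trials: int = RANSAC_MAX_TRIALS,
    seed: int = 0,
) -> EnergyCsatFit:
    """RANSAC linear fit of log10(c_sat) against per-bead energy.

    The consensus inlier set is refit by ordinary least squares; the
    reported RMSD covers inliers only. With no outliers the result equals
    plain least squares.
    """
    if len(points) < 3:
        raise ValueError(f"need at least 3 points, got {len(points)}")
    x = np.array([[p.per_bead_energy] for p in points])
    y = np.array([p.log10_csat for p in points])
    ransac = RANSACRegressor(
        estimator=LinearRegression(),
        residual_threshold=residual_threshold,
        max_trials=max_trials,
        random_state=seed,
        min_samples=2,
    )
    try:
        ransac.fit(x, y)
    except ValueError as err:
        resid = np.abs(y - np.poly1d(np.polyfit(x[:, 0], y, 1))(x[:, 0]))
        raise ValueError(
            f"no RANSAC consensus set; least-squares residuals: "
            f"{np.array2string(resid, precision=3)}"
        ) from err
    mask = ransac.inlier_mask_
    a, b = np.polyfit(x[mask, 0], y[mask], 1)
    resid = y[mask] - (a * x[mask, 0] + b)
    return EnergyCsatFit(
        a=float(a), b=float(b), inlier_mask=mask,
        rmsd_inliers=float(np.sqrt(np.mean(resid**2))),
    )


def predict_csat(per_bead_energy: float, fit: EnergyCsatFit) -> float:
    """Saturation concentration (mM) from a per-bead condensate energy."""
    return float(10.0 ** (fit.a * per_bead_energy + fit.b))


@dataclass
class OptimizationResult:
    params: ForceFieldParams
    objective: float
    trace: list[tuple[np.ndarray, float]]
    success: bool
    message: str


def optimize_params(
    evaluator: Callable[[ForceFieldParams], np.ndarray],
    experimental_log10_csat: np.ndarray,
    start: ForceFieldParams,
    free_parameters: Sequence[str] = ("epsilon_polar", "epsilon_hydrophobic", "lambda_threshold"),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    weights: np.ndarray | None = None,
    system_labels: Sequence[str] | None = None,
) -> OptimizationResult:
    """Bounded L-BFGS-B fit of force-field parameters to experimental c_sat.

    ``evaluator`` maps a candidate parameter set to predicted log10(c_sat)
    per training system (typically by re-scoring stored condensate frames
    through an energy/c_sat fit). The objective is the weighted sum of
    squared log10 deviations. The exposure threshold lambda is capped at
    0.7 by default: higher values change condensate morphology, breaking
    the frozen-ensemble assumption behind the evaluator.
    """
    experimental = np.asarray(experimental_log10_csat, dtype=float)
    weights = np.ones_like(experimental) if weights is None else np.asarray(weights, float)
    default_bounds = {
        "epsilon_polar": (0.0, 2.0),
        "epsilon_hydrophobic": (0.0, 2.0),
        "A0_polar": (0.0, 1.0),
        "A0_hydrophobic": (0.0, 1.0),
        "lambda_threshold": (1e-3, 0.7),
    }
    if bounds:
        default_bounds.update(bounds)
    box = [default_bounds[name] for name in free_parameters]
    x0 = np.array([getattr(start, name) for name in free_parameters])
    trace: list[tuple[np.ndarray, float]] = []

    def objective(x):
        candidate = start.replace(**dict(zip(free_parameters, x)))
        try:
            predicted = np.asarray(evaluator(candidate), dtype=float)
        except Exception as err:
            label = ""
            if system_labels and len(trace) < len(system_labels):
                label = f" (system {system_labels[len(trace)]!r})"
            raise RuntimeError(f"evaluator failed at x={x}{label}: {err}") from err
        value = float(np.sum(weights * (predicted - experimental) ** 2))
        trace.append((x.copy(), value))
        return value

    res = minimize(objective, x0, method="L-BFGS-B", bounds=box)
    best = start.replace(**dict(zip(free_parameters, res.x)))
    return OptimizationResult(
        params=best, objective=float(res.fun), trace=trace,
        success=bool(res.success), message=str(res.message),
    )
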