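"""Pairwise parameter-space robustness sweeps.

Each sweep varies two binding affinities on a log-spaced grid spanning a
stated fold-range (default two orders of magnitude centred on the
reference value), integrates every grid point to a late horizon, and
records the Mitfa and Sox10 steady levels plus the Sox10 maximum along
the trajectory.  A grid point is "acceptable" when it reproduces the
three behaviour requirements: maintained Mitfa, Sox10 below detection at
steady state, and a Sox10 maximum appreciably above its steady value.
The minimal model admits no acceptable points on its default pairs; the
full model is acceptable over an extensive region -- the basis on which
the model variants are rejected or retained.

All grid points are integrated simultaneously (the right-hand side
broadcasts over a leading batch axis), so a 21x21 sweep costs roughly one
trajectory's worth of Python overhead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    SPECIES,
    SPECIES_INDEX,
    Genotype,
    RegulatoryParameters,
    _AFFINITY_FIELDS,
    _rhs_masked,
    mask_params,
)
from .reference import R_MIN, THETA_DET

__all__ = [
    "SweepGrid",
    "sweep_pairwise",
    "acceptable_fraction",
    "default_sweep_pairs",
    "sweep_to_frame",
    "plot_sweep",
]

#: Steady-state division guard (nM): points with S_ss below this count as
#: satisfying the peak-ratio requirement whenever S_max is detectable.
SS_EPS = 1e-6

#: Horizon (hr) by which the reference-scale dynamics have relaxed to
#: steady state (slowest rate 0.1/hr over the swept range).
SWEEP_T1 = 240.0
SWEEP_DT = 0.02

#: Default parameter pairs per variant, following the robustness figures:
#: the minimal model varies the Sox10/Mitfa module affinities pairwise;
#: the intermediate model varies the Hdac gate on the Mitfa->S term (xi)
#: against the module affinities; the full model varies the Hdac gate on
#: the FactorA->S term (phi) against everything including xi.
_DEFAULT_PAIRS: Dict[str, List[Tuple[str, str]]] = {
    "A": [("alpha", "gamma"), ("alpha", "beta"), ("gamma", "beta")],
    "B": [("xi", o) for o in ("alpha", "beta", "delta_YM", "theta", "gamma")],
    "C": [("phi", o) for o in ("alpha", "beta", "delta_MY", "theta", "gamma", "xi")],
}


def default_sweep_pairs(variant: str) -> List[Tuple[str, str]]:
    return list(_DEFAULT_PAIRS[variant])


@dataclass(frozen=True)
class SweepGrid:
    """Result surfaces of one pairwise sweep (x index first: shape (nx, ny))."""

    variant: str
    genotype: Genotype
    param_x: str
    param_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    M_ss: np.ndarray
    S_ss: np.ndarray
    S_max: np.ndarray
    valid: np.ndarray               # False where integration failed

    def mask(self, theta_det: float = THETA_DET,
             r_min: float = R_MIN) -> np.ndarray:
        """Boolean acceptability mask, derived from the surfaces alone."""
        ratio_ok = np.where(
            self.S_ss >= SS_EPS,
            self.S_max / np.maximum(self.S_ss, SS_EPS) >= r_min,
            self.S_max >= theta_det,
        )
        return (self.valid & (self.M_ss >= theta_det)
                & (self.S_ss < theta_det) & ratio_ok)


def _batched_params(base: RegulatoryParameters, param_x: str, param_y: str,
                    xg: np.ndarray, yg: np.ndarray) -> RegulatoryParameters:
    return replace(base, **{param_x: xg.reshape(-1), param_y: yg.reshape(-1)})


def sweep_pairwise(variant: str, param_x: str, param_y: str,
                   base_params: RegulatoryParameters,
                   fold_range: float = 100.0, n_grid: int = 21,
                   genotype: Optional[Genotype] = None,
                   t0: float = 0.0, t1: float = SWEEP_T1,
                   dt: float = SWEEP_DT) -> SweepGrid:
    """Integrate every point of a log-spaced affinity grid.

    ``fold_range`` is the ratio between the largest and smallest value of
    each axis, centred geometrically on the base value; ``n_grid`` points
    per axis.  Steady levels are the late-time trajectory values (the
    horizon is many degradation times); the Sox10 maximum is tracked over
    the full trajectory.  Unstable points are recorded as invalid, never
    fatal.  Deterministic.
    """
    if param_x == param_y:
        raise ValueError("param_x and param_y must differ")
    for name in (param_x, param_y):
        if name not in _AFFINITY_FIELDS:
            raise ValueError(f"{name!r} is not an affinity parameter "
                             f"(choose from {_AFFINITY_FIELDS})")
    if fold_range < 1 or n_grid < 1:
        raise ValueError("fold_range >= 1 and n_grid >= 1 required")
    gt = genotype or Genotype.wild_type()
    half = 0.5 * np.log10(fold_range)
    bx = float(getattr(base_params, param_x))
    by = float(getattr(base_params, param_y))
    if n_grid == 1:
        x_values = np.array([bx])
        y_values = np.array([by])
    else:
        x_values = bx * np.logspace(-half, half, n_grid)
        y_values = by * np.logspace(-half, half, n_grid)
    xg, yg = np.meshgrid(x_values, y_values, indexing="ij")
    p = mask_params(_batched_params(base_params, param_x, param_y, xg, yg),
                    variant)
    n_pts = n_grid * n_grid
    state = np.zeros((n_pts, len(SPECIES)))
    cap = np.broadcast_to(p.capacity(), state.shape)
    limit = 0.5 * np.maximum(cap, 1e-12)
    n_steps = int(round((t1 - t0) / dt))
    s_max = np.zeros(n_pts)
    bad = np.zeros(n_pts, dtype=bool)
    iS = SPECIES_INDEX["S"]
    for i in range(n_steps):
        t = t0 + i * dt
        delta = dt * _rhs_masked(state, t, p, gt)
        step_bad = np.any(
            np.abs(delta) > np.maximum(limit, 0.5 * np.abs(state)), axis=-1)
        bad |= step_bad
        delta[bad] = 0.0               # freeze failed points
        state = np.maximum(state + delta, 0.0)
        s_max = np.maximum(s_max, state[:, iS])
    M_ss = state[:, SPECIES_INDEX["M"]].copy()
    S_ss = state[:, iS].copy()
    for arr in (M_ss, S_ss, s_max):
        arr[bad] = np.nan
    shape = (n_grid, n_grid)
    return SweepGrid(variant=variant, genotype=gt,
                     param_x=param_x, param_y=param_y,
                     x_values=x_values, y_values=y_values,
                     M_ss=M_ss.reshape(shape), S_ss=S_ss.reshape(shape),
                     S_max=s_max.reshape(shape),
                     valid=(~bad).reshape(shape))


def acceptable_fraction(grid: SweepGrid, theta_det: float = THETA_DET,
                        r_min: float = R_MIN) -> float:
    """Fraction of valid grid points meeting all three behaviour requirements."""
    n_valid = int(np.count_nonzero(grid.valid))
    if n_valid == 0:
        raise ValueError("all grid points invalid; nothing to score")
    return float(np.count_nonzero(grid.mask(theta_det, r_min)) / n_valid)


def sweep_to_frame(grid: SweepGrid, theta_det: float = THETA_DET,
                   r_min: float = R_MIN) -> pd.DataFrame:
    """Long-format export: one row per grid point plus the criteria mask."""
    xg, yg = np.meshgrid(grid.x_values, grid.y_values, indexing="ij")
    ok = grid.mask(theta_det, r_min)
    return pd.DataFrame({
        f"{grid.param_x}_value": xg.reshape(-1),
        f"{grid.param_y}_value": yg.reshape(-1),
        "M_ss": grid.M_ss.reshape(-1),
        "S_ss": grid.S_ss.reshape(-1),
        "S_max": grid.S_max.reshape(-1),
        "valid": grid.valid.reshape(-1),
        "ok": ok.reshape(-1),
    })


def sweep_header(grid: SweepGrid, theta_det: float = THETA_DET,
                 r_min: float = R_MIN) -> dict:
    return {
        "variant": grid.variant,
        "genotype": grid.genotype.to_dict(),
        "param_x": grid.param_x,
        "param_y": grid.param_y,
        "n_grid": int(len(grid.x_values)),
        "theta_det": theta_det,
        "r_min": r_min,
        "acceptable_fraction": acceptable_fraction(grid, theta_det, r_min),
    }


def plot_sweep(grid: SweepGrid, path, theta_det: float = THETA_DET,
               r_min: float = R_MIN) -> None:
    """Render the three surfaces and the acceptability mask as heatmaps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(16, 3.6), constrained_layout=True)
    extent = [np.log10(grid.y_values[0]), np.log10(grid.y_values[-1]),
              np.log10(grid.x_values[0]), np.log10(grid.x_values[-1])]
    panels = [
        ("Mitfa steady state (nM)", grid.M_ss, "viridis"),
        ("Sox10 steady state (nM)", grid.S_ss, "magma"),
        ("Sox10 maximum (nM)", grid.S_max, "cividis"),
        ("criteria met", grid.mask(theta_det, r_min).astype(float), "Greys"),
    ]
    for ax, (title, surf, cmap) in zip(axes, panels):
        im = ax.imshow(surf, origin="lower", aspect="auto", extent=extent,
                       cmap=cmap)
        ax.set_title(f"{grid.variant}: {title}", fontsize=9)
        ax.set_xlabel(f"log10 {grid.param_y}")
        ax.set_ylabel(f"log10 {grid.param_x}")
        fig.colorbar(im, ax=ax, shrink=0.85)
    fig.savefig(path, dpi=130)
    plt.close(fig)
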