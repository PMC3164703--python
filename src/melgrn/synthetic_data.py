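"""Synthetic experimental observations with the structure of the assays.

Two readout types are emulated so the observation-comparison layer is
testable without any external data:

* per-embryo cell scoring of detectable expression -- 20 pigmented cells
  from each of 5 embryos per time point, each cell counted positive when
  its (noisy) expression level reaches the in-situ detection threshold;
* qPCR-style fold-change readouts -- replicate measurements of a mutant
  genotype's transcript level as a percentage of wild type, with
  multiplicative (log-normal) noise.

The mapping from model concentration (nM) to "detectable" is an invented
observation model: each cell draws an independent log-normal multiplier
with median 1 and a given coefficient of variation, and is positive when
the multiplied concentration reaches ``theta_det``.  Counts are therefore
binomial with a probability set by the log-normal tail.  Only the
qualitative consequences of this model (detection fractions near 1 where
the trajectory is far above threshold, near 0 far below, and the
monotone-decline shape of the wild-type Sox10 series) are asserted
anywhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .core import SPECIES
from .dynamics import Trajectory, integrate
from .reference import THETA_DET, reference_parameters
from .scenarios import PanelResult, run_panel

__all__ = [
    "CellScoringSeries",
    "DEFAULT_SCORING_TIMES",
    "score_cells",
    "qpcr_foldchange",
    "make_fixture",
    "read_fixture",
]

#: Default scored times (hpf), bracketing the window in which wild-type
#: melanocytes go from all-positive to none for Sox10.
DEFAULT_SCORING_TIMES: Tuple[float, ...] = (30, 33, 36, 39, 42, 45, 48, 51)

#: Default per-cell noise (coefficient of variation of the log-normal
#: detection multiplier) and qPCR replicate noise (sigma on the log scale).
DEFAULT_CELL_CV = 0.3
DEFAULT_QPCR_CV = 0.25


@dataclass(frozen=True)
class CellScoringSeries:
    """Counts of expression-positive cells per scored time point."""

    species: str
    times: np.ndarray           # hpf
    counts: np.ndarray          # positive cells out of n_fish * cells_per_fish
    n_fish: int
    cells_per_fish: int
    theta_det: float
    cv: float
    seed: int

    @property
    def n_cells(self) -> int:
        return self.n_fish * self.cells_per_fish

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species,
            "time_hpf": self.times,
            "positive": self.counts,
            "n_cells": self.n_cells,
            "fraction": self.fractions,
        })


def score_cells(traj: Trajectory, species: str = "S",
                times: Sequence[float] = DEFAULT_SCORING_TIMES,
                n_fish: int = 5, cells_per_fish: int = 20,
                theta_det: float = THETA_DET, cv: float = DEFAULT_CELL_CV,
                seed: int = 0) -> CellScoringSeries:
    """Score detectable expression in individual cells along a trajectory.

    Each of the ``n_fish * cells_per_fish`` cells at each time draws an
    independent log-normal multiplier ``m`` with median 1 and coefficient
    of variation ``cv``; the cell is positive iff ``m * x(t) >= theta_det``.
    Deterministic for a given seed and configuration.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < traj.times[0]) or np.any(times > traj.times[-1]):
        raise ValueError("scored times must lie within the trajectory range")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    x = traj.at(species, times)
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    n_cells = n_fish * cells_per_fish
    counts = np.empty(len(times), dtype=int)
    for i, xi in enumerate(x):
        m = np.exp(rng.normal(0.0, sigma, size=n_cells)) if sigma > 0 \
            else np.ones(n_cells)
        counts[i] = int(np.count_nonzero(m * xi >= theta_det))
    return CellScoringSeries(species=species, times=times, counts=counts,
                             n_fish=n_fish, cells_per_fish=cells_per_fish,
                             theta_det=theta_det, cv=cv, seed=seed)


def qpcr_foldchange(panel: PanelResult, gene: str, time: float,
                    n_reps: int = 3, cv: float = DEFAULT_QPCR_CV,
                    seed: int = 0) -> pd.DataFrame:
    """Replicate percent-of-wild-type readouts for one gene and time point.

    ``gene`` is one of the transcript readouts M (*mitfa*), D (the
    *dct*-class genes) or T (*tyrp1b*).  Each replicate is
    ``100 * x_genotype(t) / x_WT(t) * exp(N(0, cv))`` with ``cv`` the
    log-scale noise; wild-type replicates therefore centre on 100%.
    """
    if gene not in ("M", "D", "T"):
        raise ValueError("gene must be one of M, D, T")
    if gene not in SPECIES:  # pragma: no cover - guarded above
        raise ValueError(f"unknown species {gene}")
    x_wt = float(panel.trajectories["WT"].at(gene, time))
    if x_wt == 0.0:
        raise ZeroDivisionError(
            f"wild-type {gene} is zero at t={time} hpf; fold change undefined")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, traj in panel.trajectories.items():
        ratio = 100.0 * float(traj.at(gene, time)) / x_wt
        noise = np.exp(rng.normal(0.0, cv, size=n_reps)) if cv > 0 \
            else np.ones(n_reps)
        for r, pct in enumerate(ratio * noise):
            rows.append({"gene": gene, "genotype": genotype,
                         "time_hpf": float(time), "replicate": r,
                         "percent_of_wt": float(pct)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

_FIXTURE_VERSION = 1
_CSV_KW = dict(index=False, float_format="%.10g", lineterminator="\n")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def make_fixture(seed: int, out_dir, dt: float = 0.02,
                 qpcr_times: Sequence[float] = (30.0, 36.0, 72.0)) -> dict:
    """Write a versioned synthetic-observation bundle for the test suite.

    Contains a wild-type cell-scoring series for Sox10 and Mitfa and a
    mutant-panel fold-change table for *mitfa*, the *dct* class and
    *tyrp1b* at the qPCR assay times, with a JSON manifest recording the
    seed and a configuration hash.  Byte-identical for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = reference_parameters()
    panel = run_panel("C", params, dt=dt)
    cells = pd.concat([
        score_cells(panel.trajectories["WT"], species=sp, seed=seed).to_frame()
        for sp in ("S", "M")
    ], ignore_index=True)
    fold = pd.concat([
        qpcr_foldchange(panel, gene, t, seed=seed)
        for gene in ("M", "D", "T") for t in qpcr_times
    ], ignore_index=True)
    config = {
        "version": _FIXTURE_VERSION,
        "seed": int(seed),
        "dt": dt,
        "qpcr_times": [float(t) for t in qpcr_times],
        "scoring_times": [float(t) for t in DEFAULT_SCORING_TIMES],
        "cell_cv": DEFAULT_CELL_CV,
        "qpcr_cv": DEFAULT_QPCR_CV,
        "params": params.to_dict(),
    }
    manifest = {"config": config, "config_sha256": _config_hash(config),
                "files": ["cell_scoring.csv", "fold_change.csv"]}
    cells.to_csv(out / "cell_scoring.csv", **_CSV_KW)
    fold.to_csv(out / "fold_change.csv", **_CSV_KW)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_fixture(in_dir) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Load a fixture bundle back (cell scoring, fold change, manifest)."""
    path = Path(in_dir)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    cells = pd.read_csv(path / "cell_scoring.csv")
    fold = pd.read_csv(path / "fold_change.csv")
    return cells, fold, manifest
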