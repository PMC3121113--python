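"""Synthetic datasets emulating the study's wet-lab measurements.

Two assay types are mimicked, each generated from the model itself with a
standard noise model:

* densitometry-style immunoblot series — pro-caspase levels normalized to
  t = 0 with multiplicative log-normal noise of a given coefficient of
  variation (the usual minimal model for blot quantification);
* flow-cytometry apoptotic fractions — binomial counts of apoptotic cells
  out of n_cells at each time or dose.

Every generator takes an explicit seed and regenerates identically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dde import IntegratorOptions, Trajectory, integrate_protocol
from .errors import InvalidArgumentError
from .params import FateParameters, KineticParameters
from .population import PopulationTrajectory, simulate_population
from .protocol import StimulusProtocol

__all__ = [
    "SyntheticDataset",
    "generate_immunoblot_series",
    "generate_flow_cytometry_counts",
    "generate_dose_response",
]


@dataclass(frozen=True)
class SyntheticDataset:
    """One synthetic measurement series.

    ``kind`` is "immunoblot", "flow_cytometry" or "dose_response";
    ``x`` holds times (s) or doses (nM); ``values`` holds relative
    densitometry or apoptotic counts; ``n_cells`` is set for count data.
    """

    kind: str
    x: np.ndarray
    values: np.ndarray
    noise: str
    seed: int
    n_cells: int | None = None
    expected: np.ndarray | None = None   # noise-free model values

    def to_frame(self):
        import pandas as pd

        if self.kind == "immunoblot":
            return pd.DataFrame({"time_s": self.x, "relative_level": self.values})
        xcol = "tnf_nM" if self.kind == "dose_response" else "time_s"
        return pd.DataFrame({
            xcol: self.x,
            "apoptotic_count": self.values.astype(int),
            "n_cells": np.full(self.x.shape, self.n_cells, dtype=int),
        })

    @property
    def f_a(self) -> np.ndarray:
        """Observed apoptotic fraction for count data."""
        if self.n_cells is None:
            raise InvalidArgumentError("f_a is defined only for count datasets")
        return self.values / self.n_cells


def generate_immunoblot_series(
    trajectory: Trajectory,
    times: np.ndarray,
    noise_cv: float = 0.1,
    seed: int = 0,
    species: str = "pro_c8",
) -> SyntheticDataset:
    """Relative pro-caspase time course with multiplicative log-normal noise.

    Values are normalized to the t = 0 level, as densitometry series are;
    sigma of the underlying normal is chosen so the multiplicative noise
    has coefficient of variation ``noise_cv`` (cv^2 = exp(sigma^2) - 1).
    """
    if noise_cv < 0:
        raise InvalidArgumentError("noise_cv must be >= 0")
    times = np.asarray(times, dtype=float)
    levels = np.asarray(trajectory.component(species, times), dtype=float)
    ref = float(trajectory.component(species, 0.0))
    expected = levels / ref
    rng = np.random.default_rng(seed)
    if noise_cv == 0.0:
        values = expected.copy()
    else:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        # mean-one log-normal multiplier
        values = expected * rng.lognormal(-0.5 * sigma**2, sigma, size=expected.shape)
    return SyntheticDataset("immunoblot", times, values,
                            f"lognormal(cv={noise_cv})", seed, expected=expected)


def generate_flow_cytometry_counts(
    pop_traj: PopulationTrajectory,
    times: np.ndarray,
    n_cells: int = 10_000,
    seed: int = 0,
) -> SyntheticDataset:
    """Binomial apoptotic counts out of ``n_cells`` at each sampling time."""
    if n_cells < 1:
        raise InvalidArgumentError("n_cells must be >= 1")
    times = np.asarray(times, dtype=float)
    fa = np.interp(times, pop_traj.times, pop_traj.f_a)
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_cells, np.clip(fa, 0.0, 1.0))
    return SyntheticDataset("flow_cytometry", times, counts.astype(float),
                            f"binomial(n={n_cells})", seed, n_cells=n_cells,
                            expected=fa)


def generate_dose_response(
    params: KineticParameters | None = None,
    fate: FateParameters | None = None,
    doses: np.ndarray | None = None,
    t_assay: float = 16 * 3600.0,
    seed: int = 0,
    n_cells: int = 10_000,
    options: IntegratorOptions | None = None,
) -> SyntheticDataset:
    """Apoptotic counts after ``t_assay`` of incubation at each dose."""
    if t_assay <= 0:
        raise InvalidArgumentError("t_assay must be > 0")
    params = params or KineticParameters()
    fate = fate or FateParameters()
    doses = np.asarray(
        doses if doses is not None else np.concatenate([[0.0], np.geomspace(0.01, 10.0, 9)]),
        dtype=float,
    )
    if np.any(doses < 0):
        raise InvalidArgumentError("doses must be >= 0")
    fa = np.empty(doses.shape)
    for i, d in enumerate(doses):
        if d == 0.0:
            fa[i] = 1.0 - np.exp(-fate.r_0 * t_assay)
        else:
            traj = integrate_protocol(params, StimulusProtocol.constant(d, t_assay), t_assay, options)
            pop = simulate_population(traj, fate, S0=1.0)
            fa[i] = float(np.interp(t_assay, pop.times, pop.f_a))
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_cells, np.clip(fa, 0.0, 1.0))
    return SyntheticDataset("dose_response", doses, counts.astype(float),
                            f"binomial(n={n_cells})", seed, n_cells=n_cells,
                            expected=fa)
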