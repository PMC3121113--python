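"""Delay-differential integration by the method of steps.

The caspase-8 signal feeding the mitochondrial arm is read at t - tau_mito.
The integration interval is cut at every multiple of the delay and at every
protocol discontinuity; on each resulting chunk the delayed term is a known,
continuous function of time (evaluated from the dense output of the chunks
already computed), so the chunk itself is an ordinary ODE solved with a
stiffness-switching integrator.  History before t = 0 is the constant
pre-stimulus value of active caspase-8 (zero when starting from rest).

Protocol steps restart the integrator rather than being smoothed, so step
protocols are reproduced exactly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .errors import InvalidArgumentError, LogicError, NumericalFailureError
from .model import STATE_FIELDS, SystemState, pre_stimulus_steady_state, system_rhs
from .params import KineticParameters
from .protocol import StimulusProtocol

__all__ = ["IntegratorOptions", "Trajectory", "integrate_protocol", "run_figure3", "run_figure4"]

_ACT_C8 = STATE_FIELDS.index("act_c8")


@dataclass(frozen=True)
class IntegratorOptions:
    rtol: float = 1e-8
    atol: float = 1e-10          # nM
    method: str = "LSODA"
    max_chunk: float = np.inf    # extra cap on chunk length (s), mostly for tau_mito = 0
    n_dense: int = 2000          # default sampling grid size for summaries


class Trajectory:
    """Dense solution of one protocol run.

    Piecewise collection of solver dense outputs with continuous evaluation
    of every component and of the delayed caspase-8 history (zero, or the
    constant initial value, before t = 0).
    """

    def __init__(
        self,
        params: KineticParameters,
        protocol: StimulusProtocol,
        history_act_c8: float = 0.0,
    ) -> None:
        self.params = params
        self.protocol = protocol
        self.history_act_c8 = float(history_act_c8)
        self._segments: list = []        # scipy OdeSolution objects
        self._ends: list[float] = []     # right endpoint of each segment
        self.t_end = 0.0

    # -- construction -----------------------------------------------------
    def _append(self, sol) -> None:
        self._segments.append(sol)
        self._ends.append(sol.t_max)
        self.t_end = sol.t_max

    # -- evaluation -------------------------------------------------------
    def __call__(self, t):
        """State matrix (5, len(t)) or vector (5,) at time(s) t in [0, t_end]."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((len(STATE_FIELDS), t_arr.size))
        for j, tj in enumerate(t_arr):
            out[:, j] = self._eval_one(tj)
        return out[:, 0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def _eval_one(self, t: float) -> np.ndarray:
        if t < -1e-12 or t > self.t_end * (1 + 1e-12) + 1e-12:
            raise LogicError(f"query at t={t} outside computed span [0, {self.t_end}]")
        t = min(max(t, 0.0), self.t_end)
        if not self._segments:
            raise LogicError("empty trajectory")
        i = bisect.bisect_left(self._ends, t)
        i = min(i, len(self._segments) - 1)
        return self._segments[i](t)

    def state_at(self, t: float) -> SystemState:
        return SystemState.from_array(self._eval_one(t))

    def evaluate_delayed(self, t: float) -> float:
        """Active caspase-8 at t - tau_mito; constant history before t = 0."""
        td = t - self.params.tau_mito
        if td <= 0.0:
            return self.history_act_c8
        # Slack of 1e-3 s absorbs provisional solver evaluations marginally
        # past the current chunk edge.
        if td > self.t_end + 1e-3:
            raise LogicError(f"delayed query at {td} beyond computed history {self.t_end}")
        return max(float(self._eval_one(min(td, self.t_end))[_ACT_C8]), 0.0)

    def act_c8(self, t):
        return self.component("act_c8", t)

    def grid(self, n: int | None = None) -> np.ndarray:
        n = n or 2000
        return np.linspace(0.0, self.t_end, n)

    def component(self, name: str, t) -> np.ndarray:
        return self.__call__(t)[STATE_FIELDS.index(name)]

    def peak(self, name: str) -> tuple[float, float]:
        """(t_peak, value) of a component, refined on the dense interpolant.

        A coarse scan brackets the maximum, then bounded scalar
        minimization on the continuous dense output localizes it; this is
        grid-independent to solver tolerance.
        """
        idx = STATE_FIELDS.index(name)
        ts = self.grid(4000)
        vals = self.__call__(ts)[idx]
        i = int(np.argmax(vals))
        lo = ts[max(i - 1, 0)]
        hi = ts[min(i + 1, len(ts) - 1)]
        if lo == hi:
            return float(ts[i]), float(vals[i])
        res = minimize_scalar(
            lambda t: -float(self._eval_one(t)[idx]),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-3},
        )
        t_peak = float(res.x)
        return t_peak, float(self._eval_one(t_peak)[idx])

    def to_frame(self, n: int | None = None):
        """Sampled trajectory as a pandas DataFrame with the canonical schema."""
        import pandas as pd

        ts = self.grid(n)
        y = self.__call__(ts)
        return pd.DataFrame({
            "time_s": ts,
            **{f"{name}_nM": y[i] for i, name in enumerate(STATE_FIELDS)},
        })


def _chunk_edges(t_end: float, tau: float, protocol: StimulusProtocol, max_chunk: float) -> np.ndarray:
    """Breakpoints: multiples of the delay, protocol steps, and the cap."""
    edges = {0.0, t_end}
    step = tau if tau > 0 else np.inf
    step = min(step, max_chunk)
    if np.isfinite(step):
        edges.update(np.arange(step, t_end, step))
    edges.update(protocol.breakpoints(t_end))
    return np.array(sorted(edges))


def integrate_protocol(
    params: KineticParameters,
    protocol: StimulusProtocol,
    t_end: float,
    options: IntegratorOptions | None = None,
    y0: SystemState | None = None,
) -> Trajectory:
    """Integrate the delayed system over [0, t_end] under a step protocol.

    ``y0`` defaults to the pre-stimulus steady state; a custom initial state
    implies a constant pre-onset history equal to its active caspase-8
    level.
    """
    if t_end <= 0:
        raise InvalidArgumentError("t_end must be > 0")
    options = options or IntegratorOptions()
    protocol = protocol.extended(t_end)
    if y0 is None:
        y0 = pre_stimulus_steady_state(params)

    traj = Trajectory(params, protocol, history_act_c8=y0.act_c8)
    # delays below a millisecond are orders of magnitude under every system
    # timescale (fastest rate ~1e-2/s): treat as undelayed instead of
    # generating astronomically many method-of-steps chunks
    tau = params.tau_mito if params.tau_mito >= 1e-3 else 0.0
    edges = _chunk_edges(t_end, tau, protocol, options.max_chunk)
    y = y0.as_array()
    for a, b in zip(edges[:-1], edges[1:]):
        tnf = protocol.tnf_at(0.5 * (a + b))

        if tau == 0.0:
            def rhs(t, yy):
                return system_rhs(t, yy, yy[_ACT_C8], tnf, params)
        else:
            def rhs(t, yy):
                return system_rhs(t, yy, traj.evaluate_delayed(t), tnf, params)

        sol = solve_ivp(
            rhs, (a, b), y, method=options.method,
            rtol=options.rtol, atol=options.atol, dense_output=True,
        )
        if not sol.success:
            raise NumericalFailureError(
                f"integration failed in chunk [{a}, {b}]: {sol.message}",
                t_failure=float(sol.t[-1]),
            )
        traj._append(sol.sol)
        y = sol.y[:, -1]
    return traj


# ---------------------------------------------------------------------------
# Reference scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSummary:
    """Peak metrics of one constant-stimulus run.

    ``peak_act_c8_fraction`` is the fraction of the resting pro-caspase-8
    pool converted into the active form at the peak, counted in monomer
    equivalents (each active dimer consumes two zymogens, hence the factor
    2); caspase-3 activates 1:1 so its fraction is a plain ratio.
    """

    peak_act_c8: float            # nM dimer
    peak_act_c3: float            # nM
    t_peak_c8: float              # s
    t_peak_c3: float              # s
    peak_act_c8_fraction: float   # converted fraction of resting pro-caspase-8 pool
    peak_act_c3_fraction: float   # fraction of resting pro-caspase-3 pool

    @property
    def peak_lag(self) -> float:
        """Caspase-3 peak delay after the caspase-8 peak (s)."""
        return self.t_peak_c3 - self.t_peak_c8


def summarize_pulse(traj: Trajectory) -> PulseSummary:
    rest = pre_stimulus_steady_state(traj.params)
    t8, a8 = traj.peak("act_c8")
    t3, a3 = traj.peak("act_c3")
    return PulseSummary(
        peak_act_c8=a8, peak_act_c3=a3, t_peak_c8=t8, t_peak_c3=t3,
        peak_act_c8_fraction=2.0 * a8 / rest.pro_c8,
        peak_act_c3_fraction=a3 / rest.pro_c3,
    )


def run_figure3(
    params: KineticParameters | None = None,
    options: IntegratorOptions | None = None,
) -> tuple[Trajectory, PulseSummary]:
    """Sustained 2.0 nM ligand for 10 h (the 100 ng/ml FasL surrogate).

    Returns the trajectory and its pulse summary: with default parameters
    active caspase-8 peaks near 2.8 % of the resting pro-caspase-8 pool at
    about 2 h, and active caspase-3 peaks near 40 % of the pro-caspase-3
    pool roughly half an hour later.
    """
    params = params or KineticParameters()
    traj = integrate_protocol(params, StimulusProtocol.constant(2.0, 10 * 3600.0), 10 * 3600.0, options)
    return traj, summarize_pulse(traj)


def run_figure4(
    params: KineticParameters | None = None,
    options: IntegratorOptions | None = None,
    low_dose: float = 0.1,
) -> tuple[Trajectory, Trajectory]:
    """Pre-exposure scenario: 10 h at a low dose, then 20 h at 2.0 nM.

    Returns (two-step trajectory, naive 2.0 nM trajectory over 30 h).  The
    weak first phase quietly consumes pro-caspase-3, so the second-phase
    caspase-3 pulse is blunted relative to naive strong stimulation.
    """
    params = params or KineticParameters()
    two_step = StimulusProtocol.from_steps([(10 * 3600.0, low_dose), (20 * 3600.0, 2.0)])
    naive = StimulusProtocol.constant(2.0, 30 * 3600.0)
    return (
        integrate_protocol(params, two_step, 30 * 3600.0, options),
        integrate_protocol(params, naive, 30 * 3600.0, options),
    )
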