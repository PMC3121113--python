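"""Kinetic and cell-fate parameter sets.

Internal units are seconds and nM throughout.  The defaults reproduce the
published rate constants of the five-species TNF-receptor / caspase-8 /
caspase-3 trigger model: ligand-receptor binding, DISC-mediated caspase-8
activation, direct (type I) and mitochondria-amplified (type II) caspase-3
cleavage, constant zeroth-order synthesis and first-order degradation of the
pro-forms, and rapid first-order degradation of both active caspases.

The active-caspase-8 degradation rate ``d_c8a`` is the one constant not fixed
by the published table.  Its default is produced by
:func:`caspulse.calibration.calibrate_active_c8_degradation`, which pins the
peak active-caspase-8 level at 2.8 % of the resting pro-caspase-8 pool under
a sustained 2.0 nM stimulus, inside the admissible band of 100-1000 times the
pro-form degradation rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

from .errors import InvalidArgumentError

__all__ = ["KineticParameters", "FateParameters", "RAPID_DEGRADATION_BAND"]

#: Admissible ratio of active-form to pro-form degradation rate ("2-3 orders
#: of magnitude faster").  Outside this band a warning is emitted.
RAPID_DEGRADATION_BAND = (1e2, 1e3)

# Calibrated so that the 2.0 nM / 10 h reference simulation peaks at 2.8 % of
# the resting pro-caspase-8 pool (see calibration module); lies inside the
# rapid-degradation band [100, 1000] x d_c8.
_D_C8A_CALIBRATED = 3.411873e-3


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the signaling model (units: s, nM).

    Attributes
    ----------
    k_on, k_off:
        Ligand-receptor association (nM^-1 s^-1) and dissociation (s^-1)
        rates; K0 = k_on/k_off is the binding constant.
    tnfr_total:
        Total receptor concentration [TNF-R]_0 (nM); caps both bound
        receptor and the number of DISCs.
    v1, K1, K2:
        Maximal DISC-mediated caspase-8 activation rate (s^-1) and the two
        quasi-equilibrium pro-caspase-8 binding constants (nM) of the
        doubly-loaded DISC.
    v2:
        Mass-action rate constant for direct cleavage of pro-caspase-3 by
        active caspase-8 (nM^-1 s^-1), the type-I arm.
    v3, K3, casp9_total, tau_mito:
        Type-II arm: first-order cleavage rate of pro-caspase-3 (s^-1)
        gated by the Michaelis-Menten caspase-9 activation fraction
        x/(K3+x) of the delayed caspase-8 signal; tau_mito (s) is the lag
        of the mitochondrial relay; casp9_total (nM) scales reported
        active caspase-9 but cancels from the flux.
    v_syn_c8, v_syn_c3, d_c8, d_c3:
        Zeroth-order synthesis (nM s^-1) and first-order degradation
        (s^-1) of the pro-caspases; their ratio sets the resting pools.
    d_c8a, d_c3a:
        Rapid degradation rates of the active caspases (s^-1); the model's
        key ingredient, responsible for pulse-shaped (rather than
        switch-like) activation.
    """

    k_on: float = 9.09e-5
    k_off: float = 1.00e-4
    tnfr_total: float = 10.0
    v1: float = 2.65e-3
    K1: float = 50.0
    K2: float = 50.0
    v2: float = 6.00e-5
    v3: float = 2.60e-4
    K3: float = 8.0
    casp9_total: float = 20.0
    tau_mito: float = 1800.0
    v_syn_c8: float = 6.67e-4
    v_syn_c3: float = 4.00e-5
    d_c8: float = 2.00e-5
    d_c3: float = 2.00e-7
    d_c8a: float = _D_C8A_CALIBRATED
    d_c3a: float = 2.40e-4

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise InvalidArgumentError(f"{f.name} must be finite, got {value!r}")
            if f.name == "tau_mito":
                if value < 0:
                    raise InvalidArgumentError(f"tau_mito must be >= 0, got {value!r}")
            elif value <= 0:
                raise InvalidArgumentError(f"{f.name} must be > 0, got {value!r}")
        lo, hi = RAPID_DEGRADATION_BAND
        # 0.15 dex slack: "2-3 orders of magnitude" is a rounded statement and
        # the published defaults themselves sit at d_c3a/d_c3 = 1200.
        slack = 10 ** 0.15
        for act, pro, name in ((self.d_c8a, self.d_c8, "d_c8a/d_c8"),
                               (self.d_c3a, self.d_c3, "d_c3a/d_c3")):
            ratio = act / pro
            if not lo / slack <= ratio <= hi * slack:
                warnings.warn(
                    f"{name} = {ratio:.3g} lies outside the rapid-degradation "
                    f"band [{lo:g}, {hi:g}]; active-form turnover is assumed "
                    "2-3 orders faster than pro-form turnover",
                    stacklevel=3,
                )

    @property
    def K0(self) -> float:
        """Ligand-receptor binding constant k_on/k_off (nM^-1)."""
        return self.k_on / self.k_off

    def with_overrides(self, **overrides: float) -> "KineticParameters":
        """Return a copy with the named rate constants replaced."""
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise InvalidArgumentError(f"unknown kinetic parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)


@dataclass(frozen=True)
class FateParameters:
    """Parameters mapping caspase-3 activity to the cell apoptosis rate.

    The apoptosis rate is r_0 plus a gain ``p_rate`` times the integral of a
    Hill function of caspase-3 activity over a sliding window of length
    ``tau_d`` (the effective time of caspase-3).  Defaults are the values
    fitted to Jurkat-cell TRAIL kinetics.
    """

    r_0: float = 3.31e-6        # basal apoptosis rate, s^-1
    p_rate: float = 1.05e-8     # rate gain multiplying the windowed Hill integral
    K4: float = 55.0            # caspase-3 activity threshold, nM
    hill_n: float = 4.0         # Hill coefficient
    tau_d: float = 11 * 3600.0  # effective time window of caspase-3, s
    r_pro: float = 0.0          # proliferation rate, s^-1

    def __post_init__(self) -> None:
        for name in ("r_0", "p_rate", "K4", "tau_d"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.hill_n < 1:
            raise InvalidArgumentError("hill_n must be >= 1")
        if self.r_pro < 0:
            raise InvalidArgumentError("r_pro must be >= 0")

    def with_overrides(self, **overrides: float) -> "FateParameters":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise InvalidArgumentError(f"unknown fate parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)
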