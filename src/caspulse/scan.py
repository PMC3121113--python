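"""Monte-Carlo parameter sweeps of activation efficiencies vs EC and RC.

Reproduces the trade-off experiment: activation parameters are drawn
log-uniformly, and for each draw the activation efficiencies (A_Casp8,
A_Casp3) and the population-level effective and resistance coefficients are
computed.  Two canonical panels mirror the published sweep: a caspase-8
panel varying {v1, d_c8a, K1 = K2} and a caspase-3 panel varying
{v2, v3, d_c3a, K3}.  The headline result is the effectiveness/resistance
compromise: EC and RC are negatively rank-correlated across the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dde import IntegratorOptions
from .errors import CaspulseError, InvalidArgumentError
from .params import FateParameters, KineticParameters
from .population import effective_coefficient, resistance_coefficient
from .sensitivity import activation_efficiency_c3, activation_efficiency_c8

__all__ = [
    "PANEL_RANGES",
    "ScanRecord",
    "sample_log_uniform",
    "scan_coefficients",
    "trend_summary",
    "run_panel",
]

#: Sweep ranges per panel.  The caspase-8 panel ties K2 to K1 ("K1 (= K2)");
#: its garbled printed upper bound for v1/d_c8a is taken as 1e-2 mirroring
#: the intact caspase-3 panel range.
PANEL_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "casp8": {"v1": (1e-5, 1e-2), "d_c8a": (1e-5, 1e-2), "K1": (10.0, 1000.0)},
    "casp3": {"v2": (1e-5, 1e-2), "v3": (1e-5, 1e-2), "d_c3a": (1e-5, 1e-2),
              "K3": (1.0, 100.0)},
}

#: Sweeps run many weak-pulse simulations; a slightly relaxed tolerance is
#: ample for rank statistics while keeping the panel affordable.
_SCAN_OPTIONS = IntegratorOptions(rtol=1e-6, atol=1e-9)


@dataclass(frozen=True)
class ScanRecord:
    overrides: dict[str, float]
    A_c8: float = np.nan
    A_c3: float = np.nan
    EC: float = np.nan
    RC: float = np.nan
    status: str = "converged"   # "converged" | "failed"


def sample_log_uniform(
    ranges: dict[str, tuple[float, float]],
    n: int,
    seed: int,
) -> list[dict[str, float]]:
    """n independent draws, each coordinate log-uniform within its range."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    for name, (lo, hi) in ranges.items():
        if not 0 < lo < hi:
            raise InvalidArgumentError(f"invalid range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    names = list(ranges)
    draws = {
        name: np.exp(rng.uniform(np.log(ranges[name][0]), np.log(ranges[name][1]), n))
        for name in names
    }
    return [{name: float(draws[name][i]) for name in names} for i in range(n)]


def _apply(base: KineticParameters, overrides: dict[str, float]) -> KineticParameters:
    eff = dict(overrides)
    if "K1" in eff and "K2" not in eff:
        eff["K2"] = eff["K1"]   # the caspase-8 panel ties the two DISC constants
    return base.with_overrides(**eff)


def scan_coefficients(
    base_params: KineticParameters,
    base_fate: FateParameters,
    overrides_list: list[dict[str, float]],
    tnf_ref: float = 2.0,
    fd_step: float = 1e-3,
    options: IntegratorOptions | None = None,
) -> list[ScanRecord]:
    """Efficiencies and EC/RC for each override set; failures are recorded.

    Each record is computed independently from the base parameters, so the
    result does not depend on execution order.
    """
    import warnings

    options = options or _SCAN_OPTIONS
    records: list[ScanRecord] = []
    for overrides in overrides_list:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # off-band degradation ratios are expected here
                params = _apply(base_params, overrides)
                rec = ScanRecord(
                    overrides=dict(overrides),
                    A_c8=activation_efficiency_c8(params),
                    A_c3=activation_efficiency_c3(params),
                    EC=effective_coefficient(params, base_fate, tnf_ref, options),
                    RC=resistance_coefficient(params, base_fate, fd_step, options),
                )
        except CaspulseError:
            rec = ScanRecord(overrides=dict(overrides), status="failed")
        records.append(rec)
    return records


def run_panel(
    panel: str,
    n: int = 500,
    seed: int = 42,
    base_params: KineticParameters | None = None,
    base_fate: FateParameters | None = None,
    options: IntegratorOptions | None = None,
) -> list[ScanRecord]:
    """Sample and scan one canonical panel ("casp8" or "casp3")."""
    if panel not in PANEL_RANGES:
        raise InvalidArgumentError(f"unknown panel {panel!r}; choose from {sorted(PANEL_RANGES)}")
    overrides = sample_log_uniform(PANEL_RANGES[panel], n, seed)
    return scan_coefficients(base_params or KineticParameters(),
                             base_fate or FateParameters(), overrides,
                             options=options)


def trend_summary(
    records: list[ScanRecord],
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
):
    """Spearman correlations of EC and RC against the efficiencies and each other.

    Returns a DataFrame with rho and a seeded bootstrap confidence
    interval per pair.  Requires >= 10 converged records.
    """
    import pandas as pd

    ok = [r for r in records if r.status == "converged" and np.isfinite(r.EC) and np.isfinite(r.RC)]
    if len(ok) < 10:
        raise InvalidArgumentError(f"need >= 10 converged records, got {len(ok)}")
    cols = {
        "A_c8": np.array([r.A_c8 for r in ok]),
        "A_c3": np.array([r.A_c3 for r in ok]),
        "EC": np.array([r.EC for r in ok]),
        "RC": np.array([r.RC for r in ok]),
    }
    pairs = [("EC", "A_c8"), ("EC", "A_c3"), ("RC", "A_c8"), ("RC", "A_c3"), ("EC", "RC")]
    rng = np.random.default_rng(seed)
    rows = []
    m = len(ok)
    alpha = (1.0 - ci_level) / 2.0
    for a, b in pairs:
        x, y = cols[a], cols[b]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho, lo, hi = 0.0, 0.0, 0.0
        else:
            rho = float(stats.spearmanr(x, y).statistic)
            boots = np.empty(n_boot)
            for i in range(n_boot):
                idx = rng.integers(0, m, m)
                if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
                    boots[i] = 0.0
                else:
                    boots[i] = stats.spearmanr(x[idx], y[idx]).statistic
            lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        rows.append({"pair": f"{a}~{b}", "rho": rho,
                     "ci_low": float(lo), "ci_high": float(hi), "n": m})
    return pd.DataFrame(rows)


def records_to_frame(records: list[ScanRecord]):
    """Flatten scan records into a DataFrame (one row per draw)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {f"param_{k}": v for k, v in r.overrides.items()}
        row.update(A_c8=r.A_c8, A_c3=r.A_c3, EC=r.EC, RC=r.RC, status=r.status)
        rows.append(row)
    return pd.DataFrame(rows)
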