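"""Stimulation protocols: equilibration, ATP steps, knockouts.

Every simulation first equilibrates the cell for 2000 s in the absence of
ATP (basal IP₃ = 0), then applies an instantaneous, sustained ATP step at
t = 0 and records the state and all six Ca²⁺ fluxes on a uniform grid.
Knockout variants zero the corresponding flux (J_IP3R for the P2Y2 knockout,
J_P2X7 for the P2X7 knockout) without touching upstream signaling.  The
P2X7 receptor pool can start entirely naive (C1) or entirely sensitized
(C4); both are exact Markov rest states at zero ATP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import core
from .core import ModelState, compute_fluxes, pump_flux, rhs_function
from .params import ModelParameters

__all__ = ["Protocol", "SimulationResult", "equilibrate", "run_protocol",
           "EquilibrationError", "SolverError"]

MARKOV_INITS = ("naive_C1", "sensitized_C4")

#: columns of the long-format CSV export
_FLUX_NAMES = ("j_inleak", "j_p2x7", "j_pmca", "j_ip3r", "j_erleak", "j_serca")
_STATE_NAMES = ("ca_i", "ca_er", "ip3", "h") + core.MARKOV_STATES


class EquilibrationError(RuntimeError):
    """Equilibration did not reach a fixed point within tolerance."""


class SolverError(RuntimeError):
    """Stiff integration failed; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Protocol:
    """One stimulation protocol.

    ``atp`` is the applied concentration in molar, held constant from t = 0.
    """

    atp: float
    duration: float = 120.0
    knockout: str = "none"
    initial_markov: str = "naive_C1"
    equilibrate: float = 2000.0
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dt: float = 0.1
    #: max solver step during the first seconds after the step, to resolve
    #: the sub-second P2X7 transients that set the flux-AUC diagnostics
    fast_window: float = 10.0
    fast_max_step: float = 0.05

    def __post_init__(self) -> None:
        if self.atp < 0:
            raise ValueError("atp must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        core._check_knockout(self.knockout)
        if self.initial_markov not in MARKOV_INITS:
            raise ValueError(
                f"initial_markov must be one of {MARKOV_INITS}"
            )


@dataclass
class SimulationResult:
    """Trajectory, flux time-courses and diagnostics for one protocol."""

    time: np.ndarray
    states: np.ndarray           # (n_times, 16)
    fluxes: pd.DataFrame         # columns _FLUX_NAMES
    protocol: Protocol
    resting_state: ModelState
    n_rhs_evaluations: int = 0

    def state_at(self, index: int) -> ModelState:
        return ModelState.from_array(self.states[index])

    @property
    def ca_i(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def ca_er(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def ip3(self) -> np.ndarray:
        return self.states[:, 2]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: time + 16 state columns + 6 flux columns."""
        df = pd.DataFrame(self.states, columns=_STATE_NAMES)
        df.insert(0, "time", self.time)
        return pd.concat([df, self.fluxes.reset_index(drop=True)], axis=1)

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV (time, variable, value) + JSON protocol sidecar."""
        path = Path(path)
        long = self.to_frame().melt(
            id_vars="time", var_name="variable", value_name="value"
        )
        long.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(self.protocol), indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimulationResult":
        path = Path(path)
        long = pd.read_csv(path)
        wide = long.pivot(index="time", columns="variable", values="value")
        time = wide.index.to_numpy(dtype=float)
        states = wide[list(_STATE_NAMES)].to_numpy()
        fluxes = wide[list(_FLUX_NAMES)].reset_index(drop=True)
        sidecar = path.with_suffix(path.suffix + ".json")
        proto = Protocol(**json.loads(sidecar.read_text()))
        resting = ModelState.from_array(states[0])
        return cls(time=time, states=states, fluxes=fluxes,
                   protocol=proto, resting_state=resting)


def resting_closed_form(p: ModelParameters) -> tuple[float, float, float]:
    """Closed-form rest point (ca_i*, ca_er*, h*) at [ATP] = 0.

    With IP₃ = 0 the IP₃R is shut, so the cytosol rests where the constant
    inward leak balances the PMCA Hill pump,
    ca_i* = k_pmca·sqrt(j_inleak/(v_pmca − j_inleak)), and the ER rests where
    SERCA balances the ER leak.  h relaxes to h∞ at that calcium level.
    """
    if p.v_pmca <= p.j_inleak:
        raise ValueError("no rest state: PMCA cannot balance the inward leak")
    ca_i = p.k_pmca * np.sqrt(p.j_inleak / (p.v_pmca - p.j_inleak))
    ca_er = ca_i + float(pump_flux(ca_i, p.v_serca, p.k_serca)) / p.v_erleak
    q2_gate = p.d2 * p.d1 / p.d3
    h = q2_gate / (q2_gate + ca_i)
    return float(ca_i), float(ca_er), float(h)


def _initial_vector(p: ModelParameters, initial_markov: str) -> np.ndarray:
    y0 = np.zeros(core.N_STATES)
    ca_i, ca_er, h = resting_closed_form(p)
    y0[0] = ca_i
    y0[1] = ca_er
    y0[2] = 0.0      # basal IP3 assumed zero
    y0[3] = h
    name = "C1" if initial_markov == "naive_C1" else "C4"
    y0[4 + core.MARKOV_STATES.index(name)] = 1.0
    return y0


def equilibrate(p: ModelParameters, knockout: str = "none",
                initial_markov: str = "naive_C1", duration: float = 2000.0,
                residual_tol: float = 1e-6) -> ModelState:
    """Resting state after ``duration`` seconds at [ATP] = 0.

    Raises :class:`EquilibrationError` if any component of the right-hand
    side at the final state exceeds ``residual_tol``.
    """
    if initial_markov not in MARKOV_INITS:
        raise ValueError(f"initial_markov must be one of {MARKOV_INITS}")
    f = rhs_function(0.0, p, knockout)
    sol = solve_ivp(f, (0.0, duration), _initial_vector(p, initial_markov),
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise EquilibrationError(f"integration failed: {sol.message}")
    y = sol.y[:, -1]
    residual = np.abs(f(0.0, y))
    if residual.max() > residual_tol:
        raise EquilibrationError(
            f"not at rest after {duration} s: max |rhs| = {residual.max():.3e}"
        )
    # scrub integrator-level noise from the conserved Markov block
    y[4:] = np.clip(y[4:], 0.0, None)
    y[4:] /= y[4:].sum()
    return ModelState.from_array(y)


def run_protocol(proto: Protocol, p: ModelParameters,
                 resting: ModelState | None = None) -> SimulationResult:
    """Equilibrate (unless ``resting`` is supplied), step [ATP], integrate.

    Integration uses LSODA at the protocol's tolerances, with the maximum
    step capped during the first ``fast_window`` seconds.  The state and the
    six fluxes are reported on a uniform grid of spacing ``output_dt``.
    """
    if resting is None:
        resting = equilibrate(p, proto.knockout, proto.initial_markov,
                              proto.equilibrate)
    y0 = resting.as_array()
    f = rhs_function(proto.atp, p, proto.knockout)

    t_switch = min(proto.fast_window, proto.duration)
    grid1 = np.arange(0.0, t_switch + proto.output_dt / 2, proto.output_dt)
    nfev = 0

    sol1 = solve_ivp(f, (0.0, t_switch), y0, method="LSODA", t_eval=grid1,
                     rtol=proto.rtol, atol=proto.atol,
                     max_step=proto.fast_max_step)
    if not sol1.success:
        raise SolverError(f"solver failed: {sol1.message}",
                          last_time=float(sol1.t[-1]) if sol1.t.size else 0.0)
    nfev += sol1.nfev
    times, states = sol1.t, sol1.y

    if proto.duration > t_switch:
        grid2 = np.arange(t_switch, proto.duration + proto.output_dt / 2,
                          proto.output_dt)
        sol2 = solve_ivp(f, (t_switch, proto.duration), sol1.y[:, -1],
                         method="LSODA", t_eval=grid2,
                         rtol=proto.rtol, atol=proto.atol)
        if not sol2.success:
            raise SolverError(f"solver failed: {sol2.message}",
                              last_time=float(sol2.t[-1]))
        nfev += sol2.nfev
        times = np.concatenate([times, sol2.t[1:]])
        states = np.concatenate([states, sol2.y[:, 1:]], axis=1)

    states = states.T.copy()
    # renormalize the Markov block only if conservation drift is visible
    sums = states[:, 4:].sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-7:
        states[:, 4:] /= sums[:, None]

    flux_rows = [asdict(compute_fluxes(y, proto.atp, p, proto.knockout))
                 for y in states]
    fluxes = pd.DataFrame(flux_rows, columns=list(_FLUX_NAMES))
    return SimulationResult(time=times, states=states, fluxes=fluxes,
                            protocol=proto, resting_state=resting,
                            n_rhs_evaluations=int(nfev))
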