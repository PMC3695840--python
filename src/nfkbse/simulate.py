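"""Stimulation protocols and ODE integration.

The standard protocol mirrors the model's published use: start from all
NF-κB free in the cytoplasm and everything else at zero, equilibrate for
33 h with no stimulus (TR = 0), then apply a persistent stimulus that turns
on IKK activation (IKKn → IKKa at rate TR·K1) for the stimulation window.
Integration is classical fixed-step 4th-order Runge-Kutta with a
non-negativity clamp; the default step is 1 s, well below the fastest
first-order timescale in the rate table (~0.6 s⁻¹), and validated by the
step-halving property in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import network as _net
from ._kernels import get_kernel

__all__ = [
    "StimulusProtocol",
    "Trajectory",
    "DoseResponseCurve",
    "integrate_rk4",
    "equilibrate",
    "simulate_response",
    "dose_response",
    "default_tr_grid",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Equilibrate-then-stimulate protocol.

    Parameters
    ----------
    TR
        Dimensionless stimulus dosage multiplying the IKK activation rate K1.
    t_equilibrate_h, t_stimulate_h
        Pre-stimulus equilibration length and stimulation window, hours.
    dt_s
        RK4 step, seconds.
    output_stride_s
        Sampling interval of the stored trajectory, seconds (a multiple of dt_s).
    """

    TR: float = 1.0
    t_equilibrate_h: float = 33.0
    t_stimulate_h: float = 10.0
    dt_s: float = 1.0
    output_stride_s: float = 60.0

    def __post_init__(self):
        if self.TR < 0:
            raise ValueError("TR must be >= 0")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.t_equilibrate_h < 0 or self.t_stimulate_h < 0:
            raise ValueError("durations must be >= 0")
        if self.output_stride_s < self.dt_s:
            raise ValueError("output_stride_s must be >= dt_s")
        if abs(self.output_stride_s / self.dt_s - round(self.output_stride_s / self.dt_s)) > 1e-9:
            raise ValueError("output_stride_s must be an integer multiple of dt_s")

    @property
    def stride_steps(self) -> int:
        return int(round(self.output_stride_s / self.dt_s))

    def n_steps(self, duration_h: float) -> int:
        return int(round(duration_h * 3600.0 / self.dt_s))


@dataclass(frozen=True)
class Trajectory:
    """Time-resolved species concentrations; t = 0 is stimulation onset."""

    t_h: np.ndarray
    y: np.ndarray  # (time × species), canonical SPECIES order
    species: tuple[str, ...]
    protocol: StimulusProtocol
    params: _net.ParameterSet

    def series(self, name: str) -> np.ndarray:
        """Concentration time series of one species (μM)."""
        return self.y[:, _net.species_index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: time_h plus one column per species."""
        df = pd.DataFrame(self.y, columns=list(self.species))
        df.insert(0, "time_h", self.t_h)
        return df

    def to_tidy(self) -> pd.DataFrame:
        """Tidy (time_h, species, value) DataFrame."""
        return self.to_frame().melt(id_vars="time_h", var_name="species", value_name="value")

    def total_nfkb(self) -> np.ndarray:
        """Volume-weighted total NF-κB at every stored time (conserved)."""
        net = _net.get_network()
        return self.y @ net.nfkb_weights(self.params)


def integrate_rk4(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    state0: np.ndarray,
    duration: float,
    dt: float,
    output_stride: float | None = None,
    clamp: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic classical RK4 on an arbitrary ``rhs(t, y)``.

    Reference integrator used for oracle tests and cross-checks; the
    network fast path lives in :mod:`nfkbse._kernels`.  Returns
    ``(times, states)`` with the initial state in row 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    stride = 1 if output_stride is None else int(round(output_stride / dt))
    y = np.atleast_1d(np.asarray(state0, dtype=float)).copy()
    n_steps = int(round(duration / dt))
    rows = [y.copy()]
    times = [0.0]
    t = 0.0
    for step in range(n_steps):
        if clamp:
            y = _net.clamp_state(y)
        k1 = np.asarray(rhs(t, y))
        k2 = np.asarray(rhs(t + dt / 2, y + dt / 2 * k1))
        k3 = np.asarray(rhs(t + dt / 2, y + dt / 2 * k2))
        k4 = np.asarray(rhs(t + dt, y + dt * k3))
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (step + 1) * dt
        if not np.all(np.isfinite(y)):
            bad = int(np.argmax(~np.isfinite(y)))
            raise RuntimeError(f"integration diverged at t={t:g}, component {bad}")
        if (step + 1) % stride == 0:
            rows.append(np.clip(y, 0.0, None) if clamp else y.copy())
            times.append(t)
    return np.array(times), np.array(rows)


def equilibrate(
    params: _net.ParameterSet,
    protocol: StimulusProtocol | None = None,
    rel_deriv_tol: float = 0.01,
) -> np.ndarray:
    """Pre-stimulus state: integrate the standard initial condition for
    ``t_equilibrate_h`` with TR = 0 and return the final state.

    Warns (does not raise) if the state is still moving at the end — the
    relative derivative max(|dy/dt| · 1h / y) exceeding *rel_deriv_tol* —
    matching the fixed-length pre-run convention.
    """
    protocol = protocol or StimulusProtocol()
    net = _net.get_network()
    kern = get_kernel()
    y0 = net.initial_state(params)
    k = params.as_array()
    y, _ = kern.integrate(y0, k, 0.0, protocol.n_steps(protocol.t_equilibrate_h),
                          protocol.dt_s, protocol.stride_steps, store=False)
    dy = net.derivatives(y, params, 0.0)
    scale = np.where(y > 0, y, 1.0)
    rel = np.max(np.abs(dy) * 3600.0 / scale)
    if rel > rel_deriv_tol:
        k_worst = int(np.argmax(np.abs(dy) * 3600.0 / scale))
        warnings.warn(
            f"equilibration not fully converged after {protocol.t_equilibrate_h} h: "
            f"max relative derivative {rel:.2e}/h ({_net.SPECIES[k_worst]})",
            stacklevel=2,
        )
    return y


def simulate_response(
    params: _net.ParameterSet,
    protocol: StimulusProtocol | None = None,
    state0: np.ndarray | None = None,
) -> Trajectory:
    """Equilibrate, then stimulate with constant TR; trajectory time 0 is
    stimulation onset and row 0 the equilibrated pre-stimulus state.

    Passing *state0* skips equilibration and stimulates from that state
    (used for protocol chaining and dose sweeps).
    """
    protocol = protocol or StimulusProtocol()
    kern = get_kernel()
    if state0 is None:
        state0 = equilibrate(params, protocol)
    k = params.as_array()
    n_steps = protocol.n_steps(protocol.t_stimulate_h)
    _, rows = kern.integrate(np.array(state0, dtype=float), k, protocol.TR,
                             n_steps, protocol.dt_s, protocol.stride_steps)
    t_h = np.arange(rows.shape[0]) * protocol.output_stride_s / 3600.0
    return Trajectory(t_h=t_h, y=rows, species=_net.SPECIES, protocol=protocol, params=params)


def default_tr_grid(points_per_decade: int = 20) -> np.ndarray:
    """Logarithmic dosage grid over [1e-5, 1e-1] plus TR = 0."""
    grid = np.logspace(-5, -1, 4 * points_per_decade + 1)
    return np.concatenate([[0.0], grid])


@dataclass(frozen=True)
class DoseResponseCurve:
    """Quasi-steady-state nuclear NF-κB level per dosage, both sweep directions."""

    tr: np.ndarray
    forward: np.ndarray
    backward: np.ndarray
    window_h: tuple[float, float] = (20.0, 30.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"TR": self.tr, "forward_level": self.forward,
                             "backward_level": self.backward})

    def max_relative_gap(self) -> float:
        """max over TR of |forward − backward| / max(forward, backward)."""
        hi = np.maximum(self.forward, self.backward)
        with np.errstate(invalid="ignore", divide="ignore"):
            gap = np.abs(self.forward - self.backward) / hi
        return float(np.nanmax(np.where(hi > 0, gap, 0.0)))

    def has_hysteresis(self, threshold: float = 0.05) -> bool:
        return self.max_relative_gap() > threshold


def dose_response(
    params: _net.ParameterSet,
    tr_grid: Sequence[float] | None = None,
    hold_h: float = 30.0,
    window_h: tuple[float, float] = (20.0, 30.0),
    dt_s: float = 1.0,
    output_stride_s: float = 60.0,
    equilibrate_h: float = 33.0,
) -> DoseResponseCurve:
    """Step-like forward/backward dosage sweep.

    Each dosage of the ascending grid is held for *hold_h* hours starting
    from the previous step's final state; the quasi-steady-state level is
    the mean nuclear NF-κB over *window_h* within each hold.  The backward
    sweep retraces the grid descending, continuing from the forward sweep's
    end state.  Forward/backward disagreement beyond a few percent would
    signal hysteresis.
    """
    grid = np.asarray(default_tr_grid() if tr_grid is None else tr_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("tr_grid must be non-empty")
    if np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise ValueError("tr_grid must be strictly ascending")
    if np.any(grid < 0):
        raise ValueError("dosages must be >= 0")
    proto = StimulusProtocol(TR=0.0, t_equilibrate_h=equilibrate_h,
                             t_stimulate_h=hold_h, dt_s=dt_s,
                             output_stride_s=output_stride_s)
    kern = get_kernel()
    k = params.as_array()
    n_steps = proto.n_steps(hold_h)
    t_h = np.arange(n_steps // proto.stride_steps + 1) * output_stride_s / 3600.0
    in_window = (t_h >= window_h[0]) & (t_h <= window_h[1])
    if not np.any(in_window):
        raise ValueError("averaging window lies outside the hold duration")
    nn = _net.species_index("NFkBn")

    state = equilibrate(params, proto)

    def sweep(trs: np.ndarray, state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        levels = np.empty(trs.size)
        for j, tr in enumerate(trs):
            state, rows = kern.integrate(state, k, float(tr), n_steps,
                                         dt_s, proto.stride_steps)
            levels[j] = rows[in_window, nn].mean()
        return levels, state

    fwd, state = sweep(grid, state)
    bwd_desc, _ = sweep(grid[::-1], state)
    return DoseResponseCurve(tr=grid, forward=fwd, backward=bwd_desc[::-1],
                             window_h=window_h)
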