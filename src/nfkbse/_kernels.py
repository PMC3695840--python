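"""Compiled fixed-step RK4 integrator for the signaling network.

The mass-action right-hand side is code-generated from the packaged
reaction list as one fully unrolled function (one local per reaction flux,
one accumulation line per species) and compiled with numba, together with a
classical RK4 loop that clamps round-off negatives to zero before every
flux evaluation.  Kv enters the generated code symbolically through the
parameter vector, so a single compiled kernel serves every parameter set.

Compilation happens once per process, on first use.
"""

from __future__ import annotations

import numpy as np

from . import network as _net

__all__ = ["get_kernel", "CompiledKernel", "DivergenceError"]

_CLAMP_TOL = 1e-12


class DivergenceError(RuntimeError):
    """Raised when the integrator produces a non-finite or strongly
    negative state; carries the offending time and species."""

    def __init__(self, time_h: float, species: str, value: float):
        self.time_h = time_h
        self.species = species
        self.value = value
        super().__init__(
            f"integration diverged at t = {time_h:.4f} h: {species} = {value:g}"
        )


def _generate_rhs_source(net: _net.ReactionNetwork) -> str:
    """Unrolled RHS: dy[i] = Σ ±(Kv**p)·v_r with v_r = k_r·(TR)·Π y_j."""
    sidx = {name: k for k, name in enumerate(net.species)}
    pidx = {sym: k for k, sym in enumerate(_net.SYMBOLS)}
    kv = pidx["Kv"]
    lines = ["def _rhs(y, k, tr, dy):"]
    terms: list[list[str]] = [[] for _ in net.species]
    for r, rxn in enumerate(net.reactions):
        expr = f"k[{pidx[rxn.symbol]}]"
        if rxn.tr_scaled:
            expr += " * tr"
        for name in rxn.reactants:
            expr += f" * y[{sidx[name]}]"
        lines.append(f"    v{r} = {expr}")
        for name, coeff, kvp in rxn.stoich:
            if kvp == 1:
                piece = f"k[{kv}] * v{r}"
            elif kvp == -1:
                piece = f"v{r} / k[{kv}]"
            else:
                piece = f"v{r}"
            if coeff == 1.0:
                terms[sidx[name]].append(f"+ {piece}")
            elif coeff == -1.0:
                terms[sidx[name]].append(f"- {piece}")
            else:
                terms[sidx[name]].append(f"+ ({coeff!r}) * {piece}")
    for s in range(len(net.species)):
        body = " ".join(terms[s]) if terms[s] else "0.0"
        lines.append(f"    dy[{s}] = {body.lstrip('+ ')}")
    return "\n".join(lines)


class CompiledKernel:
    """Numba-compiled RHS + RK4 loop for the packaged network."""

    def __init__(self, net: _net.ReactionNetwork):
        import numba

        src = _generate_rhs_source(net)
        namespace: dict = {}
        exec(compile(src, "<nfkbse-generated-rhs>", "exec"), namespace)
        rhs = numba.njit(namespace["_rhs"], fastmath=False)
        self.rhs = rhs
        self.source = src
        self.n_species = net.n_species

        @numba.njit(fastmath=False)
        def _integrate(y, k, tr, dt, n_steps, stride, out):
            n = y.shape[0]
            k1 = np.empty(n)
            k2 = np.empty(n)
            k3 = np.empty(n)
            k4 = np.empty(n)
            yt = np.empty(n)
            for i in range(n):
                if y[i] < 0.0:
                    if y[i] < -_CLAMP_TOL:
                        return -1
                    y[i] = 0.0
            row = 0
            if out.shape[0] > 0:
                out[0] = y
            for step in range(n_steps):
                rhs(y, k, tr, k1)
                for i in range(n):
                    yt[i] = y[i] + 0.5 * dt * k1[i]
                    if yt[i] < 0.0:
                        yt[i] = 0.0
                rhs(yt, k, tr, k2)
                for i in range(n):
                    yt[i] = y[i] + 0.5 * dt * k2[i]
                    if yt[i] < 0.0:
                        yt[i] = 0.0
                rhs(yt, k, tr, k3)
                for i in range(n):
                    yt[i] = y[i] + dt * k3[i]
                    if yt[i] < 0.0:
                        yt[i] = 0.0
                rhs(yt, k, tr, k4)
                for i in range(n):
                    y[i] += (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                    if y[i] < 0.0:
                        y[i] = 0.0
                if (step + 1) % stride == 0:
                    row += 1
                    if row < out.shape[0]:
                        out[row] = y
                    ok = True
                    for i in range(n):
                        if not np.isfinite(y[i]):
                            ok = False
                    if not ok:
                        return step + 1
            return 0

        self._integrate = _integrate

    def integrate(
        self,
        state0: np.ndarray,
        k: np.ndarray,
        TR: float,
        n_steps: int,
        dt: float,
        stride: int,
        store: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Integrate n_steps of size dt; returns (final_state, sampled_rows).

        sampled_rows has ``n_steps // stride + 1`` rows (initial state
        first) when *store* is true, else zero rows.
        """
        y = np.array(state0, dtype=float)
        if y.shape != (self.n_species,):
            raise ValueError(f"state has shape {y.shape}, expected ({self.n_species},)")
        n_rows = n_steps // stride + 1 if store else 0
        out = np.empty((n_rows, self.n_species))
        status = self._integrate(y, np.asarray(k, dtype=float), float(TR),
                                 float(dt), int(n_steps), int(stride), out)
        if status != 0:
            at = 0.0 if status < 0 else status * dt / 3600.0
            bad = int(np.argmin(np.isfinite(y))) if not np.all(np.isfinite(y)) else int(np.argmin(y))
            raise DivergenceError(at, _net.SPECIES[bad], float(y[bad]))
        return y, out


_kernel: CompiledKernel | None = None


def get_kernel() -> CompiledKernel:
    """Process-wide compiled kernel (built and jitted on first call)."""
    global _kernel
    if _kernel is None:
        _kernel = CompiledKernel(_net.get_network())
    return _kernel
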