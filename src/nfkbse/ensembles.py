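"""Statistical ensembles of parameter sets via Latin hypercube sampling.

Extrinsic (cell-to-cell) noise is modeled by giving every replicate its own
kinetic constants, drawn uniformly from (x₀(1−χ), x₀(1+χ)) around each
reference value x₀ with heterogeneity factor χ (working value 0.3).  For N
replicates, each sampled constant's range is split into N equal-width
(hence equal-probability, under the uniform density) strata; one value is
drawn uniformly inside each stratum and the per-constant columns are
combined by independent random permutations — classical Latin hypercube
sampling.

Each constant draws from its own RNG stream, derived deterministically from
the master seed and the constant's name, so adding a symbol to the sampled
set does not reshuffle the draws of the others, and identical configs are
bitwise reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import network as _net
from .simulate import StimulusProtocol, Trajectory, simulate_response

__all__ = [
    "EnsembleConfig",
    "Ensemble",
    "lhs_sample",
    "run_ensemble",
    "ensemble_average",
    "simulate_ensemble",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Replicate count N, heterogeneity χ ∈ [0, 1), master seed, reference
    parameters and the set of randomized symbols (default: every kinetic
    rate constant with a nonzero reference; Kv and NFkB_total stay fixed)."""

    reference: _net.ParameterSet
    n: int = 1000
    chi: float = 0.3
    seed: int = 0
    sampled_symbols: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("N must be >= 1")
        if not (0.0 <= self.chi < 1.0):
            raise ValueError("chi must lie in [0, 1)")
        if self.sampled_symbols is not None:
            syms = tuple(self.sampled_symbols)
            unknown = set(syms) - set(_net.SYMBOLS)
            if unknown:
                raise ValueError(f"unknown sampled symbols: {sorted(unknown)}")
            object.__setattr__(self, "sampled_symbols", syms)

    def resolved_symbols(self) -> tuple[str, ...]:
        """Symbols actually randomized: zero-reference constants keep a
        zero-width interval and are never sampled."""
        base = self.sampled_symbols if self.sampled_symbols is not None else _net.RATE_SYMBOLS
        return tuple(s for s in base if self.reference[s] > 0)


@dataclass
class Ensemble:
    """N parameter sets (plus, after :func:`run_ensemble`, N trajectories)."""

    config: EnsembleConfig
    parameter_sets: list[_net.ParameterSet]
    genotype: _net.Genotype = field(default_factory=_net.Genotype.wild_type)
    trajectories: list[Trajectory] | None = None
    failed_replicates: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.parameter_sets)

    def param_frame(self) -> pd.DataFrame:
        """replicate_id × symbol DataFrame of the sampled parameter values."""
        df = pd.DataFrame([dict(p) for p in self.parameter_sets])
        df.insert(0, "replicate_id", np.arange(self.n))
        return df


def _symbol_rng(seed: int, symbol: str) -> np.random.Generator:
    # crc32 gives a stable, platform-independent per-symbol stream key.
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(symbol.encode())]))


def lhs_sample(config: EnsembleConfig) -> Ensemble:
    """Latin-hypercube ensemble around the reference parameter set.

    For every sampled symbol the N values stratify (x₀(1−χ), x₀(1+χ))
    exactly — one draw per equal-width stratum — and the strata are paired
    across symbols by independent permutations.
    """
    ref = config.reference
    n, chi = config.n, config.chi
    columns: dict[str, np.ndarray] = {}
    for sym in config.resolved_symbols():
        x0 = ref[sym]
        rng = _symbol_rng(config.seed, sym)
        u = rng.random(n)
        strata = x0 * (1.0 - chi) + (np.arange(n) + u) * (2.0 * chi * x0 / n)
        perm = rng.permutation(n)
        columns[sym] = strata[perm]
    base = dict(ref)
    psets = []
    for r in range(n):
        vals = dict(base)
        for sym, col in columns.items():
            vals[sym] = col[r]
        psets.append(_net.ParameterSet(vals))
    return Ensemble(config=config, parameter_sets=psets)


def run_ensemble(
    ensemble: Ensemble,
    protocol: StimulusProtocol | None = None,
    genotype: _net.Genotype | None = None,
    on_error: str = "raise",
    overwrite: bool = False,
) -> Ensemble:
    """Simulate every replicate independently and attach trajectories.

    The genotype knockout is applied to each replicate's parameters (exact
    zeroing, whatever was sampled).  Replicates are independent, so the
    execution order cannot affect the result.  ``on_error="skip"`` records
    a failed (diverged) replicate's index and excludes it instead of
    aborting.
    """
    if ensemble.trajectories is not None and not overwrite:
        raise ValueError("ensemble already has trajectories (pass overwrite=True)")
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    protocol = protocol or StimulusProtocol()
    genotype = genotype or ensemble.genotype
    trajectories: list[Trajectory] = []
    failed: list[int] = []
    for idx, params in enumerate(ensemble.parameter_sets):
        p = _net.apply_knockout(params, genotype)
        try:
            trajectories.append(simulate_response(p, protocol))
        except Exception as exc:  # noqa: BLE001 - replicate divergence policy
            if on_error == "raise":
                raise RuntimeError(f"replicate {idx} failed: {exc}") from exc
            warnings.warn(f"replicate {idx} failed and was skipped: {exc}", stacklevel=2)
            trajectories.append(None)  # placeholder keeps replicate ids aligned
            failed.append(idx)
    ensemble.trajectories = trajectories
    ensemble.genotype = genotype
    ensemble.failed_replicates = failed
    return ensemble


def ensemble_average(ensemble: Ensemble, species: str = "NFkBn") -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight pointwise mean of one species across replicates.

    Returns (t_h, mean); skipped replicates are excluded.  All trajectories
    must share one time grid.
    """
    if ensemble.trajectories is None:
        raise ValueError("ensemble has no trajectories; call run_ensemble first")
    live = [tr for tr in ensemble.trajectories if tr is not None]
    if not live:
        raise ValueError("no successful replicates to average")
    t0 = live[0].t_h
    for tr in live[1:]:
        if tr.t_h.shape != t0.shape or not np.array_equal(tr.t_h, t0):
            raise ValueError("trajectories do not share a common time grid")
    stack = np.stack([tr.series(species) for tr in live])
    return t0, stack.mean(axis=0)


def simulate_ensemble(
    reference: _net.ParameterSet,
    genotype: _net.Genotype | None = None,
    protocol: StimulusProtocol | None = None,
    n: int = 1000,
    chi: float = 0.3,
    seed: int = 0,
    sampled_symbols: Sequence[str] | None = None,
    on_error: str = "raise",
) -> Ensemble:
    """One-shot convenience: knockout → LHS sample → simulate.

    Sampling operates on the post-knockout reference, so knocked-out rates
    have zero-width intervals and stay exactly zero in every replicate.
    """
    genotype = genotype or _net.Genotype.wild_type()
    ref = _net.apply_knockout(reference, genotype)
    config = EnsembleConfig(
        reference=ref, n=n, chi=chi, seed=seed,
        sampled_symbols=None if sampled_symbols is None else tuple(sampled_symbols),
    )
    ens = lhs_sample(config)
    ens.genotype = genotype
    return run_ensemble(ens, protocol, genotype, on_error=on_error)
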