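"""Heuristic ensemble-average fitting.

Tunes kinetic constants so that the six dynamic features of the
ensemble-averaged nuclear NF-κB curve match population-level target
features.  The procedure is a coordinate-descent heuristic, not a gradient
method: at each iteration the feature with the largest relative deviation
is identified and the two kinetic constants most strongly (rank-)
correlated with that feature across a pilot ensemble are nudged
multiplicatively in the direction the correlation sign dictates.  Rejected
steps (the worst deviation did not improve) are rolled back and the step
size halved; when steps stall, the heterogeneity factor χ is lowered in
fixed decrements.

Every ensemble evaluated during a fit uses the same master-seed-derived
random numbers (common random numbers), so accept/reject decisions compare
like with like and a fit is bitwise reproducible from its config.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import network as _net
from .ensembles import ensemble_average, simulate_ensemble
from .features import (
    FEATURE_NAMES,
    FeatureSettings,
    ensemble_features,
    extract_features_series,
)
from .simulate import StimulusProtocol

__all__ = [
    "FeatureTarget",
    "FitTargets",
    "FitConfig",
    "FitIteration",
    "FitState",
    "CorrelationResult",
    "feature_parameter_correlation",
    "fit_to_targets",
]

MIN_CORRELATION_REPLICATES = 50
MIN_DEFINED_PER_FEATURE = 10


@dataclass(frozen=True)
class FeatureTarget:
    """Target value for one dynamic feature, with relative tolerance and weight."""

    value: float
    tolerance: float = 0.15
    weight: float = 1.0

    def __post_init__(self):
        if not math.isfinite(self.value) or self.value == 0:
            raise ValueError("target value must be finite and nonzero (deviations are relative)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class FitTargets:
    """Active-feature targets for the SE-average nuclear NF-κB curve."""

    entries: dict[str, FeatureTarget]

    def __post_init__(self):
        unknown = set(self.entries) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature(s): {sorted(unknown)}")
        if not self.entries:
            raise ValueError("at least one feature must be active")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @classmethod
    def from_values(cls, values: dict[str, float], tolerance: float = 0.15) -> "FitTargets":
        return cls({f: FeatureTarget(v, tolerance) for f, v in values.items()})


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the heuristic search (defaults follow the package's
    documented conventions: N_fit = 200 replicates per evaluation, initial
    χ = 0.3 with 0.05 decrements, multiplicative steps of ±20%)."""

    n_fit: int = 200
    n_pilot: int = 100
    chi: float = 0.3
    chi_step: float = 0.05
    chi_min: float = 0.05
    eta: float = 0.2
    eta_min: float = 0.02
    max_iterations: int = 30
    seed: int = 0
    genotype: _net.Genotype = field(default_factory=_net.Genotype.wild_type)
    protocol: StimulusProtocol = field(default_factory=lambda: StimulusProtocol(t_stimulate_h=6.0))
    settings: FeatureSettings = field(default_factory=FeatureSettings)
    adjustable_symbols: tuple[str, ...] | None = None
    pairs: dict[str, tuple[str, str]] | None = None
    undefined_penalty: float = 5.0

    def __post_init__(self):
        if self.n_fit < 1 or self.n_pilot < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.eta <= 0 or self.eta >= 1:
            raise ValueError("eta must lie in (0, 1)")


@dataclass(frozen=True)
class CorrelationResult:
    """Rank correlations between sampled parameters and per-replicate features."""

    matrix: pd.DataFrame                      # symbols × features, Spearman rho
    top_pairs: dict[str, tuple[str, str]]     # feature -> two strongest |rho| symbols
    excluded_features: tuple[str, ...]


def feature_parameter_correlation(
    ensemble,
    features: pd.DataFrame | None = None,
    species: str = "NFkBn",
    settings: FeatureSettings | None = None,
    symbols: Sequence[str] | None = None,
) -> CorrelationResult:
    """Spearman correlation of every sampled parameter with every feature.

    Parameters held fixed across replicates have no variance; their
    correlation is undefined (NaN) and they never enter the top-2 ranking.
    Features defined in fewer than 10 replicates are excluded with a warning.
    """
    if ensemble.n < MIN_CORRELATION_REPLICATES:
        raise ValueError(
            f"need >= {MIN_CORRELATION_REPLICATES} replicates for a stable ranking, got {ensemble.n}"
        )
    if features is None:
        features = ensemble_features(ensemble, species, settings)
    pframe = ensemble.param_frame().set_index("replicate_id")
    if "replicate_id" in features.columns:
        features = features.set_index("replicate_id")
    pframe = pframe.loc[features.index]
    syms = tuple(symbols) if symbols is not None else _net.RATE_SYMBOLS
    mat = pd.DataFrame(index=list(syms), columns=list(FEATURE_NAMES), dtype=float)
    excluded = []
    for feat in FEATURE_NAMES:
        fvals = features[feat].to_numpy(dtype=float)
        defined = np.isfinite(fvals)
        if defined.sum() < MIN_DEFINED_PER_FEATURE:
            warnings.warn(
                f"feature {feat!r} defined in only {int(defined.sum())} replicates; excluded",
                stacklevel=2,
            )
            excluded.append(feat)
            continue
        fv = fvals[defined]
        for sym in syms:
            pv = pframe[sym].to_numpy(dtype=float)[defined]
            if np.ptp(pv) == 0.0 or np.ptp(fv) == 0.0:
                mat.loc[sym, feat] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearmanr(pv, fv).statistic
            mat.loc[sym, feat] = rho
    top: dict[str, tuple[str, str]] = {}
    for feat in FEATURE_NAMES:
        if feat in excluded:
            continue
        col = mat[feat].abs().dropna().sort_values(ascending=False)
        if len(col) >= 2:
            top[feat] = (col.index[0], col.index[1])
    return CorrelationResult(matrix=mat, top_pairs=top, excluded_features=tuple(excluded))


@dataclass(frozen=True)
class FitIteration:
    """Bookkeeping for one heuristic step."""

    iteration: int
    chi: float
    deviations: dict[str, float]
    worst_feature: str | None
    adjusted: tuple[str, ...]
    factors: tuple[float, ...]
    accepted: bool


@dataclass
class FitState:
    """Outcome of a fit: final parameters, χ, full history, convergence flag."""

    params: _net.ParameterSet
    chi: float
    iterations: list[FitIteration]
    converged: bool
    deviations: dict[str, float]
    pairs: dict[str, tuple[str, str]]

    def log_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.iterations:
            row = {"iteration": it.iteration, "chi": it.chi,
                   "worst_feature": it.worst_feature,
                   "adjusted": "+".join(it.adjusted),
                   "accepted": it.accepted}
            row.update({f"dev_{k}": v for k, v in it.deviations.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _evaluate(params, targets: FitTargets, config: FitConfig, chi: float):
    """SE average under current parameters → (deviation, signed deviation) per feature."""
    ens = simulate_ensemble(
        params, genotype=config.genotype, protocol=config.protocol,
        n=config.n_fit, chi=chi, seed=config.seed,
    )
    t, avg = ensemble_average(ens)
    feats, _ = extract_features_series(t, avg, config.settings)
    dev: dict[str, float] = {}
    signed: dict[str, float] = {}
    for f, tgt in targets.entries.items():
        val = feats.value(f)
        if math.isfinite(val):
            s = (val - tgt.value) / tgt.value
            d = abs(s) * tgt.weight
        else:
            # Feature missing from the average (e.g. no second peak):
            # finite penalty, treated as "far below target".
            s = -1.0
            d = config.undefined_penalty * tgt.weight
        if not math.isfinite(d):
            raise RuntimeError(f"non-finite deviation for feature {f!r} (value {val!r})")
        dev[f] = d
        signed[f] = s
    return dev, signed


def _resolve_pairs(targets: FitTargets, init, config: FitConfig) -> tuple[dict, pd.DataFrame | None]:
    if config.pairs is not None:
        return dict(config.pairs), None
    pilot = simulate_ensemble(
        init, genotype=config.genotype, protocol=config.protocol,
        n=config.n_pilot, chi=config.chi, seed=config.seed + 1,
    )
    corr = feature_parameter_correlation(
        pilot, settings=config.settings, symbols=config.adjustable_symbols
    )
    return dict(corr.top_pairs), corr.matrix


def fit_to_targets(
    targets: FitTargets, init: _net.ParameterSet, config: FitConfig | None = None
) -> FitState:
    """Iterative worst-feature coordinate search (see module docstring).

    Convergence: every active feature's relative deviation within its
    tolerance.  Returns the best parameters seen, converged or not.
    """
    config = config or FitConfig()
    pairs, corr_matrix = _resolve_pairs(targets, init, config)
    missing = [f for f in targets.features if f not in pairs]
    if missing:
        raise ValueError(f"no parameter pair available for feature(s) {missing}")

    params = init
    chi = config.chi
    eta = {f: config.eta for f in targets.features}
    dirmul = {f: 1.0 for f in targets.features}   # flipped once before halving eta
    flipped = {f: False for f in targets.features}
    dev, signed = _evaluate(params, targets, config, chi)
    history: list[FitIteration] = [
        FitIteration(0, chi, dict(dev), None, (), (), True)
    ]

    def within_tol(d: dict[str, float]) -> bool:
        return all(d[f] <= targets.entries[f].tolerance for f in targets.features)

    converged = within_tol(dev)
    it = 0
    while not converged and it < config.max_iterations:
        it += 1
        worst = max(dev, key=lambda f: dev[f] / targets.entries[f].tolerance)
        p1, p2 = pairs[worst]
        updates: dict[str, float] = {}
        factors: list[float] = []
        for sym in (p1, p2):
            rho = float(corr_matrix.loc[sym, worst]) if corr_matrix is not None else 1.0
            if not math.isfinite(rho) or rho == 0.0:
                rho = 1.0
            direction = (
                -math.copysign(1.0, rho) * math.copysign(1.0, signed[worst]) * dirmul[worst]
            )
            factor = 1.0 + eta[worst] * direction
            updates[sym] = params[sym] * factor
            factors.append(factor)
        candidate = params.replace(**updates)
        cand_dev, cand_signed = _evaluate(candidate, targets, config, chi)
        accepted = cand_dev[worst] <= dev[worst]
        if accepted:
            params, dev, signed = candidate, cand_dev, cand_signed
            flipped[worst] = False
        elif not flipped[worst]:
            # try the opposite direction at the same step size first
            dirmul[worst] *= -1.0
            flipped[worst] = True
        else:
            dirmul[worst] *= -1.0
            flipped[worst] = False
            eta[worst] /= 2.0
            if eta[worst] < config.eta_min:
                if chi - config.chi_step >= config.chi_min - 1e-12:
                    chi = round(chi - config.chi_step, 10)
                    eta = {f: config.eta for f in targets.features}
                    dev, signed = _evaluate(params, targets, config, chi)
                else:
                    history.append(FitIteration(it, chi, dict(cand_dev), worst,
                                                (p1, p2), tuple(factors), False))
                    break
        history.append(FitIteration(it, chi, dict(dev), worst, (p1, p2),
                                    tuple(factors), accepted))
        converged = within_tol(dev)

    return FitState(params=params, chi=chi, iterations=history,
                    converged=converged, deviations=dict(dev), pairs=pairs)
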