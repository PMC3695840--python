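"""Dynamic features and pattern taxonomy of nuclear NF-κB profiles.

Six per-trajectory features summarize a nuclear NF-κB time course: the
amplitude and timing of the first peak (first maximum, first translocation
time), the gap between the first two peaks (first period), and — normalized
by the first maximum — the first inter-peak minimum, the second maximum and
the asymptotic steady state.  Each trajectory is then classified into one
of four dynamic patterns: sustained oscillation, damped oscillation,
single-peaked or monotonic-increasing ("hyperbolic").

Peak calling is deliberately conservative: a local extremum counts only if
its prominence exceeds a fraction of the trajectory's global maximum, so
small wiggles on a decaying tail do not register as oscillation peaks.  The
prominence fraction, amplitude floor and the sustained/damped decision
threshold are declared, tunable conventions (the four-way taxonomy is
sharp; where a trajectory lands can depend on them).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .ensembles import Ensemble
from .simulate import Trajectory

__all__ = [
    "PeakSettings",
    "FeatureSettings",
    "PeakList",
    "DynamicFeatures",
    "PatternLabel",
    "detect_peaks",
    "extract_features",
    "extract_features_series",
    "classify_pattern",
    "classify_series",
    "ensemble_features",
    "feature_distributions",
    "pattern_distribution",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "first_maximum",
    "first_translocation_time",
    "first_period",
    "ratio_first_min_to_first_max",
    "ratio_second_max_to_first_max",
    "ratio_steady_state_to_first_max",
)


@dataclass(frozen=True)
class PeakSettings:
    """Peak-calling convention.

    prominence_frac: minimum prominence as a fraction of the global max.
    amplitude_floor: absolute minimum peak height, μM (default 1e-4 of the
    total NF-κB concentration 0.06 μM).
    """

    prominence_frac: float = 0.05
    amplitude_floor: float = 6e-6

    def __post_init__(self):
        if not (0 <= self.prominence_frac < 1):
            raise ValueError("prominence_frac must lie in [0, 1)")
        if self.amplitude_floor < 0:
            raise ValueError("amplitude_floor must be >= 0")


@dataclass(frozen=True)
class FeatureSettings:
    """Feature-extraction and classification convention."""

    peaks: PeakSettings = field(default_factory=PeakSettings)
    steady_window: float = 0.1       # trailing fraction averaged as steady state
    sustain_threshold: float = 0.6   # second/first peak ratio for "sustained"
    min_peaks_sustained: int = 3

    def __post_init__(self):
        if not (0 < self.steady_window <= 1):
            raise ValueError("steady_window must lie in (0, 1]")


@dataclass(frozen=True)
class PeakList:
    """Interleaved local maxima and minima of one time series."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    trough_times: np.ndarray
    trough_values: np.ndarray
    settings: PeakSettings

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)


class PatternLabel(str, enum.Enum):
    SUSTAINED_OSCILLATION = "sustained_oscillation"
    DAMPED_OSCILLATION = "damped_oscillation"
    SINGLE_PEAKED = "single_peaked"
    MONOTONIC_INCREASING = "monotonic_increasing"


def _interleave(events: list[tuple[float, float, bool]]) -> list[tuple[float, float, bool]]:
    """Discard the lesser of two consecutive same-type extrema so peaks and
    troughs strictly alternate (for troughs, 'lesser' = less extreme, i.e.
    the higher one)."""
    out: list[tuple[float, float, bool]] = []
    for ev in events:
        if out and out[-1][2] == ev[2]:
            is_peak = ev[2]
            keep_new = ev[1] > out[-1][1] if is_peak else ev[1] < out[-1][1]
            if keep_new:
                out[-1] = ev
        else:
            out.append(ev)
    return out


def detect_peaks(t: np.ndarray, y: np.ndarray, settings: PeakSettings | None = None) -> PeakList:
    """Prominence-filtered local maxima and minima of a finite series."""
    settings = settings or PeakSettings()
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or y.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    gmax = float(y.max())
    prom = settings.prominence_frac * gmax if gmax > 0 else 0.0
    if prom > 0:
        maxima, _ = find_peaks(y, prominence=prom)
        minima, _ = find_peaks(-y, prominence=prom)
    else:  # flat or all-zero series: no structure by definition
        maxima = np.array([], dtype=int)
        minima = np.array([], dtype=int)
    maxima = maxima[y[maxima] >= settings.amplitude_floor]
    events = sorted(
        [(t[i], y[i], True) for i in maxima] + [(t[i], y[i], False) for i in minima]
    )
    events = _interleave(events)
    pk = [(tt, vv) for tt, vv, is_p in events if is_p]
    tr = [(tt, vv) for tt, vv, is_p in events if not is_p]
    return PeakList(
        peak_times=np.array([e[0] for e in pk]),
        peak_values=np.array([e[1] for e in pk]),
        trough_times=np.array([e[0] for e in tr]),
        trough_values=np.array([e[1] for e in tr]),
        settings=settings,
    )


@dataclass(frozen=True)
class DynamicFeatures:
    """The six dynamic features; undefined entries are NaN with the
    corresponding ``defined`` flag False (never silently zero).

    Times are hours, amplitudes μM; the three ratios are normalized by the
    first maximum.  ``responder`` records whether the trajectory moved at
    all: (global max − initial level) above the amplitude floor.
    """

    first_maximum: float
    first_translocation_time: float
    first_period: float
    ratio_first_min_to_first_max: float
    ratio_second_max_to_first_max: float
    ratio_steady_state_to_first_max: float
    steady_state: float
    n_peaks: int
    responder: bool

    def value(self, name: str) -> float:
        return getattr(self, name)

    def defined(self, name: str) -> bool:
        return math.isfinite(self.value(name))

    def as_dict(self) -> dict:
        return asdict(self)


def extract_features_series(
    t: np.ndarray, y: np.ndarray, settings: FeatureSettings | None = None
) -> tuple[DynamicFeatures, PeakList]:
    """Features of an arbitrary (t, y) series (t in hours)."""
    settings = settings or FeatureSettings()
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    peaks = detect_peaks(t, y, settings.peaks)
    n_tail = max(1, int(round(settings.steady_window * y.size)))
    steady = float(y[-n_tail:].mean())
    nan = float("nan")
    first_max = first_time = period = r_min = r_2nd = r_ss = nan
    if peaks.n_peaks >= 1:
        first_max = float(peaks.peak_values[0])
        first_time = float(peaks.peak_times[0])
        r_ss = steady / first_max
    if peaks.n_peaks >= 2:
        period = float(peaks.peak_times[1] - peaks.peak_times[0])
        r_2nd = float(peaks.peak_values[1] / first_max)
        between = (peaks.trough_times > peaks.peak_times[0]) & (
            peaks.trough_times < peaks.peak_times[1]
        )
        if np.any(between):
            r_min = float(peaks.trough_values[between][0] / first_max)
    responder = bool(y.max() - y[0] >= settings.peaks.amplitude_floor)
    feats = DynamicFeatures(
        first_maximum=first_max,
        first_translocation_time=first_time,
        first_period=period,
        ratio_first_min_to_first_max=r_min,
        ratio_second_max_to_first_max=r_2nd,
        ratio_steady_state_to_first_max=r_ss,
        steady_state=steady,
        n_peaks=peaks.n_peaks,
        responder=responder,
    )
    return feats, peaks


def extract_features(
    trajectory: Trajectory, species: str = "NFkBn", settings: FeatureSettings | None = None
) -> DynamicFeatures:
    """Six dynamic features of one species in a simulated trajectory."""
    feats, _ = extract_features_series(trajectory.t_h, trajectory.series(species), settings)
    return feats


def classify_pattern(
    features: DynamicFeatures, peaks: PeakList, settings: FeatureSettings | None = None
) -> PatternLabel:
    """Four-way dynamic-pattern call.

    No prominent peak → monotonic-increasing (the hyperbolic class, which
    also absorbs flat non-responders); exactly one → single-peaked; two or
    more with slowly decaying amplitude (second/first ≥ sustain_threshold
    and at least min_peaks_sustained peaks in the window) → sustained
    oscillation; any other multi-peak profile → damped oscillation.
    """
    settings = settings or FeatureSettings()
    n = peaks.n_peaks
    if n == 0:
        return PatternLabel.MONOTONIC_INCREASING
    if n == 1:
        return PatternLabel.SINGLE_PEAKED
    if (
        features.ratio_second_max_to_first_max >= settings.sustain_threshold
        and n >= settings.min_peaks_sustained
    ):
        return PatternLabel.SUSTAINED_OSCILLATION
    return PatternLabel.DAMPED_OSCILLATION


def classify_series(
    t: np.ndarray, y: np.ndarray, settings: FeatureSettings | None = None
) -> PatternLabel:
    """Convenience: features + classification of a raw series."""
    settings = settings or FeatureSettings()
    feats, peaks = extract_features_series(t, y, settings)
    return classify_pattern(feats, peaks, settings)


def ensemble_features(
    ensemble: Ensemble, species: str = "NFkBn", settings: FeatureSettings | None = None
) -> pd.DataFrame:
    """Per-replicate feature table: replicate_id, six features, steady
    state, peak count, pattern label and responder flag."""
    settings = settings or FeatureSettings()
    if ensemble.trajectories is None:
        raise ValueError("ensemble has no trajectories; call run_ensemble first")
    records = []
    for idx, traj in enumerate(ensemble.trajectories):
        if traj is None:
            continue
        feats, peaks = extract_features_series(traj.t_h, traj.series(species), settings)
        rec = {"replicate_id": idx, **feats.as_dict(),
               "pattern": classify_pattern(feats, peaks, settings).value}
        records.append(rec)
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class FeatureSummary:
    """Histogram + summary statistics of one feature across an ensemble."""

    name: str
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    mode: float
    std: float
    n_defined: int
    n_undefined: int

    @property
    def defined_fraction(self) -> float:
        total = self.n_defined + self.n_undefined
        return self.n_defined / total if total else 0.0

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "mean": self.mean,
            "mode": self.mode,
            "std": self.std,
            "n_defined": self.n_defined,
            "n_undefined": self.n_undefined,
            "defined_fraction": self.defined_fraction,
        }


def feature_distributions(
    features: pd.DataFrame | Iterable[DynamicFeatures],
    names: Sequence[str] = FEATURE_NAMES,
    bins: int = 50,
) -> dict[str, FeatureSummary]:
    """Histograms (uniform bins over the observed range), mean, mode and
    dispersion per feature; undefined values are counted separately.  The
    mode is the center of the fullest histogram bin."""
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame.from_records([f.as_dict() for f in features])
    out: dict[str, FeatureSummary] = {}
    for name in names:
        col = features[name].to_numpy(dtype=float)
        vals = col[np.isfinite(col)]
        n_undef = col.size - vals.size
        if vals.size == 0:
            out[name] = FeatureSummary(name, np.array([]), np.array([], dtype=int),
                                       float("nan"), float("nan"), float("nan"),
                                       0, n_undef)
            continue
        counts, edges = np.histogram(vals, bins=bins)
        mode = float((edges[:-1] + edges[1:])[np.argmax(counts)] / 2.0)
        out[name] = FeatureSummary(
            name=name, bin_edges=edges, counts=counts,
            mean=float(vals.mean()), mode=mode,
            std=float(vals.std(ddof=0)),
            n_defined=int(vals.size), n_undefined=int(n_undef),
        )
    return out


def pattern_distribution(labels: Iterable[PatternLabel | str]) -> dict[str, float]:
    """Fraction of trajectories per dynamic pattern (sums to 1)."""
    labels = [PatternLabel(l) for l in labels]
    if not labels:
        raise ValueError("no labels given")
    n = len(labels)
    return {
        member.value: sum(1 for l in labels if l is member) / n
        for member in PatternLabel
    }
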