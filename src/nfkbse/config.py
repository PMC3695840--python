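"""Run configuration: strict YAML schema plus figure-style presets.

A RunConfig fully specifies a run — genotype, parameter column, stimulus,
ensemble size/heterogeneity/seed, metric settings and output directory.
Unknown keys are rejected rather than ignored, and all randomness flows
from the single top-level seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from . import network as _net
from .features import FeatureSettings, PeakSettings
from .simulate import StimulusProtocol

__all__ = ["RunConfig", "PRESETS"]


@dataclass(frozen=True)
class RunConfig:
    genotype: tuple[str, ...] = ()
    column: str = "nominal"
    table: str | None = None          # custom parameter table path
    TR: float = 1.0
    tr_grid: tuple[float, ...] | None = None
    n: int = 1000
    chi: float | None = 0.3           # None -> single deterministic simulation
    seed: int = 0
    t_equilibrate_h: float = 33.0
    t_stimulate_h: float = 10.0
    dt_s: float = 1.0
    output_stride_s: float = 60.0
    hold_h: float = 30.0
    window_h: tuple[float, float] = (20.0, 30.0)
    species: str = "NFkBn"
    prominence_frac: float = 0.05
    amplitude_floor: float = 6e-6
    sustain_threshold: float = 0.6
    min_peaks_sustained: int = 3
    steady_window: float = 0.1
    input: str | None = None          # trajectory CSV for features/classify
    targets: dict | None = None       # feature -> target value (fit)
    fit: dict = field(default_factory=dict)  # FitConfig overrides
    outdir: str = "out"

    def __post_init__(self):
        _net.Genotype.parse(list(self.genotype))  # validates gene names
        if self.column not in ("nominal", "fitted"):
            raise ValueError("column must be 'nominal' or 'fitted'")
        if self.chi is not None and not (0.0 <= self.chi < 1.0):
            raise ValueError("chi must lie in [0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict({**raw, **overrides})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        preset = raw.pop("preset", None)
        if preset is not None:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}; valid: {sorted(PRESETS)}")
            raw = {**PRESETS[preset], **raw}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("genotype", "tr_grid", "window_h"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genotype"] = list(self.genotype)
        d["window_h"] = list(self.window_h)
        if self.tr_grid is not None:
            d["tr_grid"] = list(self.tr_grid)
        return d

    # --- resolved library objects ------------------------------------------

    def load_params(self) -> _net.ParameterSet:
        return _net.load_parameter_table(self.table, self.column)

    def genotype_obj(self) -> _net.Genotype:
        return _net.Genotype.parse(list(self.genotype))

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(
            TR=self.TR,
            t_equilibrate_h=self.t_equilibrate_h,
            t_stimulate_h=self.t_stimulate_h,
            dt_s=self.dt_s,
            output_stride_s=self.output_stride_s,
        )

    def feature_settings(self) -> FeatureSettings:
        return FeatureSettings(
            peaks=PeakSettings(
                prominence_frac=self.prominence_frac,
                amplitude_floor=self.amplitude_floor,
            ),
            steady_window=self.steady_window,
            sustain_threshold=self.sustain_threshold,
            min_peaks_sustained=self.min_peaks_sustained,
        )


#: Convenience presets mapping to the canonical study conditions.
PRESETS: dict[str, dict] = {
    "wt-tr1": {},
    "a20-ko": {"genotype": ["A20"]},
    "bkeko": {"genotype": ["IkBb", "IkBe"]},
    "abko": {"genotype": ["IkBa", "IkBb"]},
    "aeko": {"genotype": ["IkBa", "IkBe"]},
    "tr-small": {"TR": 0.01},
    "dose-sweep": {"n": 50, "hold_h": 30.0, "window_h": [20.0, 30.0]},
}
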