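"""Result serialization with provenance.

Every output file either embeds the provenance record (JSON/YAML payloads)
or carries a leading ``# provenance:`` comment naming the sidecar
``provenance.yaml`` written alongside it, so two runs differing only in
output directory produce identical payloads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

__all__ = [
    "provenance_record",
    "write_provenance",
    "write_csv",
    "read_csv",
    "write_json",
]


def provenance_record(config_dict: dict, seed: int) -> dict:
    return {
        "package": "nfkbse",
        "version": __version__,
        "seed": int(seed),
        "config": config_dict,
    }


def write_provenance(outdir: str | Path, record: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "provenance.yaml"
    path.write_text(yaml.safe_dump(record, sort_keys=True))
    return path


def write_csv(df: pd.DataFrame, path: str | Path, provenance_ref: str = "provenance.yaml") -> Path:
    """CSV with a leading provenance comment line (readable via read_csv)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# provenance: {provenance_ref}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so written doubles come back bit-identical
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(payload: dict, path: str | Path, provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = dict(payload)
    if provenance is not None:
        body["provenance"] = provenance
    path.write_text(json.dumps(_jsonable(body), indent=2, sort_keys=True))
    return path
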