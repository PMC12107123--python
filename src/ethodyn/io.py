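"""Result serialization: CSV for tabular estimates, JSON for nested fits.

Round-trip stable: ``read_results(write_results(x), kind)`` reproduces the
numerical content of ``x`` (model back-references are not serialized).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .boutfit import CCDFBand, DistributionFit
from .dfa import DFAResults
from .hazard import HazardResults
from .predictivity import AMICurve, DecayFit

__all__ = ["write_results", "read_results", "write_sequence"]


def write_sequence(seq, path) -> Path:
    """Write a behavioral sequence as an ``index,state`` CSV (segment breaks
    encoded as index jumps)."""
    path = Path(path)
    idx = np.arange(len(seq))
    for b in seq.segment_breaks:
        idx[b:] += 2  # a gap of more than one window marks the break
    pd.DataFrame({"index": idx, "state": seq.states}).to_csv(path, index=False)
    return path


def write_results(obj, path) -> Path:
    """Serialize a results object; format chosen by type (CSV/JSON)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, HazardResults):
        df = obj.to_frame()
        df.attrs = {}
        header = f"# state={obj.state} display_cutoff={obj.display_cutoff}\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    elif isinstance(obj, (AMICurve, CCDFBand)):
        obj.to_frame().to_csv(path, index=False)
    elif isinstance(obj, DFAResults):
        pd.DataFrame({"box_size": obj.box_sizes,
                      "fluctuation": obj.fluctuation}).assign(
            state=obj.state, alpha=obj.alpha).to_csv(path, index=False)
    elif isinstance(obj, list) and obj and isinstance(obj[0], DistributionFit):
        payload = {f.family: _fit_dict(f) for f in obj}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    elif isinstance(obj, list) and obj and isinstance(obj[0], DecayFit):
        payload = {f.family: dataclasses.asdict(f) for f in obj}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    elif isinstance(obj, dict):
        path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
    else:
        raise TypeError(f"don't know how to serialize {type(obj).__name__}")
    return path


def _fit_dict(f: DistributionFit) -> dict:
    d = dataclasses.asdict(f)
    d["params"] = {k: float(v) for k, v in f.params.items()}
    return d


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _jsonable({k: v for k, v in dataclasses.asdict(x).items()
                          if k != "model"})
    return x


def read_results(path, kind: str):
    """Read back a serialized result.

    ``kind`` is one of ``hazard``, ``ami_curve``, ``ccdf``, ``dfa``,
    ``distribution_fits``, ``decay_fits``, ``json``.
    """
    path = Path(path)
    if kind == "hazard":
        with open(path) as fh:
            meta = fh.readline().lstrip("# ").split()
        df = pd.read_csv(path, comment="#")
        fields = dict(kv.split("=", 1) for kv in meta)
        return df, fields
    if kind == "ami_curve":
        df = pd.read_csv(path)
        return AMICurve(df["lag"].to_numpy(), df["ami"].to_numpy(),
                        df["ci_lo"].to_numpy(), df["ci_hi"].to_numpy(),
                        df["n_pairs"].to_numpy())
    if kind == "ccdf":
        df = pd.read_csv(path)
        return CCDFBand(df["t"].to_numpy(), df["ccdf"].to_numpy(),
                        df["ci_lo"].to_numpy(), df["ci_hi"].to_numpy())
    if kind == "dfa":
        return pd.read_csv(path)
    if kind == "distribution_fits":
        raw = json.loads(path.read_text())
        fits = [DistributionFit(**v) for v in raw.values()]
        fits.sort(key=lambda f: (f.aic, f.n_params))
        return fits
    if kind == "decay_fits":
        raw = json.loads(path.read_text())
        fits = [DecayFit(**v) for v in raw.values()]
        fits.sort(key=lambda f: f.aic)
        return fits
    if kind == "json":
        return json.loads(path.read_text())
    raise ValueError(f"unknown kind {kind!r}")
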