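"""Plain-text serialization: segment CSV, filter-trace CSV and YAML config.

Segment files carry their metadata in a single comment header line so a
directory of segments is self-describing; floats are printed with 17
significant digits so a round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ckf import FilterConfig, FilterTrace
from .model import ModelParameters, Segment, SigmoidParameters, TypePreset

__all__ = [
    "write_segment",
    "read_segment",
    "write_trace",
    "load_config",
    "dump_config",
]


def write_segment(seg: Segment, path: str | Path) -> None:
    path = Path(path)
    header = f"# fs={seg.fs:.17g} kind={seg.kind} label={seg.label} seed={seg.seed}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for v in seg.samples:
            fh.write(f"{v:.17g}\n")


def read_segment(path: str | Path) -> Segment:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        meta = {}
        if first.startswith("#"):
            for tok in first.lstrip("#").split():
                k, _, v = tok.partition("=")
                meta[k] = v
            samples = np.loadtxt(fh, ndmin=1)
        else:
            samples = np.loadtxt(path, ndmin=1)
    seed = meta.get("seed")
    return Segment(
        samples=samples,
        fs=float(meta.get("fs", 480.0)),
        kind=meta.get("kind", "recorded"),
        label=meta.get("label", "unknown"),
        seed=None if seed in (None, "None") else int(seed),
    )


def write_trace(trace: FilterTrace, path: str | Path) -> None:
    """Filter trace as CSV with the configuration echoed in comment lines."""
    path = Path(path)
    n = len(trace)
    cols = {f"x{i + 1}": trace.x_hat[:, i] for i in range(trace.x_hat.shape[1])}
    df = pd.DataFrame(
        {"step": np.arange(n), "time_s": np.arange(n) / trace.fs}
        | cols
        | {"i_ba": trace.i_ba, "innovation": trace.innovation}
    )
    cfg = trace.config
    with open(path, "w") as fh:
        fh.write(f"# fs={trace.fs:.17g} measurement={cfg.measurement} "
                 f"A={cfg.model.A:.17g} G={cfg.model.G:.17g} "
                 f"q_states={cfg.q_states:.17g} q_param={cfg.q_param:.17g} "
                 f"r_meas={cfg.r_meas:.17g} "
                 f"x12_bounds={cfg.x12_bounds[0]:.17g}:{cfg.x12_bounds[1]:.17g}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def dump_config(params: ModelParameters, path: str | Path, *, presets=None, **extra) -> None:
    """Write model constants (and optional presets / run settings) as YAML."""
    doc: dict = {"model": dataclasses.asdict(params)}
    if presets is not None:
        doc["presets"] = [dataclasses.asdict(p) for p in presets]
    doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> dict:
    """Read a YAML config into {'model': ModelParameters, 'presets': [...], ...}."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out = dict(doc)
    if "model" in doc:
        m = dict(doc["model"])
        if "sigmoid" in m:
            m["sigmoid"] = SigmoidParameters(**m["sigmoid"])
        out["model"] = ModelParameters(**m)
    if "presets" in doc:
        out["presets"] = [TypePreset(**p) for p in doc["presets"]]
    if "filter" in doc:
        f = dict(doc["filter"])
        if "x12_bounds" in f:
            f["x12_bounds"] = tuple(f["x12_bounds"])
        out["filter"] = f
    return out
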