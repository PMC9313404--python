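"""Shared fixtures.

The expensive fixtures (filter runs over many simulated segments) are
session-scoped and shared between the behavioural tests and the
acceptance tests so each segment is simulated and filtered once.
"""

from __future__ import annotations

import numpy as np
import pytest

from epikf.ckf import FilterConfig, run_filter, summarize_iba
from epikf.model import ModelParameters, TypePreset, generate_type_set

PRESET_ORDER = ["I", "II", "III", "IV", "Normal"]
PRESET_RATIOS = {"I": 3.0, "II": 4.0, "III": 6.0, "IV": 8.0, "Normal": 10.0}


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    return ModelParameters()


def _estimates(kind: str, label: str, n: int, seed: int, base: ModelParameters) -> list[float]:
    preset = TypePreset(label, base.A, PRESET_RATIOS[label] * base.A)
    pairs = generate_type_set([preset], n, 5.0, 480.0, seed, base=base)
    out = []
    for z, y in pairs:
        seg = z if kind == "z" else y
        cfg = FilterConfig.for_segment(seg, model=base)
        out.append(summarize_iba(run_filter(seg, cfg)))
    return out


@pytest.fixture(scope="session")
def z_iba(base_params) -> dict[str, list[float]]:
    """Filter estimates on DC-preserved z segments, 10 per activity type."""
    return {lab: _estimates("z", lab, 10, 1, base_params) for lab in PRESET_ORDER}


@pytest.fixture(scope="session")
def y_iba(base_params) -> dict[str, list[float]]:
    """Filter estimates on AC-coupled y segments: 30 Type I, 8 each of II-IV."""
    out = {"I": _estimates("y", "I", 30, 1, base_params)}
    for lab in ("II", "III", "IV"):
        out[lab] = _estimates("y", lab, 8, 1, base_params)
    return out


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
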