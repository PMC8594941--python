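"""Genotype presets composing circuit, channel and release parameters."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .channels import CavParams, ClCaParams
from .circuit import CircuitState
from .release import ReleaseParams


@dataclass
class GenotypePreset:
    label: str  # "wt" or "ko"
    circuit: CircuitState
    cav: CavParams
    clca: ClCaParams
    release: ReleaseParams


def _build(label: str, raw: dict) -> GenotypePreset:
    circ = dict(raw["circuit"])
    if "r_a_MOhm" in circ:
        circ["g_s_nS"] = 1e3 / circ.pop("r_a_MOhm")
    return GenotypePreset(
        label=label,
        circuit=CircuitState(**circ),
        cav=CavParams(**raw["cav"]),
        clca=ClCaParams(**raw.get("clca", {})),
        release=ReleaseParams(**raw["release"]),
    )


def load_presets(path: str | None = None) -> dict[str, GenotypePreset]:
    if path is None:
        text = (resources.files("rodribbon") / "data" / "presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {k: _build(k, v) for k, v in raw.items()}


def get_preset(label: str) -> GenotypePreset:
    presets = load_presets()
    if label not in presets:
        raise ValueError(f"unknown preset {label!r}; have {sorted(presets)}")
    return presets[label]
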