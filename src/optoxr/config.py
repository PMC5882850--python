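"""Layered run configuration: defaults < config file < command-line flags.

The namespace is flat with dotted per-module keys (``topology.window``,
``construct.linker`` ...) so resolved configurations diff cleanly and can be
serialized verbatim into output manifests. Every key carries provenance
(``default`` | ``file`` | ``flag``); unknown keys and type mismatches are
rejected before any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .errors import ConfigError

DEFAULTS: dict[str, Any] = {
    # topology calling
    "topology.window": 9,
    "topology.threshold": 0.2,
    "topology.min_tm_len": 15,
    "topology.max_tm_len": 30,
    "topology.min_loop_len": 4,
    "topology.orientation": "extracellular",
    # pairwise / star alignment
    "align.matrix": "BLOSUM62",
    "align.gap_open": 10,
    "align.gap_extend": 1,
    # chimera assembly
    "chimera.swap": "IL1,IL2,IL3,Ct",
    # cassette compilation
    "construct.host": "Mus musculus",
    "construct.style": "direct_fusion",
    "construct.linker": "GCGGCCGCC",
    "construct.stop_codon": "TAA",
    "construct.upstream_site": "KpnI",
    "construct.downstream_site": "BamHI",
    "construct.promoter": "hSyn",
    # primer design / screening
    "primers.primer_len_min": 18,
    "primers.primer_len_max": 25,
    "primers.amplicon_min": 80,
    "primers.amplicon_max": 300,
    "primers.junction_anchor": 6,
    "primers.max_mismatch": 2,
    "primers.three_prime_exact": 5,
    "primers.max_product": 2000,
    # scenario simulation
    "simulate.n_homologs": 5,
    "simulate.sub_rate": 0.05,
    "simulate.n_samples": 3,
    "simulate.n_replicates": 3,
    "simulate.qpcr_noise_sd": 0.3,
    "simulate.qpcr_folds": "4.0",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved parameter set with per-key provenance."""

    values: dict[str, Any]
    provenance: dict[str, str]

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def section(self, prefix: str) -> dict[str, Any]:
        """All keys of one module, with the prefix stripped."""
        p = prefix + "."
        return {k[len(p):]: v for k, v in self.values.items() if k.startswith(p)}

    def as_manifest(self) -> dict[str, dict[str, Any]]:
        return {
            k: {"value": self.values[k], "provenance": self.provenance[k]}
            for k in sorted(self.values)
        }


def _flatten(mapping: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in mapping.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def _check_type(key: str, value: Any, default: Any) -> Any:
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"key {key!r}: expected bool, got {value!r}")
        return value
    if isinstance(default, int) and not isinstance(default, bool):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"key {key!r}: expected int, got {value!r}")
        return value
    if isinstance(default, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"key {key!r}: expected number, got {value!r}")
        return float(value)
    if isinstance(default, str):
        if not isinstance(value, str):
            raise ConfigError(f"key {key!r}: expected string, got {value!r}")
        return value
    return value


def resolve_config(
    defaults: Optional[Mapping[str, Any]] = None,
    config_file: Optional[str] = None,
    flags: Optional[Mapping[str, Any]] = None,
) -> RunConfig:
    """Resolve the layered configuration (precedence: flags > file > defaults)."""
    base = dict(DEFAULTS if defaults is None else defaults)
    values = dict(base)
    provenance = {k: "default" for k in base}

    if config_file:
        raw = yaml.safe_load(Path(config_file).read_text()) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {config_file} must be a mapping")
        for key, value in _flatten(raw).items():
            if key not in base:
                raise ConfigError(f"unknown configuration key {key!r}")
            values[key] = _check_type(key, value, base[key])
            provenance[key] = "file"

    for key, value in (flags or {}).items():
        if value is None:
            continue
        if key not in base:
            raise ConfigError(f"unknown configuration key {key!r}")
        values[key] = _check_type(key, value, base[key])
        provenance[key] = "flag"

    return RunConfig(values=values, provenance=provenance)
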