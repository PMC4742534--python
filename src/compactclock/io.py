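"""Configuration and table I/O.

* Parameter files are flat ``name = value`` text, one parameter per line,
  ``#`` comments allowed; the shipped reference set lives in
  ``compactclock/data/params_ref.txt`` (core clock) and
  ``params_hypocotyl_ref.txt`` (output module).
* Genotype presets can be extended from a YAML mapping of mutant name to
  ``{tx_scale: {...}, ox: {...}}``.
* Light-protocol specs are YAML/dict with a ``type`` key
  (``ld`` | ``skeleton`` | ``constant`` | ``composite``).
* Scan results are written as TSV with a ``#``-prefixed metadata header.

Units everywhere: hours, with ZT0 = lights-on of the entraining cycle.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import pandas as pd
import yaml

from .clock_model import Genotype, PARAM_NAMES, ParameterSet
from .hypocotyl import HYPOCOTYL_PARAM_NAMES, HypocotylParams
from .light_protocols import (
    CompositeProtocol,
    LightProtocol,
    constant,
    entrain_release,
    ld_cycle,
    skeleton,
)

__all__ = [
    "read_param_file",
    "write_param_file",
    "load_reference_parameters",
    "load_reference_hypocotyl_parameters",
    "load_genotypes",
    "parse_protocol",
    "write_table",
    "param_file_hash",
]


def _parse_flat(text: str) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: expected 'name = value', got {raw!r}")
        name, value = (s.strip() for s in line.split("=", 1))
        out[name] = float(value)
    return out


def read_param_file(path: Union[str, Path]) -> ParameterSet:
    """Read a 34-parameter clock set from flat name=value text."""
    return ParameterSet.from_dict(_parse_flat(Path(path).read_text()))


def read_hypocotyl_param_file(path: Union[str, Path]) -> HypocotylParams:
    return HypocotylParams.from_dict(_parse_flat(Path(path).read_text()))


def write_param_file(params, path: Union[str, Path],
                     header: Optional[str] = None) -> None:
    """Write a parameter set (clock or hypocotyl) as flat text."""
    lines = []
    if header:
        lines += [f"# {ln}" for ln in header.splitlines()]
    for name, value in params.to_dict().items():
        lines.append(f"{name} = {value:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def param_file_hash(path: Union[str, Path]) -> str:
    """Short content hash recorded in output-table metadata."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _data_text(name: str) -> str:
    return resources.files("compactclock").joinpath("data", name).read_text()


def load_reference_parameters() -> ParameterSet:
    """The shipped optimized 34-parameter clock set."""
    return ParameterSet.from_dict(_parse_flat(_data_text("params_ref.txt")))


def load_reference_hypocotyl_parameters() -> HypocotylParams:
    """The shipped 9-parameter hypocotyl set (fitted after the clock)."""
    return HypocotylParams.from_dict(
        _parse_flat(_data_text("params_hypocotyl_ref.txt")))


def load_genotypes(path: Union[str, Path]) -> Dict[str, Genotype]:
    """Load extra genotype definitions from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: Dict[str, Genotype] = {}
    for name, spec in raw.items():
        spec = spec or {}
        out[name] = Genotype(name=name,
                             tx_scale=dict(spec.get("tx_scale", {})),
                             ox=dict(spec.get("ox", {})))
    return out


def parse_protocol(spec: Union[str, Path, Mapping]):
    """Build a protocol from a YAML file path or an already-parsed dict.

    Schemas::

        {type: ld, photoperiod: 8, cycle_length: 24}
        {type: skeleton, pulse1: 3, gap1: 6, pulse2: 3, gap2: 12}
        {type: constant, L: 1}
        {type: composite, entrain: {...}, n_cycles: 16, release: {...}}
    """
    if isinstance(spec, (str, Path)):
        spec = yaml.safe_load(Path(spec).read_text())
    if not isinstance(spec, Mapping) or "type" not in spec:
        raise ValueError("protocol spec must be a mapping with a 'type' key")
    kind = spec["type"]
    if kind == "ld":
        return ld_cycle(float(spec["photoperiod"]),
                        float(spec.get("cycle_length", 24.0)))
    if kind == "skeleton":
        return skeleton(float(spec["pulse1"]), float(spec["gap1"]),
                        float(spec["pulse2"]), float(spec["gap2"]))
    if kind == "constant":
        return constant(int(spec["L"]))
    if kind == "composite":
        return entrain_release(parse_protocol(spec["entrain"]),
                               int(spec["n_cycles"]),
                               parse_protocol(spec["release"]))
    raise ValueError(f"unknown protocol type {kind!r}")


def write_table(df: pd.DataFrame, path: Union[str, Path],
                metadata: Optional[Mapping] = None) -> None:
    """TSV writer with ``#``-prefixed provenance header."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
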