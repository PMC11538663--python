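"""Config parsing, TSV serialization, and run manifests.

All on-disk formats are plain text: network configs are YAML, tabular
results are TSV with a header row.  A :class:`RunManifest` records the
seeds, config hash, and output files of a pipeline run so that reruns
are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .network import NetworkSpec

__all__ = [
    "load_config",
    "dump_config",
    "load_cac_network",
    "params_to_table",
    "params_from_table",
    "RunManifest",
]


def load_config(path) -> NetworkSpec:
    """Load and validate a network config from a YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return NetworkSpec.from_dict(d)


def loads_config(text: str) -> NetworkSpec:
    d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError("config must be a YAML mapping")
    return NetworkSpec.from_dict(d)


def dump_config(net: NetworkSpec, path=None) -> str:
    """Serialize a network to YAML; round-trips losslessly."""
    text = yaml.safe_dump(net.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_cac_network(**input_levels) -> NetworkSpec:
    """Load the packaged cancer-adipose conversion network.

    The packaged parameter set is a synthetic reconstruction: the wiring
    follows the published circuit description and the kinetic constants
    were calibrated against the printed bifurcation thresholds and
    drug-condition attractor counts (see the calibration script).
    Keyword arguments override drug input levels, e.g.
    ``load_cac_network(TGFB=4.3, MEKI=0.02, ROSI=1.5)``.
    """
    ref = resources.files("caclandscape") / "data" / "cac_network_synthetic.yaml"
    net = loads_config(ref.read_text())
    if input_levels:
        net = net.with_inputs(**input_levels)
    return net


def params_to_table(net: NetworkSpec) -> pd.DataFrame:
    """Tabular parameter export: columns (parameter, entity, value, units)."""
    rows = []
    units = {"g": "conc/time", "k": "1/time", "lam": "fold", "S": "conc", "n": "1",
             "input": "conc"}
    for name in net.parameter_names():
        fld, _, entity = name.partition(":")
        rows.append({"parameter": name, "entity": entity,
                     "value": net.get_param(name), "units": units[fld]})
    return pd.DataFrame(rows)


def params_from_table(net: NetworkSpec, table: pd.DataFrame) -> NetworkSpec:
    """Apply a parameter table (as written by :func:`params_to_table`)."""
    return net.with_params(dict(zip(table["parameter"], table["value"])))


def _hash_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash, seeds, outputs, timings."""

    config_hash: str
    seed: int
    stages: list = dc_field(default_factory=list)
    outputs: dict = dc_field(default_factory=dict)

    @classmethod
    def for_network(cls, net: NetworkSpec, seed: int) -> "RunManifest":
        return cls(config_hash=_hash_text(dump_config(net)), seed=seed)

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the manifest seed (documented rule)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def record(self, stage: str, elapsed: float, outputs: dict | None = None):
        self.stages.append({"stage": stage, "elapsed_s": round(elapsed, 3)})
        for key, pth in (outputs or {}).items():
            self.outputs[f"{stage}:{key}"] = str(pth)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a TSV with an optional leading '#' comment line (units etc.)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
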