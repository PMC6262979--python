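"""Reading and writing ΔF/F matrices, configurations, and sweep specs."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import h5py
import numpy as np
import yaml

from .arrays import AssemblyConfiguration, GeneratorParams
from .harness import SweepSpec
from .simulate import DffMatrix, SimulationParams

__all__ = [
    "save_dff",
    "load_dff",
    "save_configuration",
    "load_configuration",
    "load_sweep_spec",
]


def save_dff(
    path: str | Path,
    dff: DffMatrix,
    params: SimulationParams,
    seed: int | None = None,
) -> None:
    """Write ΔF/F (dataset ``dff``, neurons x bins) with params as attrs."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("dff", data=dff.dff)
        f.create_dataset("baseline", data=dff.baseline)
        for fld in dataclasses.fields(params):
            value = getattr(params, fld.name)
            if isinstance(value, float) and math.isinf(value):
                value = "inf"
            ds.attrs[fld.name] = value
        if seed is not None:
            ds.attrs["seed"] = seed


def load_dff(path: str | Path) -> tuple[DffMatrix, SimulationParams, int | None]:
    """Read a ΔF/F file written by :func:`save_dff`."""
    with h5py.File(path, "r") as f:
        ds = f["dff"]
        dff = DffMatrix(dff=ds[...], baseline=f["baseline"][...])
        attrs = dict(ds.attrs)
    seed = attrs.pop("seed", None)
    kwargs = {}
    for fld in dataclasses.fields(SimulationParams):
        if fld.name in attrs:
            v = attrs[fld.name]
            if isinstance(v, (bytes, str)) and str(v) == "inf":
                v = math.inf
            if isinstance(v, np.ndarray):
                v = tuple(v.tolist())
            kwargs[fld.name] = v
    return dff, SimulationParams(**kwargs), None if seed is None else int(seed)


def save_configuration(path: str | Path, config: AssemblyConfiguration) -> None:
    Path(path).write_text(config.to_json())


def load_configuration(path: str | Path) -> AssemblyConfiguration:
    return AssemblyConfiguration.from_json(Path(path).read_text())


def load_sweep_spec(path: str | Path) -> SweepSpec:
    """Build a :class:`SweepSpec` from a YAML/JSON config file.

    Recognised top-level keys mirror the dataclass fields; ``sim_params``
    and ``gen_params`` are nested mappings with the benchmark parameter
    names (``kappa: inf`` is accepted).
    """
    text = Path(path).read_text()
    obj = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    sim_kwargs = obj.pop("sim_params", {})
    if str(sim_kwargs.get("kappa", "")).lower() in ("inf", "infinity"):
        sim_kwargs["kappa"] = math.inf
    if "R" in sim_kwargs:
        sim_kwargs["R"] = tuple(sim_kwargs["R"])
    gen_kwargs = obj.pop("gen_params", {})
    if "overlap_range" in gen_kwargs:
        gen_kwargs["overlap_range"] = tuple(gen_kwargs["overlap_range"])
    return SweepSpec(
        sim_params=SimulationParams(**sim_kwargs),
        gen_params=GeneratorParams(**gen_kwargs),
        **obj,
    )
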