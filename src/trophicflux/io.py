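"""Delimited-text readers/writers, parameter tables, and run configuration.

All artifact files are comma-separated, dot-decimal, UTF-8 text with a
``#`` comment header declaring the dialect — community-ecology inputs
are spreadsheets, so no binary formats.  Every writer emits the header;
every reader skips comments.  Round-tripping a web through
write -> read is the identity on the data model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allometry import LengthMassRegression, MetabolicRegression
from .exceptions import ConfigError
from .flux_engine import FluxSolution
from .function_metrics import FunctionReport, report_frame
from .sensitivity import SensitivityReport
from .web_model import FoodWeb, build_web

_HEADER = "# trophicflux {kind}; comma-separated, dot-decimal, UTF-8\n"

NODE_COLUMNS = [
    "node_id", "name", "guild", "resource_type", "biomass",
    "abundance", "mean_body_mass", "loss", "is_basal",
]
LINK_COLUMNS = ["resource_id", "consumer_id", "active_weight"]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path, comment="#", skip_blank_lines=True, float_precision="round_trip"
    )


def _write_table(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.format(kind=kind))
        df.to_csv(fh, index=False, float_format="%.17g")  # exact float round-trip


# ---------------------------------------------------------------------------
# webs


def read_nodes(path) -> pd.DataFrame:
    return _read_table(path)


def read_links(path) -> pd.DataFrame:
    return _read_table(path)


def read_body_masses(path) -> pd.DataFrame:
    """Long-format per-individual masses: columns node_id, body_mass."""
    return _read_table(path)


def read_web(
    nodes_path,
    links_path,
    body_masses_path=None,
    losses_per_unit_biomass: bool = True,
    temperature_C: float = 20.0,
    units: dict | None = None,
) -> FoodWeb:
    nodes = read_nodes(nodes_path)
    links = read_links(links_path)
    records = nodes.to_dict("records")
    if body_masses_path is not None:
        bm = read_body_masses(body_masses_path)
        per_node = bm.groupby("node_id")["body_mass"].apply(list).to_dict()
        for rec in records:
            masses = per_node.get(rec["node_id"])
            if masses:
                rec["body_masses"] = tuple(float(m) for m in masses)
    return build_web(
        records,
        links,
        options=dict(
            losses_per_unit_biomass=losses_per_unit_biomass,
            temperature_C=temperature_C,
            units=units or {},
        ),
    )


def write_web(web: FoodWeb, nodes_path, links_path, body_masses_path=None) -> None:
    nrows = []
    for nd in web.nodes:
        nrows.append(
            dict(
                node_id=nd.node_id,
                name=nd.name,
                guild=nd.guild,
                resource_type=nd.resource_type,
                biomass=nd.biomass,
                abundance=nd.abundance,
                mean_body_mass=nd.mean_body_mass,
                loss=nd.loss,
                is_basal=nd.is_basal,
            )
        )
    _write_table(pd.DataFrame(nrows, columns=NODE_COLUMNS), nodes_path, "nodes table")
    lrows = [
        dict(resource_id=lk.resource_id, consumer_id=lk.consumer_id, active_weight=lk.active_weight)
        for lk in web.links
    ]
    _write_table(pd.DataFrame(lrows, columns=LINK_COLUMNS), links_path, "links table")
    if body_masses_path is not None:
        mrows = [
            dict(node_id=nd.node_id, body_mass=m)
            for nd in web.nodes
            if nd.body_masses is not None
            for m in nd.body_masses
        ]
        _write_table(
            pd.DataFrame(mrows, columns=["node_id", "body_mass"]),
            body_masses_path,
            "individual body-mass table",
        )


# ---------------------------------------------------------------------------
# parameter tables


def read_efficiency_table(path_or_buffer):
    """Returns (mapping resource_type -> e, reference_temperature_C, sources)."""
    df = _read_table(path_or_buffer)
    table = dict(zip(df["resource_type"].astype(str), df["e"].astype(float)))
    ref = (
        float(df["reference_temperature_C"].iloc[0])
        if "reference_temperature_C" in df
        else 20.0
    )
    sources = dict(zip(df["resource_type"].astype(str), df.get("source", "")))
    return table, ref, sources


def load_default_efficiency_table():
    with resources.files("trophicflux.data").joinpath(
        "assimilation_efficiencies.csv"
    ).open("r", encoding="utf-8") as fh:
        return read_efficiency_table(fh)


def read_metabolic_regressions(path_or_buffer) -> dict[str, MetabolicRegression]:
    df = _read_table(path_or_buffer)
    out = {}
    for rec in df.to_dict("records"):
        out[str(rec["key"])] = MetabolicRegression(
            key=str(rec["key"]),
            ln_x0=float(rec["ln_x0"]),
            mass_exp=float(rec["mass_exp"]),
            activation_energy_eV=float(rec.get("activation_energy_eV", 0.0) or 0.0),
            mass_unit=str(rec.get("mass_unit", "mg")),
            out_unit=str(rec.get("out_unit", "J/h")),
            source=str(rec.get("source", "")),
        )
    return out


def load_default_metabolic_regressions() -> dict[str, MetabolicRegression]:
    with resources.files("trophicflux.data").joinpath(
        "metabolic_regressions.csv"
    ).open("r", encoding="utf-8") as fh:
        return read_metabolic_regressions(fh)


def read_length_mass_regressions(path_or_buffer) -> dict[str, LengthMassRegression]:
    df = _read_table(path_or_buffer)
    out = {}
    for rec in df.to_dict("records"):
        ew = rec.get("exp_width")
        if ew is not None and isinstance(ew, float) and np.isnan(ew):
            ew = None
        out[str(rec["key"])] = LengthMassRegression(
            key=str(rec["key"]),
            scale=str(rec["scale"]),
            intercept=float(rec["intercept"]),
            exp_length=float(rec["exp_length"]),
            exp_width=None if ew is None else float(ew),
            mass_basis=str(rec.get("mass_basis", "fresh")),
            in_unit=str(rec.get("in_unit", "mm")),
            out_unit=str(rec.get("out_unit", "mg")),
            source=str(rec.get("source", "")),
        )
    return out


def load_default_length_mass_regressions() -> dict[str, LengthMassRegression]:
    with resources.files("trophicflux.data").joinpath(
        "length_mass_regressions.csv"
    ).open("r", encoding="utf-8") as fh:
        return read_length_mass_regressions(fh)


# ---------------------------------------------------------------------------
# results


def write_flux_solution(
    solution: FluxSolution,
    web: FoodWeb,
    links_path,
    nodes_path,
    losses=None,
) -> None:
    """Write per-link fluxes and the per-node summary (G, L, X, residual)."""
    _write_table(solution.link_frame(web), links_path, "link fluxes")
    X = web.node_loss_vector() if losses is None else np.asarray(losses, dtype=float)
    df = pd.DataFrame(
        {
            "node_id": list(solution.node_ids),
            "G": solution.consumption,
            "L": solution.loss_to_consumption,
            "X": X,
            "residual": solution.residuals,
        }
    )
    _write_table(df, nodes_path, "node flux summary")


def write_flux_matrix(solution: FluxSolution, path) -> None:
    """Matrix export, consumers in columns and resources in rows."""
    df = pd.DataFrame(
        solution.flux, index=list(solution.node_ids), columns=list(solution.node_ids)
    )
    df.index.name = "resource_id"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.format(kind="flux matrix (consumers in columns)"))
        df.to_csv(fh, float_format="%.17g")


def write_function_report(reports: list[FunctionReport], path) -> None:
    _write_table(report_frame(reports), path, "function-flux report")


def write_sensitivity_report(report: SensitivityReport, nodes_path, links_path, trace_path=None) -> None:
    _write_table(report.node_frame(), nodes_path, "sensitivity node report")
    _write_table(report.link_frame(), links_path, "sensitivity link report")
    if trace_path is not None and report.factors is not None:
        rows = [
            {"draw": d, **{f"f{i}": v for i, v in enumerate(fac)}}
            for d, fac in enumerate(report.factors)
        ]
        _write_table(pd.DataFrame(rows), trace_path, "sensitivity factor trace")


# ---------------------------------------------------------------------------
# configuration and provenance


@dataclass
class RunConfig:
    """One energy-flux run, start to finish (the Table-1 pipeline)."""

    nodes: str
    links: str
    body_masses: str | None = None
    efficiencies: str | None = None  # path; bundled defaults if None
    regressions: str | None = None  # path; bundled defaults if None
    temperature_C: float = 20.0
    losses_per_unit_biomass: bool = True
    use_biomass_preferences: bool = True
    efficiency_level: str = "resource"
    fmr_multiplier: float = 1.0
    out_dir: str = "."
    seed: int | None = None
    units: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.temperature_C <= -273.15:
            raise ConfigError("temperature below absolute zero")
        if self.fmr_multiplier <= 0:
            raise ConfigError("fmr_multiplier must be > 0")
        if self.efficiency_level not in ("resource", "consumer"):
            raise ConfigError("efficiency_level must be 'resource' or 'consumer'")


def load_run_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, inputs: dict, seed=None, parameters: dict | None = None) -> dict:
    """Machine-readable provenance: input hashes, seed, parameter notes."""
    block = {
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
        "seed": seed,
        "parameters": parameters or {},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(block, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return block
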