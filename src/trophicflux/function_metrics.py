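"""Aggregate link fluxes into ecosystem-process proxies.

The summed flux out of all plant nodes is a proxy for herbivory, out of
detritus for detritivory, and out of animal nodes for predation (the
*out-of-resource* convention, matching the definition of F as flux out
of the resource node).  The *into-consumer* convention instead sums flux
arriving at consumers of a named guild (herbivore / detritivore /
predator) — the two agree on simple webs but differ when omnivores blur
the classes, so both are exposed and the convention is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flux_engine import FluxSolution
from .web_model import FoodWeb

PROCESSES = ("herbivory", "detritivory", "predation")

_RESOURCE_TYPE_OF = {"herbivory": "plant", "detritivory": "detritus", "predation": "animal"}
_CONSUMER_GUILD_OF = {
    "herbivory": "herbivore",
    "detritivory": "detritivore",
    "predation": "predator",
}


@dataclass
class FunctionReport:
    """Process-name -> flux mapping for one web."""

    values: dict[str, float]
    convention: str
    web_id: str = ""
    multifunctionality: float | None = field(default=None, compare=False)

    def __getitem__(self, process: str) -> float:
        return self.values[process]


def function_flux(
    solution: FluxSolution,
    web: FoodWeb,
    process: str,
    convention: str = "out-of-resource",
) -> float:
    """Summed flux for one process class.

    ``out-of-resource``: sum of F over links whose resource node has the
    process's resource type (plant / detritus / animal).
    ``into-consumer``: sum of F over links whose consumer node has the
    process's guild (herbivore / detritivore / predator).
    """
    if process not in PROCESSES:
        raise ValueError(f"unknown process {process!r}; choose from {PROCESSES}")
    if convention not in ("out-of-resource", "into-consumer"):
        raise ValueError(f"unknown convention {convention!r}")
    F = solution.flux
    if convention == "out-of-resource":
        rt = _RESOURCE_TYPE_OF[process]
        rows = [i for i, nd in enumerate(web.nodes) if nd.resource_type == rt]
        return float(F[rows, :].sum())
    guild = _CONSUMER_GUILD_OF[process]
    cols = [i for i, nd in enumerate(web.nodes) if nd.guild == guild]
    return float(F[:, cols].sum())


def total_flux(solution: FluxSolution) -> float:
    """Sum of all link fluxes in the solution."""
    return float(solution.flux.sum())


def compute_function_report(
    solution: FluxSolution,
    web: FoodWeb,
    processes=PROCESSES,
    convention: str = "out-of-resource",
    web_id: str = "",
) -> FunctionReport:
    values = {p: function_flux(solution, web, p, convention) for p in processes}
    return FunctionReport(values=values, convention=convention, web_id=web_id)


def multifunctionality_index(reports: list[FunctionReport], processes=PROCESSES) -> np.ndarray:
    """Average-z multifunctionality across webs.

    Each process is z-scored across the supplied webs; a web's index is
    the mean of its z-scores.  This is one of several reasonable indices
    (unweighted average-z); zero-variance processes carry no comparative
    information and are dropped with a warning.
    """
    if len(reports) < 2:
        raise ValueError("need at least two webs to compare")
    mat = np.array([[rep.values[p] for p in processes] for rep in reports], dtype=float)
    keep = []
    for j, p in enumerate(processes):
        if np.std(mat[:, j]) == 0:
            warnings.warn(
                f"process {p!r} has zero variance across webs; dropped from "
                "the multifunctionality index",
                UserWarning,
                stacklevel=2,
            )
        else:
            keep.append(j)
    if not keep:
        return np.zeros(len(reports))
    sub = mat[:, keep]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
    idx = z.mean(axis=1)
    for rep, v in zip(reports, idx):
        rep.multifunctionality = float(v)
    return idx


def report_frame(reports: list[FunctionReport]) -> pd.DataFrame:
    """Long-format export: web_id, process, convention, value."""
    rows = [
        (rep.web_id, p, rep.convention, v)
        for rep in reports
        for p, v in rep.values.items()
    ]
    return pd.DataFrame(rows, columns=["web_id", "process", "convention", "value"])
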