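"""Realized feeding preferences and assimilation efficiencies.

Preferences follow the standard active x passive decomposition: the
realized diet share of resource r in consumer c's diet is

    W[r, c] = w_rc * B_r / sum_r' (w_r'c * B_r')      (passive x active)

where w is the consumer's active choice weight (equal weights being the
null assumption) and B is resource biomass (encounter-rate proxy).
Columns are normalized per consumer; basal columns are zero.

Assimilation efficiency e_a — the fraction of ingested energy absorbed
through the gut wall rather than egested — is conventionally assigned by
resource type.  The bundled literature means at 20 °C are 0.158 for
detritus, 0.545 for plant and 0.906 for animal resources (Lang et al.
2017).  Temperature dependence of e_a is supported through a pluggable
hook; the default is the identity (constant e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .exceptions import EfficiencyError, PreferenceError
from .web_model import FoodWeb

#: Literature-mean assimilation efficiencies by resource type at 20 °C.
DEFAULT_EFFICIENCIES: dict[str, float] = {
    "detritus": 0.158,
    "plant": 0.545,
    "animal": 0.906,
}
DEFAULT_EFFICIENCY_REFERENCE_C = 20.0


@dataclass
class PreferenceMatrix:
    """Column-normalized realized diet shares, consumers in columns."""

    matrix: np.ndarray
    node_ids: tuple[str, ...]
    mode: str  # active-only | passive-only | combined | user-supplied

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.node_ids)
        if self.matrix.shape != (n, n):
            raise PreferenceError("preference matrix shape does not match node list")
        if np.any(self.matrix < 0):
            raise PreferenceError("preference entries must be nonnegative")
        colsum = self.matrix.sum(axis=0)
        bad = [
            self.node_ids[j]
            for j in range(n)
            if colsum[j] > 0 and abs(colsum[j] - 1.0) > 1e-12
        ]
        if bad:
            raise PreferenceError(f"consumer columns not normalized: {bad}")

    def column(self, consumer_id: str) -> np.ndarray:
        return self.matrix[:, self.node_ids.index(consumer_id)]

    def share(self, resource_id: str, consumer_id: str) -> float:
        return float(
            self.matrix[self.node_ids.index(resource_id), self.node_ids.index(consumer_id)]
        )


@dataclass
class EfficiencyAssignment:
    """Per-node assimilation efficiencies.

    ``level`` is ``resource`` (e indexed by the node being eaten — the
    usual choice, since a mixed diet spans resource types) or
    ``consumer`` (e indexed by the feeding node).  Entries are NaN where
    no efficiency is defined (e.g. basal nodes at consumer level).
    """

    level: str
    e: np.ndarray
    node_ids: tuple[str, ...]
    reference_temperature_C: float = DEFAULT_EFFICIENCY_REFERENCE_C
    source: str = ""

    def __post_init__(self):
        if self.level not in ("resource", "consumer"):
            raise EfficiencyError("level must be 'resource' or 'consumer'")
        self.e = np.asarray(self.e, dtype=float)
        defined = self.e[np.isfinite(self.e)]
        if np.any(defined <= 0) or np.any(defined > 1):
            raise EfficiencyError("efficiencies must lie in (0, 1]")

    def value(self, node_id: str) -> float:
        return float(self.e[self.node_ids.index(node_id)])


def compute_preferences(web: FoodWeb, use_biomass: bool = True) -> PreferenceMatrix:
    """Realized diet-share matrix W for a web.

    With ``use_biomass`` (passive x active), shares are active weights
    times resource biomass, column-normalized; otherwise active weights
    only (equal weights where unspecified — the null assumption).

    A consumer whose passive denominator is zero falls back to its
    explicit active weights (with a warning) when it has any; otherwise
    normalization is impossible and a :class:`PreferenceError` is raised.
    """
    n = web.n
    ids = web.node_ids
    idx = {nid: i for i, nid in enumerate(ids)}
    biomass = web.biomass_vector()
    w_active = web.active_weight_matrix()
    any_explicit = any(lk.active_weight is not None for lk in web.links)
    explicit_cols = {lk.consumer_id for lk in web.links if lk.active_weight is not None}

    W = np.zeros((n, n))
    for cid in web.consumer_ids:
        j = idx[cid]
        # links with weight exactly 0 are structural but contribute no diet
        all_rows = [idx[r] for r in web.resources_of(cid)]
        score = w_active[all_rows, j] * (biomass[all_rows] if use_biomass else 1.0)
        denom = score.sum()
        if denom <= 0:
            if (
                use_biomass
                and cid in explicit_cols
                and w_active[all_rows, j].sum() > 0
            ):
                warnings.warn(
                    f"consumer {cid!r}: all resources have zero biomass; "
                    "falling back to active-only preferences for this column",
                    UserWarning,
                    stacklevel=2,
                )
                score = w_active[all_rows, j]
                denom = score.sum()
            else:
                raise PreferenceError(
                    f"consumer {cid!r}: preference normalization denominator is 0"
                )
        W[all_rows, j] = score / denom

    if use_biomass:
        mode = "combined" if any_explicit else "passive-only"
    else:
        mode = "active-only"
    return PreferenceMatrix(W, ids, mode)


def preference_matrix_from_array(web: FoodWeb, matrix) -> PreferenceMatrix:
    """Wrap a user-supplied (possibly unnormalized) preference matrix.

    Entries must be zero exactly where the web has no link; columns are
    normalized per consumer.
    """
    M = np.asarray(matrix, dtype=float).copy()
    mask = web.link_mask()
    if M.shape != mask.shape:
        raise PreferenceError("matrix shape does not match web")
    if np.any((M != 0) & ~mask):
        raise PreferenceError("nonzero preference on a nonexistent link")
    colsum = M.sum(axis=0)
    for j, nid in enumerate(web.node_ids):
        if mask[:, j].any():
            if colsum[j] <= 0:
                raise PreferenceError(f"consumer {nid!r}: zero preference column")
            M[:, j] /= colsum[j]
    return PreferenceMatrix(M, web.node_ids, "user-supplied")


TemperatureHook = Callable[[float, float], float]


def assign_efficiencies(
    web: FoodWeb,
    table: Mapping[str, float] | None = None,
    temperature_C: float | None = None,
    hook: TemperatureHook | None = None,
    level: str = "resource",
    reference_temperature_C: float = DEFAULT_EFFICIENCY_REFERENCE_C,
    source: str = "",
) -> EfficiencyAssignment:
    """Assign assimilation efficiencies to web nodes.

    Parameters
    ----------
    table
        ``resource`` level: mapping resource_type -> e covering every node
        that is eaten.  ``consumer`` level: mapping guild -> e covering
        every consumer.  Defaults to the bundled literature means
        (resource level only).
    temperature_C
        Ambient temperature; defaults to the web's.  Only used when a
        ``hook`` is supplied.
    hook
        Optional temperature model ``(base_e, delta_T) -> e`` where
        delta_T = ambient - reference.  The result is clamped to at most
        1; a nonpositive result is an error.  Default: identity
        (temperature-independent e).
    """
    if table is None:
        if level != "resource":
            raise EfficiencyError("bundled defaults are resource-level; supply a table")
        table = DEFAULT_EFFICIENCIES
        source = source or "bundled literature means at 20 degC"
    for key, val in table.items():
        if not (0 < float(val) <= 1):
            raise EfficiencyError(f"efficiency for {key!r} is {val}; must be in (0, 1]")
    temp = web.temperature_C if temperature_C is None else temperature_C
    dT = temp - reference_temperature_C

    def _adjust(base: float, what: str) -> float:
        e = float(base) if hook is None else float(hook(float(base), dT))
        if e <= 0:
            raise EfficiencyError(f"temperature hook produced e <= 0 for {what}")
        return min(e, 1.0)

    e = np.full(web.n, np.nan)
    if level == "resource":
        eaten = {lk.resource_id for lk in web.links}
        for i, nd in enumerate(web.nodes):
            if nd.resource_type in table:
                e[i] = _adjust(table[nd.resource_type], nd.node_id)
            elif nd.node_id in eaten:
                raise EfficiencyError(
                    f"node {nd.node_id!r} is eaten but resource_type "
                    f"{nd.resource_type!r} is not covered by the efficiency table"
                )
    elif level == "consumer":
        consumers = set(web.consumer_ids)
        for i, nd in enumerate(web.nodes):
            if nd.guild in table:
                e[i] = _adjust(table[nd.guild], nd.node_id)
            elif nd.node_id in consumers:
                raise EfficiencyError(
                    f"consumer {nd.node_id!r}: guild {nd.guild!r} not covered "
                    "by the consumer-level efficiency table"
                )
    else:
        raise EfficiencyError("level must be 'resource' or 'consumer'")
    return EfficiencyAssignment(
        level=level,
        e=e,
        node_ids=web.node_ids,
        reference_temperature_C=reference_temperature_C,
        source=source,
    )
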