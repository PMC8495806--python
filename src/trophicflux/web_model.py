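"""Data model, validation and topology operations for trophic networks.

A :class:`FoodWeb` is an ordered collection of :class:`TrophicNode`
compartments plus a set of feeding links (resource -> consumer), each with
an optional *active* preference weight.  Matrix-facing code uses the
fluxweb orientation throughout: consumers in columns, resources in rows,
node order equal to input order.

Design notes
------------
* Basal status is always derived from topology (a node with no resources);
  a user-supplied ``is_basal`` column is cross-checked, never trusted.
* Cannibalistic self-links are permitted only with an explicit active
  weight, so that biomass-driven (passive) preferences cannot silently
  send a large share of a node's diet to itself.
* Units are opaque coherent tags.  Nothing is converted automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import CycleError, WebBuildError

#: Resource-type vocabulary used when a node is eaten.  Assimilation
#: efficiencies are conventionally keyed on these.
RESOURCE_TYPES = ("animal", "plant", "detritus")

UNIT_KEYS = ("mass", "area", "energy", "time")


class SerialAggregationWarning(UserWarning):
    """Emitted when an aggregation merges nodes that feed on each other."""


class AggregationWarning(UserWarning):
    """Emitted for non-parallel (heterogeneous) merges other than serial."""


@dataclass(frozen=True)
class TrophicNode:
    """One compartment of the web: a population, species or feeding guild.

    Parameters
    ----------
    node_id
        Unique token identifying the node.
    guild
        Functional feeding guild (open vocabulary: plant, detritus,
        detritivore, herbivore, omnivore, predator, ...).
    resource_type
        One of ``animal | plant | detritus`` — the category used when this
        node is eaten (drives assimilation efficiency).
    biomass
        Fresh-mass density per unit area, in the web's declared mass/area
        units.  Nonnegative.
    abundance
        Individuals per unit area (optional).
    body_masses
        Individual fresh body masses (optional; a sub-sample of the
        population is fine).
    mean_body_mass
        Mean individual fresh mass (optional; fallback when individual
        masses are unavailable).
    loss
        Metabolic loss term X, either per unit biomass or per node
        depending on the web-level ``losses_per_unit_biomass`` flag.
        ``None`` until computed or supplied.
    is_basal
        Derived from topology by :func:`build_web`.
    """

    node_id: str
    guild: str
    resource_type: str
    biomass: float = 0.0
    name: str = ""
    abundance: float | None = None
    body_masses: tuple[float, ...] | None = None
    mean_body_mass: float | None = None
    loss: float | None = None
    is_basal: bool = False

    def __post_init__(self):
        if self.resource_type not in RESOURCE_TYPES:
            raise WebBuildError(
                f"node {self.node_id!r}: resource_type {self.resource_type!r} "
                f"not in {RESOURCE_TYPES}"
            )
        if not np.isfinite(self.biomass) or self.biomass < 0:
            raise WebBuildError(f"node {self.node_id!r}: negative biomass")
        if self.abundance is not None and self.abundance < 0:
            raise WebBuildError(f"node {self.node_id!r}: negative abundance")
        if self.body_masses is not None:
            if len(self.body_masses) < 1:
                raise WebBuildError(f"node {self.node_id!r}: empty body-mass list")
            if any(m <= 0 for m in self.body_masses):
                raise WebBuildError(f"node {self.node_id!r}: nonpositive body mass")
        if self.mean_body_mass is not None and self.mean_body_mass <= 0:
            raise WebBuildError(f"node {self.node_id!r}: nonpositive mean body mass")
        if self.loss is not None and self.loss < 0:
            raise WebBuildError(f"node {self.node_id!r}: negative loss")


@dataclass(frozen=True)
class Link:
    """A feeding link from ``resource_id`` to ``consumer_id``.

    ``active_weight`` is the consumer-choice weight w (>= 0); ``None``
    means "unspecified", which downstream preference code treats as the
    equal-weight null assumption (w = 1).
    """

    resource_id: str
    consumer_id: str
    active_weight: float | None = None

    def __post_init__(self):
        if self.active_weight is not None and (
            not np.isfinite(self.active_weight) or self.active_weight < 0
        ):
            raise WebBuildError(
                f"link {self.resource_id!r}->{self.consumer_id!r}: "
                "negative or non-finite active weight"
            )


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    code: str
    message: str


@dataclass
class FoodWeb:
    """A validated trophic network.

    ``losses_per_unit_biomass`` declares the semantics of each node's
    ``loss`` field (fluxweb's ``bioms.losses``): if True, losses are per
    unit biomass and are multiplied by node biomass before solving.
    """

    nodes: list[TrophicNode]
    links: list[Link]
    losses_per_unit_biomass: bool = True
    temperature_C: float = 20.0
    units: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict, compare=False)

    # -- lookups ----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(nd.node_id for nd in self.nodes)

    def index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(node_id) from None

    def node(self, node_id: str) -> TrophicNode:
        return self.nodes[self.index(node_id)]

    def resources_of(self, consumer_id: str) -> list[str]:
        return [lk.resource_id for lk in self.links if lk.consumer_id == consumer_id]

    def consumers_of(self, resource_id: str) -> list[str]:
        return [lk.consumer_id for lk in self.links if lk.resource_id == resource_id]

    @property
    def basal_ids(self) -> tuple[str, ...]:
        return tuple(nd.node_id for nd in self.nodes if nd.is_basal)

    @property
    def consumer_ids(self) -> tuple[str, ...]:
        consumers = {lk.consumer_id for lk in self.links}
        return tuple(nid for nid in self.node_ids if nid in consumers)

    # -- matrix views (consumers in columns, resources in rows) -----------
    def link_mask(self) -> np.ndarray:
        """Boolean adjacency, ``mask[r, c]`` True where c eats r."""
        idx = {nid: i for i, nid in enumerate(self.node_ids)}
        mask = np.zeros((self.n, self.n), dtype=bool)
        for lk in self.links:
            mask[idx[lk.resource_id], idx[lk.consumer_id]] = True
        return mask

    def active_weight_matrix(self) -> np.ndarray:
        """Active weights with the equal-weight null (1.0) where unspecified;
        0 where no link exists."""
        idx = {nid: i for i, nid in enumerate(self.node_ids)}
        w = np.zeros((self.n, self.n))
        for lk in self.links:
            w[idx[lk.resource_id], idx[lk.consumer_id]] = (
                1.0 if lk.active_weight is None else lk.active_weight
            )
        return w

    def biomass_vector(self) -> np.ndarray:
        return np.array([nd.biomass for nd in self.nodes], dtype=float)

    def node_loss_vector(self) -> np.ndarray:
        """Per-node metabolic demand X, resolving the loss basis.

        Per-unit-biomass losses are multiplied by node biomass; basal
        nodes without a loss contribute 0.
        """
        from .exceptions import LossDerivationError

        out = np.zeros(self.n)
        for i, nd in enumerate(self.nodes):
            if nd.loss is None:
                if nd.is_basal:
                    continue
                raise LossDerivationError(
                    f"consumer node {nd.node_id!r} has no loss value; "
                    "run node_losses() or supply one"
                )
            out[i] = nd.loss * nd.biomass if self.losses_per_unit_biomass else nd.loss
        return out

    def digraph(self) -> nx.DiGraph:
        """Consumer -> resource digraph (edge direction opposite to energy flow)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((lk.consumer_id, lk.resource_id) for lk in self.links)
        return g


# ---------------------------------------------------------------------------
# construction


def _records(table) -> list[dict]:
    if isinstance(table, pd.DataFrame):
        recs = table.to_dict("records")
    else:
        recs = [dict(r) for r in table]
    # NaN (from pandas) -> None
    clean = []
    for r in recs:
        clean.append(
            {
                k: (None if (isinstance(v, float) and np.isnan(v)) else v)
                for k, v in r.items()
            }
        )
    return clean


def build_web(
    node_records,
    link_records,
    options: Mapping | None = None,
) -> FoodWeb:
    """Assemble and validate a :class:`FoodWeb` from tabular records.

    Parameters
    ----------
    node_records
        DataFrame or iterable of mappings with at least ``node_id``,
        ``guild``, ``resource_type``, ``biomass``; optionally ``name``,
        ``abundance``, ``mean_body_mass``, ``body_masses`` (sequence),
        ``loss``, ``is_basal``.
    link_records
        DataFrame or iterable of mappings with ``resource_id``,
        ``consumer_id`` and optionally ``active_weight``.
    options
        ``losses_per_unit_biomass`` (default True), ``temperature_C``
        (default 20), ``units`` (mapping of mass/area/energy/time tags).

    Raises
    ------
    WebBuildError
        On duplicate node ids, dangling link endpoints, negative
        biomass/weights, missing basal or consumer nodes, a passive-only
        self-link, or a user basal flag contradicting topology.
    """
    options = dict(options or {})
    nrecs = _records(node_records)
    lrecs = _records(link_records)

    seen: set[str] = set()
    user_basal: dict[str, bool] = {}
    nodes: list[TrophicNode] = []
    for rec in nrecs:
        nid = rec.get("node_id")
        if nid is None or str(nid) == "":
            raise WebBuildError("node record without node_id")
        nid = str(nid)
        if nid in seen:
            raise WebBuildError(f"duplicate node_id {nid!r}")
        seen.add(nid)
        if rec.get("is_basal") is not None:
            user_basal[nid] = bool(rec["is_basal"])
        bm = rec.get("body_masses")
        nodes.append(
            TrophicNode(
                node_id=nid,
                name=str(rec.get("name") or ""),
                guild=str(rec.get("guild") or ""),
                resource_type=str(rec.get("resource_type") or ""),
                biomass=float(rec.get("biomass", 0.0) or 0.0),
                abundance=None if rec.get("abundance") is None else float(rec["abundance"]),
                body_masses=None if bm is None else tuple(float(m) for m in bm),
                mean_body_mass=(
                    None if rec.get("mean_body_mass") is None else float(rec["mean_body_mass"])
                ),
                loss=None if rec.get("loss") is None else float(rec["loss"]),
            )
        )

    links: list[Link] = []
    pair_seen: set[tuple[str, str]] = set()
    for rec in lrecs:
        rid, cid = str(rec.get("resource_id")), str(rec.get("consumer_id"))
        for endpoint in (rid, cid):
            if endpoint not in seen:
                raise WebBuildError(f"link endpoint {endpoint!r} is not a node")
        if (rid, cid) in pair_seen:
            raise WebBuildError(f"duplicate link {rid!r}->{cid!r}")
        pair_seen.add((rid, cid))
        w = rec.get("active_weight")
        if rid == cid and w is None:
            raise WebBuildError(
                f"cannibalistic self-link on {rid!r} requires an explicit "
                "active weight (passive preferences alone would not "
                "down-weight self-consumption)"
            )
        links.append(Link(rid, cid, None if w is None else float(w)))

    consumers = {lk.consumer_id for lk in links}
    # nodes whose ONLY resource is themselves are still basal energetically?
    # No: a self-link makes the node a consumer; feasibility is the solver's
    # problem.  Basal <=> no incoming resources at all.
    nodes = [replace(nd, is_basal=nd.node_id not in consumers) for nd in nodes]

    for nid, flag in user_basal.items():
        derived = nid not in consumers
        if flag != derived:
            raise WebBuildError(
                f"user is_basal={flag} for node {nid!r} contradicts topology "
                f"(derived is_basal={derived})"
            )

    if not any(nd.is_basal for nd in nodes):
        raise WebBuildError("no basal node (every node has resources)")
    if not consumers:
        raise WebBuildError("no consumer node (web has no links)")

    units = dict(options.get("units") or {})
    return FoodWeb(
        nodes=nodes,
        links=links,
        losses_per_unit_biomass=bool(options.get("losses_per_unit_biomass", True)),
        temperature_C=float(options.get("temperature_C", 20.0)),
        units=units,
        metadata=dict(options.get("metadata") or {}),
    )


# ---------------------------------------------------------------------------
# validation


def validate_web(web: FoodWeb, passive_preferences: bool = True) -> list[Diagnostic]:
    """Data-hygiene diagnostics for a structurally well-formed web.

    Returns a list of :class:`Diagnostic` (severity ``error`` or
    ``warning``); an empty list means the web is clean.  Nothing is
    raised — callers decide what blocks a run.
    """
    diags: list[Diagnostic] = []

    # reachability from basal nodes, following energy flow (resource -> consumer)
    g = web.digraph().reverse(copy=False)
    reachable: set[str] = set()
    for b in web.basal_ids:
        reachable.add(b)
        reachable |= nx.descendants(g, b)
    for nid in web.node_ids:
        if nid not in reachable:
            diags.append(
                Diagnostic(
                    "warning",
                    "unreachable",
                    f"node {nid!r} is unreachable from any basal node",
                )
            )

    biomass = {nd.node_id: nd.biomass for nd in web.nodes}
    for cid in web.consumer_ids:
        res = web.resources_of(cid)
        if passive_preferences and res and all(biomass[r] == 0 for r in res):
            diags.append(
                Diagnostic(
                    "error",
                    "zero-biomass-diet",
                    f"consumer {cid!r}: all resources have biomass 0; "
                    "passive preferences would divide by zero",
                )
            )
        nd = web.node(cid)
        if (
            nd.loss is None
            and nd.body_masses is None
            and not (nd.mean_body_mass is not None and nd.abundance is not None)
        ):
            diags.append(
                Diagnostic(
                    "error",
                    "no-metabolic-route",
                    f"consumer {cid!r}: cannot derive metabolic demand "
                    "(no loss, no body masses, no mean mass + abundance)",
                )
            )

    missing_units = [k for k in UNIT_KEYS if not web.units.get(k)]
    if missing_units:
        diags.append(
            Diagnostic(
                "warning",
                "missing-units",
                "unit tags missing: " + ", ".join(missing_units),
            )
        )
    return diags


# ---------------------------------------------------------------------------
# aggregation


def _merge_loss(members: list[TrophicNode], per_unit: bool) -> float | None:
    if any(m.loss is None for m in members):
        return None
    if not per_unit:
        return float(sum(m.loss for m in members))
    total_b = sum(m.biomass for m in members)
    if total_b == 0:
        return float(np.mean([m.loss for m in members]))
    return float(sum(m.loss * m.biomass for m in members) / total_b)


def aggregate_nodes(web: FoodWeb, partition: Mapping[str, str]) -> FoodWeb:
    """Merge nodes into groups, rebuilding links and conserving biomass.

    ``partition`` maps every node_id to a group_id.  Within each group:
    biomass and abundance are summed, individual body-mass lists
    concatenated, per-node losses summed (per-unit-biomass losses are
    combined as a biomass-weighted mean, which conserves the total
    per-node demand).  Links are rebuilt as the union of member links,
    active weights combined as resource-biomass-weighted means.
    Intra-group links disappear into the merged node; their presence
    classifies the merge as *serial* and triggers a warning — the
    aggregated web no longer resolves that internal energy flow.

    A merge of nodes that share identical resource and consumer sets
    outside the group is *parallel* (safe, silent); anything else that is
    not serial warns as heterogeneous.  Classifications are recorded in
    ``metadata['aggregation']`` of the returned web.
    """
    missing = [nid for nid in web.node_ids if nid not in partition]
    if missing:
        raise WebBuildError(f"partition does not cover nodes: {missing}")

    groups: dict[str, list[str]] = {}
    for nid in web.node_ids:  # preserve input order of first appearance
        groups.setdefault(str(partition[nid]), []).append(nid)
    for gid, members in groups.items():
        if not members:
            raise WebBuildError(f"empty group {gid!r}")

    classification: dict[str, str] = {}
    new_nodes: list[dict] = []
    for gid, member_ids in groups.items():
        members = [web.node(m) for m in member_ids]
        rtypes = {m.resource_type for m in members}
        if len(rtypes) > 1:
            raise WebBuildError(
                f"group {gid!r}: members have conflicting resource_type {sorted(rtypes)}"
            )
        mset = set(member_ids)
        serial = any(
            lk.resource_id in mset and lk.consumer_id in mset for lk in web.links
        )
        outside = [
            (
                frozenset(set(web.resources_of(m)) - mset),
                frozenset(set(web.consumers_of(m)) - mset),
            )
            for m in member_ids
        ]
        if serial:
            classification[gid] = "serial"
            warnings.warn(
                f"serial aggregation in group {gid!r}: members feed on each "
                "other; flux results for this node may be unreliable",
                SerialAggregationWarning,
                stacklevel=2,
            )
        elif len(set(outside)) == 1:
            classification[gid] = "parallel"
        else:
            classification[gid] = "heterogeneous"
            if len(member_ids) > 1:
                warnings.warn(
                    f"group {gid!r}: members differ in resource/consumer sets "
                    "(not a parallel merge)",
                    AggregationWarning,
                    stacklevel=2,
                )

        abund = [m.abundance for m in members if m.abundance is not None]
        masses: list[float] = []
        for m in members:
            if m.body_masses is not None:
                masses.extend(m.body_masses)
        mm_pairs = [
            (m.abundance, m.mean_body_mass)
            for m in members
            if m.abundance is not None and m.mean_body_mass is not None
        ]
        mm = None
        if mm_pairs and sum(a for a, _ in mm_pairs) > 0:
            mm = sum(a * m for a, m in mm_pairs) / sum(a for a, _ in mm_pairs)
        guilds = sorted({m.guild for m in members})
        new_nodes.append(
            dict(
                node_id=gid,
                name="+".join(m.name or m.node_id for m in members),
                guild=guilds[0] if len(guilds) == 1 else "+".join(guilds),
                resource_type=members[0].resource_type,
                biomass=float(sum(m.biomass for m in members)),
                abundance=float(sum(abund)) if abund else None,
                body_masses=tuple(masses) if masses else None,
                mean_body_mass=mm,
                loss=_merge_loss(members, web.losses_per_unit_biomass),
            )
        )

    # rebuild links: union across groups, skipping intra-group links
    gmap = {nid: str(partition[nid]) for nid in web.node_ids}
    bio = {nd.node_id: nd.biomass for nd in web.nodes}
    pooled: dict[tuple[str, str], list[Link]] = {}
    for lk in web.links:
        gr, gc = gmap[lk.resource_id], gmap[lk.consumer_id]
        if gr == gc:
            continue
        pooled.setdefault((gr, gc), []).append(lk)
    new_links: list[dict] = []
    for (gr, gc), lks in pooled.items():
        if all(lk.active_weight is None for lk in lks):
            w = None
        else:
            ws = [1.0 if lk.active_weight is None else lk.active_weight for lk in lks]
            bs = [bio[lk.resource_id] for lk in lks]
            w = (
                float(np.average(ws, weights=bs))
                if sum(bs) > 0
                else float(np.mean(ws))
            )
        new_links.append(dict(resource_id=gr, consumer_id=gc, active_weight=w))

    out = build_web(
        new_nodes,
        new_links,
        options=dict(
            losses_per_unit_biomass=web.losses_per_unit_biomass,
            temperature_C=web.temperature_C,
            units=dict(web.units),
        ),
    )
    out.metadata["aggregation"] = classification
    out.metadata["aggregation_weight_rule"] = "resource-biomass-weighted mean"
    return out


# ---------------------------------------------------------------------------
# ordering


def cycle_nodes(web: FoodWeb) -> frozenset[str]:
    """Node ids that sit on at least one feeding loop (empty if acyclic)."""
    g = web.digraph()
    on_cycle: set[str] = set()
    for comp in nx.strongly_connected_components(g):
        if len(comp) > 1:
            on_cycle |= comp
    on_cycle |= {n for n in g.nodes if g.has_edge(n, n)}
    return frozenset(on_cycle)


def topological_order(web: FoodWeb) -> list[str]:
    """Order nodes from top consumers downward.

    In the returned order every consumer precedes all of its resources,
    so Eq.-style sequential flux calculation can accumulate loss to
    consumption top-down.  Deterministic: ties break on input order.

    Raises
    ------
    CycleError
        If the web contains feeding loops; the exception carries the set
        of nodes on cycles.
    """
    bad = cycle_nodes(web)
    if bad:
        raise CycleError(bad)
    g = web.digraph()
    pos = {nid: i for i, nid in enumerate(web.node_ids)}
    return list(nx.lexicographical_topological_sort(g, key=lambda n: pos[n]))
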