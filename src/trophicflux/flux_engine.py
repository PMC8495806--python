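"""Steady-state energy balance: solve every link flux in one pass.

Each single flux follows F = (X + L) / e_a: the energy leaving a resource
node along a link must cover the consumer's metabolic demand X plus the
consumer's own loss to consumption L, inflated by the assimilation
inefficiency of the transfer.  At steady state every consumer c with
total consumption G_c satisfies

    ebar_c * G_c - sum_k W[c, k] * G_k = X_c

where ebar_c = sum_r e_r * W[r, c] is the diet-weighted efficiency under
resource-level efficiencies (or e_c itself at consumer level), and the
sum over k collects what c's own consumers take out of it.  Basal nodes
have G = 0; per-link fluxes follow as F[r, c] = W[r, c] * G_c.

Two solvers share this contract: :func:`solve_fluxes` assembles the
linear system over consumers (handles omnivory and feeding loops) and
:func:`solve_fluxes_sequential` walks the acyclic web top-down, serving
as an independent oracle for the matrix route.

The result is the *minimum* flux needed to keep the community alive:
losses are (typically basal) metabolic rates, and no production or
reproduction surplus is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EfficiencyError, InfeasibleFluxError
from .trophic_params import EfficiencyAssignment, PreferenceMatrix, assign_efficiencies
from .web_model import FoodWeb, topological_order

#: default numerical tolerances (relative)
RESIDUAL_TOL = 1e-9
NEGATIVE_G_TOL = 1e-10


@dataclass
class FluxSolution:
    """Per-link fluxes and per-node energy bookkeeping.

    ``flux[r, c]`` is energy flowing from resource r to consumer c per
    area per time (consumers in columns).  ``consumption`` is
    G_c = sum_r F[r, c]; ``loss_to_consumption`` is L_r = sum_c F[r, c];
    ``residuals`` are per-node balance errors relative to X.
    """

    node_ids: tuple[str, ...]
    flux: np.ndarray
    consumption: np.ndarray
    loss_to_consumption: np.ndarray
    residuals: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def flux_between(self, resource_id: str, consumer_id: str) -> float:
        i = self.node_ids.index(resource_id)
        j = self.node_ids.index(consumer_id)
        return float(self.flux[i, j])

    def link_frame(self, web: FoodWeb | None = None) -> pd.DataFrame:
        """Long-format link fluxes.  With a web, rows follow its link list
        (zero-flux links included); otherwise all nonzero entries."""
        rows = []
        if web is not None:
            for lk in web.links:
                rows.append(
                    (lk.resource_id, lk.consumer_id, self.flux_between(lk.resource_id, lk.consumer_id))
                )
        else:
            rr, cc = np.nonzero(self.flux)
            for i, j in zip(rr, cc):
                rows.append((self.node_ids[i], self.node_ids[j], float(self.flux[i, j])))
        return pd.DataFrame(rows, columns=["resource_id", "consumer_id", "flux"])


def _efficiency_vector(eff: EfficiencyAssignment, node_ids) -> np.ndarray:
    if tuple(eff.node_ids) != tuple(node_ids):
        raise EfficiencyError("efficiency assignment node order differs from web")
    return np.asarray(eff.e, dtype=float)


def _prepare(web, W, losses, eff):
    if W is None:
        from .trophic_params import compute_preferences

        W = compute_preferences(web, use_biomass=True)
    if tuple(W.node_ids) != web.node_ids:
        raise InfeasibleFluxError("preference matrix node order differs from web")
    if eff is None:
        eff = assign_efficiencies(web)
    if losses is None:
        X = web.node_loss_vector()
    else:
        X = np.asarray(losses, dtype=float)
        if X.shape != (web.n,):
            raise InfeasibleFluxError("loss vector length differs from web size")
    if np.any(X < 0):
        raise InfeasibleFluxError("negative metabolic loss supplied")
    e = _efficiency_vector(eff, web.node_ids)
    Wm = W.matrix
    # coverage: every eaten node needs a defined e at resource level,
    # every consumer at consumer level
    if eff.level == "resource":
        eaten = Wm.sum(axis=1) > 0
        if np.any(eaten & ~np.isfinite(e)):
            bad = [web.node_ids[i] for i in np.flatnonzero(eaten & ~np.isfinite(e))]
            raise EfficiencyError(f"eaten nodes without efficiency: {bad}")
    else:
        cons = Wm.sum(axis=0) > 0
        if np.any(cons & ~np.isfinite(e)):
            bad = [web.node_ids[i] for i in np.flatnonzero(cons & ~np.isfinite(e))]
            raise EfficiencyError(f"consumers without efficiency: {bad}")
    return W, Wm, X, eff, e


def _ebar(Wm: np.ndarray, e: np.ndarray, level: str) -> np.ndarray:
    """Per-consumer effective efficiency of one unit of consumption."""
    e0 = np.where(np.isfinite(e), e, 0.0)
    if level == "resource":
        return e0 @ Wm
    return e0


def _finalize(web, Wm, G, X, e, level, units_tag):
    F = Wm * G[np.newaxis, :]
    L = F.sum(axis=1)
    sol = FluxSolution(
        node_ids=web.node_ids,
        flux=F,
        consumption=G,
        loss_to_consumption=L,
        residuals=np.zeros(web.n),
        units=units_tag,
    )
    sol.residuals = _residuals(sol, Wm, X, e, level)
    return sol


def _residuals(solution, Wm, X, e, level, eps=1e-12):
    e0 = np.where(np.isfinite(e), e, 0.0)
    F = solution.flux
    if level == "resource":
        assimilated = e0 @ F
    else:
        assimilated = e0 * F.sum(axis=0)
    out_to_consumers = F.sum(axis=1)
    is_consumer = Wm.sum(axis=0) > 0
    res = np.abs(assimilated - X - out_to_consumers) / np.maximum(X, eps)
    res[~is_consumer] = 0.0
    return res


def solve_fluxes(
    web: FoodWeb,
    W: PreferenceMatrix | None = None,
    losses=None,
    eff: EfficiencyAssignment | None = None,
) -> FluxSolution:
    """Solve all link fluxes as one linear system over consumer nodes.

    Parameters
    ----------
    W
        Preference matrix; computed with passive x active defaults if
        omitted.
    losses
        Per-node metabolic demand X (length-n array).  If omitted, taken
        from the web's nodes, multiplying per-unit-biomass losses by
        biomass first.
    eff
        Efficiency assignment; bundled resource-type defaults if omitted.

    Raises
    ------
    InfeasibleFluxError
        If the system is singular or any consumption turns out negative
        (an energetically infeasible configuration), naming the nodes.
    """
    W, Wm, X, eff, e = _prepare(web, W, losses, eff)
    ebar = _ebar(Wm, e, eff.level)
    cons = np.flatnonzero(Wm.sum(axis=0) > 0)
    m = len(cons)
    A = np.diag(ebar[cons]) - Wm[np.ix_(cons, cons)]
    b = X[cons]
    try:
        g = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise InfeasibleFluxError(
            "singular energy-balance system: the web structure admits no "
            "unique steady-state flux"
        ) from None
    scale = max(1.0, float(np.abs(g).max(initial=0.0)))
    neg = np.flatnonzero(g < -NEGATIVE_G_TOL * scale)
    if neg.size:
        bad = [web.node_ids[cons[i]] for i in neg]
        raise InfeasibleFluxError(
            f"energetically infeasible configuration: negative consumption at {bad}",
            offending_nodes=bad,
        )
    g = np.maximum(g, 0.0)
    G = np.zeros(web.n)
    G[cons] = g
    return _finalize(web, Wm, G, X, e, eff.level, web.units.get("energy", ""))


def solve_fluxes_sequential(
    web: FoodWeb,
    W: PreferenceMatrix | None = None,
    losses=None,
    eff: EfficiencyAssignment | None = None,
) -> FluxSolution:
    """Top-down sequential solver for acyclic webs (the hand method).

    Starts from the terminal consumers and walks down: at each consumer
    the accumulated loss to consumption L is known, so
    G = (X + L) / ebar applies directly.  Identical contract to
    :func:`solve_fluxes` on DAGs; raises :class:`CycleError` on loops
    (use the matrix solver there).
    """
    order = topological_order(web)  # raises CycleError on loops
    W, Wm, X, eff, e = _prepare(web, W, losses, eff)
    ebar = _ebar(Wm, e, eff.level)
    idx = {nid: i for i, nid in enumerate(web.node_ids)}
    G = np.zeros(web.n)
    F = np.zeros((web.n, web.n))
    for nid in order:
        i = idx[nid]
        if Wm[:, i].sum() <= 0:
            continue  # basal
        L = F[i, :].sum()  # consumers of i all precede it in the order
        if ebar[i] <= 0:
            raise InfeasibleFluxError(
                f"consumer {nid!r}: zero diet-weighted efficiency"
            )
        G[i] = (X[i] + L) / ebar[i]
        F[:, i] = Wm[:, i] * G[i]
    sol = _finalize(web, Wm, G, X, e, eff.level, web.units.get("energy", ""))
    return sol


def balance_residuals(
    solution: FluxSolution,
    web: FoodWeb,
    W: PreferenceMatrix,
    losses=None,
    eff: EfficiencyAssignment | None = None,
    eps: float = 1e-12,
) -> np.ndarray:
    """Per-node balance error |assimilated - X - loss to consumption| / max(X, eps).

    Zero (to rounding) for any true solution; returned for auditing.
    """
    if eff is None:
        eff = assign_efficiencies(web)
    X = web.node_loss_vector() if losses is None else np.asarray(losses, dtype=float)
    e = _efficiency_vector(eff, web.node_ids)
    return _residuals(solution, W.matrix, X, e, eff.level, eps=eps)
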