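"""Monte-Carlo propagation of parameter uncertainty to fluxes.

Each draw multiplies the chosen parameter (metabolic losses, assimilation
efficiencies, or preference entries) elementwise by independent factors
uniform on [1 - v, 1 + v], re-solves the balance, and records relative
deviations from the unperturbed solution.  Uniform multiplicative noise
is a modeling choice (no distribution is canonical for these parameter
uncertainties); perturbed efficiencies are clamped to at most 1 (clamp
events are counted), and perturbed preference columns are re-normalized.
Preference noise is applied link-wise (then re-normalized) rather than
node-wise.

Factors are drawn once per draw as u ~ U(-1, 1) and scaled by v, so a
fixed seed yields a nested, reproducible stress sequence: increasing v
on the same seed monotonically widens the same perturbation directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InfeasibleFluxError
from .flux_engine import solve_fluxes
from .trophic_params import EfficiencyAssignment, PreferenceMatrix
from .web_model import FoodWeb

PARAMETERS = ("losses", "efficiencies", "preferences")


@dataclass
class SensitivityReport:
    """Aggregated deviations of fluxes under parameter perturbation."""

    parameter: str
    v: float
    n_draws: int
    seed: int | None
    node_ids: tuple[str, ...]
    link_index: tuple[tuple[str, str], ...]
    link_mean_rel_dev: np.ndarray  # mean over feasible draws, per link
    node_mean_rel_dev: np.ndarray  # per node (consumption G)
    link_cv: np.ndarray  # coefficient of variation of perturbed flux, per link
    node_cv: np.ndarray
    mean_link_rel_dev: float
    mean_node_rel_dev: float
    infeasible_draws: int
    clamp_events: int
    factors: list[np.ndarray] | None = field(default=None, compare=False)

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.node_ids),
                "mean_rel_dev_G": self.node_mean_rel_dev,
                "cv_G": self.node_cv,
            }
        )

    def link_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resource_id": [r for r, _ in self.link_index],
                "consumer_id": [c for _, c in self.link_index],
                "mean_rel_dev_flux": self.link_mean_rel_dev,
                "cv_flux": self.link_cv,
            }
        )


def _perturbed_inputs(parameter, Wm, X, e, u, node_ids, link_rows, link_cols):
    """Apply one factor vector; returns (Wm', X', e', clamp_count)."""
    clamps = 0
    Wp, Xp, ep = Wm, X, e
    if parameter == "losses":
        Xp = X * (1.0 + u)
    elif parameter == "efficiencies":
        ep = e.copy()
        fin = np.isfinite(e)
        ep[fin] = e[fin] * (1.0 + u[fin])
        over = fin & (ep > 1.0)
        clamps = int(over.sum())
        ep[over] = 1.0
    elif parameter == "preferences":
        Wp = Wm.copy()
        Wp[link_rows, link_cols] *= 1.0 + u
        colsum = Wp.sum(axis=0)
        cols = colsum > 0
        Wp[:, cols] /= colsum[cols]
    return Wp, Xp, ep, clamps


def perturb_and_recompute(
    web: FoodWeb,
    W: PreferenceMatrix,
    losses,
    eff: EfficiencyAssignment,
    parameter: str,
    v: float,
    n: int,
    seed: int | None = None,
    trace: bool = False,
) -> SensitivityReport:
    """Perturb one parameter n times and measure flux deviations.

    Parameters
    ----------
    parameter
        One of ``losses``, ``efficiencies``, ``preferences``.
    v
        Perturbation half-width as a fraction, 0 <= v < 1.
    n
        Number of Monte-Carlo draws (>= 1).
    seed
        Seed for the factor stream; identical seed + inputs reproduce the
        report exactly.
    trace
        Keep the drawn factor vectors on the report for auditing.

    Infeasible draws (negative consumption after perturbation) are
    excluded from the statistics but counted.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; choose from {PARAMETERS}")
    if not (0 <= v < 1):
        raise ValueError("half-width v must satisfy 0 <= v < 1")
    if n < 1:
        raise ValueError("need at least one draw")

    X = np.asarray(losses, dtype=float)
    base = solve_fluxes(web, W, X, eff)
    Wm = W.matrix
    e = np.asarray(eff.e, dtype=float)
    link_rows, link_cols = np.nonzero(Wm)
    link_index = tuple(
        (web.node_ids[i], web.node_ids[j]) for i, j in zip(link_rows, link_cols)
    )
    base_link = base.flux[link_rows, link_cols]
    base_node = base.consumption

    size = {"losses": web.n, "efficiencies": web.n, "preferences": len(link_rows)}[
        parameter
    ]
    rng = np.random.default_rng(seed)

    link_dev_sum = np.zeros(len(link_rows))
    node_dev_sum = np.zeros(web.n)
    link_vals = []
    node_vals = []
    factors: list[np.ndarray] = []
    infeasible = 0
    clamp_events = 0

    for _ in range(n):
        u = v * rng.uniform(-1.0, 1.0, size=size)
        Wp, Xp, ep, clamps = _perturbed_inputs(
            parameter, Wm, X, e, u, web.node_ids, link_rows, link_cols
        )
        Wobj = PreferenceMatrix(Wp, web.node_ids, W.mode) if Wp is not Wm else W
        eobj = (
            EfficiencyAssignment(
                eff.level, ep, eff.node_ids, eff.reference_temperature_C, eff.source
            )
            if ep is not e
            else eff
        )
        try:
            sol = solve_fluxes(web, Wobj, Xp, eobj)
        except InfeasibleFluxError:
            infeasible += 1
            if trace:
                factors.append(1.0 + u)
            continue
        clamp_events += clamps
        pl = sol.flux[link_rows, link_cols]
        pn = sol.consumption
        with np.errstate(divide="ignore", invalid="ignore"):
            ld = np.where(base_link > 0, np.abs(pl - base_link) / base_link, 0.0)
            nd = np.where(base_node > 0, np.abs(pn - base_node) / base_node, 0.0)
        link_dev_sum += ld
        node_dev_sum += nd
        link_vals.append(pl)
        node_vals.append(pn)
        if trace:
            factors.append(1.0 + u)

    feasible = n - infeasible
    if feasible == 0:
        raise InfeasibleFluxError(
            f"all {n} perturbation draws were energetically infeasible"
        )
    link_mean = link_dev_sum / feasible
    node_mean = node_dev_sum / feasible
    lv = np.array(link_vals)
    nv = np.array(node_vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        link_cv = np.where(lv.mean(axis=0) > 0, lv.std(axis=0) / lv.mean(axis=0), 0.0)
        node_cv = np.where(nv.mean(axis=0) > 0, nv.std(axis=0) / nv.mean(axis=0), 0.0)

    return SensitivityReport(
        parameter=parameter,
        v=float(v),
        n_draws=n,
        seed=seed,
        node_ids=web.node_ids,
        link_index=link_index,
        link_mean_rel_dev=link_mean,
        node_mean_rel_dev=node_mean,
        link_cv=link_cv,
        node_cv=node_cv,
        mean_link_rel_dev=float(link_mean.mean()) if link_mean.size else 0.0,
        mean_node_rel_dev=float(node_mean[base_node > 0].mean())
        if np.any(base_node > 0)
        else 0.0,
        infeasible_draws=infeasible,
        clamp_events=clamp_events,
        factors=factors if trace else None,
    )
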