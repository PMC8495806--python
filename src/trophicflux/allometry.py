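"""Body-dimension -> body-mass and body-mass + temperature -> metabolic loss.

Length-mass regressions are power laws on one or two body dimensions,
with an explicit log convention per record (log10 vs natural log — a
classic source of silent unit bugs, so it is never inferred).  Metabolic
rates follow the standard allometric/Arrhenius form

    ln X = ln_x0 + a * ln M - E / (k * T)

with M fresh body mass, T in Kelvin (all interfaces accept Celsius) and
k the Boltzmann constant in eV/K.

Regression coefficients are data, not code: the bundled tables under
``trophicflux/data`` carry provenance columns and clearly marked
placeholder values; replace them with fits from the primary literature
(e.g. Ehnes et al. 2011 for soil invertebrates, Sohlström et al. 2018 or
Mercer et al. 2001 for length-mass) for real analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import LossDerivationError, WebBuildError
from .web_model import FoodWeb, TrophicNode

#: Boltzmann constant in eV per Kelvin (fixed by the regression contract).
BOLTZMANN_EV = 8.62e-5

_LOG_SCALES = ("log10", "ln")


class MeanMassFallbackWarning(UserWarning):
    """Mean-mass fallback ignores size structure; per-capita metabolism is a
    concave power law of mass, so the fallback overstates the summed demand
    of an unequal-mass population at fixed count."""


@dataclass(frozen=True)
class LengthMassRegression:
    """Power-law regression from body length (and optionally width) to mass.

    mass = base ** (intercept + exp_length * log(L) [+ exp_width * log(W)])

    with base/log given by ``scale`` ("log10" or "ln").  ``mass_basis``
    declares whether the output is fresh or dry mass; dry outputs are
    converted on the way out of :func:`length_to_mass`.
    """

    key: str
    scale: str
    intercept: float
    exp_length: float
    exp_width: float | None = None
    mass_basis: str = "fresh"
    in_unit: str = "mm"
    out_unit: str = "mg"
    source: str = ""

    def __post_init__(self):
        if self.scale not in _LOG_SCALES:
            raise WebBuildError(f"regression {self.key!r}: scale must be log10 or ln")
        if self.exp_length <= 0:
            raise WebBuildError(f"regression {self.key!r}: length exponent must be > 0")
        if self.mass_basis not in ("fresh", "dry"):
            raise WebBuildError(f"regression {self.key!r}: mass_basis must be fresh or dry")


@dataclass(frozen=True)
class DryFreshRegression:
    """Power-law dry -> fresh conversion: fresh = base**(intercept + exponent*log(dry))."""

    scale: str
    intercept: float
    exponent: float

    def __post_init__(self):
        if self.scale not in _LOG_SCALES:
            raise WebBuildError("dry->fresh regression: scale must be log10 or ln")


@dataclass(frozen=True)
class MetabolicRegression:
    """Allometric/Arrhenius metabolic-rate regression for one taxon/guild.

    X(M, T) = exp(ln_x0 + mass_exp * ln M - activation_energy_eV / (k * T_K))

    The output is a per-capita rate in ``out_unit`` (energy per individual
    per time) for mass supplied in ``mass_unit``.
    """

    key: str
    ln_x0: float
    mass_exp: float
    activation_energy_eV: float = 0.0
    mass_unit: str = "mg"
    out_unit: str = "J/h"
    source: str = ""

    def __post_init__(self):
        if self.activation_energy_eV < 0:
            raise WebBuildError(f"regression {self.key!r}: activation energy must be >= 0")


def _log(scale: str, x: float) -> float:
    return math.log10(x) if scale == "log10" else math.log(x)


def _pow(scale: str, x: float) -> float:
    return 10.0 ** x if scale == "log10" else math.exp(x)


def dry_to_fresh(
    dry_mass: float,
    factor: float = 1.0,
    regression: DryFreshRegression | None = None,
) -> float:
    """Convert dry mass to fresh mass.

    Either a simple multiplicative ``factor`` (default 1 — i.e. no hidden
    conversion; override explicitly) or a power-law ``regression``.
    """
    if dry_mass < 0:
        raise ValueError("dry mass must be nonnegative")
    if regression is not None:
        if dry_mass == 0:
            return 0.0
        return _pow(
            regression.scale,
            regression.intercept + regression.exponent * _log(regression.scale, dry_mass),
        )
    if factor <= 0:
        raise ValueError("dry->fresh factor must be > 0")
    return dry_mass * factor


def length_to_mass(
    length: float,
    regression: LengthMassRegression,
    width: float | None = None,
    dry_to_fresh_factor: float = 1.0,
    dry_to_fresh_regression: DryFreshRegression | None = None,
) -> float:
    """Fresh body mass from body length (mm) via a length-mass regression.

    ``width`` is required iff the regression has a width exponent.  If the
    regression outputs dry mass, the dry->fresh conversion is applied
    before returning (factor defaults to 1, i.e. you must opt in).
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    if regression.exp_width is not None and width is None:
        raise ValueError(f"regression {regression.key!r} requires a width measurement")
    if regression.exp_width is None and width is not None:
        raise ValueError(f"regression {regression.key!r} takes no width measurement")
    val = regression.intercept + regression.exp_length * _log(regression.scale, length)
    if regression.exp_width is not None:
        if width <= 0:
            raise ValueError("width must be > 0")
        val += regression.exp_width * _log(regression.scale, width)
    mass = _pow(regression.scale, val)
    if regression.mass_basis == "dry":
        mass = dry_to_fresh(mass, dry_to_fresh_factor, dry_to_fresh_regression)
    return mass


def metabolic_rate(mass, temperature_C: float, regression: MetabolicRegression):
    """Per-capita metabolic loss X for fresh mass(es) at ambient temperature.

    Accepts a scalar or array of masses; strictly increasing in mass for
    a positive mass exponent and in temperature for positive activation
    energy.
    """
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0):
        raise ValueError("body mass must be > 0")
    if temperature_C <= -273.15:
        raise ValueError("temperature below absolute zero")
    t_kelvin = temperature_C + 273.15
    ln_x = (
        regression.ln_x0
        + regression.mass_exp * np.log(m)
        - regression.activation_energy_eV / (BOLTZMANN_EV * t_kelvin)
    )
    out = np.exp(ln_x)
    return float(out) if np.isscalar(mass) or out.ndim == 0 else out


def node_losses(
    web: FoodWeb,
    regressions,
    fmr_multiplier: float = 1.0,
    temperature_C: float | None = None,
) -> FoodWeb:
    """Fill per-node metabolic losses for every consumer in the web.

    For each consumer node, in order of preference:

    1. a pre-supplied ``loss`` is kept (converted to the per-node basis if
       the web declares per-unit-biomass losses) — no multiplier applied,
       since a supplied value may already be a field rate;
    2. an individual body-mass list: loss = fmr * sum_i X(M_i, T);
    3. mean mass + abundance fallback: loss = fmr * N * X(mean M, T),
       with a warning (ignores the nonlinearity of metabolic scaling).

    Basal-node losses are set to 0: the approach quantifies energy
    flowing out of, not into, the basal level, so basal metabolism is
    not needed.  ``fmr_multiplier`` rescales basal (resting) metabolic
    rates towards field rates — typically about 3.

    ``regressions`` maps guild -> :class:`MetabolicRegression`; a
    ``"default"`` key is used for guilds without their own entry.

    Returns a new web with ``losses_per_unit_biomass=False``.
    """
    if fmr_multiplier <= 0:
        raise ValueError("fmr_multiplier must be > 0")
    temp = web.temperature_C if temperature_C is None else temperature_C
    new_nodes: list[TrophicNode] = []
    for nd in web.nodes:
        if nd.is_basal:
            new_nodes.append(replace(nd, loss=0.0))
            continue
        if nd.loss is not None:
            x = nd.loss * nd.biomass if web.losses_per_unit_biomass else nd.loss
            new_nodes.append(replace(nd, loss=float(x)))
            continue
        reg = None
        if nd.guild in regressions:
            reg = regressions[nd.guild]
        elif "default" in regressions:
            reg = regressions["default"]
        if reg is None:
            raise LossDerivationError(
                f"no metabolic regression for guild {nd.guild!r} (node {nd.node_id!r}) "
                "and no 'default' entry"
            )
        if nd.body_masses is not None:
            x = fmr_multiplier * float(
                np.sum(metabolic_rate(np.asarray(nd.body_masses), temp, reg))
            )
        elif nd.mean_body_mass is not None and nd.abundance is not None:
            warnings.warn(
                f"node {nd.node_id!r}: using mean-mass fallback for metabolic "
                "demand; individual-level masses capture size structure that "
                "the fallback ignores",
                MeanMassFallbackWarning,
                stacklevel=2,
            )
            x = fmr_multiplier * nd.abundance * metabolic_rate(nd.mean_body_mass, temp, reg)
        else:
            raise LossDerivationError(
                f"consumer node {nd.node_id!r}: no loss, no body masses, "
                "no mean mass + abundance — cannot derive metabolic demand"
            )
        new_nodes.append(replace(nd, loss=float(x)))
    return FoodWeb(
        nodes=new_nodes,
        links=list(web.links),
        losses_per_unit_biomass=False,
        temperature_C=web.temperature_C,
        units=dict(web.units),
        metadata={**web.metadata, "fmr_multiplier": fmr_multiplier},
    )
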