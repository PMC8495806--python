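"""Guild-structured synthetic communities and the worked chain fixture.

The generator emulates a plot-scale community assessment of a temperate
grassland arthropod web: plants and detritus as basal pools, detritivore,
herbivore, omnivore and predator guilds as consumers, each node carrying
a lognormal sample of individual fresh body masses (mg) and an abundance
density (individuals / m^2), with biomass coherent with abundance times
mean mass.  Feeding links follow guild adjacency rules with a connection
probability per guild pair; the guild hierarchy is acyclic by
construction, and every consumer is guaranteed at least one resource, so
generated webs are always energetically feasible.

Guild-based generation is used instead of a niche-model topology because
guild labels are what downstream efficiency assignment and
function-metric aggregation key on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import WebBuildError
from .web_model import FoodWeb, build_web

#: fixed generation order: basal guilds first, consumers in trophic order
GUILD_ORDER = ("plant", "detritus", "detritivore", "herbivore", "omnivore", "predator")

BASAL_GUILDS = ("plant", "detritus")

#: guild -> resource_type when eaten
_RESOURCE_TYPE = {
    "plant": "plant",
    "detritus": "detritus",
    "detritivore": "animal",
    "herbivore": "animal",
    "omnivore": "animal",
    "predator": "animal",
}

DEFAULT_COUNTS = {
    "plant": 4,
    "detritus": 2,
    "detritivore": 3,
    "herbivore": 3,
    "omnivore": 2,
    "predator": 3,
}

# natural-log mean / sd of individual fresh mass (mg): detritivores and
# herbivores a few mg, omnivores ~8 mg, predators ~20 mg
DEFAULT_BODY_MASS_LOGNORM = {
    "detritivore": (np.log(2.0), 0.6),
    "herbivore": (np.log(3.0), 0.6),
    "omnivore": (np.log(8.0), 0.6),
    "predator": (np.log(20.0), 0.6),
}

# individuals / m^2
DEFAULT_ABUNDANCE_LOGNORM = {
    "detritivore": (np.log(200.0), 0.5),
    "herbivore": (np.log(150.0), 0.5),
    "omnivore": (np.log(30.0), 0.5),
    "predator": (np.log(20.0), 0.5),
}

# basal biomass pools, mg fresh mass / m^2 (plants ~50 g, litter ~100 g)
DEFAULT_BASAL_BIOMASS_LOGNORM = {
    "plant": (np.log(5.0e4), 0.4),
    "detritus": (np.log(1.0e5), 0.4),
}

# consumer guild -> {resource guild: connection probability}
DEFAULT_LINK_RULES = {
    "detritivore": {"detritus": 0.9},
    "herbivore": {"plant": 0.8},
    "omnivore": {"plant": 0.5, "detritus": 0.5, "herbivore": 0.4, "detritivore": 0.4},
    "predator": {"herbivore": 0.6, "detritivore": 0.6, "omnivore": 0.5},
}

DEFAULT_UNITS = {"mass": "mg fresh", "area": "m^2", "energy": "J", "time": "h"}


@dataclass
class GeneratorConfig:
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    body_mass_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BODY_MASS_LOGNORM)
    )
    abundance_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCE_LOGNORM)
    )
    basal_biomass_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASAL_BIOMASS_LOGNORM)
    )
    link_rules: dict[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_LINK_RULES.items()}
    )
    individuals_sampled: tuple[int, int] = (8, 25)  # sub-sample size per node
    temperature_C: float = 20.0
    seed: int | None = None

    def __post_init__(self):
        for g, c in self.counts.items():
            if c < 0:
                raise WebBuildError(f"negative count for guild {g!r}")
        for g, rules in self.link_rules.items():
            for r, p in rules.items():
                if not (0 <= p <= 1):
                    raise WebBuildError(f"connection probability {g}->{r} outside [0,1]")


def generate_web(config: GeneratorConfig | None = None, seed: int | None = None) -> FoodWeb:
    """Draw one reproducible guild-structured web.

    ``seed`` overrides ``config.seed``.  Raises :class:`WebBuildError`
    for impossible configurations (no basal guild, or a consumer guild
    whose permitted resource guilds are all empty).
    """
    config = config or GeneratorConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    counts = {g: int(config.counts.get(g, 0)) for g in GUILD_ORDER}
    n_basal = sum(counts[g] for g in BASAL_GUILDS)
    consumer_guilds = [g for g in GUILD_ORDER if g not in BASAL_GUILDS and counts[g] > 0]
    if n_basal == 0:
        raise WebBuildError("impossible config: no basal guild present")
    if not consumer_guilds:
        raise WebBuildError("impossible config: no consumer guild present")
    for g in consumer_guilds:
        rules = config.link_rules.get(g, {})
        if not any(counts.get(r, 0) > 0 and p > 0 for r, p in rules.items()):
            raise WebBuildError(
                f"impossible config: consumer guild {g!r} has no permitted "
                "resource guild with nodes"
            )

    node_recs: list[dict] = []
    by_guild: dict[str, list[str]] = {}
    for guild in GUILD_ORDER:
        for i in range(counts[guild]):
            nid = f"{guild}_{i + 1}"
            by_guild.setdefault(guild, []).append(nid)
            rec = dict(node_id=nid, guild=guild, resource_type=_RESOURCE_TYPE[guild])
            if guild in BASAL_GUILDS:
                mu, sd = config.basal_biomass_lognorm[guild]
                rec["biomass"] = float(rng.lognormal(mu, sd))
            else:
                mu, sd = config.body_mass_lognorm[guild]
                lo, hi = config.individuals_sampled
                m = int(rng.integers(lo, hi + 1))
                masses = rng.lognormal(mu, sd, size=m)
                amu, asd = config.abundance_lognorm[guild]
                abundance = float(rng.lognormal(amu, asd))
                rec["body_masses"] = tuple(float(x) for x in masses)
                rec["mean_body_mass"] = float(masses.mean())
                rec["abundance"] = abundance
                rec["biomass"] = abundance * float(masses.mean())
            node_recs.append(rec)

    link_recs: list[dict] = []
    for guild in consumer_guilds:
        rules = config.link_rules.get(guild, {})
        for cid in by_guild.get(guild, []):
            candidates: list[str] = []
            chosen: list[str] = []
            for rguild, p in rules.items():
                for rid in by_guild.get(rguild, []):
                    candidates.append(rid)
                    if rng.random() < p:
                        chosen.append(rid)
            if not chosen:  # rejection-resample: every consumer eats something
                chosen = [candidates[int(rng.integers(len(candidates)))]]
            link_recs.extend(
                dict(resource_id=rid, consumer_id=cid) for rid in chosen
            )

    return build_web(
        node_recs,
        link_recs,
        options=dict(
            losses_per_unit_biomass=False,
            temperature_C=config.temperature_C,
            units=dict(DEFAULT_UNITS),
            metadata={"generator_seed": seed},
        ),
    )


def fixture_chain() -> FoodWeb:
    """The three-node plant -> herbivore -> predator worked chain.

    Losses are per node in abstract energy units: X = 2 for the
    herbivore, X = 1 for the predator.  With the bundled efficiency
    defaults the hand solution is F(herb->pred) = 1/0.906 and
    F(plant->herb) = (2 + 1/0.906)/0.545.
    """
    nodes = [
        dict(
            node_id="plant", name="plant", guild="plant", resource_type="plant",
            biomass=1000.0,
        ),
        dict(
            node_id="herbivore", name="herbivore", guild="herbivore",
            resource_type="animal", biomass=100.0, loss=2.0,
        ),
        dict(
            node_id="predator", name="predator", guild="predator",
            resource_type="animal", biomass=10.0, loss=1.0,
        ),
    ]
    links = [
        dict(resource_id="plant", consumer_id="herbivore"),
        dict(resource_id="herbivore", consumer_id="predator"),
    ]
    return build_web(
        nodes,
        links,
        options=dict(
            losses_per_unit_biomass=False,
            temperature_C=20.0,
            units={"mass": "mg fresh", "area": "m^2", "energy": "a.u.", "time": "a.u."},
        ),
    )
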