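"""Web construction, validation, aggregation and ordering."""

import pytest

import trophicflux as tf
from trophicflux.web_model import AggregationWarning

from conftest import make_solved_web


def simple_nodes(**overrides):
    nodes = [
        dict(node_id="plant", guild="plant", resource_type="plant", biomass=100.0),
        dict(node_id="herb", guild="herbivore", resource_type="animal", biomass=10.0, loss=2.0),
        dict(node_id="pred", guild="predator", resource_type="animal", biomass=1.0, loss=1.0),
    ]
    for rec in nodes:
        rec.update(overrides.get(rec["node_id"], {}))
    return nodes


SIMPLE_LINKS = [
    dict(resource_id="plant", consumer_id="herb"),
    dict(resource_id="herb", consumer_id="pred"),
]


class TestBuildWeb:
    def test_chain_structure(self):
        web = tf.build_web(simple_nodes(), SIMPLE_LINKS)
        assert web.basal_ids == ("plant",)
        assert len(web.links) == 2
        assert web.node("plant").is_basal and not web.node("herb").is_basal

    @pytest.mark.parametrize(
        "nodes,links,match",
        [
            (  # no consumer: one node, zero links
                [dict(node_id="p", guild="plant", resource_type="plant", biomass=1.0)],
                [],
                "no consumer",
            ),
            (  # duplicated id names the offender
                simple_nodes() + [dict(node_id="plant", guild="plant", resource_type="plant", biomass=1.0)],
                SIMPLE_LINKS,
                "plant",
            ),
            (  # dangling endpoint
                simple_nodes(),
                SIMPLE_LINKS + [dict(resource_id="ghost", consumer_id="pred")],
                "ghost",
            ),
            (  # negative biomass
                simple_nodes(plant={"biomass": -1.0}),
                SIMPLE_LINKS,
                "negative biomass",
            ),
            (  # negative active weight
                simple_nodes(),
                [dict(resource_id="plant", consumer_id="herb", active_weight=-0.5),
                 dict(resource_id="herb", consumer_id="pred")],
                "negative",
            ),
            (  # user basal flag contradicting topology
                simple_nodes(herb={"is_basal": True}),
                SIMPLE_LINKS,
                "contradicts topology",
            ),
            (  # passive-only cannibalism is refused
                simple_nodes(),
                SIMPLE_LINKS + [dict(resource_id="pred", consumer_id="pred")],
                "explicit",
            ),
        ],
    )
    def test_rejects_bad_input(self, nodes, links, match):
        with pytest.raises(tf.WebBuildError, match=match):
            tf.build_web(nodes, links)

    def test_self_link_with_explicit_weight_allowed(self):
        links = SIMPLE_LINKS + [dict(resource_id="pred", consumer_id="pred", active_weight=0.05)]
        web = tf.build_web(simple_nodes(), links)
        assert len(web.links) == 3

    def test_user_basal_flag_accepted_when_consistent(self):
        web = tf.build_web(simple_nodes(plant={"is_basal": True}), SIMPLE_LINKS)
        assert web.node("plant").is_basal


class TestValidateWeb:
    def test_clean_chain_has_no_diagnostics(self, chain):
        assert tf.validate_web(chain) == []

    def test_zero_biomass_diet_is_an_error(self):
        web = tf.build_web(simple_nodes(plant={"biomass": 0.0}), SIMPLE_LINKS)
        diags = tf.validate_web(web, passive_preferences=True)
        assert any(d.severity == "error" and d.code == "zero-biomass-diet" for d in diags)

    def test_missing_metabolic_route_is_an_error(self):
        web = tf.build_web(simple_nodes(herb={"loss": None}), SIMPLE_LINKS)
        diags = tf.validate_web(web)
        assert any(d.code == "no-metabolic-route" and "herb" in d.message for d in diags)

    def test_missing_units_and_unreachable_warn(self):
        # c1 and c2 form a mutual-predation island with no basal support
        nodes = simple_nodes() + [
            dict(node_id="c1", guild="predator", resource_type="animal", biomass=1.0, loss=0.1),
            dict(node_id="c2", guild="predator", resource_type="animal", biomass=1.0, loss=0.1),
        ]
        links = SIMPLE_LINKS + [
            dict(resource_id="c1", consumer_id="c2"),
            dict(resource_id="c2", consumer_id="c1"),
        ]
        web = tf.build_web(nodes, links)
        diags = tf.validate_web(web)
        codes = {d.code for d in diags}
        assert "missing-units" in codes  # no unit tags supplied here
        unreachable = {d.message.split("'")[1] for d in diags if d.code == "unreachable"}
        assert unreachable == {"c1", "c2"}


class TestAggregation:
    def test_identity_partition_is_identity(self, chain):
        part = {nid: nid for nid in chain.node_ids}
        agg = tf.aggregate_nodes(chain, part)
        assert agg.node_ids == chain.node_ids
        assert [ (l.resource_id, l.consumer_id) for l in agg.links ] == [
            (l.resource_id, l.consumer_id) for l in chain.links
        ]
        assert agg.biomass_vector() == pytest.approx(chain.biomass_vector())

    def test_parallel_merge_conserves_biomass_loss_and_influx(self):
        # 5-node web: two parallel predators share the same prey
        nodes = [
            dict(node_id="plant", guild="plant", resource_type="plant", biomass=100.0),
            dict(node_id="h1", guild="herbivore", resource_type="animal", biomass=20.0, loss=2.0),
            dict(node_id="h2", guild="herbivore", resource_type="animal", biomass=10.0, loss=1.0),
            dict(node_id="p1", guild="predator", resource_type="animal", biomass=2.0, loss=0.5),
            dict(node_id="p2", guild="predator", resource_type="animal", biomass=1.0, loss=0.25),
        ]
        links = [
            dict(resource_id="plant", consumer_id="h1"),
            dict(resource_id="plant", consumer_id="h2"),
            dict(resource_id="h1", consumer_id="p1"),
            dict(resource_id="h2", consumer_id="p1"),
            dict(resource_id="h1", consumer_id="p2"),
            dict(resource_id="h2", consumer_id="p2"),
        ]
        web = tf.build_web(nodes, links, options=dict(losses_per_unit_biomass=False))

        def solve(w):
            return tf.solve_fluxes(
                w, tf.compute_preferences(w), w.node_loss_vector(), tf.assign_efficiencies(w)
            )

        before = solve(web)
        flux_into_preds = before.consumption[3] + before.consumption[4]

        part = {"plant": "plant", "h1": "h1", "h2": "h2", "p1": "P", "p2": "P"}
        agg = tf.aggregate_nodes(web, part)
        assert agg.metadata["aggregation"]["P"] == "parallel"
        assert agg.node("P").biomass == pytest.approx(3.0)
        assert agg.node("P").loss == pytest.approx(0.75, rel=1e-9)  # per-node losses sum
        after = solve(agg)
        assert after.consumption[agg.index("P")] == pytest.approx(flux_into_preds, rel=1e-9)

    def test_serial_merge_warns(self):
        web = tf.build_web(simple_nodes(), SIMPLE_LINKS)
        part = {"plant": "plant", "herb": "HP", "pred": "HP"}
        with pytest.warns(tf.SerialAggregationWarning):
            agg = tf.aggregate_nodes(web, part)
        assert agg.metadata["aggregation"]["HP"] == "serial"
        # the internal herb->pred link is gone
        assert all(l.resource_id != l.consumer_id for l in agg.links)

    def test_conflicting_resource_type_rejected(self):
        web = tf.build_web(simple_nodes(), SIMPLE_LINKS)
        with pytest.raises(tf.WebBuildError, match="resource_type"):
            tf.aggregate_nodes(web, {"plant": "G", "herb": "G", "pred": "pred"})

    def test_partition_must_cover_all_nodes(self, chain):
        with pytest.raises(tf.WebBuildError, match="cover"):
            tf.aggregate_nodes(chain, {"plant": "a"})

    def test_heterogeneous_merge_warns(self):
        nodes = simple_nodes() + [
            dict(node_id="h2", guild="herbivore", resource_type="animal", biomass=5.0, loss=1.0),
            dict(node_id="plant2", guild="plant", resource_type="plant", biomass=50.0),
        ]
        links = SIMPLE_LINKS + [dict(resource_id="plant2", consumer_id="h2")]
        web = tf.build_web(nodes, links)
        with pytest.warns(AggregationWarning):
            tf.aggregate_nodes(
                web, {"plant": "plant", "plant2": "plant2", "herb": "H", "h2": "H", "pred": "pred"}
            )


class TestTopologicalOrder:
    def test_chain_order_is_top_down(self, chain):
        assert tf.topological_order(chain) == ["predator", "herbivore", "plant"]

    def test_mutual_predation_reports_the_cycle(self):
        nodes = simple_nodes() + []
        links = SIMPLE_LINKS + [dict(resource_id="pred", consumer_id="herb")]
        web = tf.build_web(nodes, links)
        assert tf.cycle_nodes(web) == {"herb", "pred"}
        with pytest.raises(tf.CycleError) as exc:
            tf.topological_order(web)
        assert exc.value.cycle_nodes == {"herb", "pred"}

    @pytest.mark.parametrize("seed", range(5))
    def test_consumers_precede_resources_on_random_dags(self, seed):
        web, *_ = make_solved_web(seed)
        order = tf.topological_order(web)
        pos = {nid: i for i, nid in enumerate(order)}
        for lk in web.links:  # brute-force scan of the ordering property
            assert pos[lk.consumer_id] < pos[lk.resource_id]

    def test_order_is_deterministic(self, chain):
        assert tf.topological_order(chain) == tf.topological_order(chain)
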