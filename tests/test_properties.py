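"""Property-based invariants (hypothesis, derandomized for reproducibility)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lysompn import assoc, bulkrna, diffnet, enrich

SETTINGS = dict(derandomize=True, max_examples=30, deadline=None)

cells = st.integers(min_value=1, max_value=500)


class TestAssocProperties:
    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(**SETTINGS)
    def test_or_swap_reciprocal(self, a, b, c, d):
        forward = assoc.logistic_or(a, b, c, d).odds_ratio
        backward = assoc.logistic_or(c, d, a, b).odds_ratio
        assert forward * backward == pytest.approx(1.0, rel=1e-8)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(**SETTINGS)
    def test_or_matches_cross_product(self, a, b, c, d):
        res = assoc.logistic_or(a, b, c, d)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), abs=1e-8)

    @given(f=st.floats(min_value=0.0, max_value=1.0))
    @settings(**SETTINGS)
    def test_render_percent_in_range(self, f):
        pct = int(assoc.render_percent(f).rstrip("%"))
        assert 0 <= pct <= 100
        assert abs(pct - f * 100) <= 0.5


@st.composite
def gene_sets(draw):
    universe = [f"g{i}" for i in range(12)]
    names = draw(st.lists(st.sampled_from("ABCD"), min_size=2, max_size=4,
                          unique=True))
    return {
        n: set(draw(st.lists(st.sampled_from(universe), min_size=0, max_size=12,
                             unique=True)))
        for n in names
    }


class TestSetProperties:
    @given(sets=gene_sets())
    @settings(**SETTINGS)
    def test_overlap_partition_identity(self, sets):
        out = bulkrna.overlap_sets(sets)
        union = set.union(*sets.values())
        assert out["count"].sum() == len(union)
        listed = {g for s in out["genes"] if s for g in s.split(",")}
        assert listed == union


@st.composite
def rankings(draw):
    n = draw(st.integers(min_value=4, max_value=12))
    vals = draw(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=n, max_size=n, unique=True,
        )
    )
    return enrich.rank_genes(pd.Series(vals, index=[f"g{i}" for i in range(n)]))


class TestEnrichProperties:
    @given(ranked=rankings(), data=st.data())
    @settings(**SETTINGS)
    def test_es_bounded(self, ranked, data):
        genes = list(ranked.index)
        size = data.draw(st.integers(min_value=1, max_value=len(genes) - 1))
        gs = set(genes[:size])
        es = enrich.gsea_es(ranked, gs)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    @given(ranked=rankings())
    @settings(**SETTINGS)
    def test_full_prefix_set_has_positive_es(self, ranked):
        """The set of all strictly-positive top genes scores positive when
        the ranking has both signs."""
        positive = {g for g, v in ranked.items() if v > 0}
        if not positive or len(positive) == len(ranked):
            return
        assert enrich.gsea_es(ranked, positive) > 0

    @given(data=st.data())
    @settings(**SETTINGS)
    def test_ora_p_in_unit_interval(self, data):
        universe = {f"g{i}" for i in range(15)}
        hits = set(data.draw(st.lists(st.sampled_from(sorted(universe)),
                                      min_size=1, max_size=10, unique=True)))
        gs = set(data.draw(st.lists(st.sampled_from(sorted(universe)),
                                    min_size=1, max_size=10, unique=True)))
        p = enrich.ora_hypergeometric(hits, gs, universe)
        assert 0.0 < p <= 1.0

    @given(data=st.data())
    @settings(**SETTINGS)
    def test_tf_nes_mode_flip(self, data):
        rng = np.random.default_rng(0)
        stats_ = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        targets = data.draw(
            st.lists(st.sampled_from([f"g{i}" for i in range(20)]),
                     min_size=5, max_size=12, unique=True)
        )
        plus = pd.DataFrame({"tf": "T", "target": targets, "mode": 1})
        minus = pd.DataFrame({"tf": "T", "target": targets, "mode": -1})
        a = enrich.tf_nes(stats_, plus).loc[0, "nes"]
        b = enrich.tf_nes(stats_, minus).loc[0, "nes"]
        assert a == pytest.approx(-b)


class TestNetworkProperties:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(**SETTINGS)
    def test_identical_groups_yield_no_differential_edges(self, seed):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.normal(size=(8, 6)), index=[f"g{i}" for i in range(8)]
        )
        net = diffnet.correlation_network(expr, 0.6, group="x")
        template = pd.DataFrame(
            {"gene_a": ["g0"], "gene_b": ["g1"], "score": [999]}
        )
        assert diffnet.differential_edges(net, net, template).n_edges == 0

    @given(seed=st.integers(min_value=0, max_value=10_000),
           thr=st.floats(min_value=0.1, max_value=0.9))
    @settings(**SETTINGS)
    def test_edge_count_monotone_in_threshold(self, seed, thr):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.normal(size=(10, 5)), index=[f"g{i}" for i in range(10)]
        )
        low = diffnet.correlation_network(expr, thr)
        high = diffnet.correlation_network(expr, min(thr + 0.2, 0.99))
        assert len(high.edges) <= len(low.edges)


class TestDegProperties:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, deadline=None, max_examples=10)
    def test_deg_antisymmetric_and_bh_dominates(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.poisson(80, size=(25, 8)),
            index=[f"g{i}" for i in range(25)],
            columns=[f"s{i}" for i in range(8)],
        )
        meta = pd.DataFrame(
            {"sample_id": counts.columns,
             "ld_status": ["carrier"] * 4 + ["noncarrier"] * 4}
        )
        fwd = bulkrna.run_deg(counts, meta)
        rev = bulkrna.run_deg(counts, meta, case="noncarrier", control="carrier")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        assert (fwd["q"] >= fwd["p"] - 1e-12).all()
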