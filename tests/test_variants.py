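import numpy as np
import pandas as pd
import pytest

from lysompn import variants
from tests.conftest import make_variant_row

PANEL = ["GBA", "HEXA", "NPC1"]


def _table(rows):
    return pd.DataFrame(rows)


class TestFilterVariants:
    def test_retained_variant_has_empty_reason(self):
        out = variants.filter_variants(_table([make_variant_row()]), PANEL)
        assert out["excluded_reason"].tolist() == [""]

    @pytest.mark.parametrize(
        "overrides,reason",
        [
            ({"gene": "BRCA1"}, "off_panel"),
            ({"depth": 10, "alt_reads": 6}, "low_depth"),
            ({"alt_reads": 5}, "low_alt"),
            ({"gnomad_af": 0.0051}, "common_af"),
        ],
    )
    def test_exclusion_reasons(self, overrides, reason):
        out = variants.filter_variants(_table([make_variant_row(**overrides)]), PANEL)
        assert out["excluded_reason"].tolist() == [reason]

    def test_boundaries_are_strict(self):
        # depth 11 / alt 6 / AF exactly 0.005 all pass
        keep = make_variant_row(depth=11, alt_reads=6, gnomad_af=0.005)
        out = variants.filter_variants(_table([keep]), PANEL)
        assert out["excluded_reason"].tolist() == [""]

    def test_missing_af_is_retained(self):
        out = variants.filter_variants(
            _table([make_variant_row(gnomad_af=np.nan)]), PANEL
        )
        assert out["excluded_reason"].tolist() == [""]

    def test_off_panel_takes_precedence(self):
        row = make_variant_row(gene="BRCA1", depth=5, alt_reads=1, gnomad_af=0.2)
        out = variants.filter_variants(_table([row]), PANEL)
        assert out["excluded_reason"].tolist() == ["off_panel"]

    def test_empty_panel_raises(self):
        with pytest.raises(ValueError, match="panel"):
            variants.filter_variants(_table([make_variant_row()]), [])

    def test_row_order_invariance(self):
        rows = [
            make_variant_row(subject_id=f"S{i}", depth=d, gnomad_af=af)
            for i, (d, af) in enumerate([(50, 0.001), (8, 0.001), (50, 0.2)])
        ]
        a = variants.filter_variants(_table(rows), PANEL)
        b = variants.filter_variants(_table(rows[::-1]), PANEL)
        merged = a.merge(b, on="subject_id", suffixes=("_a", "_b"))
        assert (merged["excluded_reason_a"] == merged["excluded_reason_b"]).all()


class TestAssignTiers:
    @pytest.mark.parametrize(
        "consequence",
        sorted(variants.DEFAULT_PTV_TERMS),
    )
    def test_ptv_terms_are_tier1(self, consequence):
        out = variants.assign_tiers(_table([make_variant_row(consequence=consequence)]))
        assert out["tier1"].tolist() == [True]

    def test_frameshift_indel_is_tier1(self):
        row = make_variant_row(consequence="frameshift_variant", is_indel=True)
        out = variants.assign_tiers(_table([row]))
        assert bool(out["tier1"][0])

    @pytest.mark.parametrize(
        "sig", ["Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic"]
    )
    def test_clinvar_pathogenic_is_tier2(self, sig):
        out = variants.assign_tiers(
            _table([make_variant_row(clinvar_significance=sig)])
        )
        assert out["tier2"].tolist() == [True]
        assert out["tier1"].tolist() == [False]

    def test_both_tiers_possible(self):
        row = make_variant_row(
            consequence="stop_gained", clinvar_significance="Pathogenic"
        )
        out = variants.assign_tiers(_table([row]))
        assert bool(out["tier1"][0]) and bool(out["tier2"][0])

    def test_benign_missense_is_non_qualifying(self):
        out = variants.assign_tiers(
            _table([make_variant_row(clinvar_significance="Benign")])
        )
        assert out["excluded_reason"].tolist() == ["non_qualifying"]

    def test_excluded_variants_never_tiered(self):
        row = make_variant_row(consequence="stop_gained", depth=5)
        filtered = variants.filter_variants(_table([row]), PANEL)
        out = variants.assign_tiers(filtered)
        assert not out["tier1"].any() and not out["tier2"].any()

    def test_unknown_consequence_warns(self):
        with pytest.warns(UserWarning, match="unknown consequence"):
            out = variants.assign_tiers(
                _table([make_variant_row(consequence="made_up_term")])
            )
        assert out["excluded_reason"].tolist() == ["non_qualifying"]


class TestCallCarriers:
    def _roster(self, ids):
        return pd.DataFrame({"subject_id": ids, "group": ["PV"] * len(ids)})

    def test_carrier_and_noncarrier(self):
        tiered = variants.assign_tiers(
            _table(
                [
                    make_variant_row(subject_id="A", consequence="stop_gained"),
                    make_variant_row(subject_id="B"),  # non-qualifying
                ]
            )
        )
        out = variants.call_carriers(tiered, self._roster(["A", "B", "C"]))
        assert dict(zip(out["subject_id"], out["is_carrier"])) == {
            "A": True,
            "B": False,
            "C": False,
        }

    def test_set_union_oracle(self, cohort_data, sim):
        """Carrier set == union of subjects with >= 1 qualifying variant."""
        from lysompn import synthio

        cohort, _ = cohort_data
        table = synthio.simulate_variant_table(cohort, synthio.LD_PANEL, sim)
        tiered = variants.assign_tiers(
            variants.filter_variants(table, synthio.LD_PANEL)
        )
        called = variants.call_carriers(tiered, cohort)
        oracle = set(tiered.loc[tiered["tier1"] | tiered["tier2"], "subject_id"])
        assert set(called.loc[called["is_carrier"], "subject_id"]) == oracle

    def test_unknown_subject_raises(self):
        tiered = variants.assign_tiers(
            _table([make_variant_row(subject_id="GHOST")])
        )
        with pytest.raises(ValueError, match="not in roster"):
            variants.call_carriers(tiered, self._roster(["A"]))

    def test_duplicate_roster_raises(self):
        tiered = variants.assign_tiers(_table([make_variant_row(subject_id="A")]))
        with pytest.raises(ValueError, match="duplicate"):
            variants.call_carriers(tiered, self._roster(["A", "A"]))


class TestTierSummary:
    def test_inclusion_exclusion_identity(self):
        rows = (
            [make_variant_row(subject_id=f"T1_{i}", consequence="stop_gained")
             for i in range(3)]
            + [make_variant_row(subject_id=f"T2_{i}",
                                clinvar_significance="Pathogenic")
               for i in range(4)]
            + [make_variant_row(subject_id=f"TB_{i}", consequence="stop_gained",
                                clinvar_significance="Pathogenic")
               for i in range(2)]
        )
        s = variants.tier_summary(variants.assign_tiers(_table(rows)))
        assert s["n_distinct"] == s["n_tier1"] + s["n_tier2"] - s["n_both"]
        assert (s["n_tier1"], s["n_tier2"], s["n_both"]) == (5, 6, 2)

    def test_genes_hit_sorted_unique(self):
        rows = [
            make_variant_row(gene=g, consequence="stop_gained")
            for g in ["NPC1", "GBA", "NPC1"]
        ]
        s = variants.tier_summary(variants.assign_tiers(_table(rows)))
        assert s["genes_hit"] == ["GBA", "NPC1"]
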