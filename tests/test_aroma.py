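import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tomatoq as tq
from tomatoq.aroma import CANONICAL_AROMA_TYPES, OAVMatrix, parse_descriptor_field


def _matrix(values: dict, thresholds: dict) -> OAVMatrix:
    df = pd.DataFrame(values).T
    return OAVMatrix(values=df, thresholds=pd.Series(thresholds))


class TestComputeOav:
    def test_at_threshold(self):
        assert tq.compute_oav(4.5, 4.5) == 1.0

    def test_not_detected(self):
        assert tq.compute_oav(0.0, 3.0) == 0.0

    def test_hexanal_cell(self):
        # 136.53 ug/kg over the 4.5 ug/kg threshold
        assert tq.compute_oav(136.53, 4.5) == pytest.approx(30.34)

    @given(c=st.floats(0, 1e6), k=st.floats(0.01, 100))
    def test_homogeneous_in_concentration(self, c, k):
        assert tq.compute_oav(k * c, 2.0) == pytest.approx(
            k * tq.compute_oav(c, 2.0), rel=1e-12
        )

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            tq.compute_oav(1.0, 0.0)


class TestOavMatrix:
    def test_built_from_concentrations(self):
        conc = pd.DataFrame(
            {
                "variety_id": ["V1", "V2", "V1"],
                "compound_name": ["hexanal", "hexanal", "decanal"],
                "concentration": [9.0, 4.5, 0.2],
            }
        )
        registry = [
            tq.CompoundRecord("hexanal", odor_threshold=4.5),
            tq.CompoundRecord("decanal", odor_threshold=0.1),
        ]
        m = tq.oav_matrix(conc, registry)
        assert m.values.loc["hexanal", "V1"] == pytest.approx(2.0)
        assert m.values.loc["decanal", "V2"] == 0.0  # not detected there

    def test_missing_threshold_skipped_with_warning(self, caplog):
        conc = pd.DataFrame(
            {"variety_id": ["V1"], "compound_name": ["styrene"], "concentration": [5.0]}
        )
        with caplog.at_level("WARNING"):
            m = tq.oav_matrix(conc, [tq.CompoundRecord("styrene")])
        assert m.compounds == []
        assert "styrene" in caplog.text


class TestSelectCharacteristic:
    def test_reference_panel_has_34(self, table2):
        matrix, _, _ = table2
        assert len(tq.select_characteristic(matrix)) == 34

    def test_all_zero_matrix(self):
        m = _matrix({"c1": {"V1": 0.0, "V2": 0.0}}, {"c1": 1.0})
        assert tq.select_characteristic(m) == []

    def test_boundary_exactly_one_excluded(self):
        m = _matrix({"c1": {"V1": 1.0, "V2": 0.5}}, {"c1": 1.0})
        assert tq.select_characteristic(m) == []

    def test_union_of_per_variety_sets(self, table2):
        matrix, _, _ = table2
        union = set()
        for v in matrix.varieties:
            union |= set(tq.shared_compounds(matrix, [v]))
        assert union == set(tq.select_characteristic(matrix))


class TestSharedCompounds:
    def test_regular_group_contains_printed_set(self, table2, group_varieties):
        matrix, _, _ = table2
        shared = {c.lower() for c in tq.shared_compounds(matrix, group_varieties["regular"])}
        printed = {
            "linalool",
            "β-ionone",
            "decanal",
            "hexanal",
            "(z)-3-hexenal",
            "(e)-2-hexenal",
            "2-isobutylthiazole",
            "3-methylbutanal",
            "(e)-2-octenal",
            "1-octen-3-one",
        }
        assert printed <= shared

    def test_single_variety_equals_characteristic_set(self, table2):
        matrix, _, _ = table2
        v = matrix.varieties[0]
        per_variety = matrix.values.index[matrix.values[v] > 1.0]
        assert tq.shared_compounds(matrix, [v]) == list(per_variety)

    def test_disjoint_detection_patterns(self):
        m = _matrix(
            {"c1": {"V1": 5.0, "V2": 0.0}, "c2": {"V1": 0.0, "V2": 5.0}},
            {"c1": 1.0, "c2": 1.0},
        )
        assert tq.shared_compounds(m, ["V1", "V2"]) == []

    def test_unknown_variety_rejected(self, table2):
        matrix, _, _ = table2
        with pytest.raises(KeyError, match="Z9"):
            tq.shared_compounds(matrix, ["P1", "Z9"])

    def test_intersection_over_union_of_subsets(self, table2, group_varieties):
        matrix, _, _ = table2
        s1, s2 = group_varieties["regular"], group_varieties["tasty"]
        combined = tq.shared_compounds(matrix, s1 + s2)
        expected = set(tq.shared_compounds(matrix, s1)) & set(
            tq.shared_compounds(matrix, s2)
        )
        assert set(combined) == expected


class TestDescriptors:
    def test_already_canonical(self):
        dmap = tq.DescriptorMap.default()
        assert tq.normalize_descriptors(["fruity", "sweet", "green"], dmap) == {
            "fruity",
            "sweet",
            "green",
        }

    def test_synonyms_fold_to_canonical(self):
        dmap = tq.DescriptorMap.default()
        assert tq.normalize_descriptors(["citrus", "floral", "sweet"], dmap) == {
            "fruity",
            "floral",
            "sweet",
        }

    def test_empty(self):
        assert tq.normalize_descriptors([], tq.DescriptorMap.default()) == set()

    def test_unmapped_descriptor_named_in_error(self):
        dmap = tq.DescriptorMap.default()
        with pytest.raises(KeyError, match="smoky"):
            tq.normalize_descriptors(["smoky"], dmap)

    def test_fused_token_yields_both_types(self):
        dmap = tq.DescriptorMap.default()
        assert tq.normalize_descriptors(["fruity sweet"], dmap) == {"fruity", "sweet"}

    def test_parse_field(self):
        assert parse_descriptor_field("Citrus, floral, sweet") == [
            "citrus",
            "floral",
            "sweet",
        ]

    def test_every_reference_descriptor_is_mapped(self, table2):
        matrix, descriptors, _ = table2
        dmap = tq.DescriptorMap.default()
        for comp in matrix.compounds:
            types = tq.normalize_descriptors(descriptors[comp], dmap)
            assert types <= set(CANONICAL_AROMA_TYPES)
            assert types


class TestAromaTypeProfile:
    def test_multi_type_duplication_rule(self):
        m = _matrix({"c1": {"V1": 5.0}}, {"c1": 1.0})
        prof = tq.aroma_type_profile(
            m, ["V1"], {"c1": ["fruity", "green"]}, tq.DescriptorMap.default()
        )
        assert prof["fruity"] == 5.0
        assert prof["green"] == 5.0
        assert prof.drop(["fruity", "green"]).sum() == 0.0

    def test_additive_within_type(self):
        m = _matrix({"c1": {"V1": 2.0}, "c2": {"V1": 3.0}}, {"c1": 1.0, "c2": 1.0})
        prof = tq.aroma_type_profile(
            m, ["V1"], {"c1": ["woody"], "c2": ["woody"]}, tq.DescriptorMap.default()
        )
        assert prof["woody"] == 5.0

    def test_additive_over_disjoint_compound_subsets(self, table2, group_varieties):
        matrix, descriptors, _ = table2
        dmap = tq.DescriptorMap.default()
        vs = group_varieties["tasty"]
        half = matrix.compounds[:17]
        rest = matrix.compounds[17:]
        full = tq.aroma_type_profile(matrix, vs, descriptors, dmap)
        split = tq.aroma_type_profile(
            matrix, vs, descriptors, dmap, compounds=half
        ) + tq.aroma_type_profile(matrix, vs, descriptors, dmap, compounds=rest)
        assert np.allclose(full, split)

    def test_group_mean_vs_sum_scaling(self, table2, group_varieties):
        matrix, descriptors, _ = table2
        dmap = tq.DescriptorMap.default()
        vs = group_varieties["cherry"]
        mean_prof = tq.aroma_type_profile(matrix, vs, descriptors, dmap, agg="mean")
        sum_prof = tq.aroma_type_profile(matrix, vs, descriptors, dmap, agg="sum")
        assert np.allclose(sum_prof, mean_prof * len(vs))

    def test_profile_has_13_ordered_types(self, table2, group_varieties):
        matrix, descriptors, _ = table2
        prof = tq.aroma_type_profile(
            matrix, group_varieties["regular"], descriptors, tq.DescriptorMap.default()
        )
        assert list(prof.index) == list(CANONICAL_AROMA_TYPES)
        assert (prof >= 0).all()
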