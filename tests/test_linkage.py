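import itertools

import numpy as np
import pandas as pd
import pytest

from vpop import (
    FieldComparison,
    LinkageConfig,
    assemble,
    build_candidate_sets,
    matching_weight,
)
from vpop.errors import ConfigError
from vpop.linkage import weights_from_mu_probabilities

F2 = [FieldComparison(field=f, agreement_weight=2.0, disagreement_weight=-1.0)
      for f in ("a", "b", "c")]


class TestMatchingWeight:
    def test_all_agree(self):
        rec = {"a": 1, "b": "x", "c": 3}
        assert matching_weight(rec, dict(rec), F2) == 6.0

    def test_all_disagree(self):
        fields = [FieldComparison(field=f, agreement_weight=2.0,
                                  disagreement_weight=-1.0) for f in "abc"]
        assert matching_weight({"a": 1, "b": 1, "c": 1},
                               {"a": 2, "b": 2, "c": 2}, fields) == -3.0

    def test_mixed_agreement_hand_sum(self):
        got = matching_weight({"a": 1, "b": 2, "c": 9},
                              {"a": 1, "b": 2, "c": 3}, F2)
        # per-field enumeration: +2 +2 -1
        assert got == 3.0

    def test_missing_field_contributes_zero(self):
        fields = [FieldComparison(field="a"), FieldComparison(field="b")]
        assert matching_weight({"a": 1}, {"a": 1, "b": 2}, fields) == 1.0
        assert matching_weight({"a": 1, "b": float("nan")},
                               {"a": 1, "b": 2}, fields) == 1.0

    def test_numeric_comparator_uses_tolerance(self):
        fields = [FieldComparison(field="x", comparator="numeric",
                                  agreement_weight=1.0,
                                  disagreement_weight=-1.0, tolerance=0.5)]
        assert matching_weight({"x": 1.0}, {"x": 1.4}, fields) == 1.0
        assert matching_weight({"x": 1.0}, {"x": 1.6}, fields) == -1.0


class TestConfigInvariants:
    def test_agreement_must_exceed_disagreement(self):
        with pytest.raises(ConfigError):
            FieldComparison(field="x", agreement_weight=-1.0,
                            disagreement_weight=1.0)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ConfigError):
            FieldComparison(field="x", comparator="numeric", tolerance=-0.1)

    def test_absent_field_rejected(self):
        config = LinkageConfig(0, 0, [FieldComparison(field="nope")],
                               [FieldComparison(field="g")])
        a = pd.DataFrame({"a": [1]})
        b = pd.DataFrame({"g": [1]})
        c = pd.DataFrame({"nope": [1], "g": [1]})
        with pytest.raises(ConfigError, match="nope"):
            build_candidate_sets(a, b, c, config)

    def test_fellegi_sunter_weights(self):
        agree, disagree = weights_from_mu_probabilities(0.9, 0.1)
        assert agree == pytest.approx(np.log2(9))
        assert disagree == pytest.approx(np.log2(1 / 9))
        with pytest.raises(ConfigError):
            weights_from_mu_probabilities(0.1, 0.9)


def _toy_tables():
    a = pd.DataFrame({"sex": ["m", "f", "m"], "diabetes": [1, 0, 0]})
    b = pd.DataFrame({"vessel": ["LAD", "RCA"]})
    c = pd.DataFrame({"sex": ["m", "f"], "diabetes": [1, 1],
                      "vessel": ["LAD", "LAD"]})
    config = LinkageConfig(
        threshold_ac=0.0, threshold_bc=0.0,
        fields_ac=[FieldComparison(field="sex"),
                   FieldComparison(field="diabetes")],
        fields_bc=[FieldComparison(field="vessel")],
    )
    return a, b, c, config


class TestCandidateSets:
    def test_threshold_above_max_empties_all_sets(self):
        a, b, c, config = _toy_tables()
        config.threshold_ac = 99.0
        sets = build_candidate_sets(a, b, c, config)
        assert all(len(v) == 0 for v in sets.v_ac)

    def test_threshold_below_min_admits_everything(self):
        a, b, c, config = _toy_tables()
        config.threshold_ac = -99.0
        config.threshold_bc = -99.0
        sets = build_candidate_sets(a, b, c, config)
        assert all(v == [0, 1, 2] for v in sets.v_ac)
        assert all(v == [0, 1] for v in sets.v_bc)

    def test_strict_inequality_excludes_ties(self):
        a, b, c, config = _toy_tables()
        # weight of A row 1 vs C row 1: sex agrees (+1), diabetes disagrees (-1) -> 0
        config.threshold_ac = 0.0
        sets = build_candidate_sets(a, b, c, config)
        assert 1 not in sets.v_ac[1]

    def test_toy_sets_match_exhaustive_enumeration(self):
        a, b, c, config = _toy_tables()
        sets = build_candidate_sets(a, b, c, config)
        for k in range(len(c)):
            expected_a = [
                i for i in range(len(a))
                if matching_weight(a.iloc[i].to_dict(), c.iloc[k].to_dict(),
                                   config.fields_ac) > config.threshold_ac
            ]
            assert sets.v_ac[k] == expected_a


def _brute_force_size(a, b, c, config):
    """Independent enumeration of |C| + sum over c_k of |V_AC^k|*|V_BC^k|."""
    total = len(c)
    for k in range(len(c)):
        rc = c.iloc[k].to_dict()
        n_a = sum(
            1 for i in range(len(a))
            if matching_weight(a.iloc[i].to_dict(), rc, config.fields_ac)
            > config.threshold_ac
        )
        n_b = sum(
            1 for j in range(len(b))
            if matching_weight(b.iloc[j].to_dict(), rc, config.fields_bc)
            > config.threshold_bc
        )
        total += n_a * n_b
    return total


class TestAssemble:
    def test_no_links_returns_bridge_only(self):
        a, b, c, config = _toy_tables()
        config.threshold_ac = 99.0
        pop = assemble(a, b, c, config)
        assert pop.size == len(c)
        assert (pop.records["provenance"] == "bridge").all()

    def test_size_formula_example(self):
        # |C|=2, every A matches (3), every B matches (2): 2 + 2*(3*2) = 14
        a = pd.DataFrame({"grp": [1, 1, 1]})
        b = pd.DataFrame({"band": [2, 2]})
        c = pd.DataFrame({"grp": [1, 1], "band": [2, 2]})
        config = LinkageConfig(0.5, 0.5, [FieldComparison(field="grp")],
                               [FieldComparison(field="band")])
        pop = assemble(a, b, c, config)
        assert pop.size == 14
        assert pop.counts == {"bridge": 2, "linked": 12}

    def test_duplication_across_candidate_sets_allowed(self):
        a = pd.DataFrame({"grp": [1]})
        b = pd.DataFrame({"band": [2]})
        c = pd.DataFrame({"grp": [1, 1], "band": [2, 2]})
        config = LinkageConfig(0.5, 0.5, [FieldComparison(field="grp")],
                               [FieldComparison(field="band")])
        pop = assemble(a, b, c, config)
        linked = pop.records[pop.records.provenance == "linked"]
        assert len(linked) == 2  # the single A row linked through both c_k

    def test_no_field_mixing(self):
        a, b, c, config = _toy_tables()
        pop = assemble(a, b, c, config)
        linked = pop.records[pop.records.provenance == "linked"]
        for _, row in linked.iterrows():
            assert (row["sex"], row["diabetes"]) in {
                tuple(r) for r in a.itertuples(index=False)
            }
            assert row["vessel"] in set(b["vessel"])

    @pytest.mark.parametrize("seed", range(6))
    def test_size_matches_brute_force_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        na, nb, nc = rng.integers(1, 6, size=3)
        a = pd.DataFrame({"f1": rng.integers(0, 3, na), "f2": rng.integers(0, 2, na)})
        b = pd.DataFrame({"g1": rng.integers(0, 3, nb)})
        c = pd.DataFrame({"f1": rng.integers(0, 3, nc), "f2": rng.integers(0, 2, nc),
                          "g1": rng.integers(0, 3, nc)})
        config = LinkageConfig(
            threshold_ac=float(rng.uniform(-2, 2)),
            threshold_bc=float(rng.uniform(-1, 1)),
            fields_ac=[FieldComparison(field="f1"), FieldComparison(field="f2")],
            fields_bc=[FieldComparison(field="g1")],
        )
        pop = assemble(a, b, c, config)
        assert pop.size == _brute_force_size(a, b, c, config)

    def test_raising_threshold_never_grows_population(self):
        a, b, c, config = _toy_tables()
        sizes = []
        for t in (-5.0, -1.0, 0.0, 1.0, 5.0):
            config.threshold_ac = t
            sizes.append(assemble(a, b, c, config).size)
        assert sizes == sorted(sizes, reverse=True)


def test_config_json_round_trip(tmp_path):
    config = LinkageConfig(
        threshold_ac=1.5, threshold_bc=0.5,
        fields_ac=[FieldComparison(field="age", comparator="numeric",
                                   agreement_weight=2.0,
                                   disagreement_weight=-0.5, tolerance=5.0)],
        fields_bc=[FieldComparison(field="vessel_label")],
    )
    path = tmp_path / "link.json"
    config.to_json(path)
    again = LinkageConfig.from_json(path)
    assert again.threshold_ac == 1.5
    assert again.fields_ac[0].tolerance == 5.0
    assert again.fields_bc[0].field == "vessel_label"
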