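"""Network data model, resources, resource sets, and table validation."""

import random
from itertools import combinations, product

import pytest

from qualnet.network import (
    BRN,
    ConstraintSet,
    GeneVariable,
    Interaction,
    NetworkParseError,
    NetworkValidationError,
    ParameterTable,
    brn_to_sif,
    dump_network,
    load_network,
    parameter_table_from_csv,
    parameter_table_to_csv,
    resource_sets,
    resources,
    sif_to_interactions,
    validate_parameter_table,
)
from qualnet.synthetic import random_brn, random_table


class TestLoadNetwork:
    def test_packaged_network_counts(self, dnmt1):
        assert len(dnmt1.variables) == 6
        assert len(dnmt1.interactions) == 9

    def test_single_node_degenerate_network(self):
        brn = load_network("variables:\n  - {name: A, max: 1}\n")
        assert brn.variable_names == ("A",)
        assert brn.interactions == ()
        assert brn.n_states() == 2

    def test_threshold_above_source_domain_rejected(self):
        text = (
            "variables:\n"
            "  - {name: A, max: 2}\n"
            "  - {name: B, max: 1}\n"
            "interactions:\n"
            "  - {source: B, target: A, sign: '+', threshold: 3}\n"
        )
        with pytest.raises(NetworkValidationError, match="threshold 3"):
            load_network(text)

    @pytest.mark.parametrize(
        "text, match",
        [
            ("variables:\n  - {name: A}\ninteractions:\n"
             "  - {source: A, target: Z, sign: '+'}\n", "undeclared"),
            ("variables:\n  - {name: A}\ninteractions:\n"
             "  - {source: A, target: A, sign: '+'}\n"
             "  - {source: A, target: A, sign: '-'}\n", "duplicate"),
            ("variables:\n  - {name: A}\n  - {name: A}\n", "duplicate"),
        ],
    )
    def test_validation_errors_name_the_offender(self, text, match):
        with pytest.raises(NetworkValidationError, match=match):
            load_network(text)

    def test_parse_error_on_malformed_document(self):
        with pytest.raises(NetworkParseError):
            load_network("interactions: []\n")
        with pytest.raises(NetworkParseError):
            load_network("variables:\n  - {name: A}\ninteractions:\n  - {source: A}\n")

    def test_threshold_defaults_to_one(self):
        brn = load_network(
            "variables: [{name: A}, {name: B}]\n"
            "interactions: [{source: A, target: B, sign: '+'}]\n"
        )
        assert brn.interactions[0].threshold == 1

    def test_round_trip_preserves_everything(self, dnmt1):
        again = load_network(dump_network(dnmt1))
        assert again == dnmt1

    def test_sif_round_trip(self, dnmt1):
        back = sif_to_interactions(brn_to_sif(dnmt1))
        assert set((e.source, e.sign, e.target) for e in back) == set(
            (e.source, e.sign, e.target) for e in dnmt1.interactions
        )


class TestResources:
    def test_dnmt1_resources_with_cmyc_on_and_inhibitors_off(self, dnmt1):
        # c-myc present, p21 and p53 absent: all three regulators favor DNMT1
        state = (0, 0, 0, 1, 0, 0)
        assert resources(dnmt1, state, "DNMT1") == {"CMYC", "P21", "P53"}

    def test_unregulated_variable_has_empty_resources(self):
        brn = load_network("variables: [{name: A}, {name: B}]\n")
        for state in [(0, 0), (1, 1)]:
            assert resources(brn, state, "A") == frozenset()

    def test_unknown_variable_rejected(self, dnmt1):
        with pytest.raises(NetworkValidationError):
            resources(dnmt1, (0, 0, 0, 0, 0, 0), "NOPE")

    def test_matches_direct_predicate_on_random_networks(self):
        # brute-force re-evaluation of the resource predicate per regulator
        rng = random.Random(704)
        for trial in range(20):
            brn = random_brn(seed=1000 + trial, n_vars=5, edge_density=0.4,
                             max_level=rng.choice([1, 2]))
            states = list(
                product(*(brn.variable(n).domain for n in brn.state_order))
            )
            for state in states:
                for var in brn.variable_names:
                    expected = set()
                    for e in brn.regulators(var):
                        lvl = state[brn.state_index(e.source)]
                        if e.sign == "+" and lvl >= e.threshold:
                            expected.add(e.source)
                        if e.sign == "-" and lvl < e.threshold:
                            expected.add(e.source)
                    assert resources(brn, state, var) == expected


class TestResourceSets:
    def test_dnmt1_has_eight_resource_sets(self, dnmt1):
        assert len(resource_sets(dnmt1, "DNMT1")) == 8

    def test_unregulated_variable_has_single_empty_set(self):
        brn = load_network("variables: [{name: A}]\n")
        assert resource_sets(brn, "A") == [frozenset()]

    def test_four_regulators_match_powerset_oracle(self):
        text = "variables:\n" + "".join(
            f"  - {{name: V{i}}}\n" for i in range(5)
        ) + "interactions:\n" + "".join(
            f"  - {{source: V{i}, target: V0, sign: '+'}}\n" for i in range(1, 5)
        )
        brn = load_network(text)
        subs = resource_sets(brn, "V0")
        names = [f"V{i}" for i in range(1, 5)]
        oracle = set()
        for k in range(5):
            for combo in combinations(names, k):
                oracle.add(frozenset(combo))
        assert len(subs) == 16
        assert set(subs) == oracle
        # canonical order: by size then lexicographic
        assert subs == sorted(subs, key=lambda s: (len(s), tuple(sorted(s))))

    def test_count_is_two_to_in_degree(self):
        for seed in range(5):
            brn = random_brn(seed=seed, n_vars=4, edge_density=0.5)
            for var in brn.variable_names:
                k = len(brn.regulators(var))
                assert len(resource_sets(brn, var)) == 2 ** k


def _two_var_brn():
    return load_network(
        "variables: [{name: A}, {name: B}]\n"
        "interactions: [{source: B, target: A, sign: '+'}]\n"
    )


class TestValidateParameterTable:
    def test_snoussi_violation_is_reported(self):
        brn = _two_var_brn()
        table = ParameterTable(
            {("A", frozenset()): 1, ("A", frozenset({"B"})): 0,
             ("B", frozenset()): 0}
        )
        diags = validate_parameter_table(brn, table, ConstraintSet(snoussi=True))
        assert [d.kind for d in diags] == ["snoussi"]
        assert "K_A" in diags[0].detail

    def test_complete_in_range_table_is_clean(self):
        brn = _two_var_brn()
        table = ParameterTable(
            {("A", frozenset()): 0, ("A", frozenset({"B"})): 1,
             ("B", frozenset()): 0}
        )
        assert validate_parameter_table(brn, table) == []

    def test_missing_and_domain_violations(self):
        brn = _two_var_brn()
        table = ParameterTable({("A", frozenset()): 5})
        kinds = {d.kind for d in validate_parameter_table(brn, table)}
        assert kinds == {"missing", "domain"}

    def test_random_tables_match_all_pairs_oracle(self):
        for seed in range(30):
            brn = random_brn(seed=seed, n_vars=3, edge_density=0.6, max_level=2)
            table = random_table(brn, seed=seed + 500)
            diags = validate_parameter_table(
                brn, table, ConstraintSet(snoussi=True)
            )
            reported = {(d.variable, d.detail) for d in diags if d.kind == "snoussi"}
            expected = set()
            for var in brn.variable_names:
                subs = resource_sets(brn, var)
                for a in subs:
                    for b in subs:
                        if a < b and table.k(var, a) > table.k(var, b):
                            expected.add(var)
            assert {v for v, _ in reported} == expected
            # one diagnostic per offending subset pair
            n_pairs = sum(
                1
                for var in brn.variable_names
                for a in resource_sets(brn, var)
                for b in resource_sets(brn, var)
                if a < b and table.k(var, a) > table.k(var, b)
            )
            assert len(reported) == len(diags) == n_pairs

    def test_observability_diagnostic(self):
        brn = _two_var_brn()
        flat = ParameterTable(
            {("A", frozenset()): 1, ("A", frozenset({"B"})): 1,
             ("B", frozenset()): 0}
        )
        diags = validate_parameter_table(
            brn, flat, ConstraintSet(observability=True)
        )
        assert [d.kind for d in diags] == ["observability"]
        assert "B->A" in diags[0].detail


class TestParameterTableIO:
    def test_csv_round_trip(self, selected_model):
        _, _, table = selected_model
        again = parameter_table_from_csv(parameter_table_to_csv(table))
        assert again == table

    def test_duplicate_rows_rejected(self):
        text = "variable,resource_set,K\nA,,0\nA,,1\n"
        with pytest.raises(NetworkParseError, match="duplicate"):
            parameter_table_from_csv(text)


class TestTypes:
    def test_variable_domain_must_be_nontrivial(self):
        with pytest.raises(NetworkValidationError):
            GeneVariable("A", 0)

    def test_interaction_sign_checked(self):
        with pytest.raises(NetworkValidationError):
            Interaction("A", "B", "x")

    def test_state_order_must_be_permutation(self):
        with pytest.raises(NetworkValidationError):
            BRN([GeneVariable("A"), GeneVariable("B")], (), state_order=["A", "A"])
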