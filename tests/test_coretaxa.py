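import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizostab import (
    RelAbundTable,
    abundance_stability_correlation,
    core_taxa,
    keystones,
    shared_taxa,
    spec_occu,
    zi_pi,
)


def make_rel(values, treatments, compartment="root"):
    samples = [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"t{i}" for i in range(values.shape[0])],
                      columns=samples)
    meta = pd.DataFrame(
        {
            "compartment": compartment,
            "treatment": treatments,
            "stage": "tillering",
            "replicate": range(1, len(samples) + 1),
        },
        index=samples,
    )
    tmeta = pd.DataFrame({"kingdom": "prokaryote", "taxonomy": "k"},
                         index=df.index)
    return RelAbundTable(df, meta, tmeta)


class TestZiPi:
    def test_all_links_in_own_module(self):
        g = nx.complete_graph(4)
        modules = {n: 0 for n in g}
        roles = zi_pi(g, modules)
        assert (roles["Pi"] == 0).all()

    def test_even_four_way_split(self):
        g = nx.star_graph(4)  # centre 0 linked to 4 leaves
        modules = {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}
        roles = zi_pi(g, modules)
        assert roles.loc[0, "Pi"] == pytest.approx(0.75)

    def test_worked_example_triangle_plus_edge(self):
        """Modules {a,b,c} (triangle) and {d,e} (edge), bridge a-d:
        Pi(a) = 1 - ((2/3)^2 + (1/3)^2) = 4/9, Zi(a) = 0."""
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"),
                      ("a", "d")])
        modules = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}
        roles = zi_pi(g, modules)
        assert roles.loc["a", "Pi"] == pytest.approx(4 / 9, abs=1e-12)
        assert roles.loc["a", "Zi"] == pytest.approx(0.0, abs=1e-12)

    def test_degree_zero_node(self):
        g = nx.Graph([("a", "b")])
        g.add_node("c")
        roles = zi_pi(g, {"a": 0, "b": 0, "c": 1})
        assert roles.loc["c", "Pi"] == 0.0
        assert roles.loc["c", "role"] == "peripheral"

    def test_role_partition_exhaustive_exclusive(self, rng):
        g = nx.gnm_random_graph(30, 80, seed=1)
        modules, _ = __import__("rhizostab").detect_modules(g, seed=0)
        roles = zi_pi(g, modules)
        assert set(roles["role"]) <= {"peripheral", "connector", "module hub",
                                      "network hub"}
        assert len(roles) == 30

    def test_role_precedence_at_boundaries(self):
        from rhizostab.coretaxa import ROLES  # noqa: F401
        # synthesise Zi/Pi directly through a crafted graph is brittle;
        # check the printed rules via the classification of zi_pi outputs
        # on a graph engineered to have a high-Zi node
        g = nx.star_graph(30)
        for i in range(1, 15):
            g.add_edge(i, i + 15)
        modules = {n: 0 for n in g}
        roles = zi_pi(g, modules)
        assert roles.loc[0, "Zi"] > 2.5
        assert roles.loc[0, "role"] == "module hub"  # Pi = 0 <= 0.62

    def test_matches_brute_force_enumeration(self, rng):
        """Zi and Pi equal direct per-module link counting on random
        partitioned graphs with <= 15 nodes."""
        for seed in range(8):
            g = nx.gnm_random_graph(12, 25, seed=seed)
            local = np.random.default_rng(seed)
            modules = {n: int(local.integers(0, 3)) for n in g}
            roles = zi_pi(g, modules)
            for node in g:
                k_to = {}
                for nbr in g[node]:
                    k_to[modules[nbr]] = k_to.get(modules[nbr], 0) + 1
                members = [n for n in g if modules[n] == modules[node]]
                within = [
                    sum(1 for nbr in g[m] if modules[nbr] == modules[m])
                    for m in members
                ]
                sd = np.std(within, ddof=1) if len(within) > 1 else 0.0
                expect_zi = (
                    0.0 if sd == 0
                    else (k_to.get(modules[node], 0) - np.mean(within)) / sd
                )
                k = g.degree(node)
                expect_pi = (
                    0.0 if k == 0
                    else 1.0 - sum((v / k) ** 2 for v in k_to.values())
                )
                assert roles.loc[node, "Zi"] == pytest.approx(expect_zi,
                                                              abs=1e-12)
                assert roles.loc[node, "Pi"] == pytest.approx(expect_pi,
                                                              abs=1e-12)


class TestSpecOccu:
    def test_exclusive_taxon(self):
        values = np.array([[0.5, 0.5, 0.0, 0.0], [0.5, 0.5, 1.0, 1.0]])
        rel = make_rel(values, ["CK", "CK", "MD", "MD"])
        table = spec_occu(rel)
        assert table.loc[("t0", "CK"), "specificity"] == pytest.approx(1.0)
        assert table.loc[("t0", "MD"), "specificity"] == pytest.approx(0.0)

    def test_specificity_ratio_arithmetic(self):
        values = np.array(
            [[0.02, 0.01, 0.01], [0.98, 0.99, 0.99]]
        )
        rel = make_rel(values, ["A", "B", "C"])
        table = spec_occu(rel)
        assert table.loc[("t0", "A"), "specificity"] == pytest.approx(0.5)
        assert table.loc[("t0", "B"), "specificity"] == pytest.approx(0.25)

    def test_occupancy_fraction(self):
        values = np.zeros((2, 5))
        values[0, :4] = 0.2
        values[1] = 1 - values[0]
        # single habitat is rejected; add a second
        values = np.hstack([values, values])
        rel = make_rel(values, ["A"] * 5 + ["B"] * 5)
        table = spec_occu(rel)
        assert table.loc[("t0", "A"), "occupancy"] == pytest.approx(0.8)

    def test_specificity_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        raw = rng.random((6, 9))
        raw /= raw.sum(axis=0)
        rel = make_rel(raw, ["CK", "CK", "CK", "MD", "MD", "MD",
                             "SD", "SD", "SD"])
        table = spec_occu(rel)
        sums = table["specificity"].groupby(level="zotu_id").sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_boundary_point_seven_not_specialist(self):
        # specificity exactly 0.7 and occupancy exactly 0.7 fail the
        # strict comparisons
        values = np.array(
            [[0.7, 0.7, 0.7, 0.7, 0.7, 0.0, 0.0, 0.0, 0.3, 0.3],
             [0.3, 0.3, 0.3, 0.3, 0.3, 1.0, 1.0, 1.0, 0.7, 0.7]]
        )
        # habitat A: 5 samples (last gets zero for t0 -> occupancy tweak)
        values[0, 4] = 0.0
        values[1, 4] = 1.0
        rel = make_rel(values, ["A"] * 5 + ["B"] * 5)
        table = spec_occu(rel)
        spec_a = table.loc[("t0", "A"), "specificity"]
        if spec_a == pytest.approx(0.7, abs=0.02):
            assert not (spec_a > 0.7 and table.loc[("t0", "A"),
                                                   "occupancy"] > 0.7)

    def test_top_n_rank_gate(self):
        values = np.array(
            [[0.80, 0.80, 0.0, 0.0],
             [0.15, 0.15, 0.01, 0.01],
             [0.05, 0.05, 0.99, 0.99]]
        )
        rel = make_rel(values, ["A", "A", "B", "B"])
        narrow = spec_occu(rel, top_n=1)
        wide = spec_occu(rel, top_n=500)
        # t1 is specific+prevalent in A but only rank 2 by abundance
        assert wide.loc[("t1", "A"), "specialist"]
        assert not narrow.loc[("t1", "A"), "specialist"]

    def test_single_habitat_rejected(self):
        rel = make_rel(np.array([[0.5, 0.5], [0.5, 0.5]]), ["A", "A"])
        with pytest.raises(ValueError):
            spec_occu(rel)


class TestSharedTaxa:
    def test_taxon_absent_from_one_treatment_not_shared(self, toy_table):
        # fun_zOTU1 is absent from CK samples (s1: 0... s2 has 60) -> present
        counts = toy_table.counts.copy()
        counts.loc["fun_zOTU1", ["s1", "s2"]] = 0
        from rhizostab import CountTable
        t = CountTable(counts, toy_table.sample_meta, toy_table.taxon_meta)
        shared, regions = shared_taxa(t, min_rel_abund=0.0)
        assert "fun_zOTU1" not in shared

    def test_identical_tables_all_shared(self, toy_table):
        shared, regions = shared_taxa(toy_table, min_rel_abund=0.0)
        assert shared == {"pro_zOTU1", "pro_zOTU2", "fun_zOTU1"}

    def test_venn_counts_sum_to_union(self, toy_table):
        shared, regions = shared_taxa(toy_table, min_rel_abund=0.0)
        union = set()
        total = sum(regions.values())
        assert total == 3  # all three taxa detected somewhere


class TestCoreScreen:
    def test_disjoint_inputs_empty_core(self):
        res = core_taxa({"a"}, {"b"}, {"c"})
        assert res.core == set()

    def test_core_is_subset_of_each_input(self):
        res = core_taxa({"a", "b", "c"}, {"b", "c"}, {"c", "d"})
        assert res.core == {"c"}
        assert res.core <= res.shared and res.core <= res.keystones

    def test_abundance_attached(self, toy_table):
        from rhizostab import relative_abundance
        rel = relative_abundance(toy_table)
        res = core_taxa({"pro_zOTU2"}, {"pro_zOTU2"}, {"pro_zOTU2"}, rel)
        assert res.abundance is not None
        idx = res.abundance.index
        assert ("pro_zOTU2", "CK", "tillering") in idx


class TestAbundanceStabilityCorrelation:
    def test_perfect_linear(self):
        x = pd.DataFrame([[1.0, 2, 3, 4]], index=["z"],
                         columns=list("abcd"))
        y = pd.Series([3.0, 5, 7, 9], index=list("abcd"))
        out = abundance_stability_correlation(x, y)
        assert out.loc["z", "r"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = pd.DataFrame([[1.0, 2, 3, 4]], index=["z"], columns=list("abcd"))
        y = pd.Series([-1.0, -2, -3, -4], index=list("abcd"))
        out = abundance_stability_correlation(x, y)
        assert out.loc["z", "r"] == pytest.approx(-1.0)

    def test_hand_computed(self):
        x = pd.DataFrame([[1.0, 2, 3, 4]], index=["z"], columns=list("abcd"))
        y = pd.Series([1.0, 3, 2, 4], index=list("abcd"))
        out = abundance_stability_correlation(x, y)
        assert out.loc["z", "r"] == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_missing(self):
        x = pd.DataFrame([[1.0, 1, 1, 1]], index=["z"], columns=list("abcd"))
        y = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        out = abundance_stability_correlation(x, y)
        assert np.isnan(out.loc["z", "r"])

    def test_too_few_pairs(self):
        x = pd.DataFrame([[1.0, 2, 3]], index=["z"], columns=list("abc"))
        y = pd.Series([1.0, 2, 3], index=list("abc"))
        with pytest.raises(ValueError):
            abundance_stability_correlation(x, y)
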