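import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizostab import (
    avd,
    avd_by_treatment,
    cohesion,
    connectedness,
    generate_counts,
    natural_connectivity,
    relative_abundance,
    robustness_curve,
    stability_report,
    vulnerability,
)
from rhizostab.synthetic import SyntheticDesign


def kn_natural_connectivity(n):
    """Closed form for the complete graph: eigenvalues n-1 and -1 (x n-1)."""
    return np.log((np.exp(n - 1) + (n - 1) * np.exp(-1)) / n)


class TestNaturalConnectivity:
    def test_edgeless_graph_is_zero(self):
        g = nx.Graph()
        g.add_nodes_from(range(7))
        assert natural_connectivity(g) == 0.0

    def test_single_edge(self):
        assert natural_connectivity(nx.path_graph(2)) == pytest.approx(
            np.log(np.cosh(1.0)), abs=1e-12
        )

    def test_triangle(self):
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.99631, abs=1e-5)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_complete_graph_closed_form(self, n):
        assert natural_connectivity(nx.complete_graph(n)) == pytest.approx(
            kn_natural_connectivity(n), abs=1e-9
        )

    def test_overflow_safe_on_large_dense_graph(self):
        # K_800 has lead eigenvalue 799; e^799 overflows without log-sum-exp
        val = natural_connectivity(nx.complete_graph(800))
        assert np.isfinite(val)
        assert val == pytest.approx(799 - np.log(800), abs=1e-6)


class TestRobustness:
    def test_fraction_zero_reproduces_intact_value(self):
        g = nx.gnm_random_graph(20, 40, seed=1)
        curve = robustness_curve(g, fractions=[0.0, 0.2], n_rep=10, seed=0)
        assert curve.nc_mean[0] == pytest.approx(natural_connectivity(g),
                                                 abs=1e-12)
        assert curve.nc_sd[0] == pytest.approx(0.0, abs=1e-12)

    def test_complete_graph_single_removal_deterministic(self):
        curve = robustness_curve(
            nx.complete_graph(10), fractions=[0.1], n_rep=25, seed=3
        )
        assert curve.nc_sd[0] == pytest.approx(0.0, abs=1e-12)
        assert curve.nc_mean[0] == pytest.approx(
            kn_natural_connectivity(9), abs=1e-9
        )

    def test_average_degree_non_increasing_for_complete_graph(self):
        curve = robustness_curve(
            nx.complete_graph(12), fractions=np.arange(0, 0.81, 0.1),
            n_rep=20, seed=0,
        )
        assert (np.diff(curve.avg_degree_mean) <= 1e-9).all()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            robustness_curve(nx.complete_graph(4), fractions=[1.0])

    def test_reproducible(self):
        g = nx.gnm_random_graph(15, 30, seed=2)
        c1 = robustness_curve(g, n_rep=5, seed=9)
        c2 = robustness_curve(g, n_rep=5, seed=9)
        np.testing.assert_allclose(c1.nc_mean, c2.nc_mean)

    def test_edge_addition_never_decreases_connectivity(self):
        """Adding any edge to any small graph raises lambda-bar (checked
        against a direct eigenvalue computation)."""
        for g in nx.graph_atlas_g()[2:20]:
            base = natural_connectivity(g)
            for u, v in itertools.combinations(g.nodes(), 2):
                if g.has_edge(u, v):
                    continue
                h = g.copy()
                h.add_edge(u, v)
                assert natural_connectivity(h) >= base - 1e-12


class TestConnectednessAndCohesion:
    def test_connectedness_mean_of_signed_edges(self, signed_graph):
        conn = connectedness(signed_graph)
        assert conn.loc["a", "positive"] == pytest.approx((0.9 + 0.85) / 2)
        assert conn.loc["a", "negative"] == 0.0
        assert conn.loc["d", "negative"] == pytest.approx(-0.88)
        assert conn.loc["d", "positive"] == 0.0

    def test_connectedness_sum_option(self, signed_graph):
        conn = connectedness(signed_graph, agg="sum")
        assert conn.loc["a", "positive"] == pytest.approx(1.75)

    def test_cohesion_hand_case_positive(self):
        abund = pd.DataFrame({"s1": [0.5, 0.5]}, index=["a", "b"])
        conn = pd.DataFrame(
            {"positive": [0.8, 0.8], "negative": [0.0, 0.0]}, index=["a", "b"]
        )
        res = cohesion(abund, conn)
        assert res.samples.loc["s1", "positive"] == pytest.approx(0.8,
                                                                  abs=1e-12)

    def test_cohesion_hand_case_negative(self):
        abund = pd.DataFrame({"s1": [0.25, 0.75]}, index=["a", "b"])
        conn = pd.DataFrame(
            {"positive": [0.0, 0.0], "negative": [-0.4, -0.2]},
            index=["a", "b"],
        )
        res = cohesion(abund, conn)
        assert res.samples.loc["s1", "negative"] == pytest.approx(-0.25,
                                                                  abs=1e-12)
        assert res.samples.loc["s1", "total"] == pytest.approx(0.25, abs=1e-12)

    def test_zero_connectedness_zero_cohesion(self):
        abund = pd.DataFrame({"s1": [0.3, 0.7]}, index=["a", "b"])
        conn = pd.DataFrame(
            {"positive": [0.0, 0.0], "negative": [0.0, 0.0]}, index=["a", "b"]
        )
        res = cohesion(abund, conn)
        assert res.samples.loc["s1", "total"] == 0.0
        assert np.isnan(res.samples.loc["s1", "neg_pos_ratio"])

    def test_cohesion_linear_in_abundance(self):
        conn = pd.DataFrame(
            {"positive": [0.9, 0.0], "negative": [0.0, 0.0]}, index=["a", "b"]
        )
        lo = cohesion(pd.DataFrame({"s": [0.1, 0.9]}, index=["a", "b"]), conn)
        hi = cohesion(pd.DataFrame({"s": [0.2, 0.8]}, index=["a", "b"]), conn)
        assert hi.samples.loc["s", "positive"] == pytest.approx(
            2 * lo.samples.loc["s", "positive"]
        )

    def test_renormalized_variant(self):
        abund = pd.DataFrame({"s1": [0.1, 0.1]}, index=["a", "b"])
        conn = pd.DataFrame(
            {"positive": [0.8, 0.8], "negative": [0.0, 0.0]}, index=["a", "b"]
        )
        raw = cohesion(abund, conn).samples.loc["s1", "positive"]
        renorm = cohesion(abund, conn, renormalize=True).samples.loc[
            "s1", "positive"
        ]
        assert raw == pytest.approx(0.16)
        assert renorm == pytest.approx(0.8)


class TestAvd:
    def _abund(self, rows, samples):
        return pd.DataFrame(
            rows, index=[f"t{i}" for i in range(len(rows))], columns=samples
        )

    def test_identical_replicates_zero(self):
        a = self._abund([[0.2, 0.2, 0.2], [0.8, 0.8, 0.8]], ["r1", "r2", "r3"])
        assert avd(a, ["r1", "r2", "r3"]) == 0.0

    def test_two_replicates_closed_form(self):
        a = self._abund([[0.2, 0.4]], ["r1", "r2"])
        assert avd(a, ["r1", "r2"]) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_scale_invariance_per_taxon(self, rng):
        base = rng.random((4, 5))
        a = self._abund(base, [f"r{i}" for i in range(5)])
        scaled = a.copy()
        scaled.iloc[2] *= 7.5
        assert avd(a, list(a.columns)) == pytest.approx(
            avd(scaled, list(a.columns)), abs=1e-12
        )

    def test_single_replicate_rejected(self):
        a = self._abund([[0.5]], ["r1"])
        with pytest.raises(ValueError):
            avd(a, ["r1"])

    def test_avd_increases_with_replicate_instability(self):
        """Less stable communities (stronger dispersion and more
        conditionally-rare blooms) score a higher AVD."""
        def level(noise, seeds=8):
            vals = []
            for seed in range(seeds):
                d = SyntheticDesign(
                    n_taxa_per_kingdom={"prokaryote": 40, "fungus": 10,
                                        "protist": 10},
                    n_rare_per_kingdom={"prokaryote": 80, "fungus": 40,
                                        "protist": 40},
                    noise_sd=noise, seed=seed,
                )
                table, _ = generate_counts(d)
                vals.append(
                    avd_by_treatment(relative_abundance(table)).mean()
                )
            return np.mean(vals)

        assert level(0.6) < level(1.4)


class TestVulnerability:
    def test_path_three_nodes(self):
        v, per_node = vulnerability(nx.path_graph(3))
        assert v == pytest.approx(1.0, abs=1e-12)
        assert per_node[1] == pytest.approx(1.0, abs=1e-12)
        assert per_node[0] == pytest.approx(-0.2, abs=1e-12)

    def test_complete_graph_zero(self):
        v, per_node = vulnerability(nx.complete_graph(4))
        assert v == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(per_node, 0.0, atol=1e-12)

    def test_v_bounded_by_one(self):
        g = nx.gnm_random_graph(12, 18, seed=5)
        if g.number_of_edges():
            v, per_node = vulnerability(g)
            assert v <= 1.0 + 1e-12

    def test_edgeless_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        with pytest.raises(ValueError):
            vulnerability(g)


class TestStabilityReport:
    def test_report_bundle(self, signed_graph, tmp_path):
        rep = stability_report(signed_graph, abund=None, n_rep=5, seed=0)
        assert rep.natural_connectivity > 0
        assert rep.vulnerability is not None
        rep.write(tmp_path / "summary.tsv", tmp_path / "rob.tsv")
        assert (tmp_path / "summary.tsv").exists()
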