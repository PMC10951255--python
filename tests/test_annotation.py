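import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msihetero.annotation import (
    ADDUCT_RULES,
    ATOMIC_MASS,
    ELECTRON_MASS,
    adduct_mz,
    annotate_peaks,
    correlation_network,
    enrich_pathways,
    load_demo_mass_table,
    load_demo_pathways,
    monoisotopic_mass,
)

GLUCOSE = 180.063388


class TestAdducts:
    def test_five_rules_present(self):
        assert set(ADDUCT_RULES) == {"M-H", "M-H2O-H", "M+K-2H", "M+Na-2H", "M+Cl"}

    def test_shifts_match_atomic_mass_recomputation(self):
        H, O = ATOMIC_MASS["H"], ATOMIC_MASS["O"]
        e = ELECTRON_MASS
        expected = {
            "M-H": -H + e,
            "M-H2O-H": -(2 * H + O) - H + e,
            "M+K-2H": ATOMIC_MASS["K"] - 2 * H + e,
            "M+Na-2H": ATOMIC_MASS["Na"] - 2 * H + e,
            "M+Cl": ATOMIC_MASS["Cl"] + e,
        }
        for name, rule in ADDUCT_RULES.items():
            assert rule.mass_shift == pytest.approx(expected[name], abs=1e-6)

    def test_m_minus_h_is_minus_proton(self):
        assert ADDUCT_RULES["M-H"].mass_shift == pytest.approx(-1.007276, abs=1e-6)

    def test_glucose_m_minus_h(self):
        assert adduct_mz(GLUCOSE, "M-H") == pytest.approx(179.056112, abs=1e-5)

    def test_glucose_m_plus_cl(self):
        assert adduct_mz(GLUCOSE, "M+Cl") == pytest.approx(215.032790, abs=1e-5)

    def test_glucose_formula_mass(self):
        assert monoisotopic_mass("C6H12O6") == pytest.approx(GLUCOSE, abs=1e-5)

    def test_unknown_rule(self):
        with pytest.raises(KeyError):
            adduct_mz(100.0, "M+H")

    def test_bad_formula(self):
        with pytest.raises(ValueError):
            monoisotopic_mass("X7")

    def test_negative_mass(self):
        with pytest.raises(ValueError):
            adduct_mz(-5.0, "M-H")


class TestAnnotatePeaks:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["id", "monoisotopic_mass"])

    def test_exact_hit(self):
        table = self._table([("glucose", GLUCOSE)])
        hits = annotate_peaks([179.056112], table, tol_ppm=4)
        assert len(hits) == 1
        assert hits.loc[0, "adduct"] == "M-H"
        assert abs(hits.loc[0, "ppm_error"]) < 0.1

    def test_empty_table(self):
        hits = annotate_peaks([179.0], self._table([]), tol_ppm=4)
        assert hits.empty

    def test_tolerance_boundary(self):
        theo = adduct_mz(GLUCOSE, "M-H")
        off = theo * (1 + 1e-6)  # 1 ppm away
        assert annotate_peaks([off], self._table([("g", GLUCOSE)]), tol_ppm=0.1).empty
        assert len(annotate_peaks([off], self._table([("g", GLUCOSE)]), tol_ppm=2)) == 1

    def test_round_trip_random_masses(self):
        rng = np.random.default_rng(0)
        masses = np.sort(rng.uniform(100, 900, 40))
        masses = masses[np.diff(np.concatenate([[0], masses])) > 0.5]  # non-colliding
        table = self._table([(f"m{i}", m) for i, m in enumerate(masses)])
        for rule in ADDUCT_RULES.values():
            peaks = [adduct_mz(m, rule) for m in masses]
            hits = annotate_peaks(peaks, table, tol_ppm=1)
            exact = hits[np.abs(hits["ppm_error"]) < 1e-6]
            assert set(exact["metabolite"]) == set(table["id"])
            assert (exact.groupby("metabolite")["adduct"].apply(lambda s: rule.name in set(s))).all()

    def test_hits_ranked_by_ppm_within_peak(self):
        table = self._table([("a", 200.0), ("b", 200.0001)])
        hits = annotate_peaks([adduct_mz(200.0, "M-H")], table, tol_ppm=5)
        assert hits.loc[0, "metabolite"] == "a"


class TestEnrichment:
    def test_perfect_overlap_example(self):
        universe = {f"m{i}" for i in range(20)}
        pathway = {f"m{i}" for i in range(10)}
        res = enrich_pathways(pathway, universe, {"pw": pathway})
        from math import comb

        assert res.loc[0, "p"] == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_disjoint_query(self):
        universe = {f"m{i}" for i in range(20)}
        res = enrich_pathways(
            {"m0", "m1"}, universe, {"pw": {f"m{i}" for i in range(10, 15)}}
        )
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_one_sided_fisher(self):
        rng = np.random.default_rng(1)
        universe = {f"m{i}" for i in range(30)}
        for _ in range(20):
            pw = set(rng.choice(sorted(universe), 8, replace=False))
            q = set(rng.choice(sorted(universe), 10, replace=False))
            res = enrich_pathways(q, universe, {"pw": pw})
            a = len(q & pw)
            table = [[a, len(q) - a], [len(pw) - a, 30 - len(q) - len(pw) + a]]
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert res.loc[0, "p"] == pytest.approx(p_fisher, abs=1e-12)

    def test_chance_overlap_has_large_p(self):
        rng = np.random.default_rng(2)
        universe = {f"m{i}" for i in range(100)}
        ps = []
        for _ in range(50):
            pw = set(rng.choice(sorted(universe), 20, replace=False))
            q = set(rng.choice(sorted(universe), 20, replace=False))
            ps.append(enrich_pathways(q, universe, {"pw": pw}).loc[0, "p"])
        assert np.median(ps) >= 0.3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_pathways(set(), set(), {})

    def test_demo_data_loads(self):
        masses = load_demo_mass_table()
        pathways = load_demo_pathways()
        assert len(masses) >= 40 and len(pathways) >= 5
        assert (masses["monoisotopic_mass"] > 50).all()


class TestCorrelationNetwork:
    def test_duplicated_channel_gives_rho_one(self):
        rng = np.random.default_rng(3)
        x = rng.random(50)
        X = np.column_stack([x, x, rng.random(50)])
        g, pairs = correlation_network(X, channel_names=["a", "a2", "b"])
        assert g.has_edge("a", "a2")
        assert g.edges["a", "a2"]["rho"] == pytest.approx(1.0)

    def test_symmetric_graph(self):
        rng = np.random.default_rng(4)
        X = rng.random((100, 5)) + np.outer(rng.random(100), np.ones(5))
        g, _ = correlation_network(X)
        for a, b in g.edges:
            assert g.has_edge(b, a)
            assert g.edges[a, b]["rho"] == g.edges[b, a]["rho"]

    def test_null_edges_rare_after_bh(self):
        rng = np.random.default_rng(5)
        X = rng.random((1000, 15))  # independent channels
        g, pairs = correlation_network(X)
        n_pairs = len(pairs)
        raw_rate = (pairs["p"] < 0.05).mean()
        assert 0.005 <= raw_rate <= 0.12  # ~5% before adjustment
        assert g.number_of_edges() / n_pairs < 0.05

    def test_planted_latent_factor(self):
        rng = np.random.default_rng(6)
        z = rng.random(200)
        X = np.column_stack(
            [z + 0.1 * rng.random(200), z + 0.1 * rng.random(200), rng.random(200)]
        )
        g, _ = correlation_network(X, channel_names=["a", "b", "c"])
        assert g.has_edge("a", "b")
        assert abs(g.edges["a", "b"]["rho"]) >= 0.5

    def test_constant_channel_excluded(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([rng.random(60), np.full(60, 2.0), rng.random(60)])
        g, pairs = correlation_network(X, channel_names=["a", "const", "b"])
        assert not any("const" in e for e in pairs[["a", "b"]].itertuples(index=False))

    def test_too_few_pixels(self):
        with pytest.raises(ValueError):
            correlation_network(np.random.default_rng(8).random((5, 3)))

    def test_edge_weight_is_abs_rho(self):
        rng = np.random.default_rng(9)
        z = rng.random(100)
        X = np.column_stack([z, -z + 0.05 * rng.random(100)])
        g, _ = correlation_network(X, channel_names=["a", "b"])
        assert g.edges["a", "b"]["sign"] == "negative"
        assert g.edges["a", "b"]["weight"] == pytest.approx(
            abs(g.edges["a", "b"]["rho"])
        )
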