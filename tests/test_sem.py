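import itertools

import numpy as np
import pandas as pd
import pytest

from pollinet import synth
from pollinet.io import IslandAttributes
from pollinet.metrics import NetworkMetrics
from pollinet.networks import CommunityMetrics
from pollinet.sem import (EXOGENOUS, FittedSem, IndependenceClaim, Path,
                          PathStructure, SemFitter, backward_select, basis_set,
                          default_structure, effects_decomposition, fit_sem,
                          interaction_column, path_tracing, prepare_design,
                          sem_aic, standardized_coefficients)
from pollinet.mixed import fit_gaussian


def gaussian_table(seed=0, n_islands=40, cols=("A", "B", "C")):
    rng = np.random.default_rng(seed)
    island = np.repeat([f"i{k}" for k in range(n_islands)], 2)
    table = pd.DataFrame({"island": island})
    for c in cols:
        table[c] = rng.normal(size=2 * n_islands)
    return table


class TestPrepareDesign:
    def make_inputs(self, n=3):
        attrs = {f"I{k}": IslandAttributes(f"I{k}", float(k + 1), 100.0 * (k + 1), 1)
                 for k in range(n)}
        community = {}
        network = {}
        rng = np.random.default_rng(0)
        for k in range(n):
            for cls in ("edge", "interior"):
                community[(f"I{k}", cls)] = CommunityMetrics(1.0, 2, 3, 1)
                network[(f"I{k}", cls)] = NetworkMetrics(*rng.uniform(0.2, 0.8, 4))
        return attrs, community, network

    def test_one_hectare_island_has_zero_da(self):
        attrs, community, network = self.make_inputs()
        table = prepare_design(attrs, community, network)
        assert table.loc[table["island"] == "I0", "DA"].iloc[0] == pytest.approx(0.0)

    def test_row_count_is_islands_times_classes(self):
        attrs, community, network = self.make_inputs(n=5)
        table = prepare_design(attrs, community, network)
        assert len(table) == 10
        assert set(table["PE"]) == {0.0, 1.0}

    def test_sign_convention_flips(self):
        attrs, community, network = self.make_inputs()
        a = prepare_design(attrs, community, network, negate_area=True)
        b = prepare_design(attrs, community, network, negate_area=False)
        assert np.allclose(a["DA"], -b["DA"])

    def test_missing_attributes_raise(self):
        attrs, community, network = self.make_inputs()
        del attrs["I1"]
        with pytest.raises(KeyError, match="I1"):
            prepare_design(attrs, community, network)

    def test_centered_interaction_column_mean_near_zero(self):
        table = gaussian_table(seed=1)
        col = interaction_column(table, "B", "A")
        assert abs(col.mean()) < 0.2
        assert col.name == "A:B"


class TestStandardizedCoefficients:
    def test_unit_variance_identity_and_scale_invariance(self):
        table = gaussian_table(seed=2)
        y = table["A"].to_numpy()
        x = table[["B"]]
        fit = fit_gaussian(y, x, table["island"].to_numpy())
        std = standardized_coefficients(fit, x, y)
        x2 = x * 7.0
        fit2 = fit_gaussian(y, x2, table["island"].to_numpy())
        std2 = standardized_coefficients(fit2, x2, y)
        assert std["B"] == pytest.approx(std2["B"], abs=1e-6)

    def test_single_predictor_equals_pearson(self):
        rng = np.random.default_rng(103)
        table = gaussian_table(seed=3)
        table["A"] = 0.6 * table["B"] + rng.normal(0, 0.8, len(table))
        y = table["A"].to_numpy()
        x = table[["B"]]
        fit = fit_gaussian(y, x, table["island"].to_numpy())
        std = standardized_coefficients(fit, x, y)
        r = np.corrcoef(table["A"], table["B"])[0, 1]
        assert std["B"] == pytest.approx(r, abs=5e-3)


class TestBasisSet:
    def struct(self, edges, **kw):
        return PathStructure([Path(s, t, i + 1) for i, (s, t) in enumerate(edges)],
                             **kw)

    def test_saturated_dag_has_empty_basis(self):
        s = self.struct([("A", "B"), ("A", "C"), ("B", "C")])
        assert basis_set(s) == []

    def test_chain_yields_single_claim(self):
        s = self.struct([("A", "B"), ("B", "C")])
        assert basis_set(s) == [IndependenceClaim("A", "C", ("B",))]

    def test_correlated_errors_excluded(self):
        s = self.struct([("A", "B"), ("A", "C")], correlated_errors=[("B", "C")])
        assert basis_set(s) == []

    def test_exogenous_pairs_excluded(self):
        s = self.struct([("A", "C"), ("B", "C")])
        assert basis_set(s) == []

    def test_counts_match_pair_enumeration(self, rng):
        for _ in range(10):
            nodes = list("ABCDEF")
            edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                     if rng.random() < 0.4]
            if not edges:
                continue
            s = self.struct(edges)
            exog = {v for v in s.variables if not s.parents(v)}
            expected = sum(
                1 for a, b in itertools.combinations(sorted(s.variables), 2)
                if not s.adjacent(a, b) and not (a in exog and b in exog))
            assert len(basis_set(s)) == expected

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            self.struct([("A", "B"), ("B", "A")]).topological_order()


class TestFishersC:
    def test_no_claims_is_perfect_fit(self):
        fitter = SemFitter(gaussian_table())
        assert fitter.fishers_c([]) == (0.0, 0, 1.0)

    def test_five_half_pvalues(self):
        # -2 * 5 * ln(0.5) = 6.931..., df = 10
        pvals = np.clip(np.full(5, 0.5), 1e-300, 1)
        c = float(-2 * np.log(pvals).sum())
        assert c == pytest.approx(6.931, abs=1e-3)
        fitter = SemFitter(gaussian_table())
        claims = [IndependenceClaim("A", "C", ("B",))] * 5
        c_hat, df, _ = fitter.fishers_c(claims)
        assert df == 10

    def test_independent_data_accepts_chain(self):
        table = gaussian_table(seed=4)
        rng = np.random.default_rng(104)
        table["B"] = 0.7 * table["A"] + rng.normal(0, 0.7, len(table))
        table["C"] = 0.7 * table["B"] + rng.normal(0, 0.7, len(table))
        s = PathStructure([Path("A", "B", 1), Path("B", "C", 2)])
        fitted = fit_sem(s, table)
        assert fitted.dsep_df == 2
        assert fitted.dsep_p > 0.001


class TestSemAic:
    def test_printed_triple_satisfies_identity(self):
        # C = 51.83 with K = 45 parameters gives AIC = 141.83
        dummy = FittedSem(default_structure(), pd.DataFrame(), {}, 51.83, 0, 1.0,
                          45, 51.83 + 2 * 45, {})
        assert sem_aic(dummy) == pytest.approx(141.83)

    def test_empty_basis_set_aic_is_twice_k(self):
        dummy = FittedSem(default_structure(), pd.DataFrame(), {}, 0.0, 0, 1.0,
                          3, 6.0, {})
        assert sem_aic(dummy) == pytest.approx(6.0)

    def test_adding_one_path_adds_one_parameter(self):
        table = gaussian_table(seed=5)
        small = PathStructure([Path("A", "C", 1)])
        big = PathStructure([Path("A", "C", 1), Path("B", "C", 2)])
        f_small = fit_sem(small, table, compute_dsep=False)
        f_big = fit_sem(big, table, compute_dsep=False)
        assert f_big.k_params - f_small.k_params == 1


class TestBackwardSelect:
    def test_noise_path_removed(self):
        rng = np.random.default_rng(106)
        table = gaussian_table(seed=6, cols=("A", "B", "N"))
        table["C"] = 0.8 * table["A"] + 0.5 * table["B"] + rng.normal(0, 0.5, len(table))
        s = PathStructure([Path("A", "C", 1), Path("B", "C", 2), Path("N", "C", 3)])
        final = backward_select(s, table)
        kept = {(p.source, p.target) for p in final.structure.paths}
        assert ("N", "C") not in kept
        assert ("A", "C") in kept and ("B", "C") in kept

    def test_minimal_structure_is_fixed_point(self):
        rng = np.random.default_rng(107)
        table = gaussian_table(seed=7, cols=("A",))
        table["C"] = 0.9 * table["A"] + rng.normal(0, 0.3, len(table))
        s = PathStructure([Path("A", "C", 1)])
        final = backward_select(s, table)
        assert [(p.source, p.target) for p in final.structure.paths] == [("A", "C")]

    def test_deterministic(self):
        rng = np.random.default_rng(108)
        table = gaussian_table(seed=8, cols=("A", "B", "N"))
        table["C"] = 0.6 * table["A"] + rng.normal(0, 0.6, len(table))
        s = PathStructure([Path("A", "C", 1), Path("B", "C", 2), Path("N", "C", 3)])
        a = backward_select(s, table)
        b = backward_select(s, table)
        assert a.coefficients.equals(b.coefficients)
        assert a.aic == b.aic

    def test_selection_never_raises_aic(self):
        rng = np.random.default_rng(109)
        table = gaussian_table(seed=9, cols=("A", "B", "N"))
        table["C"] = 0.6 * table["A"] + rng.normal(0, 0.6, len(table))
        s = PathStructure([Path("A", "C", 1), Path("B", "C", 2), Path("N", "C", 3)])
        initial = fit_sem(s, table)
        final = backward_select(s, table)
        assert final.aic <= initial.aic + 1e-9


class TestEffects:
    def test_chain_product_rule(self):
        std = {("A", "B"): 0.5, ("B", "C"): 0.4}
        direct, indirect = path_tracing(std, "A", "C")
        assert direct == 0.0
        assert indirect == pytest.approx(0.20)

    def test_parallel_paths_sum(self):
        std = {("A", "B"): 0.3, ("B", "C"): 0.2, ("A", "C"): 0.1}
        direct, indirect = path_tracing(std, "A", "C")
        assert direct + indirect == pytest.approx(0.16)

    def test_matches_matrix_closed_form(self, rng):
        nodes = list("ABCDE")
        std = {}
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if rng.random() < 0.6:
                    std[(a, b)] = float(rng.normal(scale=0.4))
        mat = np.zeros((5, 5))
        for (a, b), v in std.items():
            mat[nodes.index(b), nodes.index(a)] = v
        totals = np.linalg.inv(np.eye(5) - mat) - np.eye(5)
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                if i == j:
                    continue
                d, ind = path_tracing(std, a, b)
                assert d + ind == pytest.approx(totals[j, i], abs=1e-8)

    def test_decomposition_with_bootstrap(self):
        rng = np.random.default_rng(110)
        table = gaussian_table(seed=10, cols=("A",))
        table["B"] = 0.6 * table["A"] + rng.normal(0, 0.8, len(table))
        table["C"] = 0.5 * table["B"] + rng.normal(0, 0.85, len(table))
        s = PathStructure([Path("A", "B", 1), Path("B", "C", 2)])
        fitted = fit_sem(s, table, compute_dsep=False)
        effects = effects_decomposition(fitted, table, n_boot=60, seed=0)
        total = effects.effects.query("source == 'A' and response == 'C' "
                                      "and effect == 'total'").iloc[0]
        assert total["ci_low"] < total["estimate"] < total["ci_high"]
        direct = effects.effects.query("source == 'A' and response == 'C' "
                                       "and effect == 'direct'").iloc[0]
        indirect = effects.effects.query("source == 'A' and response == 'C' "
                                         "and effect == 'indirect'").iloc[0]
        assert total["estimate"] == pytest.approx(
            direct["estimate"] + indirect["estimate"], abs=1e-12)
        assert 0.1 < total["estimate"] < 0.55


class TestEffectsCoverage:
    def test_bootstrap_interval_covers_true_total(self):
        """95% cluster-bootstrap CIs cover the true total effect 90-99%."""
        covered = 0
        reps = 200
        s = PathStructure([Path("A", "B", 1), Path("B", "C", 2)])
        for r in range(reps):
            rng = np.random.default_rng((900, r))
            n_isl = 40
            island = np.repeat([f"i{k}" for k in range(n_isl)], 2)
            u = rng.normal(0, np.sqrt(0.2), n_isl)[np.repeat(np.arange(n_isl), 2)]
            a = rng.normal(size=2 * n_isl)
            b = 0.6 * a + u + rng.normal(0, np.sqrt(0.44), 2 * n_isl)
            c = 0.6 * b + rng.normal(0, 0.8, 2 * n_isl)
            table = pd.DataFrame({"island": island, "A": a, "B": b, "C": c})
            fitted = fit_sem(s, table, compute_dsep=False)
            eff = effects_decomposition(fitted, table, n_boot=100, seed=r)
            row = eff.effects.query("source == 'A' and response == 'C' "
                                    "and effect == 'total'").iloc[0]
            covered += row.ci_low <= 0.36 <= row.ci_high
        assert 0.90 <= covered / reps <= 0.99


class TestDefaultStructure:
    def test_forty_five_paths_with_nestedness_to_robustness_last(self):
        s = default_structure()
        assert len(s.paths) == 45
        p45 = s.path(45)
        assert (p45.source, p45.target) == ("NE", "RO")
        assert set(EXOGENOUS) < s.variables

    def test_yaml_round_trip(self, tmp_path):
        s = default_structure()
        path = tmp_path / "structure.yaml"
        s.to_yaml(path)
        back = PathStructure.from_yaml(path)
        assert [(p.source, p.target, p.path_id) for p in back.paths] == \
            [(p.source, p.target, p.path_id) for p in s.paths]
        assert back.correlated_errors == s.correlated_errors

    def test_interaction_term_enters_component_model(self):
        table = gaussian_table(seed=11, cols=("A", "B"))
        rng = np.random.default_rng(111)
        table["C"] = (0.5 * table["A"] + 0.3 * table["A"] * table["B"]
                      + rng.normal(0, 0.5, len(table)))
        s = PathStructure([Path("A", "C", 1), Path("B", "C", 2)],
                          interactions=[("B", 1)])
        fitted = fit_sem(s, table, compute_dsep=False)
        inter = fitted.coefficients[fitted.coefficients["source"] == "A:B"]
        assert len(inter) == 1
        assert inter["p"].iloc[0] < 0.05
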