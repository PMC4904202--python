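"""FBA/FVA of toy stoichiometric models against brute-force LP oracles."""

import numpy as np
import pytest

from oracles import fva_oracle, growth_oracle
from ulvahydro import datasets
from ulvahydro.composition import yield_table
from ulvahydro.fba import (
    VIABILITY_EPSILON,
    MetabolicModel,
    Reaction,
    Transporter,
    build_media_bounds,
    max_growth,
    run_experiment_panel,
    target_flux_range,
    yield_g_per_kg,
)
from ulvahydro.simulate import (
    branched_model,
    fermenter_model,
    gen_random_network,
    linear_chain_model,
)


class TestMediaBounds:
    def test_single_component_molar_cap(self):
        model, _ = fermenter_model()
        bounds = build_media_bounds(model, {"glucose": 1000.0})
        assert bounds["EX_glc"] == pytest.approx(1000.0 / 180.16, rel=1e-12)

    def test_equal_masses_inverse_mw(self):
        model = MetabolicModel(
            metabolites=["a", "b"],
            reactions=[
                Reaction("EX_a", {"a": -1.0}, lb=-1000, ub=0),
                Reaction("EX_b", {"b": -1.0}, lb=-1000, ub=0),
                Reaction("growth", {"a": -1.0, "b": -1.0}, lb=0),
            ],
            growth_reaction="growth",
            media_transporters=[Transporter("EX_a", "a", 100.0),
                                Transporter("EX_b", "b", 200.0)],
        )
        bounds = build_media_bounds(model, {"a": 50.0, "b": 50.0})
        assert bounds["EX_a"] / bounds["EX_b"] == pytest.approx(2.0)

    def test_total_mass_flux_normalised(self):
        """Caps over the whole biomass medium sum to 1 g/gDW/h of mass."""
        comp = datasets.load_biomass_composition()
        media = dict(zip(comp["compound"], comp["g_per_kg"]))
        mw = {c: 100.0 + 10 * i for i, c in enumerate(media)}
        model = MetabolicModel(
            metabolites=list(media),
            reactions=[Reaction(f"EX_{c}", {c: -1.0}, lb=-1000, ub=0) for c in media]
            + [Reaction("growth", {next(iter(media)): -1.0}, lb=0)],
            growth_reaction="growth",
            media_transporters=[Transporter(f"EX_{c}", c, mw[c]) for c in media],
        )
        bounds = build_media_bounds(model, media)
        total = sum(bounds[f"EX_{c}"] * mw[c] / 1000.0 for c in media)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_media_rejected(self):
        model, _ = fermenter_model()
        with pytest.raises(ValueError, match="no consumable"):
            build_media_bounds(model, {"unknown": 10.0})


class TestMaxGrowth:
    def test_linear_chain(self):
        model, expect = linear_chain_model(uptake_cap=10.0)
        bounds = {"EX_s": 10.0}
        assert max_growth(model, bounds).objective == pytest.approx(10.0)

    def test_no_uptake_no_growth(self):
        model, _ = linear_chain_model()
        assert max_growth(model, {"EX_s": 0.0}).objective == pytest.approx(0.0)

    def test_unbounded_model_reported_as_leak(self):
        model = MetabolicModel(
            metabolites=["a"],
            reactions=[
                Reaction("make", {"a": 1.0}, lb=0.0),
                Reaction("growth", {"a": -1.0}, lb=0.0),
            ],
            growth_reaction="growth",
        )
        with pytest.raises(RuntimeError, match="leak"):
            max_growth(model, {})

    def test_random_networks_match_enumeration_oracle(self):
        for seed in range(30):
            model = gen_random_network(seed, n_metabolites=3, n_reactions=7)
            got = max_growth(model, {}).objective
            expect = growth_oracle(model)
            assert expect is not None
            assert got == pytest.approx(expect, abs=1e-7), seed


class TestTargetFluxRange:
    def test_fully_coupled_competition(self):
        model, expect = branched_model(uptake_cap=10.0)
        bounds = {"EX_s": 10.0}
        g = max_growth(model, bounds).objective
        assert g == pytest.approx(expect.max_growth)
        assert target_flux_range(model, bounds, g, "product") == pytest.approx((0.0, 0.0), abs=1e-7)

    def test_half_demand_opens_range(self):
        model, expect = branched_model(uptake_cap=10.0, growth_cap=5.0)
        bounds = {"EX_s": 10.0}
        g = max_growth(model, bounds).objective
        lo, hi = target_flux_range(model, bounds, g, "product")
        assert (lo, hi) == pytest.approx(expect.fva["product"], abs=1e-7)
        assert expect.fva["product"] == (0.0, 5.0)

    def test_nonviable_produces_nothing(self):
        model, _ = fermenter_model()
        assert target_flux_range(model, {}, 1e-6, "ethanol") == (0.0, 0.0)

    def test_fva_contains_fba_optimum_flux(self):
        model, _ = branched_model(uptake_cap=8.0, growth_cap=3.0)
        bounds = {"EX_s": 8.0}
        sol = max_growth(model, bounds)
        lo, hi = target_flux_range(model, bounds, sol.objective, "product")
        v_target = sol.fluxes[model.reaction_index("EX_prod")]
        assert lo - 1e-7 <= v_target <= hi + 1e-7

    def test_random_networks_match_fva_oracle(self):
        checked = 0
        for seed in range(40):
            model = gen_random_network(seed, n_metabolites=3, n_reactions=7)
            g = max_growth(model, {}).objective
            if g < VIABILITY_EPSILON:
                continue
            got = target_flux_range(model, {}, g, "product")
            expect = fva_oracle(model, g, "product")
            assert expect is not None
            assert got == pytest.approx(expect, abs=1e-6), seed
            checked += 1
        assert checked >= 10


class TestMassBalance:
    def test_steady_state_at_solutions(self):
        for seed in range(20):
            model = gen_random_network(seed, n_metabolites=4, n_reactions=8)
            sol = max_growth(model, {})
            S = model.stoichiometric_matrix()
            assert np.abs(S @ sol.fluxes).max() < 1e-8

    def test_removing_component_never_helps(self):
        """Tightening an uptake bound cannot increase optimal growth."""
        model, _ = fermenter_model()
        full = max_growth(model, {"EX_glc": 5.0}).objective
        starved = max_growth(model, {"EX_glc": 2.0}).objective
        none = max_growth(model, {}).objective
        assert full >= starved >= none


class TestYieldConversion:
    def test_zero_flux(self):
        assert yield_g_per_kg(0.0, 46.07) == 0.0

    def test_unit_flux_ethanol(self):
        assert yield_g_per_kg(1.0, 46.07) == pytest.approx(46.07)

    def test_stoichiometric_ceiling(self):
        """Glucose → 2 ethanol reaches the closed-form 511.5 g per kg."""
        model, expect = fermenter_model()
        bounds = build_media_bounds(model, {"glucose": 1000.0})
        g = max_growth(model, bounds).objective
        lo, hi = target_flux_range(model, bounds, g, "ethanol")
        assert yield_g_per_kg(hi, 46.07) == pytest.approx(511.5, abs=0.1)


@pytest.fixture(scope="module")
def growth_model():
    """Growth requires glucose; sugars overwrite the base carbohydrates."""
    return MetabolicModel(
        metabolites=["glc", "etoh"],
        reactions=[
            Reaction("EX_glc", {"glc": -1.0}, lb=-1000, ub=0),
            Reaction("ferment", {"glc": -1.0, "etoh": 2.0}, lb=0),
            Reaction("growth", {"glc": -1.0}, lb=0),
            Reaction("EX_etoh", {"etoh": -1.0}, lb=0),
        ],
        growth_reaction="growth",
        media_transporters=[Transporter("EX_glc", "D-Glucose", 180.16)],
        targets={"ethanol": Transporter("EX_etoh", "ethanol", 46.07)},
    )


@pytest.fixture(scope="module")
def run_sugars(runs):
    return yield_table(runs)[["run"] + [f"{s}_g_per_kg" for s in datasets.SUGARS]]


class TestExperimentPanel:
    def test_zero_sugar_runs_are_nonviable(self, growth_model, run_sugars, runs):
        comp = datasets.load_biomass_composition()
        base = dict(zip(comp[comp["class"] != "inert"]["compound"],
                        comp[comp["class"] != "inert"]["g_per_kg"]))
        panel = run_experiment_panel(
            growth_model, base, run_sugars, ["ethanol"],
            sugar_components=datasets.SUGAR_COMPOUNDS,
        )
        nearzero = panel[panel["run"].isin([6, 11, 16])]
        assert (~nearzero["viable"]).all()
        assert (nearzero["ethanol_max_g_per_kg"] == 0).all()
        rich = panel[panel["run"].isin([3, 8, 9])]
        assert rich["viable"].all()

    def test_identical_rows_identical_output(self, growth_model, run_sugars):
        twice = run_sugars.iloc[[7, 7]].reset_index(drop=True)
        panel = run_experiment_panel(
            growth_model, {"D-Glucose": 400.0}, twice, ["ethanol"],
            sugar_components=datasets.SUGAR_COMPOUNDS,
        )
        assert panel.iloc[0].drop("run").equals(panel.iloc[1].drop("run"))

    def test_scaling_sugars_never_decreases_growth(self, growth_model, run_sugars):
        base = {"D-Glucose": 400.0}
        row = run_sugars[run_sugars["run"] == 8].copy()
        panel1 = run_experiment_panel(growth_model, base, row, ["ethanol"],
                                      sugar_components=datasets.SUGAR_COMPOUNDS)
        doubled = row.copy()
        for s in datasets.SUGARS:
            doubled[f"{s}_g_per_kg"] *= 2
        panel2 = run_experiment_panel(growth_model, base, doubled, ["ethanol"],
                                      sugar_components=datasets.SUGAR_COMPOUNDS)
        assert panel2["growth"].iloc[0] >= panel1["growth"].iloc[0] - 1e-12


class TestModelIO:
    def test_json_round_trip(self, tmp_path):
        model, _ = fermenter_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MetabolicModel.from_json(path)
        assert back.reaction_ids == model.reaction_ids
        assert back.growth_reaction == model.growth_reaction
        g1 = max_growth(model, {"EX_glc": 5.0}).objective
        g2 = max_growth(back, {"EX_glc": 5.0}).objective
        assert g1 == pytest.approx(g2)

    def test_validation_rejects_unknown_metabolite(self):
        with pytest.raises(ValueError, match="unknown metabolites"):
            MetabolicModel(
                metabolites=["a"],
                reactions=[Reaction("r", {"b": 1.0})],
                growth_reaction="r",
            )

    def test_cobra_cross_check(self):
        """Independent solver path: cobra agrees on the fermenter optimum."""
        cobra = pytest.importorskip("cobra")
        model, _ = fermenter_model()
        cm = cobra.Model("toy")
        mets = {m: cobra.Metabolite(m) for m in model.metabolites}
        for r in model.reactions:
            rx = cobra.Reaction(r.id)
            rx.lower_bound, rx.upper_bound = r.lb, min(r.ub, 1e6)
            cm.add_reactions([rx])
            rx.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        cm.objective = "ferment"
        got = cm.optimize().objective_value
        bounds = build_media_bounds(model, {"glucose": 1000.0})
        ours = max_growth(model, bounds).objective
        # cobra model uses the raw exchange bound; align the glucose cap
        cm.reactions.EX_glc.lower_bound = -bounds["EX_glc"]
        got = cm.optimize().objective_value
        assert ours == pytest.approx(got, rel=1e-8)
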