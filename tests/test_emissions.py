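"""Emission factors, substitution rules, annual/cumulative accounting."""

import numpy as np
import pandas as pd
import pytest

import foodshift as fs
from foodshift import emissions as em
from foodshift.groups import ALT_GROUPS, ASF_GROUPS, BASE_GROUPS, PLANT_GROUPS


def _protein(demand, ef):
    dens = pd.Series(
        {
            g: (em.protein_density(g, ef) if g in ef.ef_protein else 0.0)
            for g in demand.columns
        }
    )
    return demand.mul(dens).sum(axis=1)


class TestFactorTable:
    def test_default_factors_match_reference_constants(self, ef_default):
        assert ef_default.ef_kcal["meat"] == 9.9
        assert ef_default.ef_kcal["cultured_meat_fish"] == 1.2
        assert ef_default.ef_protein["pulses"] == 0.6
        assert "sugar" not in ef_default.ef_protein
        assert "oils_fats" not in ef_default.ef_protein

    def test_csv_roundtrip(self, ef_default, tmp_path):
        p = tmp_path / "ef.csv"
        ef_default.to_csv(p)
        back = fs.EmissionFactorTable.from_csv(p)
        assert back.ef_kcal == ef_default.ef_kcal
        assert back.ef_protein == ef_default.ef_protein

    def test_scaled_copies_only_requested_groups(self, ef_default):
        scaled = ef_default.scaled(["cultured_meat_fish"], 3.0)
        assert scaled.ef_kcal["cultured_meat_fish"] == pytest.approx(3.6)
        assert scaled.ef_protein["cultured_meat_fish"] == pytest.approx(7.5)
        assert scaled.ef_kcal["meat"] == 9.9

    def test_non_positive_factor_rejected(self):
        with pytest.raises(ValueError):
            fs.EmissionFactorTable(ef_kcal={"meat": -1.0}, ef_protein={})


class TestProteinDensity:
    def test_reference_densities(self):
        assert fs.protein_density("meat") == pytest.approx(0.1 * 9.9 / 13.6)
        assert fs.protein_density("pb_meat_fish") == pytest.approx(0.05)

    def test_constructed_density_of_one(self):
        ef = fs.EmissionFactorTable(ef_kcal={"x": 10.0}, ef_protein={"x": 1.0})
        assert fs.protein_density("x", ef) == pytest.approx(1.0)

    def test_zero_protein_groups_raise(self):
        with pytest.raises(KeyError, match="sugar"):
            fs.protein_density("sugar")


def _schedule(fa=0.9, t_star=2025, scenario="PB"):
    return fs.build_schedule(fs.default_params(fa=fa, t_star=t_star), scenario)


class TestSubstitution:
    def test_zero_replacement_leaves_demand_unchanged(self, bau_demand):
        sched = fs.build_schedule(fs.default_params(fa=0.0, t_star=2025, s0=0.0))
        for fn in (fs.substitute_CE, fs.substitute_PE):
            out = fn(bau_demand, sched)
            pd.testing.assert_frame_equal(
                out[list(BASE_GROUPS)], bau_demand, rtol=1e-14
            )
            assert (out[list(ALT_GROUPS)] == 0).all().all()

    def test_full_substitution_moves_all_meat_to_plant_based(self, bau_demand):
        params = fs.default_params(fa=1.0, t_star=2020, s0=0.0)
        sched = fs.build_schedule(params, scenario="PB")
        # b = 0: the curve saturates immediately; cultured enters only
        # after 2033 under PB, so early years are purely plant-based.
        out = fs.substitute_CE(bau_demand, sched)
        y = out.loc[2025]
        assert (y["meat"].abs() < 1e-3).all()
        base = bau_demand.loc[2025]
        np.testing.assert_allclose(
            y["pb_meat_fish"], base["meat"] + base["fish"], rtol=1e-12
        )

    def test_ce_conserves_calories_exactly(self, bau_demand):
        for target in ("alternatives", "plants"):
            out = fs.substitute_CE(bau_demand, _schedule(), target=target)
            np.testing.assert_allclose(
                out.sum(axis=1), bau_demand.sum(axis=1), rtol=1e-9
            )

    def test_pe_conserves_protein_exactly(self, bau_demand, ef_default):
        for target in ("alternatives", "plants"):
            out = fs.substitute_PE(bau_demand, _schedule(), target=target, ef=ef_default)
            np.testing.assert_allclose(
                _protein(out, ef_default), _protein(bau_demand, ef_default), rtol=1e-9
            )

    def test_pe_example_meat_to_plant_based_calories(self):
        """Replacing 1000 kcal of meat protein-for-protein with plant-based
        meat requires 1455.9 kcal of the substitute (densities 0.0728 vs
        0.05 g protein per kcal)."""
        idx = pd.MultiIndex.from_tuples([(2050, "R")], names=["year", "region"])
        demand = pd.DataFrame(0.0, index=idx, columns=list(BASE_GROUPS))
        demand["meat"] = 1000.0
        demand["cereals"] = 1.0  # non-degenerate plant pool
        sched = fs.build_schedule(
            fs.default_params(fa=1.0, t_star=2020, s0=0.0), scenario="PB"
        )
        out = fs.substitute_PE(demand, sched)
        cultured = out.loc[(2050, "R"), "cultured_meat_fish"]
        pb = out.loc[(2050, "R"), "pb_meat_fish"]
        # total substitute protein equals 1000 kcal * 0.0727941 g/kcal
        total_protein = pb * 0.05 + cultured * (0.1 * 1.2 / 2.5)
        assert total_protein == pytest.approx(1000 * 0.1 * 9.9 / 13.6, rel=1e-12)
        # with no cultured share the calories would be exactly 1455.88
        sched0 = fs.build_schedule(
            fs.default_params(fa=1.0, t_star=2020, s0=0.0), scenario="PB"
        )
        early = fs.substitute_PE(demand.rename(index={2050: 2025}, level=0), sched0)
        assert early.loc[(2025, "R"), "pb_meat_fish"] == pytest.approx(
            1455.8823529411766, rel=1e-12
        )

    def test_pe_needs_more_substitute_calories_than_ce(self, bau_demand, ef_default):
        """Protein matching requires at least as many substitute calories
        as calorie matching whenever the substitute is less protein-dense
        than the ASF it replaces (true of all default alternatives)."""
        ce = fs.substitute_CE(bau_demand, _schedule())
        pe = fs.substitute_PE(bau_demand, _schedule(), ef=ef_default)
        assert (
            pe[list(ALT_GROUPS)].sum(axis=1) >= ce[list(ALT_GROUPS)].sum(axis=1) - 1e-9
        ).all()

    def test_substitute_without_protein_factor_raises(self, bau_demand):
        ef = fs.EmissionFactorTable()
        ef.ef_protein.pop("pb_dairy")
        with pytest.raises(ValueError, match="pb_dairy"):
            fs.substitute_PE(bau_demand, _schedule(), ef=ef)


class TestAnnualEmissions:
    def test_meat_unit_example(self):
        idx = pd.MultiIndex.from_tuples([(2020, "R")], names=["year", "region"])
        demand = pd.DataFrame({"meat": [1.0e12]}, index=idx)
        annual = fs.annual_emissions(demand)
        assert annual[2020] == pytest.approx(0.0099)

    def test_zero_demand_gives_zero(self):
        idx = pd.MultiIndex.from_tuples([(2020, "R")], names=["year", "region"])
        demand = pd.DataFrame({"meat": [0.0]}, index=idx)
        assert fs.annual_emissions(demand)[2020] == 0.0

    def test_missing_factor_names_group(self):
        idx = pd.MultiIndex.from_tuples([(2020, "R")], names=["year", "region"])
        demand = pd.DataFrame({"unobtainium": [1.0]}, index=idx)
        with pytest.raises(KeyError, match="unobtainium"):
            fs.annual_emissions(demand)

    def test_kcal_and_protein_bases_agree_up_to_zero_protein_groups(
        self, bau_demand, ef_default
    ):
        """Both factor bases describe the same stream, so they yield the
        same emissions except for sugar and oils & fats, which only exist
        on the kcal basis."""
        kcal_basis = fs.annual_emissions(bau_demand, basis="kcal")
        protein_basis = fs.annual_emissions(bau_demand, basis="protein")
        zero_protein = fs.annual_emissions(
            bau_demand[["sugar", "oils_fats"]], basis="kcal"
        )
        np.testing.assert_allclose(
            kcal_basis - zero_protein, protein_basis, rtol=1e-9
        )

    def test_dominance_of_substitution(self, bau_demand, ef_default):
        """Replacing ASF calories with any substitute strictly lowers
        annual emissions: every ASF per-kcal factor exceeds every plant or
        alternative factor."""
        asf_min = min(ef_default.ef_kcal[g] for g in ASF_GROUPS)
        sub_max = max(
            ef_default.ef_kcal[g] for g in PLANT_GROUPS + ALT_GROUPS
        )
        assert asf_min > sub_max
        before = fs.annual_emissions(bau_demand)
        for target in ("alternatives", "plants"):
            after = fs.annual_emissions(
                fs.substitute_CE(bau_demand, _schedule(fa=0.5), target=target)
            )
            assert (after.loc[2026:] < before.loc[2026:]).all()


class TestCumulativeAndBudget:
    def test_constant_annual_series(self):
        annual = pd.Series(10.0, index=pd.Index(range(2020, 2051), name="year"))
        assert fs.cumulative(annual) == pytest.approx(310.0)

    def test_incomplete_coverage_rejected(self):
        annual = pd.Series(10.0, index=pd.Index(range(2020, 2049), name="year"))
        with pytest.raises(ValueError, match="missing"):
            fs.cumulative(annual)

    def test_default_budget_is_one_third_of_total(self):
        budget = fs.CarbonBudget()
        assert budget.food_budget == pytest.approx(1170.0 / 3.0)
        assert fs.budget_gap(390.0) == pytest.approx(0.0)
        assert fs.budget_gap(400.0) == pytest.approx(10.0)


class TestHealthyDietSpec:
    def test_caloric_target(self):
        spec = fs.eat_lancet_spec()
        assert spec.kcal_target == 2500.0
        asf = sum(spec.target_shares.get(g, 0.0) for g in ASF_GROUPS)
        assert asf < 0.249  # strictly below the Western-diet convergence target

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            fs.eat_lancet_spec({"cereals": 0.5})
        with pytest.raises(ValueError):
            fs.eat_lancet_spec({})

    def test_healthy_diet_lowers_emissions(self, fixture_seed1):
        bau = fs.run_scenario(fs.ScenarioSpec(family="BAU"), fixture_seed1)
        hd = fs.run_scenario(
            fs.ScenarioSpec(family="EATLANCET", fa=1.0, t_star=2024), fixture_seed1
        )
        assert hd.cumulative < bau.cumulative
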