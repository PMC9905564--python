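"""Gross production and the five bioerosion equations against independent
arithmetic oracles, plus linearity/additivity properties."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefbudget.io_config import RateLibrary, SchemaError, SurveyRow, default_rate_library
from reefbudget.production_bioerosion import (
    CoverProfile,
    GrazerDensity,
    broadcast_fish_densities,
    component_shares,
    gross_production,
    macroborer_rate,
    microborer_rate,
    parrotfish_percapita,
    parrotfish_rate,
    puffer_rate,
    sponge_rate,
    total_bioerosion,
    transect_budget,
    urchin_rate,
)


def make_cover(gulf="GoC", live=None, thick_turf=0.0, dead=0.0, rubble=0.0,
               framework=0.0, cca=0.0, fine_turf=0.0, macroalgae=0.0, sand=0.0):
    return CoverProfile(
        transect_id="t1", site="uva", gulf=gulf, period="spring-2018",
        live_by_taxon=live or {}, thick_turf=thick_turf, dead=dead,
        rubble=rubble, framework=framework, cca=cca, fine_turf=fine_turf,
        macroalgae=macroalgae, sand=sand,
    )


FIXTURE_RATES = RateLibrary(
    taxon_calcification={
        "pocillopora": {"GoP": 2.0, "GoC": 2.0},
        "cca": {"GoP": 0.1, "GoC": 0.1},
    },
    macroborer={
        "GoP": {"ml": 0.5, "mt": 12.0, "md": 8.0},
        "GoC": {"ml": 0.5, "mt": 12.0, "md": 8.0},
    },
    urchin={
        "GoP": {"ul": 0.1, "ud": 0.3, "ut": 0.2},
        "GoC": {"ul": 0.1, "ud": 0.3, "ut": 0.2},
    },
)


class TestGrossProduction:
    def test_full_pocillopora_cover_at_gulf_rate(self, rates):
        cover = make_cover(gulf="GoC", live={"pocillopora": 1.0})
        assert gross_production(cover, rates) == pytest.approx(20.8)

    def test_all_sand_is_zero(self, rates):
        assert gross_production(make_cover(sand=1.0), rates) == 0.0

    def test_term_by_term_sum(self):
        cover = make_cover(live={"pocillopora": 0.5}, cca=0.1, sand=0.4)
        # 0.5*2.0*10 + 0.1*0.1*10
        assert gross_production(cover, FIXTURE_RATES) == pytest.approx(10.1)

    def test_unknown_taxon_rejected(self):
        cover = make_cover(live={"porites": 0.5})
        with pytest.raises(SchemaError, match="porites"):
            gross_production(cover, FIXTURE_RATES)


class TestMacroborer:
    def test_arithmetic_oracle(self):
        cover = make_cover(live={"pocillopora": 0.75}, thick_turf=0.10, dead=0.15)
        # 0.75*0.5 + 0.10*12 + 0.15*8
        assert macroborer_rate(cover, FIXTURE_RATES) == pytest.approx(2.775)

    def test_all_sand_is_zero(self):
        assert macroborer_rate(make_cover(sand=1.0), FIXTURE_RATES) == 0.0

    def test_linearity_in_cover(self):
        half = make_cover(live={"pocillopora": 0.2}, thick_turf=0.05, dead=0.1)
        full = make_cover(live={"pocillopora": 0.4}, thick_turf=0.10, dead=0.2)
        assert macroborer_rate(full, FIXTURE_RATES) == pytest.approx(
            2.0 * macroborer_rate(half, FIXTURE_RATES)
        )

    def test_missing_gulf_rejected(self):
        with pytest.raises(SchemaError):
            macroborer_rate(make_cover(), FIXTURE_RATES, gulf="GoX")


class TestMicroborer:
    def test_flat_constant_by_default(self, rates):
        assert microborer_rate(make_cover(sand=1.0), rates) == 0.233

    @pytest.mark.parametrize("dead,expected", [(0.0, 0.0), (0.5, 0.1165)])
    def test_scaled_mode(self, rates, dead, expected):
        cover = make_cover(dead=dead)
        assert microborer_rate(cover, rates, scale_by_dead=True) == pytest.approx(expected)


class TestSponge:
    @pytest.mark.parametrize(
        "live,rc,fc,expected",
        [
            (1.0, 0.0, 0.0, 0.391),  # 1*0.46*0.85
            (0.5, 0.2, 0.1, 0.5 * 0.46 * 0.85 + 0.2 * 0.46 * 0.85 + 0.1 * 0.56 * 0.85),
            (0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_term_by_term_oracle(self, rates, live, rc, fc, expected):
        cover = make_cover(live={"pocillopora": live} if live else {}, rubble=rc,
                           framework=fc)
        assert sponge_rate(cover, rates) == pytest.approx(expected)


class TestUrchin:
    def test_zero_density_is_zero(self, rates):
        cover = make_cover(live={"pocillopora": 0.5}, dead=0.5)
        assert urchin_rate(cover, GrazerDensity("t1", urchin=0.0), rates) == 0.0

    def test_arithmetic_oracle(self):
        cover = make_cover(live={"pocillopora": 0.5}, dead=0.3, thick_turf=0.2)
        dens = GrazerDensity("t1", urchin=2.0)
        # (0.5*0.1 + 0.3*0.3 + 0.2*0.2) * 2 * 365/1000 = 0.36*0.365
        assert urchin_rate(cover, dens, FIXTURE_RATES) == pytest.approx(0.1314)

    def test_linear_in_density(self):
        cover = make_cover(live={"pocillopora": 0.5}, dead=0.3, thick_turf=0.2)
        one = urchin_rate(cover, GrazerDensity("t1", urchin=1.0), FIXTURE_RATES)
        three = urchin_rate(cover, GrazerDensity("t1", urchin=3.0), FIXTURE_RATES)
        assert three == pytest.approx(3.0 * one)


class TestFish:
    def test_parrotfish_percapita_oracle(self):
        from reefbudget.io_config import ParrotfishParams

        lib = default_rate_library()
        lib.parrotfish["demo"] = ParrotfishParams(
            bite_rate=300.0, prop_scars=0.1, scar_volume=0.05, feeding_hours=8.0
        )
        expected = 300.0 * 8.0 * 365.0 * 0.1 * 0.05 * 1.84 / 1000.0
        assert parrotfish_percapita(lib, "demo") == pytest.approx(expected)
        assert expected == pytest.approx(8.06, abs=0.01)

    def test_zero_scars_gives_zero(self):
        from reefbudget.io_config import ParrotfishParams

        lib = default_rate_library()
        lib.parrotfish["demo"] = ParrotfishParams(300.0, 0.0, 0.05, 8.0)
        assert parrotfish_percapita(lib, "demo") == 0.0

    def test_scar_volume_linearity(self, rates):
        base = parrotfish_percapita(rates, "scarus_ghobban")
        from reefbudget.io_config import ParrotfishParams

        lib = default_rate_library()
        p = lib.parrotfish["scarus_ghobban"]
        lib.parrotfish["scarus_ghobban"] = ParrotfishParams(
            p.bite_rate, p.prop_scars, 2.0 * p.scar_volume, p.feeding_hours
        )
        assert parrotfish_percapita(lib, "scarus_ghobban") == pytest.approx(2.0 * base)

    def test_parrotfish_rate_sums_over_species(self):
        dens = GrazerDensity("t1", fish={"a": 0.002, "b": 0.001})
        percapita = {"a": 8.06, "b": 10.0}
        assert parrotfish_rate(dens, percapita) == pytest.approx(0.002 * 8.06 + 0.01)
        assert parrotfish_rate(GrazerDensity("t1"), percapita) == 0.0

    def test_puffer_oracle_and_feeding_fraction_scaling(self):
        from reefbudget.io_config import PufferParams

        lib = default_rate_library()
        lib.puffer = PufferParams(d_a=5.0, feeding_fraction=0.6)
        dens = GrazerDensity("t1", fish={"arothron_meleagris": 0.01})
        assert puffer_rate(dens, lib) == pytest.approx(5.0 * 0.365 * 0.01 * 0.6)
        lib.puffer = PufferParams(d_a=5.0, feeding_fraction=1.0)
        assert puffer_rate(dens, lib) == pytest.approx(5.0 * 0.365 * 0.01)
        assert puffer_rate(GrazerDensity("t1"), lib) == 0.0


class TestTotals:
    def test_sum_oracle(self):
        components = {
            "macroborer": 2.775, "microborer": 0.233, "sponge": 0.3213,
            "urchin": 0.1314, "parrotfish": 0.0161, "puffer": 0.01095,
        }
        assert total_bioerosion(components) == pytest.approx(3.48775)

    def test_permutation_invariance_and_zero(self):
        comps = {"a": 1.0, "b": 2.0, "c": 0.5}
        flipped = dict(reversed(list(comps.items())))
        assert total_bioerosion(comps) == total_bioerosion(flipped)
        assert total_bioerosion({"a": 0.0, "b": 0.0}) == 0.0

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            total_bioerosion({"a": -0.1})

    def test_component_shares_sum_to_one(self):
        shares = component_shares({"a": 1.0, "b": 3.0})
        assert shares == {"a": 0.25, "b": 0.75}


@st.composite
def random_cover(draw):
    weights = draw(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=6, max_size=6)
    )
    total = sum(weights) or 1.0
    f = [w / total for w in weights]
    return make_cover(
        live={"pocillopora": f[0]}, thick_turf=f[1], dead=f[2] + f[3],
        rubble=f[4], framework=f[3], fine_turf=f[2], sand=f[5],
    )


class TestProperties:
    @given(cover=random_cover(), urchin=st.floats(0.0, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_components_nonnegative_and_additive(self, rates, cover, urchin):
        dens = GrazerDensity("t1", urchin=urchin,
                             fish={"scarus_ghobban": 0.002, "arothron_meleagris": 0.004})
        budget = transect_budget(cover, dens, rates)
        comps = {k: budget[k] for k in
                 ("macroborer", "microborer", "sponge", "urchin", "parrotfish", "puffer")}
        assert all(v >= 0 for v in comps.values())
        assert budget["total_bioerosion"] == pytest.approx(sum(comps.values()), rel=1e-12)

    @given(scale=st.floats(0.1, 1.0), urchin=st.floats(0.0, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_cover_scaling_linearity(self, rates, scale, urchin):
        base = make_cover(live={"pocillopora": 0.4}, thick_turf=0.2, dead=0.3)
        scaled = make_cover(
            live={"pocillopora": 0.4 * scale}, thick_turf=0.2 * scale, dead=0.3 * scale
        )
        dens = GrazerDensity("t1", urchin=urchin)
        for fn in (macroborer_rate, sponge_rate):
            assert fn(scaled, rates) == pytest.approx(scale * fn(base, rates), rel=1e-9)
        assert urchin_rate(scaled, dens, rates) == pytest.approx(
            scale * urchin_rate(base, dens, rates), rel=1e-9
        )


class TestCoverProfileConstruction:
    def test_from_counts_fractions_and_live_total(self):
        rows = [
            SurveyRow("uva", "GoC", "spring-2018", "uva-T1", "pocillopora", 40),
            SurveyRow("uva", "GoC", "spring-2018", "uva-T1", "porites", 10),
            SurveyRow("uva", "GoC", "spring-2018", "uva-T1", "thick_turf", 20),
            SurveyRow("uva", "GoC", "spring-2018", "uva-T1", "dead_framework", 10),
            SurveyRow("uva", "GoC", "spring-2018", "uva-T1", "fine_turf", 10),
            SurveyRow("uva", "GoC", "spring-2018", "uva-T1", "sand", 10),
        ]
        cover = CoverProfile.from_counts(rows)
        assert cover.live == pytest.approx(0.5)
        assert cover.live_by_taxon == {"pocillopora": 0.4, "porites": 0.1}
        assert cover.dead == pytest.approx(0.2)  # dead framework + fine turf
        assert cover.framework == pytest.approx(0.1)

    def test_rows_from_multiple_transects_rejected(self):
        rows = [
            SurveyRow("uva", "GoC", "spring-2018", "uva-T1", "sand", 100),
            SurveyRow("uva", "GoC", "spring-2018", "uva-T2", "sand", 100),
        ]
        with pytest.raises(ValueError, match="multiple transects"):
            CoverProfile.from_counts(rows)


class TestFishBroadcast:
    def test_fill_with_provenance_flag(self):
        grazers = pd.DataFrame(
            {
                "site": ["uva"] * 3,
                "gulf": ["GoC"] * 3,
                "period": ["spring-2016", "spring-2018", "spring-2018"],
                "transect_id": ["uva-T1"] * 3,
                "taxon": ["diadema_mexicanum", "scarus_ghobban", "diadema_mexicanum"],
                "density_ind_m2": [0.4, 0.01, 4.9],
            }
        )
        out = broadcast_fish_densities(grazers, ["spring-2016", "spring-2018"])
        fish = out[out["taxon"] == "scarus_ghobban"]
        assert set(fish["period"]) == {"spring-2016", "spring-2018"}
        assert fish.set_index("period")["extrapolated"].to_dict() == {
            "spring-2016": True,
            "spring-2018": False,
        }
        assert (fish["density_ind_m2"] == 0.01).all()
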