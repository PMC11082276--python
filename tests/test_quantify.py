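"""Internal-standard normalization and mole-fraction summaries."""

import numpy as np
import pandas as pd
import pytest

from tagms.quantify import (
    InternalStandard,
    InternalStandardSet,
    acyl_mole_pct,
    class_fractions,
    default_standards,
    is_normalize,
    species_fraction_within_class,
    stage_summary,
)


def peak_row(sample, stage, rep, species, response):
    return {
        "sample": sample,
        "stage": stage,
        "replicate": rep,
        "species": species,
        "response": response,
    }


@pytest.fixture
def simple_peaks():
    """One sample with the three standards plus a few endogenous species."""
    return pd.DataFrame(
        [
            peak_row("G_1", "G", 1, "PE 18:0/18:0", 1.0),
            peak_row("G_1", "G", 1, "DAG 18:0/22:6", 1.0),
            peak_row("G_1", "G", 1, "SQDG 16:0/18:0", 1.0),
            peak_row("G_1", "G", 1, "PC 16:0/18:2", 1.0),
            peak_row("G_1", "G", 1, "TAG 18:2/22:1/22:1", 2.0),
            peak_row("G_1", "G", 1, "MGDG 18:3/18:3", 0.0),
        ]
    )


class TestIsNormalize:
    def test_response_equal_to_standard_gives_spiked_amount(self, simple_peaks, standards):
        prof = is_normalize(simple_peaks, standards)
        amounts = dict(zip(prof.species, prof.amount_pmol))
        assert amounts["PC 16:0/18:2"] == pytest.approx(125.0)
        assert amounts["TAG 18:2/22:1/22:1"] == pytest.approx(250.0)
        assert amounts["MGDG 18:3/18:3"] == 0.0

    def test_standard_rows_excluded(self, simple_peaks, standards):
        prof = is_normalize(simple_peaks, standards)
        assert not set(prof.species) & standards.standard_species

    def test_homogeneity(self, simple_peaks, standards):
        """Doubling every response in a sample doubles ratios and amounts;
        mole fractions are unchanged."""
        doubled = simple_peaks.assign(response=simple_peaks.response * 2)
        a = is_normalize(simple_peaks, standards)
        b = is_normalize(doubled, standards)
        # all responses double including the standard: ratios, amounts equal
        assert np.allclose(a.amount_pmol, b.amount_pmol)
        only_endog = simple_peaks.copy()
        only_endog.loc[
            ~only_endog.species.isin(standards.standard_species), "response"
        ] *= 2
        c = is_normalize(only_endog, standards)
        assert np.allclose(c.amount_pmol, 2 * a.amount_pmol)
        assert np.allclose(
            class_fractions(c).mol_pct, class_fractions(a.assign()).mol_pct
        )

    def test_missing_standard_names_sample_and_class(self, simple_peaks, standards):
        broken = simple_peaks[simple_peaks.species != "PE 18:0/18:0"]
        with pytest.raises(ValueError, match=r"G_1.*PE 18:0/18:0"):
            is_normalize(broken, standards)

    def test_duplicate_sample_species_rejected(self, simple_peaks, standards):
        dup = pd.concat([simple_peaks, simple_peaks.iloc[[3]]])
        with pytest.raises(ValueError, match="unique"):
            is_normalize(dup, standards)

    def test_response_factor_scales_amounts(self, simple_peaks):
        std = InternalStandardSet(
            standards={
                "PE": InternalStandard("PE 18:0/18:0", 125.0, response_factor=2.0),
                "DAG": InternalStandard("DAG 18:0/22:6", 125.0),
                "SQDG": InternalStandard("SQDG 16:0/18:0", 125.0),
            },
            fallback=default_standards().fallback,
        )
        prof = is_normalize(simple_peaks, std)
        amounts = dict(zip(prof.species, prof.amount_pmol))
        assert amounts["PC 16:0/18:2"] == pytest.approx(250.0)

    def test_unmapped_class_raises(self, simple_peaks):
        std = InternalStandardSet(
            standards={"PE": InternalStandard("PE 18:0/18:0", 125.0)}, fallback={}
        )
        with pytest.raises(ValueError, match="fallback"):
            is_normalize(simple_peaks, std)

    def test_inputs_not_mutated(self, simple_peaks, standards):
        snapshot = simple_peaks.copy(deep=True)
        is_normalize(simple_peaks, standards)
        pd.testing.assert_frame_equal(simple_peaks, snapshot)


def profile_from_percents(stage, percents):
    """Build a one-sample profile whose class totals follow given mol%."""
    rows = []
    for i, (species, pct) in enumerate(percents.items()):
        rows.append(
            {
                "sample": f"{stage}_1",
                "stage": stage,
                "replicate": 1,
                "species": species,
                "amount_pmol": pct * 10.0,
            }
        )
    return pd.DataFrame(rows)


class TestClassFractions:
    def test_single_species_is_100(self):
        prof = profile_from_percents("G", {"TAG 18:2/22:1/22:1": 42.0})
        cf = class_fractions(prof)
        assert cf.mol_pct.iloc[0] == pytest.approx(100.0)

    def test_green_stage_reference_percentages_at_zero_noise(self):
        """A profile built from the green-stage class distribution returns
        exactly those mole percentages."""
        percents = {
            "TAG 18:2/22:1/22:1": 29.3,
            "PA 16:0/18:2": 28.5,
            "PC 16:0/18:2": 10.1,
            "DGDG 18:3/18:3": 8.4,
            "MGDG 18:3/18:3": 7.1,
            "PE 16:0/18:2": 3.4,
            "DAG 16:0/18:2": 3.3,
            "PG 16:0/18:2": 2.7,
            "PI 16:0/18:2": 2.4,
            "PS 16:0/18:2": 2.4,
            "SQDG 16:0/18:3": 2.4,
        }
        cf = class_fractions(profile_from_percents("G", percents))
        got = dict(zip(cf.lipid_class, cf.mol_pct))
        for species, pct in percents.items():
            cls = species.split()[0]
            assert got[cls] == pytest.approx(pct, abs=1e-9)
        assert cf.mol_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_profile_raises(self):
        prof = profile_from_percents("G", {"TAG 18:2/22:1/22:1": 0.0})
        with pytest.raises(ValueError, match="all-zero"):
            class_fractions(prof)

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            class_fractions(pd.DataFrame(columns=["sample", "stage", "replicate", "species", "amount_pmol"]))


class TestWithinClassFractions:
    def test_single_species_in_class(self):
        prof = profile_from_percents(
            "G", {"DAG 16:0/18:2": 5.0, "TAG 18:2/22:1/22:1": 95.0}
        )
        sf = species_fraction_within_class(prof, "DAG")
        assert sf.pct_of_class.iloc[0] == pytest.approx(100.0)

    def test_green_stage_dag_34_2_reference_value(self):
        """At zero noise the 34:2 diacylglycerol share of the green-stage
        DAG pool equals the calibrated 22.21%."""
        from tagms.simulate import default_stage_params, simulate_profile

        params = default_stage_params(replicate_cv=0.0)
        prof = simulate_profile(params["G"], 1, seed=0)
        sf = species_fraction_within_class(prof, "DAG")
        got = dict(zip(sf.species, sf.pct_of_class))
        assert got["DAG 16:0/18:2"] == pytest.approx(22.21, abs=1e-9)
        assert sf.pct_of_class.sum() == pytest.approx(100.0, abs=1e-9)

    def test_absent_class_raises(self):
        prof = profile_from_percents("G", {"TAG 18:2/22:1/22:1": 1.0})
        with pytest.raises(ValueError):
            species_fraction_within_class(prof, "PC")


class TestAcylMolePct:
    def test_counting_example(self):
        prof = profile_from_percents("G", {"TAG 18:2/22:1/22:1": 1.0})
        pct = acyl_mole_pct(prof)
        assert pct["22:1"] == pytest.approx(200 / 3, abs=1e-9)
        assert pct["18:2"] == pytest.approx(100 / 3, abs=1e-9)

    def test_scale_invariance(self):
        prof = profile_from_percents(
            "G", {"TAG 18:2/22:1/22:1": 3.0, "DAG 16:0/18:2": 2.0}
        )
        scaled = prof.assign(amount_pmol=prof.amount_pmol * 7.5)
        pd.testing.assert_series_equal(acyl_mole_pct(prof), acyl_mole_pct(scaled))

    def test_class_total_species_excluded_with_warning(self):
        prof = profile_from_percents(
            "G", {"TAG 62:4": 1.0, "DAG 16:0/18:2": 1.0}
        )
        with pytest.warns(UserWarning, match="class-total"):
            pct = acyl_mole_pct(prof)
        assert set(pct.index) == {"16:0", "18:2"}

    def test_agreement_with_per_chain_expansion_oracle(self):
        """Random profiles against a brute-force chain-by-chain tally."""
        from tagms.species import parse_species

        rng = np.random.default_rng(7)
        pool = [
            "TAG 18:2/22:1/22:1", "TAG 16:0/18:2/22:1", "DAG 16:0/18:2",
            "PC 18:1/18:2", "PE 16:0/18:2", "TAG 18:1/18:1/18:2",
        ]
        for _ in range(50):
            species = rng.choice(pool, size=rng.integers(1, 6), replace=False)
            amounts = rng.uniform(0.1, 100.0, size=len(species))
            prof = pd.DataFrame(
                {
                    "sample": "s1",
                    "stage": "G",
                    "replicate": 1,
                    "species": species,
                    "amount_pmol": amounts,
                }
            )
            got = acyl_mole_pct(prof)
            tally = {}
            for sp, amt in zip(species, amounts):
                for chain in parse_species(sp).acyls:
                    tally[chain.name] = tally.get(chain.name, 0.0) + amt
            total = sum(tally.values())
            for name, val in tally.items():
                assert got[name] == pytest.approx(100 * val / total, abs=1e-9)


class TestStageSummary:
    def _profile(self):
        rows = []
        for stage, reps in (("G", [10.0, 10.0, 10.0]), ("M", [20.0, 30.0])):
            for i, v in enumerate(reps, start=1):
                rows.append(
                    {
                        "sample": f"{stage}_{i}",
                        "stage": stage,
                        "replicate": i,
                        "species": "TAG 18:2/22:1/22:1",
                        "amount_pmol": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_replicates_sd_zero(self):
        out = stage_summary(self._profile())
        g = out[out.stage == "G"].iloc[0]
        assert (g["mean"], g["sd"], g["n"]) == (10.0, 0.0, 3)

    def test_mean_is_brute_average(self):
        out = stage_summary(self._profile())
        m = out[out.stage == "M"].iloc[0]
        assert m["mean"] == pytest.approx((20.0 + 30.0) / 2)

    def test_single_replicate_sd_missing(self):
        df = self._profile().iloc[[0]]
        out = stage_summary(df)
        assert np.isnan(out.sd.iloc[0])

    def test_auxiliary_anova_column(self):
        out = stage_summary(self._profile(), anova=True)
        assert "anova_p" in out.columns
        assert ((0 <= out.anova_p) & (out.anova_p <= 1)).all()


def test_standards_yaml_round_trip(tmp_path, standards):
    path = tmp_path / "standards.yaml"
    standards.to_yaml(path)
    back = InternalStandardSet.from_yaml(path)
    assert back.standards == dict(standards.standards)
    assert back.fallback == dict(standards.fallback)
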