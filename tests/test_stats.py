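import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from springboard.errors import DomainError, ValidationError
from springboard import stats as sbs


def _jump_df():
    """Small hand-built jump table: 2 animals, controls + platform jumps."""
    rows = []
    for aid, vs in (("a1", [1.4, 1.5, 1.3]), ("a2", [1.2, 1.2, 1.2])):
        for v in vs:
            rows.append(
                dict(
                    animal_id=aid, platform_id="control", line_index=np.nan,
                    time_to_takeoff=0.028, velocity=v, elevation=43.5,
                    acceleration=v / 0.028, kinetic_energy=v**2,
                    kinetic_energy_density=v**2 / 0.05, power=v**2 / 0.028,
                    power_density=v**2 / 0.0014, k_g=3.4, k_p=np.nan,
                )
            )
    for aid, k_p, v in (("a1", 1.0, 1.08), ("a1", 24.0, 1.40), ("a2", 1.0, 0.9), ("a2", 24.0, 1.2)):
        rows.append(
            dict(
                animal_id=aid, platform_id="A", line_index=1 if k_p > 3.4 else 10,
                time_to_takeoff=0.030, velocity=v, elevation=40.0,
                acceleration=v / 0.030, kinetic_energy=v**2,
                kinetic_energy_density=v**2 / 0.05, power=v**2 / 0.030,
                power_density=v**2 / 0.0015, k_g=3.4, k_p=k_p,
            )
        )
    return pd.DataFrame(rows)


class TestControlMeans:
    def test_mean_of_three(self):
        cm = sbs.control_means(_jump_df())
        assert cm.loc["a1", "velocity"] == pytest.approx(1.4)

    def test_single_and_identical_jumps(self):
        df = _jump_df()
        assert sbs.control_means(df).loc["a2", "velocity"] == pytest.approx(1.2)

    def test_animal_without_controls_named(self):
        df = _jump_df()
        df = df[~((df.animal_id == "a2") & (df.platform_id == "control"))]
        with pytest.raises(ValidationError, match="a2"):
            sbs.control_means(df)


class TestNormalize:
    def test_ratio_and_difference(self):
        df = _jump_df()
        norm = sbs.normalize_jumps(df, mean_k_g=3.42)
        row = norm[(norm.animal_id == "a1") & (norm.k_p == 1.0)].iloc[0]
        assert row["velocity"] == pytest.approx(1.08 / 1.4)
        assert row["elevation"] == pytest.approx(40.0 - 43.5)

    def test_elevation_difference_against_printed_mean(self):
        # elevation is a polar quantity: difference, not ratio
        assert 40.0 - 43.5 == pytest.approx(-3.5)

    def test_control_normalized_by_itself_is_unity(self):
        df = _jump_df()
        controls = sbs.control_means(df)
        ctrl = df[df.platform_id == "control"].copy()
        ctrl["platform_id"] = "A"  # treat controls as experimental
        ctrl["k_p"] = 100.0
        norm = sbs.normalize_jumps(
            pd.concat([df[df.platform_id == "control"], ctrl]),
            controls=controls, mean_k_g=3.42,
        )
        for aid, grp in norm.groupby("animal_id"):
            assert grp["velocity"].mean() == pytest.approx(1.0)
            assert grp["elevation"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_regime_assignment_exhaustive_exclusive(self):
        norm = sbs.normalize_jumps(_jump_df(), mean_k_g=3.42)
        assert set(norm["regime"]) == {"compliant", "stiff"}
        assert (norm.loc[norm.k_p < 3.42, "regime"] == "compliant").all()
        assert (norm.loc[norm.k_p >= 3.42, "regime"] == "stiff").all()

    def test_tie_goes_to_stiff(self):
        assert sbs.assign_regime(3.42, 3.42) == "stiff"


class TestOneSampleTest:
    def test_symmetric_sample_null(self):
        r = sbs.one_sample_test([0.9, 1.0, 1.1], 1.0)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.pvalue == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            sbs.one_sample_test([2.0, 2.0, 2.0, 2.0], 1.0)

    def test_clear_shift_rejects_null(self):
        # n=4, mean 1.275, sd 0.0645 -> t = 8.521
        r = sbs.one_sample_test([1.2, 1.3, 1.25, 1.35], 1.0)
        assert r.statistic == pytest.approx(8.5206, abs=1e-3)
        assert r.pvalue < 0.05

    def test_nonnormal_sample_reports_wilcoxon(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(size=40) * 2)  # heavily skewed
        r = sbs.one_sample_test(x, 1.0)
        assert not r.normal
        assert r.wilcoxon_pvalue is not None

    @given(c=st.floats(-10, 10))
    def test_location_equivariance(self, c):
        x = np.array([0.82, 1.05, 1.3, 0.9, 1.12])
        r0 = sbs.one_sample_test(x, 1.0)
        r1 = sbs.one_sample_test(x + c, 1.0 + c)
        assert r1.statistic == pytest.approx(r0.statistic, rel=1e-9, abs=1e-9)
        assert r1.pvalue == pytest.approx(r0.pvalue, rel=1e-9, abs=1e-9)


def _synthetic_regime_data(seed, slope, n_animals=6, n_per=8, sd_animal=0.05, sd_noise=0.05):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        b = rng.normal(0, sd_animal)
        for k in rng.uniform(0.5, 3.0, n_per):
            rows.append(
                dict(
                    animal_id=f"a{a}", platform_id="A", regime="compliant",
                    k_p=k, velocity=0.2 + slope * k + b + rng.normal(0, sd_noise),
                )
            )
    return pd.DataFrame(rows)


class TestRegimeModel:
    def test_recovers_known_slope(self):
        df = _synthetic_regime_data(seed=0, slope=0.23)
        res = sbs.RegimeModel(df, "velocity", "compliant").fit()
        name = [n for n in res.params.index if "k_p" in n][0]
        lo, hi = res.conf_int.loc[name]
        assert lo <= 0.23 <= hi
        assert res.params[name] == pytest.approx(0.23, abs=0.05)

    def test_single_animal_rejected(self):
        df = _synthetic_regime_data(seed=1, slope=0.1, n_animals=1)
        with pytest.raises(ValidationError, match="2 animals"):
            sbs.RegimeModel(df, "velocity", "compliant")

    def test_stiff_regime_drops_null_interaction(self):
        rng = np.random.default_rng(7)
        rows = []
        for a in range(6):
            b = rng.normal(0, 0.02)
            for pid, ks in (("A", [5, 10, 40, 120]), ("B", [24, 120, 500])):
                for k in ks:
                    rows.append(
                        dict(
                            animal_id=f"a{a}", platform_id=pid, regime="stiff",
                            k_p=k, velocity=1.0 + b + rng.normal(0, 0.03),
                        )
                    )
        res = sbs.RegimeModel(pd.DataFrame(rows), "velocity", "stiff").fit()
        assert res.dropped_interaction
        assert not any(":" in t for t in res.terms["term"])
        # no true effects: stiffness slope CI covers zero
        name = [n for n in res.params.index if "k_p" in n][0]
        lo, hi = res.conf_int.loc[name]
        assert lo <= 0.0 <= hi

    def test_summary_mentions_terms(self):
        df = _synthetic_regime_data(seed=2, slope=0.23)
        res = sbs.RegimeModel(df, "velocity", "compliant").fit()
        out = res.summary()
        assert "k_p" in out and "compliant" in out

    def test_report_stacks_all_variables(self):
        df = _synthetic_regime_data(seed=3, slope=0.2)
        df["elevation"] = np.random.default_rng(0).normal(0, 2, len(df))
        rep = sbs.regime_model_report(df, variables=["velocity", "elevation"])
        assert set(rep["variable"]) == {"velocity", "elevation"}
        assert {"regime", "term", "estimate", "F", "df_num", "df_den", "p"} <= set(rep.columns)
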