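import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vigilpred import ddm, synthetic_data as sd
from vigilpred.core import default_protocol
from vigilpred.synthetic_data import (
    PopulationConfig, SleepPressureModel, day_drift, sample_first_passage,
    sample_profiles, simulate_session, simulate_study, sleep_pressure,
)


class TestSleepPressure:
    def test_all_nine_hour_protocol_has_zero_pressure(self):
        proto = default_protocol("g5h")
        proto = type(proto)(
            days=[type(d)(d.label, d.index, 9.0, d.phase) for d in proto.days],
            group_label="g5h", sessions_per_day=proto.sessions_per_day)
        assert all(p == 0.0 for p in sleep_pressure(proto).values())

    def test_hand_recursion_g5h(self):
        p = sleep_pressure(default_protocol("g5h"), SleepPressureModel(rho=0.5))
        assert p["M1_1"] == pytest.approx(4.0)
        assert p["M1_2"] == pytest.approx(6.0)

    def test_first_manipulation_night_g6p5h(self):
        p = sleep_pressure(default_protocol("g6p5h"), SleepPressureModel(rho=0.5))
        assert p["M1_1"] == pytest.approx(2.5)

    def test_dose_dependence_every_manipulation_day(self):
        """The 5-h group carries strictly more pressure on every M-day."""
        p5 = sleep_pressure(default_protocol("g5h"))
        p6 = sleep_pressure(default_protocol("g6p5h"))
        m_days = [lab for lab in p5 if lab.startswith("M")]
        assert m_days and all(p5[d] > p6[d] for d in m_days)

    def test_recovery_decays_pressure_geometrically(self):
        """Two 9-h recovery nights shrink pressure by rho^2 (to a quarter of
        its peak at the default carry-over)."""
        p = sleep_pressure(default_protocol("g5h"), SleepPressureModel(rho=0.5))
        assert p["R2_1"] == pytest.approx(0.5 * p["M2_3"])
        assert p["R2_2"] == pytest.approx(0.25 * p["M2_3"])
        assert p["R2_2"] < p["M1_1"]


class TestDayDrift:
    def test_zero_pressure_returns_baseline(self, typical_profile):
        assert day_drift(typical_profile, 0.0, False) == typical_profile.v_base

    def test_zero_kappa_is_pressure_invariant(self, typical_profile):
        prof = sd.SubjectProfile(**{**typical_profile.__dict__, "kappa": 0.0})
        assert day_drift(prof, 7.0, True) == prof.v_base

    def test_week2_multiplier_arithmetic(self):
        prof = sd.SubjectProfile("s", "g5h", v_base=4.0, eta=1.0, a=1.0,
                                 ter_s=0.3, st_s=0.1, kappa=0.2, kappa2=0.5,
                                 p_false_start=0.0)
        # pressure 6 is above the severity gate, so the multiplier engages
        assert day_drift(prof, 6.0, True, floor=0.25) == pytest.approx(2.2)
        assert day_drift(prof, 6.0, False, floor=0.25) == pytest.approx(2.8)

    def test_floor_binds(self):
        prof = sd.SubjectProfile("s", "g5h", v_base=4.0, eta=1.0, a=1.0,
                                 ter_s=0.3, st_s=0.1, kappa=2.0, kappa2=0.5,
                                 p_false_start=0.0)
        assert day_drift(prof, 8.0, True, floor=0.25) == pytest.approx(1.0)


class TestFirstPassageSampler:
    def test_wald_mean(self):
        rng = np.random.default_rng(3)
        t = sample_first_passage(6.0, 1.0, rng, size=20_000)
        se = t.std() / np.sqrt(t.size)
        assert abs(t.mean() - 1 / 6) < 3 * se

    def test_matches_wald_distribution_ks(self):
        """eta=0 sampler matches the closed-form Wald law (KS < 0.01 at 1e5)."""
        u, a = 3.0, 1.0
        rng = np.random.default_rng(11)
        t = sample_first_passage(u, a, rng, size=100_000)
        # IG(mu=a/u, lambda=a^2) in scipy's parameterization
        dist = stats.invgauss(mu=(a / u) / (a * a), scale=a * a)
        d = stats.kstest(t, dist.cdf).statistic
        assert d < 0.01

    def test_negative_drift_absorption_probability(self):
        u, a = -1.5, 1.0
        rng = np.random.default_rng(5)
        t = sample_first_passage(u, a, rng, size=200_000)
        frac = np.isfinite(t).mean()
        expect = np.exp(2 * u * a)
        assert abs(frac - expect) < 3 * np.sqrt(expect * (1 - expect) / t.size)

    def test_matches_marginal_decision_density_chisq(self):
        """With eta > 0 the sampled law matches ddm.decision_density
        (20-bin chi-square, p > 0.01, five seeds)."""
        v, eta, a = 4.0, 1.5, 1.0
        edges = np.linspace(0.01, 1.2, 20)
        cdf = ddm.decision_cdf(edges, v, eta, a)
        probs = np.diff(cdf)
        p_tail = 1.0 - cdf[-1] + cdf[0]
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            u = rng.normal(v, eta, size=100_000)
            t = sample_first_passage(u, a, rng)
            counts, _ = np.histogram(t[np.isfinite(t)], bins=edges)
            n_tail = t.size - counts.sum()
            obs = np.append(counts, n_tail)
            exp = t.size * np.append(probs, p_tail)
            chi2 = np.sum((obs - exp) ** 2 / exp)
            p = stats.chi2.sf(chi2, df=len(obs) - 1)
            assert p > 0.01, f"seed {seed}: chi-square p={p:.4f}"


class TestSimulateSession:
    def test_deterministic_wald_session(self):
        prof = sd.SubjectProfile("s", "g5h", v_base=6.0, eta=0.0, a=1.0,
                                 ter_s=0.25, st_s=0.0, kappa=0.0, kappa2=0.0,
                                 p_false_start=0.0)
        parts = [simulate_session(prof, 6.0, np.random.default_rng(k),
                                  duration_s=600.0) for k in range(20)]
        df = pd.concat(parts)
        assert len(df) >= 1500
        assert (df["rt_ms"] >= 250.0).all()
        dec = df["rt_ms"] / 1000.0 - 0.25
        se = dec.std() / np.sqrt(len(dec))
        assert abs(dec.mean() - 1 / 6) < 3 * se

    def test_trial_count_in_ten_minute_session(self, typical_profile):
        counts = [len(simulate_session(typical_profile, 8.0,
                                       np.random.default_rng(k)))
                  for k in range(10)]
        assert 85 <= np.mean(counts) <= 100

    def test_degraded_drift_increases_lapses(self, typical_profile):
        def lapse_frac(drift, seed):
            df = simulate_session(typical_profile, drift,
                                  np.random.default_rng(seed),
                                  duration_s=3000.0)
            return ((df["rt_ms"] >= 500) | df["timeout"]).mean()
        assert lapse_frac(0.8, 1) > lapse_frac(6.0, 1)

    def test_same_seed_identical_output(self, typical_profile):
        a = simulate_session(typical_profile, 5.0, np.random.default_rng(9))
        b = simulate_session(typical_profile, 5.0, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_isi_range_and_censoring(self, typical_profile):
        df = simulate_session(typical_profile, 1.2, np.random.default_rng(2))
        assert df["isi_ms"].between(2000, 10000).all()
        assert (df.loc[df["timeout"], "rt_ms"] == 10000.0).all()
        assert (df["rt_ms"] <= 10000.0).all()

    def test_nonfinite_parameters_rejected(self, typical_profile):
        with pytest.raises(ValueError):
            simulate_session(typical_profile, np.nan, np.random.default_rng(0))


class TestSimulateStudy:
    def test_structure_matches_protocol(self):
        study = simulate_study(n_per_group=(2, 2), seed=4)
        counts = (study.trials.groupby(["subject_id", "day_label"])
                  ["session_index"].nunique())
        for sid in study.subjects["subject_id"]:
            assert counts[(sid, "B0")] == 2
            assert counts[(sid, "M1_3")] == 3
            assert (sid, "R2_2") not in counts.index

    def test_truth_table_joins_exactly_once(self):
        study = simulate_study(n_per_group=(3, 2), seed=4)
        subjects = set(study.trials["subject_id"])
        assert subjects == set(study.subjects["subject_id"])
        assert study.subjects["subject_id"].is_unique

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        from vigilpred.core import write_trials
        a = simulate_study(n_per_group=(2, 2), seed=7)
        b = simulate_study(n_per_group=(2, 2), seed=7)
        pa = write_trials(a.trials, tmp_path / "a.csv")
        pb = write_trials(b.trials, tmp_path / "b.csv")
        assert pa.read_bytes() == pb.read_bytes()

    def test_planted_correlation_recovered(self):
        cfg = PopulationConfig(corr_v_kappa=-0.6)
        rng = np.random.default_rng(12)
        profs = sample_profiles((28, 29), cfg, rng)
        v = np.array([p.v_base for p in profs])
        k = np.array([p.kappa for p in profs])
        assert abs(np.corrcoef(v, k)[0, 1] - (-0.6)) < 0.15

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(corr_v_kappa=-1.0)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = PopulationConfig(kappa_mean=0.3, corr_v_kappa=-0.4)
        path = cfg.to_yaml(tmp_path / "pop.yaml")
        assert PopulationConfig.from_yaml(path) == cfg
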