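"""Synthetic cohort generator: structure, calibration and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import lipidcascade as lc
from lipidcascade.cohort import (GeneratorConfig, Stage, Subject,
                                 generate_cohort, generate_followup,
                                 generate_proteins, lesion_group,
                                 progression_outcome, read_bundle, write_bundle)
from lipidcascade.io_qc import log_normalize

from conftest import small_config


class TestStructure:
    def test_default_cohort_sizes_match_study_design(self, default_bundle):
        b = default_bundle
        tab = b.subject_table()
        d = tab[tab.cohort == "discovery"]
        v = tab[tab.cohort == "validation"]
        assert len(d) == 200 and len(v) == 200
        # discovery: 169 lesions + 31 in the GC group (22 HGIN + 9 invasive)
        assert (d.severity <= 4).sum() == 169
        assert (d.severity == 5).sum() == 22 and (d.severity == 6).sum() == 9
        # validation: 152 lesions followed prospectively, 76 with >=3 visits
        assert (v.severity <= 4).sum() == 152
        assert len(b.prospective_ids) == 152
        assert len(b.subcohort_ids) == 76
        assert b.lipids.values.shape == (400, 624)
        assert b.proteins.shape == (104, 23)

    def test_visit_structure(self, default_bundle):
        pro = set(default_bundle.prospective_ids)
        sub = set(default_bundle.subcohort_ids)
        for s in default_bundle.subjects["validation"]:
            days = [d for d, _ in s.visits]
            assert days[0] == 0 and days == sorted(days)
            if s.id in sub:
                assert len(s.visits) >= 3
            elif s.id in pro:
                assert len(s.visits) == 2

    def test_fixed_seed_reproduces_bundle_bit_identically(self):
        b1 = generate_cohort(small_config(seed=42))
        b2 = generate_cohort(small_config(seed=42))
        assert b1.lipids.values.equals(b2.lipids.values)
        assert b1.proteins.equals(b2.proteins)
        assert b1.prospective_ids == b2.prospective_ids
        assert [s.visits for s in b1.subjects["validation"]] == \
            [s.visits for s in b2.subjects["validation"]]

    def test_progression_flag_matches_severity_comparison(self, default_bundle):
        for s in default_bundle.subjects["validation"]:
            expected = (int(s.endpoint[1]) > int(s.baseline_stage)) \
                - (int(s.endpoint[1]) < int(s.baseline_stage))
            assert progression_outcome(s) == expected

    @pytest.mark.parametrize("kw", [
        dict(n_prospective=500), dict(n_subcohort=500),
        dict(signal_correlation=1.0), dict(n_lipids=0),
        dict(discovery_stage_counts={Stage.SG: 3}),
    ])
    def test_inconsistent_config_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)

    def test_roundtrip_through_csv_yaml(self, tmp_path, small_bundle):
        write_bundle(small_bundle, tmp_path)
        b2 = read_bundle(tmp_path)
        pd.testing.assert_frame_equal(small_bundle.lipids.values, b2.lipids.values)
        assert b2.truth["signal_ids"] == small_bundle.truth["signal_ids"]
        assert [s.visits for s in b2.subjects["validation"]] == \
            [s.visits for s in small_bundle.subjects["validation"]]


class TestPlantedSignal:
    def test_planted_per_sd_or_recovered_by_adjusted_logistic(self):
        # large n: adjusted logistic of GC-group vs mild on a signal lipid
        # recovers the planted per-SD log-odds within 2 SE
        dc = {k: v * 40 for k, v in GeneratorConfig().discovery_stage_counts.items()}
        cfg = GeneratorConfig(
            n_discovery=8000, n_validation=8000, n_prospective=100, n_subcohort=50,
            n_lipids=12, signal_lipids=4, effect_size=0.8,
            signal_correlation=0.55,
            discovery_stage_counts=dc, validation_stage_counts=dc, seed=21)
        b = generate_cohort(cfg)
        tab = b.subject_table()
        d = tab[tab.cohort == "discovery"]
        ln = log_normalize(b.lipids.subset(subject_ids=d.index))
        grp = d["baseline_stage"].map(lambda s: lesion_group(Stage[s]))
        mask = grp.isin(["gc", "mild"])
        ids = mask.index[mask]
        y = (grp[mask] == "gc").astype(float).to_numpy()
        cov = d.loc[ids, ["age", "sex", "hp"]].to_numpy()
        hits = 0
        for lip in b.truth["signal_ids"]:
            r = lc.adjusted_logistic(ln.values.loc[ids, lip], y, cov)
            if abs(r.beta - (-0.8)) < 2 * r.se:
                hits += 1
        assert hits >= 3  # 2-SE coverage, 4 correlated draws

    def test_zero_effect_size_gives_null_severity_association(self):
        cfg = small_config(seed=9, effect_size=0.0, n_discovery=2000,
                          n_validation=2000, n_prospective=100, n_subcohort=50,
                          discovery_stage_counts={Stage.SG: 300, Stage.CAG: 500,
                                                  Stage.IM: 590, Stage.LGIN: 300,
                                                  Stage.HGIN: 220, Stage.GC: 90},
                          validation_stage_counts={Stage.SG: 300, Stage.CAG: 500,
                                                   Stage.IM: 590, Stage.LGIN: 300,
                                                   Stage.HGIN: 220, Stage.GC: 90})
        b = generate_cohort(cfg)
        tab = b.subject_table()
        d = tab[tab.cohort == "discovery"]
        ln = log_normalize(b.lipids.subset(subject_ids=d.index))
        grp = d["baseline_stage"].map(lambda s: lesion_group(Stage[s]))
        mask = grp.isin(["gc", "mild"])
        y = (grp[mask] == "gc").astype(float).to_numpy()
        ids = mask.index[mask]
        cov = d.loc[ids, ["age", "sex", "hp"]].to_numpy()
        ok = sum(
            abs(lc.adjusted_logistic(ln.values.loc[ids, lip], y, cov).beta)
            < 3 * lc.adjusted_logistic(ln.values.loc[ids, lip], y, cov).se
            for lip in b.truth["signal_ids"])
        assert ok >= len(b.truth["signal_ids"]) - 1

    def test_signal_correlation_matches_target(self):
        # Monte-Carlo check of the exchangeable correlation against the
        # generating covariance (0.5 within +/-0.03 at n=5000)
        cfg = small_config(seed=13, n_discovery=2500, n_validation=2500,
                          n_prospective=100, n_subcohort=50,
                          signal_correlation=0.5, age_effect=0.0,
                          discovery_stage_counts={Stage.SG: 375, Stage.CAG: 625,
                                                  Stage.IM: 740, Stage.LGIN: 375,
                                                  Stage.HGIN: 272, Stage.GC: 113},
                          validation_stage_counts={Stage.SG: 375, Stage.CAG: 625,
                                                   Stage.IM: 740, Stage.LGIN: 375,
                                                   Stage.HGIN: 272, Stage.GC: 113})
        b = generate_cohort(cfg)
        sig = np.log(b.lipids.values[b.truth["signal_ids"]].to_numpy())
        C = np.corrcoef(sig.T)
        off = C[~np.eye(len(C), dtype=bool)]
        assert abs(off.mean() - 0.5) < 0.03


class TestFollowup:
    def _subjects(self, n):
        return [Subject(id=f"S{i}", age=55, sex=0, hp=0,
                        baseline_stage=Stage.IM, cohort="validation")
                for i in range(n)]

    def test_median_followup_calibrated(self):
        subs = self._subjects(10_000)
        generate_followup(subs, GeneratorConfig(), rng=np.random.default_rng(3))
        t = np.array([s.endpoint[0] for s in subs])
        assert abs(np.median(t) - 580) < 30
        q1, q3 = np.percentile(t, [25, 75])
        # IQR width matches the calibration target
        assert abs((q3 - q1) - (806 - 390)) < 60

    def test_zero_base_rate_never_progresses(self):
        subs = self._subjects(500)
        cfg = GeneratorConfig(progression_base_rate=0.0, risk_gamma=0.0)
        generate_followup(subs, cfg, rng=np.random.default_rng(0))
        assert all(int(s.endpoint[1]) <= int(s.baseline_stage) for s in subs)

    def test_latent_risk_effect_recovered(self):
        subs = self._subjects(10_000)
        rng = np.random.default_rng(8)
        u = {s.id: float(x) for s, x in zip(subs, rng.standard_normal(len(subs)))}
        generate_followup(subs, GeneratorConfig(risk_gamma=1.0), latent_risk=u,
                          rng=np.random.default_rng(9))
        prog = np.array([int(progression_outcome(s) > 0) for s in subs])
        uu = np.array([u[s.id] for s in subs])
        r = lc.adjusted_logistic(uu, prog)
        assert abs(r.beta - 1.0) < 2 * r.se


class TestProteins:
    def test_noiseless_coupling_gives_perfect_canonical_correlation(self, rng):
        X = pd.DataFrame(rng.standard_normal((80, 5)),
                         columns=[f"L{i}" for i in range(5)])
        load = rng.standard_normal((5, 5))  # full rank: no ridge needed
        P = generate_proteins(X, load, noise_sd=0.0)
        res = lc.cca_fit(X, P)
        assert res.correlations[0] > 1 - 1e-10

    def test_loading_shape_mismatch_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 5)))
        with pytest.raises(ValueError, match="loadings"):
            generate_proteins(X, rng.standard_normal((4, 7)), 0.1)

    def test_canonical_correlations_decrease_with_orthogonal_loadings(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 6)))
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        P = generate_proteins(X, Q, noise_sd=1.0, rng=rng)
        r = lc.cca_fit(X, P).correlations
        assert np.all(np.diff(r) <= 1e-12)
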