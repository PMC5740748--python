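"""Synthetic-cohort generator: determinism, calibration, end-to-end regime."""

from __future__ import annotations

import math
import statistics

import numpy as np
import pytest

from methpat.panel import call_panel, named_threshold_sets
from methpat.simulate import (
    NACT_TIMEPOINTS,
    SimConfig,
    RegionSpec,
    _rng,
    draw_tumor_fraction,
    estimate_tumor_fraction,
    pattern_rate,
    simulate_ca125,
    simulate_cohort,
    simulate_nact_series,
    simulate_serum_counts,
    simulate_tissue_cohort,
)
from methpat.stats import predict_nact_response, sens_spec


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = simulate_cohort("set3_like", SimConfig(seed=5))
        b = simulate_cohort("set3_like", SimConfig(seed=5))
        assert a == b

    def test_different_seed_different_counts(self):
        _, qa = simulate_cohort("set3_like", SimConfig(seed=5))
        _, qb = simulate_cohort("set3_like", SimConfig(seed=6))
        assert [q.supporting for q in qa] != [q.supporting for q in qb]

    def test_sample_streams_stable_under_reordering(self):
        cfg = SimConfig(seed=9)
        r1 = _rng(cfg.seed, "serum-sample", "x1").random()
        # drawing another sample's stream in between must not disturb x1
        _ = _rng(cfg.seed, "serum-sample", "x2").random()
        assert _rng(cfg.seed, "serum-sample", "x1").random() == r1

    def test_ca125_reproducible(self):
        cfg = SimConfig(seed=4)
        v1 = simulate_ca125("oc_hgs", cfg, rng=_rng(4, "ca", "s"))
        v2 = simulate_ca125("oc_hgs", cfg, rng=_rng(4, "ca", "s"))
        assert v1 == v2 and v1 >= 0


class TestTissueGenerator:
    def test_noise_free_background_is_all_unmethylated(self):
        cfg = SimConfig(seed=1, background_noise=0.0, n_null_regions=2,
                        n_tumor_samples=1, n_wbc_samples=1,
                        fragments_per_region=50.0)
        _, _, frags, groups = simulate_tissue_cohort(cfg)
        wbc = [s for s, g in groups.items() if g == "control"][0]
        for frag in frags[wbc]:
            assert all(state.value == "U" for state in frag.calls.values())

    def test_pure_tumor_pattern_at_m_one(self):
        cfg = SimConfig(seed=1, methylated_tumor_fraction=1.0,
                        n_null_regions=0, n_tumor_samples=1, n_wbc_samples=0,
                        partial_coverage_rate=0.0, fragments_per_region=50.0)
        regions, targets, frags, groups = simulate_tissue_cohort(cfg)
        tumor = list(frags.values())[0]
        planted = {r.region_id: set(r.cpg_positions) for r in regions}
        for frag in tumor:
            assert all(state.value == "M" for state in frag.calls.values())

    def test_planted_frequency_near_m(self):
        cfg = SimConfig(seed=2, regions=(RegionSpec("#141", 7, 136),),
                        n_null_regions=0, n_tumor_samples=1, n_wbc_samples=0,
                        partial_coverage_rate=0.0,
                        fragments_per_region=2000.0)
        regions, targets, frags, _ = simulate_tissue_cohort(cfg)
        tumor = list(frags.values())[0]
        n_full = sum(
            all(s.value == "M" for s in f.calls.values()) for f in tumor
        )
        phat = n_full / len(tumor)
        m = cfg.methylated_tumor_fraction
        # 99% binomial interval at ~2000 fragments
        se = math.sqrt(m * (1 - m) / len(tumor))
        assert abs(phat - m) < 2.58 * se + 1e-9


class TestSerumGenerator:
    def test_zero_phi_zero_noise_never_supports(self):
        cfg = SimConfig(seed=3, background_noise=0.0, invalid_rate=0.0)
        for i in range(20):
            _, counts = simulate_serum_counts(
                "healthy", cfg, rng=_rng(3, "t", i))
            assert all(s == 0 for s, _ in counts.values())

    def test_mean_frequency_matches_closed_form(self):
        cfg = SimConfig(seed=7, invalid_rate=0.0, coverage_mean=20_000.0)
        phi = 1e-3
        q = pattern_rate(phi, cfg, 7)
        freqs = []
        for i in range(500):
            _, counts = simulate_serum_counts(
                "oc_hgs", cfg, rng=_rng(7, "mc", i), phi=phi)
            s, c = counts["#141"]
            freqs.append(s / c)
        mean = statistics.fmean(freqs)
        se = statistics.stdev(freqs) / math.sqrt(len(freqs))
        assert abs(mean - q) < 3 * se

    def test_doubling_leakage_halves_frequency(self):
        phi = 1e-3
        base = SimConfig(seed=8, invalid_rate=0.0, coverage_mean=100_000.0)
        diluted = SimConfig(seed=8, invalid_rate=0.0, coverage_mean=100_000.0,
                            leakage=2.0)
        means = []
        for cfg in (base, diluted):
            fs = []
            for i in range(300):
                _, counts = simulate_serum_counts(
                    "oc_hgs", cfg, rng=_rng(8, "lk", cfg.leakage, i), phi=phi)
                s, c = counts["#141"]
                fs.append(s / c)
            means.append(statistics.fmean(fs))
        assert means[1] / means[0] == pytest.approx(0.5, abs=0.08)

    def test_tumor_fraction_recovery(self):
        # phi-hat = (freq - eps^K)/(m - eps^K) recovers phi/lambda
        cfg = SimConfig(seed=13, invalid_rate=0.0, coverage_mean=100_000.0)
        phi = 1e-3 / cfg.methylated_tumor_fraction  # phi*m = 1e-3
        errors = []
        for i in range(200):
            _, counts = simulate_serum_counts(
                "oc_hgs", cfg, rng=_rng(13, "rec", i), phi=phi)
            s, c = counts["#141"]
            est = estimate_tumor_fraction(
                s / c, cfg.methylated_tumor_fraction, cfg.background_noise, 7)
            errors.append(abs(est - phi) / phi)
        assert statistics.fmean(errors) <= 0.15


class TestCa125Calibration:
    def test_case_sensitivity_near_083(self):
        cfg = SimConfig(seed=21)
        rng = _rng(21, "ca125-cal", "oc_hgs")
        draws = [simulate_ca125("oc_hgs", cfg, rng=rng) for _ in range(2000)]
        assert statistics.fmean(d > 35 for d in draws) == pytest.approx(
            0.83, abs=0.03)
        assert min(draws) >= 0

    def test_control_false_positive_near_013(self):
        cfg = SimConfig(seed=22)
        rng = _rng(22, "ca125-cal", "healthy")
        draws = [simulate_ca125("healthy", cfg, rng=rng) for _ in range(2000)]
        assert statistics.fmean(d > 35 for d in draws) == pytest.approx(
            0.13, abs=0.03)


def _panel_calls(records, quants, threshold_set):
    by_sample = {}
    for q in quants:
        by_sample.setdefault(q.sample_id, []).append(q)
    return {sid: call_panel(qs, threshold_set).overall
            for sid, qs in by_sample.items()}


class TestNactSeries:
    def test_responders_decay_below_pre(self):
        hits = total = 0
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_nact_patients=2)
            for p in simulate_nact_series(cfg):
                if p.clinical_response != "responder":
                    continue
                pre = p.timepoints["pre"][1]["#141"]
                post = p.timepoints["post_cycle2"][1]["#141"]
                if pre[1] == 0 or post[1] == 0:
                    continue
                total += 1
                hits += post[0] / post[1] < pre[0] / pre[1]
        assert total > 50 and hits / total > 0.9

    def test_decay_one_keeps_distribution(self):
        cfg = SimConfig(seed=30, nact_decay=1.0, responder_prob=1.0,
                        n_nact_patients=30)
        pre_f, post_f = [], []
        for p in simulate_nact_series(cfg):
            s0, c0 = p.timepoints["pre"][1]["#141"]
            s2, c2 = p.timepoints["post_cycle2"][1]["#141"]
            if c0 and c2:
                pre_f.append(s0 / c0)
                post_f.append(s2 / c2)
        # same generative law: means agree within Monte-Carlo error
        assert statistics.fmean(post_f) == pytest.approx(
            statistics.fmean(pre_f), rel=0.5)

    def test_prediction_recovers_responders(self):
        cfg = SimConfig(seed=31)
        ts = named_threshold_sets()["refined"]
        correct = total = 0
        for p in simulate_nact_series(cfg):
            calls = {}
            for tp in ("pre", "post_cycle2"):
                _, counts = p.timepoints[tp]
                quants = _quants_from_counts(p.patient_id, counts)
                calls[tp] = call_panel(quants, ts).overall
            pred = predict_nact_response(calls["pre"], calls["post_cycle2"])
            if p.clinical_response == "responder" and pred != "not_evaluable":
                total += 1
                correct += pred == "responder"
        assert total >= 5
        assert correct / total >= 0.8


def _quants_from_counts(sid, counts):
    from methpat.panel import MarkerQuantification

    return [MarkerQuantification(sample_id=sid, region_id=r, supporting=s,
                                 covering=c)
            for r, (s, c) in counts.items()]


class TestCohortPresets:
    def test_group_sizes_match_preset(self):
        records, quants = simulate_cohort("set3_like", SimConfig(seed=2))
        by_group = {}
        for r in records:
            by_group[r.group] = by_group.get(r.group, 0) + 1
        assert by_group == {"healthy": 20, "benign_mass": 20, "oc_hgs": 20}
        assert len(quants) == 60 * 3

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            simulate_cohort("bogus", SimConfig())

    def test_delayed_separation_raises_dna_conc(self):
        diffs = []
        for seed in range(50):
            r3, _ = simulate_cohort("set3_like", SimConfig(seed=seed))
            ru, _ = simulate_cohort("ukctocs_like", SimConfig(seed=seed))
            diffs.append(
                statistics.fmean(r.dna_conc for r in ru)
                - statistics.fmean(r.dna_conc for r in r3)
            )
        assert statistics.fmean(diffs) > 0
        ru, _ = simulate_cohort("ukctocs_like", SimConfig(seed=0))
        assert statistics.fmean(r.small_frag_fraction for r in ru) < 0.3

    def test_set3_like_operating_regime(self):
        records, quants = simulate_cohort("set3_like", SimConfig(seed=42))
        calls = _panel_calls(records, quants, named_threshold_sets()["refined"])
        truth = {r.sample_id: ("case" if r.group == "oc_hgs" else "control")
                 for r in records}
        usable = {s: c for s, c in calls.items()
                  if c in ("positive", "negative")}
        sens, spec = sens_spec(usable, truth)
        assert spec.estimate >= 0.85
        assert sens.estimate >= 0.5


class TestMonotonicity:
    def test_sensitivity_nondecreasing_in_phi_and_coverage(self):
        ts = named_threshold_sets()["refined"]

        def detection_rate(phi, coverage, n=150):
            cfg = SimConfig(seed=50, invalid_rate=0.0, coverage_mean=coverage)
            pos = 0
            for i in range(n):
                _, counts = simulate_serum_counts(
                    "oc_hgs", cfg, rng=_rng(50, "mono", phi, coverage, i),
                    phi=phi)
                quants = _quants_from_counts("s", counts)
                pos += call_panel(quants, ts).overall == "positive"
            return pos / n

        rates_phi = [detection_rate(p, 100_000)
                     for p in (1e-5, 1e-4, 1e-3)]
        assert rates_phi == sorted(rates_phi)
        rates_cov = [detection_rate(3e-5, c) for c in (20_000, 100_000, 500_000)]
        assert rates_cov == sorted(rates_cov)

    def test_specificity_nonincreasing_in_noise(self):
        ts = named_threshold_sets()["refined"]

        def fp_rate(eps, n=200):
            cfg = SimConfig(seed=51, invalid_rate=0.0, background_noise=eps,
                            regions=(RegionSpec("#141", 7, 136),
                                     RegionSpec("#204", 5, 118),
                                     RegionSpec("#228", 6, 131)))
            pos = 0
            for i in range(n):
                _, counts = simulate_serum_counts(
                    "healthy", cfg, rng=_rng(51, "eps", eps, i))
                quants = _quants_from_counts("s", counts)
                pos += call_panel(quants, ts).overall == "positive"
            return pos / n

        rates = [fp_rate(e) for e in (0.0, 0.01, 0.05)]
        assert rates[0] <= rates[1] <= rates[2]

    def test_background_full_pattern_rate_below_thresholds(self):
        cfg = SimConfig()
        eps_k = cfg.background_noise**7
        thresholds = named_threshold_sets()["ukctocs"].thresholds.values()
        assert eps_k < min(thresholds)
        assert eps_k == pytest.approx(2.187e-18, rel=1e-6)
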