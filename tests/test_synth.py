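"""Seeded generators: banks, PCM responses, six-arm acceptability surveys."""

import numpy as np
import pytest

from catqol.irt import pcm_category_probs
from catqol.psych import cliffs_delta
from catqol.synth import (
    BankSpec,
    CalibrationError,
    SynthConfig,
    calibrate_shift,
    condition_shifts,
    frame_to_records,
    generate_acceptability,
    generate_bank,
    generate_respondents,
    population_cliffs_delta,
    population_total_pmf,
    records_to_frame,
)


class TestBankGeneration:
    def test_deterministic_per_seed(self):
        a = generate_bank(BankSpec(), 42)
        b = generate_bank(BankSpec(), 42)
        assert [it.thresholds for it in a] == [it.thresholds for it in b]
        c = generate_bank(BankSpec(), 43)
        assert [it.thresholds for it in a] != [it.thresholds for it in c]

    def test_requested_counts_emitted(self):
        bank = generate_bank(BankSpec(n_items_per_domain=25), 1)
        for dom in BankSpec().domains:
            assert len(bank.for_domain(dom)) == 25

    def test_zero_dispersion_gives_identical_items(self):
        bank = generate_bank(BankSpec(dispersion=0.0), 1)
        thresholds = {it.thresholds for it in bank}
        assert len(thresholds) == 1


class TestRespondentGeneration:
    def test_empty_matrix_for_zero_respondents(self):
        bank = generate_bank(BankSpec(n_items_per_domain=3), 1)
        responses, thetas = generate_respondents(bank, 0, 2)
        assert responses.empty and thetas.empty

    def test_responses_within_category_range(self):
        bank = generate_bank(BankSpec(n_items_per_domain=5), 1)
        responses, _ = generate_respondents(bank, 200, 2)
        for item in bank:
            col = responses[item.item_id]
            assert col.min() >= 0 and col.max() <= item.max_category

    def test_sampler_frequencies_match_pmf(self):
        # marginal category frequencies over theta ~ N(0,1) must match the
        # quadrature-integrated PCM pmf within 3 binomial SE
        bank = generate_bank(
            BankSpec(n_items_per_domain=1, domains=("physical",), dispersion=0.0), 3
        )
        item = bank.items[0]
        n = 100_000
        responses, _ = generate_respondents(bank, n, 12)
        freq = np.bincount(responses[item.item_id], minlength=item.n_categories) / n
        nodes, weights = np.polynomial.hermite_e.hermegauss(61)
        weights = weights / weights.sum()
        expected = sum(
            w * pcm_category_probs(item, t) for w, t in zip(weights, nodes)
        )
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freq - expected) <= 3 * se + 1e-12)

    def test_truth_table_aligned(self):
        bank = generate_bank(BankSpec(n_items_per_domain=3), 1)
        responses, thetas = generate_respondents(bank, 50, 2)
        assert list(responses.index) == list(thetas.index)
        assert set(thetas.columns) == set(bank.domains)


class TestDeltaCalibration:
    def test_population_delta_hits_target_exactly(self):
        ref = population_total_pmf(0.0)
        for target in (-0.2, 0.0, 0.1, 0.22):
            mu = calibrate_shift(target, ref)
            realized = population_cliffs_delta(population_total_pmf(mu), ref)
            assert realized == pytest.approx(target, abs=1e-8)

    def test_brute_force_population_delta(self):
        # independent double loop over the finite 0-16 support
        p = population_total_pmf(0.4)
        q = population_total_pmf(0.0)
        acc = 0.0
        for s in range(17):
            for t in range(17):
                acc += p[s] * q[t] * np.sign(s - t)
        assert population_cliffs_delta(p, q) == pytest.approx(acc)

    def test_unattainable_target_raises_with_range(self):
        ref = population_total_pmf(0.0)
        with pytest.raises(CalibrationError, match="achievable range"):
            calibrate_shift(0.9999, ref, bounds=(-1.0, 1.0))

    def test_default_shifts_reproduce_table_targets(self):
        cfg = SynthConfig()
        shifts = condition_shifts(cfg)
        ref = population_total_pmf(0.0)
        for cond, target in cfg.target_deltas.items():
            realized = population_cliffs_delta(population_total_pmf(shifts[cond]), ref)
            assert realized == pytest.approx(target, abs=0.01)
        # pooled graphical+text arms share one shift calibrated to 0.22
        sizes = dict(cfg.condition_sizes)
        mix = (
            sizes["fixed_none"] * ref
            + sizes["cat_none"] * population_total_pmf(shifts["cat_none"])
        ) / (sizes["fixed_none"] + sizes["cat_none"])
        pooled = population_cliffs_delta(
            population_total_pmf(shifts["fixed_graphical_text"]), mix
        )
        assert pooled == pytest.approx(0.22, abs=0.01)


class TestAcceptabilityGeneration:
    def test_pure_function_of_config_and_seed(self):
        cfg = SynthConfig()
        a = generate_acceptability(cfg, 5)
        b = generate_acceptability(cfg, 5)
        assert records_to_frame(a).equals(records_to_frame(b))

    def test_null_target_recovers_zero_delta(self):
        cfg = SynthConfig(
            target_deltas={"cat_none": 0.0},
            pooled_graphical_text_delta=None,
        )
        recs = [r for r in generate_acceptability(cfg, 6) if not r.attention_failed]
        x = [r.total for r in recs if r.condition == "cat_none"]
        y = [r.total for r in recs if r.condition == "fixed_none"]
        res = cliffs_delta(x, y)
        assert abs(res.delta) <= 3 * res.se

    def test_zero_attention_rate_flags_nobody(self):
        cfg = SynthConfig(attention_fail_rate=0.0)
        recs = generate_acceptability(cfg, 7)
        assert not any(r.attention_failed for r in recs)
        assert len(recs) == sum(dict(cfg.condition_sizes).values())

    def test_feedback_seconds_only_in_feedback_arms(self):
        recs = generate_acceptability(SynthConfig(), 8)
        for r in recs:
            assert (r.feedback_seconds is None) == r.condition.endswith("_none")

    def test_viewing_time_medians_near_config(self):
        cfg = SynthConfig()
        recs = generate_acceptability(cfg, 9)
        for cond, target in dict(cfg.time_medians).items():
            secs = [r.feedback_seconds for r in recs if r.condition == cond]
            # log-normal median ratio: 3 SE of the log-median at n~230
            assert np.median(secs) == pytest.approx(target, rel=0.15)

    def test_roundtrip_through_frame(self):
        recs = generate_acceptability(SynthConfig(), 10)[:50]
        back = frame_to_records(records_to_frame(recs))
        assert [r.items for r in back] == [r.items for r in recs]
        assert [r.condition for r in back] == [r.condition for r in recs]
        assert [r.appraisal for r in back] == [r.appraisal for r in recs]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(condition_sizes={"fixed_none": 2000})
        with pytest.raises(ValueError):
            SynthConfig(target_deltas={"cat_none": 1.5})
        with pytest.raises(ValueError):
            SynthConfig(attention_fail_rate=1.0)
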