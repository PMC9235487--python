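"""Anchor search: rule semantics, perturbation sampler, bandit recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anchorseq import (BINDING, NON_BINDING, AnchorParams, AnchorRule,
                       ConstantModel, ContractViolation, Predicate,
                       SequenceSample, estimate_precision, find_anchor,
                       rule_applies, rule_coverage, sample_perturbations)
from anchorseq.anchors import kl_lower_bound, kl_upper_bound, read_rules, \
    write_rules
from anchorseq.synthetic import PlantedRuleModel


def _sample(frame, sid="x"):
    return SequenceSample(id=sid, frame=frame)


def _pool(frames):
    return [_sample(f, f"p{i}") for i, f in enumerate(frames)]


class TestRuleApplication:
    def test_empty_rule_applies_everywhere(self):
        assert rule_applies((), _sample("CASS--"))

    def test_matching_predicates(self):
        assert rule_applies((Predicate(0, "C"), Predicate(3, "S")), _sample("CASS--"))
        assert not rule_applies((Predicate(0, "K"),), _sample("CASS--"))

    def test_padding_position_is_a_real_symbol(self):
        # position 5 holds PAD, so requiring 'A' there fails but requiring
        # PAD succeeds (a rule can encode length information)
        s = _sample("CASS--")
        assert not rule_applies((Predicate(5, "A"),), s)
        assert rule_applies((Predicate(5, "-"),), s)

    def test_coverage_enumeration(self):
        samples = _pool(["CASS", "CAST", "KAST", "KASS", "CWSS"])
        rule = (Predicate(0, "C"), Predicate(3, "S"))
        assert rule_coverage(rule, samples) == pytest.approx(0.4)
        assert rule_coverage((), samples) == 1.0
        assert rule_coverage((Predicate(0, "W"),), samples) == 0.0
        with pytest.raises(ContractViolation):
            rule_coverage(rule, [])

    @given(st.data())
    def test_adding_predicate_never_increases_coverage(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        samples = _pool(["".join(rng.choice(list("ABCD"), 6)) for _ in range(20)])
        positions = rng.choice(6, size=3, replace=False)
        rule = [Predicate(int(p), str(rng.choice(list("ABCD")))) for p in positions]
        for cut in range(len(rule)):
            assert rule_coverage(rule[:cut + 1], samples) <= \
                rule_coverage(rule[:cut], samples)

    def test_two_predicates_one_position_rejected(self):
        with pytest.raises(ContractViolation):
            AnchorRule(predicates=(Predicate(0, "A"), Predicate(0, "C")),
                       prediction=BINDING, precision_estimate=1.0,
                       precision_lower_bound=0.5, coverage=0.0)


class TestPerturbationSampler:
    def test_all_positions_fixed_copies_instance(self):
        pool = _pool(["AAAA", "GGGG"])
        perturbed = sample_perturbations(_sample("AGAG"), range(4), pool, 5, seed=0)
        assert all(p.frame == "AGAG" for p in perturbed)

    def test_degenerate_pool_copies_instance(self):
        pool = _pool(["AGAG"] * 4)
        perturbed = sample_perturbations(_sample("AGAG"), (), pool, 5, seed=0)
        assert all(p.frame == "AGAG" for p in perturbed)

    def test_keep_resample_mixture_frequency(self):
        # one free position, pool 0.8 A / 0.2 G, instance A:
        # P(A) = 0.5*1 + 0.5*0.8 = 0.9
        pool = _pool(["A"] * 8 + ["G"] * 2)
        perturbed = sample_perturbations(_sample("A"), (), pool, 10_000, seed=1)
        freq_a = sum(p.frame == "A" for p in perturbed) / 10_000
        se = np.sqrt(0.9 * 0.1 / 10_000)
        assert abs(freq_a - 0.9) <= 3 * se

    def test_marginals_match_mixture_at_every_position(self):
        rng = np.random.default_rng(5)
        pool = _pool(["".join(rng.choice(list("ACGT"), 4)) for _ in range(30)])
        instance = pool[0]
        perturbed = sample_perturbations(instance, (2,), pool, 10_000, seed=2)
        frames = np.array([list(p.frame) for p in perturbed])
        pool_frames = np.array([list(p.frame) for p in pool])
        for pos in range(4):
            for symbol in "ACGT":
                pool_freq = np.mean(pool_frames[:, pos] == symbol)
                if pos == 2:
                    expected = 1.0 if instance.frame[pos] == symbol else 0.0
                else:
                    expected = 0.5 * (instance.frame[pos] == symbol) + 0.5 * pool_freq
                got = np.mean(frames[:, pos] == symbol)
                se = np.sqrt(max(expected * (1 - expected), 1e-9) / 10_000)
                assert abs(got - expected) <= max(3 * se, 1e-9)

    def test_invalid_requests(self):
        pool = _pool(["AAAA"])
        with pytest.raises(ContractViolation):
            sample_perturbations(_sample("AAAA"), (), pool, 0)
        with pytest.raises(ContractViolation):
            sample_perturbations(_sample("AAAA"), (), [], 5)


class TestKLBounds:
    def test_bounds_bracket_the_estimate(self):
        for p_hat in (0.0, 0.3, 0.9, 1.0):
            lb = kl_lower_bound(p_hat, 100, 1.9)
            ub = kl_upper_bound(p_hat, 100, 1.9)
            assert 0.0 <= lb <= p_hat <= ub <= 1.0

    def test_bounds_tighten_with_n(self):
        widths = [kl_upper_bound(0.8, n, 1.9) - kl_lower_bound(0.8, n, 1.9)
                  for n in (50, 200, 1000)]
        assert widths[0] > widths[1] > widths[2]


class TestPrecisionEstimation:
    def test_constant_model_estimate_one(self):
        pool = _pool(["AAAA", "GGGG"])
        est, lb, ub = estimate_precision((), BINDING, ConstantModel(),
                                         _sample("AAAA"), pool, 200, seed=0)
        assert est == 1.0
        assert lb < 1.0 <= ub

    def test_exact_planted_rule_has_precision_one(self):
        model = PlantedRuleModel(planted_rules=((Predicate(0, "C"), Predicate(2, "F")),))
        pool = _pool(["CAFA", "KGFA", "CGCA", "KAAA"])
        est, lb, ub = estimate_precision(
            (Predicate(0, "C"), Predicate(2, "F")), BINDING, model,
            _sample("CAFA"), pool, 500, seed=0)
        assert est == 1.0
        assert lb <= est <= ub

    def test_base_rate_matches_closed_form(self):
        # single planted predicate (0, C); pool frequency of C at 0 is 0.6;
        # empty rule precision = 0.5*1 + 0.5*0.6 = 0.8
        pool = _pool(["CA"] * 6 + ["KA"] * 4)
        model = PlantedRuleModel(planted_rules=((Predicate(0, "C"),),))
        est, _, _ = estimate_precision((), BINDING, model, _sample("CA"),
                                       pool, 10_000, seed=3)
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(est - 0.8) <= 3 * se


class TestFindAnchor:
    def test_constant_model_returns_empty_rule(self):
        pool = _pool(["AAAA", "GGGG", "CCCC"])
        rule = find_anchor(_sample("AAAA"), ConstantModel(), pool,
                           AnchorParams(seed=0))
        assert rule.predicates == ()
        assert rule.precision_estimate == 1.0
        assert not rule.below_threshold

    def test_single_predicate_rule_recovered(self):
        """Planted rule {(0, C)}: the unique arm reaching precision 1."""
        rng = np.random.default_rng(7)
        frames = ["C" + "".join(rng.choice(list("ADEF"), 5)) for _ in range(20)]
        frames += ["K" + "".join(rng.choice(list("ADEF"), 5)) for _ in range(20)]
        pool = _pool(frames)
        model = PlantedRuleModel(planted_rules=((Predicate(0, "C"),),))
        medoid = pool[0]
        hits = sum(
            find_anchor(medoid, model, pool, AnchorParams(seed=s)).predicates
            == (Predicate(0, "C"),)
            for s in range(20)
        )
        assert hits >= 19

    def test_planted_conjunction_recovered(self):
        """Planted {(0, C), (4, F)}: strict subsets stay below precision 1,
        only the full conjunction attains it."""
        rng = np.random.default_rng(11)
        frames = []
        for _ in range(40):
            f = list("".join(rng.choice(list("ADEHKL"), 6)))
            if rng.random() < 0.5:
                f[0] = "C"
            if rng.random() < 0.5:
                f[4] = "F"
            frames.append("".join(f))
        pool = _pool(frames)
        planted = (Predicate(0, "C"), Predicate(4, "F"))
        model = PlantedRuleModel(planted_rules=(planted,))
        medoid = _sample("C" + frames[0][1:4] + "F" + frames[0][5], "medoid")
        assert rule_applies(planted, medoid)
        good = sum(
            set(find_anchor(medoid, model, pool, AnchorParams(seed=s)).predicates)
            == set(planted)
            for s in range(20)
        )
        assert good >= 18

    def test_anchor_applies_to_its_own_medoid(self):
        rng = np.random.default_rng(3)
        pool = _pool(["".join(rng.choice(list("ACDG"), 5)) for _ in range(25)])
        model = PlantedRuleModel(planted_rules=((Predicate(1, pool[4].frame[1]),),))
        rule = find_anchor(pool[4], model, pool, AnchorParams(seed=0))
        assert rule_applies(rule, pool[4])
        assert all(p.symbol == pool[4].frame[p.position] for p in rule.predicates)

    def test_budget_exhaustion_flags_below_threshold(self):
        rng = np.random.default_rng(9)
        pool = _pool(["".join(rng.choice(list("ACDG"), 5)) for _ in range(25)])

        import hashlib

        class CoinFlipOnContent:
            """Deterministic but patternless labels: no rule can get precise."""
            def predict(self, samples):
                return [
                    BINDING if hashlib.blake2b(s.frame.encode(),
                                               digest_size=1).digest()[0] & 1
                    else NON_BINDING
                    for s in samples]

        rule = find_anchor(pool[0], CoinFlipOnContent(), pool,
                           AnchorParams(seed=0, max_pulls=30, max_predicates=2))
        assert rule.below_threshold
        assert rule.precision_lower_bound < 0.9

    def test_medoid_frame_mismatch_rejected(self):
        pool = _pool(["AAAA"])
        with pytest.raises(ContractViolation):
            find_anchor(_sample("AAAAAA"), ConstantModel(), pool, AnchorParams())


def test_rule_json_roundtrip(tmp_path):
    rule = AnchorRule(
        predicates=(Predicate(3, "S"), Predicate(0, "C")),
        prediction=BINDING, precision_estimate=0.97, precision_lower_bound=0.91,
        coverage=0.25, source=(BINDING, 2, "s0042"), n_samples_used=1200)
    write_rules([rule], tmp_path / "rules.jsonl")
    back = read_rules(tmp_path / "rules.jsonl")
    assert len(back) == 1
    assert set(back[0].predicates) == set(rule.predicates)
    assert back[0].source == rule.source


def test_rule_text_rendering():
    rule = AnchorRule(
        predicates=(Predicate(0, "C"), Predicate(3, "S")),
        prediction=BINDING, precision_estimate=1.0, precision_lower_bound=0.9,
        coverage=0.5)
    text = rule.to_text()
    assert "IF (amino acid C is in position 0)" in text
    assert "AND (amino acid S is in position 3)" in text
    assert "THEN the sample is BINDING" in text


def test_anchor_params_validation():
    with pytest.raises(ContractViolation):
        AnchorParams(delta=1.5)
    with pytest.raises(ContractViolation):
        AnchorParams(precision_threshold=0.0)
    with pytest.raises(ContractViolation):
        AnchorParams(tau=1.0)
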