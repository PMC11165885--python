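"""Composite risk-impact / disease-burden scores and score validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epiprior as ep
from epiprior.ahp import WeightVector


def wv(criteria, weights):
    return WeightVector(list(criteria), np.asarray(weights, dtype=float),
                        len(criteria), 0.0, 0.0, False, "eigenvector")


RISK3 = ("scope", "freq", "mitig")
DZ4 = ("severity", "prevalence", "transmissibility", "strategy")


class TestRiskImpactScore:
    def test_all_max_scores_reach_nine(self):
        c = ep.risk_impact_score(dict(zip(RISK3, (3, 3, 3))),
                                 wv(RISK3, [1 / 3] * 3), 3)
        assert c.value == pytest.approx(9)

    def test_worked_example(self):
        c = ep.risk_impact_score(dict(zip(RISK3, (2, 3, 1))),
                                 wv(RISK3, (0.5, 0.3, 0.2)), 2)
        assert c.weighted_sum == pytest.approx(2.1)
        assert c.value == pytest.approx(4.2)

    def test_all_min_scores_reach_one(self):
        c = ep.risk_impact_score(dict(zip(RISK3, (1, 1, 1))),
                                 wv(RISK3, (0.7, 0.2, 0.1)), 1)
        assert c.value == pytest.approx(1)

    def test_criterion_mismatch_rejected(self):
        with pytest.raises(ValueError, match="do not match"):
            ep.risk_impact_score({"scope": 2, "freq": 2, "other": 2},
                                 wv(RISK3, [1 / 3] * 3), 2)

    @pytest.mark.parametrize("bad", [0, 4])
    def test_out_of_range_scores_rejected(self, bad):
        with pytest.raises(ValueError):
            ep.risk_impact_score(dict(zip(RISK3, (bad, 2, 2))),
                                 wv(RISK3, [1 / 3] * 3), 2)
        with pytest.raises(ValueError):
            ep.risk_impact_score(dict(zip(RISK3, (2, 2, 2))),
                                 wv(RISK3, [1 / 3] * 3), bad)


class TestDiseaseBurdenScore:
    def test_equal_weights_mid_scores(self):
        c = ep.disease_burden_score(dict(zip(DZ4, (2, 2, 2, 2))),
                                    wv(DZ4, [0.25] * 4), 3)
        assert c.value == pytest.approx(6)

    def test_worked_example(self):
        c = ep.disease_burden_score(dict(zip(DZ4, (3, 1, 2, 2))),
                                    wv(DZ4, (0.4, 0.3, 0.2, 0.1)), 2)
        assert c.value == pytest.approx(4.2)

    def test_all_min_is_one(self):
        c = ep.disease_burden_score(dict(zip(DZ4, (1, 1, 1, 1))),
                                    wv(DZ4, (0.4, 0.3, 0.2, 0.1)), 1)
        assert c.value == pytest.approx(1)


def random_weights(rng, n):
    w = rng.dirichlet(np.ones(n))
    return np.clip(w, 1e-6, None) / np.clip(w, 1e-6, None).sum()


@pytest.mark.parametrize("crit", [RISK3, DZ4])
def test_composite_bounds_monotonicity_and_oracle(crit):
    """Random draws: value in [1,9], term-by-term oracle match, strict
    monotonicity in every criterion score."""
    rng = np.random.default_rng(7)
    n = len(crit)
    for _ in range(500):
        weights = random_weights(rng, n)
        scores = dict(zip(crit, rng.integers(1, 4, n).tolist()))
        mult = int(rng.integers(1, 4))
        c = ep.composite_score(scores, wv(crit, weights), mult, "I", "G",
                               "risk")
        oracle = sum(scores[k] * w for k, w in zip(crit, weights)) * mult
        assert abs(c.value - oracle) < 1e-12
        assert 1 - 1e-12 <= c.value <= 9 + 1e-12
        for k in crit:
            if scores[k] < 3:
                up = dict(scores, **{k: scores[k] + 1})
                c2 = ep.composite_score(up, wv(crit, weights), mult, "I",
                                        "G", "risk")
                assert c2.value > c.value


@settings(derandomize=True, max_examples=80)
@given(data=st.data())
def test_weight_shift_toward_higher_score_never_decreases_sum(data):
    scores = [data.draw(st.integers(1, 3)) for _ in range(3)]
    w = [data.draw(st.floats(0.05, 1.0)) for _ in range(3)]
    w = np.asarray(w) / sum(w)
    i, j = data.draw(st.sampled_from([(a, b) for a in range(3)
                                      for b in range(3) if a != b]))
    if scores[i] < scores[j]:
        i, j = j, i  # shift mass toward the better-scored criterion i
    delta = data.draw(st.floats(0, float(w[j]) * 0.9))
    shifted = w.copy()
    shifted[i] += delta
    shifted[j] -= delta
    before = ep.composite_score(dict(zip(RISK3, scores)), wv(RISK3, w), 1,
                                "I", "G", "risk").weighted_sum
    after = ep.composite_score(dict(zip(RISK3, scores)), wv(RISK3, shifted),
                               1, "I", "G", "risk").weighted_sum
    assert after >= before - 1e-12


class TestValidateScores:
    @pytest.fixture
    def shortlist(self):
        return ep.Shortlist("risk", [("A", 5), ("B", 3)], 2)

    def sheet(self, criteria, items, groups, value=2):
        crit = [c.id for c in criteria if c.stream == "risk"]
        return [ep.OrdinalScore(i, c, g, value)
                for i in items for c in crit for g in groups]

    def test_complete_sheet_passes(self, criteria, shortlist):
        rep = ep.validate_scores(self.sheet(criteria, ["A", "B"], ["G1"]),
                                 shortlist, criteria, ["G1"], "risk")
        assert rep.errors == []

    def test_out_of_range_value_named(self, criteria, shortlist):
        sheet = self.sheet(criteria, ["A", "B"], ["G1"])
        sheet[0] = ep.OrdinalScore("A", "scope", "G1", 4)
        rep = ep.validate_scores(sheet, shortlist, criteria, ["G1"], "risk")
        assert len(rep.errors) == 1
        err = rep.errors[0]
        assert "'A'" in err and "'scope'" in err and "'G1'" in err

    def test_non_shortlisted_item_is_error(self, criteria, shortlist):
        sheet = self.sheet(criteria, ["A", "B"], ["G1"])
        sheet.append(ep.OrdinalScore("Z", "scope", "G1", 2))
        rep = ep.validate_scores(sheet, shortlist, criteria, ["G1"], "risk")
        assert any("'Z'" in e and "shortlist" in e for e in rep.errors)

    def test_missing_cell_reported(self, criteria, shortlist):
        sheet = self.sheet(criteria, ["A", "B"], ["G1"])[:-1]
        rep = ep.validate_scores(sheet, shortlist, criteria, ["G1"], "risk")
        assert any("missing" in e for e in rep.errors)
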