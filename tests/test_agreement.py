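"""Bland-Altman, FDA gate, regression fits, Tukey-Kramer letters."""

import numpy as np
import pytest

from neobp.agreement import (AgreementReport, ComponentAgreement,
                             DegenerateFitError, EmptyInputError,
                             bland_altman, fda_check, regression_fits,
                             tukey_kramer_letters)


def _triplets(rng, n, base=(65, 40, 50), spread=8.0):
    return np.column_stack([rng.normal(b, spread, size=n) for b in base])


class TestBlandAltman:
    def test_perfect_agreement(self, rng):
        truth = _triplets(rng, 50)
        rep = bland_altman(truth, truth, mode="pooled")
        for c in rep.components.values():
            assert c.mae == 0 and c.sd == 0 and c.fda_pass

    def test_constant_offset_both_modes(self, rng):
        truth = _triplets(rng, 60)
        pids = np.repeat([f"P{i}" for i in range(6)], 10)
        for mode in ("pooled", "per_individual"):
            rep = bland_altman(truth + 3.0, truth, pids, mode=mode)
            for c in rep.components.values():
                assert c.mae == pytest.approx(3.0, abs=1e-9)
                assert c.sd == pytest.approx(0.0, abs=1e-9)

    def test_pooled_matches_bruteforce(self, rng):
        truth = _triplets(rng, 200)
        pred = truth + rng.normal(0, 5, size=truth.shape)
        rep = bland_altman(pred, truth, mode="pooled")
        for j, name in enumerate(("sbp", "dbp", "map")):
            d = (pred[:, j] - truth[:, j]).tolist()
            mu = sum(d) / len(d)
            sd = (sum((v - mu) ** 2 for v in d) / (len(d) - 1)) ** 0.5
            assert rep.components[name].mae == pytest.approx(mu, abs=1e-12)
            assert rep.components[name].sd == pytest.approx(sd, abs=1e-12)

    def test_per_individual_matches_bruteforce(self, rng):
        truth = _triplets(rng, 90)
        pred = truth + rng.normal(0, 5, size=truth.shape)
        pids = np.repeat([f"P{i}" for i in range(9)], 10)
        rep = bland_altman(pred, truth, pids, mode="per_individual")
        for j, name in enumerate(("sbp", "dbp", "map")):
            means = [np.mean(pred[pids == p, j] - truth[pids == p, j])
                     for p in dict.fromkeys(pids)]
            assert rep.components[name].mae == pytest.approx(
                np.mean(means), abs=1e-12)
            assert rep.components[name].sd == pytest.approx(
                np.std(means, ddof=1), abs=1e-12)

    def test_equal_counts_equal_means_consistency(self, rng):
        # equal points per patient with identical per-patient bias:
        # per-individual MAE equals pooled MAE
        truth = _triplets(rng, 40)
        pred = truth + 2.5
        pids = np.repeat(["a", "b", "c", "d"], 10)
        pooled = bland_altman(pred, truth, mode="pooled")
        perind = bland_altman(pred, truth, pids, mode="per_individual")
        for name in ("sbp", "dbp", "map"):
            assert pooled.components[name].mae == pytest.approx(
                perind.components[name].mae, abs=1e-12)

    def test_empty_and_single_patient_errors(self, rng):
        with pytest.raises(EmptyInputError):
            bland_altman(np.empty((0, 3)), np.empty((0, 3)))
        truth = _triplets(rng, 5)
        with pytest.raises(ValueError):
            bland_altman(truth, truth, ["p"] * 5, mode="per_individual")


class TestFdaGate:
    @staticmethod
    def _report(mae, sd):
        rep = AgreementReport(mode="per_individual")
        rep.components["sbp"] = ComponentAgreement(
            mae=mae, sd=sd, loa_low=mae - 2 * sd, loa_high=mae + 2 * sd,
            n=81, fda_pass=abs(mae) <= 5 and sd <= 8)
        return rep

    def test_typical_pass(self):
        assert fda_check(self._report(-0.1, 7.9))["sbp"]

    def test_sd_failure(self):
        assert not fda_check(self._report(-0.6, 9.2))["sbp"]

    def test_inclusive_boundary(self):
        assert fda_check(self._report(5.0, 8.0))["sbp"]
        assert not fda_check(self._report(5.01, 8.0))["sbp"]


class TestRegressionFits:
    def test_identity_data(self, rng):
        x = rng.normal(60, 10, size=50)
        f = regression_fits(x, x)
        assert f.slope == pytest.approx(1.0)
        assert f.intercept == pytest.approx(0.0, abs=1e-9)
        assert f.r2 == pytest.approx(1.0)
        assert f.rms == pytest.approx(0.0, abs=1e-9)
        assert f.identity_rms == 0.0

    def test_doubled_data_zero_intercept_slope(self, rng):
        x = rng.normal(60, 10, size=50)
        f = regression_fits(2 * x, x)
        assert f.zero_intercept_slope == pytest.approx(2.0, rel=1e-12)

    def test_rms_values_match_residual_oracle(self, rng):
        truth = rng.normal(60, 10, size=120)
        pred = 0.8 * truth + 10 + rng.normal(0, 4, size=120)
        f = regression_fits(pred, truth)
        r1 = pred - (f.slope * truth + f.intercept)
        r2 = pred - f.zero_intercept_slope * truth
        r3 = pred - truth
        for got, resid in ((f.rms, r1), (f.zero_intercept_rms, r2),
                           (f.identity_rms, r3)):
            assert got == pytest.approx(
                float(np.sqrt(np.mean(resid**2))), abs=1e-10)
        # unconstrained fit has the smallest residual by construction
        assert f.rms <= f.zero_intercept_rms + 1e-12
        assert f.rms <= f.identity_rms + 1e-12

    def test_degenerate_truth(self):
        with pytest.raises(DegenerateFitError):
            regression_fits(np.arange(5.0), np.full(5, 3.0))


class TestTukeyKramer:
    def test_identical_distributions_share_letter(self):
        rng = np.random.default_rng(12)
        pool = rng.normal(0, 1, size=60)
        comp = tukey_kramer_letters({"g1": pool[:30], "g2": pool[30:]})
        letters = {g.letters for g in comp.groups}
        assert len(letters) == 1  # both "A"

    def test_separated_means_differ(self):
        rng = np.random.default_rng(0)
        comp = tukey_kramer_letters({
            "lo": rng.normal(0, 1, 30), "hi": rng.normal(50, 1, 30)})
        a, b = comp.groups
        assert not set(a.letters) & set(b.letters)

    def test_three_similar_groups_all_share(self):
        rng = np.random.default_rng(3)
        groups = {c: rng.normal(0.0, 6.5, n)
                  for c, n in (("EPT", 15), ("MPT", 38), ("FT", 26))}
        comp = tukey_kramer_letters(groups)
        common = set(comp.groups[0].letters)
        for g in comp.groups[1:]:
            common &= set(g.letters)
        assert common  # one letter shared by every group

    def test_equal_n_matches_statsmodels_hsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        for seed in range(20):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(2, 5))
            n = int(rng.integers(5, 20))
            shift = rng.uniform(0, 3)
            data = {f"g{i}": rng.normal(i * shift, 1.0, n) for i in range(k)}
            comp = tukey_kramer_letters(data, alpha=0.05)
            vals = np.concatenate(list(data.values()))
            labs = np.repeat(list(data), n)
            sm = pairwise_tukeyhsd(vals, labs, alpha=0.05)
            mine = []
            for i in range(k):
                for j in range(i + 1, k):
                    mine.append(bool(comp.significant[i, j]))
            assert mine == list(sm.reject)

    def test_letter_display_soundness(self):
        # for every output: sharing a letter <-> not significantly different
        for seed in range(15):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(2, 6))
            data = {f"g{i}": rng.normal(rng.uniform(0, 6), 1.0,
                                        int(rng.integers(4, 25)))
                    for i in range(k)}
            comp = tukey_kramer_letters(data)
            for i in range(k):
                assert comp.groups[i].letters  # every group has >= 1 letter
                for j in range(i + 1, k):
                    share = bool(set(comp.groups[i].letters)
                                 & set(comp.groups[j].letters))
                    assert share != bool(comp.significant[i, j])

    def test_unequal_n_uses_kramer_se(self):
        # hand-computed Tukey-Kramer statistic for a tiny unequal-n fixture
        from scipy.stats import studentized_range
        g1 = np.array([0.0, 1.0, 2.0, 3.0])
        g2 = np.array([5.0, 6.0, 7.0])
        comp = tukey_kramer_letters({"a": g1, "b": g2}, alpha=0.05)
        msw = (np.sum((g1 - g1.mean())**2) + np.sum((g2 - g2.mean())**2)) / 5
        se = np.sqrt(msw / 2 * (1 / 4 + 1 / 3))
        q = abs(g1.mean() - g2.mean()) / se
        expected = q >= studentized_range.ppf(0.95, 2, 5)
        assert bool(comp.significant[0, 1]) == expected

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tukey_kramer_letters({"a": np.arange(3.0)})
        with pytest.raises(ValueError):
            tukey_kramer_letters({"a": np.arange(3.0), "b": np.array([1.0])})
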