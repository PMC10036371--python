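"""Window amplitudes, repeated-measures ANOVA, detection rates."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mmntrack import (
    DetectionDecision,
    ParadigmConfig,
    build_templates,
    detection_rates,
    ledger_frame,
    rm_anova,
    window_mean_amplitude,
)
from mmntrack.containers import RoiSeries
from mmntrack.errors import ConfigurationError, IncompleteDesignError


def _series(values, sfreq=512.0):
    t = -100.0 + np.arange(len(values)) * 1000.0 / sfreq
    return RoiSeries(np.asarray(values, dtype=float), t, "evoked-difference")


class TestWindowMean:
    def test_constant_series(self):
        s = _series(np.full(359, -2.0))
        assert window_mean_amplitude(s, (180.0, 230.0)) == -2.0
        assert window_mean_amplitude(s, (0.0, 500.0)) == -2.0

    def test_single_sample_window(self):
        vals = np.arange(359, dtype=float)
        s = _series(vals)
        t = s.time_ms
        assert window_mean_amplitude(s, (t[100], t[100])) == vals[100]

    def test_matches_analytic_gaussian_integral(self):
        """Window mean of the noiseless duration template matches the
        closed-form Gaussian integral over the export window."""
        cfg = ParadigmConfig()
        tpl = build_templates(cfg)
        diff = (tpl["duration"].total - tpl["standard"].total).mean(axis=0)
        s = RoiSeries(diff, cfg.time_ms, "evoked-difference")
        got = window_mean_amplitude(s, (180.0, 230.0))
        sd_mmn = 50.0 / (2 * math.sqrt(2 * math.log(2)))
        sd_p3a = 80.0 / (2 * math.sqrt(2 * math.log(2)))

        def analytic(t):
            return (-2.5 * math.exp(-0.5 * ((t - 205.0) / sd_mmn) ** 2)
                    + 3.0 * math.exp(-0.5 * ((t - 300.0) / sd_p3a) ** 2))

        # the discrete window mean is a midpoint rule over the included
        # samples; compare with the closed-form integral over the same span
        t = cfg.time_ms
        included = t[(t >= 180.0) & (t <= 230.0)]
        h = 1000.0 / 512.0
        lo, hi = included[0] - h / 2, included[-1] + h / 2
        expected = integrate.quad(analytic, lo, hi)[0] / (len(included) * h)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ConfigurationError):
            window_mean_amplitude(_series(np.zeros(359)), (700.0, 800.0))


def _tidy(y, subjects=None):
    n, a, b = y.shape
    subjects = subjects or [f"S{i:02d}" for i in range(n)]
    rows = []
    for s, i, j in itertools.product(range(n), range(a), range(b)):
        rows.append({
            "subject_id": subjects[s],
            "deviant": f"A{i}",
            "block": j + 1,
            "mean_amplitude_uV": y[s, i, j],
        })
    return pd.DataFrame(rows)


def _brute_force_anova(y):
    """Independent oracle: direct cell-means sums of squares via explicit
    loops, epsilon via eigenvalues of the contrast-projected covariance with
    contrasts built by Gram-Schmidt (not the implementation's path)."""
    n, a, b = y.shape
    grand = y.mean()
    ss = {}
    ss["A"] = sum(n * b * (y[:, i, :].mean() - grand) ** 2 for i in range(a))
    ss["B"] = sum(n * a * (y[:, :, j].mean() - grand) ** 2 for j in range(b))
    ss["AB"] = sum(
        n * (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand) ** 2
        for i in range(a) for j in range(b)
    )
    ss["S"] = sum(a * b * (y[s].mean() - grand) ** 2 for s in range(n))
    ss["AS"] = sum(
        b * (y[s, i, :].mean() - y[:, i, :].mean() - y[s].mean() + grand) ** 2
        for s in range(n) for i in range(a)
    )
    ss["BS"] = sum(
        a * (y[s, :, j].mean() - y[:, :, j].mean() - y[s].mean() + grand) ** 2
        for s in range(n) for j in range(b)
    )
    ss["total"] = ((y - grand) ** 2).sum()
    ss["ABS"] = ss["total"] - sum(ss[k] for k in ("A", "B", "AB", "S", "AS", "BS"))

    def gram_schmidt_contrasts(k):
        basis = []
        for i in range(1, k):
            v = np.zeros(k)
            v[0], v[i] = 1.0, -1.0
            for u in basis:
                v -= (v @ u) * u
            v -= v.mean()
            basis.append(v / np.linalg.norm(v))
        return np.array(basis)

    def eps(scores, contrast):
        m = contrast @ np.cov(scores, rowvar=False, ddof=1) @ contrast.T
        lam = np.linalg.eigvalsh(m)
        return float(lam.sum() ** 2 / (len(contrast) * (lam**2).sum()))

    ca, cb = gram_schmidt_contrasts(a), gram_schmidt_contrasts(b)
    out = {}
    for name, ss_eff, ss_err, df1, scores, contrast in [
        ("A", ss["A"], ss["AS"], a - 1, y.mean(axis=2), ca),
        ("B", ss["B"], ss["BS"], b - 1, y.mean(axis=1), cb),
        ("AB", ss["AB"], ss["ABS"], (a - 1) * (b - 1),
         y.reshape(n, a * b), np.kron(ca, cb)),
    ]:
        df2 = df1 * (n - 1)
        F = (ss_eff / df1) / (ss_err / df2)
        out[name] = {
            "F": F,
            "df": (df1, df2),
            "eps": min(1.0, eps(scores, contrast)),
            "eta_p_sq": ss_eff / (ss_eff + ss_err),
        }
    out["ss"] = ss
    return out


class TestRmAnova:
    def test_df_structure_13_subjects(self, rng):
        """13 complete subjects x 3 deviants x 5 blocks gives a (2, 24)
        deviant effect and (4, 48) block effect."""
        y = rng.normal(size=(13, 3, 5))
        table = rm_anova(_tidy(y))
        assert table.effects["deviant"].df == (2, 24)
        assert table.effects["block"].df == (4, 48)
        assert table.effects["deviant x block"].df == (8, 96)
        assert table.n_subjects == 13

    def test_no_condition_variance_gives_zero_f(self, rng):
        base = rng.normal(size=(6, 1, 1))
        y = np.broadcast_to(base, (6, 3, 4)).copy()
        table = rm_anova(_tidy(y))
        for eff in table.effects.values():
            assert eff.F == 0.0

    def test_matches_brute_force_oracle(self, rng):
        """F, df, GG epsilon and partial eta squared match an independent
        brute-force implementation on 20 random small designs."""
        for _ in range(20):
            n = int(rng.integers(4, 9))
            a = int(rng.integers(2, 5))
            b = int(rng.integers(2, 5))
            y = rng.normal(size=(n, a, b)) + rng.normal(size=(n, 1, 1))
            mine = rm_anova(_tidy(y))
            oracle = _brute_force_anova(y)
            for key, name in [("A", "deviant"), ("B", "block"),
                              ("AB", "deviant x block")]:
                eff = mine.effects[name]
                assert eff.F == pytest.approx(oracle[key]["F"], rel=1e-8)
                assert eff.df == oracle[key]["df"]
                assert eff.epsilon_gg == pytest.approx(oracle[key]["eps"], rel=1e-8)
                assert eff.eta_p_sq == pytest.approx(
                    oracle[key]["eta_p_sq"], rel=1e-8
                )

    def test_matches_pingouin(self, rng):
        """F, uncorrected p and main-effect GG epsilons agree with pingouin
        (whose two-way interaction epsilon uses a different, self-flagged
        approximation and is checked against the oracle above instead)."""
        import pingouin as pg

        y = rng.normal(size=(9, 3, 4)) + rng.normal(size=(9, 1, 1))
        df = _tidy(y)
        mine = rm_anova(df)
        theirs = pg.rm_anova(
            dv="mean_amplitude_uV", within=["deviant", "block"],
            subject="subject_id", data=df, detailed=True,
        ).set_index("Source")
        for name, src in [("deviant", "deviant"), ("block", "block")]:
            assert mine.effects[name].F == pytest.approx(
                theirs.loc[src, "F"], rel=1e-9
            )
            assert mine.effects[name].p == pytest.approx(
                theirs.loc[src, "p_unc"], rel=1e-9
            )
            assert mine.effects[name].epsilon_gg == pytest.approx(
                theirs.loc[src, "eps"], rel=1e-9
            )
        assert mine.effects["deviant x block"].F == pytest.approx(
            theirs.loc["deviant * block", "F"], rel=1e-9
        )

    def test_ss_conservation(self, rng):
        y = rng.normal(size=(8, 3, 5))
        table = rm_anova(_tidy(y))
        ss = table.ss_components
        parts = sum(v for k, v in ss.items() if k != "total")
        assert parts == pytest.approx(ss["total"], rel=1e-8)

    def test_incomplete_subjects_dropped(self, rng):
        y = rng.normal(size=(6, 3, 4))
        df = _tidy(y)
        df = df[~((df.subject_id == "S00") & (df.block == 4))]
        table = rm_anova(df)
        assert table.n_subjects == 5

    def test_single_level_factor_rejected(self, rng):
        y = rng.normal(size=(5, 1, 4))
        with pytest.raises(IncompleteDesignError):
            rm_anova(_tidy(y))

    def test_posthoc_bonferroni(self, rng):
        """A large deviant effect triggers the three pairwise post-hocs with
        Bonferroni-multiplied p-values and (first - second) differences."""
        y = rng.normal(size=(10, 3, 4), scale=0.3)
        y[:, 0] -= 2.0  # strong deviant effect
        table = rm_anova(_tidy(y))
        assert len(table.posthoc) == 3
        row = table.posthoc.set_index("pair").loc["A0 - A1"]
        marg = y.mean(axis=2)
        assert row["mean_difference_uV"] == pytest.approx(
            (marg[:, 0] - marg[:, 1]).mean()
        )
        t, p = stats.ttest_1samp(marg[:, 0] - marg[:, 1], 0.0)
        assert row["p_bonferroni"] == pytest.approx(min(1.0, p * 3))

    def test_gg_epsilon_in_valid_range(self, rng):
        y = rng.normal(size=(7, 4, 3))
        table = rm_anova(_tidy(y))
        for eff in table.effects.values():
            k = eff.df[0]
            assert 1.0 / k - 1e-12 <= eff.epsilon_gg <= 1.0 + 1e-12


def _decision(subject, block, present, method="permutation"):
    return DetectionDecision(
        subject_id=subject, block_id=block, deviant="duration",
        component="MMN", method=method, present=present, strength=0.01,
    )


class TestDetectionRates:
    def test_all_present_gives_one(self):
        ledger = ledger_frame([_decision(f"S{i}", 1, True) for i in range(17)])
        rates = detection_rates(ledger)
        assert rates.iloc[0]["proportion_present"] == 1.0
        assert rates.iloc[0]["n_subjects"] == 17

    def test_partial_presence_fraction(self):
        ledger = ledger_frame(
            [_decision(f"S{i}", 1, i < 8) for i in range(17)]
        )
        rates = detection_rates(ledger)
        assert rates.iloc[0]["proportion_present"] == pytest.approx(8 / 17)

    def test_missing_block_excluded_from_denominator(self):
        decisions = [_decision(f"S{i}", 1, True) for i in range(17)]
        decisions += [_decision(f"S{i}", 5, True) for i in range(13)]
        rates = detection_rates(ledger_frame(decisions)).set_index("block")
        assert rates.loc[1, "n_subjects"] == 17
        assert rates.loc[5, "n_subjects"] == 13

    def test_duplicate_decisions_rejected(self):
        with pytest.raises(ConfigurationError):
            ledger_frame([_decision("S1", 1, True), _decision("S1", 1, False)])
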