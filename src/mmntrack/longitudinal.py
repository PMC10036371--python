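"""Group-level aggregation across blocks.

Two jobs:

* turn per-block presence/absence decisions into detection-rate tables
  (proportion of subjects showing each component per block, deviant and
  method);
* test for habituation with a two-way within-subject (repeated-measures)
  ANOVA -- deviant type x block -- on mean difference-wave amplitudes
  exported over component-specific windows, with Greenhouse-Geisser
  sphericity correction, partial eta squared, and Bonferroni-corrected
  pairwise post-hocs on the deviant marginal means.

The ANOVA is a direct balanced sums-of-squares decomposition with subject as
random factor; it is deliberately self-contained so every SS component is
available (SS conservation is a tested invariant).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RoiSeries
from .errors import ConfigurationError, IncompleteDesignError

logger = logging.getLogger(__name__)

#: Amplitude-export windows: +/-50 ms around the group-average peak
#: (duration MMN peaks later than the frequency/intensity DRN).
EXPORT_WINDOWS_MS = {
    "duration": (180.0, 230.0),
    "frequency": (80.0, 130.0),
    "intensity": (80.0, 130.0),
}


def window_mean_amplitude(
    series: RoiSeries | np.ndarray,
    window_ms: tuple[float, float],
    time_ms: np.ndarray | None = None,
) -> float:
    """Arithmetic mean of an ROI difference series over ``window_ms`` (inclusive)."""
    if isinstance(series, RoiSeries):
        values, t = series.values, series.time_ms
    else:
        values, t = np.asarray(series, dtype=float), np.asarray(time_ms, dtype=float)
    if values.ndim != 1:
        raise ConfigurationError("window_mean_amplitude expects a single series")
    lo, hi = window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ConfigurationError(
            f"window {window_ms} outside epoch span [{t[0]}, {t[-1]}] ms"
        )
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ConfigurationError(f"window {window_ms} contains no samples")
    return float(values[mask].mean())


def amplitude_table(
    diffs: dict[tuple[str, object, str], RoiSeries],
    windows_ms: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Tidy table of window-mean amplitudes.

    ``diffs`` maps (subject_id, block, deviant) -> ROI difference series;
    window per deviant from ``windows_ms`` (default: the component-specific
    export windows).
    """
    windows_ms = windows_ms or EXPORT_WINDOWS_MS
    rows = []
    for (subject, block, deviant), series in diffs.items():
        rows.append(
            {
                "subject_id": subject,
                "block": block,
                "deviant": deviant,
                "mean_amplitude_uV": window_mean_amplitude(
                    series, windows_ms[deviant]
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaEffect:
    """One within-subject effect row."""

    name: str
    ss: float
    ss_error: float
    df: tuple[int, int]
    df_gg: tuple[float, float]
    epsilon_gg: float
    F: float
    p: float
    p_gg: float
    eta_p_sq: float


@dataclass
class AnovaTable:
    """Two-way within-subject decomposition + post-hocs.

    ``ss_components`` holds every sum of squares (effects, their error
    terms, subject, total) so that SS conservation can be verified.
    """

    effects: dict[str, AnovaEffect]
    posthoc: pd.DataFrame
    ss_components: dict[str, float]
    n_subjects: int
    factor_levels: dict[str, list]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eff in self.effects.values():
            rows.append(
                {
                    "effect": eff.name,
                    "F": eff.F,
                    "df1": eff.df[0],
                    "df2": eff.df[1],
                    "df1_gg": eff.df_gg[0],
                    "df2_gg": eff.df_gg[1],
                    "epsilon_gg": eff.epsilon_gg,
                    "p_uncorrected": eff.p,
                    "p_gg": eff.p_gg,
                    "eta_p_sq": eff.eta_p_sq,
                }
            )
        return pd.DataFrame(rows)


def _gg_epsilon(scores: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of one within-subject effect.

    ``scores`` is the (n_subjects, k) matrix of that subject's cell (or
    marginal) scores and ``contrast`` an orthonormal (df, k) basis of the
    effect space.  With M = C S C' (S the score covariance),
    epsilon = tr(M)^2 / (df * tr(M @ M)), clipped to [1/df, 1].
    """
    df_effect = contrast.shape[0]
    s = np.atleast_2d(np.cov(scores, rowvar=False, ddof=1))
    m = contrast @ s @ contrast.T
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= 0:
        return 1.0
    eps = (tr**2) / (df_effect * tr2)
    return float(min(1.0, max(eps, 1.0 / df_effect)))


def _f_p(F: float, df1: float, df2: float) -> float:
    if not np.isfinite(F) or df1 <= 0 or df2 <= 0:
        return math.nan
    return float(stats.f.sf(F, df1, df2))


def rm_anova(
    table: pd.DataFrame,
    dv: str = "mean_amplitude_uV",
    factors: tuple[str, str] = ("deviant", "block"),
    subject: str = "subject_id",
    posthoc_alpha: float = 0.05,
) -> AnovaTable:
    """Two-way within-subject ANOVA on a tidy amplitude table.

    Complete cases only: subjects missing any factor cell are dropped
    (listwise deletion, logged); an explicit error lists missing cells if no
    complete subject remains or a factor has a single level.  Effects carry
    uncorrected and Greenhouse-Geisser-corrected p-values (GG is applied
    whenever epsilon < 1) and partial eta squared
    SS_effect / (SS_effect + SS_error).  When the first factor's effect is
    significant (GG-corrected p < ``posthoc_alpha``), Bonferroni-corrected
    pairwise paired t-tests on its marginal means are run; mean differences
    are signed (first level - second level) of the named pair.
    """
    fa, fb = factors
    levels_a = sorted(table[fa].unique().tolist())
    levels_b = sorted(table[fb].unique().tolist())
    a, b = len(levels_a), len(levels_b)
    if a < 2 or b < 2:
        raise IncompleteDesignError(
            f"each factor needs >= 2 levels (got {a} x {b})"
        )
    pivot = table.pivot_table(
        index=subject, columns=[fa, fb], values=dv, aggfunc="mean"
    )
    full_cols = list(itertools.product(levels_a, levels_b))
    pivot = pivot.reindex(columns=pd.MultiIndex.from_tuples(full_cols))
    complete = pivot.dropna(axis=0)
    dropped = sorted(set(pivot.index) - set(complete.index))
    if dropped:
        missing = {
            subj: [c for c in full_cols if pd.isna(pivot.loc[subj, c])]
            for subj in dropped
        }
        logger.info("rm_anova: dropping incomplete subjects %s", missing)
    n = len(complete)
    if n < 3:
        raise IncompleteDesignError(
            f"need >= 3 complete-case subjects, have {n}; incomplete: {dropped}"
        )
    y = complete.to_numpy().reshape(n, a, b)

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_subject = a * b * ((m_s - grand) ** 2).sum()
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bs = a * ((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_abs = ss_total - (ss_subject + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    from scipy.linalg import helmert

    h_a = helmert(a)  # orthonormal (a-1, a) contrast basis
    h_b = helmert(b)
    specs = [
        (fa, ss_a, ss_as, a - 1, (a - 1) * (n - 1), m_as, h_a),
        (fb, ss_b, ss_bs, b - 1, (b - 1) * (n - 1), m_bs, h_b),
        (
            f"{fa} x {fb}",
            ss_ab,
            ss_abs,
            (a - 1) * (b - 1),
            (a - 1) * (b - 1) * (n - 1),
            y.reshape(n, a * b),
            np.kron(h_a, h_b),
        ),
    ]
    effects: dict[str, AnovaEffect] = {}
    for name, ss_eff, ss_err, df1, df2, scores, contrast in specs:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ss_eff <= 1e-30:
            F = 0.0
        elif ms_err <= 0:
            F = math.inf
        else:
            F = ms_eff / ms_err
        eps = _gg_epsilon(np.asarray(scores), contrast)
        df_gg = (df1 * eps, df2 * eps)
        p = _f_p(F, df1, df2)
        p_gg = _f_p(F, *df_gg) if eps < 1.0 else p
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        effects[name] = AnovaEffect(
            name=name,
            ss=float(ss_eff),
            ss_error=float(ss_err),
            df=(df1, df2),
            df_gg=df_gg,
            epsilon_gg=eps,
            F=float(F),
            p=p,
            p_gg=p_gg,
            eta_p_sq=float(eta),
        )

    ss_components = {
        "subject": float(ss_subject),
        fa: float(ss_a),
        fb: float(ss_b),
        f"{fa} x {fb}": float(ss_ab),
        f"{fa} error": float(ss_as),
        f"{fb} error": float(ss_bs),
        f"{fa} x {fb} error": float(ss_abs),
        "total": float(ss_total),
    }

    posthoc_rows = []
    if effects[fa].p_gg < posthoc_alpha:
        pairs = list(itertools.combinations(range(a), 2))
        n_comp = len(pairs)
        marg = m_as  # (n, a) marginal means averaged over the other factor
        for i, j in pairs:
            diff = marg[:, i] - marg[:, j]
            t, p_raw = stats.ttest_1samp(diff, 0.0)
            posthoc_rows.append(
                {
                    "pair": f"{levels_a[i]} - {levels_a[j]}",
                    "mean_difference_uV": float(diff.mean()),
                    "t": float(t),
                    "p_uncorrected": float(p_raw),
                    "p_bonferroni": float(min(1.0, p_raw * n_comp)),
                }
            )
    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=["pair", "mean_difference_uV", "t", "p_uncorrected", "p_bonferroni"],
    )
    return AnovaTable(
        effects=effects,
        posthoc=posthoc,
        ss_components=ss_components,
        n_subjects=n,
        factor_levels={fa: levels_a, fb: levels_b},
    )


# ---------------------------------------------------------------------------
# detection rates
# ---------------------------------------------------------------------------


def ledger_frame(decisions) -> pd.DataFrame:
    """Tidy DataFrame from an iterable of DetectionDecision."""
    rows = [
        {
            "subject_id": d.subject_id,
            "block": d.block_id,
            "deviant": d.deviant,
            "component": d.component,
            "method": d.method,
            "present": bool(d.present),
            "strength": d.strength,
            "annotator": d.annotator,
        }
        for d in decisions
    ]
    df = pd.DataFrame(rows)
    if len(df):
        dup = df.duplicated(
            subset=["subject_id", "block", "deviant", "component", "method"]
        )
        if dup.any():
            raise ConfigurationError(
                "duplicate detection decisions for the same "
                "(subject, block, deviant, component, method)"
            )
    return df


def detection_rates(ledger: pd.DataFrame) -> pd.DataFrame:
    """Proportion of subjects showing each component per block/deviant/method.

    Denominators count only subjects with a decision for that block
    (subjects who did not record a block are excluded from it).
    """
    if not len(ledger):
        raise ConfigurationError("detection ledger is empty")
    grouped = ledger.groupby(["component", "deviant", "block", "method"])
    rows = []
    for (component, deviant, block, method), grp in grouped:
        n = grp["subject_id"].nunique()
        rows.append(
            {
                "component": component,
                "deviant": deviant,
                "block": block,
                "method": method,
                "n_subjects": n,
                "proportion_present": grp["present"].sum() / n,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["component", "deviant", "block", "method"]
    ).reset_index(drop=True)
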