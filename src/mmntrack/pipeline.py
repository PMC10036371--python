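"""End-to-end orchestration: epochs in, detection ledger and tables out.

``analyze_study`` runs, for every subject x block:

* preprocessing (filter, baseline, artifact rejection, averaging);
* single-subject detection (independent-samples permutation + Bayes across
  trials, deviant vs standard) for each deviant and component;

and at the group level, per block, the paired designs across subject-evoked
pairs, plus the amplitude table and the deviant x block repeated-measures
ANOVA.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import EpochsSet, RoiSeries
from .detect import (
    ComponentWindow,
    ContrastResult,
    DetectionDecision,
    analyze_contrast,
    difference_series,
    roi_mean,
)
from .errors import EmptyConditionError
from .longitudinal import (
    EXPORT_WINDOWS_MS,
    amplitude_table,
    detection_rates,
    ledger_frame,
    rm_anova,
)
from .preprocess import average_by_condition, preprocess
from .simulate import DEVIANTS, STANDARD, simulate_group

logger = logging.getLogger(__name__)


def component_windows(cfg: RunConfig) -> list[ComponentWindow]:
    det = cfg.detection
    return [
        ComponentWindow("MMN", tuple(det.mmn_window_ms), "negative"),
        ComponentWindow("P3a", tuple(det.p3a_window_ms), "positive"),
    ]


@dataclass
class StudyResult:
    """Everything a study run produces."""

    ledger: pd.DataFrame
    group_ledger: pd.DataFrame
    rates: pd.DataFrame
    group_rates: pd.DataFrame | None
    amplitudes: pd.DataFrame
    anova: object | None
    effects: pd.DataFrame
    log: dict = field(default_factory=dict)


def simulate_study(cfg: RunConfig) -> list[EpochsSet]:
    """Simulate the configured scenario (one EpochsSet per subject x block)."""
    return simulate_group(
        cfg.paradigm,
        cfg.noise,
        n_subjects=cfg.n_subjects,
        n_blocks=cfg.n_blocks,
        subject_amplitude_sd=cfg.subject_amplitude_sd,
        block_gains=cfg.block_gains(),
        seed=cfg.seed,
    )


def analyze_study(
    blocks: list[EpochsSet],
    cfg: RunConfig,
    single_subject: bool = True,
    group_level: bool = True,
    manual_annotations: pd.DataFrame | None = None,
) -> StudyResult:
    """Run the full analysis over a list of subject x block epoch sets."""
    t0 = time.time()
    windows = component_windows(cfg)
    roi = cfg.detection.roi
    rules = cfg.detection.rules()
    rng = np.random.default_rng(cfg.seed + 1)

    decisions: list[DetectionDecision] = []
    group_decisions: list[DetectionDecision] = []
    diffs: dict[tuple[str, object, str], RoiSeries] = {}
    effect_rows: list[dict] = []
    n_rejected = 0
    n_trials = 0

    # -- per subject x block ----------------------------------------------
    evoked_store: dict[tuple[str, object], dict] = {}
    for ep in blocks:
        clean = preprocess(ep, cfg.preprocessing)
        n_trials += clean.n_trials
        n_rejected += int(clean.rejected.sum())
        block = clean.block_id[0]
        try:
            evoked = average_by_condition(
                clean,
                exclude_post_deviant_standards=
                cfg.preprocessing.exclude_post_deviant_standards,
            )
        except EmptyConditionError:
            logger.warning(
                "skipping subject %s block %s: empty condition",
                clean.subject_id, block,
            )
            raise
        evoked_store[(clean.subject_id, block)] = evoked

        trial_roi = roi_mean(clean, roi)
        unrejected = ~clean.rejected
        for deviant in DEVIANTS:
            if deviant not in evoked:
                continue
            diff = difference_series(evoked[deviant], evoked[STANDARD], roi)
            diffs[(clean.subject_id, block, deviant)] = diff
            if not single_subject:
                continue
            dev_mask = (clean.condition == deviant) & unrejected
            std_mask = (clean.condition == STANDARD) & unrejected
            res = analyze_contrast(
                trial_roi.values[dev_mask],
                trial_roi.values[std_mask],
                design="independent",
                diff=diff,
                windows=windows,
                n_permutations=cfg.detection.n_permutations,
                rules=rules,
                seed=rng,
                time_ms=clean.time_ms,
                bayes_method=cfg.detection.bayes_method,
                subject_id=clean.subject_id,
                block_id=block,
                deviant=deviant,
                equal_var=cfg.detection.equal_var,
            )
            decisions.extend(res.decisions)
            effect_rows.extend(
                _effect_rows(res, clean.subject_id, block, deviant, "independent")
            )

    # -- group level per block --------------------------------------------
    subject_ids = sorted({sid for sid, _ in evoked_store})
    block_ids = sorted({blk for _, blk in evoked_store})
    if group_level and len(subject_ids) >= 2:
        for block in block_ids:
            for deviant in DEVIANTS:
                dev_stack, std_stack = [], []
                for sid in subject_ids:
                    ev = evoked_store.get((sid, block))
                    if ev is None or deviant not in ev:
                        continue
                    dev_stack.append(roi_mean(ev[deviant], roi).values)
                    std_stack.append(roi_mean(ev[STANDARD], roi).values)
                if len(dev_stack) < 2:
                    continue
                dev_mat = np.vstack(dev_stack)
                std_mat = np.vstack(std_stack)
                grand_diff = RoiSeries(
                    values=(dev_mat - std_mat).mean(axis=0),
                    time_ms=blocks[0].time_ms,
                    source="evoked-difference",
                )
                res = analyze_contrast(
                    dev_mat,
                    std_mat,
                    design="paired",
                    diff=grand_diff,
                    windows=windows,
                    n_permutations=cfg.detection.n_permutations,
                    rules=rules,
                    seed=rng,
                    time_ms=blocks[0].time_ms,
                    bayes_method=cfg.detection.bayes_method,
                    subject_id="GROUP",
                    block_id=block,
                    deviant=deviant,
                )
                group_decisions.extend(res.decisions)
                effect_rows.extend(
                    _effect_rows(res, "GROUP", block, deviant, "paired")
                )

    # -- ledgers and tables -------------------------------------------------
    ledger = ledger_frame(decisions) if decisions else pd.DataFrame()
    if manual_annotations is not None and len(ledger):
        manual = manual_annotations.rename(columns={"block": "block"})
        manual = manual.assign(method="manual-visual", strength=np.nan)
        ledger = pd.concat([ledger, manual], ignore_index=True)
    group_ledger = ledger_frame(group_decisions) if group_decisions else pd.DataFrame()
    rates = detection_rates(ledger) if len(ledger) else pd.DataFrame()
    group_rates = detection_rates(group_ledger) if len(group_ledger) else None

    amplitudes = amplitude_table(diffs, EXPORT_WINDOWS_MS) if diffs else pd.DataFrame()
    anova = None
    if len(amplitudes) and amplitudes["subject_id"].nunique() >= 3 and (
        amplitudes["block"].nunique() >= 2
    ):
        try:
            anova = rm_anova(amplitudes)
        except Exception as exc:  # incomplete designs are reported, not fatal
            logger.warning("rm_anova skipped: %s", exc)

    return StudyResult(
        ledger=ledger,
        group_ledger=group_ledger,
        rates=rates,
        group_rates=group_rates,
        amplitudes=amplitudes,
        anova=anova,
        effects=pd.DataFrame(effect_rows),
        log={
            "n_trials": n_trials,
            "n_rejected": n_rejected,
            "n_subjects": len(subject_ids),
            "blocks": [str(b) for b in block_ids],
            "seed": cfg.seed,
            "runtime_s": round(time.time() - t0, 2),
        },
    )


def _effect_rows(
    res: ContrastResult, subject: str, block, deviant: str, design: str
) -> list[dict]:
    rows = []
    for name, eff in res.effects.items():
        bs = res.bayes[name]
        perm = res.perm[name]
        rows.append(
            {
                "subject_id": subject,
                "block": block,
                "deviant": deviant,
                "component": name,
                "design": design,
                "peak_latency_ms": eff.peak_latency_ms,
                "peak_amplitude_uV": eff.peak_amplitude_uV,
                "d_50": eff.d_50,
                "d_100": eff.d_100,
                "hedges_g_100": eff.hedges_g_100,
                "max_bf10": bs.max_bf10,
                "bf_latency_ms": bs.max_latency_ms,
                "evidence": bs.category,
                "min_p_corr": perm.min_p_corr,
                "n_sig_intervals": len(perm.significant_intervals),
            }
        )
    return rows
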