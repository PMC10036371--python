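"""Detect MMN and P3a in a single subject's block.

Runs the full single-subject route: preprocessing, independent-samples
serial permutation t-test with Tmax correction across trials, Bayes-factor
timecourse, peak detection and effect sizes.
"""

from mmntrack import (
    NoiseModel,
    ParadigmConfig,
    analyze_contrast,
    average_by_condition,
    difference_series,
    preprocess,
    roi_mean,
    simulate_block,
)

cfg = ParadigmConfig(seed=3)
epochs = simulate_block(cfg, NoiseModel(seed=3))
clean = preprocess(epochs)  # 0.1-30 Hz, baseline, 200 uV p-p rejection
evoked = average_by_condition(clean)

diff = difference_series(evoked["duration"], evoked["standard"])
trials = roi_mean(clean)
result = analyze_contrast(
    trials.values[clean.condition == "duration"],
    trials.values[clean.condition == "standard"],
    design="independent",
    diff=diff,
    time_ms=clean.time_ms,
    seed=3,
)

for name in ("MMN", "P3a"):
    eff = result.effects[name]
    bayes = result.bayes[name]
    perm = result.perm[name]
    print(f"{name}: peak {eff.peak_amplitude_uV:+.2f} uV at "
          f"{eff.peak_latency_ms:.0f} ms, d100 = {eff.d_100:+.2f}, "
          f"min corrected p = {perm.min_p_corr:.3f}, "
          f"max BF10 = {bayes.max_bf10:.3g} ({bayes.category})")
for d in result.decisions:
    print(f"  {d.component}/{d.method}: {'present' if d.present else 'absent'}")
# A present call needs >= 10 ms of contiguous Tmax-corrected significance of
# the right polarity inside the component window (permutation route) or a
# windowed maximum BF10 >= 3 (Bayes route).
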