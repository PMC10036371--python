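"""Synthetic multi-deviant auditory oddball EEG.

The generator reproduces the statistical structure of a passive three-deviant
oddball block: 2,400 tones at a regular 450 ms stimulus onset asynchrony, 82%
standards (50 ms / 1,000 Hz / 80 dB SPL) and 6% each of duration (125 ms),
frequency (1,200 Hz) and intensity (90 dB SPL) deviants.  Deviant tones evoke
deviance-related components on top of the obligatory auditory response:

* duration deviants -- a mismatch negativity (MMN) peaking between 180 and
  230 ms and a P3a peaking between 250 and 350 ms;
* frequency and intensity deviants -- a deviant-related negativity (DRN, the
  spatio-temporal summation of N1 and MMN) peaking between 80 and 130 ms,
  followed by a P3a.

Components are unimodal Gaussian pulses over a small frontocentral montage,
superposed additively.  Background activity is white plus 1/f ("pink") noise
per channel, and a ``block_presence_gain`` in [0, 1] scales the
deviance-related components only -- gain 0 makes a block's deviant trials
statistically indistinguishable from standards, which is the control used to
emulate responses that wax and wane across recording blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .containers import EpochsSet
from .errors import ConfigurationError, GenerationError, RenderingError

STANDARD = "standard"
DEVIANTS = ("duration", "frequency", "intensity")
CONDITIONS = (STANDARD,) + DEVIANTS

#: Default frontocentral montage (region of interest for every statistic).
DEFAULT_CHANNELS = ["F3", "Fz", "F4", "C3", "Cz", "C4"]

EPOCH_TMIN_MS = -100.0
EPOCH_SPAN_S = 0.7  # epoch spans [-100, +600] ms

_FWHM_TO_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))

_DEFAULT_TONE_SPECS = {
    "standard": {"duration_ms": 50, "frequency_hz": 1000, "level_db_spl": 80},
    "duration": {"duration_ms": 125, "frequency_hz": 1000, "level_db_spl": 80},
    "frequency": {"duration_ms": 50, "frequency_hz": 1200, "level_db_spl": 80},
    "intensity": {"duration_ms": 50, "frequency_hz": 1000, "level_db_spl": 90},
}


def epoch_times_ms(sampling_rate_hz: float) -> np.ndarray:
    """Epoch grid t_k = -100 + k * (1000 / rate) ms, k = 0 .. floor(0.7 * rate)."""
    n = int(math.floor(EPOCH_SPAN_S * sampling_rate_hz)) + 1
    return EPOCH_TMIN_MS + np.arange(n) * (1000.0 / sampling_rate_hz)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class ParadigmConfig:
    """Composition and timing of one oddball block.

    Probabilities must sum to one; per-condition counts are fixed at
    ``round(n_tones * p)`` (exact-count sampling, no Bernoulli draws) with any
    rounding remainder assigned to standards.
    """

    n_tones: int = 2400
    soa_ms: float = 450.0
    p_standard: float = 0.82
    p_deviant: dict[str, float] = field(
        default_factory=lambda: {d: 0.06 for d in DEVIANTS}
    )
    tone_specs: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_TONE_SPECS.items()}
    )
    sampling_rate_hz: float = 512.0
    seed: int = 0
    #: require at least one standard between consecutive deviants
    enforce_deviant_separation: bool = True

    def validate(self) -> None:
        if self.n_tones <= 0:
            raise ConfigurationError("n_tones must be > 0")
        if self.soa_ms <= 0:
            raise ConfigurationError("soa_ms must be > 0")
        total = self.p_standard + sum(self.p_deviant.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"probabilities must sum to 1 (got {total!r})"
            )
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")

    def condition_counts(self) -> dict[str, int]:
        """Exact per-condition counts: round(n*p) per deviant, rest standards."""
        self.validate()
        counts = {d: int(round(self.n_tones * p)) for d, p in self.p_deviant.items()}
        n_dev = sum(counts.values())
        if n_dev > self.n_tones:
            raise ConfigurationError("deviant counts exceed n_tones")
        counts[STANDARD] = self.n_tones - n_dev
        return counts

    @property
    def time_ms(self) -> np.ndarray:
        return epoch_times_ms(self.sampling_rate_hz)


@dataclass
class StimulusSequence:
    """Timed, typed tone events of one oddball block."""

    onset_ms: np.ndarray
    condition: np.ndarray
    soa_ms: float

    def __post_init__(self) -> None:
        self.onset_ms = np.asarray(self.onset_ms, dtype=float)
        self.condition = np.asarray(self.condition)

    @property
    def n_events(self) -> int:
        return len(self.condition)

    @property
    def events(self) -> list[tuple[float, str]]:
        return [(float(t), str(c)) for t, c in zip(self.onset_ms, self.condition)]

    def counts(self) -> dict[str, int]:
        values, counts = np.unique(self.condition, return_counts=True)
        return {str(v): int(c) for v, c in zip(values, counts)}

    def post_deviant_flags(self) -> np.ndarray:
        """True for every event immediately following a deviant."""
        is_dev = np.isin(self.condition, DEVIANTS)
        flags = np.zeros(self.n_events, dtype=bool)
        flags[1:] = is_dev[:-1]
        return flags


@dataclass
class ComponentSpec:
    """One ERP component as a Gaussian pulse.

    ``width_ms`` is the full width at half maximum of the pulse (defaults:
    50 ms for N1/MMN/DRN, 80 ms for P3a).  ``channel_weights`` maps channel
    name to gain; channels absent from the mapping get weight 0.
    ``obligatory`` components (the exogenous N1) are not scaled by the
    block-presence gain; deviance-related components (MMN/DRN/P3a) are.
    """

    name: str
    polarity: str  # "negative" | "positive"
    peak_latency_ms: float
    width_ms: float
    amplitude_uV: float
    channel_weights: dict[str, float] | None = None
    obligatory: bool = False

    def validate(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if self.width_ms <= 0:
            raise ConfigurationError("width_ms must be > 0")
        if self.polarity == "negative" and self.amplitude_uV > 0:
            raise ConfigurationError(
                f"{self.name}: negative component must have amplitude <= 0"
            )
        if self.polarity == "positive" and self.amplitude_uV < 0:
            raise ConfigurationError(
                f"{self.name}: positive component must have amplitude >= 0"
            )

    def weights_for(self, channel_names: Sequence[str]) -> np.ndarray:
        if self.channel_weights is None:
            return np.ones(len(channel_names))
        return np.array([self.channel_weights.get(c, 0.0) for c in channel_names])


@dataclass
class NoiseModel:
    """Background-activity model for synthetic trials.

    * ``white_sd_uV`` -- per-sample, per-channel white noise SD;
    * ``pink_sd_uV`` -- per-sample SD of 1/f-shaped noise (independent per
      channel and trial);
    * ``trial_amplitude_jitter`` -- multiplicative SD on the whole template,
      trial by trial;
    * ``block_presence_gain`` -- scalar in [0, 1] scaling deviance-related
      components only (1 = fully present, 0 = absent).
    """

    white_sd_uV: float = 4.0
    pink_sd_uV: float = 6.0
    trial_amplitude_jitter: float = 0.1
    block_presence_gain: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.white_sd_uV < 0 or self.pink_sd_uV < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.trial_amplitude_jitter < 0:
            raise ConfigurationError("trial_amplitude_jitter must be >= 0")
        if not (0.0 <= self.block_presence_gain <= 1.0):
            raise ConfigurationError("block_presence_gain must be in [0, 1]")


# ---------------------------------------------------------------------------
# default component morphology
# ---------------------------------------------------------------------------


def default_components(condition: str) -> list[ComponentSpec]:
    """Default ERP morphology per condition.

    Standards carry the obligatory N1 only; deviants add deviance-related
    components.  Duration deviants get a dissociated MMN (205 ms) and P3a
    (300 ms); frequency/intensity deviants get a DRN (105 ms) and P3a.
    Amplitudes are ordered frequency < intensity < duration, mirroring the
    relative effect sizes typically seen with this multi-deviant paradigm.
    """
    n1 = ComponentSpec("N1", "negative", 100.0, 50.0, -1.5, obligatory=True)
    if condition == STANDARD:
        return [n1]
    if condition == "duration":
        return [
            n1,
            ComponentSpec("MMN", "negative", 205.0, 50.0, -2.5),
            ComponentSpec("P3a", "positive", 300.0, 80.0, 3.0),
        ]
    if condition == "frequency":
        return [
            n1,
            ComponentSpec("DRN", "negative", 105.0, 50.0, -1.6),
            ComponentSpec("P3a", "positive", 300.0, 80.0, 2.0),
        ]
    if condition == "intensity":
        return [
            n1,
            ComponentSpec("DRN", "negative", 105.0, 50.0, -2.0),
            ComponentSpec("P3a", "positive", 300.0, 80.0, 2.2),
        ]
    raise ConfigurationError(f"unknown condition {condition!r}")


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------


def _non_adjacent_positions(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of k positions from range(n) with no two adjacent.

    Standard bijection: choose y_1 < ... < y_k from range(n - k + 1) and map
    x_i = y_i + i; this enumerates exactly the C(n-k+1, k) admissible sets
    with equal probability.
    """
    if k == 0:
        return np.empty(0, dtype=int)
    if n - k + 1 < k:
        raise GenerationError(
            f"cannot place {k} non-adjacent deviants among {n} tones"
        )
    y = np.sort(rng.choice(n - k + 1, size=k, replace=False))
    return y + np.arange(k)


def generate_sequence(config: ParadigmConfig) -> StimulusSequence:
    """Pseudo-random oddball sequence with exact per-condition counts.

    Deviant positions are drawn uniformly over all arrangements with at least
    one standard between consecutive deviants (disable with
    ``enforce_deviant_separation=False``), then deviant types are assigned by
    a uniform random permutation.  Onsets are k * soa_ms.
    """
    config.validate()
    counts = config.condition_counts()
    n = config.n_tones
    rng = np.random.default_rng(config.seed)

    dev_labels = np.concatenate(
        [np.repeat(d, counts.get(d, 0)) for d in DEVIANTS]
    ) if any(counts.get(d, 0) for d in DEVIANTS) else np.empty(0, dtype="<U9")
    k = len(dev_labels)

    conditions = np.full(n, STANDARD, dtype="<U9")
    if k:
        if config.enforce_deviant_separation:
            pos = _non_adjacent_positions(n, k, rng)
        else:
            pos = np.sort(rng.choice(n, size=k, replace=False))
        conditions[pos] = rng.permutation(dev_labels)

    onsets = np.arange(n) * config.soa_ms
    return StimulusSequence(onset_ms=onsets, condition=conditions, soa_ms=config.soa_ms)


# ---------------------------------------------------------------------------
# template rendering
# ---------------------------------------------------------------------------


@dataclass
class ConditionTemplate:
    """Noiseless per-channel waveform split into obligatory and deviance parts."""

    condition: str
    obligatory: np.ndarray  # (channels, samples)
    deviance: np.ndarray  # (channels, samples)

    @property
    def total(self) -> np.ndarray:
        return self.obligatory + self.deviance


def _render_parts(
    condition: str,
    components: Iterable[ComponentSpec],
    config: ParadigmConfig,
    channel_names: Sequence[str],
) -> ConditionTemplate:
    t = config.time_ms
    obligatory = np.zeros((len(channel_names), len(t)))
    deviance = np.zeros_like(obligatory)
    for comp in components:
        comp.validate()
        if not (t[0] <= comp.peak_latency_ms <= t[-1]):
            raise RenderingError(
                f"component {comp.name!r} latency {comp.peak_latency_ms} ms "
                f"outside epoch window [{t[0]}, {t[-1]}] ms"
            )
        sd = comp.width_ms / _FWHM_TO_SD
        pulse = comp.amplitude_uV * np.exp(
            -0.5 * ((t - comp.peak_latency_ms) / sd) ** 2
        )
        wave = comp.weights_for(channel_names)[:, None] * pulse[None, :]
        if comp.obligatory:
            obligatory += wave
        else:
            deviance += wave
    return ConditionTemplate(condition, obligatory, deviance)


def render_template(
    condition: str,
    components: Iterable[ComponentSpec],
    config: ParadigmConfig,
    channel_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Render the noiseless per-channel waveform of one condition.

    Each component contributes a unimodal Gaussian pulse at its configured
    latency with its polarity and channel weighting; superposition is
    additive.  Returns ``(channels, samples)`` on the epoch grid.
    """
    channels = list(channel_names) if channel_names is not None else DEFAULT_CHANNELS
    return _render_parts(condition, components, config, channels).total


def build_templates(
    config: ParadigmConfig,
    components_by_condition: Mapping[str, list[ComponentSpec]] | None = None,
    channel_names: Sequence[str] | None = None,
) -> dict[str, ConditionTemplate]:
    """Templates for every condition (defaults from :func:`default_components`)."""
    channels = list(channel_names) if channel_names is not None else DEFAULT_CHANNELS
    out = {}
    for cond in CONDITIONS:
        comps = (
            components_by_condition[cond]
            if components_by_condition is not None
            else default_components(cond)
        )
        out[cond] = _render_parts(cond, comps, config, channels)
    return out


# ---------------------------------------------------------------------------
# epoch synthesis
# ---------------------------------------------------------------------------


def _pink_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_samples: int,
    sd: float,
    dtype=np.float64,
) -> np.ndarray:
    """1/f-power noise via spectrally shaped complex Gaussian spectra.

    The rFFT bins k >= 1 get amplitude proportional to f^(-1/2) (so power goes
    as 1/f); DC is zero.  The output is scaled so each sample has SD ``sd``.
    """
    if sd == 0:
        return np.zeros(shape + (n_samples,), dtype=dtype)
    n_bins = n_samples // 2 + 1
    k = np.arange(n_bins, dtype=float)
    profile = np.zeros(n_bins)
    profile[1:] = k[1:] ** -0.5
    z = rng.standard_normal(shape + (n_bins,), dtype=dtype) + 1j * rng.standard_normal(
        shape + (n_bins,), dtype=dtype
    )
    z *= profile.astype(dtype)
    if n_samples % 2 == 0:
        z[..., -1] = z[..., -1].real  # Nyquist bin must be real
    x = np.fft.irfft(z, n=n_samples, axis=-1).astype(dtype, copy=False)
    # stationary per-sample variance of the construction (see derivation in
    # docs/methods.md); normalise to the requested SD
    w2 = profile**2
    var = 4.0 * w2[1:].sum()
    if n_samples % 2 == 0:
        var -= 3.0 * w2[-1]  # real Nyquist bin is not doubled by the inverse rFFT
    var /= n_samples**2
    return x * dtype(sd / math.sqrt(var))


def synthesize_epochs(
    sequence: StimulusSequence,
    templates: Mapping[str, ConditionTemplate],
    noise: NoiseModel,
    config: ParadigmConfig,
    subject_id: str = "S01",
    block_id: object = 1,
    subject_scale: float = 1.0,
    dtype=np.float64,
) -> EpochsSet:
    """One noisy epoch per sequence event, time-locked, baseline-uncorrected.

    ``epoch = (obligatory + gain * subject_scale * deviance) * (1 + jitter)
    + pink + white``; deterministic given the noise seed.  ``subject_scale``
    multiplies deviance components only and models between-subject response
    amplitude differences.  ``dtype=np.float32`` halves memory and runtime
    for large Monte-Carlo runs (the default keeps full precision).
    """
    noise.validate()
    conditions = np.asarray(sequence.condition)
    cond_names = list(templates)
    for cond in np.unique(conditions):
        if str(cond) not in templates:
            raise ConfigurationError(f"no template for condition {cond!r}")

    t = config.time_ms
    n_trials = sequence.n_events
    any_tpl = next(iter(templates.values()))
    n_channels = any_tpl.obligatory.shape[0]
    rng = np.random.default_rng(noise.seed)

    # deterministic draw order: jitter, then pink, then white
    jitter = (
        1.0 + rng.normal(0.0, noise.trial_amplitude_jitter, size=n_trials)
        if noise.trial_amplitude_jitter > 0
        else np.ones(n_trials)
    )
    signals = np.stack(
        [
            templates[c].obligatory
            + noise.block_presence_gain * subject_scale * templates[c].deviance
            for c in cond_names
        ]
    ).astype(dtype)
    lookup = {c: i for i, c in enumerate(cond_names)}
    uniq, inverse = np.unique(conditions, return_inverse=True)
    cond_idx = np.array([lookup[str(u)] for u in uniq])[inverse]
    data = signals[cond_idx] * jitter[:, None, None].astype(dtype)
    data += _pink_noise(
        rng, (n_trials, n_channels), len(t), noise.pink_sd_uV, dtype=dtype
    )
    if noise.white_sd_uV > 0:
        data += rng.standard_normal(data.shape, dtype=dtype) * dtype(
            noise.white_sd_uV
        )

    channel_names = list(DEFAULT_CHANNELS[:n_channels])
    if n_channels != len(DEFAULT_CHANNELS):
        channel_names = [f"CH{i}" for i in range(n_channels)]
    return EpochsSet(
        data=data,
        channel_names=channel_names,
        sampling_rate_hz=config.sampling_rate_hz,
        time_ms=t,
        condition=conditions.copy(),
        block_id=np.full(n_trials, block_id, dtype=object),
        subject_id=subject_id,
        rejected=np.zeros(n_trials, dtype=bool),
        post_deviant=sequence.post_deviant_flags(),
        meta={"seed": noise.seed, "block_presence_gain": noise.block_presence_gain},
    )


def simulate_block(
    config: ParadigmConfig,
    noise: NoiseModel,
    subject_id: str = "S01",
    block_id: object = 1,
    subject_scale: float = 1.0,
    templates: Mapping[str, ConditionTemplate] | None = None,
    dtype=np.float64,
) -> EpochsSet:
    """Sequence + templates + noise for a single recording block."""
    if templates is None:
        templates = build_templates(config)
    seq = generate_sequence(config)
    return synthesize_epochs(
        seq, templates, noise, config, subject_id, block_id, subject_scale,
        dtype=dtype,
    )


# ---------------------------------------------------------------------------
# multi-subject / multi-block scenarios
# ---------------------------------------------------------------------------

#: Between-subject SD of the multiplicative deviance-amplitude scale.
DEFAULT_SUBJECT_AMPLITUDE_SD = 0.5


def rectified_normal_moments(mu: float, sd: float) -> tuple[float, float]:
    """Mean and SD of max(0, N(mu, sd)) -- the subject-scale distribution."""
    if sd == 0:
        return max(mu, 0.0), 0.0
    from scipy.stats import norm

    a = mu / sd
    mean = mu * norm.cdf(a) + sd * norm.pdf(a)
    second = (mu**2 + sd**2) * norm.cdf(a) + mu * sd * norm.pdf(a)
    var = max(second - mean**2, 0.0)
    return mean, math.sqrt(var)


def simulate_subject(
    config: ParadigmConfig,
    noise: NoiseModel,
    subject_id: str,
    block_gains: Sequence[float],
    subject_scale: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    templates: Mapping[str, ConditionTemplate] | None = None,
    dtype=np.float64,
) -> list[EpochsSet]:
    """One subject's blocks; ``block_gains[i]`` is block i+1's presence gain.

    Every random draw flows from ``seed`` through independent per-block
    substreams (sequence order and noise both differ across blocks).
    """
    if templates is None:
        templates = build_templates(config)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(block_gains))
    blocks = []
    for i, (gain, child) in enumerate(zip(block_gains, children)):
        seq_seed, noise_seed = (int(s) % (2**31) for s in child.generate_state(2))
        cfg = replace(config, seed=seq_seed)
        nz = replace(noise, seed=noise_seed, block_presence_gain=float(gain))
        seq = generate_sequence(cfg)
        blocks.append(
            synthesize_epochs(
                seq, templates, nz, cfg, subject_id, block_id=i + 1,
                subject_scale=subject_scale, dtype=dtype,
            )
        )
    return blocks


def simulate_group(
    config: ParadigmConfig,
    noise: NoiseModel,
    n_subjects: int = 17,
    n_blocks: int = 5,
    subject_amplitude_sd: float = DEFAULT_SUBJECT_AMPLITUDE_SD,
    block_gains: Sequence[float] | None = None,
    subjects_blocks: Sequence[int] | None = None,
    seed: int = 0,
    templates: Mapping[str, ConditionTemplate] | None = None,
    dtype=np.float64,
) -> list[EpochsSet]:
    """A healthy-control style study: ``n_subjects`` x up to ``n_blocks`` blocks.

    Subject amplitude scales are rectified-normal ``max(0, N(1,
    subject_amplitude_sd))`` draws, constant across a subject's blocks.
    ``subjects_blocks`` optionally gives each subject's block count (emulating
    participants who did not complete all blocks); default: all blocks.
    Returns a flat list of :class:`EpochsSet`, one per subject x block.
    """
    if templates is None:
        templates = build_templates(config)
    if block_gains is None:
        block_gains = [1.0] * n_blocks
    if subjects_blocks is None:
        subjects_blocks = [n_blocks] * n_subjects
    if len(subjects_blocks) != n_subjects:
        raise ConfigurationError("subjects_blocks must have one entry per subject")
    root = np.random.SeedSequence(seed)
    scale_rng = np.random.default_rng(root.spawn(1)[0])
    scales = np.maximum(
        0.0, scale_rng.normal(1.0, subject_amplitude_sd, size=n_subjects)
    )
    subject_seeds = root.spawn(n_subjects)
    out: list[EpochsSet] = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        nb = int(subjects_blocks[i])
        out.extend(
            simulate_subject(
                config,
                noise,
                sid,
                block_gains[:nb],
                subject_scale=float(scales[i]),
                seed=subject_seeds[i],
                templates=templates,
                dtype=dtype,
            )
        )
    return out


# ---------------------------------------------------------------------------
# programmed effect size
# ---------------------------------------------------------------------------


def template_window_mean(
    template: ConditionTemplate,
    config: ParadigmConfig,
    window_ms: tuple[float, float],
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    roi: Sequence[str] | None = None,
    channel_names: Sequence[str] | None = None,
) -> float:
    """Mean deviance amplitude over ``window_ms`` after baseline subtraction.

    This is the signal half of the programmed effect: the window-mean of the
    ROI-averaged deviance template, minus its baseline mean (matching what
    the preprocessing applies to every trial).
    """
    channels = list(channel_names) if channel_names is not None else DEFAULT_CHANNELS
    roi = list(roi) if roi is not None else channels
    idx = [channels.index(c) for c in roi]
    t = config.time_ms
    series = template.deviance[idx].mean(axis=0)
    win = (t >= window_ms[0]) & (t <= window_ms[1])
    base = (t >= baseline_ms[0]) & (t <= baseline_ms[1])
    return float(series[win].mean() - series[base].mean())


def residual_window_sd(
    noise: NoiseModel,
    config: ParadigmConfig,
    window_ms: tuple[float, float],
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    n_channels: int = len(DEFAULT_CHANNELS),
    bandpass_hz: tuple[float, float] | None = (0.1, 30.0),
    n_mc: int = 4000,
    seed: int = 987654321,
) -> float:
    """SD of the per-trial window-mean ROI noise after the standard pipeline.

    Monte-Carlo estimate on noise-only trials passed through band-pass
    filtering and baseline correction (fixed internal seed; n_mc = 4000 gives
    ~1% precision, far below the between-subject term it is combined with).
    """
    from .preprocess import bandpass_array

    t = config.time_ms
    rng = np.random.default_rng(seed)
    x = _pink_noise(rng, (n_mc, n_channels), len(t), noise.pink_sd_uV)
    if noise.white_sd_uV > 0:
        x = x + rng.normal(0.0, noise.white_sd_uV, size=x.shape)
    if bandpass_hz is not None:
        x = bandpass_array(x, config.sampling_rate_hz, *bandpass_hz)
    roi = x.mean(axis=1)  # (n_mc, samples)
    win = (t >= window_ms[0]) & (t <= window_ms[1])
    base = (t >= baseline_ms[0]) & (t <= baseline_ms[1])
    stat = roi[:, win].mean(axis=1) - roi[:, base].mean(axis=1)
    return float(stat.std(ddof=1))


def programmed_group_effect(
    config: ParadigmConfig,
    noise: NoiseModel,
    deviant: str = "duration",
    window_ms: tuple[float, float] | None = None,
    subject_amplitude_sd: float = DEFAULT_SUBJECT_AMPLITUDE_SD,
    templates: Mapping[str, ConditionTemplate] | None = None,
    bandpass_hz: tuple[float, float] | None = (0.1, 30.0),
) -> float:
    """Programmed standardized effect (population Cohen's d) of the paired
    group design on the window-mean difference amplitude.

    delta = (Delta * E[s]) / sqrt((Delta * SD[s])^2 + sigma_resid^2) where
    Delta is the deviance-template window mean, s the rectified-normal
    subject scale and sigma_resid the trial-noise contribution to a subject's
    evoked difference (noise SD per trial scaled by sqrt(1/n_dev + 1/n_std)).
    """
    if templates is None:
        templates = build_templates(config)
    if window_ms is None:
        # 100 ms centred on the deviance peak of the configured template
        t = config.time_ms
        series = templates[deviant].deviance.mean(axis=0)
        post = t >= 0
        peak = t[post][np.argmin(series[post])]
        window_ms = (peak - 50.0, peak + 50.0)
    tpl = templates[deviant]
    if bandpass_hz is not None:
        # the programmed effect is the effect the pipeline sees: apply the
        # same band-pass to the deviance template
        from .preprocess import bandpass_array

        tpl = ConditionTemplate(
            tpl.condition,
            tpl.obligatory,
            bandpass_array(tpl.deviance, config.sampling_rate_hz, *bandpass_hz),
        )
    delta_uV = template_window_mean(tpl, config, window_ms)
    counts = config.condition_counts()
    n_dev, n_std = counts[deviant], counts[STANDARD]
    sigma_trial = residual_window_sd(noise, config, window_ms, bandpass_hz=bandpass_hz)
    sigma_resid = sigma_trial * math.sqrt(1.0 / n_dev + 1.0 / n_std)
    mean_s, sd_s = rectified_normal_moments(1.0, subject_amplitude_sd)
    num = delta_uV * mean_s
    denom = math.sqrt((delta_uV * sd_s) ** 2 + sigma_resid**2)
    return num / denom
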