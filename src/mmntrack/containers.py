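"""In-memory containers for epoched EEG and averaged (evoked) responses.

All voltages are in microvolts, all times in milliseconds relative to
stimulus onset.  Epochs are stored as a dense ``trials x channels x samples``
tensor together with per-trial labels (condition, block, rejection flag), the
shape every downstream statistic in this package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, MissingChannelError


@dataclass
class EpochsSet:
    """Baseline-locked single trials: ``data[trial, channel, sample]``.

    ``time_ms`` must be strictly increasing with uniform spacing
    ``1000 / sampling_rate_hz``; ``condition``, ``block_id``, ``rejected`` and
    ``post_deviant`` are per-trial vectors of equal length.
    """

    data: np.ndarray
    channel_names: list[str]
    sampling_rate_hz: float
    time_ms: np.ndarray
    condition: np.ndarray
    block_id: np.ndarray
    subject_id: str = "S01"
    rejected: np.ndarray | None = None
    post_deviant: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.condition = np.asarray(self.condition)
        self.block_id = np.asarray(self.block_id)
        if self.rejected is None:
            self.rejected = np.zeros(self.n_trials, dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.post_deviant is None:
            self.post_deviant = np.zeros(self.n_trials, dtype=bool)
        self.post_deviant = np.asarray(self.post_deviant, dtype=bool)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ConfigurationError(
                f"epochs tensor must be 3-D (trials x channels x samples), got {self.data.shape}"
            )
        n, c, t = self.data.shape
        if len(self.channel_names) != c:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if self.time_ms.shape != (t,):
            raise ConfigurationError("time_ms length must match sample count")
        dt = np.diff(self.time_ms)
        if t > 1:
            if not np.all(dt > 0):
                raise ConfigurationError("time_ms must be strictly increasing")
            expected = 1000.0 / self.sampling_rate_hz
            if not np.allclose(dt, expected, rtol=1e-9, atol=1e-9):
                raise ConfigurationError(
                    "time_ms spacing must equal 1000 / sampling_rate_hz"
                )
        for name, arr in (
            ("condition", self.condition),
            ("block_id", self.block_id),
            ("rejected", self.rejected),
            ("post_deviant", self.post_deviant),
        ):
            if len(arr) != n:
                raise ConfigurationError(f"per-trial field {name!r} has wrong length")

    # -- selection ---------------------------------------------------------
    def select(self, mask: np.ndarray) -> "EpochsSet":
        """Return a new EpochsSet containing only trials where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            data=self.data[mask],
            condition=self.condition[mask],
            block_id=self.block_id[mask],
            rejected=self.rejected[mask],
            post_deviant=self.post_deviant[mask],
        )

    def pick_channels(self, names: Sequence[str]) -> np.ndarray:
        """Indices of ``names`` in channel order; explicit error when absent."""
        idx = []
        for nm in names:
            if nm not in self.channel_names:
                raise MissingChannelError(
                    f"channel {nm!r} not present; available: {self.channel_names}"
                )
            idx.append(self.channel_names.index(nm))
        return np.asarray(idx, dtype=int)

    def condition_counts(self, include_rejected: bool = True) -> dict[str, int]:
        cond = self.condition if include_rejected else self.condition[~self.rejected]
        values, counts = np.unique(cond, return_counts=True)
        return {str(v): int(c) for v, c in zip(values, counts)}


@dataclass
class EvokedResponse:
    """Per-condition average: ``data[channel, sample]`` on the source time grid."""

    data: np.ndarray
    channel_names: list[str]
    sampling_rate_hz: float
    time_ms: np.ndarray
    condition: str
    block_id: object
    subject_id: str
    n_trials_averaged: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("evoked data must be 2-D (channels x samples)")
        if self.n_trials_averaged < 1:
            raise ConfigurationError("n_trials_averaged must be >= 1")

    def pick_channels(self, names: Sequence[str]) -> np.ndarray:
        idx = []
        for nm in names:
            if nm not in self.channel_names:
                raise MissingChannelError(
                    f"channel {nm!r} not present; available: {self.channel_names}"
                )
            idx.append(self.channel_names.index(nm))
        return np.asarray(idx, dtype=int)


@dataclass
class RoiSeries:
    """Mean over a set of region-of-interest channels.

    ``values`` is ``(samples,)`` for an evoked/difference source or
    ``(trials, samples)`` when computed trial-wise.
    """

    values: np.ndarray
    time_ms: np.ndarray
    source: str  # "evoked-difference" | "evoked" | "trial"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.values.shape[-1] != self.time_ms.shape[0]:
            raise ConfigurationError("RoiSeries length must match the time grid")
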