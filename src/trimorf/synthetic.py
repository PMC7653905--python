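"""Synthetic disordered-protein benchmark generator.

Emulates the regime of the MoRF benchmark sets: every sequence carries
exactly one MoRF of length 5-25, MoRFs fall partly into a terminal
zone with a configurable probability, and the predicted structural
channels are plausible label-independent noise except for one signal
channel (by default the upper alpha half-sphere exposure count,
``HSEa_up``) whose mean is shifted inside the MoRF.

The signal channel's background noise is moving-average smoothed to
mimic the residue-level autocorrelation of real structural predictors;
the MoRF mean shift is added after smoothing so that the realised
between-class mean difference equals ``effect_size * background_sd``
exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import DEFAULT_FLANK
from .types import AMINO_ACIDS, CHANNELS, AnnotatedSequence, StructuralTrace, Zone


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``effect_size`` is the MoRF mean shift of the signal channel in
    units of ``background_sd``; ``terminal_placement_prob`` is the
    probability that a MoRF touches a terminal zone (otherwise it lies
    fully in the middle zone); ``smoothing_halfwidth`` is the moving-
    average half-width applied to the signal channel's noise.
    """

    n_sequences: int = 100
    length_range: tuple[int, int] = (60, 600)
    morf_length_range: tuple[int, int] = (5, 25)
    terminal_placement_prob: float = 0.3
    signal_channel: str = "HSEa_up"
    background_mean: float = 13.0
    background_sd: float = 3.0
    effect_size: float = 2.0
    smoothing_halfwidth: int = 2
    flank: int = DEFAULT_FLANK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise SimulationError("n_sequences must be >= 1")
        lo, hi = self.length_range
        mlo, mhi = self.morf_length_range
        if not (1 <= lo <= hi) or not (1 <= mlo <= mhi):
            raise SimulationError("ranges must be ordered and positive")
        if mhi > lo:
            raise SimulationError(
                "shortest sequence cannot hold the longest MoRF"
            )
        if not 0 <= self.terminal_placement_prob <= 1:
            raise SimulationError("terminal_placement_prob must be in [0, 1]")
        if self.background_sd <= 0:
            raise SimulationError("background_sd must be positive")
        if self.signal_channel not in CHANNELS:
            raise SimulationError(
                f"unknown signal channel {self.signal_channel!r}"
            )
        if self.smoothing_halfwidth < 0:
            raise SimulationError("smoothing_halfwidth must be >= 0")


def _smooth(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Truncated moving average with window 2 * halfwidth + 1."""
    if halfwidth == 0:
        return x
    kernel = np.ones(2 * halfwidth + 1)
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same"
    )


def _place_morf(
    n: int, config: SimConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Pick the MoRF interval (1-based inclusive) for a length-n sequence."""
    mlo, mhi = config.morf_length_range
    flank = config.flank
    terminal = rng.random() < config.terminal_placement_prob
    if not terminal:
        middle_width = n - 2 * flank
        if middle_width < mlo:
            # sequence too short to host any fully-middle MoRF
            terminal = True
        else:
            length = int(rng.integers(mlo, min(mhi, middle_width) + 1))
            start = int(rng.integers(flank + 1, n - flank - length + 2))
            return start, start + length - 1
    length = int(rng.integers(mlo, min(mhi, n) + 1))
    if rng.random() < 0.5:  # left terminus
        start = int(rng.integers(1, min(flank, n - length + 1) + 1))
    else:  # right terminus: end must reach past n - flank
        lo_start = max(1, n - flank - length + 2)
        start = int(rng.integers(lo_start, n - length + 2))
    return start, start + length - 1


def _background_channels(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Label-independent plausible values for every channel."""
    ss = rng.gamma(2.0, 1.0, size=(n, 3))
    ss /= ss.sum(axis=1, keepdims=True)
    return {
        "SS_H": ss[:, 0],
        "SS_E": ss[:, 1],
        "SS_C": ss[:, 2],
        "ASA": rng.beta(2.0, 2.0, size=n),
        "PHI": np.clip(rng.normal(-75.0, 40.0, size=n), -180.0, 180.0),
        "PSI": np.clip(rng.normal(145.0, 60.0, size=n), -180.0, 180.0),
        "THETA": np.clip(rng.normal(105.0, 15.0, size=n), 0.0, 180.0),
        "TAU": np.clip(rng.normal(50.0, 100.0, size=n), -180.0, 180.0),
        "HSEa_up": np.maximum(rng.normal(13.0, 3.0, size=n), 0.0),
        "HSEa_dn": np.maximum(rng.normal(15.0, 4.0, size=n), 0.0),
        "HSEb_up": np.maximum(rng.normal(12.0, 4.0, size=n), 0.0),
        "HSEb_dn": np.maximum(rng.normal(16.0, 4.0, size=n), 0.0),
        "CN": np.maximum(rng.normal(25.0, 6.0, size=n), 0.0),
    }


def simulate_dataset(
    config: SimConfig,
) -> list[tuple[AnnotatedSequence, StructuralTrace]]:
    """Generate ``n_sequences`` annotated sequences with aligned traces.

    Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    dataset = []
    for i in range(config.n_sequences):
        n = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        start, end = _place_morf(n, config, rng)
        labels = np.zeros(n, dtype=bool)
        labels[start - 1:end] = True

        channels = _background_channels(n, rng)
        noise = rng.normal(config.background_mean, config.background_sd, size=n)
        signal = _smooth(noise, config.smoothing_halfwidth).copy()
        signal[labels] += config.effect_size * config.background_sd
        channels[config.signal_channel] = signal

        seq = AnnotatedSequence(id=f"syn{i:04d}", residues=residues, labels=labels)
        trace = StructuralTrace(
            seq_id=seq.id,
            channels=CHANNELS,
            values=np.column_stack([channels[c] for c in CHANNELS]),
        )
        dataset.append((seq, trace))
    return dataset


def dataset_summary(
    dataset: list[tuple[AnnotatedSequence, StructuralTrace]],
    flank: int = DEFAULT_FLANK,
) -> dict:
    """Composition report: residue totals, MoRF-zone split, length histogram."""
    if not dataset:
        raise SimulationError("empty dataset")
    from .segmentation import run_zones, zone_of

    total = morf_total = 0
    zone_counts = {Zone.TERMINAL.value: 0, Zone.MIDDLE.value: 0}
    length_hist: dict[int, int] = {}
    n_morfs = n_touching_terminal = 0
    for seq, _trace in dataset:
        n = len(seq)
        total += n
        morf_total += int(seq.labels.sum())
        for j in np.flatnonzero(seq.labels) + 1:
            zone_counts[zone_of(int(j), n, flank).value] += 1
        for start, end in seq.morf_runs():
            n_morfs += 1
            length = end - start + 1
            length_hist[length] = length_hist.get(length, 0) + 1
            if Zone.TERMINAL in run_zones(start, end, n, flank):
                n_touching_terminal += 1
    return {
        "n_sequences": len(dataset),
        "total_residues": total,
        "morf_residues": morf_total,
        "non_morf_residues": total - morf_total,
        "morf_residues_by_zone": zone_counts,
        "n_morfs": n_morfs,
        "morf_length_histogram": dict(sorted(length_hist.items())),
        "frac_morfs_touching_terminal": n_touching_terminal / n_morfs,
    }
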