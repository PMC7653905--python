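"""Core domain types shared across the trimorf pipeline.

All residue coordinates exposed to users and files are 1-based and
inclusive; slicing into numpy arrays converts at the call site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: The 20 standard amino acids; X marks an unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Canonical structural channel names, in file order.
CHANNELS = (
    "SS_H", "SS_E", "SS_C",   # 3-state secondary-structure probabilities
    "ASA",                     # accessible surface area
    "PHI", "PSI", "THETA", "TAU",   # backbone angles
    "HSEa_up", "HSEa_dn",      # half-sphere exposure, alpha variant
    "HSEb_up", "HSEb_dn",      # half-sphere exposure, beta variant
    "CN",                      # contact number
)


class Zone(str, Enum):
    """Sequence zone of a residue: within `flank` of a terminus, or not."""

    TERMINAL = "terminal"
    MIDDLE = "middle"


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class AnnotatedSequence:
    """A protein sequence with per-residue MoRF labels.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header word).
    residues : str
        Upper-case amino-acid string (20-letter alphabet plus X).
    labels : numpy.ndarray of bool
        True where the residue belongs to a MoRF region; same length
        as ``residues``.
    """

    id: str
    residues: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=bool)
        object.__setattr__(self, "labels", labels)
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        if labels.shape != (len(self.residues),):
            raise ValueError(
                f"sequence {self.id!r}: {labels.size} labels for "
                f"{len(self.residues)} residues"
            )
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def morf_runs(self) -> list[tuple[int, int]]:
        """Maximal MoRF runs as 1-based inclusive (start, end) pairs."""
        runs: list[tuple[int, int]] = []
        start = None
        for i, lab in enumerate(self.labels):
            if lab and start is None:
                start = i
            elif not lab and start is not None:
                runs.append((start + 1, i))
                start = None
        if start is not None:
            runs.append((start + 1, len(self.labels)))
        return runs


@dataclass(frozen=True)
class StructuralTrace:
    """Per-residue matrix of named structural channels for one sequence."""

    seq_id: str
    channels: tuple[str, ...]
    values: np.ndarray  # rows = residues, columns = channels

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channels", tuple(self.channels))
        if values.ndim != 2:
            raise ValueError("trace values must be a 2-D matrix")
        if values.shape[1] != len(self.channels):
            raise ValueError(
                f"trace {self.seq_id!r}: {values.shape[1]} columns for "
                f"{len(self.channels)} channel names"
            )
        if values.shape[0] == 0:
            raise ValueError(f"trace {self.seq_id!r} has no rows")
        if not np.isfinite(values).all():
            raise ValueError(f"trace {self.seq_id!r} contains non-finite values")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channel names {sorted(unknown)}")
        ss = [c for c in ("SS_H", "SS_E", "SS_C") if c in self.channels]
        if len(ss) == 3:
            cols = [self.channels.index(c) for c in ss]
            probs = values[:, cols]
            if (probs < -1e-9).any() or (probs > 1 + 1e-9).any():
                raise ValueError("SS probabilities outside [0, 1]")
            sums = probs.sum(axis=1)
            if ((sums < 0.99) | (sums > 1.01)).any():
                raise ValueError("SS probabilities do not sum to 1 (±0.01)")

    def __len__(self) -> int:
        return self.values.shape[0]

    def column(self, channel: str) -> np.ndarray:
        try:
            j = self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"trace {self.seq_id!r} has no channel {channel!r}"
            ) from None
        return self.values[:, j]


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue real-valued MoRF propensity scores for one sequence.

    ``stage`` records where in the pipeline the scores came from:
    ``raw`` (classifier output), ``processed`` (windowed max/median
    smoothing) or ``combined`` (ensemble average).
    """

    seq_id: str
    scores: np.ndarray
    stage: str = "raw"
    residues: str | None = None

    _STAGES = ("raw", "processed", "combined")

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D vector")
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.residues is not None and len(self.residues) != scores.size:
            raise ValueError("residues/scores length mismatch")

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class StructuralMatrix:
    """An ``l x u`` slice of a trace: rows are consecutive residues of
    one segment, columns the selected channels in request order."""

    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("structural matrix must be l x u with l, u >= 1")
        if values.shape[1] != len(self.channel_names):
            raise ValueError("channel name count does not match columns")


@dataclass(frozen=True)
class Segment:
    """A 1-based inclusive residue interval used for training.

    Positive segments cover a MoRF run plus its flanks; negative
    segments are label-free intervals of matching length and zone.
    """

    seq_id: str
    start: int
    end: int
    polarity: Polarity
    zone: Zone

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid segment bounds [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class QuerySample:
    """The scoring window around one query residue.

    The window spans ``max(1, j - flank) .. min(n, j + flank)`` and is
    truncated at the sequence termini, so terminal-zone samples are
    shorter than the full ``2 * flank + 1`` residues.
    """

    seq_id: str
    position: int
    start: int
    end: int
    zone: Zone

    def __post_init__(self) -> None:
        if not self.start <= self.position <= self.end:
            raise ValueError("query position outside its own window")
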