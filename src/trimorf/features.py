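"""Structural matrices and auto-covariance feature vectors.

A segment of length ``l`` over ``u`` selected channels yields an
``l x u`` structural matrix ``M``.  Its auto-covariance features are
the lagged raw second moments

    AC(k, j) = (1 / l) * sum_{i = 1 .. l - k} M[i, j] * M[i + k, j]

for lags ``k = 1 .. df`` and channels ``j = 1 .. u``, flattened
channel-major (all lags of channel 1, then channel 2, ...) into a
fixed-length vector of ``df * u`` reals.  Channels are deliberately
*not* mean-centered first: the statistic is a raw second moment, not
the mean-centered quantity usually called auto-covariance, and the
classifier consumes it as-is.  When ``k >= l`` the sum is empty and
the lag contributes 0, which keeps the vector length fixed for short
segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import QuerySample, Segment, StructuralMatrix, StructuralTrace

DEFAULT_DF = 10


@dataclass(frozen=True)
class FeatureConfig:
    """Which channels feed the structural matrix and how many lags.

    The default single channel is the upper-sphere count of the
    alpha-variant half-sphere exposure (``HSEa_up``), the attribute a
    forward channel search leaves as the best single predictor; adding
    further channels is a configuration change, not a code change.
    """

    channels: tuple[str, ...] = ("HSEa_up",)
    df: int = DEFAULT_DF

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if not self.channels:
            raise ValueError("at least one channel is required")
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def n_features(self) -> int:
        return self.df * len(self.channels)


def build_matrix(
    trace: StructuralTrace, start: int, end: int, channels: tuple[str, ...]
) -> StructuralMatrix:
    """Slice residues ``start..end`` (1-based inclusive) of the given
    channels into an ``l x u`` matrix, columns in requested order."""
    n = len(trace)
    if not 1 <= start <= end <= n:
        raise ValueError(f"bad bounds [{start}, {end}] for trace of length {n}")
    cols = [trace.column(ch) for ch in channels]
    values = np.column_stack(cols)[start - 1:end, :]
    return StructuralMatrix(values=values, channel_names=tuple(channels))


def autocovariance(matrix: StructuralMatrix, df: int = DEFAULT_DF) -> np.ndarray:
    """Lagged second-moment features, flattened channel-major.

    Returns a vector of length ``df * u``; entry ``j * df + (k - 1)``
    holds lag ``k`` of channel ``j`` (0-based ``j``).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    m = matrix.values
    l, u = m.shape
    ac = np.zeros((u, df))
    for k in range(1, min(df, l - 1) + 1):
        ac[:, k - 1] = np.einsum("ij,ij->j", m[:-k, :], m[k:, :]) / l
    return ac.ravel()


def featurize(
    trace: StructuralTrace,
    segment_or_sample: Segment | QuerySample,
    config: FeatureConfig,
) -> np.ndarray:
    """Feature vector for a training segment or a query window.

    The code path is identical for both, so a trained classifier sees
    query windows through exactly the lens it was trained with.
    """
    s = segment_or_sample
    matrix = build_matrix(trace, s.start, s.end, config.channels)
    return autocovariance(matrix, config.df)
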