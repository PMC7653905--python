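"""Training and scoring of the two zone-specific SVM classifiers.

The terminal model is trained on segments whose MoRF run touches a
terminal zone, the middle model on segments whose run lies in the
middle zone.  Both are RBF-kernel support vector machines (C = 1000,
gamma = 0.0038, values carried over from prior MoRF work on similar
features) over z-scored auto-covariance features.  At query time each
residue's truncated window is featurized and routed to the model of
its zone; decision values are min-max normalised to [0, 1] using the
bounds observed on that model's own training samples, clipping
anything outside.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import joblib
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureConfig, featurize
from .segmentation import DEFAULT_FLANK, enumerate_query_samples, extract_training_segments
from .types import AnnotatedSequence, Polarity, ScoreTrack, StructuralTrace, Zone

BUNDLE_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Raised when a zone has no usable training material."""


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"
    C: float = 1000.0
    gamma: float = 0.0038

    def __post_init__(self) -> None:
        if self.kernel.lower() != "rbf":
            raise ValueError("only the RBF kernel is supported")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class ZoneModel:
    """One trained classifier with its scaler and score bounds."""

    estimator: SVC
    scaler: StandardScaler
    score_low: float
    score_high: float
    n_pos: int
    n_neg: int

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return self.estimator.decision_function(self.scaler.transform(features))

    def normalized_scores(self, features: np.ndarray) -> np.ndarray:
        raw = self.decision_values(features)
        span = self.score_high - self.score_low
        return np.clip((raw - self.score_low) / span, 0.0, 1.0)


@dataclass
class ModelBundle:
    """The trained terminal + middle models with their configuration.

    ``manifest`` records the seed, per-model positive/negative sample
    counts and a fingerprint of the training data, so two bundles
    trained identically are verifiably identical.
    """

    terminal_model: ZoneModel
    middle_model: ZoneModel
    feature_config: FeatureConfig
    svm_config: SvmConfig
    flank: int
    manifest: dict = field(default_factory=dict)

    def model_for(self, zone: Zone) -> ZoneModel:
        return self.terminal_model if zone is Zone.TERMINAL else self.middle_model

    def save(self, path: str) -> None:
        joblib.dump({"format_version": BUNDLE_FORMAT_VERSION, "bundle": self}, path)

    @classmethod
    def load(cls, path: str) -> "ModelBundle":
        payload = joblib.load(path)
        if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported bundle format {payload.get('format_version')!r}"
            )
        return payload["bundle"]


def _dataset_fingerprint(
    dataset: Sequence[tuple[AnnotatedSequence, StructuralTrace]]
) -> str:
    h = hashlib.sha256()
    for seq, trace in dataset:
        h.update(seq.id.encode())
        h.update(seq.residues.encode())
        h.update(seq.labels.tobytes())
        h.update(np.ascontiguousarray(trace.values).tobytes())
    return h.hexdigest()[:16]


def _fit_zone_model(
    features: np.ndarray, labels: np.ndarray, svm: SvmConfig, zone: Zone
) -> ZoneModel:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise TrainingError(
            f"{zone.value} model: need both classes, got {n_pos} positive "
            f"and {n_neg} negative segments"
        )
    scaler = StandardScaler().fit(features)
    est = SVC(kernel="rbf", C=svm.C, gamma=svm.gamma)
    est.fit(scaler.transform(features), labels.astype(int))
    train_dec = est.decision_function(scaler.transform(features))
    low, high = float(train_dec.min()), float(train_dec.max())
    if not low < high:
        # degenerate but possible on tiny data; keep normalisation valid
        high = low + 1e-9
    return ZoneModel(est, scaler, low, high, n_pos, n_neg)


def train_bundle(
    dataset: Sequence[tuple[AnnotatedSequence, StructuralTrace]],
    svm: SvmConfig | None = None,
    feature_config: FeatureConfig | None = None,
    flank: int = DEFAULT_FLANK,
    seed: int = 0,
    pooled: bool = False,
) -> ModelBundle:
    """Train the terminal/middle model pair on annotated sequences.

    Segments are extracted per sequence (balanced positives/negatives,
    negative placement seeded from ``seed``), featurized, and routed to
    their zone's model.  With ``pooled=True`` a single classifier is
    fitted on all segments and installed for both zones — the ablation
    baseline against which the two-model design is compared.
    """
    if not dataset:
        raise TrainingError("empty training dataset")
    svm = svm or SvmConfig()
    feature_config = feature_config or FeatureConfig()
    rng = np.random.default_rng(seed)

    feats: dict[Zone, list[np.ndarray]] = {Zone.TERMINAL: [], Zone.MIDDLE: []}
    labs: dict[Zone, list[int]] = {Zone.TERMINAL: [], Zone.MIDDLE: []}
    for seq, trace in dataset:
        if len(trace) != len(seq):
            raise TrainingError(
                f"trace/sequence length mismatch for {seq.id!r}"
            )
        for seg in extract_training_segments(seq, flank=flank, rng=rng):
            feats[seg.zone].append(featurize(trace, seg, feature_config))
            labs[seg.zone].append(1 if seg.polarity is Polarity.POSITIVE else 0)

    def stack(zone: Zone) -> tuple[np.ndarray, np.ndarray]:
        if not feats[zone]:
            raise TrainingError(f"{zone.value} model: no training segments")
        return np.vstack(feats[zone]), np.asarray(labs[zone])

    if pooled:
        x = np.vstack([np.vstack(feats[z]) for z in feats if feats[z]])
        y = np.concatenate([np.asarray(labs[z]) for z in labs if labs[z]])
        shared = _fit_zone_model(x, y, svm, Zone.MIDDLE)
        terminal = middle = shared
        counts = {
            "pooled": {"n_pos": shared.n_pos, "n_neg": shared.n_neg},
        }
    else:
        xt, yt = stack(Zone.TERMINAL)
        xm, ym = stack(Zone.MIDDLE)
        terminal = _fit_zone_model(xt, yt, svm, Zone.TERMINAL)
        middle = _fit_zone_model(xm, ym, svm, Zone.MIDDLE)
        counts = {
            "terminal": {"n_pos": terminal.n_pos, "n_neg": terminal.n_neg},
            "middle": {"n_pos": middle.n_pos, "n_neg": middle.n_neg},
        }

    manifest = {
        "seed": int(seed),
        "flank": int(flank),
        "pooled": bool(pooled),
        "n_sequences": len(dataset),
        "samples": counts,
        "feature_config": {"channels": list(feature_config.channels),
                           "df": feature_config.df},
        "svm": asdict(svm),
        "dataset_fingerprint": _dataset_fingerprint(dataset),
    }
    return ModelBundle(terminal, middle, feature_config, svm, flank, manifest)


def score_sequence(
    bundle: ModelBundle, seq: str, trace: StructuralTrace
) -> ScoreTrack:
    """Raw per-residue MoRF propensity scores in [0, 1].

    Each residue's truncated window is featurized exactly as training
    segments were; terminal-zone residues are scored by the terminal
    model, middle-zone residues by the middle model.  Sequences of
    length <= 2 * flank have no middle zone and are scored entirely by
    the terminal model.
    """
    n = len(seq)
    if len(trace) != n:
        raise ValueError(
            f"trace has {len(trace)} rows for sequence of length {n}"
        )
    samples = enumerate_query_samples(n, flank=bundle.flank, seq_id=trace.seq_id)
    features = np.vstack(
        [featurize(trace, s, bundle.feature_config) for s in samples]
    )
    scores = np.empty(n)
    for zone in (Zone.TERMINAL, Zone.MIDDLE):
        idx = np.array([i for i, s in enumerate(samples) if s.zone is zone])
        if idx.size:
            scores[idx] = bundle.model_for(zone).normalized_scores(features[idx])
    return ScoreTrack(seq_id=trace.seq_id, scores=scores, stage="raw",
                      residues=seq)
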