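"""Reconstruction-deviation profiles and the novelty boundary.

The driver model proposes K stochastic reconstructions per window; the
*minimum deviation* — per channel, the smallest mean absolute reconstruction
error across the K samples — is the frame's novelty feature. An isolation
forest fitted on the deviation vectors of normal training frames defines the
boundary of normal driving; frames outside it are flagged anomalous.

Deviations are computed on z-scored data (channels have incommensurate
units); explanation output denormalizes for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.ensemble import IsolationForest
from sklearn.utils.validation import check_is_fitted

from .driver_model import CategoricalPriorVAE
from .records import CHANNELS, N_CHANNELS, NormalizationStats, WindowBatch


@dataclass
class DeviationProfile:
    """Per-frame minimum reconstruction deviations for one record.

    ``deviations`` is T x N (elementwise minimum over samples, per channel);
    ``best_reconstruction`` holds, per frame, the reconstruction of the
    sample with the smallest *total* deviation (kept for explanation, may be
    None when not retained), shape T x (N*L').
    """

    record_id: str
    status: str
    center_frames: np.ndarray
    deviations: np.ndarray
    best_reconstruction: np.ndarray | None = None
    inputs_central: np.ndarray | None = None
    recon_frames: int = field(default=0)

    @property
    def n_frames(self) -> int:
        return self.deviations.shape[0]

    def to_frame(self, flags: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.deviations,
                          columns=[f"dev_{c}" for c in CHANNELS])
        df.insert(0, "frame", self.center_frames)
        if flags is not None:
            df["flag"] = flags.astype(int)
        return df


@dataclass
class FrameFlags:
    """Per-frame binary status predictions for one record (1 = anomalous)."""

    record_id: str
    status: str
    flags: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.flags.shape[0]


def sample_reconstructions(model: CategoricalPriorVAE, windows: WindowBatch,
                           K: int, rng: np.random.Generator) -> list[np.ndarray]:
    """K independent stochastic reconstructions of every window.

    Each draw runs categorical head → posterior → reparameterize → decode.
    Materializes K arrays of shape (B, N*L'); for large batches prefer
    :func:`deviation_profile`, which streams the same sample sequence.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    return [model.sample_reconstruction(windows.data, rng) for _ in range(K)]


def min_deviation(windows: WindowBatch,
                  reconstructions: Iterable[np.ndarray],
                  model: CategoricalPriorVAE,
                  keep_reconstruction: bool = True) -> DeviationProfile:
    """Fold K reconstruction samples into a per-frame minimum-deviation profile.

    Per channel the deviation is the elementwise minimum across samples of
    the mean absolute error over the L' span; the retained reconstruction is
    the one minimizing the total (channel-mean) deviation.
    """
    x_c = model.central_span(windows.data)
    B = windows.n_windows
    Lp = model._l_prime
    dev_min = np.full((B, N_CHANNELS), np.inf)
    best_total = np.full(B, np.inf)
    best_recon = np.zeros_like(x_c) if keep_reconstruction else None
    got_any = False
    for x_hat in reconstructions:
        got_any = True
        err = np.abs(x_c - x_hat).reshape(B, N_CHANNELS, Lp).mean(axis=2)
        dev_min = np.minimum(dev_min, err)
        total = err.mean(axis=1)
        better = total < best_total
        best_total = np.where(better, total, best_total)
        if keep_reconstruction:
            best_recon[better] = x_hat[better]
    if not got_any:
        raise ValueError("no reconstruction samples supplied")
    rid = windows.record_ids[0] if B else ""
    status = windows.labels[0] if windows.labels is not None and B else "normal"
    return DeviationProfile(
        record_id=str(rid), status=str(status),
        center_frames=windows.center_frames.copy(),
        deviations=dev_min, best_reconstruction=best_recon,
        inputs_central=x_c if keep_reconstruction else None,
        recon_frames=Lp)


def deviation_profile(model: CategoricalPriorVAE, windows: WindowBatch,
                      K: int, rng: np.random.Generator,
                      keep_reconstruction: bool = True) -> DeviationProfile:
    """Stream K sampled reconstructions into a profile without holding all K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    gen = (model.sample_reconstruction(windows.data, rng) for _ in range(K))
    return min_deviation(windows, gen, model,
                         keep_reconstruction=keep_reconstruction)


class DeviationIsolationForest(BaseEstimator, OutlierMixin):
    """Isolation-forest boundary on per-frame deviation vectors.

    Fitted on normal-status deviations only; ``contamination`` sets the
    fraction of the fitting data allowed outside the boundary. ``mode``
    selects the 6-dimensional per-channel vector ("vector", default) or the
    scalar total deviation ("scalar") as the detector input.
    """

    def __init__(self, contamination=0.01, n_trees=100, subsample_size=256,
                 mode="vector", random_state=0):
        self.contamination = contamination
        self.n_trees = n_trees
        self.subsample_size = subsample_size
        self.mode = mode
        self.random_state = random_state

    def _features(self, D: np.ndarray) -> np.ndarray:
        if self.mode == "vector":
            return D
        if self.mode == "scalar":
            return D.mean(axis=1, keepdims=True)
        raise ValueError(f"unknown mode {self.mode!r}")

    def fit(self, X, y=None):
        """X: (n_frames, N) deviation vectors from normal training records."""
        X = np.asarray(X, dtype=float)
        if not (0 < self.contamination < 0.5):
            raise ValueError("contamination must lie in (0, 0.5)")
        max_samples = self.subsample_size
        if X.shape[0] < max_samples:
            warnings.warn(
                f"only {X.shape[0]} frames < subsample_size "
                f"{self.subsample_size}; fitting with reduced subsample")
            max_samples = X.shape[0]
        self.forest_ = IsolationForest(
            n_estimators=self.n_trees, max_samples=max_samples,
            contamination=self.contamination,
            random_state=self.random_state)
        self.forest_.fit(self._features(X))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Return per-frame flags: 1 = outside the normal boundary."""
        check_is_fitted(self, "forest_")
        raw = self.forest_.predict(self._features(np.asarray(X, dtype=float)))
        return (raw == -1).astype(int)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.decision_function(self._features(np.asarray(X, float)))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "DeviationIsolationForest":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise ValueError("archive does not contain a detector")
        return obj


def fit_detector(profiles: Sequence[DeviationProfile],
                 detector: DeviationIsolationForest | None = None,
                 **kwargs) -> DeviationIsolationForest:
    """Fit the novelty boundary on normal-record profiles (guarded)."""
    if not profiles:
        raise ValueError("no profiles supplied")
    bad = [p.record_id for p in profiles if p.status == "drunk"]
    if bad:
        raise ValueError(
            f"novelty detector must be fitted on normal-status records only; "
            f"got drunk records {bad}")
    if detector is None:
        detector = DeviationIsolationForest(**kwargs)
    D = np.concatenate([p.deviations for p in profiles], axis=0)
    return detector.fit(D)


def score(profile: DeviationProfile,
          detector: DeviationIsolationForest) -> FrameFlags:
    """Classify each frame's deviation vector inside (0) / outside (1)."""
    flags = detector.predict(profile.deviations)
    return FrameFlags(record_id=profile.record_id, status=profile.status,
                      flags=flags)


def explain(profile: DeviationProfile, frame: int,
            stats: NormalizationStats) -> pd.DataFrame:
    """Actual-vs-predicted series for one frame's central span, denormalized.

    Returns a tidy frame with one row per (channel, frame-offset) pair and
    the per-channel deviation; channels are ordered by decreasing deviation,
    so the largest contributor comes first.
    """
    if profile.best_reconstruction is None or profile.inputs_central is None:
        raise ValueError("profile does not retain reconstructions; "
                         "recompute with keep_reconstruction=True")
    pos = np.flatnonzero(profile.center_frames == frame)
    if pos.size == 0:
        raise ValueError(f"frame {frame} not present in profile")
    i = int(pos[0])
    Lp = profile.recon_frames
    actual = profile.inputs_central[i].reshape(N_CHANNELS, Lp)
    predicted = profile.best_reconstruction[i].reshape(N_CHANNELS, Lp)
    dev = profile.deviations[i]
    order = np.argsort(-dev)
    rows = []
    offsets = np.arange(Lp) - Lp // 2
    for rank, j in enumerate(order):
        act = actual[j] * stats.std[j] + stats.mean[j]
        pred = predicted[j] * stats.std[j] + stats.mean[j]
        for off, a, p in zip(offsets, act, pred):
            rows.append({"channel": CHANNELS[j], "rank": rank,
                         "offset": int(off), "actual": a, "predicted": p,
                         "deviation": dev[j]})
    return pd.DataFrame(rows)
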