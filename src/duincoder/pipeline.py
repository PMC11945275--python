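"""End-to-end DUIncoder pipeline as a scikit-learn-style meta-estimator.

``DUIncoder.fit`` consumes *normal* driving records only: it derives
normalization statistics, windows the telemetry, trains the generative
driver model, computes minimum-deviation profiles on the training records,
and fits the isolation-forest boundary on them. ``score_records`` then flags
every frame of new records and aggregates to per-journey AnoP scores.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone

from .detector import (DeviationIsolationForest, DeviationProfile, FrameFlags,
                       deviation_profile, fit_detector, score)
from .driver_model import CategoricalPriorVAE
from .evaluation import RecordScore, anop
from .records import (DrivingRecord, compute_stats, extract_windows,
                      normalize, split_records, windows_from_records)


def _record_seed(root_seed: int, record_id: str, salt: int) -> np.random.SeedSequence:
    """Per-record inference seed: stable under reordering and batching."""
    digest = zlib.crc32(record_id.encode())
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(salt, digest))


class DUIncoder(BaseEstimator):
    """Unsupervised impaired-driving detector.

    Parameters
    ----------
    model : CategoricalPriorVAE or None
        Driver model template (cloned in fit); None builds the default.
    detector : DeviationIsolationForest or None
        Novelty-boundary template; None builds the default
        (contamination 0.01).
    window_frames : sliding-window length L in frames (odd; 101 = 10 s at
        10 Hz).
    k_infer : latent samples per window for minimum-deviation profiles.
    stats : NormalizationStats or None — z-score constants; None derives
        them from the training records.
    std_floor : optional floor for zero-variance channels in derived stats.
    max_train_windows, max_val_windows : optional caps on the number of
        windows used for model training/validation (seeded subsample); the
        detector is still fitted on every training frame.
    random_state : master seed for training, subsampling and inference.
    """

    def __init__(self, model=None, detector=None, window_frames=101,
                 k_infer=32, stats=None, std_floor=None,
                 max_train_windows=None, max_val_windows=None,
                 random_state=0):
        self.model = model
        self.detector = detector
        self.window_frames = window_frames
        self.k_infer = k_infer
        self.stats = stats
        self.std_floor = std_floor
        self.max_train_windows = max_train_windows
        self.max_val_windows = max_val_windows
        self.random_state = random_state

    # ------------------------------------------------------------------

    def fit(self, records: Sequence[DrivingRecord],
            val_records: Sequence[DrivingRecord] | None = None):
        """Train driver model + novelty boundary on normal records."""
        records = list(records)
        if not records:
            raise ValueError("no training records")
        drunk = [r.record_id for r in records if r.status == "drunk"]
        if drunk:
            raise ValueError(
                f"DUIncoder trains on normal records only; got drunk "
                f"records {drunk}")
        self.stats_ = self.stats if self.stats is not None else \
            compute_stats(records, std_floor=self.std_floor)

        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.random_state, spawn_key=(0,)))
        train_batch = windows_from_records(records, self.window_frames,
                                           self.stats_)
        X = train_batch.data
        if self.max_train_windows is not None and \
                X.shape[0] > self.max_train_windows:
            sel = rng.choice(X.shape[0], self.max_train_windows,
                             replace=False)
            X = X[np.sort(sel)]
        X_val = None
        if val_records is not None:
            val_normal = [r for r in val_records if r.status == "normal"]
            if val_normal:
                vb = windows_from_records(val_normal, self.window_frames,
                                          self.stats_)
                X_val = vb.data
                if self.max_val_windows is not None and \
                        X_val.shape[0] > self.max_val_windows:
                    sel = rng.choice(X_val.shape[0], self.max_val_windows,
                                     replace=False)
                    X_val = X_val[np.sort(sel)]

        model = clone(self.model) if self.model is not None \
            else CategoricalPriorVAE()
        model.set_params(window_frames=self.window_frames,
                         random_state=self.random_state)
        self.model_ = model.fit(X, X_val=X_val)

        self.train_profiles_ = [
            self._profile(r, salt=1, keep_reconstruction=False)
            for r in records]
        det = clone(self.detector) if self.detector is not None \
            else DeviationIsolationForest()
        det.set_params(random_state=self.random_state)
        self.detector_ = fit_detector(self.train_profiles_, detector=det)
        return self

    # ------------------------------------------------------------------

    def _profile(self, record: DrivingRecord, salt: int,
                 keep_reconstruction: bool) -> DeviationProfile:
        rec = record if record.normalized else normalize(record, self.stats_)
        batch = extract_windows(rec, self.window_frames)
        rng = np.random.default_rng(
            _record_seed(self.random_state, record.record_id, salt))
        return deviation_profile(self.model_, batch, self.k_infer, rng,
                                 keep_reconstruction=keep_reconstruction)

    def profile_records(self, records: Sequence[DrivingRecord],
                        keep_reconstruction: bool = False
                        ) -> list[DeviationProfile]:
        """Minimum-deviation profiles for arbitrary records (any status)."""
        return [self._profile(r, salt=2,
                              keep_reconstruction=keep_reconstruction)
                for r in records]

    def predict_flags(self, records: Sequence[DrivingRecord]
                      ) -> list[FrameFlags]:
        """Per-frame anomaly flags for each record."""
        return [score(p, self.detector_)
                for p in self.profile_records(records)]

    def score_records(self, records: Sequence[DrivingRecord]
                      ) -> list[RecordScore]:
        """Per-journey AnoP scores."""
        records = list(records)
        return [anop(f, route=r.route)
                for r, f in zip(records, self.predict_flags(records))]


# ---------------------------------------------------------------------------
# Study driver (used directly and by the ablation harness)


from dataclasses import dataclass as _dataclass


@_dataclass
class StudyResult:
    """Everything one train/fit/evaluate cycle produced."""

    summary: "object"
    scores: list
    pipeline: DUIncoder
    train_records: list
    val_records: list
    test_records: list

    @property
    def training_flag_fraction(self) -> float:
        """Fraction of normal training frames outside the fitted boundary."""
        D = np.concatenate([p.deviations
                            for p in self.pipeline.train_profiles_])
        return float(self.pipeline.detector_.predict(D).mean())

    @property
    def n_training_frames(self) -> int:
        return int(sum(p.n_frames for p in self.pipeline.train_profiles_))

    def heldout_normal_median_anop(self) -> float:
        vals = [s.anop for s in self.scores if s.status == "normal"]
        return float(np.median(vals))


def run_study(records=None, seed: int = 0, records_per_cell: int = 5,
              duration_s: float | None = None,
              scenario_subset: Sequence[str] | None = None,
              window_seconds: float = 10.0, frame_rate: float = 10.0,
              contamination: float = 0.01, data_proportion: float = 1.0,
              variant: str = "R", split_ratio=(7, 2, 1),
              stratify: bool = True,
              model_params: dict | None = None,
              max_train_windows: int | None = 20000,
              max_val_windows: int | None = 2048,
              k_infer: int = 32):
    """Simulate (or take) a dataset, split, train, detect, evaluate.

    Returns a :class:`StudyResult` (test-split summary and scores, fitted
    pipeline, splits). This is
    the single entry point the ablation harness perturbs: route subsets,
    window length, contamination, training-data proportion and loss variant
    are all parameters.
    """
    from .evaluation import summarize
    from .records import window_frames_for
    from .simulator import SimConfig, simulate_dataset

    if records is None:
        records = simulate_dataset(SimConfig(
            seed=seed, records_per_cell=records_per_cell,
            duration_override_s=duration_s))
    if scenario_subset is not None:
        records = [r for r in records if r.route in set(scenario_subset)]
    train, val, test = split_records(records, ratio=tuple(split_ratio),
                                     seed=seed, stratify=stratify)
    train_normal = [r for r in train if r.status == "normal"]
    if data_proportion < 1.0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(99,)))
        n_keep = max(1, int(round(data_proportion * len(train_normal))))
        idx = rng.choice(len(train_normal), n_keep, replace=False)
        train_normal = [train_normal[i] for i in np.sort(idx)]

    L = window_frames_for(window_seconds, frame_rate)
    model = CategoricalPriorVAE(variant=variant, **(model_params or {}))
    duin = DUIncoder(
        model=model,
        detector=DeviationIsolationForest(contamination=contamination),
        window_frames=L, k_infer=k_infer,
        max_train_windows=max_train_windows,
        max_val_windows=max_val_windows, random_state=seed)
    duin.fit(train_normal, val_records=val)
    scores = duin.score_records(test)
    return StudyResult(summary=summarize(scores), scores=scores,
                       pipeline=duin, train_records=train_normal,
                       val_records=val, test_records=test)
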