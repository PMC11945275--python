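"""Journey-level aggregation and the evaluation protocol.

Frame flags aggregate to a journey's *anomalous proportion* (AnoP): the
fraction of its frames flagged anomalous. Normal-vs-drunk separation is
summarized per group by outlier-trimmed boxplot statistics, a rank-based
ROC AUC over record AnoP values (drunk = positive class), and a Welch
two-sample t-test p-value.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .detector import FrameFlags
from .records import WindowBatch


@dataclass
class RecordScore:
    """One journey's evaluation unit: AnoP plus identifying metadata."""

    record_id: str
    status: str
    anop: float
    n_frames: int
    route: str = "unknown"

    def __post_init__(self) -> None:
        if not (0.0 <= self.anop <= 1.0):
            raise ValueError("anop must lie in [0, 1]")


@dataclass
class EvalSummary:
    """Per-group trimmed boxplot stats plus AUC and t-test p-value."""

    groups: dict
    auc: float
    p_value: float

    def to_json(self, path=None) -> str:
        payload = json.dumps({"schema": 1, **dataclasses.asdict(self)},
                             indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def anop(flags: FrameFlags, route: str = "unknown") -> RecordScore:
    """Anomalous proportion: flagged frames / total frames of the record."""
    T = flags.n_frames
    if T == 0:
        raise ValueError("empty flag vector")
    return RecordScore(record_id=flags.record_id, status=flags.status,
                       anop=float(flags.flags.sum() / T), n_frames=T,
                       route=route)


def journey_decision(score: RecordScore, threshold: float = 0.05) -> str:
    """Journey verdict: drunk iff AnoP strictly exceeds the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return "drunk" if score.anop > threshold else "normal"


def roc_auc(scores: Sequence[RecordScore]) -> float:
    """Rank-based AUC of AnoP for drunk (positive) vs normal records.

    Equals the probability that a uniformly drawn drunk record outranks a
    uniformly drawn normal one, ties counting one half.
    """
    y = np.array([s.status == "drunk" for s in scores], dtype=int)
    if y.all() or not y.any():
        raise ValueError("roc_auc needs both statuses present")
    x = np.array([s.anop for s in scores])
    return float(roc_auc_score(y, x))


def ttest(scores: Sequence[RecordScore]) -> float:
    """Two-sided Welch t-test p-value comparing group AnoP means."""
    a = np.array([s.anop for s in scores if s.status == "normal"])
    b = np.array([s.anop for s in scores if s.status == "drunk"])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ttest needs at least two records per group")
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def boxplot_stats(values: Sequence[float]) -> dict:
    """Min/median/max/IQR after a single pass of Tukey 1.5*IQR trimming."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    keep = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    kq1, kq3 = np.percentile(keep, [25, 75])
    return {"min": float(keep.min()), "median": float(np.median(keep)),
            "max": float(keep.max()), "iqr": float(kq3 - kq1),
            "n": int(keep.size), "n_removed": int(v.size - keep.size)}


def summarize(scores: Sequence[RecordScore]) -> EvalSummary:
    groups = {}
    for status in ("normal", "drunk"):
        vals = [s.anop for s in scores if s.status == status]
        if vals:
            groups[status] = boxplot_stats(vals)
    return EvalSummary(groups=groups, auc=roc_auc(scores),
                       p_value=ttest(scores))


def scores_to_frame(scores: Sequence[RecordScore]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in scores])


# ---------------------------------------------------------------------------
# Baselines

_SUPERVISED = ("lda", "adaboost", "gboost", "svm", "rf")


def _make_classifier(name: str, seed: int):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import (AdaBoostClassifier,
                                  HistGradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.svm import SVC
    if name == "lda":
        return LinearDiscriminantAnalysis(tol=1e-4)
    if name == "adaboost":
        return AdaBoostClassifier(n_estimators=100, learning_rate=0.05,
                                  random_state=seed)
    if name == "gboost":
        return HistGradientBoostingClassifier(max_iter=100, learning_rate=0.3,
                                              random_state=seed)
    if name == "svm":
        # sigma = 8 in the RBF kernel coefficient -> gamma = 1 / (2 sigma^2)
        return SVC(C=0.0039, gamma=1.0 / (2 * 8.0 ** 2), random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, max_depth=8,
                                      min_samples_split=2, random_state=seed)
    raise ValueError(f"unknown baseline {name!r}")


def _balanced_record_subsample(batch: WindowBatch, seed: int) -> np.ndarray:
    """Window mask keeping an equal number of normal and drunk *records*."""
    ids = batch.record_ids
    labels = batch.labels
    rec_status = {}
    for rid, lab in zip(ids, labels):
        rec_status[rid] = lab
    normal = sorted(r for r, s in rec_status.items() if s == "normal")
    drunk = sorted(r for r, s in rec_status.items() if s == "drunk")
    if not normal or not drunk:
        raise ValueError("supervised baselines need both statuses in training")
    n = min(len(normal), len(drunk))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(normal, n, replace=False)) \
        | set(rng.choice(drunk, n, replace=False))
    return np.array([rid in chosen for rid in ids])


def run_baseline(name: str, train: WindowBatch, test: WindowBatch,
                 config: Mapping | None = None,
                 route_map: Mapping[str, str] | None = None) -> list[RecordScore]:
    """Frame-level baseline → per-record AnoP scores on the test batch.

    Supervised names train a binary frame classifier on a record-balanced
    subsample; "vae" trains a plain Gaussian VAE on normal windows and runs
    the same minimum-deviation + isolation-forest detection as the main
    method.
    """
    config = dict(config or {})
    seed = int(config.pop("seed", 0))
    route_map = route_map or {}
    if name in _SUPERVISED:
        mask = _balanced_record_subsample(train, seed)
        clf = _make_classifier(name, seed)
        y_train = (train.labels[mask] == "drunk").astype(int)
        clf.fit(train.data[mask], y_train)
        pred = np.asarray(clf.predict(test.data), dtype=int)
    elif name == "vae":
        from .baselines import vae_frame_flags
        if np.any(train.labels == "drunk"):
            raise ValueError("vae baseline trains on normal windows only")
        pred = vae_frame_flags(train, test, seed=seed, **config)
    else:
        raise ValueError(f"unknown baseline {name!r}")

    scores = []
    for rid in pd.unique(test.record_ids):
        sel = test.record_ids == rid
        status = test.labels[sel][0]
        flags = FrameFlags(record_id=str(rid), status=str(status),
                           flags=pred[sel])
        scores.append(anop(flags, route=route_map.get(str(rid), "unknown")))
    return scores


# ---------------------------------------------------------------------------
# Ablation harness

ABLATION_DIMENSIONS = ("scenario_subset", "window_seconds", "contamination",
                       "data_proportion", "variant")


def run_ablation(grid: Mapping[str, Sequence], base_config=None,
                 records=None) -> pd.DataFrame:
    """One full train/fit/evaluate cycle per grid cell, shared base seed.

    ``grid`` maps dimension names (scenario_subset, window_seconds,
    contamination, data_proportion, variant) to value lists; the full cross
    product is evaluated and one row per cell is returned with AUC, p-value
    and per-group medians.
    """
    from itertools import product as iproduct

    from .pipeline import run_study

    unknown = set(grid) - set(ABLATION_DIMENSIONS)
    if unknown:
        raise ValueError(f"unknown ablation dimension(s) {sorted(unknown)}")
    base_config = dict(base_config or {})
    dims = sorted(grid)
    rows = []
    for combo in iproduct(*(grid[d] for d in dims)):
        overrides = dict(zip(dims, combo))
        cfg = {**base_config, **overrides}
        summary = run_study(records=records, **cfg).summary
        row = dict(overrides)
        row["auc"] = summary.auc
        row["p_value"] = summary.p_value
        for status, stats_d in summary.groups.items():
            row[f"{status}_median_anop"] = stats_d["median"]
        rows.append(row)
    return pd.DataFrame(rows)
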