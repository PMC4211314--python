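"""Signal-detection evaluation and experiment harnesses.

All experiments follow the judge-then-encode protocol: every instance is
judged (or completed from a masked copy) against the memory built from the
instances *before* it, and only then encoded.  Ground truth is exact-match
recurrence over all attributes.  Because the store never decays, the model's
miss count is identically zero; the interesting cells of the confusion matrix
are false alarms and correct rejections, and the weight-based similarity
turns the binary verdict into ROC curves.

RNG discipline: every harness derives independent child generators for
encoding, probe sampling, masking and judgment from its ``seed``, so runs are
bit-reproducible and settings that share a sub-seed (e.g. the same encoding
stream under different observation counts) see identical draws for the parts
they share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import (
    FIXED,
    RANDOM_COMBINATION,
    RANDOM_ORDER,
    RING,
    EdgeConfig,
    Hypernetwork,
    Token,
)
from .inference import _judge_scored, completion_flags, judge, repeated_observation_judge
from .synthetic import make_partial, truth_labels

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "roc_curve",
    "default_sweep_configs",
    "incremental_judgment_experiment",
    "configuration_sweep",
    "completion_experiment",
    "study_duration_experiment",
    "online_offline_expectation",
]


@dataclass
class ConfusionMatrix:
    hits: int = 0
    false_alarms: int = 0
    misses: int = 0
    correct_rejections: int = 0

    @property
    def total(self) -> int:
        return self.hits + self.false_alarms + self.misses + self.correct_rejections

    @property
    def hit_rate(self) -> float:
        pos = self.hits + self.misses
        return self.hits / pos if pos else float("nan")

    @property
    def false_alarm_rate(self) -> float:
        neg = self.false_alarms + self.correct_rejections
        return self.false_alarms / neg if neg else float("nan")

    def record(self, truth_old: bool, judged_old: bool) -> None:
        if truth_old:
            if judged_old:
                self.hits += 1
            else:
                self.misses += 1
        else:
            if judged_old:
                self.false_alarms += 1
            else:
                self.correct_rejections += 1

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.hits + other.hits,
            self.false_alarms + other.false_alarms,
            self.misses + other.misses,
            self.correct_rejections + other.correct_rejections,
        )


@dataclass
class RocCurve:
    """Threshold sweep of the similarity score: (FPR, TPR) points plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC from similarity scores against old/new ground truth.

    Ties share a threshold; the AUC is the trapezoidal area.  Raises on a
    degenerate label set (all old or all new).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("ROC needs at least one old and one new label")
    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores)
    return RocCurve(fpr, tpr, thr, float(_sk_auc(fpr, tpr)))


def _maybe_auc(scores: List[float], labels: List[bool]) -> float:
    try:
        return roc_curve(scores, labels).auc
    except ValueError:
        return float("nan")


def _child(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng([seed, *path])


# ---------------------------------------------------------------------------
# Experiment 0: judge-then-encode over a stream, sectioned metrics
# ---------------------------------------------------------------------------

def incremental_judgment_experiment(
    stream: Sequence[Sequence[Token]],
    config: EdgeConfig,
    section_size: int,
    *,
    C: float = 10.0,
    N_m: int = 0,
    seed: int = 0,
    observations: int = 1,
) -> Tuple[pd.DataFrame, pd.DataFrame, Hypernetwork]:
    """Judge-then-encode every instance; aggregate per consecutive section.

    The first section is judged against an initially empty memory.  Returns
    (per-section table, per-probe records, final network).  Section AUC is NaN
    when a section's labels are degenerate.
    """
    if section_size < 1:
        raise ValueError("section_size must be >= 1")
    instances = [tuple(x) for x in stream]
    if not instances:
        raise ValueError("empty stream")
    d = len(instances[0])
    net = Hypernetwork(d, config.topology, C)
    labels = truth_labels(instances)
    rng_enc = _child(seed, 0)
    rng_probe = _child(seed, 1)
    rows = []
    for i, (inst, old) in enumerate(zip(instances, labels)):
        if observations > 1:
            res = repeated_observation_judge(net, inst, config, observations, rng_probe, N_m=N_m)
            judged_old, sim = res.is_old, res.similarity
        else:
            # exact DP similarity; equivalent to judge() but enumeration-free
            judged_old, sim = _judge_scored(net, inst, config, rng_probe, N_m=N_m)
        rows.append(
            {
                "index": i,
                "section": i // section_size,
                "truth_old": old,
                "judged_old": judged_old,
                "similarity": sim,
            }
        )
        net.encode(inst, config, rng_enc)
    records = pd.DataFrame(rows)
    sections = []
    for s, grp in records.groupby("section"):
        cm = ConfusionMatrix()
        for t, j in zip(grp["truth_old"], grp["judged_old"]):
            cm.record(bool(t), bool(j))
        sections.append(
            {
                "section": s,
                "n": len(grp),
                "hits": cm.hits,
                "false_alarms": cm.false_alarms,
                "misses": cm.misses,
                "correct_rejections": cm.correct_rejections,
                "hit_rate": cm.hit_rate,
                "false_alarm_rate": cm.false_alarm_rate,
                "auc": _maybe_auc(list(grp["similarity"]), list(grp["truth_old"])),
            }
        )
    return pd.DataFrame(sections), records, net


# ---------------------------------------------------------------------------
# Experiment 1: edge-configuration sweep
# ---------------------------------------------------------------------------

def default_sweep_configs(d: int, topology: str = RING) -> List[EdgeConfig]:
    """The 13-category reconstruction of the configuration grid.

    Fixed orders 2..min(7, d-1), random orders (2,3)..(2,6), random
    combinations (2,4), (2,6), (2,d-1), clipped to valid ranges for ``d``.
    """
    configs = [
        EdgeConfig(mode=FIXED, k=k, topology=topology) for k in range(2, min(7, d - 1) + 1)
    ]
    for r2 in (3, 4, 5, 6):
        if r2 <= d - 1:
            configs.append(EdgeConfig(mode=RANDOM_ORDER, order_range=(2, r2), topology=topology))
    for r2 in (4, 6, d - 1):
        if 2 <= r2 <= d - 1:
            cfg = EdgeConfig(mode=RANDOM_COMBINATION, order_range=(2, r2), topology=topology)
            if cfg not in configs:
                configs.append(cfg)
    return configs


def configuration_sweep(
    stream: Sequence[Sequence[Token]],
    configs: Optional[Iterable[EdgeConfig]] = None,
    *,
    n_missing: int = 3,
    C: float = 10.0,
    N_m: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Scale, connectivity, ROC and completion metrics per edge configuration."""
    instances = [tuple(x) for x in stream]
    d = len(instances[0])
    if configs is None:
        configs = default_sweep_configs(d)
    rows = []
    for ci, config in enumerate(configs):
        sections, records, net = incremental_judgment_experiment(
            instances, config, section_size=len(instances), C=C, N_m=N_m, seed=seed
        )
        comp, _ = completion_experiment(
            instances, config, n_missing, C=C, N_m=N_m, seed=seed
        )
        cm_row = sections.iloc[0]
        rows.append(
            {
                "config": config.label(),
                "mode": config.mode,
                "k": config.k,
                "order_range": config.order_range,
                "n_edges": net.n_edges,
                "n_links": net.n_links,
                "connectivity": net.connectivity(),
                "hit_rate": cm_row["hit_rate"],
                "false_alarm_rate": cm_row["false_alarm_rate"],
                "auc": cm_row["auc"],
                "completeness": comp["completeness"],
                "expectation": comp["expectation"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pattern-completion experiment
# ---------------------------------------------------------------------------

def completion_experiment(
    stream: Sequence[Sequence[Token]],
    config: EdgeConfig,
    n_missing: int,
    *,
    C: float = 10.0,
    N_m: int = 0,
    seed: int = 0,
) -> Tuple[Dict[str, float], pd.DataFrame]:
    """Mask, complete, then encode each instance in stream order.

    For every probe, ``n_missing`` uniformly chosen attributes are masked and
    the partial instance is completed against the memory encoded so far;
    completeness (any completion) and expectation (the original among the
    completions) are averaged over the stream.  ``n_missing=0`` degenerates to
    plain old/new judgment.
    """
    instances = [tuple(x) for x in stream]
    d = len(instances[0])
    if not 0 <= n_missing <= d - 1:
        raise ValueError(f"n_missing={n_missing} outside [0, {d - 1}]")
    net = Hypernetwork(d, config.topology, C)
    rng_enc = _child(seed, 0)
    rng_probe = _child(seed, 2)
    rng_mask = _child(seed, 3)
    rows = []
    for i, inst in enumerate(instances):
        if n_missing == 0:
            res = judge(net, inst, config, rng_probe, N_m=N_m)
            complete = res.is_old
            expected = res.is_old
        else:
            partial = make_partial(inst, n_missing, rng_mask)
            complete, expected = completion_flags(
                net, partial, config, rng_probe, truth=inst, N_m=N_m
            )
            expected = bool(expected)
        rows.append({"index": i, "complete": complete, "expected": expected})
        net.encode(inst, config, rng_enc)
    records = pd.DataFrame(rows)
    metrics = {
        "completeness": float(records["complete"].mean()),
        "expectation": float(records["expected"].mean()),
        "n": len(records),
    }
    return metrics, records


# ---------------------------------------------------------------------------
# Study duration: repeated encodings vs repeated observations
# ---------------------------------------------------------------------------

def study_duration_experiment(
    stream: Sequence[Sequence[Token]],
    config: EdgeConfig,
    encodings: int,
    observations: int,
    *,
    n_missing: int = 3,
    C: float = 10.0,
    N_m: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Vary encoding repetitions and observation counts independently.

    Rows cover the baseline (1 encoding, 1 observation), the repeated-encoding
    setting and the repeated-observation setting.  The encode, mask and
    completion-probe RNG streams depend only on the repetition setting, and
    each probe's judgment draws come from a per-probe child generator, so the
    repeated-observation run consumes the baseline's draw as its first
    observation: false alarms can only be corrected, never added, and
    completion metrics are untouched by observation count (observation
    repetition aggregates verdicts; it does not change the memory or the
    completion routes).
    """
    instances = [tuple(x) for x in stream]
    d = len(instances[0])
    labels = truth_labels(instances)
    settings = [(1, 1)]
    if encodings > 1:
        settings.append((encodings, 1))
    if observations > 1:
        settings.append((1, observations))
    rows = []
    for rep, obs in settings:
        cfg = config.with_repetitions(rep)
        net = Hypernetwork(d, cfg.topology, C)
        rng_enc = _child(seed, 0, rep)
        rng_mask = _child(seed, 3, rep)
        rng_comp = _child(seed, 2, rep)
        cm = ConfusionMatrix()
        scores: List[float] = []
        n_complete = n_expected = 0
        for i, (inst, old) in enumerate(zip(instances, labels)):
            res = repeated_observation_judge(
                net, inst, cfg, obs, _child(seed, 1, i), N_m=N_m
            )
            cm.record(old, res.is_old)
            scores.append(res.similarity)
            partial = make_partial(inst, n_missing, rng_mask)
            complete, expected = completion_flags(net, partial, cfg, rng_comp, truth=inst, N_m=N_m)
            n_complete += complete
            n_expected += bool(expected)
            net.encode(inst, cfg, rng_enc)
        rows.append(
            {
                "repetitions": rep,
                "observations": obs,
                "n_edges": net.n_edges,
                "n_links": net.n_links,
                "connectivity": net.connectivity(),
                "hit_rate": cm.hit_rate,
                "false_alarm_rate": cm.false_alarm_rate,
                "auc": _maybe_auc(scores, labels),
                "completeness": n_complete / len(instances),
                "expectation": n_expected / len(instances),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Online vs offline expectation
# ---------------------------------------------------------------------------

def online_offline_expectation(
    stream: Sequence[Sequence[Token]],
    config: EdgeConfig,
    update_interval: int,
    n_missing: int = 3,
    *,
    C: float = 10.0,
    N_m: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Context expectation under online vs batch-updated memory.

    The online memory encodes every instance right after judging it; the
    offline memory is a snapshot frozen at the last ``update_interval``
    boundary (so its first interval is judged against an empty store).  Both
    variants see the same masks and probe draws.  Returns per-probe expected
    flags and cumulative expectation-rate trajectories; with
    ``update_interval=1`` the two are identical by construction.
    """
    if update_interval < 1:
        raise ValueError("update_interval must be >= 1")
    instances = [tuple(x) for x in stream]
    d = len(instances[0])
    net = Hypernetwork(d, config.topology, C)
    frozen = net.copy()
    rng_enc = _child(seed, 0)
    rng_mask = _child(seed, 3)
    rows = []
    for i, inst in enumerate(instances):
        if i % update_interval == 0:
            frozen = net.copy()
        partial = make_partial(inst, n_missing, rng_mask)
        _, on_exp = completion_flags(net, partial, config, _child(seed, 2, i), truth=inst, N_m=N_m)
        _, off_exp = completion_flags(
            frozen, partial, config, _child(seed, 2, i), truth=inst, N_m=N_m
        )
        rows.append(
            {
                "index": i,
                "online_expected": bool(on_exp),
                "offline_expected": bool(off_exp),
            }
        )
        net.encode(inst, config, rng_enc)
    df = pd.DataFrame(rows)
    df["online_rate"] = df["online_expected"].cumsum() / (df["index"] + 1)
    df["offline_rate"] = df["offline_expected"].cumsum() / (df["index"] + 1)
    return df
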