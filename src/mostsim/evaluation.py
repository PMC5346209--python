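"""Cross-validation, temporal validation, metrics and threshold trade-offs.

Sevenfold cross-validation operates per target: each target's ligand set
is randomly partitioned into 7 disjoint folds (~14.3% test each), so the
union of the test folds covers the whole panel exactly once.  An optional
``resample15`` mode instead draws 15% of each target's ligands
independently seven times.  Within a fold, training features are built by
leave-one-out neighbor search inside the training ligands of each target,
a single global model is fitted on the pooled rows, and each test ligand
is scored against its target's training ligands.

Metrics are pooled confusion counts over all targets: accuracy and the
Matthews correlation coefficient (MCC), the latter being the more
informative one on the heavily active-skewed panels this method is used
on.

The trade-off machinery quantifies how filtering predictions — by a
minimum neighbor similarity Tc >= k, or by a maximum p-value p <= t —
differentially retains true and false positives: f_TP(k) and f_FP(k) are
the fractions of TPs/FPs surviving the filter, and their difference is
the trade-off index (large = the filter removes FPs preferentially).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curation import CuratedPair, TargetPanel
from .fingerprints import FingerprintCache, most_similar
from .models import ModelSpec, encode_features, train, TrainedModel

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "CrossValidationSummary",
    "TradeoffCurve",
    "accuracy",
    "mcc",
    "confusion_from_trace",
    "sevenfold_split",
    "neighbor_training_rows",
    "cross_validate",
    "temporal_validate",
    "tradeoff_curve",
]

TRACE_COLUMNS = [
    "target_id",
    "ligand_id",
    "nn_ligand_id",
    "tc_most",
    "pki_most",
    "p_a",
    "p_value",
    "truth",
    "predicted",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FN + TN + FP)."""
    if c.total == 0:
        raise ValueError("accuracy is undefined for zero total counts")
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any margin is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def confusion_from_trace(trace: pd.DataFrame) -> ConfusionCounts:
    truth = trace["truth"].to_numpy(dtype=int)
    pred = trace["predicted"].to_numpy(dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((truth == 1) & (pred == 1))),
        tn=int(np.sum((truth == 0) & (pred == 0))),
        fp=int(np.sum((truth == 0) & (pred == 1))),
        fn=int(np.sum((truth == 1) & (pred == 0))),
    )


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    accuracy: float
    mcc: float
    trace: pd.DataFrame
    n_skipped: int = 0


@dataclass
class CrossValidationSummary:
    folds: list[FoldResult]
    accuracy_mean: float
    accuracy_sd: float
    mcc_mean: float
    mcc_sd: float

    @property
    def pooled_trace(self) -> pd.DataFrame:
        return pd.concat([f.trace for f in self.folds], ignore_index=True)

    def pooled_counts(self) -> ConfusionCounts:
        return confusion_from_trace(self.pooled_trace)


def sevenfold_split(
    panel: TargetPanel,
    seed: int,
    n_folds: int = 7,
    mode: str = "partition",
    test_fraction: float = 0.15,
) -> list[tuple[TargetPanel, TargetPanel]]:
    """Per-target random folds, as (train_panel, test_panel) pairs.

    ``partition`` (default): ligands of each target are shuffled and
    split into ``n_folds`` disjoint folds; fold i's test set is fold i
    and the union of test sets covers the panel exactly once.
    ``resample15``: seven independent draws of ``test_fraction`` of each
    target's ligands (sampling without replacement within a draw, but
    draws may overlap and need not cover the panel).
    """
    if mode not in ("partition", "resample15"):
        raise ValueError(f"unknown split mode: {mode!r}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, list[np.ndarray]] = {}
    for t in panel.targets:
        ids = np.array([p.ligand_id for p in panel.ligands(t)])
        if mode == "partition":
            perm = rng.permutation(len(ids))
            assignments[t] = [ids[perm[chunk]] for chunk in _chunks(len(ids), n_folds)]
        else:
            n_test = max(1, round(test_fraction * len(ids)))
            assignments[t] = [
                ids[rng.choice(len(ids), size=n_test, replace=False)]
                for _ in range(n_folds)
            ]
    splits = []
    for i in range(n_folds):
        test_map = {t: list(assignments[t][i]) for t in panel.targets}
        train_map = {
            t: [p.ligand_id for p in panel.ligands(t) if p.ligand_id not in set(assignments[t][i])]
            for t in panel.targets
        }
        splits.append((panel.subset(train_map), panel.subset(test_map)))
    return splits


def _chunks(n: int, k: int) -> list[np.ndarray]:
    """Index chunks of an n-vector into k near-equal contiguous parts."""
    edges = np.linspace(0, n, k + 1).round().astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(k)]


def neighbor_training_rows(
    train_panel: TargetPanel, spec: ModelSpec, cache: FingerprintCache
):
    """Leave-one-out neighbor features for every training ligand."""
    rows = []
    for t in train_panel.targets:
        ligands = train_panel.ligands(t)
        if len(ligands) < 2:
            continue
        fps = cache.for_target(train_panel, t)
        for i, p in enumerate(ligands):
            others = ligands[:i] + ligands[i + 1 :]
            nn = most_similar(fps[p.ligand_id], others, fps)
            fv = encode_features(nn, spec.activity_mode, spec.threshold)
            rows.append((fv, p.label_at(spec.threshold)))
    return rows


def _score_pairs(
    pairs: list[CuratedPair],
    reference_panel: TargetPanel,
    model: TrainedModel,
    cache: FingerprintCache,
) -> tuple[pd.DataFrame, int]:
    """Score query pairs against their target's reference ligand set."""
    spec = model.spec
    records = []
    n_skipped = 0
    by_target: dict[str, list[CuratedPair]] = {}
    for p in pairs:
        by_target.setdefault(p.target_id, []).append(p)
    for t in sorted(by_target):
        if t not in reference_panel or not reference_panel.ligands(t):
            n_skipped += len(by_target[t])
            continue
        ref_ligands = reference_panel.ligands(t)
        fps = cache.for_target(reference_panel, t)
        query_fps = cache.get_many([p.smiles for p in by_target[t]])
        feats, metas = [], []
        for p, qfp in zip(by_target[t], query_fps):
            nn = most_similar(qfp, ref_ligands, fps)
            fv = encode_features(nn, spec.activity_mode, spec.threshold)
            feats.append((fv.tc_most, fv.activity_feature))
            metas.append((p, nn))
        p_a = model.predict_proba_active(np.array(feats))
        for (p, nn), pa in zip(metas, p_a):
            records.append(
                (
                    p.target_id,
                    p.ligand_id,
                    nn.ligand_id,
                    nn.tc_most,
                    nn.pki_most,
                    pa,
                    1.0 - pa,
                    p.label_at(spec.threshold),
                    int(pa > 1.0 - pa),
                )
            )
    trace = pd.DataFrame(records, columns=TRACE_COLUMNS)
    return trace, n_skipped


def cross_validate(
    panel: TargetPanel,
    spec: ModelSpec,
    n_folds: int = 7,
    mode: str = "partition",
    cache: FingerprintCache | None = None,
) -> CrossValidationSummary:
    """Sevenfold cross-validation of a global model on one panel.

    The split is seeded from ``spec.seed`` so a rerun with the same spec
    reproduces folds, fits and predictions exactly.
    """
    cache = cache if cache is not None else FingerprintCache(spec.scheme)
    if cache.scheme != spec.scheme:
        raise ValueError("fingerprint cache scheme does not match model spec")
    splits = sevenfold_split(panel, seed=spec.seed, n_folds=n_folds, mode=mode)
    folds = []
    for i, (train_panel, test_panel) in enumerate(splits):
        model = train(spec, neighbor_training_rows(train_panel, spec, cache))
        trace, n_skipped = _score_pairs(test_panel.pairs(), train_panel, model, cache)
        counts = confusion_from_trace(trace)
        folds.append(
            FoldResult(
                fold=i,
                counts=counts,
                accuracy=accuracy(counts),
                mcc=mcc(counts),
                trace=trace,
                n_skipped=n_skipped,
            )
        )
    accs = np.array([f.accuracy for f in folds])
    mccs = np.array([f.mcc for f in folds])
    return CrossValidationSummary(
        folds=folds,
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)),
        mcc_mean=float(mccs.mean()),
        mcc_sd=float(mccs.std(ddof=1)),
    )


def temporal_validate(
    old_panel: TargetPanel,
    new_pairs: list[CuratedPair],
    spec: ModelSpec,
    cache: FingerprintCache | None = None,
) -> FoldResult:
    """Train on a full earlier release; test on later-release additions.

    ``new_pairs`` should come from :func:`mostsim.curation.temporal_new_pairs`.
    Pairs on targets with no ligands in the old release are skipped (and
    counted).  An empty test set yields zero counts rather than an error.
    """
    cache = cache if cache is not None else FingerprintCache(spec.scheme)
    model = train(spec, neighbor_training_rows(old_panel, spec, cache))
    trace, n_skipped = _score_pairs(new_pairs, old_panel, model, cache)
    counts = confusion_from_trace(trace)
    return FoldResult(
        fold=0,
        counts=counts,
        accuracy=accuracy(counts) if counts.total else float("nan"),
        mcc=mcc(counts),
        trace=trace,
        n_skipped=n_skipped,
    )


@dataclass
class TradeoffCurve:
    axis: str  # 'tc' or 'pvalue'
    thresholds: np.ndarray
    f_tp: np.ndarray  # NaN where no TPs exist
    f_fp: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.f_tp - self.f_fp

    def best_threshold(self) -> float:
        """Threshold maximizing f_TP - f_FP (NaN-aware)."""
        diff = self.difference
        if np.all(np.isnan(diff)):
            return float("nan")
        return float(self.thresholds[np.nanargmax(diff)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "f_tp": self.f_tp,
                "f_fp": self.f_fp,
                "difference": self.difference,
            }
        )


def tradeoff_curve(
    trace: pd.DataFrame, axis: str, thresholds=None
) -> TradeoffCurve:
    """Retained-fraction curves f_TP and f_FP along a filter axis.

    ``axis='tc'``: keep predictions with tc_most >= k (k ascending grid,
    default 0..1 step 0.05).  ``axis='pvalue'``: keep predictions with
    p_value <= t (default grid 0.5 down to 0 step 0.025).  Fractions are
    relative to the total number of TPs (respectively FPs) in the trace;
    when a class is absent its fraction is NaN, not 0.
    """
    if axis == "tc":
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10) if thresholds is None else np.asarray(thresholds, dtype=float)
        values = trace["tc_most"].to_numpy()
        keep = lambda k: values >= k
    elif axis == "pvalue":
        grid = np.round(np.arange(0.5, -0.0001, -0.025), 10) if thresholds is None else np.asarray(thresholds, dtype=float)
        values = trace["p_value"].to_numpy()
        keep = lambda k: values <= k
    else:
        raise ValueError(f"unknown trade-off axis: {axis!r}")
    truth = trace["truth"].to_numpy(dtype=int)
    pred = trace["predicted"].to_numpy(dtype=int)
    is_tp = (truth == 1) & (pred == 1)
    is_fp = (truth == 0) & (pred == 1)
    n_tp, n_fp = int(is_tp.sum()), int(is_fp.sum())
    f_tp = np.full(len(grid), np.nan)
    f_fp = np.full(len(grid), np.nan)
    for i, k in enumerate(grid):
        kept = keep(k)
        if n_tp:
            f_tp[i] = np.sum(kept & is_tp) / n_tp
        if n_fp:
            f_fp[i] = np.sum(kept & is_fp) / n_fp
    return TradeoffCurve(axis=axis, thresholds=grid, f_tp=f_tp, f_fp=f_fp)
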