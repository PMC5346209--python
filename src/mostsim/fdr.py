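"""Multi-target scanning with false-discovery-rate control.

When a query compound is screened against hundreds or thousands of
targets at once, the per-target inactive probabilities p_i — treated as
p-values — face a multiple-testing problem.  Two corrections are
provided: Benjamini-Hochberg step-up adjusted p-values, and
Storey-Tibshirani q-values with a fixed-lambda estimate of the null
proportion pi0.  Hits are ranked by adjusted p-value, with higher
neighbor similarity breaking ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .curation import TargetPanel
from .fingerprints import (
    FingerprintCache,
    NearestNeighbor,
    compute_fingerprint,
    most_similar,
)
from .models import TrainedModel, encode_features

__all__ = [
    "TargetScanResult",
    "adjust_bh",
    "estimate_pi0",
    "estimate_qvalues",
    "rank_targets",
    "scan",
]


@dataclass
class TargetScanResult:
    target_id: str
    neighbor: NearestNeighbor
    p_value: float
    p_adjusted: float | None = None
    q_value: float | None = None
    rank: int | None = None


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    With m values sorted ascending, the adjusted value at sorted
    position i is min over j >= i of min(1, p_(j) * m / j).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("adjust_bh expects a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    # p*m/m can round one ulp below p; the mathematical result is >= p
    adjusted = np.maximum(adjusted, p[order])
    out = np.empty(m)
    out[order] = adjusted
    return out


def estimate_pi0(pvalues, lam: float = 0.5) -> float:
    """Storey's fixed-lambda estimate of the proportion of true nulls.

    pi0_hat = #{p > lambda} / (m * (1 - lambda)), clipped to (0, 1].
    When every p-value is below lambda the estimate degenerates to 0; the
    conservative fallback pi0 = 1 is used instead (with a warning), which
    reduces the q-values to plain BH adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    if not 0 <= lam < 1:
        raise ValueError("lambda must lie in [0, 1)")
    pi0 = np.sum(p > lam) / (p.size * (1.0 - lam))
    if pi0 <= 0:
        warnings.warn(
            "all p-values fall below lambda; falling back to pi0 = 1",
            stacklevel=2,
        )
        return 1.0
    return float(min(pi0, 1.0))


def estimate_qvalues(pvalues, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: pi0 times the BH-adjusted p-values.

    Forcing ``pi0=1`` makes the q-values equal the BH adjustment exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if pi0 is None:
        pi0 = estimate_pi0(p, lam=lam)
    return np.minimum(1.0, pi0 * adjust_bh(p))


def rank_targets(results: list[TargetScanResult]) -> list[TargetScanResult]:
    """Order by (adjusted p ascending, Tc_most descending, target id)."""
    for r in results:
        if r.p_adjusted is None:
            raise ValueError("rank_targets requires adjusted p-values")
    ordered = sorted(
        results, key=lambda r: (r.p_adjusted, -r.neighbor.tc_most, r.target_id)
    )
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def scan(
    query_smiles: str,
    panel: TargetPanel,
    model: TrainedModel,
    cache: FingerprintCache | None = None,
    min_tc: float = 0.0,
    lam: float = 0.5,
) -> list[TargetScanResult]:
    """Scan one query against every target of a panel, FDR-corrected.

    One result per target with at least one ligand; adjustment is over
    the full scanned set (m = number of scanned targets).  ``min_tc``
    optionally drops targets whose best ligand similarity falls below a
    floor before adjustment (off by default: the scan filters by p-value,
    not similarity).
    """
    spec = model.spec
    cache = cache if cache is not None else FingerprintCache(spec.scheme)
    query_fp = (
        cache.get(query_smiles)
        if cache.scheme == spec.scheme
        else compute_fingerprint(query_smiles, spec.scheme)
    )
    results = []
    feats = []
    for t in panel.targets:
        ligands = panel.ligands(t)
        if not ligands:
            continue
        fps = cache.for_target(panel, t)
        nn = most_similar(query_fp, ligands, fps)
        if nn.tc_most < min_tc:
            continue
        fv = encode_features(nn, spec.activity_mode, spec.threshold)
        feats.append((fv.tc_most, fv.activity_feature))
        results.append(TargetScanResult(target_id=t, neighbor=nn, p_value=np.nan))
    if not results:
        return []
    p_a = model.predict_proba_active(np.array(feats))
    p_values = 1.0 - p_a
    adjusted = adjust_bh(p_values)
    qvals = estimate_qvalues(p_values, lam=lam)
    for r, pv, adj, q in zip(results, p_values, adjusted, qvals):
        r.p_value = float(pv)
        r.p_adjusted = float(adj)
        r.q_value = float(q)
    return rank_targets(results)
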