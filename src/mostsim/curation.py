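"""Curation of raw Ki bioactivity tables into per-target ligand panels.

Raw exports of binding data are noisy: the same target-ligand pair is
measured repeatedly (within and across publications), records carry
censored relations (``>``, ``<``, ``~``), missing units or references, and
low assay-confidence annotations.  This module applies a fixed sequence of
quality filters and duplicate-resolution rules and produces a
:class:`TargetPanel` mapping each target to a unique set of ligands, each
with a single consensus pKi.

Rules, in order:

1. keep only direct-binding Ki measurements (``activity_type == "Ki"``,
   ``confidence_score == 9``) with a value, units, reference and an
   unambiguous ``=`` relation;
2. within one (target, ligand, reference) group, keep the smallest Ki
   (strongest measured affinity);
3. across references, average the per-reference Ki values on the
   concentration scale (geometric/pKi-scale averaging is available as an
   option);
4. drop targets with fewer than ``min_ligands`` or more than
   ``max_ligands`` curated ligands.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BioactivityRecord",
    "CuratedPair",
    "TargetPanel",
    "CurationAudit",
    "UNIT_SCALE",
    "filter_effective",
    "deduplicate",
    "to_pki",
    "label_activity",
    "curate",
    "filter_targets",
    "temporal_new_pairs",
    "read_bioactivity_table",
    "write_records",
    "write_panel",
    "read_panel",
]

#: Accepted concentration units and their scale in mol/L.
UNIT_SCALE: Mapping[str, float] = {
    "pm": 1e-12,
    "nm": 1e-9,
    "um": 1e-6,
    "m": 1.0,
}

#: Relation operators treated as unambiguous.  Censored ('>', '<'),
#: approximate ('~') and missing relations are dropped as ambiguous.
ACCEPTED_RELATIONS = frozenset({"="})

REQUIRED_COLUMNS = (
    "target_id",
    "ligand_id",
    "smiles",
    "activity_type",
    "relation",
    "value",
    "units",
    "reference_id",
    "confidence_score",
)


def _normalize_units(token: str | None) -> str | None:
    """Map a unit token to its canonical lower-case form, or None."""
    if token is None:
        return None
    token = str(token).strip().replace("µ", "u").replace("μ", "u")
    token = token.lower()
    return token if token in UNIT_SCALE else None


@dataclass(frozen=True)
class BioactivityRecord:
    """One raw Ki measurement with provenance and quality fields.

    Optional fields are ``None`` when the source table left them blank;
    such records are rejected by :func:`filter_effective`.
    """

    target_id: str
    ligand_id: str
    smiles: str
    activity_type: str | None = "Ki"
    relation: str | None = "="
    value: float | None = None
    units: str | None = None
    reference_id: str | None = None
    confidence_score: int | None = None

    def ki_molar(self) -> float:
        """Concentration in mol/L; raises on missing/unknown units."""
        unit = _normalize_units(self.units)
        if unit is None:
            raise ValueError(f"unknown concentration units: {self.units!r}")
        if self.value is None or not self.value > 0:
            raise ValueError(f"Ki value must be positive, got {self.value!r}")
        return float(self.value) * UNIT_SCALE[unit]


@dataclass(frozen=True)
class CuratedPair:
    """A unique (target, ligand) pair with its consensus pKi."""

    target_id: str
    ligand_id: str
    smiles: str
    pki: float

    def label_at(self, threshold: float) -> int:
        return label_activity(self.pki, threshold)


@dataclass
class CurationAudit:
    """Machine-readable account of what curation dropped and why."""

    n_input: int = 0
    dropped: Counter = field(default_factory=Counter)
    n_effective: int = 0
    n_pairs: int = 0
    n_targets_size_filtered: int = 0

    def lines(self) -> list[str]:
        out = [f"input_records\t{self.n_input}"]
        for rule in sorted(self.dropped):
            out.append(f"dropped_{rule}\t{self.dropped[rule]}")
        out.append(f"effective_records\t{self.n_effective}")
        out.append(f"curated_pairs\t{self.n_pairs}")
        out.append(f"targets_removed_by_size\t{self.n_targets_size_filtered}")
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines()) + "\n")


class TargetPanel:
    """Mapping target_id -> curated ligand list, with provenance tag."""

    def __init__(self, pairs: Iterable[CuratedPair], release: str = ""):
        self.release = release
        self._by_target: dict[str, list[CuratedPair]] = {}
        seen: set[tuple[str, str]] = set()
        for p in pairs:
            key = (p.target_id, p.ligand_id)
            if key in seen:
                raise ValueError(f"duplicate (target, ligand) pair {key}")
            seen.add(key)
            self._by_target.setdefault(p.target_id, []).append(p)

    @property
    def targets(self) -> list[str]:
        return sorted(self._by_target)

    def ligands(self, target_id: str) -> list[CuratedPair]:
        return list(self._by_target[target_id])

    def __contains__(self, target_id: str) -> bool:
        return target_id in self._by_target

    def __len__(self) -> int:
        return len(self._by_target)

    def n_pairs(self) -> int:
        return sum(len(v) for v in self._by_target.values())

    def pairs(self) -> list[CuratedPair]:
        return [p for t in self.targets for p in self._by_target[t]]

    def subset(self, keep: Mapping[str, Iterable[str]]) -> "TargetPanel":
        """Panel restricted to the given target -> ligand-id mapping."""
        out = []
        for t, lids in keep.items():
            lids = set(lids)
            out.extend(p for p in self._by_target.get(t, []) if p.ligand_id in lids)
        return TargetPanel(out, release=self.release)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.target_id, p.ligand_id, p.smiles, p.pki) for p in self.pairs()],
            columns=["target_id", "ligand_id", "smiles", "pki"],
        )


def to_pki(value: float, units: str) -> float:
    """pKi = -log10(Ki in mol/L).

    >>> to_pki(1000, "nM")
    6.0
    """
    unit = _normalize_units(units)
    if unit is None:
        raise ValueError(f"unknown concentration units: {units!r}")
    if not value > 0:
        raise ValueError(f"Ki value must be positive, got {value!r}")
    return -math.log10(value * UNIT_SCALE[unit])


def label_activity(pki: float, threshold: float) -> int:
    """1 ("active") iff pKi >= threshold, else 0."""
    return 1 if pki >= threshold else 0


def filter_effective(
    records: Iterable[BioactivityRecord], audit: CurationAudit | None = None
) -> list[BioactivityRecord]:
    """Drop ineffective records; never raises, order preserved.

    A record survives only if it is a direct-binding Ki measurement
    (confidence score 9) with a positive value, recognizable units, a
    reference, and an unambiguous '=' relation.
    """
    audit = audit if audit is not None else CurationAudit()
    kept = []
    for r in records:
        audit.n_input += 1
        if r.activity_type != "Ki":
            audit.dropped["activity_type"] += 1
        elif r.confidence_score != 9:
            audit.dropped["confidence_score"] += 1
        elif r.value is None or not (isinstance(r.value, (int, float)) and r.value > 0):
            audit.dropped["missing_value"] += 1
        elif _normalize_units(r.units) is None:
            audit.dropped["missing_units"] += 1
        elif r.reference_id is None or str(r.reference_id).strip() == "":
            audit.dropped["missing_reference"] += 1
        elif r.relation not in ACCEPTED_RELATIONS:
            audit.dropped["ambiguous_relation"] += 1
        else:
            kept.append(r)
    audit.n_effective += len(kept)
    return kept


def deduplicate(
    records: Iterable[BioactivityRecord], scale: str = "ki"
) -> dict[tuple[str, str], tuple[str, float]]:
    """Resolve multiple measurements per (target, ligand) pair.

    Within one reference the smallest Ki wins (experimental optimization /
    unclear stereoisomer annotations); the per-reference minima are then
    averaged across references.  ``scale='ki'`` averages on the
    concentration scale (arithmetic mean of Ki); ``scale='pki'`` averages
    on the log scale (geometric mean of Ki).

    Returns {(target_id, ligand_id): (smiles, pKi)}.
    """
    if scale not in ("ki", "pki"):
        raise ValueError(f"unknown averaging scale: {scale!r}")
    groups: dict[tuple[str, str], dict[str, float]] = {}
    smiles: dict[tuple[str, str], str] = {}
    for r in records:
        key = (r.target_id, r.ligand_id)
        ki = r.ki_molar()
        per_ref = groups.setdefault(key, {})
        ref = str(r.reference_id)
        per_ref[ref] = min(ki, per_ref.get(ref, math.inf))
        smiles.setdefault(key, r.smiles)
    out = {}
    for key, per_ref in groups.items():
        minima = list(per_ref.values())
        if scale == "ki":
            consensus = sum(minima) / len(minima)
        else:
            consensus = math.exp(sum(math.log(k) for k in minima) / len(minima))
        out[key] = (smiles[key], -math.log10(consensus))
    return out


def curate(
    records: Iterable[BioactivityRecord],
    min_ligands: int = 10,
    max_ligands: int = 10000,
    scale: str = "ki",
    release: str = "",
    audit: CurationAudit | None = None,
) -> TargetPanel:
    """Full curation pipeline: filter, deduplicate, size-filter."""
    audit = audit if audit is not None else CurationAudit()
    effective = filter_effective(records, audit)
    consensus = deduplicate(effective, scale=scale)
    pairs = [
        CuratedPair(t, l, smi, pki) for (t, l), (smi, pki) in sorted(consensus.items())
    ]
    audit.n_pairs = len(pairs)
    panel = TargetPanel(pairs, release=release)
    return filter_targets(panel, min_ligands, max_ligands, audit=audit)


def filter_targets(
    panel: TargetPanel,
    min_ligands: int = 10,
    max_ligands: int = 10000,
    audit: CurationAudit | None = None,
) -> TargetPanel:
    """Remove targets with too few or too many ligands (idempotent)."""
    keep = {
        t: [p.ligand_id for p in panel.ligands(t)]
        for t in panel.targets
        if min_ligands <= len(panel.ligands(t)) <= max_ligands
    }
    if audit is not None:
        audit.n_targets_size_filtered += len(panel) - len(keep)
    return panel.subset(keep)


def temporal_new_pairs(old_panel: TargetPanel, new_panel: TargetPanel) -> list[CuratedPair]:
    """Pairs present in the new release but not the old, on shared targets.

    Only targets occurring in both releases are considered, so a pair on a
    newly introduced target is not part of the temporal test set.
    """
    out = []
    for t in new_panel.targets:
        if t not in old_panel:
            continue
        old_ids = {p.ligand_id for p in old_panel.ligands(t)}
        out.extend(p for p in new_panel.ligands(t) if p.ligand_id not in old_ids)
    return out


# ---------------------------------------------------------------------------
# flat-file I/O

def read_bioactivity_table(path, sep: str | None = None) -> list[BioactivityRecord]:
    """Read a TSV/CSV bioactivity table into records.

    Column names are fixed (see REQUIRED_COLUMNS); order is free.  The
    separator is sniffed from the extension unless given.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(name):
            v = d[name].strip()
            return v if v else None

        value = opt("value")
        conf = opt("confidence_score")
        records.append(
            BioactivityRecord(
                target_id=d["target_id"],
                ligand_id=d["ligand_id"],
                smiles=d["smiles"],
                activity_type=opt("activity_type"),
                relation=opt("relation"),
                value=float(value) if value is not None else None,
                units=opt("units"),
                reference_id=opt("reference_id"),
                confidence_score=int(float(conf)) if conf is not None else None,
            )
        )
    return records


def write_records(records: Iterable[BioactivityRecord], path, sep: str = "\t") -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "target_id": r.target_id,
                "ligand_id": r.ligand_id,
                "smiles": r.smiles,
                "activity_type": r.activity_type or "",
                "relation": r.relation or "",
                "value": "" if r.value is None else repr(float(r.value)),
                "units": r.units or "",
                "reference_id": r.reference_id or "",
                "confidence_score": "" if r.confidence_score is None else r.confidence_score,
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep=sep, index=False)


def write_panel(panel: TargetPanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_panel(path, release: str = "") -> TargetPanel:
    df = pd.read_csv(path, sep="\t", comment="#")
    pairs = [
        CuratedPair(str(r.target_id), str(r.ligand_id), str(r.smiles), float(r.pki))
        for r in df.itertuples(index=False)
    ]
    return TargetPanel(pairs, release=release)
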