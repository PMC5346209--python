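"""Synthetic bioactivity fixtures with a known planted ground truth.

Every stage of the pipeline — curation, neighbor search, model fitting,
cross-validation, multi-target scanning — is testable without any
database download because this module generates chemically valid panels
whose structure-activity relationship is planted by construction.

Structure family
----------------
Each target owns a core: a trisubstituted benzene with two
target-defining chains (heteroatom prefix + alkyl length).  The target's
ligands are organized into *slots*.  A slot attaches one substituent
family from a fixed, chemically diverse catalogue (ethers, amines,
amides, esters, rings, ...) and contributes three ligands:

* a **reference** ligand with alkyl tail length ``m0`` — duplicated
  under two ligand ids, so a random fold split essentially never removes
  both copies from a training set at once;
* a **probe** ligand whose tail is extended by one or two carbons.

The substituent families are mutually diverse enough that a probe's
most-similar ligand within its target is its own slot's reference (the
fingerprint Tanimoto to the reference exceeds every cross-slot
similarity), and a reference's most-similar ligand is its duplicate.
This makes the features seen by nearest-neighbor search predictable at
generation time.

Planted activity law
--------------------
Reference pKi values are drawn from a well-separated potent/weak
mixture.  Each probe's active/inactive truth is then Bernoulli with

    P(active) = sigmoid(a0 + a1 * tc_ref + a2 * pKi_ref)

where ``tc_ref`` is the probe's (computed, not assumed) best Tanimoto to
the reference ligands of its target and ``pKi_ref`` that reference's
pKi — i.e. precisely the (Tc_most, pKi_most) feature pair the pipeline
will feed to its classifier.  The probe's own pKi is placed just above
or below the labeling threshold to encode the drawn truth.  References
keep their deterministic truth ``pKi >= threshold``; with the default
bimodal pKi mixture this is consistent with the law's decision at
Tc = 1.  Setting ``a1 = a2 = 0`` removes the structure-activity signal
entirely: every truth becomes an independent coin flip with
P(active) = sigmoid(a0), which is the null panel used to check
false-discovery control.

The generator emits, alongside the panel, a truth table with every
planted probability, from which the analytic accuracy of the
law-optimal classifier on the realized panel (and its binomial standard
error) can be computed — the yardstick the cross-validation accuracy is
compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .curation import BioactivityRecord, CuratedPair, TargetPanel
from .fingerprints import FingerprintCache, tanimoto
from .models import FeatureVector

__all__ = [
    "GeneratorConfig",
    "PanelSim",
    "TableSim",
    "SLOT_TEMPLATES",
    "generate_panel",
    "generate_bioactivity_table",
    "generate_release_tables",
    "generate_feature_data",
    "generate_queries",
    "panel_to_records",
    "make_core",
]

#: Substituent families, each a SMILES fragment template with an alkyl
#: tail ``{c}``; chosen to be mutually diverse so within-slot similarity
#: dominates cross-slot similarity.
SLOT_TEMPLATES = (
    "OC{c}",
    "N(C){c}",
    "c2ccc({c})cc2",
    "C(=O)N{c}",
    "C(=O)O{c}",
    "S{c}",
    "N2CCN(CC2){c}",
    "C2CCC(CC2){c}",
    "c2ccc(O{c})cc2",
    "N(CC){c}",
    "c2ncc({c})cc2",
    "OCC(=O)N{c}",
)

_PREFIXES = ("O", "N", "C")
_CHAIN_LENGTHS = (1, 2, 3, 4)


def make_core(x: str, a: int, y: str, b: int, substituent: str) -> str:
    """Trisubstituted benzene core with a slot substituent attached."""
    return f"{x}{'C' * a}c1ccc({substituent})c({'C' * b}{y})c1"


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic fixtures.

    The default law coefficients (a0, a1, a2) = (-10, 6, 1) give a
    strong but noisy similarity/potency signal; reference potencies are
    a 60/40 potent/weak mixture (pKi ~ N(7.5, 0.4) / N(3.5, 0.4))
    mirroring the potency-skew of curated Ki panels, and activity is
    labeled at pKi >= 6.
    """

    seed: int = 0
    n_targets: int = 50
    ligands_per_target: int = 36
    true_coefficients: tuple[float, float, float] = (-10.0, 6.0, 1.0)
    threshold: float = 6.0
    potent_fraction: float = 0.6
    potent_mean: float = 7.5
    weak_mean: float = 3.5
    ref_pki_sd: float = 0.4
    probe_gap_base: float = 0.3
    probe_gap_sd: float = 0.8
    # raw-table pathology rates
    dup_same_ref_rate: float = 0.15
    dup_cross_ref_rate: float = 0.15
    ineffective_rate: float = 0.15
    # temporal split
    new_fraction: float = 0.25

    @property
    def is_null(self) -> bool:
        return self.true_coefficients[1] == 0 and self.true_coefficients[2] == 0


@dataclass
class PanelSim:
    """A generated panel plus its planted ground truth."""

    config: GeneratorConfig
    panel: TargetPanel
    truth: pd.DataFrame  # one row per ligand; see generate_panel

    def analytic_accuracy(self) -> float:
        """Expected accuracy of the Bayes-optimal classifier on this panel.

        Bernoulli-labeled rows (probes, where the truth is a coin flip
        governed by the planted law) contribute max(p, 1-p): even the
        optimal rule cannot beat the label noise.  Reference rows are
        deterministic functions of their own features, so the optimal
        rule predicts them perfectly and they contribute 1.
        """
        p = self.truth["planted_p"].to_numpy()
        bern = self.truth["bernoulli"].to_numpy(dtype=bool)
        contrib = np.where(bern, np.maximum(p, 1.0 - p), 1.0)
        return float(contrib.mean())

    def analytic_accuracy_se(self) -> float:
        """Binomial standard error of realized accuracy around the analytic value."""
        p = self.truth["planted_p"].to_numpy()
        bern = self.truth["bernoulli"].to_numpy(dtype=bool)
        var = np.where(bern, p * (1.0 - p), 0.0)
        return float(np.sqrt(var.sum()) / len(p))


def _draw_slot_plan(cfg: GeneratorConfig, rng: np.random.Generator):
    """Distinct (prefix, length, prefix, length) cores, one per target."""
    combos = [
        (x, a, y, b)
        for x in _PREFIXES
        for a in _CHAIN_LENGTHS
        for y in _PREFIXES
        for b in _CHAIN_LENGTHS
    ]
    if cfg.n_targets > len(combos):
        raise ValueError(f"at most {len(combos)} distinct targets supported")
    idx = rng.choice(len(combos), size=cfg.n_targets, replace=False)
    return [combos[i] for i in idx]


def generate_panel(cfg: GeneratorConfig, cache: FingerprintCache | None = None) -> PanelSim:
    """Generate a panel with the planted structure-activity law.

    The returned truth table has one row per ligand with columns:
    target_id, ligand_id, role (reference/reference_dup/probe), smiles,
    pki, label, planted_tc, planted_pki_most, planted_p, bernoulli.
    """
    rng = np.random.default_rng(cfg.seed)
    cache = cache if cache is not None else FingerprintCache("morgan")
    a0, a1, a2 = cfg.true_coefficients
    n_slots = cfg.ligands_per_target // 3
    if n_slots < 1 or n_slots > len(SLOT_TEMPLATES):
        raise ValueError(
            f"ligands_per_target must be in [3, {3 * len(SLOT_TEMPLATES)}]"
        )
    cores = _draw_slot_plan(cfg, rng)
    pairs: list[CuratedPair] = []
    truth_rows = []
    for t_idx, (x, a, y, b) in enumerate(cores):
        target_id = f"T{t_idx:03d}"
        # build structures first
        slot_smiles = []  # (ref_smiles, probe_smiles)
        for k in range(n_slots):
            template = SLOT_TEMPLATES[k]
            m0 = 2
            d = 1 + (k % 2)
            ref = make_core(x, a, y, b, template.format(c="C" * m0))
            probe = make_core(x, a, y, b, template.format(c="C" * (m0 + d)))
            slot_smiles.append((ref, probe))
        all_smiles = [s for pair in slot_smiles for s in pair]
        fps = {s: fp for s, fp in zip(all_smiles, cache.get_many(all_smiles))}

        # reference potencies: well-separated potent/weak mixture
        ref_draw = np.where(
            rng.random(n_slots) < cfg.potent_fraction,
            rng.normal(cfg.potent_mean, cfg.ref_pki_sd, n_slots),
            rng.normal(cfg.weak_mean, cfg.ref_pki_sd, n_slots),
        )
        ref_pki = np.empty(n_slots)
        for k, (ref_smiles, _) in enumerate(slot_smiles):
            if cfg.is_null:
                # unconditional coin-flip label; the shared pKi of the two
                # copies necessarily encodes it, so conditional on its own
                # neighbor feature a reference is still deterministic
                label = int(rng.random() < _sigmoid(a0))
                pki = _encode_pki(label, cfg, rng)
                p = float(label)
            else:
                pki = float(ref_draw[k])
                label = int(pki >= cfg.threshold)
                p = _sigmoid(a0 + a1 * 1.0 + a2 * pki)
            ref_pki[k] = pki
            for copy, role in ((0, "reference"), (1, "reference_dup")):
                lid = f"L{t_idx:03d}S{k:02d}R{copy}"
                pairs.append(CuratedPair(target_id, lid, ref_smiles, pki))
                truth_rows.append(
                    (target_id, lid, role, ref_smiles, pki, label, 1.0, pki, p, False)
                )
        for k, (ref_smiles, probe_smiles) in enumerate(slot_smiles):
            lid = f"L{t_idx:03d}S{k:02d}Q"
            # realized best similarity to the target's reference ligands
            tcs = [
                tanimoto(fps[probe_smiles], fps[rs])
                for rs, _ in slot_smiles
            ]
            best = int(np.argmax(tcs))
            tc_ref = float(tcs[best])
            pki_ref = float(ref_pki[best])
            if cfg.is_null:
                p = _sigmoid(a0)
            else:
                p = _sigmoid(a0 + a1 * tc_ref + a2 * pki_ref)
            label = int(rng.random() < p)
            pki_enc = _encode_pki(label, cfg, rng)
            pairs.append(CuratedPair(target_id, lid, probe_smiles, pki_enc))
            truth_rows.append(
                (target_id, lid, "probe", probe_smiles, pki_enc, label, tc_ref, pki_ref, p, True)
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "target_id",
            "ligand_id",
            "role",
            "smiles",
            "pki",
            "label",
            "planted_tc",
            "planted_pki_most",
            "planted_p",
            "bernoulli",
        ],
    )
    return PanelSim(config=cfg, panel=TargetPanel(pairs, release="sim"), truth=truth)


def _encode_pki(label: int, cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    gap = cfg.probe_gap_base + abs(rng.normal(0.0, cfg.probe_gap_sd))
    return cfg.threshold + gap if label else cfg.threshold - gap


# ---------------------------------------------------------------------------
# raw-table fixtures


@dataclass
class TableSim:
    """Raw records plus the curated answer the pipeline should produce."""

    config: GeneratorConfig
    records: list[BioactivityRecord]
    key: dict  # (target_id, ligand_id) -> expected consensus pKi
    panel_sim: PanelSim


_UNIT_FACTORS = {"pM": 1e-12, "nM": 1e-9, "uM": 1e-6, "M": 1.0}


def _in_units(ki_molar: float, units: str) -> float:
    return ki_molar / _UNIT_FACTORS[units]


def generate_bioactivity_table(cfg: GeneratorConfig) -> TableSim:
    """Raw-table fixture exercising every curation rule.

    Starts from a generated panel and wraps each curated pair into one
    or more raw records: same-reference duplicates with a larger Ki (the
    minimum rule must recover the original), cross-reference duplicates
    whose per-reference minima average to a value the generator records
    in the answer key, and "ineffective" junk records covering each drop
    rule (missing units/reference/value, censored or missing relations,
    low confidence scores, non-Ki activity types).  With all pathology
    rates at zero, curation is the identity on the panel's value set.
    """
    sim = generate_panel(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    units_choices = list(_UNIT_FACTORS)
    records: list[BioactivityRecord] = []
    key: dict[tuple[str, str], float] = {}
    junk_cycle = 0
    for pair in sim.panel.pairs():
        ki = 10.0 ** (-pair.pki)
        units = units_choices[rng.integers(len(units_choices))]
        base = BioactivityRecord(
            target_id=pair.target_id,
            ligand_id=pair.ligand_id,
            smiles=pair.smiles,
            activity_type="Ki",
            relation="=",
            value=_in_units(ki, units),
            units=units,
            reference_id="ref1",
            confidence_score=9,
        )
        records.append(base)
        per_ref_minima = [ki]
        if rng.random() < cfg.dup_same_ref_rate:
            # larger value in the same reference: the minimum rule drops it
            records.append(
                replace(base, value=_in_units(ki * rng.uniform(1.5, 10.0), units))
            )
        if rng.random() < cfg.dup_cross_ref_rate:
            factor = rng.uniform(0.5, 2.0)
            units2 = units_choices[rng.integers(len(units_choices))]
            records.append(
                replace(
                    base,
                    reference_id="ref2",
                    value=_in_units(ki * factor, units2),
                    units=units2,
                )
            )
            per_ref_minima.append(ki * factor)
        key[(pair.target_id, pair.ligand_id)] = -math.log10(
            sum(per_ref_minima) / len(per_ref_minima)
        )
        if rng.random() < cfg.ineffective_rate:
            records.append(_junk_record(base, junk_cycle))
            junk_cycle += 1
    return TableSim(config=cfg, records=records, key=key, panel_sim=sim)


def _junk_record(base: BioactivityRecord, cycle: int) -> BioactivityRecord:
    """One 'ineffective' record; the rule violated cycles deterministically."""
    kind = cycle % 6
    if kind == 0:
        return replace(base, units=None)
    if kind == 1:
        return replace(base, reference_id=None)
    if kind == 2:
        return replace(base, relation=(">", "<", "~", None)[cycle % 4])
    if kind == 3:
        return replace(base, confidence_score=int(cycle % 9))
    if kind == 4:
        return replace(base, activity_type="IC50")
    return replace(base, value=None)


def panel_to_records(sim: PanelSim) -> list[BioactivityRecord]:
    """Noise-free raw records whose curation reproduces the panel exactly."""
    cfg = replace(
        sim.config, dup_same_ref_rate=0.0, dup_cross_ref_rate=0.0, ineffective_rate=0.0
    )
    return generate_bioactivity_table(cfg).records


def generate_release_tables(cfg: GeneratorConfig):
    """Two-release fixture: an early table and a later superset.

    Probe ligands are assigned a synthetic deposition date; a
    ``new_fraction`` of them (plus one whole extra target, which a
    correct temporal comparison must ignore) appear only in the later
    release.  Returns (old_records, new_records, new_pair_keys) where
    new_pair_keys is the set of (target_id, ligand_id) a temporal
    comparison on shared targets should yield.
    """
    table = generate_bioactivity_table(cfg)
    sim = table.panel_sim
    rng = np.random.default_rng(cfg.seed + 2)
    probe_ids = set(
        sim.truth.loc[sim.truth["role"] == "probe", ["target_id", "ligand_id"]]
        .apply(tuple, axis=1)
    )
    late = {k for k in probe_ids if rng.random() < cfg.new_fraction}
    extra_target = max(sim.panel.targets)  # present only in the new release
    old_records = [
        r
        for r in table.records
        if (r.target_id, r.ligand_id) not in late and r.target_id != extra_target
    ]
    new_records = list(table.records)
    new_pair_keys = {k for k in late if k[0] != extra_target}
    return old_records, new_records, new_pair_keys


# ---------------------------------------------------------------------------
# feature-space fixtures


def generate_feature_data(
    cfg: GeneratorConfig, n: int = 10000
) -> tuple[list[tuple[FeatureVector, int]], np.ndarray, np.ndarray]:
    """(feature, label) rows drawn directly from the logistic law.

    tc ~ Uniform(0, 1); pKi ~ equal mixture of N(7, 1) and N(5, 1);
    label ~ Bernoulli(sigmoid(a0 + a1*tc + a2*pKi)).  Returns the rows
    together with the raw (n, 2) feature matrix and label vector.
    """
    rng = np.random.default_rng(cfg.seed)
    a0, a1, a2 = cfg.true_coefficients
    tc = rng.uniform(0.0, 1.0, n)
    comp = rng.random(n) < 0.5
    pki = np.where(comp, rng.normal(7.0, 1.0, n), rng.normal(5.0, 1.0, n))
    eta = a0 + a1 * tc + a2 * pki
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)
    X = np.column_stack([tc, pki])
    rows = [
        (FeatureVector(float(t), float(k)), int(lab))
        for t, k, lab in zip(tc, pki, y)
    ]
    return rows, X, y


def generate_queries(cfg: GeneratorConfig, n: int) -> list[str]:
    """Query structures from the same family, outside any panel."""
    rng = np.random.default_rng(cfg.seed + 3)
    out = []
    for _ in range(n):
        x = _PREFIXES[rng.integers(len(_PREFIXES))]
        y = _PREFIXES[rng.integers(len(_PREFIXES))]
        a = int(rng.integers(1, 5))
        b = int(rng.integers(1, 5))
        template = SLOT_TEMPLATES[rng.integers(len(SLOT_TEMPLATES))]
        m = int(rng.integers(5, 8))  # tail lengths no panel ligand uses
        out.append(make_core(x, a, y, b, template.format(c="C" * m)))
    return out
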