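"""Fingerprints, Tanimoto similarity and most-similar-ligand search.

Two fingerprint schemes are supported: Morgan circular fingerprints of
radius 2 (ECFP4-like) computed with RDKit and folded to 2048 bits, and
Open Babel's path-based FP2 (linear fragments up to length 7, 1024 bits).
The FP2 backend shells out to the ``obabel`` executable and is optional:
when the executable is absent the scheme is reported as unavailable
rather than silently substituted.

Both schemes are reduced to plain on-bit sets, so one Tanimoto code path
serves both.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

if TYPE_CHECKING:  # pragma: no cover
    from .curation import CuratedPair

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Fingerprint",
    "NearestNeighbor",
    "StructureParseError",
    "SchemeUnavailableError",
    "MORGAN_RADIUS",
    "MORGAN_NBITS",
    "FP2_NBITS",
    "canonical_smiles",
    "compute_fingerprint",
    "tanimoto",
    "most_similar",
    "FingerprintCache",
    "fp2_available",
    "write_fingerprints",
    "read_fingerprints",
]

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048
FP2_NBITS = 1024

SCHEMES = ("morgan", "fp2")


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


class SchemeUnavailableError(RuntimeError):
    """Raised when a fingerprint backend is not installed."""


@dataclass(frozen=True)
class Fingerprint:
    """A folded binary fingerprint as a set of on-bit indices."""

    scheme: str
    on_bits: frozenset[int]
    length: int

    def __post_init__(self):
        if self.on_bits and (min(self.on_bits) < 0 or max(self.on_bits) >= self.length):
            raise ValueError("on_bits outside [0, length)")


@dataclass(frozen=True)
class NearestNeighbor:
    """The most-similar annotated ligand of one target for a query."""

    ligand_id: str
    tc_most: float
    pki_most: float


_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS
)


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    return Chem.MolToSmiles(mol)


def _morgan_bits(smiles: str) -> frozenset[int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    return frozenset(_morgan_gen.GetFingerprint(mol).GetOnBits())


def fp2_available() -> bool:
    return shutil.which("obabel") is not None


def _fp2_bits_batch(smiles_list: Sequence[str]) -> list[frozenset[int]]:
    """FP2 on-bit sets via the obabel CLI, one subprocess per batch.

    The hex dump is decoded into bit indices with a fixed convention;
    Tanimoto values only depend on intersection/union cardinalities, so
    any consistent decoding is equivalent.
    """
    if not fp2_available():
        raise SchemeUnavailableError(
            "FP2 requires the Open Babel 'obabel' executable, which was not found on PATH"
        )
    # validate through RDKit first so the error contract matches morgan
    for smi in smiles_list:
        if Chem.MolFromSmiles(smi) is None:
            raise StructureParseError(smi)
    with tempfile.TemporaryDirectory() as tmp:
        smi_path = Path(tmp) / "mols.smi"
        smi_path.write_text(
            "".join(f"{smi} m{i}\n" for i, smi in enumerate(smiles_list))
        )
        proc = subprocess.run(
            ["obabel", str(smi_path), "-ofpt", "-xfFP2", "-xh"],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0:  # pragma: no cover - obabel failure
        raise SchemeUnavailableError(f"obabel failed: {proc.stderr.strip()}")
    out: list[frozenset[int]] = []
    hex_words: list[str] = []
    for line in proc.stdout.splitlines():
        line = line.strip()
        tokens = line.split()
        if line.startswith(">"):
            if hex_words:
                out.append(_decode_hex_words(hex_words))
                hex_words = []
        elif tokens and all(_HEX_WORD.fullmatch(tok) for tok in tokens):
            hex_words.extend(tokens)
        # anything else is obabel commentary ("Possible superstructure...")
    if hex_words:
        out.append(_decode_hex_words(hex_words))
    if len(out) != len(smiles_list):  # pragma: no cover - parse guard
        raise RuntimeError(
            f"expected {len(smiles_list)} FP2 fingerprints, parsed {len(out)}"
        )
    return out


_HEX_WORD = re.compile(r"[0-9a-fA-F]{8}")


def _decode_hex_words(words: list[str]) -> frozenset[int]:
    value = int("".join(words), 16)
    bits = []
    i = 0
    while value:
        if value & 1:
            bits.append(i)
        value >>= 1
        i += 1
    return frozenset(bits)


def compute_fingerprint(smiles: str, scheme: str = "morgan") -> Fingerprint:
    """Fingerprint of one structure; deterministic, canonicalization-stable.

    Raises :class:`StructureParseError` for unparseable SMILES and
    :class:`SchemeUnavailableError` when the FP2 backend is missing.
    """
    if scheme == "morgan":
        return Fingerprint("morgan", _morgan_bits(smiles), MORGAN_NBITS)
    if scheme == "fp2":
        return Fingerprint("fp2", _fp2_bits_batch([smiles])[0], FP2_NBITS)
    raise ValueError(f"unknown fingerprint scheme: {scheme!r}")


def compute_fingerprints(smiles_list: Sequence[str], scheme: str = "morgan") -> list[Fingerprint]:
    """Vectorized variant of :func:`compute_fingerprint` (one obabel call)."""
    if scheme == "morgan":
        return [Fingerprint("morgan", _morgan_bits(s), MORGAN_NBITS) for s in smiles_list]
    if scheme == "fp2":
        return [
            Fingerprint("fp2", bits, FP2_NBITS) for bits in _fp2_bits_batch(smiles_list)
        ]
    raise ValueError(f"unknown fingerprint scheme: {scheme!r}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B| over on-bits; two empty fingerprints give 0."""
    if a.scheme != b.scheme:
        raise ValueError(f"fingerprint scheme mismatch: {a.scheme} vs {b.scheme}")
    if not a.on_bits and not b.on_bits:
        return 0.0
    inter = len(a.on_bits & b.on_bits)
    return inter / (len(a.on_bits) + len(b.on_bits) - inter)


def most_similar(
    query_fp: Fingerprint,
    ligands: Iterable["CuratedPair"],
    fingerprints: dict[str, Fingerprint],
) -> NearestNeighbor:
    """Most-similar ligand of a target for a query fingerprint.

    Ties on Tc are broken toward the more potent ligand (higher pKi),
    then lexicographically by ligand id, so the result does not depend on
    the order of the ligand list.
    """
    best = None
    for p in ligands:
        tc = tanimoto(query_fp, fingerprints[p.ligand_id])
        key = (tc, p.pki, _NegStr(p.ligand_id))
        if best is None or key > best[0]:
            best = (key, p, tc)
    if best is None:
        raise ValueError("most_similar requires a non-empty ligand list")
    _, pair, tc = best
    return NearestNeighbor(ligand_id=pair.ligand_id, tc_most=tc, pki_most=pair.pki)


class _NegStr(str):
    """String with reversed ordering, for descending-id tie-breaks."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def write_fingerprints(fingerprints: dict[str, Fingerprint], path) -> None:
    """Persist per-ligand fingerprints as TSV.

    Columns: ligand_id, scheme, length, comma-separated on_bits (sorted).
    """
    with open(path, "w") as fh:
        fh.write("ligand_id\tscheme\tlength\ton_bits\n")
        for lid in sorted(fingerprints):
            fp = fingerprints[lid]
            bits = ",".join(str(b) for b in sorted(fp.on_bits))
            fh.write(f"{lid}\t{fp.scheme}\t{fp.length}\t{bits}\n")


def read_fingerprints(path) -> dict[str, Fingerprint]:
    out: dict[str, Fingerprint] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["ligand_id", "scheme", "length", "on_bits"]:
            raise ValueError(f"{path}: not a fingerprint TSV")
        for line in fh:
            lid, scheme, length, bits = line.rstrip("\n").split("\t")
            on_bits = frozenset(int(b) for b in bits.split(",")) if bits else frozenset()
            out[lid] = Fingerprint(scheme, on_bits, int(length))
    return out


@dataclass
class FingerprintCache:
    """Fingerprint cache keyed by structure string.

    Panel scans and cross-validation reslice the same ligand sets many
    times; caching on the SMILES string means each structure is
    fingerprinted once per scheme regardless of how panels are split.
    """

    scheme: str = "morgan"
    _store: dict = field(default_factory=dict)

    def get_many(self, smiles_list: Sequence[str]) -> list[Fingerprint]:
        missing = [s for s in dict.fromkeys(smiles_list) if s not in self._store]
        if missing:
            for s, fp in zip(missing, compute_fingerprints(missing, self.scheme)):
                self._store[s] = fp
        return [self._store[s] for s in smiles_list]

    def get(self, smiles: str) -> Fingerprint:
        return self.get_many([smiles])[0]

    def for_target(self, panel, target_id: str) -> dict[str, Fingerprint]:
        ligands = panel.ligands(target_id)
        fps = self.get_many([p.smiles for p in ligands])
        return {p.ligand_id: fp for p, fp in zip(ligands, fps)}
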