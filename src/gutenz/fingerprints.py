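"""Binary substructure fingerprints across named families.

The classification/similarity method relies on having several *diverse*
fingerprint families — path-based, graph-based, substructure-key,
circular, atom-pair, torsion and E-state — rather than on one specific
bit dialect.  Each family here is a pure function Molecule -> fixed-length
bit vector, registered with a declared length, so feature selection and
Tanimoto search can reference bits by the stable column id
``family:bitindex`` (0-based).

Count-valued variants (E-state, atom pairs, torsions) are binarized
(count > 0 -> 1): selection merit and the Tanimoto coefficient are defined
on binary vectors.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.EState.Fingerprinter import FingerprintMol as _estate_fp

from .chem_io import Molecule

PROVIDER_VERSION = "1"


@dataclass(frozen=True)
class BitFingerprint:
    family: str
    bits: np.ndarray  # uint8 vector of 0/1
    length: int

    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class FingerprintProvider:
    family: str
    declared_length: int
    compute: Callable[[Chem.Mol], np.ndarray]


def _bv_to_array(bv, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def _path1024(mol):
    return _bv_to_array(Chem.RDKFingerprint(mol, fpSize=1024), 1024)


def _graph1024(mol):
    # bond orders ignored -> a "graph only" variant of the path family
    return _bv_to_array(Chem.RDKFingerprint(mol, fpSize=1024, useBondOrder=False), 1024)


def _maccs166(mol):
    # RDKit emits 167 bits with bit 0 permanently unused; drop it
    return _bv_to_array(MACCSkeys.GenMACCSKeys(mol), 167)[1:]


def _estate79(mol):
    counts = _estate_fp(mol)[0]
    return (np.asarray(counts) > 0).astype(np.uint8)


def _pattern1024(mol):
    return _bv_to_array(Chem.PatternFingerprint(mol, fpSize=1024), 1024)


def _avalon512(mol):
    return _bv_to_array(pyAvalonTools.GetAvalonFP(mol, nBits=512), 512)


_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_ap_gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=1024)
_tt_gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=1024)


def _morgan1024(mol):
    return _bv_to_array(_morgan_gen.GetFingerprint(mol), 1024)


def _atompair1024(mol):
    return _bv_to_array(_ap_gen.GetFingerprint(mol), 1024)


def _torsion1024(mol):
    return _bv_to_array(_tt_gen.GetFingerprint(mol), 1024)


#: Registration order is the column order of fingerprint_matrix and the
#: concatenation order of the hybrid fingerprint.
REGISTRY: "OrderedDict[str, FingerprintProvider]" = OrderedDict(
    (p.family, p)
    for p in [
        FingerprintProvider("path1024", 1024, _path1024),
        FingerprintProvider("graph1024", 1024, _graph1024),
        FingerprintProvider("maccs166", 166, _maccs166),
        FingerprintProvider("estate79", 79, _estate79),
        FingerprintProvider("pattern1024", 1024, _pattern1024),
        FingerprintProvider("avalon512", 512, _avalon512),
        FingerprintProvider("morgan1024", 1024, _morgan1024),
        FingerprintProvider("atompair1024", 1024, _atompair1024),
        FingerprintProvider("torsion1024", 1024, _torsion1024),
    ]
)

#: Families used by the consensus similarity search (path-based,
#: substructure-pattern and MACCS keys respectively).
SIMILARITY_FAMILIES = ("path1024", "pattern1024", "maccs166")


def compute_fingerprint(mol: Molecule, family: str) -> BitFingerprint:
    """Compute one family's fingerprint for one molecule (deterministic)."""
    if family not in REGISTRY:
        raise KeyError(f"unregistered fingerprint family {family!r}")
    provider = REGISTRY[family]
    try:
        bits = provider.compute(mol.mol)
    except Exception as exc:
        raise ValueError(f"family {family!r} failed on molecule {mol.id!r}: {exc}") from exc
    if bits.shape != (provider.declared_length,):
        raise AssertionError(
            f"{family}: got {bits.shape[0]} bits, declared {provider.declared_length}")
    return BitFingerprint(family=family, bits=bits, length=provider.declared_length)


def column_ids(families: list[str]) -> list[str]:
    cols: list[str] = []
    for fam in families:
        if fam not in REGISTRY:
            raise KeyError(f"unregistered fingerprint family {fam!r}")
        cols.extend(f"{fam}:{i}" for i in range(REGISTRY[fam].declared_length))
    return cols


def fingerprint_matrix(
    mols: list[Molecule], families: list[str]
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Stack per-molecule fingerprints into a feature table.

    Rows follow input order (indexed by molecule id); columns are
    ``family:bitindex`` with families in registration-call order and bits
    ascending.  A molecule failing any family is excluded from the table
    and reported in the failure list; the run continues.
    """
    ordered = [f for f in families]  # preserve caller order
    cols = column_ids(ordered)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    failures: list[tuple[str, str]] = []
    for m in mols:
        try:
            vec = np.concatenate([compute_fingerprint(m, fam).bits for fam in ordered]) \
                if ordered else np.zeros(0, dtype=np.uint8)
        except Exception as exc:
            failures.append((m.id, str(exc)))
            continue
        rows.append(vec)
        ids.append(m.id)
    data = np.vstack(rows) if rows else np.zeros((0, len(cols)), dtype=np.uint8)
    return pd.DataFrame(data, index=ids, columns=cols, dtype=np.uint8), failures
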