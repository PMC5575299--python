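"""Molecule parsing, canonicalization and serialization.

Every downstream stage (curation, fingerprinting, similarity search)
operates on :class:`Molecule` objects produced here.  The canonical key is
a canonical isomeric SMILES string, so two structurally identical inputs —
regardless of atom ordering or of whether they arrived as SMILES, MOL or
SDF — map to the same key.  Salt/fragment mixtures are reduced to the
largest covalent fragment, and that action is logged in the molecule's
provenance so the automatic rule is auditable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit parse noise goes through our failure lists

FORMATS = ("sdf", "mol", "smiles-table")


@dataclass
class Molecule:
    """A parsed molecule with a structure-derived canonical key."""

    id: str
    mol: Chem.Mol
    canonical_key: str
    name: str | None = None
    provenance: list[str] = field(default_factory=list)

    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()


@dataclass
class ParseFailure:
    """A record that could not be parsed; never silently dropped."""

    index: int
    reason: str
    source: str = ""


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES; stereochemistry is retained when present."""
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def _largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol, False
    best = max(frags, key=lambda m: (m.GetNumAtoms(), canonical_smiles(m)))
    return best, True


def from_rdkit(mol: Chem.Mol, mol_id: str, name: str | None = None) -> Molecule:
    """Wrap an RDKit mol: sanitize, keep the largest fragment, derive the key."""
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"molecule {mol_id!r} has no atoms")
    provenance: list[str] = []
    mol, stripped = _largest_fragment(mol)
    if stripped:
        provenance.append("kept largest covalent fragment (salt/mixture stripped)")
    Chem.SanitizeMol(mol)
    return Molecule(id=mol_id, mol=mol, canonical_key=canonical_smiles(mol),
                    name=name, provenance=provenance)


def from_smiles(smiles: str, mol_id: str, name: str | None = None) -> Molecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {mol_id!r}: {smiles!r}")
    return from_rdkit(mol, mol_id, name)


def read_molecules(path: str, fmt: str) -> tuple[list[Molecule], list[ParseFailure]]:
    """Read molecules from ``path``.

    Parameters
    ----------
    path:
        Input file.  Must exist; an unreadable file is a fatal error.
    fmt:
        One of ``sdf`` (V2000 multi-record), ``mol`` (single MOL block) or
        ``smiles-table`` (tab-separated ``smiles<TAB>id``, UTF-8, ``#``
        comment lines ignored).

    Returns
    -------
    (molecules, failures):
        Successfully parsed molecules (each with a canonical key) and a
        list of per-record failures carrying the record index and reason.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from {FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    mols: list[Molecule] = []
    failures: list[ParseFailure] = []

    if fmt in ("sdf", "mol"):
        supplier = Chem.SDMolSupplier(path, sanitize=False)
        for i, raw in enumerate(supplier):
            if raw is None:
                failures.append(ParseFailure(i, "unparseable MOL block", path))
                continue
            mol_id = raw.GetProp("_Name").strip() if raw.HasProp("_Name") else ""
            mol_id = mol_id or f"record{i}"
            try:
                mols.append(from_rdkit(raw, mol_id))
            except Exception as exc:  # bad valence etc. — collected, not fatal
                failures.append(ParseFailure(i, str(exc), path))
        if fmt == "mol" and len(mols) + len(failures) > 1:
            raise ValueError(f"{path}: 'mol' format expects a single record")
    else:
        with open(path, encoding="utf-8") as fh:
            row = -1
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                row += 1
                parts = line.split("\t")
                smiles = parts[0].strip()
                mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"row{row}"
                try:
                    mols.append(from_smiles(smiles, mol_id))
                except Exception as exc:
                    failures.append(ParseFailure(row, f"{exc}", path))
    return mols, failures


def write_molecules(mols: list[Molecule], path: str, fmt: str) -> None:
    """Write molecules so that a read round-trip reproduces canonical keys."""
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from {FORMATS}")
    if fmt in ("sdf", "mol"):
        if fmt == "mol" and len(mols) > 1:
            raise ValueError("'mol' format holds a single molecule")
        writer = Chem.SDWriter(path)
        try:
            for m in mols:
                out = Chem.Mol(m.mol)
                out.SetProp("_Name", m.id)
                writer.write(out)
        finally:
            writer.close()
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# smiles\tid\n")
            for m in mols:
                fh.write(f"{m.canonical_key}\t{m.id}\n")
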