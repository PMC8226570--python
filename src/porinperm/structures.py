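"""Structure input: multi-conformer SDF and SMILES -> conformer ensembles.

RDKit does the parsing and conformer embedding; this module only maps its
molecules onto :class:`~porinperm.ensembles.ConformerEnsemble` objects with
the bundled vdW radius table.  Partial charges come, in order of
preference, from a per-atom charge CSV (columns ``id, atom_index,
charge``), from a ``PartialCharge``-style atom property in the SDF, or —
for SMILES input — from Gasteiger assignment.  The charge provenance is
recorded in the ensemble metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ensembles import ConformerEnsemble
from .radii import vdw_radius

__all__ = [
    "read_charge_csv",
    "read_sdf_ensembles",
    "read_smiles_ensembles",
    "read_alogp_csv",
]


def read_charge_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Per-atom charges keyed by compound id, ordered by ``atom_index``."""
    frame = pd.read_csv(path)
    required = {"id", "atom_index", "charge"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"charge CSV missing columns: {sorted(missing)}")
    charges: dict[str, np.ndarray] = {}
    for cid, group in frame.groupby("id", sort=False):
        ordered = group.sort_values("atom_index")
        charges[str(cid)] = ordered["charge"].to_numpy(dtype=float)
    return charges


def read_alogp_csv(path: str | Path) -> dict[str, float]:
    """Mapping ``id -> alogp`` from a two-column CSV."""
    frame = pd.read_csv(path)
    missing = {"id", "alogp"} - set(frame.columns)
    if missing:
        raise ValueError(f"alogp CSV missing columns: {sorted(missing)}")
    return {
        str(cid): float(v) for cid, v in zip(frame["id"], frame["alogp"])
    }


def _mol_arrays(mol, radius_overrides=None):
    symbols = [atom.GetSymbol() for atom in mol.GetAtoms()]
    radii = np.array([vdw_radius(s, radius_overrides) for s in symbols])
    masses = np.array([atom.GetMass() for atom in mol.GetAtoms()])
    return radii, masses


def _sdf_charges(mol) -> np.ndarray | None:
    """Partial charges from an atom property, if the SDF carries one."""
    values = []
    for atom in mol.GetAtoms():
        for prop in ("PartialCharge", "partial_charge", "_TriposPartialCharge"):
            if atom.HasProp(prop):
                values.append(atom.GetDoubleProp(prop))
                break
        else:
            return None
    return np.array(values)


def read_sdf_ensembles(
    path: str | Path,
    charges: dict[str, np.ndarray] | None = None,
    radius_overrides: dict[str, float] | None = None,
) -> list[ConformerEnsemble]:
    """Read a (multi-conformer) SDF; records with the same title merge.

    Consecutive SDF records sharing a molecule title become conformers of
    one ensemble.  ``charges`` overrides any charges stored in the file.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    grouped: dict[str, list] = {}
    order: list[str] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparsable SDF record #{i + 1} in {path}")
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        name = name or f"mol{i + 1}"
        if name not in grouped:
            grouped[name] = []
            order.append(name)
        grouped[name].append(mol)
    ensembles = []
    for name in order:
        mols = grouped[name]
        radii, masses = _mol_arrays(mols[0], radius_overrides)
        if charges and name in charges:
            q = charges[name]
            source = "charge CSV"
        else:
            q = _sdf_charges(mols[0])
            source = "SDF atom property"
            if q is None:
                raise ValueError(
                    f"no partial charges for {name!r}: none stored in the SDF "
                    "and none supplied via a charge CSV"
                )
        positions = np.stack(
            [m.GetConformer().GetPositions() for m in mols]
        )
        ensembles.append(
            ConformerEnsemble(
                compound_id=name,
                positions=positions,
                charges=np.asarray(q, dtype=float),
                radii=radii,
                masses=masses,
                metadata={"conformer_source": "input SDF", "charges": source},
            )
        )
    return ensembles


def read_smiles_ensembles(
    path: str | Path,
    n_conformers: int = 10,
    seed: int = 0,
    radius_overrides: dict[str, float] | None = None,
) -> list[ConformerEnsemble]:
    """Parse a ``SMILES<TAB>id`` file and embed conformers (fixed seed).

    Hydrogens are added, ``n_conformers`` conformers embedded with ETKDG
    (reproducible via ``seed``) and MMFF-optimised when parameters exist;
    Gasteiger partial charges are assigned.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    ensembles = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"smi{lineno}"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"line {lineno}: unparsable SMILES {smiles!r}")
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + lineno
        conf_ids = AllChem.EmbedMultipleConfs(mol, n_conformers, params)
        if not conf_ids:
            raise ValueError(f"line {lineno}: conformer embedding failed")
        try:
            AllChem.MMFFOptimizeMoleculeConfs(mol)
        except Exception:
            pass  # unoptimised geometries are still usable
        AllChem.ComputeGasteigerCharges(mol)
        q = np.array(
            [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]
        )
        radii, masses = _mol_arrays(mol, radius_overrides)
        positions = np.stack(
            [mol.GetConformer(c).GetPositions() for c in conf_ids]
        )
        ensembles.append(
            ConformerEnsemble(
                compound_id=cid,
                positions=positions,
                charges=q,
                radii=radii,
                masses=masses,
                metadata={
                    "conformer_source": f"ETKDG embedding (seed {seed + lineno})",
                    "charges": "Gasteiger",
                },
            )
        )
    return ensembles
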