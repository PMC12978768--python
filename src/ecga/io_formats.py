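"""Readers and writers for all external data used by the EC-GA pipeline.

The canonical interchange format for conformer ensembles is a versioned JSON
document (``ecqsar4d-ensemble/1``) carrying, per compound, the atom list,
bond list and every retained conformer with its relative energy (kcal/mol),
coordinates (Å), partial atomic charges (e) and optional named per-atom or
per-conformer properties.  SDF (V2000) ingest is supported for geometry-only
structures; electronic fields are then explicitly absent, never zero.

Activity tables, per-conformer descriptor panels and atom-correspondence
(skeleton label) maps are plain CSV: comma-separated, header row, UTF-8,
"." decimal.

Activity conventions: pIC50 is -log10 of the molar IC50 (so 1 nM -> 9.0) and
compounds with pIC50 >= 7.61 are classified as high-activity; the threshold
comparison is inclusive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ENSEMBLE_SCHEMA = "ecqsar4d-ensemble/1"

#: Default pIC50 threshold separating high- from low-activity compounds.
DEFAULT_ACTIVITY_THRESHOLD = 7.61


class FormatError(ValueError):
    """A document violates the documented schema or CSV contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    index: int                      # 1-based, unique and contiguous
    element: str
    skeleton_label: Optional[str] = None


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: Optional[float] = None
    wiberg: Optional[float] = None
    bond_energy: Optional[float] = None          # kcal/mol
    bond_polarizability: Optional[float] = None  # Å^3


@dataclass
class Conformer:
    conformer_id: str
    rel_energy: float               # kcal/mol, >= 0 after re-referencing
    has_imaginary_freq: bool
    coords: np.ndarray              # (n_atoms, 3) Å
    atomic_charge: Optional[np.ndarray] = None   # (n_atoms,) e; None for SDF ingest
    atomic_props: dict[str, np.ndarray] = field(default_factory=dict)
    descriptors: dict[str, float] = field(default_factory=dict)


@dataclass
class ConformerEnsemble:
    """A compound represented by its ensemble of retained conformers."""

    compound_id: str
    atoms: list[Atom]
    bonds: list[Bond]
    conformers: list[Conformer]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    def rel_energies(self) -> np.ndarray:
        return np.array([c.rel_energy for c in self.conformers], dtype=float)

    def conformer(self, conformer_id: str) -> Conformer:
        for c in self.conformers:
            if c.conformer_id == conformer_id:
                return c
        raise KeyError(f"compound {self.compound_id!r}: no conformer {conformer_id!r}")

    def lowest_energy_conformer(self) -> Conformer:
        return min(self.conformers, key=lambda c: (c.rel_energy, c.conformer_id))

    def bonded_pairs(self) -> set[tuple[int, int]]:
        return {(b.i, b.j) for b in self.bonds}

    def validate(self) -> None:
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise FormatError(
                f"compound {self.compound_id!r}: duplicate atom index {dupes[0]}")
        if indices != list(range(1, len(indices) + 1)):
            raise FormatError(
                f"compound {self.compound_id!r}: atom indices must be contiguous "
                f"from 1, got {indices}")
        n = len(self.atoms)
        for b in self.bonds:
            if not (1 <= b.i <= n) or not (1 <= b.j <= n):
                raise FormatError(
                    f"compound {self.compound_id!r}: bond ({b.i},{b.j}) references "
                    f"a missing atom (molecule has {n} atoms)")
            if not b.i < b.j:
                raise FormatError(
                    f"compound {self.compound_id!r}: bond ({b.i},{b.j}) must have i<j")
        if not self.conformers:
            raise FormatError(f"compound {self.compound_id!r}: no conformers")
        for c in self.conformers:
            if c.coords.shape != (n, 3):
                raise FormatError(
                    f"compound {self.compound_id!r} conformer {c.conformer_id!r}: "
                    f"expected {n} coordinate triplets, got shape {c.coords.shape}")
            if c.atomic_charge is not None and c.atomic_charge.shape != (n,):
                raise FormatError(
                    f"compound {self.compound_id!r} conformer {c.conformer_id!r}: "
                    f"expected {n} charges, got {c.atomic_charge.shape}")
            if not math.isfinite(c.rel_energy):
                raise FormatError(
                    f"compound {self.compound_id!r} conformer {c.conformer_id!r}: "
                    f"non-finite energy")

    def rereference_energies(self) -> None:
        """Shift relative energies so the ensemble minimum is exactly 0."""
        if not self.conformers:
            return
        emin = min(c.rel_energy for c in self.conformers)
        for c in self.conformers:
            c.rel_energy -= emin


@dataclass
class ActivityTable:
    """Per-compound experimental activities, classes and train/test split."""

    frame: pd.DataFrame  # columns: compound_id, pic50, activity_class, split
    label_overrides: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["compound_id", "pic50", "printed_class", "threshold_class"]))

    def __post_init__(self) -> None:
        required = {"compound_id", "pic50", "activity_class", "split"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"activity table missing columns {sorted(missing)}")
        if self.frame["compound_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["compound_id"].duplicated(), "compound_id"]
            raise FormatError(f"duplicate compound_id {dupes.iloc[0]!r}")
        if not np.isfinite(self.frame["pic50"].to_numpy(dtype=float)).all():
            raise FormatError("non-finite pic50 value in activity table")

    def classes(self) -> dict[str, str]:
        return dict(zip(self.frame["compound_id"], self.frame["activity_class"]))

    def pic50(self, compound_id: str) -> float:
        row = self.frame.loc[self.frame["compound_id"] == compound_id]
        if row.empty:
            raise KeyError(compound_id)
        return float(row["pic50"].iloc[0])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class AtomMap:
    """Correspondence between per-compound atom indices and skeleton labels."""

    frame: pd.DataFrame  # columns: compound_id, local_atom_index, skeleton_label

    def __post_init__(self) -> None:
        required = {"compound_id", "local_atom_index", "skeleton_label"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"atom map missing columns {sorted(missing)}")
        if self.frame.duplicated(["compound_id", "local_atom_index"]).any():
            raise FormatError("duplicate (compound_id, local_atom_index) row in atom map")
        if self.frame.duplicated(["compound_id", "skeleton_label"]).any():
            raise FormatError("skeleton_label maps to more than one atom in a compound")
        self._lookup = {
            (r.compound_id, r.skeleton_label): int(r.local_atom_index)
            for r in self.frame.itertuples()
        }

    def lookup(self, compound_id: str, skeleton_label: str) -> Optional[int]:
        """Local atom index for a label, or None when the label is unmapped."""
        return self._lookup.get((compound_id, skeleton_label))


@dataclass
class DescriptorPanel:
    """Per-(compound, conformer) descriptor vectors a_ni^(j), indexed 1..p."""

    frame: pd.DataFrame  # index: (compound_id, conformer_id); columns: descriptors

    def __post_init__(self) -> None:
        if list(self.frame.index.names) != ["compound_id", "conformer_id"]:
            raise FormatError(
                "descriptor panel must be indexed by (compound_id, conformer_id)")
        if len(set(self.frame.columns)) != len(self.frame.columns):
            raise FormatError("duplicate descriptor names")
        values = self.frame.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            comp, conf = self.frame.index[r]
            raise FormatError(
                f"missing/non-finite descriptor value at compound {comp!r}, "
                f"conformer {conf!r}, descriptor {self.frame.columns[c]!r}")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    def vector(self, compound_id: str, conformer_id: str) -> np.ndarray:
        return self.frame.loc[(compound_id, conformer_id)].to_numpy(dtype=float)

    def matrix(self, compound_id: str, conformer_ids: Sequence[str]) -> np.ndarray:
        rows = [self.frame.loc[(compound_id, cid)].to_numpy(dtype=float)
                for cid in conformer_ids]
        return np.vstack(rows) if rows else np.empty((0, self.p))


# ---------------------------------------------------------------------------
# Activity-unit conventions
# ---------------------------------------------------------------------------

def ic50_to_pic50(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 in molar) = 9 - log10(IC50 in nM)."""
    if not (ic50_nM > 0):
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


def classify_activity(pic50: float, threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> str:
    """'high' iff pic50 >= threshold (inclusive), else 'low'."""
    if not math.isfinite(pic50):
        raise ValueError(f"pic50 must be finite, got {pic50}")
    return "high" if pic50 >= threshold else "low"


# ---------------------------------------------------------------------------
# Ensemble JSON / SDF readers and writers
# ---------------------------------------------------------------------------

def _atom_from_json(d: Mapping, pos: int) -> Atom:
    try:
        return Atom(index=int(d["index"]), element=str(d["element"]),
                    skeleton_label=d.get("skeleton_label"))
    except KeyError as e:
        raise FormatError(f"atom #{pos}: missing field {e.args[0]!r}") from None


def ensemble_from_dict(doc: Mapping) -> ConformerEnsemble:
    if doc.get("schema") != ENSEMBLE_SCHEMA:
        raise FormatError(
            f"field 'schema': expected {ENSEMBLE_SCHEMA!r}, got {doc.get('schema')!r}")
    for f in ("compound_id", "atoms", "conformers"):
        if f not in doc:
            raise FormatError(f"missing field {f!r}")
    atoms = [_atom_from_json(a, i) for i, a in enumerate(doc["atoms"], start=1)]
    bonds = []
    for i, b in enumerate(doc.get("bonds", []), start=1):
        try:
            bonds.append(Bond(
                i=int(b["i"]), j=int(b["j"]),
                order=b.get("order"), wiberg=b.get("wiberg"),
                bond_energy=b.get("bond_energy"),
                bond_polarizability=b.get("bond_polarizability")))
        except KeyError as e:
            raise FormatError(f"bond #{i}: missing field {e.args[0]!r}") from None
    conformers = []
    for i, c in enumerate(doc["conformers"], start=1):
        for f in ("conformer_id", "rel_energy", "coords"):
            if f not in c:
                raise FormatError(f"conformer #{i}: missing field {f!r}")
        charge = c.get("atomic_charge")
        conformers.append(Conformer(
            conformer_id=str(c["conformer_id"]),
            rel_energy=float(c["rel_energy"]),
            has_imaginary_freq=bool(c.get("has_imaginary_freq", False)),
            coords=np.asarray(c["coords"], dtype=float),
            atomic_charge=None if charge is None else np.asarray(charge, dtype=float),
            atomic_props={k: np.asarray(v, dtype=float)
                          for k, v in (c.get("atomic_props") or {}).items()},
            descriptors={k: float(v) for k, v in (c.get("descriptors") or {}).items()},
        ))
    ens = ConformerEnsemble(compound_id=str(doc["compound_id"]), atoms=atoms,
                            bonds=bonds, conformers=conformers)
    ens.validate()
    ens.rereference_energies()
    return ens


def ensemble_to_dict(ens: ConformerEnsemble) -> dict:
    return {
        "schema": ENSEMBLE_SCHEMA,
        "compound_id": ens.compound_id,
        "atoms": [
            {"index": a.index, "element": a.element, "skeleton_label": a.skeleton_label}
            for a in ens.atoms],
        "bonds": [
            {"i": b.i, "j": b.j, "order": b.order, "wiberg": b.wiberg,
             "bond_energy": b.bond_energy, "bond_polarizability": b.bond_polarizability}
            for b in ens.bonds],
        "conformers": [
            {"conformer_id": c.conformer_id, "rel_energy": c.rel_energy,
             "has_imaginary_freq": c.has_imaginary_freq,
             "coords": c.coords.tolist(),
             "atomic_charge": None if c.atomic_charge is None
             else c.atomic_charge.tolist(),
             "atomic_props": {k: v.tolist() for k, v in c.atomic_props.items()},
             "descriptors": dict(c.descriptors)}
            for c in ens.conformers],
    }


def read_ensemble(path, fmt: Optional[str] = None) -> ConformerEnsemble:
    """Read a conformer ensemble from JSON (canonical) or SDF (geometry only).

    Relative energies are re-referenced so the ensemble minimum is 0.  SDF
    ingest yields conformers with ``atomic_charge=None`` (electronic fields
    absent, not zero) and per-conformer energies of 0 unless an ``rel_energy``
    SD tag is present.
    """
    path = str(path)
    if fmt is None:
        fmt = "sdf" if path.lower().endswith((".sdf", ".sd", ".mol")) else "json"
    if fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as e:
                raise FormatError(f"{path}: invalid JSON: {e}") from None
        return ensemble_from_dict(doc)
    if fmt == "sdf":
        return _read_sdf_ensemble(path)
    raise ValueError(f"unknown ensemble format {fmt!r}")


def write_ensemble(ens: ConformerEnsemble, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ensemble_to_dict(ens), fh, indent=1)


def _read_sdf_ensemble(path: str) -> ConformerEnsemble:
    from rdkit import Chem  # optional dependency; only needed for SDF ingest

    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise FormatError(f"{path}: no molecules in SDF")
    first = mols[0]
    atoms = [Atom(index=a.GetIdx() + 1, element=a.GetSymbol())
             for a in first.GetAtoms()]
    bonds = []
    for b in first.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1))
        bonds.append(Bond(i=i, j=j, order=float(b.GetBondTypeAsDouble())))
    conformers = []
    for k, mol in enumerate(mols):
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        energy = float(mol.GetProp("rel_energy")) if mol.HasProp("rel_energy") else 0.0
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        conformers.append(Conformer(
            conformer_id=name or f"conf{k + 1}", rel_energy=energy,
            has_imaginary_freq=False, coords=coords, atomic_charge=None))
    cid = first.GetProp("_Name") if first.HasProp("_Name") else "sdf_compound"
    ens = ConformerEnsemble(compound_id=cid, atoms=atoms, bonds=bonds,
                            conformers=conformers)
    ens.validate()
    ens.rereference_energies()
    return ens


# ---------------------------------------------------------------------------
# CSV readers and writers
# ---------------------------------------------------------------------------

_SPLIT_TOKENS = {"train", "test", "unassigned"}


def read_activity_table(path, threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
                        label_mode: str = "threshold") -> ActivityTable:
    """Read a CSV activity table.

    The CSV must carry ``compound_id`` and exactly one of ``pic50`` /
    ``ic50_nM``; optional ``activity_class`` and ``split`` columns.  In
    ``label_mode='threshold'`` classes are recomputed from the threshold; in
    ``'verbatim'`` the printed classes are kept and compounds whose printed
    class disagrees with the threshold are reported in
    :attr:`ActivityTable.label_overrides` (never silently fixed).
    """
    if label_mode not in ("threshold", "verbatim"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: no records")
    if "compound_id" not in df.columns:
        raise FormatError(f"{path}: missing 'compound_id' column")
    df["compound_id"] = df["compound_id"].astype(str)
    has_pic50, has_ic50 = "pic50" in df.columns, "ic50_nM" in df.columns
    if has_pic50 == has_ic50:
        raise FormatError(
            f"{path}: exactly one of 'pic50'/'ic50_nM' columns is required")
    if has_ic50:
        df["pic50"] = df["ic50_nM"].map(ic50_to_pic50)
    df["pic50"] = df["pic50"].astype(float)

    threshold_class = df["pic50"].map(lambda v: classify_activity(v, threshold))
    if label_mode == "verbatim":
        if "activity_class" not in df.columns:
            raise FormatError(f"{path}: verbatim label mode requires 'activity_class'")
        printed = df["activity_class"].astype(str).str.lower()
        bad = ~printed.isin({"high", "low"})
        if bad.any():
            raise FormatError(
                f"{path}: unknown activity_class token {printed[bad].iloc[0]!r}")
        overrides = df.loc[printed != threshold_class,
                           ["compound_id", "pic50"]].copy()
        overrides["printed_class"] = printed[printed != threshold_class]
        overrides["threshold_class"] = threshold_class[printed != threshold_class]
        df["activity_class"] = printed
    else:
        overrides = pd.DataFrame(
            columns=["compound_id", "pic50", "printed_class", "threshold_class"])
        df["activity_class"] = threshold_class

    if "split" in df.columns:
        split = df["split"].astype(str).str.lower()
        bad = ~split.isin(_SPLIT_TOKENS)
        if bad.any():
            raise FormatError(f"{path}: unknown split token {split[bad].iloc[0]!r}")
        df["split"] = split
    else:
        df["split"] = "unassigned"

    return ActivityTable(
        frame=df[["compound_id", "pic50", "activity_class", "split"]].reset_index(
            drop=True),
        label_overrides=overrides.reset_index(drop=True))


def write_activity_table(table: ActivityTable, path) -> None:
    table.frame.to_csv(path, index=False)


def read_atom_map(path) -> AtomMap:
    df = pd.read_csv(path)
    required = {"compound_id", "local_atom_index", "skeleton_label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["compound_id"] = df["compound_id"].astype(str)
    df["local_atom_index"] = df["local_atom_index"].astype(int)
    df["skeleton_label"] = df["skeleton_label"].astype(str)
    return AtomMap(frame=df)


def write_atom_map(amap: AtomMap, path) -> None:
    amap.frame.to_csv(path, index=False)


def read_descriptor_panel(path) -> DescriptorPanel:
    df = pd.read_csv(path)
    for key in ("compound_id", "conformer_id"):
        if key not in df.columns:
            raise FormatError(f"{path}: missing {key!r} column")
    df["compound_id"] = df["compound_id"].astype(str)
    df["conformer_id"] = df["conformer_id"].astype(str)
    df = df.set_index(["compound_id", "conformer_id"])
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: non-numeric descriptor column {col!r}")
    return DescriptorPanel(frame=df)


def write_descriptor_panel(panel: DescriptorPanel, path) -> None:
    panel.frame.reset_index().to_csv(path, index=False)
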