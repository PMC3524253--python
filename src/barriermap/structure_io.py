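"""PDB structure I/O and the per-residue fragment library.

Variant enzyme models are assembled combinatorially from single-residue
"fragment" PDB files: split a prepared wild-type model into one fragment per
residue (waters and the substrate become fragments too), then substitute the
fragment at any position with a modelled mutant side chain and concatenate.
Because every fragment carries its own formal charge, the net charge of an
assembled variant is exact bookkeeping, not a guess.

Only the fixed-column PDB v3.3 subset needed for this workflow is supported:
ATOM / HETATM / TER / REMARK / END records.  Alternate locations other than
blank or 'A' are rejected — crystal structures must be de-duplicated upstream.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "FragmentRecord",
    "FragmentLibrary",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "split_fragments",
    "assemble_variant",
    "write_fragment_library",
    "read_fragment_library",
]

#: residue names treated as water
WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"}

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)


class PDBFormatError(ValueError):
    """Raised for malformed fixed-column PDB input or unwritable models."""


@dataclass
class Atom:
    """One atom of a structure model.

    ``residue_key`` is ``(chain, resnum, icode)`` and identifies the residue
    the atom belongs to; ``position`` is Cartesian, in Angstrom.
    """

    serial: int
    name: str
    element: str
    residue_key: ResidueKey
    residue_name: str
    position: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class StructureModel:
    """An ordered collection of atoms partitioned into residues.

    ``net_charge`` is in elementary charges and is maintained by the
    assembly/annotation operations (a freshly parsed PDB defaults to 0).
    ``frozen_atoms`` holds serials whose Cartesians are fixed in any
    optimization; freezing lives here, not in the PDB text.
    """

    atoms: list[Atom]
    residue_order: list[ResidueKey]
    net_charge: int = 0
    frozen_atoms: set[int] = field(default_factory=set)
    waters: set[ResidueKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in structure")
        keys = {a.residue_key for a in self.atoms}
        missing = keys - set(self.residue_order)
        if missing:
            raise ValueError(f"atoms reference residues absent from residue_order: {missing}")

    # -- convenience accessors -------------------------------------------------

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.position = row.copy()

    def serial_index(self) -> dict[int, int]:
        return {a.serial: i for i, a in enumerate(self.atoms)}

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise KeyError(f"no atom with serial {serial}")

    def residue_atoms(self, key: ResidueKey) -> list[Atom]:
        return [a for a in self.atoms if a.residue_key == key]

    def copy(self) -> "StructureModel":
        return StructureModel(
            atoms=[a.copy() for a in self.atoms],
            residue_order=list(self.residue_order),
            net_charge=self.net_charge,
            frozen_atoms=set(self.frozen_atoms),
            waters=set(self.waters),
        )


@dataclass
class FragmentRecord:
    """A single residue (or water, or substrate) stored as its own unit."""

    residue_key: ResidueKey
    residue_name: str
    atoms: list[Atom]
    formal_charge: int = 0
    is_water: bool = False
    is_substrate: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"fragment {self.residue_key}: no atoms")
        if not -2 <= self.formal_charge <= 2:
            raise ValueError(
                f"fragment {self.residue_key}: formal charge {self.formal_charge} outside [-2, 2]"
            )


@dataclass
class FragmentLibrary:
    """Ordered fragment records; the order defines reassembly order."""

    records: list[FragmentRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [r.residue_key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys in fragment library")

    def record_for(self, key: ResidueKey) -> FragmentRecord:
        for r in self.records:
            if r.residue_key == key:
                return r
        raise KeyError(f"no fragment for residue {key}")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    # PDB atom-name columns: two-letter elements occupy cols 13-14; a leading
    # digit (e.g. "1HB ") marks a hydrogen variant.
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    if len(name) >= 2 and name[0] != " " and name[:2].strip().isalpha() and name[:2] in (
        "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO", "SE",
    ):
        return name[:2].capitalize()
    return stripped[0].upper()


def read_pdb(source: str | Path) -> StructureModel:
    """Parse fixed-column PDB text (or a path to it) into a :class:`StructureModel`.

    Atoms keep file order; residues appear in ``residue_order`` in order of
    first appearance.  Water residues (HOH etc. or any HETATM water name) are
    flagged.  ``net_charge`` defaults to 0 until annotated by the caller or a
    fragment manifest.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith(".pdb")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)

    atoms: list[Atom] = []
    residue_order: list[ResidueKey] = []
    seen_keys: set[ResidueKey] = set()
    seen_serials: set[int] = set()
    waters: set[ResidueKey] = set()

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBFormatError(f"line {lineno}: record too short for coordinates")
        try:
            serial = int(line[6:11])
            name = line[12:16]
            altloc = line[16]
            resname = line[17:20].strip()
            chain = line[21]
            resnum = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBFormatError(f"line {lineno}: malformed fixed-column record ({exc})") from None
        if altloc not in (" ", "A"):
            raise PDBFormatError(
                f"line {lineno}: alternate location '{altloc}' not supported; "
                "de-duplicate altLocs upstream"
            )
        if serial in seen_serials:
            raise PDBFormatError(f"line {lineno}: duplicate atom serial {serial}")
        seen_serials.add(serial)
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        element = element.capitalize()
        key: ResidueKey = (chain.strip(), resnum, icode)
        if key not in seen_keys:
            seen_keys.add(key)
            residue_order.append(key)
        is_het = rec == "HETATM"
        if resname.upper() in WATER_RESNAMES:
            waters.add(key)
        atoms.append(
            Atom(
                serial=serial,
                name=name.strip(),
                element=element,
                residue_key=key,
                residue_name=resname,
                position=np.array([x, y, z]),
                is_hetero=is_het,
            )
        )
    return StructureModel(atoms=atoms, residue_order=residue_order, waters=waters)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise PDBFormatError(f"atom name '{name}' longer than 4 characters")
    # one-letter elements start in column 14 unless the name already fills 4 cols
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel) -> str:
    """Render a model as fixed-column PDB v3.3 text.

    Coordinates are written to 3 decimals; a TER record separates chains.
    Frozen-atom state is deliberately not represented (it belongs to the
    backend input, not the structure file).
    """
    lines: list[str] = []
    prev_chain: str | None = None
    prev_atom: Atom | None = None
    for atom in model.atoms:
        chain = atom.residue_key[0]
        if prev_chain is not None and chain != prev_chain and prev_atom is not None:
            lines.append(_ter_line(prev_atom))
        rec = "HETATM" if atom.is_hetero else "ATOM  "
        x, y, z = atom.position
        lines.append(
            f"{rec}{atom.serial:>5d} {_format_atom_name(atom.name, atom.element)}"
            f" {atom.residue_name:>3s} {chain or ' '}{atom.residue_key[1]:>4d}"
            f"{atom.residue_key[2] or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{atom.element:>2s}"
        )
        prev_chain = chain
        prev_atom = atom
    if prev_atom is not None:
        lines.append(_ter_line(prev_atom))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _ter_line(last_atom: Atom) -> str:
    chain = last_atom.residue_key[0]
    return (
        f"TER   {last_atom.serial + 1:>5d}      {last_atom.residue_name:>3s} "
        f"{chain or ' '}{last_atom.residue_key[1]:>4d}{last_atom.residue_key[2] or ' '}"
    )


# ---------------------------------------------------------------------------
# Fragment split / assembly
# ---------------------------------------------------------------------------

def split_fragments(
    model: StructureModel,
    substrate_residues: Iterable[ResidueKey] = (),
    charges: Mapping[ResidueKey, int] | None = None,
) -> FragmentLibrary:
    """Split a model into one fragment record per residue, in residue order.

    Waters and substrate residues are flagged on their records.  ``charges``
    assigns formal charges per residue (default 0); unknown keys are an error.
    The concatenation of record atoms reproduces the model's atoms exactly.
    """
    charges = dict(charges or {})
    substrate = set(substrate_residues)
    unknown = set(charges) - set(model.residue_order)
    if unknown:
        raise KeyError(f"charge annotations for residues not in model: {sorted(unknown)}")
    records: list[FragmentRecord] = []
    for key in model.residue_order:
        atoms = model.residue_atoms(key)
        if not atoms:
            raise ValueError(f"residue {key} has zero atoms")
        records.append(
            FragmentRecord(
                residue_key=key,
                residue_name=atoms[0].residue_name,
                atoms=[a.copy() for a in atoms],
                formal_charge=charges.get(key, 0),
                is_water=key in model.waters,
                is_substrate=key in substrate,
            )
        )
    return FragmentLibrary(records=records, provenance="split_fragments")


def assemble_variant(
    library: FragmentLibrary,
    substitutions: Mapping[ResidueKey, FragmentRecord] | None = None,
) -> StructureModel:
    """Assemble a structure from the library, substituting mutant fragments.

    Substituted records replace wild-type records in place (library order is
    preserved); any number of simultaneous substitutions is allowed, enabling
    combination mutants.  Atom serials are renumbered 1-based consecutively
    and the net charge is the sum of formal charges over assembled records.
    """
    substitutions = dict(substitutions or {})
    lib_keys = {r.residue_key for r in library.records}
    missing = set(substitutions) - lib_keys
    if missing:
        raise KeyError(f"substitution keys absent from library: {sorted(missing)}")
    for key, frag in substitutions.items():
        if frag.residue_key != key:
            raise ValueError(
                f"substituting fragment carries residue key {frag.residue_key}, expected {key}"
            )
    atoms: list[Atom] = []
    residue_order: list[ResidueKey] = []
    waters: set[ResidueKey] = set()
    net_charge = 0
    serial = 1
    for record in library.records:
        rec = substitutions.get(record.residue_key, record)
        residue_order.append(rec.residue_key)
        if rec.is_water:
            waters.add(rec.residue_key)
        net_charge += rec.formal_charge
        for a in rec.atoms:
            atoms.append(replace(a.copy(), serial=serial))
            serial += 1
    return StructureModel(
        atoms=atoms, residue_order=residue_order, net_charge=net_charge, waters=waters
    )


# ---------------------------------------------------------------------------
# On-disk fragment library: one PDB per residue + JSON manifest
# ---------------------------------------------------------------------------

def _fragment_filename(record: FragmentRecord) -> str:
    chain, resnum, icode = record.residue_key
    return f"{chain or '_'}{resnum}{icode}{record.residue_name}.pdb"


def write_fragment_library(library: FragmentLibrary, directory: str | Path) -> Path:
    """Write one single-residue PDB per record plus a JSON manifest.

    Each fragment file carries a ``REMARK 250 FORMAL_CHARGE`` line so the
    charge is machine-readable alongside the coordinates; the manifest records
    assembly order, flags and charges.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"provenance": library.provenance, "fragments": []}
    for record in library.records:
        fname = _fragment_filename(record)
        sub = StructureModel(
            atoms=[a.copy() for a in record.atoms],
            residue_order=[record.residue_key],
            net_charge=record.formal_charge,
            waters={record.residue_key} if record.is_water else set(),
        )
        text = f"REMARK 250 FORMAL_CHARGE {record.formal_charge}\n" + write_pdb(sub)
        (directory / fname).write_text(text)
        manifest["fragments"].append(
            {
                "file": fname,
                "chain": record.residue_key[0],
                "resnum": record.residue_key[1],
                "icode": record.residue_key[2],
                "resname": record.residue_name,
                "formal_charge": record.formal_charge,
                "is_water": record.is_water,
                "is_substrate": record.is_substrate,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return directory / "manifest.json"


def read_fragment_library(directory: str | Path) -> FragmentLibrary:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    records: list[FragmentRecord] = []
    for entry in manifest["fragments"]:
        text = (directory / entry["file"]).read_text()
        m = re.search(r"^REMARK 250 FORMAL_CHARGE\s+(-?\d+)", text, re.M)
        charge = int(m.group(1)) if m else entry["formal_charge"]
        sub = read_pdb(text)
        records.append(
            FragmentRecord(
                residue_key=(entry["chain"], entry["resnum"], entry["icode"]),
                residue_name=entry["resname"],
                atoms=sub.atoms,
                formal_charge=charge,
                is_water=entry["is_water"],
                is_substrate=entry["is_substrate"],
            )
        )
    return FragmentLibrary(records=records, provenance=manifest.get("provenance", ""))
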