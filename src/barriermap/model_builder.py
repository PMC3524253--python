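"""Truncated active-site model construction and reaction-endpoint preparation.

A screening model is cut from the full enzyme by a radius criterion around a
center residue (typically the catalytic serine of a serine hydrolase),
single-residue backbone gaps are re-included, introduced C-termini are capped
as aldehydes and introduced N-termini annotated neutral.  The
enzyme-substrate (ES) endpoint is derived from the optimized tetrahedral
intermediate (TI) by swapping in externally modelled planar substrate
coordinates and transferring the serine proton back onto the nucleophile
oxygen.  Surface side chains can be frozen so that variant optimizations stay
in the wild-type basin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Atom, ResidueKey, StructureModel

__all__ = [
    "SelectionSpec",
    "ReactionCoordinate",
    "EndpointPair",
    "select_model_region",
    "fill_single_gaps",
    "cap_termini",
    "build_es_from_ti",
    "freeze_surface_sidechains",
]

#: atom names considered backbone (everything else on a residue is side chain)
BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA"}

#: name given to the aldehyde cap hydrogen added by :func:`cap_termini`
CAP_HYDROGEN_NAME = "HC"


@dataclass
class SelectionSpec:
    """Radius-based residue selection around a center residue."""

    center_residue: ResidueKey
    radius: float
    include_waters: bool = True
    fill_single_gaps: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("selection radius must be positive")


@dataclass
class ReactionCoordinate:
    """The nucleophile-oxygen to electrophile-carbon distance.

    ``es_distance`` is the separation in the reactant complex (default
    convention 3.5 A) and ``ti_distance`` the covalent-bond separation in the
    tetrahedral intermediate; the reaction proceeds from large to small.
    """

    nucleophile_atom: int
    electrophile_atom: int
    es_distance: float = 3.5
    ti_distance: float = 1.5

    def __post_init__(self) -> None:
        if not self.es_distance > self.ti_distance > 0:
            raise ValueError("require es_distance > ti_distance > 0")


@dataclass
class EndpointPair:
    """ES and TI structures sharing atom count and ordering (interpolable)."""

    es: StructureModel
    ti: StructureModel
    rc: ReactionCoordinate
    freeze_list: set[ResidueKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.es.atoms) != len(self.ti.atoms):
            raise ValueError("ES and TI atom counts differ")
        for a, b in zip(self.es.atoms, self.ti.atoms):
            if a.serial != b.serial or a.name != b.name:
                raise ValueError(
                    f"ES/TI atom ordering mismatch at serial {a.serial} ({a.name} vs {b.name})"
                )
        for key in self.freeze_list:
            if key not in self.es.residue_order or key not in self.ti.residue_order:
                raise KeyError(f"freeze-list residue {key} absent from endpoints")


def select_model_region(full: StructureModel, spec: SelectionSpec) -> StructureModel:
    """Cut the model to residues with any atom within ``spec.radius`` of the center.

    The distance criterion is any-atom-to-any-atom against the center residue.
    Water inclusion is controlled by ``spec.include_waters``; original residue
    order is preserved.  Single-residue backbone gaps are refilled when
    ``spec.fill_single_gaps`` is set.
    """
    if spec.center_residue not in full.residue_order:
        raise KeyError(f"center residue {spec.center_residue} not in structure")
    center_xyz = np.array([a.position for a in full.residue_atoms(spec.center_residue)])
    selected: list[ResidueKey] = []
    for key in full.residue_order:
        if key in full.waters and not spec.include_waters:
            continue
        xyz = np.array([a.position for a in full.residue_atoms(key)])
        if cdist(xyz, center_xyz).min() <= spec.radius:
            selected.append(key)
    if spec.fill_single_gaps:
        selected = fill_single_gaps(selected, full)
    if not selected:
        raise ValueError("empty selection")
    keep = set(selected)
    atoms = [a.copy() for a in full.atoms if a.residue_key in keep]
    return StructureModel(
        atoms=atoms,
        residue_order=[k for k in full.residue_order if k in keep],
        net_charge=full.net_charge,
        waters={k for k in full.waters if k in keep},
    )


def fill_single_gaps(
    selection: list[ResidueKey], full: StructureModel
) -> list[ResidueKey]:
    """Re-include residues interrupting the selected backbone by exactly one.

    If residues i-1 and i+1 of a chain are selected but i is not, i joins the
    selection; gaps of two or more residues are left untouched.  Waters (no
    backbone) are ignored.  Idempotent by construction: one pass closes every
    single gap and creates no new ones.
    """
    selected = set(selection)
    added: set[ResidueKey] = set()
    for key in full.residue_order:
        if key in selected or key in full.waters:
            continue
        chain, resnum, icode = key
        if icode:
            continue  # gap rule is defined on plain sequence numbering
        prev_key = (chain, resnum - 1, "")
        next_key = (chain, resnum + 1, "")
        if prev_key in selected and next_key in selected:
            added.add(key)
    if not added:
        return list(selection)
    keep = selected | added
    return [k for k in full.residue_order if k in keep]


def _contiguous_segments(model: StructureModel) -> list[list[ResidueKey]]:
    """Split each chain's amino-acid residues into runs of consecutive numbering."""
    segments: list[list[ResidueKey]] = []
    current: list[ResidueKey] = []
    for key in model.residue_order:
        if key in model.waters or all(a.is_hetero for a in model.residue_atoms(key)):
            continue
        if current and (
            key[0] != current[-1][0] or key[1] != current[-1][1] + 1
        ):
            segments.append(current)
            current = []
        current.append(key)
    if current:
        segments.append(current)
    return segments


def cap_termini(model: StructureModel) -> StructureModel:
    """Neutralize introduced N-termini and cap introduced C-termini as -CHO.

    Chain breaks are detected as residue-number discontinuities; the first and
    last residue of each chain are taken as native termini and left alone.
    At each introduced C-terminus the backbone C and O are kept and one
    aldehyde hydrogen is added at 1.09 A from C, in the backbone plane
    opposite the CA-C and C=O bonds (the direction of the removed peptide
    bond).  Introduced N-termini are an annotation only (zero charge, no
    added protons), so capping never changes the net charge.  Idempotent: a
    residue already carrying the cap hydrogen is skipped.
    """
    out = model.copy()
    segments = _contiguous_segments(out)
    if not segments:
        return out
    next_serial = max(a.serial for a in out.atoms) + 1
    # all but the last segment of each chain end in an introduced cut
    by_chain: dict[str, list[list[ResidueKey]]] = {}
    for seg in segments:
        by_chain.setdefault(seg[0][0], []).append(seg)
    new_atoms: list[tuple[int, Atom]] = []  # (insert-after index, atom)
    index_of = {id(a): i for i, a in enumerate(out.atoms)}
    for chain_segments in by_chain.values():
        for seg in chain_segments[:-1]:
            cterm = seg[-1]
            res_atoms = out.residue_atoms(cterm)
            names = {a.name: a for a in res_atoms}
            if CAP_HYDROGEN_NAME in names:
                continue  # already capped
            if "C" not in names or "O" not in names or "CA" not in names:
                raise ValueError(
                    f"cut C-terminus {cterm} lacks backbone atoms needed for -CHO cap"
                )
            c, o, ca = names["C"].position, names["O"].position, names["CA"].position
            u_ca = (ca - c) / np.linalg.norm(ca - c)
            u_o = (o - c) / np.linalg.norm(o - c)
            direction = -(u_ca + u_o)
            norm = np.linalg.norm(direction)
            if norm < 1e-8:  # degenerate (collinear) backbone; fall back to -CA axis
                direction, norm = -u_ca, 1.0
            h_pos = c + 1.09 * direction / norm
            cap = Atom(
                serial=next_serial,
                name=CAP_HYDROGEN_NAME,
                element="H",
                residue_key=cterm,
                residue_name=names["C"].residue_name,
                position=h_pos,
            )
            next_serial += 1
            new_atoms.append((index_of[id(res_atoms[-1])], cap))
    for insert_after, cap in sorted(new_atoms, key=lambda t: -t[0]):
        out.atoms.insert(insert_after + 1, cap)
    # caps are neutral and N-termini carry zero charge: net charge unchanged
    return out


def build_es_from_ti(
    ti: StructureModel,
    substrate_planar_coords: dict[int, np.ndarray],
    proton: int,
    rc: ReactionCoordinate,
) -> StructureModel:
    """Construct the ES endpoint from the optimized TI structure.

    The covalently bound (tetrahedral) substrate is replaced by externally
    modelled planar coordinates, keyed by atom serial, then rigid-shifted
    along the nucleophile->electrophile axis so the reaction-coordinate
    distance equals ``rc.es_distance``.  The serine proton is moved back onto
    the nucleophile oxygen at 0.97 A, pointing toward the electrophile
    carbon.  Atom count and ordering are identical to the TI (interpolation
    precondition).
    """
    substrate_serials = {
        a.serial
        for a in ti.atoms
        if a.is_hetero and a.residue_key not in ti.waters
    }
    provided = set(substrate_planar_coords)
    if provided != substrate_serials:
        raise ValueError(
            "planar substrate coordinates do not match TI substrate atoms: "
            f"{len(provided)} provided vs {len(substrate_serials)} in TI"
        )
    es = ti.copy()
    idx = es.serial_index()
    for serial, pos in substrate_planar_coords.items():
        es.atoms[idx[serial]].position = np.asarray(pos, dtype=float).copy()
    o_nuc = es.atoms[idx[rc.nucleophile_atom]].position
    c_ele = es.atoms[idx[rc.electrophile_atom]].position
    axis = c_ele - o_nuc
    dist = np.linalg.norm(axis)
    if dist < 1e-8:
        raise ValueError("nucleophile and electrophile coincide in planar coordinates")
    shift = o_nuc + rc.es_distance * axis / dist - c_ele
    for serial in substrate_serials:
        es.atoms[idx[serial]].position = es.atoms[idx[serial]].position + shift
    # transfer the proton back onto the nucleophile oxygen
    c_new = es.atoms[idx[rc.electrophile_atom]].position
    u = (c_new - o_nuc) / np.linalg.norm(c_new - o_nuc)
    es.atoms[idx[proton]].position = o_nuc + 0.97 * u
    return es


def freeze_surface_sidechains(
    model: StructureModel, residues: set[ResidueKey] | list[ResidueKey]
) -> StructureModel:
    """Freeze all side-chain atoms of the listed residues.

    Side chain means every atom whose name is not backbone
    (N, CA, C, O, backbone H/HA, OXT).  Used to pin surface side chains so a
    bulky active-site mutation cannot trigger spurious surface rearrangements
    that change the bonding topology between wild type and variant.
    """
    out = model.copy()
    for key in residues:
        if key not in out.residue_order:
            raise KeyError(f"freeze residue {key} not in model")
        for atom in out.residue_atoms(key):
            if atom.name not in BACKBONE_ATOM_NAMES:
                out.frozen_atoms.add(atom.serial)
    return out
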