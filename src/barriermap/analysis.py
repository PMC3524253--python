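"""Profile analytics, superposition, and the synthetic toy system.

Covers the downstream half of the screening workflow: extracting barrier
heights from mapped energy profiles (highest point minus the lowest point
before it), comparing profiles across engine configurations (convergence
with NDDO cutoff and gradient criterion), quantifying the drift between
localized-orbital and conventional energies, optimal-superposition RMSD
between structures, and a deterministic toy enzyme+substrate generator with
a matched analytic surface so the whole pipeline can be exercised — and its
barrier recovery measured against a known answer — with no external engine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .adiabatic_mapping import EnergyProfile, FrameStatus
from .model_builder import EndpointPair, ReactionCoordinate
from .qm_backend import EnergyChannel, SurrogateParams
from .structure_io import Atom, StructureModel

__all__ = [
    "BarrierEstimate",
    "DriftReport",
    "extract_barrier",
    "convergence_report",
    "drift_report",
    "kabsch_rmsd",
    "make_toy_system",
]


@dataclass
class BarrierEstimate:
    """Barrier height read off an energy profile.

    ``barrier`` = energy of the highest frame minus the energy of the lowest
    frame *preceding* it — not necessarily frame 0, because a profile may dip
    below its initial reactant energy before climbing.
    """

    barrier: float
    max_frame: int
    reference_frame: int
    channel: EnergyChannel

    def __post_init__(self) -> None:
        if self.barrier < 0:
            raise ValueError("barrier must be non-negative")


@dataclass
class DriftReport:
    """Per-frame differences between energy channels.

    ``table`` has one row per frame carrying at least two channels, with the
    pairwise differences; ``cycle_correlation`` is the Pearson correlation of
    |localized - conventional| with the SCF cycle count, when counts exist
    (long SCF histories accumulate more orthogonality error).
    """

    table: pd.DataFrame
    cycle_correlation: float | None = None


def extract_barrier(
    profile: EnergyProfile, channel: EnergyChannel | None = None
) -> BarrierEstimate:
    """Locate the highest profile point and subtract the lowest point before it.

    Failed frames and frames missing the channel are skipped.  Ties at the
    maximum (and at the preceding minimum) break toward the lowest frame
    index.  A profile whose maximum is its first usable frame is flat for
    this purpose: barrier 0 with reference_frame = max_frame.
    """
    channel = channel or profile.reference_channel
    points: list[tuple[int, float]] = []
    for frame in profile.frames:
        if frame.status == FrameStatus.FAILED:
            continue
        e = frame.energy(channel)
        if e is not None:
            points.append((frame.index, e))
    if len(points) < 2:
        raise ValueError(
            f"profile has {len(points)} usable frames in channel {channel.value}; need >= 2"
        )
    max_pos = max(range(len(points)), key=lambda i: (points[i][1], -points[i][0]))
    max_frame, e_max = points[max_pos]
    if max_pos == 0:
        return BarrierEstimate(0.0, max_frame, max_frame, channel)
    ref_pos = min(range(max_pos), key=lambda i: (points[i][1], points[i][0]))
    ref_frame, e_ref = points[ref_pos]
    return BarrierEstimate(e_max - e_ref, max_frame, ref_frame, channel)


_LABEL_RE = re.compile(r"M\(C(?P<cutoff>[\d.]+),\s*G(?P<gcc>[\d.]+)\)")


def convergence_report(profiles: list[EnergyProfile]) -> pd.DataFrame:
    """Per-configuration barriers plus frame-wise deltas between profiles.

    All profiles must share frame indexing.  The returned table has one row
    per profile (label, barrier, frames of max and reference); pairwise
    frame-wise energy deltas live in ``.attrs['frame_deltas']`` and
    ``.attrs['monotone_with_strictness']`` flags whether the barrier
    decreases monotonically as configurations get stricter (larger NDDO
    cutoff, smaller gradient criterion) — the expected convergence pattern
    toward a lower bound.
    """
    if not profiles:
        raise ValueError("no profiles given")
    index_sets = [tuple(f.index for f in p.frames) for p in profiles]
    if len(set(index_sets)) > 1:
        raise ValueError("profiles have mismatched frame indexing")
    rows = []
    for p in profiles:
        est = extract_barrier(p)
        m = _LABEL_RE.search(p.label)
        rows.append(
            {
                "label": p.label,
                "cutoff": float(m.group("cutoff")) if m else np.nan,
                "gcc": float(m.group("gcc")) if m else np.nan,
                "barrier": est.barrier,
                "max_frame": est.max_frame,
                "reference_frame": est.reference_frame,
            }
        )
    table = pd.DataFrame(rows)

    deltas = {}
    for i, a in enumerate(profiles):
        for b in profiles[i + 1 :]:
            key = f"{a.label} - {b.label}"
            pairs = [
                (fa.energy(a.reference_channel), fb.energy(b.reference_channel))
                for fa, fb in zip(a.frames, b.frames)
            ]
            deltas[key] = [
                ea - eb if ea is not None and eb is not None else np.nan
                for ea, eb in pairs
            ]
    table.attrs["frame_deltas"] = pd.DataFrame(
        deltas, index=[f.index for f in profiles[0].frames]
    )

    ordered = table.dropna(subset=["cutoff", "gcc"]).sort_values(
        ["cutoff", "gcc"], ascending=[True, False]
    )
    barriers = ordered["barrier"].to_numpy()
    table.attrs["monotone_with_strictness"] = bool(
        len(barriers) >= 2 and np.all(np.diff(barriers) <= 1e-9)
    )
    return table


def drift_report(profile: EnergyProfile) -> DriftReport:
    """Quantify localized-orbital energy drift against the other channels."""
    rows = []
    for frame in profile.frames:
        values = {rec.channel: rec for rec in frame.energies}
        if len(values) < 2:
            continue
        row: dict = {"frame": frame.index}
        for ch, rec in values.items():
            row[ch.value] = rec.heat_of_formation
            if rec.scf_cycles is not None:
                row["scf_cycles"] = rec.scf_cycles
        pairs = sorted(values, key=lambda c: c.value)
        for i, ca in enumerate(pairs):
            for cb in pairs[i + 1 :]:
                row[f"{ca.value} - {cb.value}"] = (
                    values[ca].heat_of_formation - values[cb].heat_of_formation
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    correlation = None
    if (
        not table.empty
        and "scf_cycles" in table
        and EnergyChannel.MOZYME.value in table
        and EnergyChannel.CONVENTIONAL_SP.value in table
    ):
        drift = (
            table[EnergyChannel.MOZYME.value]
            - table[EnergyChannel.CONVENTIONAL_SP.value]
        ).abs()
        cycles = table["scf_cycles"]
        if drift.nunique() > 1 and cycles.nunique() > 1:
            correlation = float(np.corrcoef(drift, cycles)[0, 1])
    return DriftReport(table=table, cycle_correlation=correlation)


# ---------------------------------------------------------------------------
# Optimal superposition
# ---------------------------------------------------------------------------

def kabsch_rmsd(
    a: StructureModel,
    b: StructureModel,
    atom_map: list[tuple[int, int]] | None = None,
    include_hydrogens: bool = False,
) -> float:
    """Minimal RMSD between two structures over rigid rotations+translations.

    Atoms are paired by ``atom_map`` (serial in a, serial in b) or, by
    default, by matching (residue_key, atom name), excluding hydrogens unless
    requested — heavy-atom geometry is the usual basis for comparing
    transition-state models across methods.  The optimal proper rotation is
    found by singular-value decomposition of the cross-covariance
    (reflections excluded).
    """
    if atom_map is None:
        bmap = {(atom.residue_key, atom.name): atom for atom in b.atoms}
        atom_map = []
        for atom in a.atoms:
            if not include_hydrogens and atom.element == "H":
                continue
            other = bmap.get((atom.residue_key, atom.name))
            if other is not None:
                atom_map.append((atom.serial, other.serial))
    if len(atom_map) < 3:
        raise ValueError(f"need >= 3 mapped atoms, got {len(atom_map)}")
    ia, ib = a.serial_index(), b.serial_index()
    pa = np.array([a.atoms[ia[s]].position for s, _ in atom_map])
    pb = np.array([b.atoms[ib[t]].position for _, t in atom_map])
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    if min(np.linalg.matrix_rank(pa, tol=1e-8), np.linalg.matrix_rank(pb, tol=1e-8)) < 2:
        raise ValueError("mapped atoms are collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(pa, pb)
    diff = pa - rot.apply(pb)  # residual computed directly: exact 0 when a == b
    return float(np.sqrt((diff**2).sum() / len(atom_map)))


# ---------------------------------------------------------------------------
# Synthetic toy enzyme + substrate
# ---------------------------------------------------------------------------

def make_toy_system(
    seed: int, n_residues: int = 6
) -> tuple[StructureModel, EndpointPair, SurrogateParams]:
    """Build a deterministic toy "enzyme + substrate" with a known barrier.

    The toy is a short pseudo-polypeptide (N/CA/C backbone, ~3.8 A residue
    spacing with small seeded jitter), a nucleophile hydroxyl (OG + HG) on
    the center residue, a four-atom pseudo-substrate whose electrophile
    carbon sits exactly 3.5 A from OG in the reactant (ES) geometry, and two
    far-away water oxygens.  The tetrahedral-intermediate (TI) endpoint
    shifts the substrate rigidly along the OG->C1 axis to 1.5 A and displaces
    the hydroxyl proton as if transferred.

    The matched surrogate surface has harmonic bonds with reference lengths
    taken from the ES geometry (so ES is an exact minimum) plus a double well
    of height exactly 10 kcal/mol along the OG-C1 distance with wells at the
    two endpoint separations.  Both the nucleophile oxygen and the
    electrophile carbon carry three non-coplanar bond anchors, so the partial
    Hessian at the profile top has exactly one negative direction.

    Same seed, same structures — byte-identical PDB output.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    residue_order = []
    waters = set()
    serial = 1
    names: dict[str, int] = {}  # label -> serial for bond bookkeeping

    def add(name, element, key, resname, pos, hetero=False, label=None):
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_key=key,
                residue_name=resname,
                position=np.asarray(pos, float),
                is_hetero=hetero,
            )
        )
        if label:
            names[label] = serial
        serial += 1

    center = n_residues // 2 + 1  # 1-based residue number of the "serine"
    for r in range(1, n_residues + 1):
        key = ("A", r, "")
        resname = "SER" if r == center else "GLY"
        residue_order.append(key)
        x0 = 3.8 * (r - 1)
        jit = lambda: rng.normal(0.0, 0.05, 3)  # noqa: E731
        add("N", "N", key, resname, [x0, 0.0, 0.0] + jit(), label=f"N{r}")
        add("CA", "C", key, resname, [x0 + 1.2, 0.8, 0.1] + jit(), label=f"CA{r}")
        add("C", "C", key, resname, [x0 + 2.4, 0.0, 0.0] + jit(), label=f"C{r}")
        if r == center:
            ca = atoms[-2].position
            add("OG", "O", key, resname, ca + [0.4, 1.3, 0.2] + jit(), label="OG")
            og = atoms[-1].position
            h_dir = np.array([0.8, 0.2, 0.56]) + rng.normal(0.0, 0.02, 3)
            add("HG", "H", key, resname, og + 0.97 * h_dir / np.linalg.norm(h_dir), label="HG")

    # pseudo-substrate: electrophile carbon exactly 3.5 A from the nucleophile
    og = atoms[[a.serial for a in atoms].index(names["OG"])].position
    axis = np.array([0.05, 1.0, 0.08]) + rng.normal(0.0, 0.02, 3)
    axis /= np.linalg.norm(axis)
    c1 = og + 3.5 * axis
    sub_key = ("A", n_residues + 1, "")
    residue_order.append(sub_key)
    for name, elem, direction, length, label in (
        ("C1", "C", None, 0.0, "C1"),
        ("O1", "O", np.array([1.0, 0.15, 0.1]), 1.23, "O1"),
        ("C2", "C", np.array([-0.8, 0.1, 0.5]), 1.50, "C2"),
        ("N1", "N", np.array([0.2, 0.3, -0.9]), 1.40, "N1s"),
    ):
        if direction is None:
            pos = c1
        else:
            d = direction + rng.normal(0.0, 0.02, 3)
            pos = c1 + length * d / np.linalg.norm(d)
        add(name, elem, sub_key, "SUB", pos, hetero=True, label=label)

    for i, wpos in enumerate(
        ([-8.0, 8.0, 8.0], [3.8 * n_residues + 8.0, -8.0, 6.0]), start=2
    ):
        key = ("A", n_residues + i, "")
        residue_order.append(key)
        waters.add(key)
        add("O", "O", key, "HOH", np.asarray(wpos) + rng.normal(0.0, 0.1, 3), hetero=True)

    es = StructureModel(
        atoms=atoms, residue_order=residue_order, net_charge=0, waters=waters
    )

    # bonds with reference lengths from the ES geometry (ES is an exact minimum)
    idx = es.serial_index()

    def dist(sa: int, sb: int) -> float:
        return float(
            np.linalg.norm(es.atoms[idx[sa]].position - es.atoms[idx[sb]].position)
        )

    bond_pairs: list[tuple[int, int, float]] = []
    for r in range(1, n_residues + 1):
        bond_pairs.append((names[f"N{r}"], names[f"CA{r}"], 100.0))
        bond_pairs.append((names[f"CA{r}"], names[f"C{r}"], 100.0))
        if r < n_residues:
            bond_pairs.append((names[f"C{r}"], names[f"N{r+1}"], 100.0))
    # three non-coplanar anchors on the nucleophile oxygen
    bond_pairs.append((names["OG"], names[f"CA{center}"], 100.0))
    bond_pairs.append((names["OG"], names[f"N{center}"], 100.0))
    bond_pairs.append((names["OG"], names["HG"], 50.0))
    # three non-coplanar anchors on the electrophile carbon
    bond_pairs.append((names["C1"], names["O1"], 100.0))
    bond_pairs.append((names["C1"], names["C2"], 100.0))
    bond_pairs.append((names["C1"], names["N1s"], 100.0))

    params = SurrogateParams(
        bonds=tuple((sa, sb, k, dist(sa, sb)) for sa, sb, k in bond_pairs),
        well_pair=(names["OG"], names["C1"]),
        barrier=10.0,
        d1=1.5,
        d2=3.5,
    )

    # TI endpoint: substrate rigidly advanced along the axis, proton displaced
    ti = es.copy()
    tidx = ti.serial_index()
    shift = (1.5 - 3.5) * axis
    for label in ("C1", "O1", "C2", "N1s"):
        atom = ti.atoms[tidx[names[label]]]
        atom.position = atom.position + shift
    hg = ti.atoms[tidx[names["HG"]]]
    c1_ti = ti.atoms[tidx[names["C1"]]].position
    hg.position = hg.position + 0.4 * (c1_ti - hg.position) / np.linalg.norm(
        c1_ti - hg.position
    )

    rc = ReactionCoordinate(
        nucleophile_atom=names["OG"],
        electrophile_atom=names["C1"],
        es_distance=3.5,
        ti_distance=1.5,
    )
    full = es.copy()
    return full, EndpointPair(es=es, ti=ti, rc=rc, freeze_list=set()), params
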