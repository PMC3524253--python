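"""Adiabatic mapping: interpolated, constrained frames between ES and TI.

The barrier of the catalytic step is estimated without any saddle-point
search: the straight-line path between the reactant complex (ES) and the
tetrahedral intermediate (TI) is divided into frames, the reaction-coordinate
atom pair is held fixed in every interior frame, all other degrees of freedom
are relaxed, and conventional single-point energies on the relaxed geometries
form the profile.  Every frame is an independent job, so a whole profile
costs one frame's wall time on enough processors.

Frame numbering: 0 is the unconstrained ES, frames 1..n_divisions are the
constrained interpolation frames (frame n_divisions coincides geometrically
with the TI but keeps its constraints), and frame n_divisions+1 is the
unconstrained TI.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_builder import EndpointPair, ReactionCoordinate
from .qm_backend import (
    BackendConfig,
    EnergyChannel,
    EnergyRecord,
    optimize,
    render_input,
)
from .structure_io import StructureModel

__all__ = [
    "FrameStatus",
    "Frame",
    "EnergyProfile",
    "interpolate_path",
    "constrain_frame",
    "run_mapping",
    "generate_jobs",
]


class FrameStatus(str, enum.Enum):
    PENDING = "pending"
    OPTIMIZED = "optimized"
    FAILED = "failed"


@dataclass
class Frame:
    """One point on the reaction path."""

    index: int
    structure: StructureModel
    constrained: bool
    rc_atoms: tuple[int, int]
    energies: list[EnergyRecord] = field(default_factory=list)
    status: FrameStatus = FrameStatus.PENDING

    def energy(self, channel: EnergyChannel) -> float | None:
        for rec in self.energies:
            if rec.channel == channel:
                return rec.heat_of_formation
        return None

    def rc_distance(self) -> float:
        idx = self.structure.serial_index()
        a = self.structure.atoms[idx[self.rc_atoms[0]]].position
        b = self.structure.atoms[idx[self.rc_atoms[1]]].position
        return float(np.linalg.norm(a - b))


@dataclass
class EnergyProfile:
    """Ordered frames plus the channel used for barrier analysis."""

    frames: list[Frame]
    reference_channel: EnergyChannel = EnergyChannel.CONVENTIONAL_SP
    label: str = ""

    def __post_init__(self) -> None:
        indices = [f.index for f in self.frames]
        if indices != sorted(indices):
            raise ValueError("frames must be ordered by index")
        counts = {len(f.structure.atoms) for f in self.frames}
        if len(counts) > 1:
            raise ValueError("all frames must share the same atom count")

    def to_frame_table(self) -> pd.DataFrame:
        """Tabulate the profile: one row per frame, one column per channel."""
        rows = []
        for f in self.frames:
            row: dict = {
                "frame": f.index,
                "rc_distance": f.rc_distance(),
                "constrained": f.constrained,
                "status": f.status.value,
            }
            for rec in f.energies:
                row[rec.channel.value] = rec.heat_of_formation
                if rec.scf_cycles is not None:
                    row[f"{rec.channel.value}_scf_cycles"] = rec.scf_cycles
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame_table().to_csv(path, index=False)


def interpolate_path(endpoints: EndpointPair, n_divisions: int = 10) -> list[Frame]:
    """Linearly interpolate frames 0..n_divisions+1 between ES and TI.

    Interior frame i places every atom at r_ES + i*(r_TI - r_ES)/n_divisions,
    so each atom moves by a constant displacement between consecutive frames
    (an atom whose endpoints differ by 2.2 A moves 0.22 A per frame at the
    default 10 divisions).  Endpoint frames 0 and n_divisions+1 are the
    unconstrained ES and TI; the interior frames carry the fixed
    reaction-coordinate pair, including frame n_divisions, which coincides
    geometrically with the TI but remains constrained.
    """
    if n_divisions < 2:
        raise ValueError("n_divisions must be >= 2")
    es, ti = endpoints.es, endpoints.ti
    if len(es.atoms) != len(ti.atoms):
        raise ValueError("ES and TI atom counts differ")
    rc = endpoints.rc
    rc_atoms = (rc.nucleophile_atom, rc.electrophile_atom)
    r_es, r_ti = es.coords(), ti.coords()
    frames: list[Frame] = [
        Frame(index=0, structure=es.copy(), constrained=False, rc_atoms=rc_atoms)
    ]
    for i in range(1, n_divisions + 1):
        xyz = r_es + i * (r_ti - r_es) / n_divisions
        structure = es.copy()
        structure.set_coords(xyz)
        frame = Frame(index=i, structure=structure, constrained=True, rc_atoms=rc_atoms)
        frames.append(constrain_frame(frame, rc))
    frames.append(
        Frame(
            index=n_divisions + 1,
            structure=ti.copy(),
            constrained=False,
            rc_atoms=rc_atoms,
        )
    )
    return frames


def constrain_frame(frame: Frame, rc: ReactionCoordinate) -> Frame:
    """Fix the reaction-coordinate atom pair of an interior frame.

    Both atoms' Cartesians join the frozen set (fixing both atoms fixes their
    distance); endpoint frames are returned unchanged — all reaction-coordinate
    constraints are discarded there.  Idempotent.
    """
    if not frame.constrained:
        return frame
    idx = frame.structure.serial_index()
    for serial in (rc.nucleophile_atom, rc.electrophile_atom):
        if serial not in idx:
            raise KeyError(f"reaction-coordinate atom serial {serial} missing from frame")
        frame.structure.frozen_atoms.add(serial)
    return frame


def run_mapping(
    frames: list[Frame],
    opt_config: BackendConfig,
    sp_config: BackendConfig,
    backend,
) -> EnergyProfile:
    """Optimize every frame independently, then add single-point energies.

    Each frame is relaxed with ``opt_config`` (its own frozen set applies:
    reaction-coordinate pair on interior frames, plus any freeze list), and
    the relaxed geometry is re-evaluated with ``sp_config``.  Both energy
    channels are stored on the frame.  Frames are fully independent — any
    execution order (or a parallel map) yields the same profile.  A frame
    whose optimization raises is marked failed and left without energies; the
    profile is still returned.
    """
    if opt_config.single_point:
        raise ValueError("opt_config must request optimization (single_point=False)")
    if not sp_config.single_point:
        raise ValueError("sp_config must request a single point (single_point=True)")
    out_frames: list[Frame] = []
    for frame in sorted(frames, key=lambda f: f.index):
        new = Frame(
            index=frame.index,
            structure=frame.structure.copy(),
            constrained=frame.constrained,
            rc_atoms=frame.rc_atoms,
        )
        try:
            result = optimize(new.structure, opt_config, backend)
            new.structure = result.final_structure
            new.energies.append(result.energy)
            e_sp, _ = (
                backend.energy_gradient(new.structure.coords())
                if hasattr(backend, "energy_gradient")
                else backend(new.structure.coords())
            )
            new.energies.append(
                EnergyRecord(channel=sp_config.channel, heat_of_formation=float(e_sp))
            )
            new.status = FrameStatus.OPTIMIZED
        except Exception:  # noqa: BLE001 — screening robustness: skip, don't abort
            new.status = FrameStatus.FAILED
        out_frames.append(new)
    label = f"{sp_config.method}//{opt_config.label}"
    return EnergyProfile(
        frames=out_frames, reference_channel=sp_config.channel, label=label
    )


def generate_jobs(
    frames: list[Frame],
    configs: list[BackendConfig],
    out_dir: str | Path,
) -> dict:
    """Write one self-contained input file per (frame, config) plus a manifest.

    File content and the manifest are deterministic, so regeneration is
    byte-identical; the manifest maps each file back to its frame index and
    configuration label, which is all a batch scheduler needs — frames carry
    no cross-frame state and can run in any order, in parallel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"jobs": []}
    for config in configs:
        slug = f"c{config.nddo_cutoff:g}_g{config.gradient_convergence:g}".replace(".", "p")
        for frame in sorted(frames, key=lambda f: f.index):
            fname = f"frame_{frame.index:03d}__{slug}.mop"
            text = render_input(
                frame.structure,
                config,
                title=f"frame {frame.index} {config.label}",
            )
            (out_dir / fname).write_text(text)
            manifest["jobs"].append(
                {
                    "file": fname,
                    "frame": frame.index,
                    "config": config.label,
                    "constrained": frame.constrained,
                }
            )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
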