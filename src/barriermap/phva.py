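"""Partial Hessian vibrational analysis (PHVA).

Transition-state character of the highest profile frame is verified by
vibrational analysis over a small subset of atoms (the reacting core) with
the environment held fixed: second derivatives are built by central finite
differences of the backend gradient over the subset coordinates only,
mass-weighted and diagonalized.  Exactly one imaginary frequency — a mode
carrying the electrophile carbon toward the nucleophile oxygen — is the
acceptance signature of a true saddle along the mapped coordinate.

Zero-point or thermal corrections are out of scope: the profile energies are
bare electronic heats of formation and the frequencies here serve only to
count and visualize imaginary modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.constants as const

from .structure_io import StructureModel

__all__ = [
    "ATOMIC_MASSES",
    "PartialHessian",
    "VibrationalResult",
    "compute_partial_hessian",
    "frequencies",
    "write_mode_animation",
]

# ---------------------------------------------------------------------------
# Pinned constants: standard atomic weights (amu) and the kcal/(mol*A^2*amu)
# -> cm^-1 conversion, built once from CODATA values so every test sees the
# same numbers.
# ---------------------------------------------------------------------------

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
}

#: multiply an eigenvalue in kcal/(mol*A^2*amu) by this to get (rad/s)^2
_LAMBDA_TO_SI = (const.calorie * 1e3 / const.Avogadro) / (1e-10**2 * const.atomic_mass)
#: 1/(2*pi*c) with c in cm/s: converts rad/s to cm^-1
_OMEGA_TO_WAVENUMBER = 1.0 / (2.0 * np.pi * const.c * 100.0)


@dataclass
class PartialHessian:
    """Second-derivative block over a subset of k atoms (3k x 3k).

    Units: kcal/(mol*A^2).  The matrix is exactly symmetric (symmetrized as
    (H+H^T)/2 after finite differencing).  ``masses`` are amu, in
    ``atom_serials`` order.
    """

    atom_serials: list[int]
    matrix: np.ndarray
    masses: np.ndarray
    origin_structure: StructureModel | None = None

    def __post_init__(self) -> None:
        k = len(self.atom_serials)
        if k < 1:
            raise ValueError("need at least one atom in the subset")
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.matrix.shape != (3 * k, 3 * k):
            raise ValueError(f"Hessian must be {3*k}x{3*k}")
        if self.masses.shape != (k,):
            raise ValueError("one mass per subset atom required")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")


@dataclass
class VibrationalResult:
    """Frequencies in cm^-1 (imaginary modes stored as negative magnitudes)
    with mass-weighted, unit-norm mode vectors as rows of ``modes``."""

    frequencies: np.ndarray
    imaginary: np.ndarray  # boolean flag per mode
    modes: np.ndarray  # (3k, 3k): row i is mode i in mass-weighted coordinates

    @property
    def n_imaginary(self) -> int:
        return int(np.count_nonzero(self.imaginary))


def compute_partial_hessian(
    model: StructureModel,
    subset: list[int],
    backend,
    step: float = 0.01,
) -> PartialHessian:
    """Central-difference Hessian over the subset coordinates only.

    Environment atoms stay at their input positions throughout — their
    coupling into the subset block is what makes this a *partial* analysis.
    ``step`` is the displacement in A; central differences are exact for
    quadratic surfaces, so the default 0.01 A is auditable by doubling it.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    idx = model.serial_index()
    rows = [idx[s] for s in subset]
    x0 = model.coords()
    k = len(subset)
    hessian = np.zeros((3 * k, 3 * k))

    def grad_subset(xyz: np.ndarray) -> np.ndarray:
        _, g = (
            backend.energy_gradient(xyz)
            if hasattr(backend, "energy_gradient")
            else backend(xyz)
        )
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient during Hessian build")
        return g[rows].ravel()

    for a in range(3 * k):
        atom, comp = divmod(a, 3)
        xp = x0.copy()
        xp[rows[atom], comp] += step
        xm = x0.copy()
        xm[rows[atom], comp] -= step
        try:
            gp, gm = grad_subset(xp), grad_subset(xm)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"non-finite gradient displacing atom serial {subset[atom]} "
                f"component {'xyz'[comp]}"
            ) from exc
        hessian[a] = (gp - gm) / (2.0 * step)
    hessian = 0.5 * (hessian + hessian.T)
    masses = np.array(
        [ATOMIC_MASSES[model.atoms[r].element] for r in rows], dtype=float
    )
    return PartialHessian(
        atom_serials=list(subset), matrix=hessian, masses=masses, origin_structure=model
    )


def frequencies(ph: PartialHessian) -> VibrationalResult:
    """Mass-weighted normal-mode frequencies of a partial Hessian.

    Diagonalizes M^(-1/2) H M^(-1/2); each eigenvalue lambda maps to
    sign(lambda)*sqrt(|lambda|) converted to cm^-1, negative eigenvalues
    flagged imaginary and reported as negative magnitudes.  Modes are rows,
    orthonormal in the mass-weighted metric.
    """
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(ph.masses), 3)
    mw = ph.matrix * np.outer(inv_sqrt_m, inv_sqrt_m)
    eigvals, eigvecs = np.linalg.eigh(mw)
    omegas = np.sign(eigvals) * np.sqrt(np.abs(eigvals) * _LAMBDA_TO_SI)
    wavenumbers = omegas * _OMEGA_TO_WAVENUMBER
    return VibrationalResult(
        frequencies=wavenumbers,
        imaginary=eigvals < 0,
        modes=eigvecs.T.copy(),
    )


def write_mode_animation(
    model: StructureModel,
    ph: PartialHessian,
    result: VibrationalResult,
    mode_index: int,
    amplitude: float = 0.5,
    n_steps: int = 20,
) -> str:
    """Render one normal mode as a multi-frame XYZ trajectory string.

    Subset atoms oscillate sinusoidally along the un-mass-weighted mode
    displacement (scaled so the largest atomic excursion over the trajectory
    equals ``amplitude`` A exactly); environment atoms stay put.
    """
    if not 0 <= mode_index < len(result.frequencies):
        raise IndexError(f"mode index {mode_index} out of range")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    idx = model.serial_index()
    rows = [idx[s] for s in ph.atom_serials]
    mode = result.modes[mode_index].reshape(-1, 3)
    disp = mode / np.sqrt(ph.masses)[:, None]  # back to Cartesian displacements
    max_disp = np.max(np.linalg.norm(disp, axis=1))
    phases = np.sin(2.0 * np.pi * np.arange(n_steps) / n_steps)
    max_phase = np.max(np.abs(phases)) if n_steps > 1 else 0.0
    if amplitude == 0.0 or max_disp == 0.0 or max_phase == 0.0:
        scaled = np.zeros_like(disp)
        phases = np.zeros(n_steps)
    else:
        scaled = disp * (amplitude / (max_disp * max_phase))
    x0 = model.coords()
    freq = result.frequencies[mode_index]
    tag = f"{abs(freq):.1f}{'i' if result.imaginary[mode_index] else ''} cm-1"
    blocks: list[str] = []
    for s, phase in enumerate(phases):
        xyz = x0.copy()
        xyz[rows] += phase * scaled
        lines = [str(len(model.atoms)), f"mode {mode_index} ({tag}) step {s}"]
        for atom, pos in zip(model.atoms, xyz):
            lines.append(
                f"{atom.element:<2s} {pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}"
            )
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\n"
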