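"""Energy-backend contract: MOPAC-dialect I/O, analytic surrogate, optimizer.

The screening pipeline only needs three things from a quantum engine:
constrained geometry optimization, single-point energies, and gradients.
This module renders deterministic MOPAC-dialect input files (PM6/MOZYME
keywords, per-coordinate optimization flags), parses the result files, and
provides an analytic surrogate potential (harmonic bonds + a double-well
along one atom-pair distance) so the entire pipeline runs and is testable
without any external quantum-chemistry program.

Three energy channels are tracked throughout: the localized-orbital (MOZYME)
optimization energy, the 1SCF re-orthogonalized energy, and the conventional
delocalized-orbital single point.  Keeping them separate matters because
localized-orbital energies accumulate orthogonality error during long
optimizations and must not be compared across frames directly.
"""

from __future__ import annotations

import enum
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from scipy.optimize import minimize

from .structure_io import StructureModel

__all__ = [
    "EnergyChannel",
    "BackendConfig",
    "EnergyRecord",
    "OptimizationResult",
    "render_input",
    "parse_output",
    "SurrogateParams",
    "SurrogateBackend",
    "surrogate_energy",
    "optimize",
    "MopacBackend",
]


class EnergyChannel(str, enum.Enum):
    """Which orbital treatment produced a heat of formation."""

    MOZYME = "mozyme"
    MOZYME_REORTH = "mozyme_reorthogonalized"
    CONVENTIONAL_SP = "conventional_sp"


@dataclass(frozen=True)
class BackendConfig:
    """One engine configuration, written M(C<cutoff>, G<gcc>) in shorthand.

    ``nddo_cutoff`` (A) is the distance beyond which NDDO interactions are
    replaced by point charges in the localized-orbital scheme;
    ``gradient_convergence`` (kcal/(mol*A)) is the geometry-optimization
    termination criterion (GNORM).  ``single_point`` requests a 1SCF energy
    evaluation with no geometry change; ``reorthogonalize`` marks a 1SCF
    re-evaluation with localized orbitals to shed accumulated
    orthogonality error.
    """

    method: str = "PM6"
    localized_orbitals: bool = True
    nddo_cutoff: float = 15.0
    gradient_convergence: float = 0.5
    charge: int = 0
    single_point: bool = False
    reorthogonalize: bool = False
    extra_keywords: tuple[str, ...] = ()

    _METHODS = ("PM6", "AM1", "PM3", "RM1")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"unsupported method {self.method!r}; expected one of {self._METHODS}")
        if self.nddo_cutoff <= 0:
            raise ValueError("nddo_cutoff must be positive")
        if self.gradient_convergence <= 0:
            raise ValueError("gradient_convergence must be positive")

    @property
    def label(self) -> str:
        """The M(Cx, Gy) shorthand for this configuration."""
        return f"M(C{self.nddo_cutoff:g}, G{self.gradient_convergence:.1f})"

    @property
    def channel(self) -> EnergyChannel:
        if not self.localized_orbitals:
            return EnergyChannel.CONVENTIONAL_SP
        if self.reorthogonalize:
            return EnergyChannel.MOZYME_REORTH
        return EnergyChannel.MOZYME


@dataclass
class EnergyRecord:
    channel: EnergyChannel
    heat_of_formation: float  # kcal/mol
    scf_cycles: int | None = None
    wall_time: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.heat_of_formation):
            raise ValueError("heat of formation must be finite")


@dataclass
class OptimizationResult:
    final_structure: StructureModel
    energy: EnergyRecord
    converged: bool
    gradient_norm: float  # max |component| over unconstrained coordinates


# ---------------------------------------------------------------------------
# MOPAC-dialect input rendering / output parsing
# ---------------------------------------------------------------------------

_OPEN_SHELL_KEYWORDS = {"UHF", "TRIPLET", "DOUBLET", "QUARTET", "QUINTET", "OPEN"}


def _num(x: float) -> str:
    return f"{x:g}"


def render_input(
    model: StructureModel,
    config: BackendConfig,
    constraints: Iterable[int] = (),
    title: str = "barriermap job",
) -> str:
    """Render a MOPAC-dialect input file for one job.

    Keyword order is fixed (method, MOZYME, CUTOFF, GNORM, CHARGE, 1SCF,
    extras) so identical inputs yield byte-identical text.  The geometry
    block carries per-coordinate flags: 0 for frozen atoms, 1 otherwise.
    CUTOFF accompanies the localized-orbital keyword only; GNORM is omitted
    for single points (no optimization to converge).
    """
    if config.localized_orbitals:
        bad = _OPEN_SHELL_KEYWORDS & {k.upper() for k in config.extra_keywords}
        if bad:
            raise ValueError(
                f"open-shell keywords {sorted(bad)} are incompatible with localized orbitals"
            )
    keywords: list[str] = [config.method]
    if config.localized_orbitals:
        keywords.append("MOZYME")
        keywords.append(f"CUTOFF={_num(config.nddo_cutoff)}")
    if not config.single_point:
        keywords.append(f"GNORM={_num(config.gradient_convergence)}")
    if config.charge != 0:
        keywords.append(f"CHARGE={config.charge:d}")
    if config.single_point:
        keywords.append("1SCF")
    keywords.extend(config.extra_keywords)

    frozen = set(constraints) | set(model.frozen_atoms)
    lines = [" ".join(keywords), title, ""]
    for atom in model.atoms:
        flag = 0 if atom.serial in frozen else 1
        x, y, z = atom.position
        lines.append(
            f"{atom.element:<2s} {x:15.8f} {flag:d} {y:15.8f} {flag:d} {z:15.8f} {flag:d}"
        )
    return "\n".join(lines) + "\n"


_HEAT_RE = re.compile(r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+\.?\d*)\s*KCAL/?MOL", re.I)
_SCF_RE = re.compile(r"(?:NO\. OF|NUMBER OF)\s+SCF\s+(?:CYCLES|CALCULATIONS)\s*[:=]?\s*(\d+)", re.I)
_COORD_RE = re.compile(
    r"^\s*\d+\s+([A-Za-z]{1,2})\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$"
)
_FAIL_MARKERS = ("UNABLE TO ACHIEVE SELF-CONSISTENCE", "EXCESS NUMBER OF OPTIMIZATION CYCLES")


def parse_output(text: str) -> dict:
    """Parse a MOPAC-dialect output file from a terminated run.

    Returns a dict with ``heat_of_formation`` (kcal/mol), ``coordinates``
    ((n,3) array), ``elements``, ``converged`` and ``scf_cycles`` (or None).
    A file with no final heat of formation is treated as truncated.
    """
    converged = not any(marker in text for marker in _FAIL_MARKERS)
    m = _HEAT_RE.search(text)
    if m is None:
        if converged:
            raise ValueError("incomplete output: no FINAL HEAT OF FORMATION found")
        heat = None
    else:
        heat = float(m.group(1))
    scf = _SCF_RE.search(text)
    coords: list[list[float]] = []
    elements: list[str] = []
    in_block = False
    for line in text.splitlines():
        if "CARTESIAN COORDINATES" in line.upper():
            in_block = True
            coords, elements = [], []  # keep the last block in the file
            continue
        if in_block:
            cm = _COORD_RE.match(line)
            if cm:
                elements.append(cm.group(1))
                coords.append([float(cm.group(i)) for i in (2, 3, 4)])
            elif coords and line.strip() and not line.strip().startswith(("NO.", "ATOM")):
                in_block = False
    return {
        "heat_of_formation": heat,
        "coordinates": np.array(coords) if coords else np.empty((0, 3)),
        "elements": elements,
        "converged": converged,
        "scf_cycles": int(scf.group(1)) if scf else None,
    }


# ---------------------------------------------------------------------------
# Analytic surrogate potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateParams:
    """Harmonic bonds + one double-well pair distance, all in kcal/mol and A.

    ``bonds`` is a tuple of (serial_i, serial_j, force constant k, r0) with
    energy 0.5*k*(d-r0)^2 per bond.  The double well acts on the distance d
    between ``well_pair``:  V(d) = A * (d-d1)^2 (d-d2)^2 / ((d2-d1)/2)^4, so
    V vanishes at both well positions d1 < d2 and equals exactly the barrier
    height A at the midpoint.
    """

    bonds: tuple[tuple[int, int, float, float], ...]
    well_pair: tuple[int, int]
    barrier: float  # A, kcal/mol
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if not self.d2 > self.d1 > 0:
            raise ValueError("require d2 > d1 > 0")
        if self.barrier < 0:
            raise ValueError("barrier must be non-negative")


class SurrogateBackend:
    """Analytic energy/gradient callable over a fixed atom-serial ordering.

    Instances are bound to a serial ordering (taken from a template model) so
    coordinate arrays can be mapped to bond terms without repeated lookups.
    """

    def __init__(self, params: SurrogateParams, template: StructureModel):
        self.params = params
        self._index = template.serial_index()
        missing = [
            s
            for bond in params.bonds
            for s in bond[:2]
            if s not in self._index
        ] + [s for s in params.well_pair if s not in self._index]
        if missing:
            raise KeyError(f"surrogate parameters reference unknown serials: {sorted(set(missing))}")
        self.n_atoms = len(self._index)

    def energy_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Energy (kcal/mol) and gradient (kcal/(mol*A), shape (n,3))."""
        xyz = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        energy = 0.0
        grad = np.zeros_like(xyz)
        for si, sj, k, r0 in self.params.bonds:
            i, j = self._index[si], self._index[sj]
            rij = xyz[i] - xyz[j]
            d = np.linalg.norm(rij)
            energy += 0.5 * k * (d - r0) ** 2
            if d > 1e-12:
                g = k * (d - r0) * rij / d
                grad[i] += g
                grad[j] -= g
        p = self.params
        i, j = self._index[p.well_pair[0]], self._index[p.well_pair[1]]
        rij = xyz[i] - xyz[j]
        d = np.linalg.norm(rij)
        scale = p.barrier / (((p.d2 - p.d1) / 2.0) ** 4)
        a, b = d - p.d1, d - p.d2
        energy += scale * a * a * b * b
        if d > 1e-12:
            dv_dd = scale * (2 * a * b * b + 2 * a * a * b)
            g = dv_dd * rij / d
            grad[i] += g
            grad[j] -= g
        return energy, grad

    def __call__(self, model_or_coords) -> tuple[float, np.ndarray]:
        if isinstance(model_or_coords, StructureModel):
            return self.energy_gradient(model_or_coords.coords())
        return self.energy_gradient(model_or_coords)


def surrogate_energy(
    model: StructureModel, params: SurrogateParams
) -> tuple[float, np.ndarray]:
    """Energy and analytic gradient of the surrogate surface for one model."""
    return SurrogateBackend(params, model)(model)


# ---------------------------------------------------------------------------
# Constrained optimization
# ---------------------------------------------------------------------------

def optimize(
    model: StructureModel,
    config: BackendConfig,
    backend: Callable[[np.ndarray], tuple[float, np.ndarray]] | SurrogateBackend,
    frozen: Iterable[int] = (),
    max_iterations: int = 2000,
) -> OptimizationResult:
    """Minimize the backend energy over all unconstrained coordinates.

    Frozen atoms (the union of ``frozen`` and ``model.frozen_atoms``) never
    move — their coordinates are excluded from the optimization variables
    entirely, so they are bit-identical before and after.  Termination: max
    absolute gradient component over unconstrained coordinates at or below
    ``config.gradient_convergence``.  Hitting the iteration cap returns an
    unconverged result rather than raising.
    """
    frozen_serials = set(frozen) | set(model.frozen_atoms)
    x0 = model.coords()
    free_mask = np.array([a.serial not in frozen_serials for a in model.atoms])
    free_idx = np.where(free_mask)[0]
    evaluate = backend.energy_gradient if hasattr(backend, "energy_gradient") else backend

    def eval_full(xyz_free: np.ndarray) -> tuple[float, np.ndarray]:
        xyz = x0.copy()
        if free_idx.size:
            xyz[free_idx] = xyz_free.reshape(-1, 3)
        e, g = evaluate(xyz)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("backend returned non-finite gradient")
        return e, g

    if free_idx.size == 0:
        e, _ = eval_full(np.empty(0))
        final = model.copy()
        return OptimizationResult(
            final_structure=final,
            energy=EnergyRecord(channel=config.channel, heat_of_formation=e),
            converged=True,
            gradient_norm=0.0,
        )

    def fun(xf: np.ndarray) -> tuple[float, np.ndarray]:
        e, g = eval_full(xf)
        return e, g[free_idx].ravel()

    res = minimize(
        fun,
        x0[free_idx].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={
            "gtol": config.gradient_convergence,
            "ftol": 1e-14,
            "maxiter": max_iterations,
            "maxls": 60,
        },
    )
    e_final, g_final = eval_full(res.x)
    gmax = float(np.max(np.abs(g_final[free_idx]))) if free_idx.size else 0.0
    xyz = x0.copy()
    xyz[free_idx] = res.x.reshape(-1, 3)
    final = model.copy()
    final.set_coords(xyz)
    return OptimizationResult(
        final_structure=final,
        energy=EnergyRecord(channel=config.channel, heat_of_formation=float(e_final)),
        converged=gmax <= config.gradient_convergence,
        gradient_norm=gmax,
    )


# ---------------------------------------------------------------------------
# External-program adapter (optional; requires a MOPAC executable on PATH)
# ---------------------------------------------------------------------------

class MopacBackend:
    """Thin adapter around an external MOPAC executable.

    Only used when ``executable`` resolves; the rest of the package never
    needs it.  ``run`` writes the rendered input into a scratch directory,
    invokes the program and parses the result.
    """

    def __init__(self, executable: str = "mopac"):
        self.executable = executable

    @property
    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def run(
        self, model: StructureModel, config: BackendConfig, constraints: Iterable[int] = ()
    ) -> dict:
        if not self.available:
            raise RuntimeError(f"external program {self.executable!r} not found on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            job = Path(tmp) / "job.mop"
            job.write_text(render_input(model, config, constraints))
            subprocess.run(
                [self.executable, str(job)], check=True, capture_output=True, cwd=tmp
            )
            out = job.with_suffix(".out")
            return parse_output(out.read_text())
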