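"""Metropolis Monte Carlo sampling of rigid waters around a rigid solute.

The analysis downstream (field distributions, radial distributions) only
needs equilibrium configurations, so configurations are generated with
rigid-body Metropolis Monte Carlo rather than molecular dynamics: each
move translates and rotates one randomly chosen water, and is accepted
with probability min(1, exp(−ΔU/kT)).  The solute never moves.

Energies are a plain pairwise sum: Lennard-Jones between oxygen centers
(water-water) and between the water oxygen and solute heavy atoms
(Lorentz-Berthelot mixing), plus Coulomb over all charged sites.  In a
cubic periodic cell the minimum-image convention is applied per molecule
pair (the image shift is decided by the oxygen-oxygen displacement and
applied to every site of the partner molecule, keeping molecules intact);
no Ewald summation.  The spherical droplet applies a hard wall on the
oxygen position instead of images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BOLTZMANN_KJMOL, KE_COULOMB
from .solute import SoluteGeometry
from .water import RigidWater, WaterModel, all_site_positions, load_water_model, random_quaternion
from scipy.spatial.transform import Rotation

__all__ = [
    "SimulationCell",
    "MCParams",
    "Frame",
    "Trajectory",
    "SingularEnergyError",
    "potential_energy",
    "mc_sample",
    "metropolis",
]


class SingularEnergyError(ValueError):
    """Two interaction sites coincide; the Coulomb sum diverges."""


@dataclass(frozen=True)
class SimulationCell:
    """Analysis volume: spherical droplet (radius) or cubic periodic box (edge)."""

    kind: str  # "droplet" | "cubic"
    size: float  # radius or edge length, Å

    def __post_init__(self):
        if self.kind not in ("droplet", "cubic"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def volume(self) -> float:
        if self.kind == "droplet":
            return 4.0 / 3.0 * math.pi * self.size**3
        return self.size**3


@dataclass(frozen=True)
class MCParams:
    """Sampling parameters.  A sweep is one attempted single-molecule move.

    ``seed`` is mandatory — there is no hidden global random state.
    """

    temperature: float  # K
    n_sweeps: int = 200_000
    equilibration_fraction: float = 0.2
    max_translation: float = 0.25  # Å
    max_rotation: float = 0.35  # rad
    seed: int = 0
    sample_stride: int = 100

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if not (0 <= self.equilibration_fraction < 1):
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if self.max_translation <= 0 or self.max_rotation <= 0:
            raise ValueError("move amplitudes must be positive")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass
class Frame:
    """One configuration: the rigid solute plus N rigid waters."""

    solute: SoluteGeometry
    oxygens: np.ndarray  # (N, 3) Å
    orientations: np.ndarray  # (N, 4) unit quaternions
    water_model: WaterModel

    @property
    def n_waters(self) -> int:
        return len(self.oxygens)

    @property
    def waters(self) -> list[RigidWater]:
        return [
            RigidWater(self.oxygens[i], self.orientations[i], self.water_model)
            for i in range(self.n_waters)
        ]

    def water_sites(self) -> np.ndarray:
        """(N, 5, 3) world-frame site positions."""
        return all_site_positions(self.oxygens, self.orientations, self.water_model)


@dataclass
class Trajectory:
    """Ordered frames at one temperature, with per-frame total energies."""

    frames: list[Frame]
    temperature: float  # K
    energies: np.ndarray = field(default_factory=lambda: np.array([]))
    acceptance_fraction: float = float("nan")
    seed: int | None = None

    def __post_init__(self):
        counts = {f.n_waters for f in self.frames}
        if len(counts) > 1:
            raise ValueError("water count varies across frames")

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------- energies


def _min_image_shift(d: np.ndarray, edge: float | None) -> np.ndarray:
    if edge is None:
        return np.zeros_like(d)
    return -edge * np.round(d / edge)


def _lj(r2: np.ndarray, sigma, epsilon) -> np.ndarray:
    s6 = (sigma**2 / r2) ** 3
    return 4.0 * epsilon * (s6**2 - s6)


def _water_water_energy(
    sites_i: np.ndarray,
    sites_others: np.ndarray,
    model: WaterModel,
    edge: float | None,
    cutoff: float | None,
) -> float:
    """Energy of water i against a stack of other waters (M, 5, 3)."""
    if len(sites_others) == 0:
        return 0.0
    d_oo = sites_others[:, 0, :] - sites_i[0]
    shift = _min_image_shift(d_oo, edge)
    d_oo = d_oo + shift
    r2_oo = np.einsum("ij,ij->i", d_oo, d_oo)
    if np.any(r2_oo < 1e-12):
        raise SingularEnergyError("coincident oxygen sites")
    mask = np.ones(len(sites_others), dtype=bool)
    if cutoff is not None:
        mask = r2_oo < cutoff**2
        if not mask.any():
            return 0.0
    others = sites_others[mask] + shift[mask][:, None, :]
    # Coulomb over charged sites (H, L); oxygen carries no charge.
    q = model.site_charges
    charged = np.nonzero(q)[0]
    disp = others[:, None, charged, :] - sites_i[charged][None, :, None, :]
    r = np.sqrt(np.einsum("mabk,mabk->mab", disp, disp))
    if np.any(r < 1e-6):
        raise SingularEnergyError("coincident charged sites")
    qq = np.outer(q[charged], q[charged])
    e_coul = KE_COULOMB * float(np.sum(qq[None, :, :] / r))
    e_lj = float(np.sum(_lj(r2_oo[mask], model.sigma, model.epsilon)))
    return e_coul + e_lj


def _water_solute_energy(
    sites_i: np.ndarray,
    solute: SoluteGeometry,
    model: WaterModel,
    edge: float | None,
) -> float:
    d = solute.positions - sites_i[0]
    shift = _min_image_shift(d, edge)
    pos = solute.positions + shift
    # LJ: water O against every solute heavy atom, Lorentz-Berthelot mixing
    d_o = pos - sites_i[0]
    r2 = np.einsum("ij,ij->i", d_o, d_o)
    if np.any(r2 < 1e-12):
        raise SingularEnergyError("water oxygen coincides with solute atom")
    sig = 0.5 * (model.sigma + solute.lj_sigma)
    eps = np.sqrt(model.epsilon * solute.lj_epsilon)
    e_lj = float(np.sum(_lj(r2, sig, eps)))
    # Coulomb: charged water sites against all solute charges
    q = model.site_charges
    charged = np.nonzero(q)[0]
    disp = pos[:, None, :] - sites_i[charged][None, :, :]
    r = np.sqrt(np.einsum("abk,abk->ab", disp, disp))
    if np.any(r < 1e-6):
        raise SingularEnergyError("coincident charged sites (water-solute)")
    e_coul = KE_COULOMB * float(np.sum(np.outer(solute.charges, q[charged]) / r))
    return e_lj + e_coul


def potential_energy(
    frame: Frame, cell: SimulationCell, cutoff: float | None = None
) -> float:
    """Total potential energy of a frame in kJ/mol.

    Water-water LJ acts between oxygen centers; Coulomb over all charged
    sites; water-solute adds LJ against solute heavy atoms.  ``cutoff``
    (Å, on the oxygen-oxygen distance, whole molecules in or out) defaults
    to none for droplets and 9 Å for periodic cells.
    """
    edge = cell.size if cell.kind == "cubic" else None
    if cutoff is None and cell.kind == "cubic":
        cutoff = min(9.0, cell.size / 2)
    sites = frame.water_sites()
    total = 0.0
    for i in range(frame.n_waters):
        total += _water_water_energy(sites[i], sites[i + 1 :], frame.water_model, edge, cutoff)
        total += _water_solute_energy(sites[i], frame.solute, frame.water_model, edge)
    return total


def _one_water_energy(i, sites, solute, model, edge, cutoff):
    others = np.delete(sites, i, axis=0)
    return _water_water_energy(sites[i], others, model, edge, cutoff) + _water_solute_energy(
        sites[i], solute, model, edge
    )


# Optional numba fast path for the per-move energy (the sampler's hot
# loop); semantics identical to _one_water_energy.  Falls back to the
# numpy implementation when numba is unavailable.
try:
    from numba import njit as _njit

    @_njit(cache=False)
    def _one_water_energy_nb(i, sites, q, sigma, epsilon,
                             sol_pos, sol_q, sol_sig, sol_eps,
                             edge, cutoff2):
        n = sites.shape[0]
        e = 0.0
        ox, oy, oz = sites[i, 0, 0], sites[i, 0, 1], sites[i, 0, 2]
        for j in range(n):
            if j == i:
                continue
            dx = sites[j, 0, 0] - ox
            dy = sites[j, 0, 1] - oy
            dz = sites[j, 0, 2] - oz
            sx = sy = sz = 0.0
            if edge > 0.0:
                sx = -edge * round(dx / edge)
                sy = -edge * round(dy / edge)
                sz = -edge * round(dz / edge)
                dx += sx
                dy += sy
                dz += sz
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-12:
                return np.inf
            if cutoff2 > 0.0 and r2 > cutoff2:
                continue
            s6 = (sigma * sigma / r2) ** 3
            e += 4.0 * epsilon * (s6 * s6 - s6)
            for a in range(1, 5):
                pax = sites[i, a, 0]
                pay = sites[i, a, 1]
                paz = sites[i, a, 2]
                for b in range(1, 5):
                    bx = sites[j, b, 0] + sx - pax
                    by = sites[j, b, 1] + sy - pay
                    bz = sites[j, b, 2] + sz - paz
                    r = np.sqrt(bx * bx + by * by + bz * bz)
                    if r < 1e-6:
                        return np.inf
                    e += KE_COULOMB * q[a] * q[b] / r
        for m in range(sol_pos.shape[0]):
            dx = sol_pos[m, 0] - ox
            dy = sol_pos[m, 1] - oy
            dz = sol_pos[m, 2] - oz
            sx = sy = sz = 0.0
            if edge > 0.0:
                sx = -edge * round(dx / edge)
                sy = -edge * round(dy / edge)
                sz = -edge * round(dz / edge)
                dx += sx
                dy += sy
                dz += sz
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-12:
                return np.inf
            sig = 0.5 * (sigma + sol_sig[m])
            eps = np.sqrt(epsilon * sol_eps[m])
            s6 = (sig * sig / r2) ** 3
            e += 4.0 * eps * (s6 * s6 - s6)
            px, py, pz = sol_pos[m, 0] + sx, sol_pos[m, 1] + sy, sol_pos[m, 2] + sz
            for a in range(1, 5):
                bx = px - sites[i, a, 0]
                by = py - sites[i, a, 1]
                bz = pz - sites[i, a, 2]
                r = np.sqrt(bx * bx + by * by + bz * bz)
                if r < 1e-6:
                    return np.inf
                e += KE_COULOMB * q[a] * sol_q[m] / r
        return e

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


# ---------------------------------------------------------------- drivers


def metropolis(energy_fn, propose_fn, x0, n_steps, kT, rng):
    """Generic Metropolis driver used for sampler verification.

    ``energy_fn(x)`` returns a scalar energy; ``propose_fn(x, rng)`` a
    trial state.  Returns (samples array of every visited state, accepted
    count).  Exposed so the acceptance rule can be checked on analytically
    solvable potentials (e.g. a harmonic well, variance kT/k per axis).
    """
    x = np.asarray(x0, dtype=float)
    u = energy_fn(x)
    out = np.empty((n_steps,) + x.shape)
    accepted = 0
    for step in range(n_steps):
        trial = propose_fn(x, rng)
        u_trial = energy_fn(trial)
        du = u_trial - u
        if du <= 0 or rng.random() < math.exp(-du / kT):
            x, u = trial, u_trial
            accepted += 1
        out[step] = x
    return out, accepted


def _initial_configuration(solute, n_waters, cell, model, rng, min_dist=2.6):
    placed = np.empty((n_waters, 3))
    quats = np.empty((n_waters, 4))
    heavy = solute.positions
    for i in range(n_waters):
        for attempt in range(20_000):
            if cell.kind == "droplet":
                p = rng.uniform(-cell.size, cell.size, 3)
                if np.linalg.norm(p) > cell.size:
                    continue
            else:
                p = rng.uniform(-cell.size / 2, cell.size / 2, 3)
            if np.min(np.linalg.norm(heavy - p, axis=1)) < min_dist:
                continue
            if i and np.min(np.linalg.norm(placed[:i] - p, axis=1)) < min_dist:
                continue
            placed[i] = p
            quats[i] = random_quaternion(rng)
            break
        else:
            raise RuntimeError(
                f"could not place water {i + 1}/{n_waters}; cell too crowded"
            )
    return placed, quats


def _rotate_quat(quat, axis, angle):
    """Left-compose an axis-angle rotation onto quat (x, y, z, w order).

    Hand-coded (with the matrix conversion below) to keep scipy object
    construction out of the sampler's hot loop.
    """
    half = 0.5 * angle
    s = math.sin(half)
    dq = (axis[0] * s, axis[1] * s, axis[2] * s, math.cos(half))
    x1, y1, z1, w1 = dq
    x2, y2, z2, w2 = quat
    out = np.array(
        [
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        ]
    )
    return out / np.linalg.norm(out)


def _quat_matrix(q):
    x, y, z, w = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def mc_sample(
    solute: SoluteGeometry,
    n_waters: int,
    cell: SimulationCell,
    params: MCParams,
    water_model: WaterModel | None = None,
    cutoff: float | None = None,
) -> Trajectory:
    """Sample equilibrium water configurations around a rigid solute.

    Frames are recorded every ``sample_stride`` attempted moves after the
    equilibration fraction of the run.  Identical parameters and seed give
    a bit-identical trajectory.
    """
    if n_waters < 1:
        raise ValueError("need at least one water")
    model = water_model or load_water_model()
    edge = cell.size if cell.kind == "cubic" else None
    if cutoff is None and cell.kind == "cubic":
        cutoff = min(9.0, cell.size / 2)
    rng = np.random.Generator(np.random.PCG64(params.seed))
    kT = BOLTZMANN_KJMOL * params.temperature

    oxygens, quats = _initial_configuration(solute, n_waters, cell, model, rng)
    sites = all_site_positions(oxygens, quats, model)
    try:
        frame0 = Frame(solute, oxygens.copy(), quats.copy(), model)
        total_u = potential_energy(frame0, cell, cutoff)
    except SingularEnergyError as err:
        raise SingularEnergyError(f"initial configuration invalid: {err}") from err

    n_equil = int(params.equilibration_fraction * params.n_sweeps)
    frames: list[Frame] = []
    energies: list[float] = []
    accepted = 0

    if _HAVE_NUMBA:
        edge_nb = edge if edge is not None else 0.0
        cutoff2 = cutoff**2 if cutoff is not None else 0.0

        def move_energy(idx):
            return float(
                _one_water_energy_nb(
                    idx, sites, model.site_charges, model.sigma, model.epsilon,
                    solute.positions, solute.charges, solute.lj_sigma,
                    solute.lj_epsilon, edge_nb, cutoff2,
                )
            )
    else:

        def move_energy(idx):
            try:
                return _one_water_energy(idx, sites, solute, model, edge, cutoff)
            except SingularEnergyError:
                return math.inf

    for sweep in range(params.n_sweeps):
        i = int(rng.integers(n_waters))
        old_u_i = move_energy(i)
        old_pos = oxygens[i].copy()
        old_quat = quats[i].copy()
        old_sites = sites[i].copy()

        new_pos = old_pos + rng.uniform(-params.max_translation, params.max_translation, 3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-params.max_rotation, params.max_rotation)
        new_quat = _rotate_quat(old_quat, axis, angle)

        inside = not (cell.kind == "droplet" and np.linalg.norm(new_pos) > cell.size)
        if inside:
            oxygens[i] = new_pos
            quats[i] = new_quat
            sites[i] = model.site_offsets @ _quat_matrix(new_quat).T + new_pos
            du = move_energy(i) - old_u_i
            if du <= 0 or rng.random() < math.exp(-du / kT):
                accepted += 1
                total_u += du
            else:
                oxygens[i], quats[i], sites[i] = old_pos, old_quat, old_sites

        if sweep >= n_equil and (sweep - n_equil) % params.sample_stride == 0:
            frames.append(Frame(solute, oxygens.copy(), quats.copy(), model))
            energies.append(total_u)

    return Trajectory(
        frames=frames,
        temperature=params.temperature,
        energies=np.asarray(energies),
        acceptance_fraction=accepted / params.n_sweeps,
        seed=params.seed,
    )
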