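"""Solvent electric field at the phosphate probe from distributed multipoles.

The field of the water shell is evaluated at the midpoint of the free
O1–O2 axis of the phosphate group and projected on the C2 symmetry axis
of PO2− (the two-fold axis through P bisecting the O–P–O angle).  Each
solvent source is a point charge, point dipole, and Buckingham traceless
quadrupole; the default source specification uses the TIP5P point
charges only, with optional per-molecule dipoles/quadrupoles loaded from
a multipole parameter file for distributed-multipole-style fidelity.

Sign convention: the projection axis ê points from P through the O–O
midpoint into the solvent, so E∥ > 0 means the solvent field points away
from the phosphorus.  The solute's own charges never contribute.

Units: positions Å, charges e, dipoles e·Å, quadrupoles e·Å²; fields in
MV/cm (prefactor ``KE_FIELD`` = (e/4πε0)/Å² ≈ 1439.96 MV/cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import KE_FIELD
from .sampler import Frame, Trajectory
from .solute import SoluteGeometry

__all__ = [
    "MultipoleSite",
    "FieldProbe",
    "FieldSample",
    "SourceSpec",
    "c2_probe",
    "field_from_charge",
    "field_from_dipole",
    "field_from_quadrupole",
    "field_from_site",
    "solvent_field",
    "trajectory_fields",
    "quadrupole_from_charges",
    "load_fragment_multipoles",
]

_TRACE_TOL = 1e-9


@dataclass
class MultipoleSite:
    """Point multipole source: charge q (e), dipole μ (e·Å), traceless
    quadrupole Θ (e·Å², Buckingham convention).  Any order may be zero."""

    position: np.ndarray
    charge: float = 0.0
    dipole: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quadrupole: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.dipole = np.asarray(self.dipole, dtype=float)
        self.quadrupole = np.asarray(self.quadrupole, dtype=float)
        q = self.quadrupole
        if np.max(np.abs(q - q.T)) > _TRACE_TOL:
            raise ValueError("quadrupole must be symmetric")
        if abs(np.trace(q)) > _TRACE_TOL:
            raise ValueError(f"quadrupole trace {np.trace(q):g} exceeds {_TRACE_TOL}")


@dataclass(frozen=True)
class FieldProbe:
    """Probe point r0 (O1–O2 midpoint) and unit projection axis ê (C2 axis)."""

    point: np.ndarray
    axis: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("probe axis must be unit-norm")
        object.__setattr__(self, "axis", axis)


@dataclass
class FieldSample:
    """Field vector and its signed C2 projection at one frame."""

    vector: np.ndarray  # MV/cm
    parallel: float  # MV/cm, signed
    frame_index: int = 0
    temperature: float = float("nan")


@dataclass(frozen=True)
class SourceSpec:
    """Which solvent multipole orders contribute.

    Default: TIP5P point charges only, consistent with the sampler's
    energetics.  ``fragment_dipole``/``fragment_quadrupole`` (body-frame,
    placed at the oxygen) add distributed-multipole-style terms; load
    them from YAML with :func:`load_fragment_multipoles`.
    """

    use_charges: bool = True
    fragment_dipole: np.ndarray | None = None
    fragment_quadrupole: np.ndarray | None = None


def c2_probe(solute: SoluteGeometry) -> FieldProbe:
    """Probe geometry from the designated P, O1, O2 atoms.

    r0 is the O1–O2 midpoint; ê points from P through r0 (into the
    solvent).  Swapping the O1/O2 labels leaves both unchanged.
    """
    p = solute.positions[solute.p_index]
    o1 = solute.positions[solute.o1_index]
    o2 = solute.positions[solute.o2_index]
    mid = 0.5 * (o1 + o2)
    axis = mid - p
    norm = np.linalg.norm(axis)
    cross = np.linalg.norm(np.cross(o1 - p, o2 - p))
    if norm < 1e-9 or cross < 1e-9:
        raise ValueError("degenerate probe geometry: P, O1, O2 collinear")
    return FieldProbe(point=mid, axis=axis / norm)


def field_from_charge(site: MultipoleSite, point) -> np.ndarray:
    """Coulomb field K·q·R/|R|³ at ``point`` (MV/cm), away from + charge."""
    r = np.asarray(point, dtype=float) - site.position
    d2 = float(r @ r)
    if d2 < 1e-12:
        raise ZeroDivisionError("field evaluation point coincides with source")
    return KE_FIELD * site.charge * r / d2**1.5


def field_from_dipole(site: MultipoleSite, point) -> np.ndarray:
    """Ideal-dipole field K·(3(μ·n̂)n̂ − μ)/|R|³ (MV/cm)."""
    r = np.asarray(point, dtype=float) - site.position
    d = np.linalg.norm(r)
    if d < 1e-6:
        raise ZeroDivisionError("field evaluation point coincides with source")
    n = r / d
    return KE_FIELD * (3.0 * (site.dipole @ n) * n - site.dipole) / d**3


def field_from_quadrupole(site: MultipoleSite, point) -> np.ndarray:
    """Traceless-quadrupole field K·(5 n̂(n̂·Θ·n̂) − 2 Θ·n̂)/|R|⁴ (MV/cm).

    Derived from the Buckingham potential φ = K (R·Θ·R)/|R|⁵; falls off
    as |R|⁻⁴.
    """
    r = np.asarray(point, dtype=float) - site.position
    d = np.linalg.norm(r)
    if d < 1e-6:
        raise ZeroDivisionError("field evaluation point coincides with source")
    n = r / d
    tn = site.quadrupole @ n
    return KE_FIELD * (5.0 * n * (n @ tn) - 2.0 * tn) / d**4


def field_from_site(site: MultipoleSite, point) -> np.ndarray:
    """Superposition of the charge, dipole and quadrupole contributions."""
    total = np.zeros(3)
    if site.charge != 0.0:
        total += field_from_charge(site, point)
    if np.any(site.dipole):
        total += field_from_dipole(site, point)
    if np.any(site.quadrupole):
        total += field_from_quadrupole(site, point)
    return total


def quadrupole_from_charges(positions, charges, origin=None) -> np.ndarray:
    """Buckingham traceless quadrupole Θij = ½ Σ q (3 ri rj − r² δij)
    of a point-charge distribution about ``origin``."""
    pos = np.asarray(positions, dtype=float)
    if origin is not None:
        pos = pos - np.asarray(origin, dtype=float)
    q = np.asarray(charges, dtype=float)
    r2 = np.einsum("ij,ij->i", pos, pos)
    theta = 1.5 * np.einsum("i,ij,ik->jk", q, pos, pos)
    theta -= 0.5 * np.sum(q * r2) * np.eye(3)
    return theta


def load_fragment_multipoles(path) -> SourceSpec:
    """Source spec from a YAML multipole parameter file.

    Keys: ``use_charges`` (bool), ``dipole`` (3-list, e·Å, body frame),
    ``quadrupole`` (3×3 nested list, e·Å², traceless symmetric)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    dip = np.asarray(raw["dipole"], dtype=float) if "dipole" in raw else None
    quad = np.asarray(raw["quadrupole"], dtype=float) if "quadrupole" in raw else None
    if quad is not None:
        MultipoleSite(np.zeros(3), quadrupole=quad)  # validates symmetry/trace
    return SourceSpec(
        use_charges=bool(raw.get("use_charges", True)),
        fragment_dipole=dip,
        fragment_quadrupole=quad,
    )


def _water_multipole_sites(frame: Frame, spec: SourceSpec) -> list[MultipoleSite]:
    from scipy.spatial.transform import Rotation

    sites: list[MultipoleSite] = []
    all_sites = frame.water_sites()
    charges = frame.water_model.site_charges
    for w in range(frame.n_waters):
        if spec.use_charges:
            for s in range(5):
                if charges[s] != 0.0:
                    sites.append(MultipoleSite(all_sites[w, s], charge=charges[s]))
        if spec.fragment_dipole is not None or spec.fragment_quadrupole is not None:
            rot = Rotation.from_quat(frame.orientations[w]).as_matrix()
            dip = rot @ spec.fragment_dipole if spec.fragment_dipole is not None else np.zeros(3)
            quad = (
                rot @ spec.fragment_quadrupole @ rot.T
                if spec.fragment_quadrupole is not None
                else np.zeros((3, 3))
            )
            sites.append(MultipoleSite(frame.oxygens[w], dipole=dip, quadrupole=quad))
    return sites


def solvent_field(
    frame: Frame,
    probe: FieldProbe,
    spec: SourceSpec | None = None,
    frame_index: int = 0,
    temperature: float = float("nan"),
) -> FieldSample:
    """Total solvent field at the probe point, with its C2 projection.

    Vector superposition of every selected water site's contribution;
    the solute's own charges are excluded by construction.  A frame with
    zero waters returns a zero field (with a warning).
    """
    spec = spec or SourceSpec()
    if frame.n_waters == 0:
        import warnings

        warnings.warn("frame contains no waters; returning zero field", stacklevel=2)
        return FieldSample(np.zeros(3), 0.0, frame_index, temperature)

    total = np.zeros(3)
    if spec.use_charges:
        # vectorized point-charge sum over all water sites
        sites = frame.water_sites().reshape(-1, 3)
        q = np.tile(frame.water_model.site_charges, frame.n_waters)
        live = q != 0.0
        r = probe.point[None, :] - sites[live]
        d2 = np.einsum("ij,ij->i", r, r)
        if np.any(d2 < 1e-12):
            raise ZeroDivisionError(
                f"water site coincides with probe point in frame {frame_index}"
            )
        total += KE_FIELD * np.einsum("i,ij->j", q[live] / d2**1.5, r)
    if spec.fragment_dipole is not None or spec.fragment_quadrupole is not None:
        frag_spec = SourceSpec(
            use_charges=False,
            fragment_dipole=spec.fragment_dipole,
            fragment_quadrupole=spec.fragment_quadrupole,
        )
        for site in _water_multipole_sites(frame, frag_spec):
            total += field_from_site(site, probe.point)
    return FieldSample(total, float(total @ probe.axis), frame_index, temperature)


def trajectory_fields(
    traj: Trajectory, probe: FieldProbe | None = None, spec: SourceSpec | None = None
) -> list[FieldSample]:
    """Per-frame field samples for a whole trajectory."""
    if probe is None:
        probe = c2_probe(traj.frames[0].solute)
    return [
        solvent_field(f, probe, spec, frame_index=i, temperature=traj.temperature)
        for i, f in enumerate(traj.frames)
    ]
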