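"""Rigid solute geometry: the dimethylphosphate (DMP) anion.

DMP, (CH3O)2PO2−, is the minimal model of the DNA backbone phosphate.
The solute is held completely rigid; only its partial charges and
Lennard-Jones parameters enter the water-solute energy, and its free
PO2 oxygens define the electric-field probe geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = ["SoluteGeometry", "dmp_gauche_gauche", "load_solute"]


@dataclass
class SoluteGeometry:
    """Atom labels, positions (Å), partial charges (e), LJ parameters.

    ``p_index``, ``o1_index``, ``o2_index`` designate the phosphorus and
    the two free phosphate oxygens used by the field probe.
    """

    labels: list[str]
    positions: np.ndarray  # (n, 3) Å
    charges: np.ndarray  # (n,) e
    lj_sigma: np.ndarray  # (n,) Å
    lj_epsilon: np.ndarray  # (n,) kJ/mol
    p_index: int
    o1_index: int
    o2_index: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        idx = {self.p_index, self.o1_index, self.o2_index}
        if len(idx) != 3 or not idx.issubset(range(len(self.labels))):
            raise ValueError("P, O1, O2 must be present and distinct")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def validate_net_charge(self, expected: float = -1.0, tol: float = 1e-6) -> None:
        if abs(self.net_charge - expected) > tol:
            raise ValueError(
                f"solute net charge {self.net_charge:g} e != expected {expected:g} e"
            )


def _place_dihedral(a, b, c, bond, angle_deg, dihedral_deg):
    """Position a fourth atom from three reference atoms and internal
    coordinates (standard natural-extension-of-reference-frame step)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dmp_gauche_gauche(param_path=None) -> SoluteGeometry:
    """Build the gauche-gauche DMP conformer from packaged internal
    coordinates and (stand-in) charges.

    Geometry convention: P at the origin; the free oxygens O1/O2 lie
    symmetrically about the +x axis in the xy-plane, so the C2 symmetry
    axis of the PO2− group is +x and points into the solvent.
    """
    if param_path is None:
        raw = yaml.safe_load(
            resources.files("shellfield.data").joinpath("dmp_gg.yaml").read_text()
        )
    else:
        with open(param_path) as fh:
            raw = yaml.safe_load(fh)
    ic = raw["internal_coordinates"]

    half_free = math.radians(ic["o_p_o_free_angle"]) / 2
    half_ester = math.radians(ic["o_p_o_ester_angle"]) / 2
    p = np.zeros(3)
    o1 = ic["r_po_free"] * np.array([math.cos(half_free), math.sin(half_free), 0.0])
    o2 = ic["r_po_free"] * np.array([math.cos(half_free), -math.sin(half_free), 0.0])
    o3 = ic["r_po_ester"] * np.array(
        [-math.cos(half_ester), 0.0, math.sin(half_ester)]
    )
    o4 = ic["r_po_ester"] * np.array(
        [-math.cos(half_ester), 0.0, -math.sin(half_ester)]
    )
    dih = ic["c_o_p_o_dihedral"]
    c1 = _place_dihedral(o4, p, o3, ic["r_oc"], ic["p_o_c_angle"], dih)
    c2 = _place_dihedral(o3, p, o4, ic["r_oc"], ic["p_o_c_angle"], dih)

    order = ["P", "O1", "O2", "O3", "O4", "C1", "C2"]
    coords = {"P": p, "O1": o1, "O2": o2, "O3": o3, "O4": o4, "C1": c1, "C2": c2}
    atoms = raw["atoms"]
    geom = SoluteGeometry(
        labels=order,
        positions=np.array([coords[k] for k in order]),
        charges=np.array([atoms[k]["charge"] for k in order]),
        lj_sigma=np.array([atoms[k]["sigma"] for k in order]),
        lj_epsilon=np.array([atoms[k]["epsilon"] for k in order]),
        p_index=0,
        o1_index=1,
        o2_index=2,
    )
    geom.validate_net_charge(-1.0)
    return geom


load_solute = dmp_gauche_gauche
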