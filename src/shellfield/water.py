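"""Rigid five-site water molecules (TIP5P-style).

A water molecule is a rigid body: an oxygen position plus a unit
quaternion.  The five interaction sites (O Lennard-Jones center, two
hydrogens, two lone pairs) live at fixed body-frame offsets; world-frame
site positions are obtained by rotating the template and translating.
The oxygen site carries the Lennard-Jones center and zero charge; the
hydrogen and lone-pair sites carry the point charges, so every molecule
is net neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "WaterModel",
    "RigidWater",
    "load_water_model",
    "build_water_sites",
    "random_quaternion",
    "orientation_from_sites",
]

_QUAT_TOL = 1e-9


@dataclass(frozen=True)
class WaterModel:
    """Parameters of a rigid 5-site water model.

    site_offsets: (5, 3) body-frame positions in Å, order O, H1, H2, L1, L2.
    site_charges: (5,) charges in e (oxygen zero).
    sigma, epsilon: O–O Lennard-Jones parameters (Å, kJ/mol).
    """

    name: str
    site_offsets: np.ndarray
    site_charges: np.ndarray
    sigma: float
    epsilon: float

    def __post_init__(self):
        offsets = np.asarray(self.site_offsets, dtype=float)
        charges = np.asarray(self.site_charges, dtype=float)
        if offsets.shape != (5, 3) or charges.shape != (5,):
            raise ValueError("water model requires 5 sites")
        if abs(charges.sum()) > 1e-12:
            raise ValueError(f"water model not neutral: net {charges.sum():g} e")
        object.__setattr__(self, "site_offsets", offsets)
        object.__setattr__(self, "site_charges", charges)


def _tip5p_offsets(r_oh: float, hoh_deg: float, r_ol: float, lol_deg: float) -> np.ndarray:
    """Body-frame template: H's in the +z half of the xz-plane, lone pairs
    in the −z half of the yz-plane (standard TIP5P construction)."""
    ah = math.radians(hoh_deg) / 2.0
    al = math.radians(lol_deg) / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [r_oh * math.sin(ah), 0.0, r_oh * math.cos(ah)],
            [-r_oh * math.sin(ah), 0.0, r_oh * math.cos(ah)],
            [0.0, r_ol * math.sin(al), -r_ol * math.cos(al)],
            [0.0, -r_ol * math.sin(al), -r_ol * math.cos(al)],
        ]
    )


def load_water_model(path=None) -> WaterModel:
    """Load a water model from YAML (packaged TIP5P parameters by default)."""
    if path is None:
        source = resources.files("shellfield.data").joinpath("tip5p.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    geom = raw["geometry"]
    offsets = _tip5p_offsets(
        geom["r_oh"], geom["hoh_angle"], geom["r_ol"], geom["lol_angle"]
    )
    q = raw["charges"]
    charges = np.array([0.0, q["H"], q["H"], q["L"], q["L"]])
    lj = raw["lennard_jones"]
    return WaterModel(raw["name"], offsets, charges, lj["sigma"], lj["epsilon"])


@dataclass
class RigidWater:
    """One rigid water: oxygen position (Å) + orientation quaternion (x,y,z,w)."""

    oxygen_position: np.ndarray
    orientation: np.ndarray
    model: WaterModel

    def __post_init__(self):
        self.oxygen_position = np.asarray(self.oxygen_position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)


def build_water_sites(water: RigidWater) -> list[tuple[np.ndarray, float]]:
    """World-frame (position, charge) pairs for the 5 sites of one water.

    Raises ValueError if the quaternion is not unit-norm within 1e-9.
    """
    q = water.orientation
    norm = float(np.linalg.norm(q))
    if abs(norm - 1.0) > _QUAT_TOL:
        raise ValueError(f"quaternion norm {norm:.12g} deviates from 1 beyond {_QUAT_TOL}")
    rot = Rotation.from_quat(q)
    world = rot.apply(water.model.site_offsets) + water.oxygen_position
    return [(world[i], float(water.model.site_charges[i])) for i in range(5)]


def site_positions(oxygen: np.ndarray, quat: np.ndarray, model: WaterModel) -> np.ndarray:
    """(5, 3) world-frame site positions; vectorized workhorse (no charge pairing)."""
    return Rotation.from_quat(quat).apply(model.site_offsets) + oxygen


def all_site_positions(oxygens: np.ndarray, quats: np.ndarray, model: WaterModel) -> np.ndarray:
    """(N, 5, 3) world-frame site positions for N waters at once."""
    n = len(oxygens)
    if n == 0:
        return np.zeros((0, 5, 3))
    mats = Rotation.from_quat(quats).as_matrix()  # (N, 3, 3)
    return np.einsum("nij,sj->nsi", mats, model.site_offsets) + oxygens[:, None, :]


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion (Shoemake's method)."""
    u1, u2, u3 = rng.random(3)
    a, b = math.sqrt(1 - u1), math.sqrt(u1)
    return np.array(
        [
            a * math.sin(2 * math.pi * u2),
            a * math.cos(2 * math.pi * u2),
            b * math.sin(2 * math.pi * u3),
            b * math.cos(2 * math.pi * u3),
        ]
    )


def orientation_from_sites(
    o_pos: np.ndarray, h1_pos: np.ndarray, h2_pos: np.ndarray, model: WaterModel
) -> np.ndarray:
    """Recover the quaternion of a rigid water from its O, H1, H2 positions.

    Lone pairs are virtual sites fully determined by the three real atoms,
    so trajectory files need only store O/H coordinates.  Uses Kabsch
    alignment of the H offsets onto the body-frame template.
    """
    body = model.site_offsets[1:3]  # template H offsets
    world = np.asarray([h1_pos, h2_pos], dtype=float) - np.asarray(o_pos, dtype=float)
    rot, _ = Rotation.align_vectors(world, body)
    return rot.as_quat()
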