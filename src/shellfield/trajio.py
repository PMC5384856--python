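"""Trajectory reading and writing: multi-frame XYZ, PDB, and HDF5 cache.

Files store only the real atoms (solute heavy atoms; O, H1, H2 per
water).  TIP5P lone pairs are virtual sites fully determined by the
three real atoms, so on read each water's orientation quaternion is
rebuilt by Kabsch alignment of its hydrogens onto the body-frame
template.  Water molecules are identified by the atom-name convention
documented here: in XYZ, the solute block (count taken from the comment
line) is followed by repeated O/H/H triplets; in PDB, waters are HETATM
records with residue name SOL and atom names O, H1, H2.
"""

from __future__ import annotations

import numpy as np

from .sampler import Frame, Trajectory
from .solute import SoluteGeometry, dmp_gauche_gauche
from .water import WaterModel, load_water_model, orientation_from_sites

__all__ = ["FormatError", "read_frames", "write_frames", "save_hdf5", "load_hdf5"]


class FormatError(ValueError):
    """Unparseable trajectory file; message carries the offending line number."""


def _solute_template(solute, positions, labels):
    tmpl = solute if solute is not None else dmp_gauche_gauche()
    if list(labels) != list(tmpl.labels):
        raise FormatError(
            f"solute atom labels {labels} do not match template {tmpl.labels}"
        )
    return SoluteGeometry(
        labels=list(labels),
        positions=np.asarray(positions),
        charges=tmpl.charges,
        lj_sigma=tmpl.lj_sigma,
        lj_epsilon=tmpl.lj_epsilon,
        p_index=tmpl.p_index,
        o1_index=tmpl.o1_index,
        o2_index=tmpl.o2_index,
    )


def _frame_from_atoms(labels, coords, n_solute, solute, model, lineno):
    body = labels[n_solute:]
    if len(body) % 3 != 0:
        raise FormatError(f"water block near line {lineno} is not O/H/H triplets")
    n_w = len(body) // 3
    oxy = np.empty((n_w, 3))
    quat = np.empty((n_w, 4))
    for w in range(n_w):
        trip = body[3 * w : 3 * w + 3]
        if trip[0][0] != "O" or trip[1][0] != "H" or trip[2][0] != "H":
            raise FormatError(
                f"unexpected water atom labels {trip} near line {lineno}"
            )
        o, h1, h2 = coords[n_solute + 3 * w : n_solute + 3 * w + 3]
        oxy[w] = o
        quat[w] = orientation_from_sites(o, h1, h2, model)
    geom = _solute_template(solute, coords[:n_solute], labels[:n_solute])
    return Frame(geom, oxy, quat, model)


# ----------------------------------------------------------------- XYZ


def _write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for idx, frame in enumerate(traj.frames):
            sites = frame.water_sites()
            n_solute = len(frame.solute.labels)
            n_atoms = n_solute + 3 * frame.n_waters
            fh.write(f"{n_atoms}\n")
            fh.write(
                f"shellfield frame={idx} T={traj.temperature:g} n_solute={n_solute}\n"
            )
            for lab, pos in zip(frame.solute.labels, frame.solute.positions):
                fh.write(f"{lab:<4s} {pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}\n")
            for w in range(frame.n_waters):
                for lab, s in zip(("O", "H", "H"), sites[w, :3]):
                    fh.write(f"{lab:<4s} {s[0]:12.6f} {s[1]:12.6f} {s[2]:12.6f}\n")


def _read_xyz(path, solute, model):
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty trajectory file (line 1)")
    frames = []
    temperature = float("nan")
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as err:
            raise FormatError(f"line {i + 1}: expected atom count") from err
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok
        )
        n_solute = int(meta.get("n_solute", 7))
        if "T" in meta:
            temperature = float(meta["T"])
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise FormatError(f"line {i + 1}: truncated frame ({len(block)}/{n_atoms} atoms)")
        labels, coords = [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"line {i + 3 + j}: malformed atom record")
            labels.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError as err:
                raise FormatError(
                    f"line {i + 3 + j}: unparseable coordinates"
                ) from err
        frames.append(
            _frame_from_atoms(labels, np.asarray(coords), n_solute, solute, model, i + 3)
        )
        i += 2 + n_atoms
    return Trajectory(frames=frames, temperature=temperature)


# ----------------------------------------------------------------- PDB


def _write_pdb(traj: Trajectory, path) -> None:
    def record(serial, name, resname, resseq, pos):
        # strict PDB columns: name 13-16, resName 18-20, chain 22, resSeq 23-26
        return (
            f"HETATM{serial % 100000:>5d} {name:<4s} {resname:<3s} A"
            f"{resseq % 10000:>4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00\n"
        )

    with open(path, "w") as fh:
        fh.write(f"REMARK   shellfield trajectory T={traj.temperature:g} K\n")
        for idx, frame in enumerate(traj.frames):
            fh.write(f"MODEL {idx + 1:>8d}\n")
            serial = 1
            for lab, pos in zip(frame.solute.labels, frame.solute.positions):
                fh.write(record(serial, lab, "DMP", 1, pos))
                serial += 1
            sites = frame.water_sites()
            for w in range(frame.n_waters):
                for name, s in zip(("O", "H1", "H2"), sites[w, :3]):
                    fh.write(record(serial, name, "SOL", w + 2, s))
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_pdb(path, solute, model):
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty trajectory file (line 1)")
    temperature = float("nan")
    frames = []
    labels, coords = [], []
    in_model = False
    saw_model = False
    for lineno, line in enumerate(lines, 1):
        rec = line[:6].strip()
        if line.startswith("REMARK") and "T=" in line:
            temperature = float(line.split("T=")[1].split()[0])
        elif rec == "MODEL":
            in_model, saw_model = True, True
            labels, coords = [], []
        elif rec == "ENDMDL":
            if not in_model:
                raise FormatError(f"line {lineno}: ENDMDL without MODEL")
            n_solute = sum(1 for lab, res in labels if res == "DMP")
            names = [lab for lab, _ in labels]
            # normalize water H1/H2 to H for the triplet check
            names = [n if not (n.startswith("H") and labels[i][1] == "SOL") else "H"
                     for i, n in enumerate(names)]
            frames.append(
                _frame_from_atoms(names, np.asarray(coords), n_solute, solute, model, lineno)
            )
            in_model = False
        elif rec in ("ATOM", "HETATM") and in_model:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as err:
                raise FormatError(f"line {lineno}: bad coordinates") from err
            if resname not in ("DMP", "SOL"):
                raise FormatError(f"line {lineno}: unknown residue {resname!r}")
            labels.append((name, resname))
            coords.append(xyz)
    if not saw_model:
        raise FormatError(f"{path}: no MODEL records found")
    counts = {f.n_waters for f in frames}
    if len(counts) > 1:
        raise FormatError(f"{path}: water count varies across frames ({sorted(counts)})")
    return Trajectory(frames=frames, temperature=temperature)


# ----------------------------------------------------------------- API


def write_frames(traj: Trajectory, path, format: str = "xyz") -> None:
    """Write a trajectory as multi-frame XYZ or PDB (real atoms only)."""
    if format == "xyz":
        _write_xyz(traj, path)
    elif format == "pdb":
        _write_pdb(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_frames(
    path,
    format: str = "xyz",
    solute: SoluteGeometry | None = None,
    water_model: WaterModel | None = None,
) -> Trajectory:
    """Read a multi-frame XYZ or PDB trajectory.

    Charges and LJ parameters are not stored in either format; they are
    taken from ``solute``/``water_model`` (packaged DMP + TIP5P defaults).
    """
    model = water_model or load_water_model()
    if format == "xyz":
        return _read_xyz(path, solute, model)
    if format == "pdb":
        return _read_pdb(path, solute, model)
    raise ValueError(f"unknown trajectory format {format!r}")


def save_hdf5(traj: Trajectory, path) -> None:
    """Cache a trajectory (oxygens + quaternions + solute) in HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["temperature"] = traj.temperature
        if traj.seed is not None:
            h5.attrs["seed"] = traj.seed
        h5.create_dataset("energies", data=traj.energies)
        h5.create_dataset("oxygens", data=np.array([f.oxygens for f in traj.frames]))
        h5.create_dataset(
            "orientations", data=np.array([f.orientations for f in traj.frames])
        )
        sol = traj.frames[0].solute
        h5.create_dataset("solute_positions", data=sol.positions)
        h5.attrs["solute_labels"] = ",".join(sol.labels)


def load_hdf5(path, solute: SoluteGeometry | None = None,
              water_model: WaterModel | None = None) -> Trajectory:
    import h5py

    model = water_model or load_water_model()
    with h5py.File(path, "r") as h5:
        labels = h5.attrs["solute_labels"].split(",")
        geom = _solute_template(solute, h5["solute_positions"][...], labels)
        frames = [
            Frame(geom, oxy, quat, model)
            for oxy, quat in zip(h5["oxygens"][...], h5["orientations"][...])
        ]
        return Trajectory(
            frames=frames,
            temperature=float(h5.attrs["temperature"]),
            energies=h5["energies"][...],
            seed=int(h5.attrs["seed"]) if "seed" in h5.attrs else None,
        )
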