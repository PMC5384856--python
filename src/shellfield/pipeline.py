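"""Pipeline orchestration, configuration, and fixture generation.

Ties the stages together: sample hydration shells at a ladder of
temperatures, evaluate projected fields, build field distributions and
radial distributions, map the mean-field change to a Stark shift, and
(independently) simulate and fit kinetic traces and run the dosimetry
calculator.  Every stochastic stage receives an explicit seed derived
from the global seed plus a fixed stage offset, so one config + seed
reproduces the summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distributions, dosimetry, fields, kinetics, sampler, solute, stark, trajio

logger = logging.getLogger("shellfield")

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "make_fixtures",
    "write_trace_csv",
    "read_trace_csv",
]

# stage seed offsets: global seed + offset (+ index within stage)
_SEED_OFFSETS = {"shell": 0, "kinetics": 100, "bootstrap": 200, "fixtures": 300}


@dataclass
class ShellConfig:
    temperatures: list[float] = field(default_factory=lambda: [298.0, 310.0, 320.0, 330.0])
    n_waters: int = 250
    cell_kind: str = "droplet"
    cell_size: float = 14.0
    n_sweeps: int = 200_000
    equilibration_fraction: float = 0.2
    sample_stride: int = 100
    max_translation: float = 0.25
    max_rotation: float = 0.35
    field_bin_width: float = 2.0
    rdf_r_max: float = 8.0
    rdf_bins: int = 80


@dataclass
class StarkConfig:
    tuning_rate: float = 0.4  # cm⁻¹/(MV/cm), symmetric PO2 stretch
    band_center: float = 1087.0  # cm⁻¹
    band_fwhm: float = 20.0
    band_amplitude: float = 1.0


@dataclass
class KineticsConfig:
    form: str = "biphasic_rise"
    tau1: float = 1.1
    tau2: float = 11.0
    a1: float = 1.2
    a2: float = 0.4
    noise_sigma: float = 0.03
    t_min: float = 0.2
    t_max: float = 100.0
    n_delays: int = 80
    n_replicates: int = 20


@dataclass
class DosimetryConfig:
    pulse_energy: float = 1.6  # μJ
    spot_diameter: float = 100.0  # μm
    pump_wavenumber: float = 3450.0  # cm⁻¹
    concentration: float = 44.0  # mol/L
    penetration_depth: float = 2.4  # μm
    convention: str = "absorbed_in_one_depth"
    heat_capacity: float = 75.3  # J/(mol K)


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: ["shell", "kinetics", "dosimetry"])
    seed: int = 0
    outdir: str = "shellfield_out"
    log_level: str = "INFO"
    shell: ShellConfig = field(default_factory=ShellConfig)
    stark: StarkConfig = field(default_factory=StarkConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    dosimetry: DosimetryConfig = field(default_factory=DosimetryConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location and log
        verbosity excluded, so relocated reruns stay comparable)."""
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("outdir", "log_level")}
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(cls, raw: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    return cls(**raw)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML, validating every key."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    nested = {
        "shell": ShellConfig, "stark": StarkConfig,
        "kinetics": KineticsConfig, "dosimetry": DosimetryConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = _build(nested[key], value or {}, key)
        elif key in ("stages", "seed", "outdir", "log_level"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return PipelineConfig(**kwargs)


def demo_config(outdir="shellfield_out", seed=0) -> PipelineConfig:
    """Small-droplet two-temperature demo that completes in minutes."""
    cfg = PipelineConfig(seed=seed, outdir=outdir)
    cfg.shell = ShellConfig(
        temperatures=[298.0, 330.0], n_waters=64, cell_size=9.0,
        n_sweeps=30_000, sample_stride=50,
    )
    cfg.kinetics = KineticsConfig(n_replicates=10)
    return cfg


# --------------------------------------------------------------- trace CSV


def write_trace_csv(trace: kinetics.TransientTrace, path, header_meta: dict | None = None):
    """CSV trace format: '#'-prefixed metadata lines, then delay_ps,dA_mOD."""
    meta = {"probe_frequency_cm1": trace.probe_frequency,
            "noise_sigma_mOD": trace.noise_sigma}
    meta.update(header_meta or {})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("delay_ps,dA_mOD\n")
        for t, a in zip(trace.delays, trace.delta_a):
            fh.write(f"{t:.6g},{a:.6g}\n")


def read_trace_csv(path) -> kinetics.TransientTrace:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            body_start = i
            break
    df = pd.read_csv(path, skiprows=body_start)
    return kinetics.TransientTrace(
        df["delay_ps"].to_numpy(),
        df["dA_mOD"].to_numpy(),
        probe_frequency=float(meta.get("probe_frequency_cm1", "nan")),
        noise_sigma=float(meta.get("noise_sigma_mOD", "0")),
    )


# --------------------------------------------------------------- stages


def _stamp(cfg: PipelineConfig) -> str:
    return f"# shellfield config_hash={cfg.config_hash} seed={cfg.seed}\n"


def _write_csv(path, header_cols, rows, cfg):
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        fh.write(",".join(header_cols) + "\n")
        for row in rows:
            fh.write(",".join(f"{v:.8g}" for v in row) + "\n")


def _run_shell_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    sc = cfg.shell
    dmp = solute.dmp_gauche_gauche()
    cell = sampler.SimulationCell(sc.cell_kind, sc.cell_size)
    probe = fields.c2_probe(dmp)
    dists = []
    summary = {"temperatures": list(sc.temperatures)}
    all_samples = {}
    for i, temp in enumerate(sc.temperatures):
        t0 = time.perf_counter()
        params = sampler.MCParams(
            temperature=temp, n_sweeps=sc.n_sweeps,
            equilibration_fraction=sc.equilibration_fraction,
            max_translation=sc.max_translation, max_rotation=sc.max_rotation,
            seed=cfg.seed + _SEED_OFFSETS["shell"] + i, sample_stride=sc.sample_stride,
        )
        traj = sampler.mc_sample(dmp, sc.n_waters, cell, params)
        samples = fields.trajectory_fields(traj, probe)
        all_samples[temp] = np.array([s.parallel for s in samples])
        logger.info(
            "shell T=%g K: %d frames, acceptance %.2f, %.1f s",
            temp, len(traj), traj.acceptance_fraction,
            time.perf_counter() - t0,
        )
        rdf = distributions.radial_distribution(
            traj, "solute:O1,O2", "water:O", sc.rdf_r_max, sc.rdf_bins, cell
        )
        _write_csv(outdir / f"rdf_T{temp:g}.csv", ["r_angstrom", "g"],
                   zip(rdf.bin_centers, rdf.g), cfg)
        trajio.write_frames(traj, outdir / f"traj_T{temp:g}.xyz", "xyz")

    lo = min(v.min() for v in all_samples.values())
    hi = max(v.max() for v in all_samples.values())
    w = sc.field_bin_width
    edges = np.arange(w * np.floor(lo / w), w * np.ceil(hi / w) + w / 2, w)
    for temp in sc.temperatures:
        d = distributions.field_distribution(all_samples[temp], bin_edges=edges,
                                             temperature=temp)
        dists.append(d)
        _write_csv(outdir / f"fielddist_T{temp:g}.csv",
                   ["E_parallel_MV_cm", "occurrence"],
                   zip(d.bin_centers, d.occurrence), cfg)

    d_lo, d_hi = dists[0], dists[-1]
    diff = distributions.occurrence_difference(d_lo, d_hi)
    _write_csv(outdir / "fielddiff.csv", ["E_parallel_MV_cm", "difference"],
               zip(d_lo.bin_centers, diff.difference), cfg)
    de, de_err = distributions.mean_field_change(
        d_lo, d_hi, seed=cfg.seed + _SEED_OFFSETS["bootstrap"]
    )
    coeff = stark.StarkCoefficient(cfg.stark.tuning_rate, "nu_P2")
    shift = stark.stark_shift(de, coeff)
    band = stark.AbsorptionBand(cfg.stark.band_center, cfg.stark.band_fwhm,
                                cfg.stark.band_amplitude)
    ds = stark.difference_spectrum(band, shift if shift != 0 else 1e-6)
    _write_csv(outdir / "stark_difference_spectrum.csv",
               ["wavenumber_cm1", "dA"], zip(ds.frequencies, ds.delta_a), cfg)
    summary.update(
        mean_field_change_MV_cm=de,
        mean_field_change_stderr=de_err,
        stark_shift_cm1=shift,
        field_std_by_T={f"{t:g}": float(all_samples[t].std(ddof=1)) for t in sc.temperatures},
        occurrence_difference_extrema_separation_MV_cm=diff.extrema_separation,
    )
    return summary


def _run_kinetics_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    kc = cfg.kinetics
    model = kinetics.KineticModel(kc.form)
    delays = kinetics.log_spaced_delays(kc.t_min, kc.t_max, kc.n_delays)
    if kc.form == "mono_decay_offset":
        params = {"amplitude": kc.a1, "tau": kc.tau1, "offset": kc.a2}
    else:
        params = {"a1": kc.a1, "tau1": kc.tau1, "a2": kc.a2, "tau2": kc.tau2}
    taus = []
    for r in range(kc.n_replicates):
        trace = kinetics.simulate_transient(
            model, params, delays, kc.noise_sigma,
            seed=cfg.seed + _SEED_OFFSETS["kinetics"] + r,
        )
        if r == 0:
            write_trace_csv(trace, outdir / "trace_replicate0.csv",
                            {"config_hash": cfg.config_hash, "seed": cfg.seed})
        if kc.form == "mono_decay_offset":
            fit = kinetics.fit_monoexponential(trace)
            taus.append((fit.params["tau"],))
        else:
            fit = kinetics.fit_biphasic(trace, kc.form)
            taus.append((fit.params["tau1"], fit.params["tau2"]))
    arr = np.array(taus)
    out = {"form": kc.form, "n_replicates": kc.n_replicates,
           "tau1_mean_ps": float(arr[:, 0].mean()), "tau1_std_ps": float(arr[:, 0].std(ddof=1))}
    if arr.shape[1] > 1:
        out.update(tau2_mean_ps=float(arr[:, 1].mean()),
                   tau2_std_ps=float(arr[:, 1].std(ddof=1)))
    return out


def _run_dosimetry_stage(cfg: PipelineConfig) -> dict:
    dc = cfg.dosimetry
    geom = dosimetry.ExcitationGeometry(
        dc.pulse_energy, dc.spot_diameter, dc.pump_wavenumber,
        dc.concentration, dc.penetration_depth, dc.convention,
    )
    e_j, e_kjmol = dosimetry.photon_energy(dc.pump_wavenumber)
    frac = dosimetry.excited_fraction(geom)
    dt = dosimetry.temperature_jump(frac, dc.pump_wavenumber, dc.heat_capacity)
    return {
        "photon_energy_J": e_j, "photon_energy_kJ_mol": e_kjmol,
        "excited_fraction": frac, "temperature_jump_K": dt,
        "convention": dc.convention,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; write artifacts and summary.json.

    Identical config and seed give an identical summary.  A stage
    failure aborts with the stage name in the log and the exception.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    runners = {"shell": lambda: _run_shell_stage(cfg, outdir),
               "kinetics": lambda: _run_kinetics_stage(cfg, outdir),
               "dosimetry": lambda: _run_dosimetry_stage(cfg)}
    unknown = [s for s in cfg.stages if s not in runners]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    for stage in cfg.stages:
        t0 = time.perf_counter()
        try:
            report[stage] = runners[stage]()
        except Exception:
            logger.error("stage %r failed (config %s, seed %d)",
                         stage, cfg.config_hash, cfg.seed)
            raise
        logger.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# --------------------------------------------------------------- fixtures


def make_fixtures(seed: int = 0, outdir="fixtures") -> list[Path]:
    """Write the small test fixtures used across the suite.

    Regenerating with the same seed gives identical files; every fixture
    parses through the corresponding reader.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    rng_seed = seed + _SEED_OFFSETS["fixtures"]

    # 3-water frame around DMP, as XYZ and PDB
    dmp = solute.dmp_gauche_gauche()
    cell = sampler.SimulationCell("droplet", 6.0)
    params = sampler.MCParams(temperature=298.0, n_sweeps=200,
                              equilibration_fraction=0.5, seed=rng_seed,
                              sample_stride=100)
    traj = sampler.mc_sample(dmp, 3, cell, params)
    for fmt in ("xyz", "pdb"):
        path = out / f"three_waters.{fmt}"
        trajio.write_frames(traj, path, fmt)
        written.append(path)

    # toy multipole parameter file (water-like dipole, traceless quadrupole)
    multipole = {
        "use_charges": False,
        "dipole": [0.0, 0.0, 0.48],
        "quadrupole": [[0.4, 0.0, 0.0], [0.0, -0.3, 0.0], [0.0, 0.0, -0.1]],
    }
    path = out / "toy_multipoles.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(multipole, fh)
    written.append(path)

    # synthetic transient traces at the published kinetic constants
    delays = kinetics.log_spaced_delays()
    specs = {
        "solution_biphasic.csv": ("biphasic_rise",
                                  {"a1": 1.2, "tau1": 1.1, "a2": 0.4, "tau2": 11.0}),
        "film_biphasic.csv": ("biphasic_rise",
                              {"a1": 1.2, "tau1": 1.0, "a2": 0.4, "tau2": 17.0}),
        "water_decay.csv": ("decay_plus_rise",
                            {"a1": 1.5, "tau1": 1.1, "a2": 0.0, "tau2": 10.0}),
    }
    for i, (name, (form, pars)) in enumerate(specs.items()):
        trace = kinetics.simulate_transient(
            kinetics.KineticModel(form), pars, delays, 0.03, seed=rng_seed + 1 + i
        )
        path = out / name
        write_trace_csv(trace, path, {"model": form, "seed": rng_seed + 1 + i,
                                      **{k: v for k, v in pars.items()}})
        written.append(path)

    # harmonic-well MC parameters for sampler verification
    path = out / "harmonic_well.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump({"spring_constant_kJ_mol_A2": 5.0, "temperature_K": 298.0,
                        "n_steps": 100_000, "seed": rng_seed}, fh)
    written.append(path)
    return written
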