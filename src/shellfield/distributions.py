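"""Shell structure and field statistics.

Radial distribution functions between solute atoms and water oxygens,
temperature-resolved histograms of the projected field amplitude, their
occurrence differences, and the mean-field change between temperatures
with a bootstrap standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import FieldSample
from .sampler import SimulationCell, Trajectory

__all__ = [
    "RadialDistribution",
    "FieldDistribution",
    "OccurrenceDifference",
    "radial_distribution",
    "field_distribution",
    "occurrence_difference",
    "mean_field_change",
    "first_shell_occupancy",
]


@dataclass
class RadialDistribution:
    bin_centers: np.ndarray  # Å
    g: np.ndarray
    counts: np.ndarray  # raw pair counts per bin
    reference: str
    target: str
    n_frames: int

    def first_minimum(self, r_min: float = 2.0) -> float:
        """Location of the first local minimum of g(r) beyond ``r_min`` Å."""
        mask = self.bin_centers > r_min
        idx = np.where(mask)[0]
        g = self.g
        for i in idx[1:-1]:
            if g[i] <= g[i - 1] and g[i] <= g[i + 1] and g[i - 1] > 0:
                return float(self.bin_centers[i])
        raise ValueError("no interior minimum found in g(r)")


@dataclass
class FieldDistribution:
    bin_edges: np.ndarray  # MV/cm
    occurrence: np.ndarray  # normalized, sums to 1
    temperature: float  # K
    n_samples: int
    mean: float  # bin-free arithmetic mean, MV/cm
    std: float  # bin-free standard deviation, MV/cm
    samples: np.ndarray | None = None  # retained for bootstrap resampling

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class OccurrenceDifference:
    bin_edges: np.ndarray
    difference: np.ndarray  # d2 − d1 per bin
    temperature_low: float
    temperature_high: float
    max_location: float  # MV/cm, bin center of the positive extremum
    min_location: float
    extrema_separation: float  # |max_location − min_location|, MV/cm


def _select(frame, selection: str) -> np.ndarray:
    """Atom selection mini-language: 'water:O' (water oxygens) or
    'solute:LBL1,LBL2' (named solute atoms)."""
    kind, _, names = selection.partition(":")
    if kind == "water":
        if names not in ("", "O"):
            raise ValueError(f"unsupported water selection {names!r}")
        return frame.oxygens
    if kind == "solute":
        labels = names.split(",") if names else frame.solute.labels
        missing = [n for n in labels if n not in frame.solute.labels]
        if missing:
            raise ValueError(f"unknown solute atom labels {missing}")
        idx = [frame.solute.labels.index(n) for n in labels]
        return frame.solute.positions[idx]
    raise ValueError(f"selection must start with 'water:' or 'solute:': {selection!r}")


def radial_distribution(
    traj: Trajectory,
    reference: str,
    target: str,
    r_max: float,
    n_bins: int,
    cell: SimulationCell | None = None,
) -> RadialDistribution:
    """Shell-volume-normalized pair distribution g(r), frame-averaged.

    The target number density is the mean target count per frame divided
    by the analysis volume (``cell.volume`` if given, else the sphere of
    radius ``r_max``).  For a periodic cell, ``r_max`` must not exceed
    half the edge.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if cell is not None and cell.kind == "cubic" and r_max > cell.size / 2:
        raise ValueError("r_max exceeds half the periodic box edge")
    if not traj.frames:
        raise ValueError("empty trajectory")

    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    n_ref_total = 0
    n_target_total = 0
    for frame in traj.frames:
        ref = _select(frame, reference)
        tgt = _select(frame, target)
        if len(ref) == 0 or len(tgt) == 0:
            raise ValueError("empty selection")
        d = np.linalg.norm(tgt[None, :, :] - ref[:, None, :], axis=-1).ravel()
        d = d[d > 1e-9]  # drop self-pairs when selections overlap
        counts += np.histogram(d, bins=edges)[0]
        n_ref_total += len(ref)
        n_target_total += len(tgt)

    n_frames = len(traj.frames)
    volume = cell.volume if cell is not None else 4.0 / 3.0 * np.pi * r_max**3
    rho = (n_target_total / n_frames) / volume
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = rho * shell_vol * n_ref_total
    g = np.divide(counts, norm, out=np.zeros_like(counts), where=norm > 0)
    return RadialDistribution(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        g=g,
        counts=counts,
        reference=reference,
        target=target,
        n_frames=n_frames,
    )


def first_shell_occupancy(rdf: RadialDistribution, r_cut: float) -> float:
    """Mean pair count per frame within ``r_cut`` Å (the integral of the
    pair histogram up to, typically, the first g(r) minimum)."""
    mask = rdf.bin_centers <= r_cut
    return float(rdf.counts[mask].sum() / rdf.n_frames)


def field_distribution(
    samples: list[FieldSample] | np.ndarray,
    bin_edges: np.ndarray | None = None,
    bin_width: float = 2.0,
    temperature: float | None = None,
) -> FieldDistribution:
    """Normalized histogram of the projected field amplitude E∥.

    ``samples`` may be FieldSample objects (which must share one
    temperature label) or a bare array of E∥ values with ``temperature``
    given.  Default bin width 2 MV/cm; pass explicit ``bin_edges`` to put
    several temperatures on one grid.
    """
    if isinstance(samples, (list, tuple)) and samples and isinstance(samples[0], FieldSample):
        temps = {s.temperature for s in samples if not np.isnan(s.temperature)}
        if len(temps) > 1:
            raise ValueError(f"samples mix temperatures {sorted(temps)}")
        if temperature is None:
            temperature = temps.pop() if temps else float("nan")
        values = np.array([s.parallel for s in samples], dtype=float)
    else:
        values = np.asarray(samples, dtype=float)
        if temperature is None:
            temperature = float("nan")
    if values.size == 0:
        raise ValueError("need at least one field sample")
    if bin_edges is None:
        lo = bin_width * np.floor(values.min() / bin_width)
        hi = bin_width * np.ceil(values.max() / bin_width)
        if hi <= lo:
            hi = lo + bin_width
        bin_edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    hist = np.histogram(values, bins=bin_edges)[0].astype(float)
    total = hist.sum()
    if total == 0:
        raise ValueError("all samples fall outside the supplied bin edges")
    return FieldDistribution(
        bin_edges=np.asarray(bin_edges, dtype=float),
        occurrence=hist / total,
        temperature=float(temperature),
        n_samples=values.size,
        mean=float(values.mean()),
        std=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        samples=values,
    )


def occurrence_difference(
    d1: FieldDistribution, d2: FieldDistribution
) -> OccurrenceDifference:
    """Per-bin occurrence difference d2 − d1 on a shared grid.

    Both inputs must be normalized on identical bin edges (no silent
    rebinning), so the differences sum to zero exactly.  The locations of
    the positive and negative extrema and their separation are reported.
    """
    if d1.bin_edges.shape != d2.bin_edges.shape or not np.allclose(
        d1.bin_edges, d2.bin_edges, atol=1e-12
    ):
        raise ValueError("bin grids differ; rebin explicitly before differencing")
    diff = d2.occurrence - d1.occurrence
    centers = d1.bin_centers
    i_max = int(np.argmax(diff))
    i_min = int(np.argmin(diff))
    return OccurrenceDifference(
        bin_edges=d1.bin_edges.copy(),
        difference=diff,
        temperature_low=d1.temperature,
        temperature_high=d2.temperature,
        max_location=float(centers[i_max]),
        min_location=float(centers[i_min]),
        extrema_separation=float(abs(centers[i_max] - centers[i_min])),
    )


def mean_field_change(
    d1: FieldDistribution,
    d2: FieldDistribution,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Signed change of the mean projected field, mean(d2) − mean(d1),
    with a seeded bootstrap standard error (MV/cm).

    Antisymmetric under argument swap.  Uses the retained raw samples
    when available (bin-free means); falls back to histogram means."""
    delta = d2.mean - d1.mean
    if d1.samples is None or d2.samples is None:
        return delta, float("nan")
    rng = np.random.Generator(np.random.PCG64(seed))
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        m1 = rng.choice(d1.samples, size=d1.samples.size, replace=True).mean()
        m2 = rng.choice(d2.samples, size=d2.samples.size, replace=True).mean()
        reps[b] = m2 - m1
    return float(delta), float(reps.std(ddof=1))
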