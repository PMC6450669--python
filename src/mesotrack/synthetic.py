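"""Synthetic trajectories, pairs, masks and filopodia with known truth.

The generators emulate the study design the analysis targets: two
mesoderm populations sampled every 20 minutes for ~150 minutes, one
directional-but-meandering (embryonic: faster, persistent headings) and
one tortuous (extra-embryonic: slower, little heading persistence);
division-generated daughter pairs with correlated headings; ellipsoidal
cell masks on anisotropic voxel grids; and filopodia polylines with
Poisson counts.  Every generator is a pure function of its seed.

The motion model is a persistent random walk on the unit sphere: each
step's heading is drawn from a von Mises–Fisher distribution centred on
the previous heading with concentration ``kappa`` (kappa = 0 is an
uncorrelated random walk, large kappa a near-straight line), and step
lengths are speed × dt with lognormal speeds of given mean and CV.
This is a test fixture spanning the two observed regimes, not a
mechanistic claim about mesoderm motility.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model import (
    CellPairRecord,
    FilopodiumTrace,
    LabeledCellMask,
    PairClass,
    Region,
    TrackDataset,
    Trajectory,
    ValidationError,
)

__all__ = [
    "WalkParams",
    "PopulationSpec",
    "SimulatedPopulation",
    "EMBRYONIC_PARAMS",
    "EXTRA_EMBRYONIC_PARAMS",
    "DEFAULT_POPULATION",
    "simulate_prw",
    "simulate_population",
    "simulate_daughter_pair",
    "rasterize_ellipsoid",
    "generate_filopodia",
    "add_drift",
]


@dataclasses.dataclass(frozen=True)
class WalkParams:
    """Parameters of one persistent-random-walk population.

    speed_mean is the mean instantaneous speed in µm/min, speed_cv the
    coefficient of variation of the lognormal step speeds, kappa the
    von Mises–Fisher concentration of each heading about the previous
    one (µm/min, dimensionless, and dimensionless respectively).
    """

    n_steps: int = 8
    dt: float = 20.0
    speed_mean: float = 0.5
    speed_cv: float = 0.3
    kappa: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.speed_mean <= 0:
            raise ValidationError("speed_mean must be positive")
        if self.speed_cv < 0:
            raise ValidationError("speed_cv must be non-negative")
        if self.kappa < 0:
            raise ValidationError("kappa must be non-negative")


#: Conditions mirroring the two tracked cohorts: 8 steps of 20 min
#: (~160 min of track), embryonic cells at 0.67 µm/min with persistent
#: headings, extra-embryonic cells at 0.44 µm/min with nearly
#: uncorrelated headings.
EMBRYONIC_PARAMS = WalkParams(n_steps=8, dt=20.0, speed_mean=0.67,
                              speed_cv=0.3, kappa=5.0)
EXTRA_EMBRYONIC_PARAMS = WalkParams(n_steps=8, dt=20.0, speed_mean=0.44,
                                    speed_cv=0.3, kappa=0.3)


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """Cohort layout: per-region walk parameters and cell counts."""

    region_params: dict[Region, WalkParams] = dataclasses.field(
        default_factory=lambda: {
            Region.EMBRYONIC: EMBRYONIC_PARAMS,
            Region.EXTRA_EMBRYONIC: EXTRA_EMBRYONIC_PARAMS,
        }
    )
    n_cells: dict[Region, int] = dataclasses.field(
        default_factory=lambda: {Region.EMBRYONIC: 34, Region.EXTRA_EMBRYONIC: 17}
    )
    division_rate: float = 0.0  # fraction of cells generated as daughter pairs
    pair_jitter: float = 50.0
    drift_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        for region, n in self.n_cells.items():
            if n < 1:
                raise ValidationError(f"n_cells[{region}] must be >= 1")
            if region not in self.region_params:
                raise ValidationError(f"no WalkParams for region {region}")
        if not 0.0 <= self.division_rate <= 1.0:
            raise ValidationError("division_rate must be in [0, 1]")
        if self.pair_jitter < 0:
            raise ValidationError("pair_jitter must be non-negative")


DEFAULT_POPULATION = PopulationSpec()


@dataclasses.dataclass
class SimulatedPopulation:
    """A simulated cohort: dataset, per-cell ground truth, daughter pairs."""

    dataset: TrackDataset
    truth: pd.DataFrame
    pairs: list[CellPairRecord]


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One draw from the von Mises–Fisher distribution on S² (Wood 1994)."""
    if kappa < 1e-9:
        return _random_unit_vector(rng)
    u = rng.uniform()
    # marginal of the cosine of the angle to mu
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = float(np.clip(w, -1.0, 1.0))
    # orthonormal basis perpendicular to mu
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mu[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _lognormal_speeds(mean: float, cv: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    if cv == 0.0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _walk(params: WalkParams, rng: np.random.Generator,
          start: np.ndarray, heading: np.ndarray,
          base_headings: np.ndarray | None = None,
          pair_jitter: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Positions (n_steps+1, 3) and times of one walk.

    When ``base_headings`` is given each step's heading is a vMF draw
    around the shared base heading with concentration ``pair_jitter``
    (daughter-pair mode); otherwise the heading evolves as a vMF chain
    with concentration ``params.kappa``.
    """
    n = params.n_steps
    speeds = _lognormal_speeds(params.speed_mean, params.speed_cv, n, rng)
    pos = np.empty((n + 1, 3))
    pos[0] = start
    h = heading.copy()
    for k in range(n):
        if base_headings is not None:
            h = _sample_vmf(base_headings[k], pair_jitter or 0.0, rng)
        else:
            h = _sample_vmf(h, params.kappa, rng)
        pos[k + 1] = pos[k] + h * speeds[k] * params.dt
    times = np.arange(n + 1, dtype=float) * params.dt
    return pos, times


def simulate_prw(
    params: WalkParams,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell",
    embryo_id: str = "sim",
    region: Region = Region.UNASSIGNED,
    start: np.ndarray | None = None,
) -> Trajectory:
    """Simulate one persistent-random-walk trajectory."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    start = np.zeros(3) if start is None else np.asarray(start, dtype=float)
    heading = _random_unit_vector(rng)
    pos, times = _walk(params, rng, start, heading)
    return Trajectory(embryo_id, cell_id, region, times, pos)


def simulate_daughter_pair(
    params: WalkParams,
    pair_jitter: float,
    rng: np.random.Generator | None = None,
    pair_id: str = "pair",
    embryo_id: str = "sim",
    region: Region = Region.EMBRYONIC,
    start: np.ndarray | None = None,
) -> CellPairRecord:
    """Two walks sharing a start point and a common base heading chain.

    The base heading evolves with the population's kappa; each
    daughter's realized step heading is an additional vMF draw around
    the base with concentration ``pair_jitter``, so large jitter values
    give near-parallel trajectories.
    """
    if pair_jitter < 0:
        raise ValidationError("pair_jitter must be non-negative")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    start = np.zeros(3) if start is None else np.asarray(start, dtype=float)
    base = np.empty((params.n_steps, 3))
    h = _random_unit_vector(rng)
    for k in range(params.n_steps):
        h = _sample_vmf(h, params.kappa, rng)
        base[k] = h
    trajs = []
    for suffix in ("a", "b"):
        pos, times = _walk(params, rng, start, base[0],
                           base_headings=base, pair_jitter=pair_jitter)
        trajs.append(Trajectory(embryo_id, f"{pair_id}_{suffix}", region, times, pos))
    return CellPairRecord(
        pair_id=pair_id, a=trajs[0], b=trajs[1],
        pair_class=PairClass.DAUGHTER,
        window=(0.0, params.n_steps * params.dt),
    )


def simulate_population(spec: PopulationSpec = DEFAULT_POPULATION,
                        rng: np.random.Generator | None = None,
                        ) -> SimulatedPopulation:
    """Simulate a two-region cohort with ground truth.

    A fraction ``division_rate`` of each region's cells is generated as
    daughter pairs (both siblings enter the dataset and the pair list).
    The reference track is stationary at the origin plus the constant
    ``drift_velocity``; the same drift is added to every cell so drift
    correction can be exercised end to end.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    trajectories: list[Trajectory] = []
    pairs: list[CellPairRecord] = []
    truth_rows = []
    max_steps = 0
    for region in sorted(spec.n_cells, key=lambda r: r.value):
        params = spec.region_params[region]
        max_steps = max(max_steps, params.n_steps)
        n = spec.n_cells[region]
        n_pairs = int(round(spec.division_rate * n / 2.0))
        n_singles = n - 2 * n_pairs
        idx = 0
        for _ in range(n_pairs):
            pid = f"{region.value}_pair{idx:03d}"
            start = rng.uniform(-50.0, 50.0, size=3)
            rec = simulate_daughter_pair(
                params, spec.pair_jitter, rng=rng, pair_id=pid,
                embryo_id="sim", region=region, start=start,
            )
            trajectories.extend([rec.a, rec.b])
            pairs.append(rec)
            for tr in (rec.a, rec.b):
                truth_rows.append((tr.cell_id, region.value, params.speed_mean,
                                   params.speed_cv, params.kappa, pid))
            idx += 1
        for j in range(n_singles):
            cid = f"{region.value}_{j:03d}"
            start = rng.uniform(-50.0, 50.0, size=3)
            tr = simulate_prw(params, rng=rng, cell_id=cid,
                              embryo_id="sim", region=region, start=start)
            trajectories.append(tr)
            truth_rows.append((cid, region.value, params.speed_mean,
                               params.speed_cv, params.kappa, ""))
    dt = spec.region_params[next(iter(spec.region_params))].dt
    times = np.arange(max_steps + 1, dtype=float) * dt
    drift = np.outer(times, np.asarray(spec.drift_velocity, dtype=float))
    reference = Trajectory("sim", "__reference__", Region.UNASSIGNED,
                           times, np.zeros((times.size, 3)) + drift)
    if np.any(np.asarray(spec.drift_velocity) != 0.0):
        drifted = []
        for tr in trajectories:
            idx = np.searchsorted(times, tr.times)
            drifted.append(Trajectory(tr.embryo_id, tr.cell_id, tr.region,
                                      tr.times, tr.positions + drift[idx]))
        trajectories = drifted
    truth = pd.DataFrame(
        truth_rows,
        columns=["cell_id", "region", "speed_mean", "speed_cv", "kappa", "pair_id"],
    ).sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    dataset = TrackDataset(trajectories=trajectories, reference=reference,
                           frame_interval=dt)
    return SimulatedPopulation(dataset=dataset, truth=truth, pairs=pairs)


def rasterize_ellipsoid(
    semi_axes: tuple[float, float, float],
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    rotation: np.ndarray | None = None,
    cell_id: str = "1",
    margin_voxels: int = 2,
) -> LabeledCellMask:
    """Boolean occupancy of an ellipsoid sampled at voxel centres.

    ``semi_axes`` are the (x, y, z) semi-axis lengths in µm;
    ``rotation`` an optional 3×3 matrix applied to the ellipsoid (acting
    on (x, y, z) vectors).  The grid is sized to contain the rotated
    ellipsoid with a small margin; voxel centres sit at (i + ½)·h so no
    sample falls exactly on the ellipsoid centre or, for semi-axes that
    are voxel multiples, exactly on the boundary (the standard
    pixel-centre convention, which halves tip-pixel moment bias).
    """
    a = np.asarray(semi_axes, dtype=float)
    if np.any(a <= 0):
        raise ValidationError("semi-axes must be positive")
    if any(v <= 0 for v in voxel_size):
        raise ValidationError("voxel_size components must be positive")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    r_max = float(a.max())
    vz, vy, vx = voxel_size
    half = (
        int(np.ceil(r_max / vz)) + margin_voxels,
        int(np.ceil(r_max / vy)) + margin_voxels,
        int(np.ceil(r_max / vx)) + margin_voxels,
    )
    zc = (np.arange(-half[0], half[0]) + 0.5) * vz
    yc = (np.arange(-half[1], half[1]) + 0.5) * vy
    xc = (np.arange(-half[2], half[2]) + 0.5) * vx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    # rotate world coords back into the ellipsoid frame (x, y, z order)
    pts = np.stack([X, Y, Z], axis=-1)
    local = pts @ R  # R^T applied to each row vector
    occ = ((local[..., 0] / a[0]) ** 2
           + (local[..., 1] / a[1]) ** 2
           + (local[..., 2] / a[2]) ** 2) <= 1.0
    if not occ.any():
        raise ValidationError("ellipsoid smaller than one voxel at this grid")
    return LabeledCellMask(occupancy=occ, voxel_size=voxel_size, cell_id=cell_id)


def generate_filopodia(
    n_cells: int,
    count_mean: float,
    length_mean: float,
    seed: int | None = None,
    n_timepoints: int = 1,
    length_cv: float = 0.3,
    n_vertices: int = 2,
    target_probs: dict[str, float] | None = None,
) -> tuple[list[FilopodiumTrace], pd.DataFrame]:
    """Poisson filopodium counts per cell per timepoint, with polylines
    of controlled arc length.

    Each filopodium is a polyline whose segment directions are random
    but whose total arc length is drawn lognormally with mean
    ``length_mean`` and CV ``length_cv`` (a CV of 0 gives exact
    lengths).  Returns the traces and a ground-truth table of per-cell
    counts.
    """
    if n_cells < 1 or count_mean < 0 or length_mean <= 0 or n_timepoints < 1:
        raise ValidationError("invalid filopodia generator parameters")
    if n_vertices < 2 or length_cv < 0:
        raise ValidationError("invalid filopodia generator parameters")
    rng = np.random.default_rng(seed)
    targets = list(target_probs) if target_probs else [None]
    probs = (np.array([target_probs[t] for t in target_probs])
             if target_probs else None)
    traces: list[FilopodiumTrace] = []
    truth_rows = []
    for c in range(n_cells):
        cell = f"cell{c:04d}"
        total = 0
        for ti in range(n_timepoints):
            t = 20.0 * ti
            k = int(rng.poisson(count_mean))
            total += k
            for f in range(k):
                length = float(_lognormal_speeds(length_mean, length_cv, 1, rng)[0])
                segs = rng.normal(size=(n_vertices - 1, 2))
                seg_len = np.linalg.norm(segs, axis=1, keepdims=True)
                segs = segs / seg_len  # unit directions
                frac = rng.dirichlet(np.ones(n_vertices - 1))
                segs = segs * (frac[:, None] * length)
                verts = np.vstack([np.zeros((1, 2)), np.cumsum(segs, axis=0)])
                verts += rng.uniform(-20.0, 20.0, size=2)
                target = (targets[rng.choice(len(targets), p=probs)]
                          if target_probs else None)
                traces.append(FilopodiumTrace(
                    cell_id=cell, t=t, vertices=verts,
                    target=target, filopodium_id=f"f{f:03d}",
                ))
        truth_rows.append((cell, n_timepoints, total / n_timepoints))
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "n_timepoints", "true_mean_count"]
    )
    return traces, truth


def add_drift(dataset: TrackDataset, velocity: tuple[float, float, float],
              ) -> TrackDataset:
    """Add a constant drift (µm/min) to every trajectory and the reference."""
    v = np.asarray(velocity, dtype=float)

    def shift(tr: Trajectory) -> Trajectory:
        offs = np.outer(tr.times - tr.times[0], v)
        return Trajectory(tr.embryo_id, tr.cell_id, tr.region,
                          tr.times.copy(), tr.positions + offs)

    return TrackDataset(
        trajectories=[shift(tr) for tr in dataset.trajectories],
        reference=None if dataset.reference is None else shift(dataset.reference),
        frame_interval=dataset.frame_interval,
        voxel_size=dataset.voxel_size,
    )
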