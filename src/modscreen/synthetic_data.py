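"""Synthetic assay data with the statistical structure each stage assumes.

Each generator emulates one published assay design at its stated scale:

* countercurrent runs — 3 replicate groups of ~20 flies, 5 climb trials;
* arena trajectories — 10 min at 30 fps in a circular chamber, either
  wall-following (periphery-hugging angular walk) or "tremor" (jittery,
  center-biased walk);
* heat-induced seizures — 3 groups of 30 flies, scored every 5 s for 2 min,
  exponential onset hazard, no remission;
* bang-sensitivity recovery — log-normal recovery times, right-censored at
  the observation horizon;
* penetrance/viability tables — binomial affected counts;
* RNA-seq counts — negative-binomial gene x sample matrices with
  sample-specific size factors and spiked log2 fold changes, including by
  default one gene knocked down two-fold in the mutant condition (the
  GstS1-like signature).

Everything is deterministic given (seed, parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countercurrent import ClimbModel, TubeCounts, simulate_countercurrent
from .locomotion import DEFAULT_INNER_RATIO, ChamberGeometry, Trajectory
from .phenotype_tables import PhenotypeRecord, ViabilityRecord
from .seizure_recovery import BIN_SECONDS, N_BINS, RecoveryTimes, SeizureTimeCourse

__all__ = [
    "SimulationConfig",
    "gen_countercurrent",
    "gen_trajectory",
    "gen_trajectories",
    "simulate_positions",
    "simulate_center_occupancy",
    "default_geometry",
    "gen_seizure",
    "gen_recovery",
    "gen_phenotypes",
    "gen_viability",
    "gen_counts",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of per-generator parameter blocks plus the master seed.

    The defaults are the assay designs the analysis expects: group sizes,
    recording lengths and replicate structure as used in the screen.
    """

    seed: int = 0
    climb_p: float = 0.5
    climb_replicates: int = 3
    climb_flies: int = 20
    trajectory_mode: str = "wall"
    seizure_hazard_per_s: float = 0.02
    seizure_replicates: int = 3
    seizure_flies: int = 30
    recovery_log_mean: float = math.log(60.0)
    recovery_log_sd: float = 0.6
    recovery_n: int = 20
    recovery_horizon_s: float = 600.0
    penetrance: dict = field(default_factory=lambda: {"wings": 0.886, "thorax": 0.909})
    phenotype_n: int = 44
    counts_genes: int = 2000
    counts_reps: int = 4
    counts_dispersion: float = 0.05
    counts_spikes: dict = field(default_factory=lambda: {"GstS1_like": -1.0})

    def __post_init__(self) -> None:
        if not 0 <= self.climb_p <= 1:
            raise ValueError("climb_p must lie in [0, 1]")
        if self.seizure_hazard_per_s < 0:
            raise ValueError("hazard must be >= 0")
        if self.recovery_log_sd <= 0:
            raise ValueError("recovery_log_sd must be > 0")
        if self.counts_dispersion <= 0:
            raise ValueError("counts_dispersion must be > 0")
        if any(not 0 <= v <= 1 for v in self.penetrance.values()):
            raise ValueError("penetrances must lie in [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Countercurrent
# ---------------------------------------------------------------------------

def gen_countercurrent(
    p: float,
    *,
    n_replicates: int = 3,
    n_flies: int = 20,
    trials: int = 5,
    group_label: str = "",
    seed=None,
) -> list[TubeCounts]:
    """Replicate countercurrent runs at per-trial climb probability ``p``."""
    rng = _rng(seed)
    model = ClimbModel(p=p, trials=trials, n_flies=n_flies)
    return [
        simulate_countercurrent(model, rng, group_label=group_label)
        for _ in range(n_replicates)
    ]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

DEFAULT_RADIUS_PX = 100.0
WALL_RADIUS_FRAC = 0.9
WALL_RADIUS_SD_FRAC = 0.02
WALL_ANGLE_STEP_SD = 0.12  # radians per frame
TREMOR_MEAN_REVERSION = 0.05  # per-frame pull toward the center
TREMOR_STEP_SD_FRAC = 0.10  # per-axis step SD as a fraction of R


def default_geometry(radius: float = DEFAULT_RADIUS_PX) -> ChamberGeometry:
    return ChamberGeometry(xc=0.0, yc=0.0, radius=radius, inner_ratio=DEFAULT_INNER_RATIO)


def simulate_positions(
    mode: str,
    n_flies: int,
    n_frames: int,
    *,
    radius: float = DEFAULT_RADIUS_PX,
    mixture_weight: float = 0.5,
    seed=None,
) -> np.ndarray:
    """(n_flies, n_frames, 2) positions in an arena centered at the origin.

    ``wall``: angular random walk at radial distance ~ N(0.9 R, 0.02 R),
    clipped inside the arena — the periphery-hugging pattern of coordinated
    flies.  ``tremor``: a mean-reverting Gaussian jitter about the center
    (reflected at the arena wall) whose stationary spread keeps the fly
    inside the 0.743 R disc most of the time.  ``mixture``: each fly is a
    tremor walker with probability ``mixture_weight``, else a wall-follower.
    """
    rng = _rng(seed)
    if mode == "mixture":
        is_tremor = rng.random(n_flies) < mixture_weight
        out = np.empty((n_flies, n_frames, 2))
        for sub_mode, mask in (("tremor", is_tremor), ("wall", ~is_tremor)):
            if mask.any():
                out[mask] = simulate_positions(
                    sub_mode, int(mask.sum()), n_frames, radius=radius, seed=rng
                )
        return out
    if mode == "wall":
        r = rng.normal(WALL_RADIUS_FRAC * radius, WALL_RADIUS_SD_FRAC * radius, (n_flies, n_frames))
        r = np.clip(r, 0.0, radius * 0.999)
        theta0 = rng.uniform(0, 2 * np.pi, (n_flies, 1))
        steps = rng.normal(0.0, WALL_ANGLE_STEP_SD, (n_flies, n_frames))
        theta = theta0 + np.cumsum(steps, axis=1)
        return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)
    if mode == "tremor":
        pos = np.zeros((n_flies, 2))
        out = np.empty((n_flies, n_frames, 2))
        step_sd = TREMOR_STEP_SD_FRAC * radius
        theta = TREMOR_MEAN_REVERSION
        limit = radius * 0.999
        for t in range(n_frames):
            pos = (1.0 - theta) * pos + rng.normal(0.0, step_sd, (n_flies, 2))
            # reflect flies that stepped outside the arena back inside
            dist = np.hypot(pos[:, 0], pos[:, 1])
            outside = dist > limit
            if outside.any():
                scale = (2.0 * limit - dist[outside]) / dist[outside]
                pos[outside] *= scale[:, None]
            out[:, t, :] = pos
        return out
    raise ValueError(f"unknown trajectory mode {mode!r}")


def simulate_center_occupancy(
    mode: str,
    n_flies: int,
    *,
    duration_s: float = 600.0,
    fps: float = 30.0,
    radius: float = DEFAULT_RADIUS_PX,
    inner_ratio: float = DEFAULT_INNER_RATIO,
    keep_last_s: float = 300.0,
    mixture_weight: float = 0.5,
    seed=None,
) -> np.ndarray:
    """Per-fly center occupancy over the analysis window, computed in a
    streaming fashion (same dynamics as :func:`simulate_positions`, but
    without materializing trajectories — used for large power studies; draws
    only what the occupancy needs, so it is statistically, not bit-for-bit,
    equivalent to windowing a full trajectory)."""
    rng = _rng(seed)
    n_frames = int(round(duration_s * fps))
    start = n_frames - int(round(keep_last_s * fps))
    if start < 0:
        raise ValueError("keep_last_s exceeds the recording length")
    r_in2 = (inner_ratio * radius) ** 2
    if mode == "mixture":
        is_tremor = rng.random(n_flies) < mixture_weight
        out = np.empty(n_flies)
        for sub_mode, mask in (("tremor", is_tremor), ("wall", ~is_tremor)):
            if mask.any():
                out[mask] = simulate_center_occupancy(
                    sub_mode, int(mask.sum()), duration_s=duration_s, fps=fps,
                    radius=radius, inner_ratio=inner_ratio, keep_last_s=keep_last_s, seed=rng,
                )
        return out
    if mode == "wall":
        inside = np.zeros(n_flies, dtype=np.int64)
        for chunk_start in range(start, n_frames, 2000):
            chunk = min(2000, n_frames - chunk_start)
            r = rng.normal(WALL_RADIUS_FRAC * radius, WALL_RADIUS_SD_FRAC * radius, (n_flies, chunk))
            r = np.clip(r, 0.0, radius * 0.999)
            inside += (r * r < r_in2).sum(axis=1)
        # the angular coordinate does not change the radial distance
        return inside / (n_frames - start)
    if mode == "tremor":
        pos = np.zeros((n_flies, 2))
        step_sd = TREMOR_STEP_SD_FRAC * radius
        theta = TREMOR_MEAN_REVERSION
        limit = radius * 0.999
        inside = np.zeros(n_flies, dtype=np.int64)
        for t in range(n_frames):
            pos = (1.0 - theta) * pos + rng.normal(0.0, step_sd, (n_flies, 2))
            dist = np.hypot(pos[:, 0], pos[:, 1])
            outside = dist > limit
            if outside.any():
                pos[outside] *= ((2.0 * limit - dist[outside]) / dist[outside])[:, None]
            if t >= start:
                inside += dist * dist < r_in2
        return inside / (n_frames - start)
    raise ValueError(f"unknown trajectory mode {mode!r}")


def gen_trajectory(
    mode: str,
    *,
    fly_id: str = "fly0",
    duration_s: float = 600.0,
    fps: float = 30.0,
    radius: float = DEFAULT_RADIUS_PX,
    mixture_weight: float = 0.5,
    seed=None,
) -> Trajectory:
    """A single fly's trajectory in the given locomotor mode."""
    n_frames = int(round(duration_s * fps))
    pos = simulate_positions(
        mode, 1, n_frames, radius=radius, mixture_weight=mixture_weight, seed=seed
    )[0]
    return Trajectory(np.arange(n_frames), pos[:, 0], pos[:, 1], fly_id=fly_id, fps=fps)


def gen_trajectories(
    mode: str,
    n_flies: int,
    *,
    duration_s: float = 600.0,
    fps: float = 30.0,
    radius: float = DEFAULT_RADIUS_PX,
    mixture_weight: float = 0.5,
    seed=None,
) -> list[Trajectory]:
    """Trajectories for a cohort of flies (one shared simulation batch)."""
    n_frames = int(round(duration_s * fps))
    pos = simulate_positions(
        mode, n_flies, n_frames, radius=radius, mixture_weight=mixture_weight, seed=seed
    )
    frames = np.arange(n_frames)
    return [
        Trajectory(frames, pos[i, :, 0], pos[i, :, 1], fly_id=f"fly{i}", fps=fps)
        for i in range(n_flies)
    ]


# ---------------------------------------------------------------------------
# Seizures and recovery
# ---------------------------------------------------------------------------

def gen_seizure(
    hazard_per_s: float,
    *,
    genotype: str = "g",
    n_replicates: int = 3,
    n_flies: int = 30,
    temperature_c: float = 40.0,
    seed=None,
) -> list[SeizureTimeCourse]:
    """Exponential-onset seizure time-courses, no remission.

    A fly with onset time T is scored as seizing at every 5-s assessment at
    or after T, so the bin-k state is 1 iff T <= 5(k+1); final-bin incidence
    is 1 - exp(-120 * hazard).
    """
    if hazard_per_s < 0:
        raise ValueError("hazard must be >= 0")
    rng = _rng(seed)
    courses = []
    bin_edges = BIN_SECONDS * (np.arange(N_BINS) + 1)
    for rep in range(n_replicates):
        if hazard_per_s == 0:
            onsets = np.full(n_flies, np.inf)
        else:
            onsets = rng.exponential(1.0 / hazard_per_s, n_flies)
        states = onsets[:, None] <= bin_edges[None, :]
        for i in range(n_flies):
            courses.append(
                SeizureTimeCourse(
                    fly_id=f"{genotype}_r{rep}_f{i}",
                    genotype=genotype,
                    replicate=rep,
                    states=tuple(int(s) for s in states[i]),
                    temperature_c=temperature_c,
                )
            )
    return courses


def gen_recovery(
    log_mean: float,
    log_sd: float,
    *,
    genotype: str = "g",
    n: int = 20,
    horizon_s: float = 600.0,
    seed=None,
) -> RecoveryTimes:
    """Log-normal recovery times, right-censored at ``horizon_s``."""
    if log_sd <= 0:
        raise ValueError("log_sd must be > 0")
    rng = _rng(seed)
    times = rng.lognormal(log_mean, log_sd, n)
    censored = times > horizon_s
    times = np.where(censored, horizon_s, times)
    return RecoveryTimes(genotype=genotype, times_s=times, censored=censored, horizon_s=horizon_s)


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

def gen_phenotypes(
    penetrance: dict[str, float],
    n: int,
    *,
    label: str = "synthetic",
    seed=None,
) -> PhenotypeRecord:
    """Binomial affected counts per trait at the given true penetrances."""
    rng = _rng(seed)
    affected = {trait: int(rng.binomial(n, p)) for trait, p in penetrance.items()}
    return PhenotypeRecord(label=label, flies_scored=n, affected=affected)


def gen_viability(
    total_male: int,
    mutant_prob: float,
    fertility_tested: int,
    fertile_prob: float,
    *,
    genotype: str = "synthetic",
    seed=None,
) -> ViabilityRecord:
    """Binomial viability/fertility record at the given class probabilities."""
    rng = _rng(seed)
    mutant = int(rng.binomial(total_male, mutant_prob))
    fertile = int(rng.binomial(fertility_tested, fertile_prob))
    return ViabilityRecord(
        genotype=genotype,
        total_male=total_male,
        balancer_class=total_male - mutant,
        mutant_class=mutant,
        fertility_tested=fertility_tested,
        sterile=fertility_tested - fertile,
        fertile=fertile,
    )


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def gen_counts(
    *,
    n_genes: int = 2000,
    n_reps: int = 4,
    conditions: tuple[str, str] = ("control", "mutant"),
    mean_log10_range: tuple[float, float] = (1.0, 4.0),
    dispersion: float = 0.05,
    size_factor_range: tuple[float, float] = (0.5, 2.0),
    spikes: dict[str, float] | None = None,
    spike_mean: float = 5000.0,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial counts with known size factors and spiked signals.

    Returns ``(counts, design, truth)``: a genes x samples integer matrix,
    a sample/condition/replicate design table, and the true log2 fold
    changes of the spiked genes (mutant over control).  By default one
    "GstS1_like" gene is spiked at log2FC = -1 (a two-fold knockdown) at a
    high baseline mean; all other genes are null.  Sample size factors are
    drawn log-uniformly from ``size_factor_range`` and then normalized to
    geometric mean 1, the scale on which median-of-ratios recovers them.
    """
    if n_reps < 2:
        raise ValueError("need >= 2 replicates per condition")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = _rng(seed)
    if spikes is None:
        spikes = {"GstS1_like": -1.0}

    genes = [f"gene{i:04d}" for i in range(n_genes)]
    spike_names = list(spikes)
    if len(spike_names) > n_genes:
        raise ValueError("more spiked genes than genes")
    genes[: len(spike_names)] = spike_names

    base = 10.0 ** rng.uniform(*mean_log10_range, n_genes)
    base[: len(spike_names)] = spike_mean
    lfc = np.zeros(n_genes)
    lfc[: len(spike_names)] = [spikes[g] for g in spike_names]

    n_samples = 2 * n_reps
    log_sf = rng.uniform(np.log(size_factor_range[0]), np.log(size_factor_range[1]), n_samples)
    sf = np.exp(log_sf - log_sf.mean())  # geometric mean 1

    samples, cond_labels = [], []
    for cond in conditions:
        for r in range(n_reps):
            samples.append(f"{cond}_{r + 1}")
            cond_labels.append(cond)
    is_mutant = np.array([c == conditions[1] for c in cond_labels])

    mu = base[:, None] * np.where(is_mutant[None, :], 2.0 ** lfc[:, None], 1.0) * sf[None, :]
    # NB via gamma-Poisson: shape 1/alpha, scale alpha * mu
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": cond_labels,
            "replicate": [r + 1 for _ in conditions for r in range(n_reps)],
        }
    )
    truth = pd.Series(spikes, name="log2_fold_change", dtype=float)
    counts_df.attrs["size_factors"] = pd.Series(sf, index=samples)
    return counts_df, design, truth
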