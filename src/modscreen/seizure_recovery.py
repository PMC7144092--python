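"""Heat-induced seizure time-courses and bang-sensitivity recovery analysis.

Seizure assays score each fly every 5 s over a 2-min immersion (24 bins,
binary seizing/not).  Incidence curves are per-bin proportions within
replicate groups, summarized as mean and SEM across groups, and compared
between genotypes with a mixed two-way repeated-measures ANOVA (replicate
group as subject, bin as the within factor).

Bang-sensitivity assays vortex flies and time their return to standing.
Recovery times may be right-censored at the observation horizon; censored
flies rank above every observed time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core_stats

__all__ = [
    "SeizureTimeCourse",
    "RecoveryTimes",
    "N_BINS",
    "BIN_SECONDS",
    "incidence_curve",
    "compare_incidence",
    "recovery_summary",
    "compare_recovery",
]

N_BINS = 24
BIN_SECONDS = 5.0


@dataclass(frozen=True)
class SeizureTimeCourse:
    """Binary seizure state of one fly per 5-s bin over 2 min."""

    fly_id: str
    genotype: str
    replicate: int
    states: tuple[int, ...]
    temperature_c: float = 40.0

    def __post_init__(self) -> None:
        if len(self.states) != N_BINS:
            raise ValueError(f"expected {N_BINS} bins, got {len(self.states)}")
        if any(s not in (0, 1) for s in self.states):
            raise ValueError("states must be 0 or 1")


@dataclass(frozen=True)
class RecoveryTimes:
    """Per-fly recovery times (s) with right-censoring at a common horizon."""

    genotype: str
    times_s: np.ndarray
    censored: np.ndarray
    horizon_s: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        cens = np.asarray(self.censored, dtype=bool)
        if times.size == 0:
            raise ValueError("need at least one fly")
        if times.size != cens.size:
            raise ValueError("times and censoring flags must align")
        if np.any(times < 0):
            raise ValueError("recovery times must be >= 0")
        observed = times[~cens]
        if observed.size and self.horizon_s < observed.max():
            raise ValueError("censoring horizon below the largest observed time")
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "censored", cens)

    def __len__(self) -> int:
        return int(self.times_s.size)


def incidence_curve(
    courses: list[SeizureTimeCourse], genotype: str | None = None
) -> pd.DataFrame:
    """Per-bin proportion of flies seizing, within each replicate group.

    Returns a DataFrame indexed by bin with one column per replicate plus
    ``mean`` and ``sem`` across replicates (SEM = SD/sqrt(groups), the
    error bars behavioral time-courses are reported with).
    """
    if genotype is not None:
        courses = [c for c in courses if c.genotype == genotype]
    if not courses:
        raise ValueError("no time-courses for the requested genotype")
    by_rep: dict[int, list[SeizureTimeCourse]] = {}
    for c in courses:
        by_rep.setdefault(c.replicate, []).append(c)
    data = {}
    for rep, members in sorted(by_rep.items()):
        states = np.array([m.states for m in members], dtype=float)
        data[f"rep{rep}"] = states.mean(axis=0)
    df = pd.DataFrame(data, index=pd.RangeIndex(N_BINS, name="bin"))
    reps = df.to_numpy()
    df["mean"] = reps.mean(axis=1)
    if reps.shape[1] > 1:
        df["sem"] = reps.std(axis=1, ddof=1) / np.sqrt(reps.shape[1])
    else:
        df["sem"] = np.nan
    df["time_s"] = (df.index.to_numpy() + 1) * BIN_SECONDS
    return df


def _proportion_table(courses: list[SeizureTimeCourse]) -> pd.DataFrame:
    rows = []
    for (genotype, rep), members in pd.DataFrame(
        [(c.genotype, c.replicate, c) for c in courses], columns=["g", "r", "c"]
    ).groupby(["g", "r"])["c"]:
        states = np.array([m.states for m in members], dtype=float)
        props = states.mean(axis=0)
        for b in range(N_BINS):
            rows.append((genotype, f"{genotype}/{rep}", b, props[b]))
    return pd.DataFrame(rows, columns=["genotype", "subject", "time", "value"])


def compare_incidence(
    courses: list[SeizureTimeCourse],
    genotype_a: str,
    genotype_b: str,
    *,
    sphericity_correction: str = "none",
) -> core_stats.RMAnovaResult:
    """Mixed repeated-measures ANOVA on the replicate x bin proportion table
    of two genotypes, with per-bin Holm-Sidak pairwise comparisons."""
    selected = [c for c in courses if c.genotype in (genotype_a, genotype_b)]
    present = {c.genotype for c in selected}
    missing = {genotype_a, genotype_b} - present
    if missing:
        raise ValueError(f"no time-courses for genotype(s) {sorted(missing)}")
    table = _proportion_table(selected)
    return core_stats.rm_anova_two_way(table, sphericity_correction=sphericity_correction)


def recovery_summary(rec: RecoveryTimes, horizon_s: float) -> tuple[float, float]:
    """(median recovery time, fraction recovered by ``horizon_s``).

    Censored flies sort above every observed time, so the median is the
    middle order statistic of that combined ordering; it is ``inf`` when the
    median position falls among censored flies.  The recovered fraction
    counts uncensored times <= horizon over all flies.
    """
    if horizon_s <= 0:
        raise ValueError("horizon must be positive")
    effective = np.where(rec.censored, np.inf, rec.times_s)
    median = float(np.median(effective))
    frac = float(np.mean(~rec.censored & (rec.times_s <= horizon_s)))
    return median, frac


def compare_recovery(rec_a: RecoveryTimes, rec_b: RecoveryTimes) -> core_stats.MannWhitneyResult:
    """Mann-Whitney U comparison of recovery times.

    Censored flies enter as ties at a common value above every observed time
    (the larger censoring horizon), which is their exact rank contribution
    under right-censoring at a shared horizon.
    """
    ceiling = max(rec_a.horizon_s, rec_b.horizon_s)
    x = np.where(rec_a.censored, ceiling, rec_a.times_s)
    y = np.where(rec_b.censored, ceiling, rec_b.times_s)
    return core_stats.mann_whitney_u(x, y)


@dataclass(frozen=True)
class RecoveryReport:
    summary: pd.DataFrame = field(repr=False)
    test: core_stats.MannWhitneyResult = None


def recovery_report(
    rec_a: RecoveryTimes, rec_b: RecoveryTimes, horizon_s: float
) -> RecoveryReport:
    """Side-by-side recovery summaries for two genotypes plus the U test."""
    rows = []
    for rec in (rec_a, rec_b):
        median, frac = recovery_summary(rec, horizon_s)
        rows.append((rec.genotype, len(rec), median, 100.0 * frac, int(rec.censored.sum())))
    summary = pd.DataFrame(
        rows, columns=["genotype", "n", "median_s", "pct_recovered", "n_censored"]
    )
    return RecoveryReport(summary=summary, test=compare_recovery(rec_a, rec_b))
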