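"""Benzer countercurrent climbing assay: the climbing index and a binomial
generative model of the apparatus.

Flies start in tube 0 and over five trials are given the chance to climb; a
fly that climbs in a trial is transferred to the next tube, so its final tube
number counts its successes.  The climbing index

    CI = sum(N_i * i) / (5 * sum(N_i)),   i in 0..5,

is the mean final tube number divided by the number of trials.  Under the
binomial model (each fly gets 5 independent Bernoulli(p) climb
opportunities) the CI is the maximum-likelihood estimate of the per-trial
climb probability p, and E[CI] = p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core_stats

__all__ = [
    "TubeCounts",
    "ClimbModel",
    "climbing_index",
    "simulate_countercurrent",
    "estimate_climb_prob",
    "compare_climbing",
]

N_TUBES = 6
DEFAULT_TRIALS = 5


@dataclass(frozen=True)
class TubeCounts:
    """Fly counts per tube (0..5) after a countercurrent run."""

    counts: tuple[int, ...]
    group_label: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) != N_TUBES:
            raise ValueError(f"expected {N_TUBES} tubes, got {len(self.counts)}")
        if any((not isinstance(c, (int, np.integer))) or c < 0 for c in self.counts):
            raise ValueError(f"tube counts must be non-negative integers: {self.counts}")
        if sum(self.counts) < 1:
            raise ValueError("at least one fly required")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class ClimbModel:
    """Generative model: each fly receives ``trials`` independent
    Bernoulli(``p``) climb opportunities; its final tube is the number of
    successes.  ``sequential=True`` switches to the alternative reading in
    which a fly that fails a trial is not tested again (final tube = number
    of successes before the first failure).  ``heterogeneity`` > 0 draws each
    fly's climb probability from a Beta distribution with mean ``p`` and
    that concentration-scaled variance (over-dispersion across flies)."""

    p: float
    trials: int = DEFAULT_TRIALS
    n_flies: int = 20
    sequential: bool = False
    heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")


def climbing_index(tubes: TubeCounts) -> float:
    """CI = sum(N_i * i) / (trials * sum(N_i)); 0 when every fly stayed in
    tube 0, 1 when every fly reached tube 5."""
    total = tubes.total
    weighted = sum(i * n for i, n in enumerate(tubes.counts))
    return weighted / (DEFAULT_TRIALS * total)


def simulate_countercurrent(
    model: ClimbModel, rng: np.random.Generator | int | None = None, group_label: str = ""
) -> TubeCounts:
    """Draw one countercurrent run.  Final tube ~ Binomial(trials, p) per fly
    under the default semantics."""
    rng = np.random.default_rng(rng)
    if model.heterogeneity > 0 and 0 < model.p < 1:
        # Beta with mean p; heterogeneity = 1 / (a + b) controls spread.
        conc = 1.0 / model.heterogeneity
        probs = rng.beta(model.p * conc, (1 - model.p) * conc, size=model.n_flies)
    else:
        probs = np.full(model.n_flies, model.p)
    if model.sequential:
        # Fly stops at its first failure: P(tube = k) = p^k (1-p) for k < trials.
        draws = rng.random((model.n_flies, model.trials)) < probs[:, None]
        fails = np.argmin(draws, axis=1)
        tube = np.where(draws.all(axis=1), model.trials, fails)
    else:
        tube = rng.binomial(model.trials, probs)
    counts = np.bincount(tube, minlength=N_TUBES)
    return TubeCounts(tuple(int(c) for c in counts), group_label=group_label)


def estimate_climb_prob(tubes: TubeCounts) -> tuple[float, tuple[float, float]]:
    """MLE of the per-trial climb probability with a 95% Wilson interval.

    Under the binomial model the total number of Bernoulli trials is
    ``5 * total`` and the number of successes is ``sum(i * N_i)``, so the
    MLE coincides with the climbing index.
    """
    n = DEFAULT_TRIALS * tubes.total
    successes = sum(i * c for i, c in enumerate(tubes.counts))
    p_hat = successes / n
    z = 1.959963984540054  # Phi^-1(0.975)
    denom = 1.0 + z * z / n
    center = (p_hat + z * z / (2 * n)) / denom
    half = z * math.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n)) / denom
    return p_hat, (max(0.0, center - half), min(1.0, center + half))


@dataclass(frozen=True)
class ClimbingReport:
    per_replicate: pd.DataFrame = field(repr=False)
    summary: pd.DataFrame = field(repr=False)
    kruskal: core_stats.KruskalWallisResult
    dunn: pd.DataFrame | None = field(repr=False, default=None)


def compare_climbing(
    groups: dict[str, list[TubeCounts]],
    control: str,
    *,
    dunn_adjust: str = "bonferroni",
) -> ClimbingReport:
    """Compare per-replicate climbing indices across genotypes.

    Computes the CI of every replicate run, reports per-genotype medians,
    and applies the Kruskal-Wallis test with Dunn's control comparisons.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 genotypes")
    if control not in groups:
        raise ValueError(f"control {control!r} not among genotypes")
    rows = []
    for label, replicates in groups.items():
        if len(replicates) < 1:
            raise ValueError(f"genotype {label!r} has no replicates")
        for idx, tubes in enumerate(replicates):
            rows.append((label, idx, tubes.total, climbing_index(tubes)))
    per_rep = pd.DataFrame(rows, columns=["genotype", "replicate", "n_flies", "ci"])
    summary = (
        per_rep.groupby("genotype")["ci"]
        .agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75), n="count")
        .reset_index()
    )
    ci_groups = {label: sub["ci"].to_numpy() for label, sub in per_rep.groupby("genotype")}
    kw = core_stats.kruskal_wallis(ci_groups)
    dunn = core_stats.dunn_posthoc(ci_groups, control, adjust=dunn_adjust)
    return ClimbingReport(per_replicate=per_rep, summary=summary, kruskal=kw, dunn=dunn)
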