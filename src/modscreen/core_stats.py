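"""Statistical tests and multiplicity adjustments used throughout the screen.

Every routine here is implemented from first principles (exact hypergeometric
enumeration for Fisher's test, rank statistics with midranks and tie
corrections, the classical mixed-model sums-of-squares decomposition for the
repeated-measures ANOVA).  SciPy is used only for reference distributions
(chi-squared, normal, t), never for the test statistics themselves.

Conventions follow the common desktop-statistics defaults: two-sided Fisher
p-values by the probability-mass method, Dunn's post hoc with Bonferroni
correction over control comparisons, continuity-corrected normal
approximation for the Mann-Whitney U outside the exact range.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "MannWhitneyResult",
    "KruskalWallisResult",
    "RMAnovaResult",
    "fisher_exact",
    "bonferroni_threshold",
    "bh_adjust",
    "holm_sidak_adjust",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "rm_anova_two_way",
]


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts: row 1 = group of interest (affected, unaffected),
    row 2 = control (affected, unaffected)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    odds_ratio_defined: bool = True


def fisher_exact(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value is the sum of hypergeometric probabilities, over all tables
    with the observed margins, that do not exceed the probability of the
    observed table (probability-mass two-sided convention).  All arithmetic
    is exact integer arithmetic, so tables whose probabilities tie are
    handled without floating-point ambiguity.

    Returns the sample odds ratio (a*d)/(b*c); ``inf`` when ``b*c == 0`` with
    ``a*d > 0``, and ``nan`` with ``odds_ratio_defined=False`` when both
    products vanish.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_rows(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # Exact integer numerators of the conditional hypergeometric pmf.
    masses = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = masses[a - lo]
    numer = sum(m for m in masses if m <= observed)
    p = numer / math.comb(n, c1)
    p = min(1.0, p)

    ad, bc = a * d, b * c
    if bc == 0 and ad == 0:
        return FisherResult(math.nan, p, odds_ratio_defined=False)
    if bc == 0:
        return FisherResult(math.inf, p)
    return FisherResult(ad / bc, p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison type I error rate, ``alpha / m``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    return alpha / m


# ---------------------------------------------------------------------------
# p-value adjustment families
# ---------------------------------------------------------------------------

def _validate_p(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("need a one-dimensional, non-empty collection of p-values")
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bh_adjust(p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order.

    ``m`` defaults to ``len(p)``; it may be larger when only part of the
    family is supplied.
    """
    arr = _validate_p(p)
    k = arr.size
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of p-values {k}")
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, k + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(k)
    out[order] = adjusted
    return out


def holm_sidak_adjust(p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in input order.

    In ascending order the i-th adjusted value is the running maximum of
    ``1 - (1 - p_(j)) ** (m - j + 1)`` for j <= i, clipped to [0, 1].
    """
    arr = _validate_p(p)
    k = arr.size
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of p-values {k}")
    order = np.argsort(arr, kind="stable")
    exponents = m - np.arange(k)  # m, m-1, ...
    stepwise = 1.0 - (1.0 - arr[order]) ** exponents
    adjusted = np.maximum.accumulate(stepwise)
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(k)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean of the tied positions."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "normal"


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    *,
    continuity: bool = True,
    method: str = "auto",
    exact_limit: int = 12,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is the statistic for the first sample, computed from midrank sums.
    When ``n1 + n2 <= exact_limit`` (and ``method`` is not "normal") the
    p-value is found by enumerating every assignment of the pooled midranks
    to the two samples, which remains exact under ties; otherwise a normal
    approximation with tie correction and (optionally) continuity correction
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n1 + n2 <= exact_limit)

    if use_exact:
        mean_u = n1 * n2 / 2.0
        observed_dev = abs(u - mean_u)
        total = 0
        extreme = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            total += 1
            u_perm = ranks[list(combo)].sum() - base
            if abs(u_perm - mean_u) >= observed_dev - 1e-12:
                extreme += 1
        return MannWhitneyResult(u, extreme / total, "exact")

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var_u <= 0:  # all observations identical
        return MannWhitneyResult(u, 1.0, "normal")
    dev = u - mean_u
    if continuity:
        dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev) if dev != 0 else 0.0
    z = dev / math.sqrt(var_u)
    p = 2.0 * _stats.norm.sf(abs(z))
    return MannWhitneyResult(u, min(1.0, p), "normal")


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    p_value: float
    df: int


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        out = {str(i): np.asarray(v, dtype=float) for i, v in enumerate(groups)}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for label, v in out.items():
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
    return out


def kruskal_wallis(groups) -> KruskalWallisResult:
    """Kruskal-Wallis one-way ANOVA on ranks with tie correction.

    ``groups`` is a mapping label -> observations or a sequence of
    observation sequences.  The p-value uses the chi-squared approximation
    with k-1 degrees of freedom.
    """
    g = _as_groups(groups)
    sizes = [v.size for v in g.values()]
    pooled = np.concatenate(list(g.values()))
    n = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        rsum = ranks[start : start + size].sum()
        h += rsum * rsum / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:  # every observation identical
        return KruskalWallisResult(0.0, 1.0, len(sizes) - 1)
    h /= correction
    df = len(sizes) - 1
    return KruskalWallisResult(h, float(_stats.chi2.sf(h, df)), df)


def dunn_posthoc(
    groups,
    control: str,
    *,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's post hoc rank comparisons of each group against a control.

    z statistics come from mean-rank differences with the tie-corrected
    pooled variance ``(N(N+1)/12 - sum(t^3-t)/(12(N-1))) * (1/n_i + 1/n_c)``.
    The adjustment over the k-1 control comparisons is Bonferroni by default
    ("sidak" is also accepted).  Returns a DataFrame indexed by group with
    columns z, p_raw, p_adj.
    """
    g = _as_groups(groups)
    if control not in g:
        raise ValueError(f"control label {control!r} not among groups {sorted(g)}")
    pooled = np.concatenate(list(g.values()))
    n = pooled.size
    ranks = _midranks(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for label, v in g.items():
        mean_ranks[label] = float(ranks[start : start + v.size].mean())
        start += v.size
    base_var = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))

    rows = []
    others = [label for label in g if label != control]
    k = len(others)
    for label in others:
        se2 = base_var * (1.0 / g[label].size + 1.0 / g[control].size)
        if se2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[label] - mean_ranks[control]) / math.sqrt(se2)
            p = 2.0 * float(_stats.norm.sf(abs(z)))
        rows.append((label, z, min(1.0, p)))
    df = pd.DataFrame(rows, columns=["group", "z", "p_raw"]).set_index("group")
    if adjust == "bonferroni":
        df["p_adj"] = np.clip(df["p_raw"] * k, 0.0, 1.0)
    elif adjust == "sidak":
        df["p_adj"] = 1.0 - (1.0 - df["p_raw"]) ** k
    elif adjust == "none":
        df["p_adj"] = df["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


# ---------------------------------------------------------------------------
# Two-way repeated-measures (mixed) ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RMAnovaResult:
    """Mixed two-way ANOVA: one between factor (genotype), one within factor
    (time), subjects (replicate groups) nested in genotype."""

    table: pd.DataFrame = field(repr=False)
    pairwise: pd.DataFrame = field(repr=False)
    gg_epsilon: float = 1.0

    @property
    def f_genotype(self) -> float:
        return float(self.table.loc["genotype", "F"])

    @property
    def f_time(self) -> float:
        return float(self.table.loc["time", "F"])

    @property
    def f_interaction(self) -> float:
        return float(self.table.loc["genotype:time", "F"])

    @property
    def p_genotype(self) -> float:
        return float(self.table.loc["genotype", "p"])

    @property
    def p_time(self) -> float:
        return float(self.table.loc["time", "p"])

    @property
    def p_interaction(self) -> float:
        return float(self.table.loc["genotype:time", "p"])


def _check_balanced(df: pd.DataFrame) -> tuple[list, list, dict]:
    genotypes = sorted(df["genotype"].unique())
    times = sorted(df["time"].unique())
    subjects_by_g: dict = {}
    counts = set()
    for g_label, sub in df.groupby("genotype"):
        subjects = sorted(sub["subject"].unique())
        subjects_by_g[g_label] = subjects
        counts.add(len(subjects))
        pivot = sub.pivot_table(index="subject", columns="time", values="value", aggfunc="count")
        if pivot.shape != (len(subjects), len(times)) or not (pivot == 1).all().all():
            raise ValueError(
                f"unbalanced design: genotype {g_label!r} lacks a complete "
                "subject x time crossing with one observation per cell"
            )
    if len(counts) != 1:
        raise ValueError(f"unbalanced design: unequal subject counts per genotype {sorted(counts)}")
    return genotypes, times, subjects_by_g


def _gg_epsilon(within: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-genotype covariance
    of the subject x time matrix (rows already centered per genotype)."""
    t = within.shape[1]
    if within.shape[0] < 2 or t < 2:
        return 1.0
    s = np.cov(within, rowvar=False)
    c = np.eye(t) - np.ones((t, t)) / t
    m = c @ s @ c
    tr = np.trace(m)
    denom = (t - 1) * np.sum(m * m)
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(1.0, max(eps, 1.0 / (t - 1))))


def rm_anova_two_way(
    data: pd.DataFrame,
    *,
    sphericity_correction: str = "none",
    pairwise_adjust: str = "holm-sidak",
) -> RMAnovaResult:
    """Classical univariate mixed ANOVA on a long-format table.

    ``data`` needs columns ``genotype`` (between factor), ``subject``
    (replicate group, nested in genotype), ``time`` (within factor) and
    ``value`` (the response, e.g. a seizure proportion).  The design must be
    balanced; unbalanced input raises rather than imputing.

    Sums of squares::

        SS_genotype          between genotypes            df g-1
        SS_subjects(geno)    subjects within genotype     df g(n-1)   (error for genotype)
        SS_time              within factor                df t-1
        SS_genotype:time     interaction                  df (g-1)(t-1)
        SS_error             residual                     df g(n-1)(t-1)

    ``sphericity_correction``: "none" (default) or "greenhouse-geisser",
    which scales the within-factor degrees of freedom by the
    Greenhouse-Geisser epsilon.

    The pairwise report compares genotypes within every time bin with
    two-sample pooled-variance t tests on the subject values, adjusted over
    all bins x pairs (Holm-Sidak by default).
    """
    required = {"genotype", "subject", "time", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    genotypes, times, subjects_by_g = _check_balanced(data)
    g, t = len(genotypes), len(times)
    n = len(subjects_by_g[genotypes[0]])
    if g < 2:
        raise ValueError("need at least two genotypes")

    # cube[i, j, k] = value for genotype i, subject j, time k
    cube = np.empty((g, n, t))
    for i, g_label in enumerate(genotypes):
        sub = data[data["genotype"] == g_label]
        pivot = sub.pivot(index="subject", columns="time", values="value")
        cube[i] = pivot.loc[subjects_by_g[g_label], times].to_numpy(dtype=float)

    grand = cube.mean()
    subj_means = cube.mean(axis=2)          # (g, n)
    geno_means = cube.mean(axis=(1, 2))     # (g,)
    time_means = cube.mean(axis=(0, 1))     # (t,)
    cell_means = cube.mean(axis=1)          # (g, t)

    ss_total = float(((cube - grand) ** 2).sum())
    ss_between_subj = float(t * ((subj_means - grand) ** 2).sum())
    ss_geno = float(n * t * ((geno_means - grand) ** 2).sum())
    ss_subj = ss_between_subj - ss_geno
    ss_time = float(g * n * ((time_means - grand) ** 2).sum())
    interaction_dev = cell_means - geno_means[:, None] - time_means[None, :] + grand
    ss_inter = float(n * (interaction_dev**2).sum())
    ss_error = ss_total - ss_between_subj - ss_time - ss_inter

    df_geno, df_subj = g - 1, g * (n - 1)
    df_time, df_inter = t - 1, (g - 1) * (t - 1)
    df_error = g * (n - 1) * (t - 1)
    if df_subj == 0 or df_error == 0:
        raise ValueError("need at least two subjects per genotype and two time bins")

    eps = 1.0
    if sphericity_correction == "greenhouse-geisser":
        centered = np.concatenate([cube[i] - cube[i].mean(axis=0) for i in range(g)])
        eps = _gg_epsilon(centered)
    elif sphericity_correction != "none":
        raise ValueError(f"unknown sphericity correction {sphericity_correction!r}")

    def _f_and_p(ss_num, df_num, ss_den, df_den, scale=1.0):
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den
        if ms_den <= 0:
            f = math.inf if ms_num > 0 else 0.0
            return f, 0.0 if ms_num > 0 else 1.0
        f = ms_num / ms_den
        return f, float(_stats.f.sf(f, df_num * scale, df_den * scale))

    f_geno, p_geno = _f_and_p(ss_geno, df_geno, ss_subj, df_subj)
    f_time, p_time = _f_and_p(ss_time, df_time, ss_error, df_error, scale=eps)
    f_inter, p_inter = _f_and_p(ss_inter, df_inter, ss_error, df_error, scale=eps)

    table = pd.DataFrame(
        {
            "SS": [ss_geno, ss_subj, ss_time, ss_inter, ss_error],
            "df": [df_geno, df_subj, df_time, df_inter, df_error],
            "F": [f_geno, math.nan, f_time, f_inter, math.nan],
            "p": [p_geno, math.nan, p_time, p_inter, math.nan],
        },
        index=["genotype", "subjects_within", "time", "genotype:time", "error"],
    )

    rows = []
    for k, time_label in enumerate(times):
        for i, j in itertools.combinations(range(g), 2):
            xi, xj = cube[i, :, k], cube[j, :, k]
            diff = xi.mean() - xj.mean()
            sp2 = (xi.var(ddof=1) + xj.var(ddof=1)) / 2.0
            if sp2 <= 0:
                t_stat, p = (math.inf if diff != 0 else 0.0), (0.0 if diff != 0 else 1.0)
            else:
                t_stat = diff / math.sqrt(sp2 * 2.0 / n)
                p = 2.0 * float(_stats.t.sf(abs(t_stat), 2 * n - 2))
            rows.append((time_label, genotypes[i], genotypes[j], diff, t_stat, min(1.0, p)))
    pairwise = pd.DataFrame(
        rows, columns=["time", "genotype_a", "genotype_b", "mean_diff", "t", "p_raw"]
    )
    if pairwise_adjust == "holm-sidak":
        pairwise["p_adj"] = holm_sidak_adjust(pairwise["p_raw"].to_numpy())
    elif pairwise_adjust == "bonferroni":
        pairwise["p_adj"] = np.clip(pairwise["p_raw"] * len(pairwise), 0, 1)
    elif pairwise_adjust == "none":
        pairwise["p_adj"] = pairwise["p_raw"]
    else:
        raise ValueError(f"unknown pairwise adjustment {pairwise_adjust!r}")

    return RMAnovaResult(table=table, pairwise=pairwise, gg_epsilon=eps)
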