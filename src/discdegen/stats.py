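"""The study's statistical battery.

Height indices and T2 values are compared with a two-way repeated-measures
ANOVA (treatment x time, both within-subject for the biweekly radiographs)
followed by Bonferroni or Tukey HSD post hoc comparisons; ordinal histology
grades use the Kruskal-Wallis test between groups and the Friedman test
over time; T2 and histology are related by rank (Spearman, default for
ordinal grades) or Pearson correlation.  The significance level throughout
is 0.05.

The repeated-measures decomposition is computed directly from the balanced
sum-of-squares formulas (each effect tested against its interaction with
subjects), which keeps 1000-replicate null calibrations cheap; it is
cross-checked against an independent implementation in the test suite.
Rank tests offer exact permutation p-values alongside the chi-square
approximation for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "LongTable",
    "TestResult",
    "rm_anova_two_way",
    "posthoc",
    "kruskal_wallis",
    "friedman",
    "correlate",
]

ALPHA = 0.05


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    method: str
    statistic: dict[str, float]
    df: dict[str, float]
    p_value: dict[str, float]
    posthoc_table: pd.DataFrame | None = None
    degenerate: bool = False
    notes: str = ""


@dataclass
class LongTable:
    """Tidy response table with explicit factor roles.

    ``within`` and ``between`` name the columns acting as within-subject
    and between-subject factors; the constructor verifies that subject x
    factor combinations are unique and reports whether the design is
    balanced.
    """

    data: pd.DataFrame
    subject: str
    response: str
    within: tuple[str, ...] = ()
    between: tuple[str, ...] = ()
    balanced: bool = field(init=False)

    def __post_init__(self) -> None:
        factors = list(self.within) + list(self.between)
        if not factors:
            raise ValueError("at least one factor is required")
        dup = self.data.duplicated(subset=[self.subject, *factors])
        if dup.any():
            raise ValueError("subject x factor combinations must be unique")
        counts = self.data.groupby(factors, observed=True).size()
        self.balanced = counts.nunique() == 1
        if not np.all(np.isfinite(self.data[self.response].to_numpy(float))):
            raise ValueError("responses must be finite")


def rm_anova_two_way(
    table: LongTable | pd.DataFrame,
    dv: str | None = None,
    subject: str | None = None,
    factors: tuple[str, str] | None = None,
) -> TestResult:
    """Balanced two-way fully-within repeated-measures ANOVA.

    One observation per subject x A x B cell.  Each effect is tested
    against its interaction with subjects: F_A = MS_A / MS_{AxS}, etc.
    Missing or duplicated cells raise with the offending cells listed.
    With zero between-cell variance the F ratios are undefined and the
    result is flagged degenerate.
    """
    if isinstance(table, LongTable):
        df, dv, subject = table.data, table.response, table.subject
        factors = tuple(table.within)
        if len(factors) != 2 or table.between:
            raise ValueError("rm_anova_two_way needs exactly two within factors")
    else:
        df = table
        if dv is None or subject is None or factors is None or len(factors) != 2:
            raise ValueError("dv, subject and two factors are required")
    fa, fb = factors
    subjects = np.sort(df[subject].unique())
    a_levels = np.sort(df[fa].unique())
    b_levels = np.sort(df[fb].unique())
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least 2 levels")

    counts = df.groupby([subject, fa, fb], observed=True).size()
    expected = pd.MultiIndex.from_product([subjects, a_levels, b_levels])
    missing = expected.difference(counts.index)
    bad = counts[counts != 1]
    if len(missing) or len(bad):
        raise ValueError(
            "unbalanced design; missing cells: "
            f"{list(missing)[:10]}; duplicated cells: {list(bad.index)[:10]}"
        )

    # cube Y[s, i, j]
    piv = df.pivot_table(index=subject, columns=[fa, fb], values=dv, observed=True)
    piv = piv.reindex(index=subjects, columns=pd.MultiIndex.from_product([a_levels, b_levels]))
    y = piv.to_numpy(float).reshape(n, a, b)

    gm = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_as - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((m_bs - m_s[:, None] - m_b[None, :] + gm) ** 2)
    ss_tot = np.sum((y - gm) ** 2)
    ss_s = a * b * np.sum((m_s - gm) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    d = {
        fa: (a - 1, (a - 1) * (n - 1), ss_a, ss_as),
        fb: (b - 1, (b - 1) * (n - 1), ss_b, ss_bs),
        f"{fa}*{fb}": ((a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), ss_ab, ss_abs),
    }
    stat, dof, pval = {}, {}, {}
    degenerate = False
    tiny = 1e-12 * max(float(ss_tot), 1e-300)  # float dust from exact-zero effects
    for eff, (df1, df2, ss_eff, ss_err) in d.items():
        ss_eff = 0.0 if ss_eff < tiny else ss_eff
        ss_err = 0.0 if ss_err < tiny else ss_err
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2 if df2 > 0 else np.nan
        if not np.isfinite(ms_err) or ms_err <= 0:
            # zero error variance: a null effect is F=0/p=1, a real effect
            # with no within-cell noise saturates at F=inf/p=0
            f, p = (0.0, 1.0) if ss_eff == 0.0 else (float("inf"), 0.0)
            degenerate = True
        else:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, df1, df2))
        stat[eff] = float(f)
        dof[eff] = (df1, df2)
        pval[eff] = p
    return TestResult(
        method="two-way repeated-measures ANOVA",
        statistic=stat,
        df=dof,
        p_value=pval,
        degenerate=degenerate,
        notes="effects tested against their subject interactions; no sphericity correction",
    )


def posthoc(
    df: pd.DataFrame,
    dv: str,
    group: str,
    method: str = "bonferroni",
    paired_on: str | None = None,
) -> pd.DataFrame:
    """All pairwise group comparisons with adjusted p-values.

    ``bonferroni`` runs t-tests (paired when ``paired_on`` names a subject
    column present in all groups) and multiplies the raw p by the number of
    comparisons, capped at 1; ``tukey_hsd`` uses the studentized-range
    distribution on independent groups.
    """
    levels = list(pd.unique(df[group]))
    if len(levels) < 2:
        raise ValueError("post hoc comparisons need at least 2 groups")
    pairs = list(itertools.combinations(levels, 2))
    if method == "tukey_hsd":
        samples = [df.loc[df[group] == g, dv].to_numpy(float) for g in levels]
        res = sps.tukey_hsd(*samples)
        rows = [
            {
                "group_a": levels[i],
                "group_b": levels[j],
                "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                "p_adjusted": float(res.pvalue[i, j]),
                "method": "tukey_hsd",
            }
            for i, j in itertools.combinations(range(len(levels)), 2)
        ]
        return pd.DataFrame(rows)
    if method != "bonferroni":
        raise ValueError(f"unknown post hoc method {method!r}")
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        xa = df.loc[df[group] == ga]
        xb = df.loc[df[group] == gb]
        if paired_on is not None:
            merged = xa.merge(xb, on=paired_on, suffixes=("_a", "_b"))
            t, p = sps.ttest_rel(merged[f"{dv}_a"], merged[f"{dv}_b"])
            diff = float(np.mean(merged[f"{dv}_a"] - merged[f"{dv}_b"]))
        else:
            t, p = sps.ttest_ind(xa[dv], xb[dv])
            diff = float(xa[dv].mean() - xb[dv].mean())
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_diff": diff,
                "p_raw": float(p),
                "p_adjusted": float(min(1.0, p * m)),
                "method": "bonferroni",
            }
        )
    return pd.DataFrame(rows)


def _kw_statistic(ranks: np.ndarray, sizes: np.ndarray, tie_factor: float) -> float:
    """Tie-corrected Kruskal-Wallis H for one assignment of pooled ranks."""
    ntot = len(ranks)
    means = []
    start = 0
    for s in sizes:
        means.append(ranks[start : start + s].mean())
        start += s
    h = 12.0 / (ntot * (ntot + 1)) * float(np.sum(sizes * (np.array(means) - (ntot + 1) / 2.0) ** 2))
    return h / tie_factor if tie_factor > 0 else 0.0


def kruskal_wallis(
    groups: list[np.ndarray],
    p_method: str = "asymptotic",
    max_exact: int = 200_000,
    seed: int = 0,
) -> TestResult:
    """Kruskal-Wallis rank test with tie correction.

    ``p_method='exact'`` enumerates every distinct assignment of the pooled
    values to the group sizes (up to ``max_exact`` assignments, Monte Carlo
    beyond that) and reports the permutation tail probability of H.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(
            method="kruskal-wallis", statistic={"H": 0.0}, df={"H": len(groups) - 1},
            p_value={"H": 1.0}, degenerate=True, notes="all values tied in every group",
        )
    sizes = np.array([len(g) for g in groups])
    ntot = int(sizes.sum())
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - float(np.sum(counts**3 - counts)) / (ntot**3 - ntot)
    h_obs = _kw_statistic(ranks, sizes, tie_factor)
    dof = len(groups) - 1
    if p_method == "asymptotic":
        p = float(sps.chi2.sf(h_obs, dof))
    elif p_method == "exact":
        n_assign = math.factorial(ntot) // math.prod(math.factorial(int(s)) for s in sizes)
        rng = np.random.default_rng(seed)
        if n_assign <= max_exact:
            count = total = 0
            for perm in _distinct_assignments(ranks, sizes):
                total += 1
                if _kw_statistic(perm, sizes, tie_factor) >= h_obs - 1e-12:
                    count += 1
            p = count / total
        else:
            reps = 20_000
            hits = sum(
                _kw_statistic(rng.permutation(ranks), sizes, tie_factor) >= h_obs - 1e-12
                for _ in range(reps)
            )
            p = (hits + 1) / (reps + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return TestResult(
        method="kruskal-wallis", statistic={"H": float(h_obs)}, df={"H": dof}, p_value={"H": p}
    )


def _distinct_assignments(values: np.ndarray, sizes: np.ndarray):
    """Yield every distinct split of ``values`` into ordered groups of the
    given sizes (each split once, by index combinations)."""
    idx = tuple(range(len(values)))

    def rec(remaining: tuple[int, ...], k: int):
        if k == len(sizes):
            yield ()
            return
        for chosen in itertools.combinations(remaining, int(sizes[k])):
            rest = tuple(i for i in remaining if i not in set(chosen))
            for tail in rec(rest, k + 1):
                yield chosen + tail

    for assignment in rec(idx, 0):
        yield values[np.array(assignment)]


def friedman(
    blocked: np.ndarray,
    p_method: str = "asymptotic",
    max_exact: int = 200_000,
    seed: int = 0,
) -> TestResult:
    """Friedman test on a blocks x treatments matrix (tie-corrected).

    Rows are blocks (subjects), columns repeated conditions.  The exact
    option enumerates within-block rank permutations (k!^n assignments) up
    to ``max_exact``, Monte Carlo beyond.
    """
    y = np.asarray(blocked, float)
    if y.ndim != 2 or y.shape[1] < 2 or y.shape[0] < 2:
        raise ValueError("need a blocks x treatments matrix with >= 2 of each")
    n, k = y.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, y)
    if np.allclose(ranks, ranks[:, :1]):
        return TestResult(
            method="friedman", statistic={"chi2": 0.0}, df={"chi2": k - 1},
            p_value={"chi2": 1.0}, degenerate=True, notes="all values tied within every block",
        )

    def stat(r: np.ndarray) -> float:
        col = r.sum(axis=0)
        chi = 12.0 / (n * k * (k + 1)) * float(np.sum((col - n * (k + 1) / 2.0) ** 2))
        ties = 0.0  # within-block rank-tie correction
        for row in r:
            _, c = np.unique(row, return_counts=True)
            ties += float(np.sum(c**3 - c))
        corr = 1.0 - ties / (n * k * (k**2 - 1))
        return chi / corr if corr > 0 else 0.0

    chi_obs = stat(ranks)
    dof = k - 1
    if p_method == "asymptotic":
        p = float(sps.chi2.sf(chi_obs, dof))
    elif p_method == "exact":
        n_assign = math.factorial(k) ** n
        rng = np.random.default_rng(seed)
        if n_assign <= max_exact:
            perms = list(itertools.permutations(range(k)))
            count = total = 0
            for combo in itertools.product(perms, repeat=n):
                r = np.vstack([ranks[i, list(combo[i])] for i in range(n)])
                total += 1
                if stat(r) >= chi_obs - 1e-12:
                    count += 1
            p = count / total
        else:
            reps = 20_000
            hits = 0
            for _ in range(reps):
                r = np.vstack([row[rng.permutation(k)] for row in ranks])
                hits += stat(r) >= chi_obs - 1e-12
            p = (hits + 1) / (reps + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return TestResult(
        method="friedman", statistic={"chi2": float(chi_obs)}, df={"chi2": dof}, p_value={"chi2": p}
    )


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Correlation coefficient and two-sided p.

    Spearman is the default (histology grades are ordinal); Pearson is
    available.  Requires >= 3 paired finite values and non-zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)
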