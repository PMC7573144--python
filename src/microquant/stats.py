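"""The study's statistical procedures.

Two-group comparisons follow a normality/variance dispatch: Shapiro-Wilk on
each sample, Levene's test (mean-centred, as in SPSS) for equal variances,
then Student's t (normal + equal variances), Welch's t (normal, unequal
variances) or the Mann-Whitney U test; all two-tailed.  Contingency tables
are tested with Fisher's exact test, extended to r x c tables by the
Freeman-Halton construction (complete enumeration when feasible, otherwise
Monte Carlo over margin-preserving tables).  More than two groups use
Kruskal-Wallis followed by Dunn's pairwise z tests with Bonferroni
adjustment.  Normalisation helpers implement percent-of-control scaling and
the delta-delta-Ct relative expression calculation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    """Outcome of a dispatched two-group test."""

    test_used: str  # "student-t" | "welch-t" | "mann-whitney"
    statistic: float
    p_value: float
    df: float | None = None
    dispatch_trace: dict = field(default_factory=dict)


def dispatch_two_group(a, b, alpha: float = 0.05) -> GroupComparison:
    """Two-tailed two-group test chosen by normality and variance checks.

    Both samples normal by Shapiro-Wilk at ``alpha`` -> t-test (Student's
    form when Levene accepts equal variances, Welch's otherwise); any
    non-normal sample -> Mann-Whitney U.  Samples must have n >= 3.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3")
    sw_a = sps.shapiro(a).pvalue if a.std() > 0 else 0.0
    sw_b = sps.shapiro(b).pvalue if b.std() > 0 else 0.0
    trace = {"shapiro_p_a": float(sw_a), "shapiro_p_b": float(sw_b), "alpha": alpha}
    normal = sw_a > alpha and sw_b > alpha
    if normal:
        lev_p = sps.levene(a, b, center="mean").pvalue if (a.std() or b.std()) else 1.0
        trace["levene_p"] = float(lev_p)
        equal_var = lev_p > alpha
        trace["branch"] = "student-t" if equal_var else "welch-t"
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        return GroupComparison(trace["branch"], float(res.statistic), float(res.pvalue),
                               df=float(res.df), dispatch_trace=trace)
    trace["branch"] = "mann-whitney"
    u, p = mann_whitney_u(a, b)
    return GroupComparison("mann-whitney", u, p, dispatch_trace=trace)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact p by enumeration of the null U distribution when the smaller
    sample has n <= 8 and there are no ties; otherwise the normal
    approximation with tie correction and no continuity correction (so two
    identical samples give U = n1*n2/2 and p = 1 exactly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if min(len(a), len(b)) <= 8 and not ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables (Freeman-Halton)


def _table_log_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """log P(table | margins) under the multivariate hypergeometric null."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(lgamma(r + 1) for r in rows)
        + sum(lgamma(c + 1) for c in cols)
        - lgamma(n + 1)
        - sum(lgamma(x + 1) for x in table.ravel())
    )
    return lp


def _iter_tables(rows: tuple[int, ...], cols: tuple[int, ...]):
    """Yield every non-negative integer table with the given margins."""
    r, c = len(rows), len(cols)
    if r == 1:
        yield np.array([cols])
        return
    # enumerate the first row, recurse on the remainder
    def first_rows(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for v in range(min(total, caps[0]) + 1):
            for rest in first_rows(total - v, caps[1:]):
                yield (v,) + rest

    for top in first_rows(rows[0], cols):
        rem_cols = tuple(cj - tj for cj, tj in zip(cols, top))
        for sub in _iter_tables(rows[1:], rem_cols):
            yield np.vstack([np.array([top]), sub])


def count_margin_tables(rows, cols) -> int:
    """Number of tables compatible with the margins (dynamic programme)."""
    states = {tuple(cols): 1}
    for r in rows[:-1]:
        new: dict = {}
        for state, mult in states.items():
            for top in _compositions_capped(r, state):
                nxt = tuple(c - t for c, t in zip(state, top))
                new[nxt] = new.get(nxt, 0) + mult
        states = new
    return sum(states.values())


def _compositions_capped(total, caps):
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for v in range(min(total, caps[0]) + 1):
        for rest in _compositions_capped(total - v, caps[1:]):
            yield (v,) + rest


@dataclass
class ExactTestResult:
    p_value: float
    method: str  # "hypergeometric" | "enumeration" | "monte-carlo"
    n_tables: int | None = None
    mc_se: float | None = None


def fisher_exact_rc(
    table, enumeration_cap: int = 200_000, n_mc: int = 20_000, seed: int = 0
) -> ExactTestResult:
    """Exact two-sided test of independence for an r x c count table.

    2x2 tables use the hypergeometric two-sided test.  Larger tables use
    the Freeman-Halton extension: the p-value is the null probability of
    all margin-compatible tables no more probable than the observed one.
    Complete enumeration is used when the number of compatible tables is at
    most ``enumeration_cap``; beyond that, margin-preserving Monte Carlo
    with ``n_mc`` samples (Patefield sampling, add-one estimator) and the
    Monte-Carlo standard error is reported.  Rows/columns with zero margin
    are dropped.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        # after dropping empty margins independence is trivially satisfied
        return ExactTestResult(1.0, "degenerate")
    if table.shape == (2, 2):
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return ExactTestResult(float(p), "hypergeometric")

    rows = tuple(int(x) for x in table.sum(axis=1))
    cols = tuple(int(x) for x in table.sum(axis=0))
    lp_obs = _table_log_prob(table)
    tol = 1e-9
    n_tables = count_margin_tables(rows, cols)
    if n_tables <= enumeration_cap:
        p = 0.0
        for t in _iter_tables(rows, cols):
            lp = _table_log_prob(t)
            if lp <= lp_obs + tol:
                p += math.exp(lp)
        return ExactTestResult(min(p, 1.0), "enumeration", n_tables=n_tables)

    rng = np.random.default_rng(seed)
    dist = sps.random_table(rows, cols)
    samples = dist.rvs(n_mc, random_state=rng)
    hits = sum(1 for t in samples if _table_log_prob(t.astype(np.int64)) <= lp_obs + tol)
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return ExactTestResult(p, "monte-carlo", n_tables=n_tables, mc_se=se)


# ---------------------------------------------------------------------------
# k-group testing


@dataclass
class KGroupResult:
    h_statistic: float
    kw_p_value: float
    pairwise: dict[tuple[int, int], dict[str, float]]  # (i, j) -> z, p, p_adjusted


def compare_k_groups(samples: list) -> KGroupResult:
    """Kruskal-Wallis across k >= 3 groups, then Dunn's pairwise z tests.

    Dunn's z uses the pooled mid-ranks with tie correction; both the
    unadjusted and the Bonferroni-adjusted (family = all pairs) p-values
    are reported, the adjusted one being the headline value.
    """
    if len(samples) < 3:
        raise ValueError("need k >= 3 groups")
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h, kw_p = 0.0, 1.0
    else:
        h, kw_p = sps.kruskal(*samples)
    ranks = sps.rankdata(pooled)
    sizes = [len(s) for s in samples]
    n = len(pooled)
    mean_ranks = []
    start = 0
    for m in sizes:
        mean_ranks.append(ranks[start : start + m].mean())
        start += m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n - 1))) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    n_pairs = len(samples) * (len(samples) - 1) // 2
    pairwise = {}
    for i, j in itertools.combinations(range(len(samples)), 2):
        se = math.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * sps.norm.sf(abs(z))
        pairwise[(i, j)] = {
            "z": float(z),
            "p": float(min(p, 1.0)),
            "p_adjusted": float(min(p * n_pairs, 1.0)),
        }
    return KGroupResult(float(h), float(kw_p), pairwise)


# ---------------------------------------------------------------------------
# normalisation conventions


def percent_of_control(values, control_values):
    """Scale values so the control mean maps to 100%."""
    control_values = np.asarray(control_values, dtype=float)
    m = control_values.mean()
    if m == 0:
        raise ValueError("control mean is zero; cannot normalise")
    return np.asarray(values, dtype=float) * 100.0 / m


def delta_delta_ct(ct_target, ct_ref, control_mean_dct: float):
    """Relative expression (%) by the delta-delta-Ct method.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the control
    group's mean dCt; expression = 2^(-ddCt) * 100, so ddCt = 1 halves and
    ddCt = -2 quadruples expression.  Rescaling the control group's mean
    expression to exactly 100% per batch is done with
    :func:`percent_of_control`.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_ref).all()):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_ref) - control_mean_dct
    return 100.0 * np.power(2.0, -ddct)
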