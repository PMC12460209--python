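"""Statistical battery over region means and dichotomized lesions.

Omnibus comparison across the four compartments follows the normality-
gated scheme: Shapiro–Wilk per region, then either the Friedman test with
Dunn's rank-based post-hoc contrasts (any region non-normal) or one-way
repeated-measures ANOVA with Dunnett-style contrasts against the control
region (all normal).  Dichotomized groups use the paired two-tailed t-test
or the exact Mann–Whitney U.  Inter-rater agreement uses the two-way
random-effects single-measure absolute-agreement ICC (Shrout–Fleiss
ICC(2,1)) with an F-based confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "friedman_test",
    "rm_anova",
    "dunn_posthoc",
    "dunnett_posthoc",
    "compare_regions",
    "compare_dichotomy",
    "icc_agreement",
]


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison: omnibus test name/statistic/
    p-value, adjusted post-hoc p-values keyed by contrast, effect
    directions (sign of region-minus-reference), and any per-region
    normality screen."""

    test: str
    statistic: float
    p_value: float
    posthoc: dict[str, float] = field(default_factory=dict)
    raw_posthoc: dict[str, float] = field(default_factory=dict)
    direction: dict[str, float] = field(default_factory=dict)
    normality: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# omnibus tests


def friedman_test(table: np.ndarray, method: str = "auto") -> tuple[float, float]:
    """Friedman test over a subjects × conditions table, mid-ranks with the
    standard tie correction.

    ``method='auto'`` uses the exact within-row permutation null when the
    table is small enough to enumerate (computed by convolving the per-row
    rank-sum distributions, not by brute force) and the chi-square
    reference otherwise; ``'exact'`` and ``'chi2'`` force either."""
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    ranks = sps.rankdata(x, axis=1)
    # tie correction (invariant under within-row permutation)
    tie = sum(float(np.sum(c**3 - c))
              for c in (np.unique(row, return_counts=True)[1] for row in x))
    denom_c = 1.0 - tie / (n * k * (k**2 - 1))
    if denom_c <= 0:  # every row fully tied
        return 0.0, 1.0

    def q_of(rank_sums):
        q = 12.0 / (n * k * (k + 1)) * np.sum(np.square(rank_sums)) \
            - 3.0 * n * (k + 1)
        return q / denom_c

    q_obs = float(q_of(ranks.sum(axis=0)))
    if method == "auto":
        method = "exact" if (n <= 6 and k <= 4) else "chi2"
    if method == "chi2":
        return q_obs, float(sps.chi2.sf(q_obs, k - 1))
    if method != "exact":
        raise ValueError("method must be 'auto', 'exact' or 'chi2'")

    # exact permutation null: distribute each row's ranks over conditions
    # uniformly; convolve rank-sum-vector distributions across subjects
    from itertools import permutations

    states: dict[tuple, int] = {(0.0,) * k: 1}
    for row in ranks:
        new: dict[tuple, int] = {}
        for state, cnt in states.items():
            for p in permutations(row):
                s = tuple(a + b for a, b in zip(state, p))
                new[s] = new.get(s, 0) + cnt
        states = new
    total = sum(states.values())
    ge = sum(cnt for s, cnt in states.items()
             if q_of(np.asarray(s)) >= q_obs - 1e-9)
    return q_obs, ge / total


def rm_anova(table: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA F-test over subjects × conditions."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        return 0.0, 1.0
    f = (ss_cond / df1) / ms_err
    return float(f), float(sps.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# post-hoc contrasts


def _holm(raw: np.ndarray) -> np.ndarray:
    order = np.argsort(raw)
    m = raw.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * raw[i])
        adj[i] = min(1.0, running)
    return adj


def dunn_posthoc(
    table: np.ndarray,
    columns: list[str],
    control: str,
    family: str = "control",
    adjust: str = "holm",
) -> tuple[dict[str, float], dict[str, float]]:
    """Dunn's rank-based multiple comparisons after the Friedman test.

    z contrasts of mean within-subject ranks with SE sqrt(k(k+1)/(6n));
    family is either every region versus the control column (default) or
    all pairs; adjustment is Holm step-down (default) or Bonferroni.
    Returns (adjusted, raw) p-value dicts keyed ``"A vs B"``.
    """
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    ranks = sps.rankdata(x, axis=1).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    ci = columns.index(control)
    if family == "control":
        pairs = [(j, ci) for j in range(k) if j != ci]
    elif family == "all":
        pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    else:
        raise ValueError("family must be 'control' or 'all'")
    z = np.array([(ranks[a] - ranks[b]) / se for a, b in pairs])
    raw = 2.0 * sps.norm.sf(np.abs(z))
    if adjust == "holm":
        adj = _holm(raw)
    elif adjust == "bonferroni":
        adj = np.minimum(1.0, raw * len(pairs))
    else:
        raise ValueError("adjust must be 'holm' or 'bonferroni'")
    keys = [f"{columns[a]} vs {columns[b]}" for a, b in pairs]
    adj = np.maximum(adj, raw)
    return dict(zip(keys, adj)), dict(zip(keys, raw))


def dunnett_posthoc(
    table: np.ndarray,
    columns: list[str],
    control: str,
    random_state: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Dunnett-style many-to-one contrasts for the repeated-measures design.

    Each region's paired differences against the control give a t statistic
    with n-1 df; the family adjustment evaluates P(max |T| >= |t|) under a
    multivariate t whose correlation is estimated from the difference
    vectors (integrated with a fixed QMC seed, so results are repeatable).
    """
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    ci = columns.index(control)
    others = [j for j in range(k) if j != ci]
    d = x[:, others] - x[:, [ci]]
    means = d.mean(axis=0)
    ses = d.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(ses > 0, means / ses, 0.0)
    df = n - 1
    raw = 2.0 * sps.t.sf(np.abs(t), df)

    m = len(others)
    if m == 1:
        adj = raw.copy()
    else:
        corr = np.corrcoef(d, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        # nudge to positive definite if estimation made it borderline
        w, v = np.linalg.eigh(corr)
        corr = (v * np.maximum(w, 1e-6)) @ v.T
        dcor = np.sqrt(np.diag(corr))
        corr = corr / np.outer(dcor, dcor)
        mvt = sps.multivariate_t(loc=np.zeros(m), shape=corr, df=df, seed=random_state)
        adj = np.empty(m)
        for j, tj in enumerate(np.abs(t)):
            inside = mvt.cdf(np.full(m, tj), lower_limit=np.full(m, -tj))
            adj[j] = min(1.0, max(0.0, 1.0 - inside))
    adj = np.maximum(adj, raw)
    # enforce monotonicity in the raw p-values (QMC integration jitter)
    order = np.argsort(raw)
    adj[order] = np.maximum.accumulate(adj[order])
    keys = [f"{columns[j]} vs {control}" for j in others]
    return dict(zip(keys, adj)), dict(zip(keys, raw))


# ---------------------------------------------------------------------------
# high-level comparisons


def compare_regions(
    table: pd.DataFrame | np.ndarray,
    mode: str = "auto",
    control: str = "C",
    alpha_normality: float = 0.05,
    dunn_family: str = "control",
) -> ComparisonResult:
    """Compare region means across compartments (subjects × regions).

    ``mode='auto'`` screens each region with Shapiro–Wilk and runs
    Friedman + Dunn if any region departs from normality, otherwise
    repeated-measures ANOVA + Dunnett versus the control region.
    Missing cells are rejected (complete-case design).
    """
    if isinstance(table, pd.DataFrame):
        columns = list(table.columns)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        columns = [f"r{j}" for j in range(x.shape[1])]
        if control not in columns:
            control = columns[-1]
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 3 subjects and >= 2 regions")
    bad = np.flatnonzero(~np.isfinite(x).all(axis=1))
    if bad.size:
        raise ValueError(f"missing cells in rows {bad.tolist()}; complete cases required")
    if control not in columns:
        raise ValueError(f"control column {control!r} not in table")

    normality = {}
    if mode == "auto":
        for j, name in enumerate(columns):
            col = x[:, j]
            normality[name] = 1.0 if np.ptp(col) == 0 else float(
                sps.shapiro(col).pvalue)
        mode = ("friedman" if any(p < alpha_normality for p in normality.values())
                else "rm_anova")

    ci = columns.index(control)
    direction = {f"{columns[j]} vs {control}":
                 float(np.sign(x[:, j].mean() - x[:, ci].mean()))
                 for j in range(len(columns)) if j != ci}

    if mode == "friedman":
        stat, p = friedman_test(x)
        adj, raw = dunn_posthoc(x, columns, control, family=dunn_family)
        name = "friedman+dunn"
    elif mode == "rm_anova":
        stat, p = rm_anova(x)
        adj, raw = dunnett_posthoc(x, columns, control)
        name = "rm_anova+dunnett"
    else:
        raise ValueError("mode must be 'auto', 'friedman' or 'rm_anova'")
    return ComparisonResult(test=name, statistic=stat, p_value=p, posthoc=adj,
                            raw_posthoc=raw, direction=direction,
                            normality=normality)


def compare_dichotomy(
    values_a,
    values_b,
    paired: bool = True,
    parametric: bool = True,
) -> ComparisonResult:
    """Two-group comparison: paired two-tailed t-test (parametric) or
    Mann–Whitney U with the exact small-sample distribution (non-parametric,
    unpaired)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per arm")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length arms")
        if not parametric:
            raise ValueError("paired non-parametric design is not provided")
        d = a - b
        if np.all(d == 0):
            res_stat, res_p = 0.0, 1.0
        else:
            r = sps.ttest_rel(a, b)
            res_stat, res_p = float(r.statistic), float(r.pvalue)
        name = "paired_t"
    elif parametric:
        r = sps.ttest_ind(a, b)
        res_stat, res_p = float(r.statistic), float(r.pvalue)
        name = "student_t"
    else:
        method = "exact" if (a.size + b.size) <= 25 else "auto"
        r = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        res_stat, res_p = float(r.statistic), float(r.pvalue)
        name = "mann_whitney_u"
    return ComparisonResult(
        test=name, statistic=res_stat, p_value=res_p,
        direction={"a vs b": float(np.sign(np.mean(a) - np.mean(b)))})


# ---------------------------------------------------------------------------
# agreement


# Shrout–Fleiss names -> pingouin type labels (A: absolute, C: consistency)
_ICC_FORMS = {"icc1": "ICC(1,1)", "icc2": "ICC(A,1)", "icc3": "ICC(C,1)",
              "icc1k": "ICC(1,k)", "icc2k": "ICC(A,k)", "icc3k": "ICC(C,k)"}


def icc_agreement(
    ratings: np.ndarray,
    form: str = "icc2",
) -> tuple[float, tuple[float, float]]:
    """Intraclass correlation over a subjects × raters matrix.

    Default form is ICC(2,1): two-way random effects, single measure,
    absolute agreement — the appropriate form for inter-rater VOI
    delineation.  All six Shrout–Fleiss forms are available via ``form``.
    Returns the estimate and its F-based 95% confidence interval.
    """
    import pingouin as pg

    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects × raters matrix with >= 2 raters")
    if x.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    if np.ptp(x) == 0:
        raise ValueError("ratings are constant across all subjects: ICC undefined")
    if form not in _ICC_FORMS:
        raise ValueError(f"form must be one of {sorted(_ICC_FORMS)}")
    n, r = x.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), r),
        "rater": np.tile(np.arange(r), n),
        "score": x.ravel(),
    })
    res = pg.intraclass_corr(df, targets="subject", raters="rater",
                             ratings="score").set_index("Type")
    row = res.loc[_ICC_FORMS[form]]
    ci = row["CI95"] if "CI95" in row.index else row["CI95%"]
    return float(row["ICC"]), (float(ci[0]), float(ci[1]))
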