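"""Group statistics, per-CpG testing, co-methylation networks, genotype
association and repeatability for panel methylation data.

The analysis works on two levels. Region-level mean methylation percentages
are logit-transformed (the variance of a proportion is maximal at 50% and
vanishes at the extremes; the logit homogenizes it) and compared between
controls and patients — or across the four severity strata — with a test
chosen from the data's own diagnostics: Shapiro-Wilk normality per group
and Levene homoscedasticity across groups decide between Student, Welch,
one-way ANOVA and the rank-based Wilcoxon / Kruskal-Wallis alternatives.
Site-level methylation is compared by Fisher's exact test on pooled
methylated/unmethylated read counts with Bonferroni control of the
family-wise error rate (FWER, default 5%) over the sites tested per tissue.
Co-methylation networks connect (gene, tissue) mean-methylation variables
whose Spearman correlation survives Bonferroni at a 10% FWER, separately in
the control and patient strata. Genotype association correlates a 0/1/2
allele dosage with methylation (Spearman). Repeatability of the assay is
the pooled within-pair SD of duplicated measurements on the logit scale.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_FWER_SITES = 0.05
DEFAULT_FWER_NETWORK = 0.10
DEFAULT_MIN_PAIRS = 5


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Logit transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogitValue:
    value: float
    source: float
    clamped: bool


def logit_transform(
    fraction: float, eps: float | None = None, n: int | None = None
) -> LogitValue:
    """ln(p/(1-p)) after clamping p into [eps, 1-eps].

    ``eps`` defaults to half the smallest observable fraction, 1/(2n), when
    a read count ``n`` is given (n-adaptive: keeps the ordering of exact 0s
    from different depths), else to 1e-6.
    """
    if not 0.0 <= fraction <= 1.0:
        raise StatsError(f"fraction {fraction} outside [0, 1]")
    if eps is None:
        eps = 1.0 / (2.0 * n) if n else 1e-6
    p = min(max(fraction, eps), 1.0 - eps)
    return LogitValue(math.log(p / (1.0 - p)), fraction, p != fraction)


def logit_array(fractions, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(np.asarray(fractions, dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# Repeatability from duplicated measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatabilityEstimate:
    sd: float          # pooled within-pair SD, logit scale
    df: int            # one per complete duplicate pair
    n_pairs: int
    n_missing: int


def estimate_repeatability(pairs: np.ndarray | pd.DataFrame) -> RepeatabilityEstimate:
    """Pooled within-pair SD of duplicate measurements (logit scale).

    ``pairs`` is an (m, 2) array of replicate pairs; rows with any missing
    value are excluded and counted. For duplicates the pooled estimator is
    sqrt(sum(d_i^2) / (2 k)) over the k complete pairs, with k degrees of
    freedom.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise StatsError("pairs must be an (m, 2) array")
    complete = ~np.isnan(arr).any(axis=1)
    k = int(complete.sum())
    if k == 0:
        raise StatsError("no complete duplicate pairs")
    d = arr[complete, 0] - arr[complete, 1]
    return RepeatabilityEstimate(
        sd=float(np.sqrt(np.sum(d**2) / (2.0 * k))),
        df=k,
        n_pairs=int(arr.shape[0]),
        n_missing=int(arr.shape[0] - k),
    )


# ---------------------------------------------------------------------------
# Group comparison with data-driven test selection
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    groups: tuple[str, ...]
    test: str
    statistic: float
    pvalue: float
    significant: bool
    normality_p: dict[str, float] = field(default_factory=dict)
    levene_p: float = float("nan")
    n: dict[str, int] = field(default_factory=dict)


def _is_normal(x: np.ndarray, alpha: float) -> tuple[bool, float]:
    if x.size < 3 or np.ptp(x) == 0:
        return False, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps.shapiro(x).pvalue)
    if not np.isfinite(p):
        return False, p
    return p >= alpha, p


def compare_groups(
    values: dict[str, np.ndarray],
    variable: str = "",
    alpha: float = DEFAULT_P_THRESHOLD,
    normality_alpha: float = 0.05,
    levene_alpha: float = 0.05,
) -> GroupComparison:
    """Compare >= 2 groups, choosing the test from the data's diagnostics.

    Two groups: Student (normal, homoscedastic), Welch (normal,
    heteroscedastic) or the Wilcoxon rank-sum test; more groups: one-way
    ANOVA or Kruskal-Wallis. Normality is Shapiro-Wilk per group,
    homoscedasticity is median-centered Levene across groups; both at the
    stated alphas, and both recorded so the choice is reproducible.
    """
    names = tuple(values)
    arrays = [np.asarray(values[g], dtype=float) for g in names]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2:
        raise StatsError("need at least two groups")
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise StatsError(f"group {g!r} has fewer than 2 values")
    norm_p: dict[str, float] = {}
    all_normal = True
    for g, a in zip(names, arrays):
        ok, p = _is_normal(a, normality_alpha)
        norm_p[g] = p
        all_normal &= ok
    pooled = np.concatenate(arrays)
    degenerate = np.ptp(pooled) == 0
    if degenerate:
        levene_p = float("nan")
        homoscedastic = True
    else:
        levene_p = float(sps.levene(*arrays, center="median").pvalue)
        homoscedastic = levene_p >= levene_alpha

    if degenerate:
        test, stat, pval = ("wilcoxon" if len(arrays) == 2 else "kruskal-wallis",
                            0.0, 1.0)
    elif len(arrays) == 2:
        if all_normal and homoscedastic:
            test = "student"
            r = sps.ttest_ind(arrays[0], arrays[1], equal_var=True)
        elif all_normal:
            test = "welch"
            r = sps.ttest_ind(arrays[0], arrays[1], equal_var=False)
        else:
            test = "wilcoxon"
            r = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        stat, pval = float(r.statistic), float(r.pvalue)
    else:
        if all_normal and homoscedastic:
            test = "anova"
            r = sps.f_oneway(*arrays)
        else:
            test = "kruskal-wallis"
            r = sps.kruskal(*arrays)
        stat, pval = float(r.statistic), float(r.pvalue)

    return GroupComparison(
        variable=variable,
        groups=names,
        test=test,
        statistic=stat,
        pvalue=pval,
        significant=pval < alpha,
        normality_p=norm_p,
        levene_p=levene_p,
        n={g: int(a.size) for g, a in zip(names, arrays)},
    )


# ---------------------------------------------------------------------------
# Per-CpG Fisher exact tests with Bonferroni FWER control
# ---------------------------------------------------------------------------

def _lchoose(n, k):
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]:
    the sum of hypergeometric point probabilities (over the table's
    support at fixed margins) not exceeding the observed one.

    Evaluated over the whole support in one vectorized log-gamma pass,
    with a 1e-7 relative guard absorbing floating-point ties.
    """
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = (
        _lchoose(r1, k) + _lchoose(r2, c1 - k) - _lchoose(n, c1)
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[int(a - k[0])]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def per_cpg_fisher(
    tables: pd.DataFrame, fwer: float = DEFAULT_FWER_SITES
) -> pd.DataFrame:
    """Two-sided Fisher exact test per CpG site on pooled read counts.

    ``tables`` needs columns gene, site, meth_case, unmeth_case,
    meth_control, unmeth_control (reads pooled within group at each site).
    Adds two-sided p, the Bonferroni-adjusted q = min(1, m p) over the m
    rows tested, a significance flag at ``p <= fwer/m``, and the direction
    of change in cases versus controls ('+' hyper, '-' hypo, '' none).
    All-zero tables get p = 1 and are flagged.
    """
    out = tables.copy()
    m = len(out)
    pvals = np.ones(m)
    direction = []
    flagged = np.zeros(m, dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        a, b = int(row.meth_case), int(row.unmeth_case)
        c, d = int(row.meth_control), int(row.unmeth_control)
        if a + b + c + d == 0:
            pvals[i], flagged[i] = 1.0, True
            direction.append("")
            continue
        pvals[i] = fisher_exact_two_sided(a, b, c, d)
        f_case = a / (a + b) if a + b else float("nan")
        f_ctrl = c / (c + d) if c + d else float("nan")
        if np.isnan(f_case) or np.isnan(f_ctrl) or f_case == f_ctrl:
            direction.append("")
        else:
            direction.append("+" if f_case > f_ctrl else "-")
    out["p"] = pvals
    out["q"] = np.minimum(1.0, pvals * m)
    out["significant"] = pvals <= (fwer / m if m else np.inf)
    out["direction"] = direction
    out["empty_table"] = flagged
    return out


def build_site_tables(
    sites: pd.DataFrame, sample_sheet: pd.DataFrame, tissue: str
) -> pd.DataFrame:
    """Pool per-site methylated/unmethylated read counts within cases and
    controls for one tissue, from the per-library site table."""
    sheet = sample_sheet[["library_id", "group", "tissue"]]
    df = sites.merge(sheet, on="library_id")
    df = df[df["tissue"] == tissue].copy()
    df["case"] = df["group"] != "control"
    df["unmeth"] = df["total"] - df["methylated"]
    g = df.groupby(["gene", "site", "case"])[["methylated", "unmeth"]].sum().unstack(
        "case", fill_value=0
    )
    out = pd.DataFrame(
        {
            "gene": [i[0] for i in g.index],
            "site": [i[1] for i in g.index],
            "meth_case": g.get(("methylated", True), pd.Series(0, index=g.index)),
            "unmeth_case": g.get(("unmeth", True), pd.Series(0, index=g.index)),
            "meth_control": g.get(("methylated", False), pd.Series(0, index=g.index)),
            "unmeth_control": g.get(("unmeth", False), pd.Series(0, index=g.index)),
        }
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Co-methylation network
# ---------------------------------------------------------------------------

def variable_name(gene: str, tissue: str) -> str:
    return f"{'b' if tissue == 'blood' else 'n'}-{gene}"


def comethylation_network(
    wide: pd.DataFrame,
    stratum: str,
    fwer: float = DEFAULT_FWER_NETWORK,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> pd.DataFrame:
    """Spearman correlation network over (gene, tissue) mean-methylation
    variables for one stratum.

    ``wide`` is subjects x variables (columns named 'b-GENE'/'n-GENE',
    missing values allowed; correlations use pairwise-complete observations
    with at least ``min_pairs`` pairs). An edge is significant when its
    two-sided p-value passes Bonferroni at the given FWER over the number
    of pairs actually tested. Constant or under-covered pairs are skipped
    and reported with r = NaN and tested = False.
    """
    cols = list(wide.columns)
    arr = wide.to_numpy(dtype=float)
    fast = arr.size > 0 and not np.isnan(arr).any()
    if fast:
        # complete data: all pairwise Spearman r and t-approximation
        # p-values in one shot (identical to scipy.stats.spearmanr per pair)
        n_obs = arr.shape[0]
        ranks = sps.rankdata(arr, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rmat = np.corrcoef(ranks, rowvar=False)
            tstat = rmat * np.sqrt((n_obs - 2) / (1.0 - rmat**2))
            pmat = 2.0 * sps.t.sf(np.abs(tstat), n_obs - 2)
        pmat[np.isclose(np.abs(rmat), 1.0)] = 0.0
    rows = []
    for (i1, v1), (i2, v2) in itertools.combinations(enumerate(cols), 2):
        if fast:
            n = arr.shape[0]
            r, p = float(rmat[i1, i2]), float(pmat[i1, i2])
            tested = n >= min_pairs and np.isfinite(r)
            if not tested:
                r = p = float("nan")
        else:
            sub = wide[[v1, v2]].dropna()
            n = len(sub)
            tested = n >= min_pairs and sub[v1].nunique() > 1 and sub[v2].nunique() > 1
            if tested:
                r, p = sps.spearmanr(sub[v1], sub[v2])
                r, p = float(r), float(p)
            else:
                r, p = float("nan"), float("nan")
        rows.append(
            {
                "stratum": stratum, "var1": v1, "var2": v2, "n": n,
                "r": r, "p": p, "tested": tested,
                "inter_tissue": "-" in v1 and "-" in v2
                and v1.split("-", 1)[1] == v2.split("-", 1)[1],
            }
        )
    edges = pd.DataFrame(rows)
    m = int(edges["tested"].sum())
    edges["significant"] = edges["tested"] & (edges["p"] <= (fwer / m if m else np.inf))
    return edges


# ---------------------------------------------------------------------------
# Genotype-methylation association
# ---------------------------------------------------------------------------

def genotype_association(
    methylation: np.ndarray, dosage: np.ndarray
) -> tuple[float, float, int]:
    """Spearman correlation between allele dosage (0/1/2) and methylation.

    Pairs with missing values are dropped. Negative r means methylation
    decreases with each copy of the indexed allele. Returns (r, p, n);
    monomorphic dosages give (nan, nan, n).
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(methylation, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise StatsError("need at least 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan"), int(x.size)
    r, p = sps.spearmanr(x, y)
    return float(r), float(p), int(x.size)


# ---------------------------------------------------------------------------
# Assembling analysis tables from calling output
# ---------------------------------------------------------------------------

def build_region_table(
    regions: pd.DataFrame, sample_sheet: pd.DataFrame, retained_only: bool = True
) -> pd.DataFrame:
    """Join region means with sample metadata and average technical
    replicates, yielding one row per (subject, tissue, gene)."""
    keep = regions[regions["retained"]] if retained_only else regions
    df = keep.merge(
        sample_sheet[["library_id", "subject_id", "group", "tissue", "replicate"]],
        on="library_id",
    )
    return (
        df.groupby(["subject_id", "group", "tissue", "gene"], as_index=False)
        .agg(region_mean=("region_mean", "mean"), n_reads=("n_reads", "sum"))
    )


def region_wide(region_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the region table to subjects x 'b-GENE'/'n-GENE' variables."""
    df = region_table.copy()
    df["variable"] = [
        variable_name(g, t) for g, t in zip(df["gene"], df["tissue"])
    ]
    return df.pivot_table(
        index="subject_id", columns="variable", values="region_mean", aggfunc="mean"
    )


def replicate_pairs_logit(
    regions: pd.DataFrame, sample_sheet: pd.DataFrame, eps: float = 1e-3
) -> np.ndarray:
    """Extract (replicate 1, replicate 2) logit-scale pairs of region means
    for every duplicated (subject, tissue, gene) measurement; a replicate
    dropped by the coverage filter yields a missing value in its pair."""
    sheet = sample_sheet[["library_id", "subject_id", "tissue", "replicate"]]
    df = regions.merge(sheet, on="library_id")
    dup_subjects = (
        sheet.groupby(["subject_id", "tissue"])["replicate"].max().reset_index()
    )
    dup_subjects = dup_subjects[dup_subjects["replicate"] >= 2]
    pairs = []
    for _, row in dup_subjects.iterrows():
        sub = df[(df["subject_id"] == row["subject_id"]) & (df["tissue"] == row["tissue"])]
        for gene, block in sub.groupby("gene"):
            vals = []
            for rep in (1, 2):
                b = block[(block["replicate"] == rep) & block["retained"]]
                vals.append(
                    logit_transform(float(b["region_mean"].iloc[0]), eps=eps).value
                    if len(b)
                    else float("nan")
                )
            pairs.append(vals)
    return np.asarray(pairs, dtype=float)
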