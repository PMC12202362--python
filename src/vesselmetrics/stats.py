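"""Group-comparison statistics protocol for vascular metric tables.

Per metric cell (metric x zone x vessel class) across >= 2 groups:

1. each group is tested for normality (Kolmogorov-Smirnov; Lilliefors
   correction by default since the null parameters are estimated);
2. if every group passes at alpha, a one-way ANOVA is run and a
   variance-homogeneity gate (Levene, mean-centered) chooses the post hoc:
   Fisher's LSD (pooled-variance pairwise t, unadjusted) under homogeneous
   variances, Tamhane's T2 (pairwise Welch t with Sidak adjustment)
   otherwise;
3. if any group fails normality, a Kruskal-Wallis test replaces the ANOVA
   (no LSD/Tamhane post hoc is emitted on this branch).

All p-values are two-tailed; cells are flagged significant at alpha = 0.05.
Missing metric values (undefined cells) are dropped pairwise.  No
multiple-testing correction is applied by default (raw p-values are
reported); a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class SummaryGroup:
    """Summary statistics of one group: size, mean, standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class GroupComparisonResult:
    metric: str
    zone: str
    vessel_class: str
    group_names: list[str]
    group_n: list[int]
    group_mean: list[float]
    group_sd: list[float]
    normality_p: list[float]
    levene_p: float | None
    test: str  # "anova" | "kruskal" | "skipped"
    statistic: float
    p: float
    posthoc_method: str | None  # "LSD" | "tamhane_t2" | None
    posthoc_p: dict[tuple[str, str], float] | None
    significant: bool
    note: str = ""


@dataclass
class StatsConfig:
    alpha: float = 0.05
    normality_test: str = "lilliefors"  # or "ks" (plain, estimated params)
    min_cell_n: int = 3
    mtc: str | None = None  # None or "fdr_bh"


# ---------------------------------------------------------------------------
# elementary tests


def ks_normality(values, method: str = "lilliefors") -> float:
    """Normality p-value of one sample (K-S against a fitted normal).

    ``lilliefors`` corrects for the estimated mean/SD; ``ks`` is the plain
    one-sample K-S with plugged-in estimates, as some statistics packages
    compute it.  Constant samples are undefined (NaN).
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(x) == 0:
        return float("nan")
    if method == "lilliefors":
        return float(lilliefors(x, dist="norm")[1])
    if method == "ks":
        return float(sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
    raise ValueError(f"unknown normality test {method!r}")


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA on raw samples: (F, df_between, df_within, p)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


def anova_from_summary(groups: list[SummaryGroup]) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group (n, mean, SD) summaries.

    SSB = sum n_i (m_i - m_bar)^2, SSW = sum (n_i - 1) SD_i^2; this lets the
    test run on published group summaries without the raw observations.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g.n for g in groups], float)
    ms = np.array([g.mean for g in groups], float)
    sds = np.array([g.sd for g in groups], float)
    n_total = ns.sum()
    k = len(groups)
    grand = (ns * ms).sum() / n_total
    ssb = (ns * (ms - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, int(n_total) - k
    if ssw == 0:
        return (0.0, df1, df2, 1.0) if ssb == 0 else (float("inf"), df1, df2, 0.0)
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


def levene(groups: list[np.ndarray], center: str = "mean") -> float:
    """Levene variance-homogeneity p (absolute deviations from group means)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Levene needs >= 2 groups with n >= 2 each")
    return float(sps.levene(*groups, center=center).pvalue)


def posthoc_lsd(groups: list[np.ndarray], names: list[str] | None = None) -> dict:
    """Fisher's LSD: pairwise t with the pooled ANOVA MSW, df = N - k, raw p."""
    groups = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("LSD needs n >= 2 per group")
    names = names or [str(i) for i in range(len(groups))]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df = n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    out = {}
    for i, j in combinations(range(k), 2):
        gi, gj = groups[i], groups[j]
        se = np.sqrt(msw * (1 / len(gi) + 1 / len(gj)))
        if se == 0:
            out[(names[i], names[j])] = 1.0 if gi.mean() == gj.mean() else 0.0
            continue
        t = (gi.mean() - gj.mean()) / se
        out[(names[i], names[j])] = float(2 * sps.t.sf(abs(t), df))
    return out


def _welch(gi: np.ndarray, gj: np.ndarray) -> tuple[float, float]:
    vi, vj = gi.var(ddof=1) / len(gi), gj.var(ddof=1) / len(gj)
    se2 = vi + vj
    if se2 == 0:
        return (0.0, 1.0) if gi.mean() == gj.mean() else (float("inf"), 0.0)
    t = (gi.mean() - gj.mean()) / np.sqrt(se2)
    df = se2**2 / (vi**2 / (len(gi) - 1) + vj**2 / (len(gj) - 1))
    return float(t), float(2 * sps.t.sf(abs(t), df))


def posthoc_tamhane_t2(groups: list[np.ndarray], names: list[str] | None = None) -> dict:
    """Tamhane's T2: pairwise Welch t, Sidak-adjusted over the m comparisons."""
    groups = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("Tamhane T2 needs n >= 2 per group")
    names = names or [str(i) for i in range(len(groups))]
    pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    out = {}
    for i, j in pairs:
        _, p = _welch(groups[i], groups[j])
        out[(names[i], names[j])] = float(min(1.0, 1.0 - (1.0 - p) ** m))
    return out


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H and p (tie-corrected, chi-square with k-1 df)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return float("nan"), float("nan")
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def chi_square_table(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must hold non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero row or column sum")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# full protocol


def compare_groups(
    groups: list[np.ndarray],
    names: list[str],
    config: StatsConfig | None = None,
    metric: str = "",
    zone: str = "",
    vessel_class: str = "",
) -> GroupComparisonResult:
    """Run the gated protocol on one metric cell."""
    config = config or StatsConfig()
    groups = [np.asarray(g, float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    base = dict(metric=metric, zone=zone, vessel_class=vessel_class, group_names=list(names))
    if any(len(g) < config.min_cell_n for g in groups):
        return GroupComparisonResult(
            **base,
            group_n=[len(g) for g in groups],
            group_mean=[float(g.mean()) if len(g) else float("nan") for g in groups],
            group_sd=[float(g.std(ddof=1)) if len(g) > 1 else float("nan") for g in groups],
            normality_p=[float("nan")] * len(groups),
            levene_p=None,
            test="skipped",
            statistic=float("nan"),
            p=float("nan"),
            posthoc_method=None,
            posthoc_p=None,
            significant=False,
            note=f"group below minimum usable n = {config.min_cell_n}",
        )
    norm_p = []
    for g in groups:
        try:
            norm_p.append(ks_normality(g, config.normality_test))
        except ValueError:
            norm_p.append(float("nan"))
    all_normal = all(np.isnan(p) or p > config.alpha for p in norm_p)
    posthoc_method = None
    posthoc_p = None
    levene_p = None
    if all_normal:
        stat, _, _, p = one_way_anova(groups)
        test = "anova"
        levene_p = levene(groups)
        if len(groups) >= 3:
            if levene_p > config.alpha:
                posthoc_method = "LSD"
                posthoc_p = posthoc_lsd(groups, names)
            else:
                posthoc_method = "tamhane_t2"
                posthoc_p = posthoc_tamhane_t2(groups, names)
    else:
        stat, p = kruskal_wallis(groups)
        test = "kruskal"
    return GroupComparisonResult(
        **base,
        group_n=[len(g) for g in groups],
        group_mean=[float(g.mean()) for g in groups],
        group_sd=[float(g.std(ddof=1)) for g in groups],
        normality_p=norm_p,
        levene_p=levene_p,
        test=test,
        statistic=stat,
        p=p,
        posthoc_method=posthoc_method,
        posthoc_p=posthoc_p,
        significant=bool(np.isfinite(p) and p < config.alpha),
    )


_ID_COLS = ("eye_id", "zone", "vessel_class", "group")


def compare_metric_across_groups(
    metric_table: pd.DataFrame,
    grouping: pd.DataFrame | dict[str, str],
    config: StatsConfig | None = None,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Apply the protocol to every metric x zone x class cell of a table.

    ``metric_table`` is the output of :func:`vesselmetrics.metrics.metrics_by_zone`
    stacked over eyes; ``grouping`` maps eye_id -> group label (dict or a
    DataFrame with eye_id/group columns).  Returns one row per cell with the
    gate p-values, the test used, its p and the post hoc pairs (JSON-ish
    string column).  Optionally applies Benjamini-Hochberg across cells.
    """
    config = config or StatsConfig()
    table = metric_table.copy()
    if isinstance(grouping, pd.DataFrame):
        grouping = dict(zip(grouping["eye_id"], grouping["group"]))
    if "group" not in table.columns:
        table["group"] = table["eye_id"].map(grouping)
    if table["group"].isna().any():
        missing = table.loc[table["group"].isna(), "eye_id"].unique().tolist()
        raise ValueError(f"eyes without a group label: {missing}")
    if metrics is None:
        metrics = [c for c in table.columns if c not in _ID_COLS and table[c].dtype.kind == "f"]
    group_names = sorted(table["group"].unique())
    rows = []
    for (zone, cls), cell in table.groupby(["zone", "vessel_class"], sort=True):
        for m in metrics:
            samples = [cell.loc[cell["group"] == g, m].to_numpy() for g in group_names]
            res = compare_groups(samples, group_names, config, m, zone, cls)
            rows.append(
                {
                    "metric": m,
                    "zone": zone,
                    "vessel_class": cls,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p,
                    "significant": res.significant,
                    "levene_p": res.levene_p,
                    "posthoc_method": res.posthoc_method,
                    "posthoc_p": (
                        "; ".join(f"{a}|{b}={p:.4g}" for (a, b), p in res.posthoc_p.items())
                        if res.posthoc_p
                        else ""
                    ),
                    **{f"n_{g}": n for g, n in zip(group_names, res.group_n)},
                    **{f"mean_{g}": v for g, v in zip(group_names, res.group_mean)},
                    **{f"sd_{g}": v for g, v in zip(group_names, res.group_sd)},
                    **{f"normality_p_{g}": v for g, v in zip(group_names, res.normality_p)},
                    "note": res.note,
                }
            )
    out = pd.DataFrame(rows)
    if config.mtc == "fdr_bh" and len(out):
        usable = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if usable.any():
            adj[usable.to_numpy()] = multipletests(out.loc[usable, "p"], method="fdr_bh")[1]
        out["p_adj"] = adj
        out["significant"] = out["p_adj"] < config.alpha
    return out
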