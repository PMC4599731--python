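"""Descriptive and hypothesis statistics for route records.

The battery mirrors a standard movement-ecology workflow at a receiver
curtain: width-weighted strait-use binomial tests, uniformity of the
cross-strait distribution, one-sample signed-rank tests of east-west
displacement against zero, two-sample rank-sum comparisons between species,
Kendall's tau-b between milling duration and displacement, release-group
weighted ANOVA of route proportions with Tukey HSD, Welch t-tests between
species, Fisher's exact test of survival by entry strait, and Pearson
confounding checks against migration rate.

Exact null distributions are used for the rank tests whenever the sample is
small (n <= 25) and tie-free; otherwise the normal approximation with
continuity correction is used.  No multiplicity correction is applied
across the battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ReceiverArrayGeometry

__all__ = [
    "TestResult",
    "strait_use_test",
    "uniformity_test",
    "signed_rank_zero_test",
    "ranksum_test",
    "kendall_tau",
    "route_proportion_anova",
    "species_proportion_ttest",
    "fisher_2x2",
    "confound_correlations",
    "big_westward_tally",
    "duration_by_route",
    "tukey_hsd_weighted",
]

EXACT_N_MAX = 25


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    estimates: dict = field(default_factory=dict)
    groups: tuple = ()
    pairwise: pd.DataFrame | None = None

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def strait_use_test(p_initial: np.ndarray, geom: ReceiverArrayGeometry) -> TestResult:
    """Exact binomial test of eastern-channel (Malaspina) arrivals against
    the proportion expected from relative strait width (receiver count)."""
    p_initial = np.asarray(p_initial, dtype=int)
    n = len(p_initial)
    if n == 0:
        raise ValueError("strait_use_test needs at least one arrival position")
    expected = len(geom.malaspina_indices) / geom.n_receivers
    k = int(sum(1 for i in p_initial if i in geom.malaspina_indices))
    res = stats.binomtest(k, n, expected, alternative="two-sided")
    return TestResult(
        "strait_use_binomial",
        float(k),
        res.pvalue,
        n,
        {"observed_proportion": k / n, "expected_proportion": expected},
    )


def uniformity_test(receivers: np.ndarray, geom: ReceiverArrayGeometry) -> TestResult:
    """Chi-square goodness of fit of per-receiver counts against uniformity."""
    receivers = np.asarray(receivers, dtype=int)
    n = len(receivers)
    counts = np.bincount(receivers, minlength=geom.n_receivers + 1)[1:]
    stat, p = stats.chisquare(counts)
    return TestResult("uniformity_chisq", float(stat), float(p), n)


def _exact_ok(values: np.ndarray) -> bool:
    return len(values) <= EXACT_N_MAX and len(np.unique(np.abs(values))) == len(values)


def signed_rank_zero_test(values: np.ndarray) -> TestResult:
    """One-sample Wilcoxon signed-rank test of signed displacements against
    zero.  Exact zeros are discarded (classical zero-drop convention); a
    degenerate all-zero sample returns p = 1 with a warning."""
    values = np.asarray(values, dtype=float)
    n_total = len(values)
    nz = values[values != 0.0]
    if len(nz) == 0:
        warnings.warn("signed-rank test degenerate: all values zero", stacklevel=2)
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, n_total, {"n_nonzero": 0})
    method = "exact" if _exact_ok(nz) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method, correction=(method == "approx"))
    return TestResult(
        "wilcoxon_signed_rank",
        float(res.statistic),
        float(res.pvalue),
        n_total,
        {"n_nonzero": len(nz), "mean": float(values.mean()), "median": float(np.median(values))},
    )


def ranksum_test(values_a: np.ndarray, values_b: np.ndarray) -> TestResult:
    """Two-sample Mann-Whitney U test; reports min(U, n1*n2 - U)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ranksum_test requires two nonempty samples")
    pooled = np.concatenate([a, b])
    exact = (
        max(len(a), len(b)) <= EXACT_N_MAX and len(np.unique(pooled)) == len(pooled)
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u = float(res.statistic)
    u_min = min(u, len(a) * len(b) - u)
    return TestResult(
        "mann_whitney_u",
        u_min,
        float(res.pvalue),
        len(a) + len(b),
        {"mean_a": float(a.mean()), "mean_b": float(b.mean())},
    )


def kendall_tau(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Kendall's tau-b (tie-corrected) correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("kendall_tau requires paired samples of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("kendall_tau undefined for a zero-variance variable")
    res = stats.kendalltau(x, y, variant="b")
    return TestResult("kendall_tau_b", float(res.statistic), float(res.pvalue), len(x), {"tau": float(res.statistic)})


def _weighted_anova(groups: list[np.ndarray], weights: list[np.ndarray]):
    """One-way fixed-effects ANOVA with case weights.

    Each observation i in group g carries weight w_gi; group means are
    weighted means, sums of squares are weight-metric sums.  Equivalent to
    the F-test of a WLS fit of y ~ group with those case weights.
    """
    k = len(groups)
    n_obs = sum(len(g) for g in groups)
    W = [float(np.sum(w)) for w in weights]
    means = [float(np.sum(w * g) / Wg) for g, w, Wg in zip(groups, weights, W)]
    grand = sum(Wg * m for Wg, m in zip(W, means)) / sum(W)
    ssb = sum(Wg * (m - grand) ** 2 for Wg, m in zip(W, means))
    ssw = sum(float(np.sum(w * (g - m) ** 2)) for g, w, m in zip(groups, weights, means))
    df_b, df_w = k - 1, n_obs - k
    if df_w <= 0:
        raise ValueError("not enough replicates for ANOVA")
    msw = ssw / df_w
    if msw == 0.0:
        f = 0.0 if ssb == 0.0 else np.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f = (ssb / df_b) / msw
        p = float(stats.f.sf(f, df_b, df_w))
    return f, p, means, W, msw, df_w


def tukey_hsd_weighted(
    labels: list, groups: list[np.ndarray], weights: list[np.ndarray]
) -> pd.DataFrame:
    """Tukey-Kramer HSD pairwise table using the weighted model's error
    variance; the effective group size is the group's total weight."""
    _, _, means, W, msw, df_w = _weighted_anova(groups, weights)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = means[i] - means[j]
            se = np.sqrt(msw / 2.0 * (1.0 / W[i] + 1.0 / W[j]))
            if se == 0.0:
                q, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, len(groups), df_w))
            rows.append({"group_a": labels[i], "group_b": labels[j], "diff": diff, "q": q, "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


def route_proportion_anova(tallies: pd.DataFrame) -> TestResult:
    """Weighted one-way ANOVA comparing the three route classes' proportions,
    with release groups as replicates and the number of route-classified fish
    per group as case weights; Tukey HSD pairwise comparisons attached."""
    t = tallies[tallies["n_classified"] > 0]
    labels = ["linear", "counterclockwise", "clockwise"]
    cols = ["prop_linear", "prop_counterclockwise", "prop_clockwise"]
    groups = [t[c].to_numpy(dtype=float) for c in cols]
    weights = [t["n_classified"].to_numpy(dtype=float) for _ in cols]
    if any(len(g) < 2 for g in groups):
        raise ValueError("route_proportion_anova needs >= 2 release groups per route class")
    f, p, means, _, _, _ = _weighted_anova(groups, weights)
    pairwise = tukey_hsd_weighted(labels, groups, weights)
    return TestResult(
        "route_proportion_weighted_anova",
        float(f),
        float(p),
        sum(len(g) for g in groups),
        dict(zip((f"mean_prop_{l}" for l in labels), means)),
        tuple(labels),
        pairwise,
    )


def species_proportion_ttest(props_a: np.ndarray, props_b: np.ndarray) -> TestResult:
    """Welch two-sample t-test on release-group route proportions."""
    a = np.asarray(props_a, dtype=float)
    b = np.asarray(props_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("species_proportion_ttest needs >= 2 release groups per species")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        "welch_t",
        float(res.statistic),
        float(res.pvalue),
        len(a) + len(b),
        {"mean_a": float(a.mean()), "mean_b": float(b.mean())},
    )


def fisher_2x2(table: np.ndarray) -> TestResult:
    """Fisher's exact test on a 2x2 contingency table with the conditional
    maximum-likelihood odds ratio."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("fisher_2x2 requires a nonnegative 2x2 integer table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("a margin of the 2x2 table is zero; odds ratio undefined", stacklevel=2)
        return TestResult("fisher_exact", np.nan, 1.0, int(table.sum()), {"odds_ratio": np.nan})
    _, p = stats.fisher_exact(table, alternative="two-sided")
    orr = stats.contingency.odds_ratio(table, kind="conditional")
    return TestResult(
        "fisher_exact", float(orr.statistic), float(p), int(table.sum()), {"odds_ratio": float(orr.statistic)}
    )


CONFOUND_VARS = ("p_initial", "julian_day", "duration12_h")


def confound_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of candidate survival covariates with migration
    rate: time from release to the upstream curtain (all fish) and time from
    there to the downstream curtain (survivors only)."""
    rows = []
    targets = [
        ("entry_to_nsog_days", records),
        ("nsog_to_qcs_days", records[records["survived_qcs"] == True]),  # noqa: E712
    ]
    for target, frame in targets:
        for var in CONFOUND_VARS:
            sub = frame[[var, target]].dropna()
            if len(sub) < 3:
                warnings.warn(f"skipping correlation {var} vs {target}: n < 3", stacklevel=2)
                continue
            r, p = stats.pearsonr(sub[var], sub[target])
            rows.append({"variable": var, "against": target, "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows, columns=["variable", "against", "r", "p", "n"])


def big_westward_tally(records: pd.DataFrame, threshold_km: float = 8.0) -> pd.DataFrame:
    """Count multi-sequence smolts per species whose first lateral displacement
    is westward and at least ``threshold_km`` in magnitude.  Island-spanning
    moves necessarily exceed the default threshold (minimum spanning
    magnitude 0.8 + 8.0 km), so they are included by construction."""
    rows = []
    for species, grp in records.groupby("species"):
        multi = grp.dropna(subset=["dx12_km"])
        big = multi[(multi["dx12_km"] < 0) & (multi["dx12_km"].abs() >= threshold_km)]
        n_multi = len(multi)
        rows.append(
            {
                "species": species,
                "n_multi_sequence": n_multi,
                "n_big_westward": len(big),
                "fraction": len(big) / n_multi if n_multi else np.nan,
            }
        )
    return pd.DataFrame(rows)


def duration_by_route(records: pd.DataFrame) -> TestResult:
    """One-way ANOVA of downstream transit duration (survivors) across route
    classes, with Tukey HSD and per-route means/SDs."""
    from .routes import ROUTE_CLASSES

    surv = records[(records["survived_qcs"] == True) & records["nsog_to_qcs_days"].notna()]  # noqa: E712
    groups, labels, means = [], [], {}
    for route in ROUTE_CLASSES:
        vals = surv.loc[surv["route"] == route, "nsog_to_qcs_days"].to_numpy(dtype=float)
        if len(vals) < 2:
            if len(vals) > 0:
                warnings.warn(f"route {route} has < 2 survivors; dropped from ANOVA", stacklevel=2)
            continue
        groups.append(vals)
        labels.append(route)
        means[f"mean_{route.lower()}"] = float(vals.mean())
        means[f"sd_{route.lower()}"] = float(vals.std(ddof=1))
    if len(groups) < 2:
        raise ValueError("duration_by_route needs >= 2 route classes with >= 2 survivors")
    weights = [np.ones_like(g) for g in groups]
    f, p, _, _, _, _ = _weighted_anova(groups, weights)
    pairwise = tukey_hsd_weighted(labels, groups, weights)
    return TestResult(
        "duration_by_route_anova", float(f), float(p), sum(len(g) for g in groups), means, tuple(labels), pairwise
    )
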