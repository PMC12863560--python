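"""Classical statistics for cohort screening and group comparison.

Implements the screening and comparison machinery used around the curve
fits: single-outlier Grubbs screening, Welch two-sample tests, a Pearson
correlation matrix, extra-sum-of-squares F comparisons of nested curve
fits (shared vs per-group parameters), and a two-way mixed-design
repeated-measures ANOVA with Greenhouse–Geisser correction.

All tests are two-sided at α = 0.05 by default and no multiple-testing
correction is applied anywhere in this module — fractions of "significant"
variables reported downstream are therefore descriptive, not
family-wise-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable, VariableTable
from .demand import _fit_q0_alpha, build_demand_curve
from .iudr import GaussianDoseResponse

__all__ = [
    "GrubbsResult",
    "WelchResult",
    "PearsonMatrix",
    "CurveComparisonResult",
    "AnovaResult",
    "grubbs_test",
    "grubbs_critical_value",
    "welch_t",
    "pearson_matrix",
    "compare_gaussian_curves",
    "compare_demand_curves",
    "rm_anova",
]


# ---------------------------------------------------------------------------
# Grubbs single-outlier screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrubbsResult:
    statistic: float          # max |x - mean| / sd (NaN if sd == 0)
    outlier_id: str | None    # flagged identifier, or None
    critical_value: float
    sample_mean: float
    sample_sem: float
    alpha: float

    def to_dict(self):
        return self.__dict__.copy()


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile.

    G_crit = (n−1)/√n · sqrt(t² / (n−2+t²)) with t the upper
    α/(2n) quantile of t with n−2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, ids=None, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-pass Grubbs test.

    Flags the most extreme observation if its standardized deviation from
    the sample mean exceeds the critical value.  With zero variance the
    statistic is undefined and nothing is flagged.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = list(ids)
    if len(ids) != n:
        raise ValueError("ids must align with values")
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    sem = sd / np.sqrt(n)
    crit = grubbs_critical_value(n, alpha)
    if sd == 0:
        return GrubbsResult(float("nan"), None, crit, mean, sem, alpha)
    dev = np.abs(values - mean)
    g = float(dev.max() / sd)
    outlier = ids[int(np.argmax(dev))] if g > crit else None
    return GrubbsResult(g, outlier, crit, mean, sem, alpha)


# ---------------------------------------------------------------------------
# Welch's t and Pearson correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float      # Welch–Satterthwaite, fractional
    p: float       # two-sided
    mean_a: float
    mean_b: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    def to_dict(self):
        return self.__dict__.copy()


def welch_t(group_a, group_b) -> WelchResult:
    """Unpaired two-sample t-test with Welch's correction, two-sided."""
    import warnings

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    with warnings.catch_warnings():
        # identical constant groups trip scipy's precision warning; that
        # degenerate case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):  # identical constant groups
        t, p = 0.0, 1.0
    return WelchResult(t, float(res.df) if np.isfinite(res.df) else float(a.size + b.size - 2),
                       p, float(a.mean()), float(b.mean()))


@dataclass
class PearsonMatrix:
    variables: list[str]
    r: pd.DataFrame    # correlation coefficients
    p: pd.DataFrame    # two-sided p-values
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def significant_pairs(self, alpha: float = 0.05):
        out = []
        for i, vi in enumerate(self.variables):
            for j, vj in enumerate(self.variables):
                if j > i and self.p.iloc[i, j] < alpha:
                    out.append((vi, vj))
        return out

    def to_dict(self):
        return {"variables": self.variables,
                "r": self.r.values, "p": self.p.values,
                "undefined": [list(t) for t in self.undefined]}


def pearson_matrix(table: VariableTable) -> PearsonMatrix:
    """Pairwise Pearson r and two-sided p for every pair of variables.

    Zero-variance columns are flagged in ``undefined`` and their entries
    set to r=0, p=1 rather than propagating NaN.
    """
    if table.n_subjects < 3:
        raise ValueError("need >= 3 subjects")
    names = table.variables
    if len(names) < 2:
        raise ValueError("need >= 2 variables")
    m = len(names)
    R = np.eye(m)
    P = np.zeros((m, m))
    undefined = []
    sds = table.values.std(axis=0, ddof=1)
    for i in range(m):
        for j in range(i + 1, m):
            if sds[i] == 0 or sds[j] == 0:
                undefined.append((names[i], names[j]))
                R[i, j] = R[j, i] = 0.0
                P[i, j] = P[j, i] = 1.0
                continue
            r, p = sps.pearsonr(table.values[:, i], table.values[:, j])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    return PearsonMatrix(list(names),
                         pd.DataFrame(R, index=names, columns=names),
                         pd.DataFrame(P, index=names, columns=names),
                         undefined)


# ---------------------------------------------------------------------------
# Extra-sum-of-squares curve comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveComparisonResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    shared_sse: float
    separate_sse: float

    def to_dict(self):
        return self.__dict__.copy()


def _resolve_partition(cohort_subjects, partition):
    """Accept a GroupAssignment-like object, a labels mapping, or a pair of
    id collections; return two ordered id lists covering the cohort."""
    if hasattr(partition, "low_ids") and hasattr(partition, "high_ids"):
        groups = [list(partition.low_ids), list(partition.high_ids)]
    elif hasattr(partition, "labels"):  # ClusterResult
        lab = partition.labels
        uniq = sorted(set(lab.values()))
        if len(uniq) != 2:
            raise ValueError("need exactly two groups")
        groups = [[s for s in cohort_subjects if lab[s] == u] for u in uniq]
    elif isinstance(partition, dict):
        uniq = sorted(set(partition.values()))
        if len(uniq) != 2:
            raise ValueError("need exactly two groups")
        groups = [[s for s in cohort_subjects if partition[s] == u] for u in uniq]
    else:
        groups = [list(g) for g in partition]
        if len(groups) != 2:
            raise ValueError("need exactly two groups")
    known = set(cohort_subjects)
    for g in groups:
        missing = [s for s in g if s not in known]
        if missing:
            raise ValueError(f"unknown subjects in partition: {missing}")
    return groups


def _extra_ss_f(shared_sse, separate_sse, df_num, df_den):
    separate_sse = min(separate_sse, shared_sse)  # nested models; numeric guard
    f = ((shared_sse - separate_sse) / df_num) / (separate_sse / df_den)
    return CurveComparisonResult(float(f), int(df_num), int(df_den),
                                 float(sps.f.sf(f, df_num, df_den)),
                                 float(shared_sse), float(separate_sse))


def _pooled_gaussian_sse(cohort: CohortTable, subjects) -> float:
    """SSE of one 3-parameter log-log Gaussian fitted to the pooled
    per-subject log10 responses of ``subjects`` at the nonzero doses."""
    nz = cohort.doses > 0
    doses = np.tile(cohort.doses[nz], len(subjects))
    resp = np.concatenate([cohort.row(s)[nz] for s in subjects])
    res = GaussianDoseResponse(doses, resp).fit()
    return res.params.residual_ss


def compare_gaussian_curves(cohort: CohortTable, partition) -> CurveComparisonResult:
    """Shared vs per-group Gaussian dose-response curves.

    Pools each subject's log10 responses at the nonzero doses (individual
    points, not group means), fits one shared 3-parameter curve against
    separate per-group curves (6 parameters), and reports the
    extra-sum-of-squares F with df = (3, n_points − 6): the joint test of
    whether amplitude, mean and width differ between the groups.
    """
    groups = _resolve_partition(cohort.subjects, partition)
    n_nz = int(np.sum(cohort.doses > 0))
    for g in groups:
        if len(g) * n_nz < 4:
            raise ValueError("each group needs >= 4 usable points")
    shared = _pooled_gaussian_sse(cohort, groups[0] + groups[1])
    separate = sum(_pooled_gaussian_sse(cohort, g) for g in groups)
    n_points = n_nz * (len(groups[0]) + len(groups[1]))
    return _extra_ss_f(shared, separate, 3, n_points - 6)


def _group_mean_demand(cohort: CohortTable, subjects):
    nz = cohort.doses > 0
    mean_resp = np.mean([cohort.row(s) for s in subjects], axis=0)
    return build_demand_curve(cohort.doses, mean_resp, cohort.fixed_ratio)


def _demand_sse(curves, k, share_q0, share_alpha):
    """SSE of the exponential demand model over one or two group curves
    with the requested parameters shared across groups, k always fixed."""
    if len(curves) == 1 or (share_q0 and share_alpha):
        prices = np.concatenate([c.prices for c in curves])
        logq = np.concatenate([np.log10(c.consumptions) for c in curves])
        _, sse = _fit_q0_alpha(prices, logq, k)
        return sse
    if not share_q0 and not share_alpha:
        return sum(_demand_sse([c], k, True, True) for c in curves)

    # one parameter shared, the other per-group: 3 free parameters
    from scipy.optimize import least_squares

    p0s, l0s = [], []
    for c in curves:
        (lq0, la), _ = _fit_q0_alpha(c.prices, np.log10(c.consumptions), k)
        p0s.append(lq0)
        l0s.append(la)

    def residuals(theta):
        if share_alpha:
            la1 = la2 = theta[0]
            lq01, lq02 = theta[1], theta[2]
        else:
            lq01 = lq02 = theta[0]
            la1, la2 = theta[1], theta[2]
        out = []
        for c, lq0, la in zip(curves, (lq01, lq02), (la1, la2)):
            pred = lq0 + k * (np.exp(-(10.0**la) * (10.0**lq0) * c.prices) - 1.0)
            out.append(pred - np.log10(c.consumptions))
        return np.concatenate(out)

    if share_alpha:
        theta0 = [np.mean(l0s), p0s[0], p0s[1]]
    else:
        theta0 = [np.mean(p0s), l0s[0], l0s[1]]
    sol = least_squares(residuals, theta0, xtol=1e-14, ftol=1e-14)
    return 2.0 * sol.cost


def compare_demand_curves(cohort: CohortTable, partition, k: float,
                          scope: str = "both") -> CurveComparisonResult:
    """Shared vs per-group exponential demand curves at a fixed k.

    Demand points are built from the *group-mean* responses at the nonzero
    doses (one curve per group), k held fixed throughout.  ``scope``
    chooses the null hypothesis: "both" shares (Q0, α) in the null
    (df_num = 2), "alpha" shares only α, "q0" shares only Q0
    (df_num = 1).  The alternative always frees all four per-group
    parameters, so df_den = n_points − 4.
    """
    if scope not in {"both", "alpha", "q0"}:
        raise ValueError("scope must be 'both', 'alpha' or 'q0'")
    groups = _resolve_partition(cohort.subjects, partition)
    curves = [_group_mean_demand(cohort, g) for g in groups]
    n_points = sum(c.n_points for c in curves)
    separate = _demand_sse(curves, k, False, False)
    if scope == "both":
        shared = _demand_sse(curves, k, True, True)
        df_num = 2
    elif scope == "alpha":
        shared = _demand_sse(curves, k, False, True)
        df_num = 1
    else:
        shared = _demand_sse(curves, k, True, False)
        df_num = 1
    return _extra_ss_f(shared, separate, df_num, n_points - 4)


# ---------------------------------------------------------------------------
# Mixed-design repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Two-way mixed ANOVA: between = group, within = dose.

    ``effects`` is a per-effect table with uncorrected F, df, p and
    Greenhouse–Geisser-corrected df/p for the within-subject effects;
    ``epsilon`` the GG sphericity estimate.
    """

    effects: pd.DataFrame
    epsilon: float
    scale: str

    def effect(self, name: str) -> pd.Series:
        return self.effects.loc[name]

    def to_dict(self):
        return {"epsilon": self.epsilon, "scale": self.scale,
                "effects": {idx: row.to_dict()
                            for idx, row in self.effects.iterrows()}}


def rm_anova(cohort: CohortTable, partition, scale: str = "log10") -> AnovaResult:
    """Mixed-design ANOVA on responses at the nonzero doses.

    Between-subject factor: group (2 levels); within-subject factor: dose.
    The response is log10 infusions by default (consistent with the
    curve fits); ``scale='raw'`` analyses untransformed counts.
    Greenhouse–Geisser correction is applied to the within-subject
    effects (dose and the interaction); the between-group effect is
    unaffected by sphericity.
    """
    import pingouin as pg

    if scale not in {"log10", "raw"}:
        raise ValueError("scale must be 'log10' or 'raw'")
    groups = _resolve_partition(cohort.subjects, partition)
    membership = {s: gi for gi, g in enumerate(groups) for s in g}
    nz = np.flatnonzero(cohort.doses > 0)
    rows = []
    for s in groups[0] + groups[1]:
        resp = cohort.row(s)
        for j in nz:
            y = resp[j]
            rows.append({
                "subject": s,
                "dose": f"{cohort.doses[j]:g}",
                "group": f"g{membership[s]}",
                "y": np.log10(y) if scale == "log10" else y,
            })
    df = pd.DataFrame(rows)
    aov = pg.mixed_anova(df, dv="y", within="dose", subject="subject",
                         between="group", correction=True)
    aov = aov.set_index("Source")
    eps = float(aov.loc["dose", "eps"])
    n_levels = len(nz)
    table = pd.DataFrame(index=["group", "dose", "interaction"],
                         columns=["F", "df1", "df2", "p", "df1_gg", "df2_gg",
                                  "p_gg"], dtype=float)
    for name, src in [("group", "group"), ("dose", "dose"),
                      ("interaction", "Interaction")]:
        row = aov.loc[src]
        F, d1, d2 = float(row["F"]), float(row["DF1"]), float(row["DF2"])
        p_unc = float(row["p_unc"] if "p_unc" in row else row["p-unc"])
        table.loc[name, ["F", "df1", "df2", "p"]] = [F, d1, d2, p_unc]
        if name == "group":
            table.loc[name, ["df1_gg", "df2_gg", "p_gg"]] = [d1, d2, p_unc]
        else:
            d1c, d2c = eps * d1, eps * d2
            table.loc[name, ["df1_gg", "df2_gg", "p_gg"]] = [
                d1c, d2c, float(sps.f.sf(F, d1c, d2c))]
    if not (1.0 / (n_levels - 1) < eps <= 1.0 + 1e-12):
        raise RuntimeError(f"Greenhouse-Geisser epsilon {eps} out of range")
    return AnovaResult(table, eps, scale)
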