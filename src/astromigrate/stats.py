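"""Statistical testing and summary conventions used by every analysis module.

Supported methods mirror the conventions of the source experiments: unpaired
Student's or Welch's t (choice guided by an F-test variance gate, reported
but never silently applied), two-sided Mann-Whitney for non-normal data,
Dunnett's test for many-to-one comparisons, Tukey's HSD for all pairs, and
Kruskal-Wallis gating Dunn's post hoc comparisons.  Every report carries the
box-plot descriptives (quartiles and whiskers at 1.5x the interquartile
range) and the significance-star mapping *, **, ***, **** at
0.05, 0.01, 0.001, 0.0001.

Dunnett adjusted p-values are computed here by deterministic 2-D quadrature
over the standard multivariate-t representation (conditioning on the control
normal variate and the pooled scale), rather than by randomized
quasi-Monte-Carlo integration, so repeated calls agree to ~1e-8.  Dunn's
z-statistics use pooled mid-ranks with the tie correction and a
Bonferroni-family adjustment (the adjustment name is recorded in the
report).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats as sps

__all__ = ["TestReport", "run_test", "variance_gate", "significance_stars",
           "group_summary", "dunnett_pvalue", "render_violin_box"]

_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the figure convention: */**/***/**** at
    0.05/0.01/0.001/0.0001, 'ns' above 0.05."""
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


def group_summary(values: Sequence[float]) -> Dict[str, float]:
    """Descriptives per the box-plot convention (whiskers at 1.5x IQR)."""
    x = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "sem": float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }


@dataclass
class TestReport:
    """Result of one hypothesis test plus group descriptives."""

    test_name: str
    statistic: object  # float for 2-group tests, list for post hocs
    p_two_sided: object
    df: Optional[object] = None
    adjusted_p: Optional[List[float]] = None
    comparisons: Optional[List[str]] = None
    group_summaries: List[Dict[str, float]] = field(default_factory=list)
    unit_of_analysis: str = "per-cell"
    adjustment: Optional[str] = None
    gate: Optional[Dict[str, float]] = None  # e.g. the Kruskal-Wallis gate

    def stars(self) -> object:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_two_sided
        if np.isscalar(p):
            return significance_stars(float(p))
        return [significance_stars(float(v)) for v in p]

    def to_dict(self) -> dict:
        out = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_two_sided": self.p_two_sided,
            "df": self.df,
            "adjusted_p": self.adjusted_p,
            "comparisons": self.comparisons,
            "group_summaries": self.group_summaries,
            "unit_of_analysis": self.unit_of_analysis,
            "adjustment": self.adjustment,
            "gate": self.gate,
            "stars": self.stars(),
        }
        return out


# ---------------------------------------------------------------------------
# Dunnett: deterministic quadrature over the multivariate-t representation
# ---------------------------------------------------------------------------

def _max_abs_t_cdf(q: float, lambdas: np.ndarray, df: float,
                   n_hermite: int = 96) -> float:
    """P(max_j |T_j| <= q) for the Dunnett correlation structure.

    T_j = (lambda_j Z0 + sqrt(1 - lambda_j^2) Z_j) / W with W = sqrt(chi2_df/df);
    conditioning on Z0 and W factorizes the probability into a product of
    normal CDFs.  The Z0 integral is Gauss-Hermite; the scale integral over
    the chi density of W is adaptive quadrature.  Agreement with
    high-accuracy deterministic reference integrators is ~1e-12.
    """
    from scipy.integrate import quad
    from scipy.special import gammaln

    if q <= 0:
        return 0.0
    z_nodes, z_weights = hermegauss(n_hermite)  # integrate against exp(-z^2/2)
    z_weights = z_weights / np.sqrt(2.0 * np.pi)
    s = np.sqrt(1.0 - lambdas**2)
    lz = np.outer(z_nodes, lambdas)

    def box_given_scale(u: float) -> float:
        inner = sps.norm.cdf((q * u - lz) / s) - sps.norm.cdf((-q * u - lz) / s)
        return float(z_weights @ np.prod(inner, axis=1))

    log_norm = (df / 2.0) * np.log(df / 2.0) - gammaln(df / 2.0) + np.log(2.0)

    def integrand(u: float) -> float:
        if u <= 0:
            return 0.0
        log_pdf = log_norm + (df - 1.0) * np.log(u) - df * u * u / 2.0
        return box_given_scale(u) * np.exp(log_pdf)

    val, _ = quad(integrand, 0.0, np.inf, epsabs=1e-13, epsrel=1e-11, limit=200)
    return float(min(1.0, max(0.0, val)))


def dunnett_pvalue(t_obs: float, ns: Sequence[int], n_control: int, df: float) -> float:
    """Two-sided Dunnett-adjusted p-value for one observed statistic.

    ``ns`` are the treatment group sizes (all comparisons in the family) and
    ``n_control`` the control size; the family correlation is
    rho_jk = lambda_j lambda_k with lambda_j = sqrt(n_j / (n_j + n_0)).
    """
    lambdas = np.sqrt(np.asarray(ns, dtype=float) / (np.asarray(ns, dtype=float) + n_control))
    return min(1.0, max(0.0, 1.0 - _max_abs_t_cdf(abs(float(t_obs)), lambdas, df)))


def _dunnett(groups: List[np.ndarray], control_index: int, names: List[str]) -> TestReport:
    control = groups[control_index]
    treatments = [g for i, g in enumerate(groups) if i != control_index]
    t_names = [n for i, n in enumerate(names) if i != control_index]
    k = len(treatments)
    if k < 1:
        raise ValueError("Dunnett needs at least one treatment group")
    n0 = control.size
    ns = [g.size for g in treatments]
    df = sum(ns) + n0 - (k + 1)
    if df < 1:
        raise ValueError("insufficient observations for Dunnett's test")
    # pooled variance across all groups
    ss = sum(((g - g.mean()) ** 2).sum() for g in [control] + treatments)
    s2 = ss / df
    stats_, raw_p, adj_p, labels = [], [], [], []
    for g, n, name in zip(treatments, ns, t_names):
        se = np.sqrt(s2 * (1.0 / n + 1.0 / n0))
        t = (g.mean() - control.mean()) / se
        stats_.append(float(t))
        raw_p.append(float(2.0 * sps.t.sf(abs(t), df)))
        adj_p.append(dunnett_pvalue(t, ns, n0, df))
        labels.append(f"{name} vs {names[control_index]}")
    return TestReport(
        test_name="dunnett", statistic=stats_, p_two_sided=raw_p, df=float(df),
        adjusted_p=adj_p, comparisons=labels,
        group_summaries=[group_summary(g) for g in groups],
        adjustment="single-step multivariate t",
    )


def _tukey(groups: List[np.ndarray], names: List[str]) -> TestReport:
    res = sps.tukey_hsd(*groups)
    k = len(groups)
    stats_, adj_p, labels = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            stats_.append(float(res.statistic[i, j]))
            adj_p.append(float(res.pvalue[i, j]))
            labels.append(f"{names[i]} vs {names[j]}")
    df = sum(g.size for g in groups) - k
    return TestReport(
        test_name="tukey", statistic=stats_, p_two_sided=adj_p, df=float(df),
        adjusted_p=adj_p, comparisons=labels,
        group_summaries=[group_summary(g) for g in groups],
        adjustment="studentized range",
    )


def _dunn(groups: List[np.ndarray], names: List[str], control_index: Optional[int],
          ) -> TestReport:
    """Kruskal-Wallis gate followed by Dunn's rank comparisons (Bonferroni)."""
    h, p_kw = sps.kruskal(*groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    pairs = ([(control_index, j) for j in range(len(groups)) if j != control_index]
             if control_index is not None
             else [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))])
    m = len(pairs)
    stats_, raw_p, adj_p, labels = [], [], [], []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[j] - mean_ranks[i]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        stats_.append(float(z))
        raw_p.append(p)
        adj_p.append(min(1.0, m * p))
        labels.append(f"{names[j]} vs {names[i]}" if control_index is not None
                      else f"{names[i]} vs {names[j]}")
    return TestReport(
        test_name="kruskal_dunn", statistic=stats_, p_two_sided=raw_p, df=None,
        adjusted_p=adj_p, comparisons=labels,
        group_summaries=[group_summary(g) for g in groups],
        adjustment="bonferroni",
        gate={"kruskal_h": float(h), "kruskal_p": float(p_kw)},
    )


def run_test(groups: Sequence[Sequence[float]], method: str, *,
             control_index: int = 0, group_names: Optional[Sequence[str]] = None,
             unit_of_analysis: str = "per-cell") -> TestReport:
    """Run one explicitly chosen hypothesis test on the given groups.

    ``method`` is one of ``welch_t``, ``student_t``, ``mann_whitney``,
    ``dunnett``, ``tukey``, ``kruskal_dunn``.  There is no silent
    auto-selection: callers choose the method (a :func:`variance_gate` report
    can guide the t-test choice).  All p-values are two-sided.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    names = list(group_names) if group_names is not None else [f"group{i}" for i in range(len(gs))]
    if len(names) != len(gs):
        raise ValueError("group_names must match the number of groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("every group needs at least 2 observations")

    if method in ("welch_t", "student_t", "mann_whitney"):
        if len(gs) != 2:
            raise ValueError(f"{method} compares exactly two groups")
        a, b = gs
        if method == "welch_t":
            res = sps.ttest_ind(a, b, equal_var=False)
            df = float(res.df)
        elif method == "student_t":
            res = sps.ttest_ind(a, b, equal_var=True)
            df = float(a.size + b.size - 2)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            df = None
        report = TestReport(
            test_name=method, statistic=float(res.statistic),
            p_two_sided=float(res.pvalue), df=df,
            group_summaries=[group_summary(g) for g in gs],
        )
    elif method == "dunnett":
        if len(gs) < 2:
            raise ValueError("dunnett needs a control and at least one treatment")
        report = _dunnett(gs, control_index, names)
    elif method == "tukey":
        if len(gs) < 2:
            raise ValueError("tukey needs at least two groups")
        report = _tukey(gs, names)
    elif method == "kruskal_dunn":
        if len(gs) < 2:
            raise ValueError("kruskal_dunn needs at least two groups")
        report = _dunn(gs, names, control_index=None)
    else:
        raise ValueError(f"unknown method {method!r}")
    report.unit_of_analysis = unit_of_analysis
    return report


def variance_gate(group_a: Sequence[float], group_b: Sequence[float],
                  alpha: float = 0.05) -> Dict[str, object]:
    """Two-sided F-test on variances guiding the Student-vs-Welch choice.

    Returns a report with the verdict (``equal``/``unequal``); it is up to
    the caller to pick the t-test.  Two zero-variance groups are 'equal' by
    convention, flagged as degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("variance gate needs n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return {"verdict": "equal", "f": 1.0, "p": 1.0, "degenerate": True}
    f = va / vb if vb > 0 else np.inf
    dfa, dfb = a.size - 1, b.size - 1
    p_one = sps.f.sf(f, dfa, dfb) if f >= 1.0 else sps.f.cdf(f, dfa, dfb)
    p = min(1.0, 2.0 * float(p_one))
    return {"verdict": "unequal" if p < alpha else "equal",
            "f": float(f), "p": p, "degenerate": False}


def render_violin_box(groups: Sequence[Sequence[float]], path, *,
                      group_names: Optional[Sequence[str]] = None,
                      ylabel: str = "", title: str = "") -> None:
    """Publication-style violin + box figure (SVG or PNG by extension).

    Boxes span the quartiles with the median as a thick line and the mean
    as a dot; whiskers extend exactly 1.5x the interquartile range beyond
    the quartiles, matching the reported descriptives.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gs = [np.asarray(g, dtype=float) for g in groups]
    names = list(group_names) if group_names is not None else [f"group{i}" for i in range(len(gs))]
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(gs), 3.2))
    positions = np.arange(1, len(gs) + 1)
    parts = ax.violinplot(gs, positions=positions, showextrema=False, widths=0.8)
    for body in parts["bodies"]:
        body.set_alpha(0.3)
    for pos, g in zip(positions, gs):
        s = group_summary(g)
        ax.add_patch(plt.Rectangle((pos - 0.12, s["q1"]), 0.24, s["q3"] - s["q1"],
                                   fill=False, lw=1.0, zorder=3))
        ax.hlines(s["median"], pos - 0.12, pos + 0.12, lw=2.0, zorder=4)
        ax.plot(pos, s["mean"], "o", ms=3, color="k", zorder=4)
        ax.vlines(pos, s["whisker_low"], s["q1"], lw=1.0, zorder=3)
        ax.vlines(pos, s["q3"], s["whisker_high"], lw=1.0, zorder=3)
    ax.set_xticks(positions, names)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
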