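"""Statistical layer: normality screening, Poisson GLMs, habitat comparison.

The genus-level count summaries (sum / mean of MDCs, per-length
normalisation) are heavily right-skewed, so associations with predictors
(number of species, number of specimens, mean pairwise identity) are fitted
as log-link Poisson regressions on log10-scaled predictors; the Wald
statistic reported is the squared z of the slope, and a likelihood-ratio
chi-square against the intercept-only model is attached.  Habitat groups
(open / woodland / mixed) are compared with a tie-corrected Kruskal-Wallis
test followed by Dunn's pairwise z tests with Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class NormalityGate:
    shapiro_w: float
    shapiro_p: float
    skewness: float


@dataclass
class GlmResult:
    slope: float          # coefficient on log10(x)
    slope_se: float
    wald_stat: float      # (slope / se)^2, chi-square with 1 df
    p_value: float
    loglik: float
    chi2: float           # LR statistic vs intercept-only
    chi2_p: float
    intercept: float = 0.0
    slope_ln: float = 0.0  # same slope re-expressed per natural-log unit
    n: int = 0


@dataclass
class DunnPair:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adj: float


@dataclass
class HabitatTest:
    h_stat: float
    df: int
    p_value: float
    n: int
    dunn_pairs: list[DunnPair] = field(default_factory=list)


class DegenerateInputError(ValueError):
    pass


def normality_gate(values: Sequence[float]) -> NormalityGate:
    """Shapiro-Wilk test plus adjusted Fisher-Pearson sample skewness."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateInputError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant vector has no distribution shape")
    w, p = sps.shapiro(x)
    return NormalityGate(shapiro_w=float(w), shapiro_p=float(p),
                         skewness=float(sps.skew(x, bias=False)))


def poisson_glm(y: Sequence[float], x: Sequence[float],
                round_y: bool = True) -> GlmResult:
    """Log-link Poisson regression ``y ~ log10(x)``.

    ``y`` must be non-negative counts; non-integer values are rounded to
    the nearest integer unless ``round_y=False`` (quasi-count outcomes such
    as per-genus means).  ``x`` must be strictly positive.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D and equally long")
    if (y < 0).any():
        raise ValueError("y must be non-negative counts")
    if (x <= 0).any():
        raise ValueError("x must be strictly positive for log scaling")
    if round_y:
        # per-genus means are quasi-counts; the default rounds them so the
        # Poisson likelihood is exact, --no-round fits them verbatim
        y = np.rint(y)

    lx = np.log10(x)
    X = sm.add_constant(lx)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        fit = model.fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely
        raise RuntimeError(f"Poisson GLM failed to converge: {exc}") from exc
    if not fit.converged:
        raise RuntimeError("Poisson GLM did not converge within 200 iterations")
    null_fit = sm.GLM(y, np.ones((y.size, 1)),
                      family=sm.families.Poisson()).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    z = slope / se
    chi2 = 2.0 * (fit.llf - null_fit.llf)
    return GlmResult(
        slope=slope,
        slope_se=se,
        wald_stat=z * z,
        p_value=float(sps.chi2.sf(z * z, df=1)),
        loglik=float(fit.llf),
        chi2=float(max(chi2, 0.0)),
        chi2_p=float(sps.chi2.sf(max(chi2, 0.0), df=1)),
        intercept=float(fit.params[0]),
        slope_ln=slope / math.log(10),
        n=int(y.size),
    )


def _dunn_pairs(values: np.ndarray, labels: np.ndarray,
                groups: list[str]) -> list[DunnPair]:
    """Dunn's post-hoc z tests on the pooled ranks, Bonferroni-adjusted."""
    n = values.size
    ranks = sps.rankdata(values)
    # tie correction term: sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    mean_ranks = {g: float(ranks[labels == g].mean()) for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for a, b in combinations(groups, 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append(DunnPair(group_a=a, group_b=b, z=float(z),
                            p_raw=float(p_raw),
                            p_adj=float(min(1.0, m * p_raw))))
    return out


def habitat_comparison(values: Sequence[float],
                       groups: Sequence[str]) -> HabitatTest:
    """Kruskal-Wallis across habitat groups plus Dunn pairwise tests.

    Groups with fewer than 2 observations are dropped with a warning; at
    least two groups must remain.
    """
    import logging

    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("values and groups must be equally long")
    names = [g for g in dict.fromkeys(labels.tolist())]
    kept = []
    for g in names:
        if (labels == g).sum() >= 2:
            kept.append(g)
        else:
            logging.getLogger(__name__).warning(
                "group %r has < 2 observations; excluded", g)
    if len(kept) < 2:
        raise DegenerateInputError("need >= 2 groups with >= 2 observations")
    mask = np.isin(labels, kept)
    values, labels = values[mask], labels[mask]
    samples = [values[labels == g] for g in kept]
    h, p = sps.kruskal(*samples)
    return HabitatTest(h_stat=float(h), df=len(kept) - 1, p_value=float(p),
                       n=int(values.size),
                       dunn_pairs=_dunn_pairs(values, labels, kept))


def stats_report(summaries_df, round_y: bool = True) -> dict:
    """The full inferential battery on a master genus table.

    Mirrors the study design: normality gates on the three outcome
    variables, Poisson GLMs of (sum of MDCs ~ n species), (MDCs per length
    ~ n specimens) and (mean MDCs ~ identity), and the habitat comparison
    of mean pairwise identity.
    """
    df = summaries_df
    report: dict = {"normality": {}, "glm": {}, "habitat": None}
    outcomes = {
        "mdc_sum": df["mdc_sum"],
        "mdc_per_length_e4": df["mdc_per_length_e4"],
        "mdc_mean": df["mdc_mean"],
    }
    for name, col in outcomes.items():
        try:
            g = normality_gate(col.to_numpy())
            report["normality"][name] = vars(g)
        except DegenerateInputError:
            report["normality"][name] = None
    models = {
        "mdc_sum~n_species": ("mdc_sum", "n_species_analyzed"),
        "mdc_per_length~n_specimens": ("mdc_per_length_e4", "n_specimens"),
        "mdc_mean~identity": ("mdc_mean", "mean_identity_pct"),
    }
    for name, (yc, xc) in models.items():
        res = poisson_glm(df[yc].to_numpy(), df[xc].to_numpy(),
                          round_y=round_y)
        report["glm"][name] = vars(res)
    if "habitat" in df and df["habitat"].astype(bool).any():
        sub = df[df["habitat"].astype(bool)]
        try:
            ht = habitat_comparison(sub["mean_identity_pct"].to_numpy(),
                                    sub["habitat"].to_numpy())
            report["habitat"] = {
                "h_stat": ht.h_stat, "df": ht.df, "p_value": ht.p_value,
                "n": ht.n,
                "dunn": [vars(d) for d in ht.dunn_pairs],
            }
        except DegenerateInputError:
            report["habitat"] = None
    return report
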