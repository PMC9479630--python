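"""Inference suite: Spearman correlations with permutation nulls, paired
eye-swap and region-specificity resampling tests, Fisher r-to-z comparison of
two correlations, bootstrap confidence bands for linear fits, Student t-tests
and Cohen's d, and the omnibus factorial ANOVA.

Permutation conventions: midranks for ties; two-tailed p-values; sampled
permutation p-values carry the +1 correction p = (1 + #extreme) / (1 + B) so
they are never exactly zero.  Exhaustive enumeration (all n! shuffles or all
2^n label swaps) replaces sampling automatically when it is cheaper.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

_EPS = 1e-12


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_perm: float
    n_perm: int
    seed: int | None = None
    method: str = "sampled"


@dataclass
class FisherZResult:
    z: float
    p_two_tailed: float
    rho1: float
    n1: int
    rho2: float
    n2: int


@dataclass
class EffectSize:
    d: float


@dataclass
class AnovaTable:
    table: pd.DataFrame             # columns: effect, sum_sq, df, F, p

    @property
    def effects(self):
        return list(self.table["effect"])

    def f_value(self, effect: str) -> float:
        row = self.table[self.table["effect"] == effect]
        if row.empty:
            raise KeyError(effect)
        return float(row["F"].iloc[0])


def _centered_ranks(x) -> np.ndarray:
    r = sps.rankdata(np.asarray(x, dtype=float))
    return r - r.mean()


def spearman(x, y) -> float:
    """Spearman rho: the Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("spearman requires finite values")
    ux, uy = _centered_ranks(x), _centered_ranks(y)
    denom = np.linalg.norm(ux) * np.linalg.norm(uy)
    if denom == 0:
        return 0.0
    return float(ux @ uy / denom)


def _rho_rows(u_rows: np.ndarray, u_x: np.ndarray) -> np.ndarray:
    """Correlations of centered-rank rows against a centered-rank vector."""
    norms = np.linalg.norm(u_rows, axis=1) * np.linalg.norm(u_x)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (u_rows @ u_x) / norms
    return np.where(norms == 0, 0.0, rho)


def perm_test_rho(x, y, n_perm: int = 100_000, seed: int = 0,
                  method: str = "auto") -> CorrelationResult:
    """Two-tailed permutation test of Spearman rho != 0.

    The null shuffles y against x.  ``method='exhaustive'`` enumerates all n!
    pairings (p = #{|rho_perm| >= |rho_obs|} / n!, identity included);
    ``'auto'`` switches to enumeration when n! <= n_perm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 and method != "exhaustive":
        method = "exhaustive"
    rho_obs = spearman(x, y)
    ux = _centered_ranks(x)
    uy = _centered_ranks(y)
    if method == "auto" and math.factorial(x.size) <= n_perm:
        method = "exhaustive"
    if method == "exhaustive":
        perms = np.array(list(itertools.permutations(uy)))
        rhos = _rho_rows(perms, ux)
        count = int(np.sum(np.abs(rhos) >= abs(rho_obs) - _EPS))
        return CorrelationResult(rho=rho_obs, n=x.size,
                                 p_perm=count / len(perms),
                                 n_perm=len(perms), seed=None,
                                 method="exhaustive")
    rng = np.random.default_rng(seed)
    mat = np.tile(uy, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    rhos = _rho_rows(mat, ux)
    count = int(np.sum(np.abs(rhos) >= abs(rho_obs) - _EPS))
    return CorrelationResult(rho=rho_obs, n=x.size,
                             p_perm=(1 + count) / (1 + n_perm),
                             n_perm=n_perm, seed=seed, method="sampled")


def _rank_rows(values: np.ndarray) -> np.ndarray:
    r = sps.rankdata(values, axis=1)
    return r - r.mean(axis=1, keepdims=True)


def perm_test_delta_rho_eyes(gaba, value_de, value_nde,
                             n_perm: int = 10_000, seed: int = 0,
                             method: str = "auto"):
    """Paired eye-difference test of Delta-rho = rho(g, DE) - rho(g, NDE).

    Under the null of no eye difference each subject's DE/NDE pair is
    exchangeable, so the null distribution is built by independently swapping
    each subject's two values.  Returns (delta_rho_observed, p_two_tailed).
    """
    g = np.asarray(gaba, dtype=float)
    de = np.asarray(value_de, dtype=float)
    nde = np.asarray(value_nde, dtype=float)
    if not g.size == de.size == nde.size:
        raise ValueError("gaba, value_de and value_nde must be paired")
    n = g.size
    obs = spearman(g, de) - spearman(g, nde)
    ug = _centered_ranks(g)
    if method == "auto":
        method = "exhaustive" if 2 ** n <= n_perm else "sampled"
    if method == "exhaustive":
        swaps = np.array(list(itertools.product([False, True], repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        swaps = rng.random((n_perm, n)) < 0.5
    de_mat = np.where(swaps, nde, de)
    nde_mat = np.where(swaps, de, nde)
    deltas = _rho_rows(_rank_rows(de_mat), ug) - _rho_rows(_rank_rows(nde_mat), ug)
    count = int(np.sum(np.abs(deltas) >= abs(obs) - _EPS))
    if method == "exhaustive":
        p = count / len(swaps)
    else:
        p = (1 + count) / (1 + len(swaps))
    return obs, p


def perm_test_region_specificity(gaba_visual, gaba_motor, behavior,
                                 n_boot: int = 10_000, seed: int = 0,
                                 method: str = "bootstrap"):
    """Anatomical specificity of a GABA/behavior correlation.

    Observed statistic: Delta-rho = rho(GABA_visual, behavior) -
    rho(GABA_motor, behavior) over subjects with paired region values.

    ``method='bootstrap'`` (default): subjects are resampled with replacement
    and the two-tailed p is the bootstrap probability that Delta-rho crosses
    zero.  ``method='label_perm'``: each subject's region labels are swapped
    at random and the observed difference is compared to that null.
    Returns (delta_rho_observed, p_two_tailed).
    """
    gv = np.asarray(gaba_visual, dtype=float)
    gm = np.asarray(gaba_motor, dtype=float)
    b = np.asarray(behavior, dtype=float)
    if not gv.size == gm.size == b.size:
        raise ValueError("region values and behavior must be paired per subject")
    n = gv.size
    obs = spearman(gv, b) - spearman(gm, b)
    rng = np.random.default_rng(seed)
    if method == "bootstrap":
        idx = rng.integers(0, n, size=(n_boot, n))
        deltas = (_rho_rows_pairwise(gv[idx], b[idx])
                  - _rho_rows_pairwise(gm[idx], b[idx]))
        n_le = int(np.sum(deltas <= _EPS))
        n_ge = int(np.sum(deltas >= -_EPS))
        p = min(1.0, 2.0 * min(1 + n_le, 1 + n_ge) / (1 + n_boot))
    elif method == "label_perm":
        swaps = rng.random((n_boot, n)) < 0.5
        v_mat = np.where(swaps, gm, gv)
        m_mat = np.where(swaps, gv, gm)
        ub = _centered_ranks(b)
        deltas = _rho_rows(_rank_rows(v_mat), ub) - _rho_rows(_rank_rows(m_mat), ub)
        count = int(np.sum(np.abs(deltas) >= abs(obs) - _EPS))
        p = (1 + count) / (1 + n_boot)
    else:
        raise ValueError(f"unknown method {method!r}")
    return obs, p


def _rho_rows_pairwise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho for paired matrices (resampled draws)."""
    ua = _rank_rows(a)
    ub = _rank_rows(b)
    norms = np.linalg.norm(ua, axis=1) * np.linalg.norm(ub, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.einsum("ij,ij->i", ua, ub) / norms
    return np.where(norms == 0, 0.0, rho)


def fisher_z_compare(rho1: float, n1: int, rho2: float, n2: int) -> FisherZResult:
    """Compare two independent correlations via the Fisher r-to-z transform.

    z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)), referred to
    the standard normal, two-tailed.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z comparison needs n > 3 in each sample")
    if abs(rho1) >= 1 or abs(rho2) >= 1:
        raise ValueError("Fisher z comparison needs |rho| < 1")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(rho1) - math.atanh(rho2)) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return FisherZResult(z=z, p_two_tailed=float(p),
                         rho1=rho1, n1=n1, rho2=rho2, n2=n2)


def one_sample_t(values, mu0: float):
    """Two-tailed one-sample t-test; returns (t, df, p)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("one_sample_t needs n >= 2")
    res = sps.ttest_1samp(values, popmean=mu0)
    return float(res.statistic), values.size - 1, float(res.pvalue)


def two_sample_t(a, b):
    """Two-tailed independent-samples t-test (pooled variance); (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample_t needs n >= 2 per sample")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), a.size + b.size - 2, float(res.pvalue)


def cohens_d(a, b) -> EffectSize:
    """Pooled-SD standardized mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                       / (na + nb - 2))
    if pooled == 0:
        return EffectSize(d=0.0 if a.mean() == b.mean() else math.inf)
    return EffectSize(d=float((a.mean() - b.mean()) / pooled))


def bootstrap_linear_ci(x, y, n_boot: int = 2000, seed: int = 0,
                        x_eval=None) -> dict:
    """Least-squares line with subject-resampled 95% confidence intervals.

    Resamples (x, y) pairs with replacement; returns the fit, the percentile
    2.5/97.5 slope and intercept intervals, and a confidence band at
    ``x_eval`` (defaults to 50 points spanning the data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("bootstrap_linear_ci needs n >= 4")
    rng = np.random.default_rng(seed)
    if x_eval is None:
        x_eval = np.linspace(x.min(), x.max(), 50)
    x_eval = np.asarray(x_eval, dtype=float)

    def fit(xv, yv):
        xm, ym = xv.mean(), yv.mean()
        vx = ((xv - xm) ** 2).sum()
        if vx == 0:
            return None
        slope = ((xv - xm) * (yv - ym)).sum() / vx
        return slope, ym - slope * xm

    slope, intercept = fit(x, y)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    slopes, intercepts = [], []
    for row in idx:
        res = fit(x[row], y[row])
        if res is None:
            continue
        slopes.append(res[0])
        intercepts.append(res[1])
    slopes = np.array(slopes)
    intercepts = np.array(intercepts)
    band = slopes[:, None] * x_eval[None, :] + intercepts[:, None]
    lo, hi = np.percentile(band, [2.5, 97.5], axis=0)
    return {"slope": float(slope), "intercept": float(intercept),
            "slope_ci": (float(np.percentile(slopes, 2.5)),
                         float(np.percentile(slopes, 97.5))),
            "intercept_ci": (float(np.percentile(intercepts, 2.5)),
                             float(np.percentile(intercepts, 97.5))),
            "x_eval": x_eval, "band_lo": lo, "band_hi": hi,
            "n_boot": int(slopes.size), "seed": seed}


_ANOVA_EFFECTS = [
    ("orientation", "C(orientation)"),
    ("ocular_config", "C(ocular_config)"),
    ("eye", "C(eye)"),
    ("group", "C(group)"),
    ("ocular_config:eye", "C(ocular_config):C(eye)"),
    ("group:eye", "C(group):C(eye)"),
    ("ocular_config:group:eye", "C(ocular_config):C(group):C(eye)"),
]


def omnibus_anova(long: pd.DataFrame, value_col: str = "t_rel") -> AnovaTable:
    """Fixed-effects factorial ANOVA of selected relative thresholds.

    Effects: the four main effects (orientation, ocular configuration, eye,
    group) plus the configuration x eye, group x eye and configuration x
    group x eye interactions.  Type-II sums of squares accommodate imbalance.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    needed = {"orientation", "ocular_config", "eye", "group", value_col}
    missing = needed - set(long.columns)
    if missing:
        raise ValueError(f"long table missing columns {sorted(missing)}")
    data = long.dropna(subset=[value_col]).copy()
    formula = f"{value_col} ~ " + " + ".join(term for _, term in _ANOVA_EFFECTS)
    model = smf.ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rows = []
    for name, term in _ANOVA_EFFECTS:
        if term not in aov.index:
            raise RuntimeError(f"effect {term} absent from ANOVA table")
        ss = float(aov.loc[term, "sum_sq"])
        f_val = float(aov.loc[term, "F"])
        p_val = float(aov.loc[term, "PR(>F)"])
        if ss < 1e-12 or not np.isfinite(f_val):
            # degenerate data (e.g. all cells equal): no variance attributable
            f_val, p_val = 0.0, 1.0
        rows.append({"effect": name, "sum_sq": ss,
                     "df": float(aov.loc[term, "df"]), "F": f_val, "p": p_val})
    return AnovaTable(table=pd.DataFrame(rows))
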