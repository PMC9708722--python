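"""Statistical layer: group comparisons, regression, and bootstrap mediation.

Conventions are fixed to the SPSS-style choices that reproduce published
two-group tables computed from summary data:

- Student (pooled-variance) t-test, not Welch.
- Pearson chi-square without Yates continuity correction; odds ratio
  ad/(bc) for the 2x2 table as passed (row 1 = index group).
- Mann-Whitney U with midranks and the tie-corrected normal approximation,
  Z = (U - mu_U)/sigma_U with U computed for the first sample.
- Logistic regression by maximum likelihood with Wald confidence
  intervals; an optional ``percent`` transform multiplies a designated
  predictor by 100 before fitting (indices near 1 are easier to read per
  percentage point).
- Mediation a la the PROCESS macro: OLS paths (a: X->M; b, c': Y on X and
  M; c: Y on X), indirect effect a*b, percentile bootstrap over case
  resampling.  The OLS identity c = c' + a*b holds exactly.  The mediation
  ratio defaults to indirect/total; indirect/(|direct| + |indirect|) is
  available since both definitions circulate.

Two-sided alpha = 0.05 throughout; no multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA = 0.05


class SeparationError(ValueError):
    """Logistic regression diverged (complete or quasi-complete separation)."""


class CollinearityError(ValueError):
    """Perfectly collinear design; carries the VIF table in ``.vif_table``."""

    def __init__(self, message: str, vif_table: pd.Series | None = None):
        super().__init__(message)
        self.vif_table = vif_table


# ---------------------------------------------------------------------------
# Two-group tests
# ---------------------------------------------------------------------------

def t_from_summary(m1, s1, n1, m2, s2, n2) -> dict[str, float]:
    """Pooled-variance (Student) two-sample t-test from summary statistics.

    s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2);
    t = (m1-m2)/(s_p sqrt(1/n1 + 1/n2)); df = n1+n2-2; two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        raise ValueError("degenerate variances: both group SDs are zero")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p)}


def t_test(x, y) -> dict[str, float]:
    """Pooled t-test on raw samples (wrapper over :func:`t_from_summary`)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return t_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def chi2_2x2(a, b, c, d) -> dict[str, float]:
    """Uncorrected Pearson chi-square for a 2x2 table [[a, b], [c, d]].

    chi2 = N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1;
    odds ratio ad/(bc) (inf when bc = 0).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("2x2 table has a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(sps.chi2.sf(chi2, df=1))
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return {"chi2": float(chi2), "df": 1, "p": p, "odds_ratio": float(odds)}


def mann_whitney(x, y) -> dict[str, float]:
    """Mann-Whitney U with midrank ties and tie-corrected normal Z.

    U is computed for the first sample; Z = (U - mu_U)/sigma_U where
    sigma_U uses the tie-corrected permutation variance; two-sided p from
    the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        log.warning("mann_whitney: all values tied; Z set to 0")
        return {"U": float(u), "Z": 0.0, "p": 1.0}
    z = (u - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return {"U": float(u), "Z": float(z), "p": float(p)}


def correlate(x, y, method: str = "pearson") -> dict[str, float]:
    """Pearson or Spearman correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate requires paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlate requires finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return {"r": float(r), "p": float(p)}


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.copy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(X.shape[1])])


def logistic_fit(
    X, y, alpha: float = ALPHA, percent: str | None = None
) -> pd.DataFrame:
    """Binary logistic regression; per-coefficient OR, Wald CI, and p.

    ``percent`` names a predictor to multiply by 100 before fitting (its OR
    is then per percentage point).  Raises :class:`SeparationError` on
    divergence and ValueError on a rank-deficient design.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(Xf) <= Xf.shape[1]:
        raise ValueError("need more observations than predictors")
    if percent is not None:
        Xf[percent] = Xf[percent] * 100.0
    design = sm.add_constant(Xf, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear predictor)")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit diverged: {exc}") from exc
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 30:
        raise SeparationError(
            "logistic fit diverged (complete separation suspected): "
            f"max |coef| = {np.abs(res.params).max():.2f}"
        )
    z = sps.norm.ppf(1 - alpha / 2)
    out = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "OR": np.exp(res.params),
            "ci_low": np.exp(res.params - z * res.bse),
            "ci_high": np.exp(res.params + z * res.bse),
            "p": res.pvalues,
        }
    )
    return out.drop(index="const")


def linear_fit_standardized(X, y) -> pd.DataFrame:
    """OLS on z-scored y and predictors: standardized betas, p, and VIF.

    VIF_j = 1/(1 - R^2_j) from regressing predictor j on the others (with
    intercept).  Perfect collinearity raises :class:`CollinearityError`
    carrying the VIF table (infinite entries flag the offenders).
    """
    import statsmodels.api as sm

    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float).ravel()
    n, k = Xf.shape
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    if np.any(Xf.std(ddof=1) == 0) or y.std(ddof=1) == 0:
        raise ValueError("zero-variance variable in the design")
    Z = (Xf - Xf.mean()) / Xf.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)

    vif = {}
    Zn = Z.to_numpy()
    for j, name in enumerate(Z.columns):
        if k == 1:
            vif[name] = 1.0
            continue
        others = np.column_stack([np.ones(n), np.delete(Zn, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, Zn[:, j], rcond=None)
        resid = Zn[:, j] - others @ beta
        ss_tot = float(((Zn[:, j] - Zn[:, j].mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        vif[name] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    vif_s = pd.Series(vif, name="VIF")
    if np.isinf(vif_s).any():
        raise CollinearityError(
            f"perfect collinearity among predictors: "
            f"{vif_s[np.isinf(vif_s)].index.tolist()}",
            vif_table=vif_s,
        )
    res = sm.OLS(zy, sm.add_constant(Z)).fit()
    out = pd.DataFrame(
        {"beta_std": res.params, "p": res.pvalues, "VIF": vif_s}
    ).drop(index="const")
    return out


# ---------------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    a: float  # X -> M
    b: float  # M -> Y | X
    c: float  # total X -> Y
    c_prime: float  # direct X -> Y | M
    indirect: float  # a * b
    ci: tuple[float, float]
    level: float
    n_boot: int
    seed: object
    mediation_ratio: float
    ratio_definition: str
    covariates: tuple[str, ...]
    n: int
    boot_sd: float = np.nan

    @property
    def significant(self) -> bool:
        """Mediation is declared when the bootstrap CI excludes zero."""
        return not (self.ci[0] <= 0.0 <= self.ci[1])

    def as_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "c_prime": self.c_prime,
            "indirect": self.indirect, "ci_low": self.ci[0],
            "ci_high": self.ci[1], "level": self.level, "n_boot": self.n_boot,
            "mediation_ratio": self.mediation_ratio,
            "ratio_definition": self.ratio_definition,
            "covariates": list(self.covariates), "n": self.n,
        }


def _paths(Xc: np.ndarray, xv: np.ndarray, mv: np.ndarray, yv: np.ndarray):
    """OLS path coefficients (a, b, c_prime, c) for one (re)sample.

    Xc is the covariate block (may be empty); designs carry an intercept.
    """
    n = len(xv)
    ones = np.ones((n, 1))
    d_m = np.hstack([ones, xv[:, None], Xc])
    coef_m, *_ = np.linalg.lstsq(d_m, mv, rcond=None)
    a = coef_m[1]
    d_y = np.hstack([ones, xv[:, None], mv[:, None], Xc])
    coef_y, *_ = np.linalg.lstsq(d_y, yv, rcond=None)
    c_prime, b = coef_y[1], coef_y[2]
    coef_c, *_ = np.linalg.lstsq(d_m, yv, rcond=None)
    c = coef_c[1]
    return a, b, c_prime, c


def mediate(
    data: pd.DataFrame,
    x: str = "mean_alps",
    m: str = "Eg",
    y: str = "MoCA",
    covariates=("age", "sex", "education"),
    n_boot: int = 5000,
    level: float = 0.95,
    seed=None,
    ratio_definition: str = "indirect_over_total",
) -> MediationResult:
    """Single-mediator analysis with a percentile bootstrap CI.

    Paths by OLS on complete cases: M on {X, covariates} gives a; Y on
    {X, M, covariates} gives b and c'; Y on {X, covariates} gives c.
    indirect = a*b; the CI is the percentile interval of a*b over ``n_boot``
    seeded case resamples.  ``ratio_definition`` is 'indirect_over_total'
    (indirect/c) or 'indirect_over_components'
    (indirect/(|c'| + |indirect|)).
    """
    covariates = tuple(covariates)
    cols = [x, m, y, *covariates]
    df = data[cols].dropna()
    n = len(df)
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    xv = df[x].to_numpy(dtype=float)
    mv = df[m].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if xv.std() == 0 or mv.std() == 0:
        raise ValueError("zero variance in X or M")
    Xc = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))

    d_y = np.column_stack([np.ones(n), xv, mv, Xc])
    if np.linalg.matrix_rank(d_y) < d_y.shape[1]:
        log.warning(
            "mediate: outcome design is rank-deficient (mediator collinear "
            "with X or covariates); path b is not identified"
        )
    a, b, c_prime, c = _paths(Xc, xv, mv, yv)
    indirect = a * b

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ba, bb, _, _ = _paths(Xc[idx], xv[idx], mv[idx], yv[idx])
        boot[i] = ba * bb
    lo_q = (1.0 - level) / 2.0
    ci = (float(np.quantile(boot, lo_q)), float(np.quantile(boot, 1.0 - lo_q)))

    if ratio_definition == "indirect_over_total":
        ratio = indirect / c if c != 0 else np.nan
    elif ratio_definition == "indirect_over_components":
        denom = abs(c_prime) + abs(indirect)
        ratio = indirect / denom if denom > 0 else np.nan
    else:
        raise ValueError(f"unknown ratio_definition {ratio_definition!r}")

    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        indirect=float(indirect), ci=ci, level=level, n_boot=n_boot,
        seed=seed, mediation_ratio=float(ratio),
        ratio_definition=ratio_definition, covariates=covariates, n=n,
        boot_sd=float(boot.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Table-1 style group comparison
# ---------------------------------------------------------------------------

#: default variable -> test routing (t: pooled t on raw data; chi2: 2x2;
#: mw: Mann-Whitney with median (IQR) summaries)
DEFAULT_ROUTING = {
    "age": "t",
    "sex": "chi2",
    "education": "t",
    "hypertension": "chi2",
    "hyperlipemia": "chi2",
    "diabetes": "chi2",
    "smoking": "chi2",
    "fsrp": "t",
    "MoCA": "t",
    "mean_alps": "t",
    "Eg": "t",
    "lacune_count": "mw",
    "wmh_volume_ml": "mw",
    "epvs_bg": "mw",
    "epvs_cs": "mw",
}


def _summary_mean_sd(v: np.ndarray) -> str:
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"


def _summary_median_iqr(v: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    return f"{q2:.2f} ({q1:.2f}-{q3:.2f})"


def group_compare_table(
    cohort: pd.DataFrame,
    grouping: str = "group",
    routing: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group comparison table (one row per variable).

    Continuous variables get the pooled t-test with mean +/- SD summaries,
    binary variables the uncorrected chi-square with n (%) summaries, and
    skewed counts/scores the Mann-Whitney test with median (IQR).
    Variables constant in both groups are reported as NA with a note.
    """
    routing = dict(DEFAULT_ROUTING if routing is None else routing)
    groups = [g for g in cohort[grouping].unique()]
    if len(groups) < 2:
        raise ValueError("group comparison requires at least two groups")
    if len(groups) > 2:
        raise ValueError(
            f"only two-group comparison is supported, got {len(groups)} groups"
        )
    g1, g2 = groups
    d1 = cohort[cohort[grouping] == g1]
    d2 = cohort[cohort[grouping] == g2]
    rows = []
    for var, test in routing.items():
        if var not in cohort.columns:
            continue
        v1 = d1[var].dropna().to_numpy(dtype=float)
        v2 = d2[var].dropna().to_numpy(dtype=float)
        row = {"variable": var, "test": test, "statistic": np.nan,
               "p": np.nan, "note": ""}
        if len(v1) and len(v2) and v1.max() == v1.min() == v2.max() == v2.min():
            row["note"] = "constant in both groups"
            row[f"{g1}"] = row[f"{g2}"] = f"{v1[0]:.2f}"
            rows.append(row)
            continue
        try:
            if test == "t":
                res = t_test(v1, v2)
                row["statistic"] = res["t"]
                row["p"] = res["p"]
                row[f"{g1}"] = _summary_mean_sd(v1)
                row[f"{g2}"] = _summary_mean_sd(v2)
            elif test == "chi2":
                a, b = int((v1 == 1).sum()), int((v1 != 1).sum())
                c, d = int((v2 == 1).sum()), int((v2 != 1).sum())
                res = chi2_2x2(a, b, c, d)
                row["statistic"] = res["chi2"]
                row["p"] = res["p"]
                row[f"{g1}"] = f"{a} ({100 * a / max(a + b, 1):.1f}%)"
                row[f"{g2}"] = f"{c} ({100 * c / max(c + d, 1):.1f}%)"
            elif test == "mw":
                res = mann_whitney(v1, v2)
                row["statistic"] = res["Z"]
                row["p"] = res["p"]
                row[f"{g1}"] = _summary_median_iqr(v1)
                row[f"{g2}"] = _summary_median_iqr(v2)
            else:
                raise ValueError(f"unknown test {test!r} for {var}")
        except ValueError as exc:
            row["note"] = str(exc)
        rows.append(row)
    cols = ["variable", f"{g1}", f"{g2}", "test", "statistic", "p", "note"]
    return pd.DataFrame(rows)[cols]


def table_to_text(table: pd.DataFrame) -> str:
    """Human-readable rendering of a comparison table."""
    return table.to_string(
        index=False,
        float_format=lambda v: f"{v:.3f}" if np.isfinite(v) else "NA",
    )
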