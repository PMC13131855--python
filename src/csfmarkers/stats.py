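"""Cohort-level statistics: permutation regression with lobe-wise Bonferroni.

Every imaging marker is analysed with the same three-term linear model,

    y ~ 1 + group + age_c + group:age_c,

where group is coded 0 (control) / 1 (case) and age_c is age centered at
the full-sample mean.  Because many markers are non-normal, inference on
each term uses a Freedman-Lane permutation test: the model without the
term of interest is fitted, its residuals are permuted and added back to
the reduced-model fit, the full model is refitted on each permuted
response, and the two-sided p-value is the add-one tail proportion of
permuted |t| statistics at least as large as the observed one.

Multiple comparisons over the perivascular-space features are corrected
within Bonferroni families defined per anatomical lobe by mask count
(frontal 22, parietal 10, temporal 16, occipital 8); the paired ventricle
and choroid-plexus volumes use alpha/2 = 0.025 and the single ALPS index
0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TERMS",
    "TermResult",
    "ThresholdScheme",
    "center_age",
    "shapiro_screen",
    "permutation_regression",
    "bonferroni_thresholds",
    "demographic_tests",
    "run_marker_analysis",
    "summarize_effects_by_lobe",
    "DEFAULT_FAMILIES",
]

TERMS: tuple[str, ...] = ("Group", "Age", "Group⋅Age")

#: model design columns, aligned with TERMS (column 0 is the intercept)
_TERM_COLUMNS: dict[str, int] = {"Group": 1, "Age": 2, "Group⋅Age": 3}

#: Bonferroni families: lobe families count bilateral masks, the paired
#: volume families count two ROIs each, ALPS is a single test.
DEFAULT_FAMILIES: dict[str, int] = {
    "frontal": 22,
    "parietal": 10,
    "temporal": 16,
    "occipital": 8,
    "lateral_ventricle": 2,
    "choroid_plexus": 2,
    "alps": 1,
}


@dataclass
class TermResult:
    """Permutation-regression result for one model term of one outcome."""

    outcome: str
    term: str
    beta: float
    se: float
    t: float
    p_perm: float
    n: int
    n_permutations: int
    family: str | None = None
    threshold: float | None = None
    significant: bool | None = None


@dataclass
class ThresholdScheme:
    """Per-family Bonferroni-adjusted alpha levels.

    ``exact`` thresholds (alpha / n_masks) drive significance calls;
    ``display`` holds the same values rounded to three significant figures
    for reporting.
    """

    alpha: float
    n_masks: dict[str, int]
    exact: dict[str, float]
    display: dict[str, float]


def _round_3sf(x: float) -> float:
    """Round half-up to three significant figures."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = d.adjusted()  # exponent of the leading digit
    quantum = Decimal(1).scaleb(shift - 2)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def bonferroni_thresholds(
    families: dict[str, int] | None = None, alpha: float = 0.05
) -> ThresholdScheme:
    """Family-wise thresholds alpha / n_masks per family.

    Display values are rounded half-up to 3 significant figures (so 22
    masks gives 0.00227 and 16 masks 0.00313); significance comparisons
    use the unrounded values.
    """
    families = DEFAULT_FAMILIES if families is None else families
    exact, display = {}, {}
    for fam, n in families.items():
        if n < 1:
            raise ValueError(f"family {fam!r} needs at least one mask")
        exact[fam] = alpha / n
        display[fam] = _round_3sf(alpha / n)
    return ThresholdScheme(alpha=alpha, n_masks=dict(families), exact=exact, display=display)


def center_age(table: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh ``age_centered`` = age - mean(age) over included subjects."""
    if "age" not in table.columns:
        raise ValueError("cohort table has no 'age' column")
    if table["age"].isna().any():
        bad = table.index[table["age"].isna()].tolist()
        raise ValueError(f"missing age for subject(s): {bad[:5]}")
    out = table.copy()
    out["age_centered"] = out["age"] - out["age"].mean()
    return out


def shapiro_screen(
    table: pd.DataFrame, outcomes: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Shapiro-Wilk normality screen over outcome columns.

    Advisory only — permutation inference proceeds regardless.  Constant
    columns are flagged degenerate with no p-value.
    """
    rows = []
    for col in outcomes:
        y = table[col].dropna().to_numpy(dtype=float)
        if y.size < 3:
            raise ValueError(f"outcome {col!r} has fewer than 3 observations")
        if np.ptp(y) == 0:
            rows.append({"outcome": col, "w": np.nan, "p": np.nan,
                         "non_normal": False, "degenerate": True})
            continue
        w, p = sps.shapiro(y)
        rows.append({"outcome": col, "w": float(w), "p": float(p),
                     "non_normal": bool(p < alpha), "degenerate": False})
    return pd.DataFrame(rows).set_index("outcome")


# --- OLS helpers ----------------------------------------------------------


def _design_matrix(table: pd.DataFrame) -> np.ndarray:
    g = table["group"].to_numpy(dtype=float)
    if not set(np.unique(g)) <= {0.0, 1.0}:
        raise ValueError("group must be coded 0/1")
    a = table["age_centered"].to_numpy(dtype=float)
    return np.column_stack([np.ones_like(g), g, a, g * a])


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """beta, se, t and residual SS for a full-rank OLS fit."""
    n, p = x.shape
    xtx = x.T @ x
    if np.linalg.cond(xtx) > 1e12:
        raise ValueError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    return beta, se, t, rss


def permutation_regression(
    y: np.ndarray | pd.Series,
    table: pd.DataFrame,
    n_permutations: int = 5000,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
    outcome_name: str = "y",
) -> list[TermResult]:
    """Freedman-Lane permutation test of each term of y ~ 1 + group + age_c + group:age_c.

    For each term the reduced model (without that term's column) is fitted;
    permuted responses y* = reduced fit + permuted reduced residuals are
    refitted under the full model, and the two-sided p-value is

        p = (1 + #{|t*| >= |t_obs|}) / (1 + B)

    with B random permutations from a seeded generator.  With
    ``exhaustive=True`` all n! residual orderings are enumerated (n <= 8)
    and p = #{|t*| >= |t_obs|} / n! — the identity ordering makes this an
    exact test.  Subjects with a missing outcome are dropped listwise.
    """
    yv = np.asarray(pd.Series(y), dtype=float)
    if yv.size != len(table):
        raise ValueError("outcome vector and cohort table must have equal length")
    keep = ~np.isnan(yv)
    tbl = table[keep] if not keep.all() else table  # listwise drop for this model
    yv = yv[keep]
    x = _design_matrix(tbl)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more than {p} subjects, got {n}")
    if np.ptp(yv) == 0:
        raise ValueError(f"outcome {outcome_name!r} is constant")

    beta, se, t_obs, rss = _ols(x, yv)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    diag = np.diag(xtx_inv)
    dof = n - p

    results = []
    for term, j in _TERM_COLUMNS.items():
        xr = np.delete(x, j, axis=1)
        br, *_ = np.linalg.lstsq(xr, yv, rcond=None)
        mu_r = xr @ br
        e_r = yv - mu_r

        if exhaustive:
            if n > 8:
                raise ValueError("exhaustive enumeration is limited to n <= 8")
            perms = np.array(list(itertools.permutations(range(n))))
        else:
            perms = np.tile(np.arange(n), (n_permutations, 1))
            perms = rng.permuted(perms, axis=1)

        ystar = mu_r[None, :] + e_r[perms]  # (B, n)
        bstar = ystar @ pinv.T  # (B, p)
        resid = ystar - bstar @ x.T
        rss_star = np.einsum("bi,bi->b", resid, resid)
        sigma2 = rss_star / dof
        denom = np.sqrt(np.maximum(sigma2 * diag[j], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstar = np.where(denom > 0, bstar[:, j] / np.where(denom > 0, denom, 1.0), np.inf)

        t_abs = abs(t_obs[j])
        # tiny relative slack so exact ties under floating point still count
        count = int(np.sum(np.abs(tstar) >= t_abs * (1.0 - 1e-12)))
        if exhaustive:
            p_perm = count / len(perms)
        else:
            if math.isinf(t_abs):
                count = 0
            p_perm = (1 + count) / (1 + len(perms))

        results.append(
            TermResult(
                outcome=outcome_name,
                term=term,
                beta=float(beta[j]),
                se=float(se[j]),
                t=float(t_obs[j]),
                p_perm=float(p_perm),
                n=n,
                n_permutations=len(perms),
            )
        )
    return results


def demographic_tests(
    table: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Group comparisons of demographics.

    Continuous variables: classical equal-variance two-sample t-test.
    Categorical variables (e.g. sex): Pearson chi-square on the
    contingency table without continuity correction.
    """
    continuous = continuous or []
    categorical = categorical or []
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    g0 = table[table["group"] == groups[0]]
    g1 = table[table["group"] == groups[1]]
    if g0.empty or g1.empty:
        raise ValueError("both groups must be non-empty")

    rows = []
    for col in continuous:
        t, p = sps.ttest_ind(g0[col].dropna(), g1[col].dropna(), equal_var=True)
        rows.append({"variable": col, "test": "t", "statistic": float(t), "p": float(p)})
    for col in categorical:
        ct = pd.crosstab(table["group"], table[col])
        chi2, p, _dof, _exp = sps.chi2_contingency(ct, correction=False)
        rows.append({"variable": col, "test": "chi2", "statistic": float(chi2), "p": float(p)})
    return pd.DataFrame(rows).set_index("variable")


def run_marker_analysis(
    table: pd.DataFrame,
    outcome_manifest: pd.DataFrame,
    n_permutations: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
    families: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Permutation regression of every marker with family-wise thresholds.

    ``outcome_manifest`` has one row per outcome column with columns
    ``outcome`` and ``family`` (optionally ``lobe``, ``hemisphere``,
    ``metric``, ``mask``).  Each outcome gets its own child seed derived
    from ``seed`` so results do not depend on analysis order.  Returns the
    long results table: one row per outcome x term with beta, SE, t,
    permutation p, family threshold, and significance flags.
    """
    manifest = outcome_manifest.set_index("outcome") if "outcome" in outcome_manifest else outcome_manifest
    missing = [c for c in manifest.index if c not in table.columns]
    if missing:
        raise ValueError(f"manifest outcome(s) not in cohort table: {missing[:5]}")

    scheme = bonferroni_thresholds(families, alpha=alpha)
    for fam in manifest["family"].unique():
        if fam not in scheme.exact:
            raise ValueError(f"family {fam!r} has no threshold defined")

    tbl = center_age(table)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(manifest.index))

    rows = []
    for child, outcome in zip(children, manifest.index):
        fam = manifest.loc[outcome, "family"]
        res = permutation_regression(
            tbl[outcome],
            tbl,
            n_permutations=n_permutations,
            seed=np.random.default_rng(child),
            outcome_name=outcome,
        )
        for r in res:
            row = {
                "outcome": r.outcome,
                "term": r.term,
                "beta": r.beta,
                "se": r.se,
                "t": r.t,
                "p_perm": r.p_perm,
                "n": r.n,
                "family": fam,
                "threshold": scheme.exact[fam],
                "threshold_display": scheme.display[fam],
                "uncorrected_significant": r.p_perm < alpha,
                "significant": r.p_perm < scheme.exact[fam],
            }
            for extra in ("lobe", "hemisphere", "metric", "mask"):
                if extra in manifest.columns:
                    row[extra] = manifest.loc[outcome, extra]
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_effects_by_lobe(
    results: pd.DataFrame, alpha: float = 0.05
) -> dict[str, dict]:
    """Lobar distribution of uncorrected-significant effects per term.

    For each model term, takes the rows with p_perm < alpha that carry a
    lobe label and reports the percentage per lobe (denominator: that
    term's significant rows, rounded to 1 decimal) plus the L/R hemisphere
    tally.  Terms with no significant rows report ``n_significant`` 0 and
    no percentages.
    """
    from .atlas import LOBES

    out: dict[str, dict] = {}
    has_lobe = results["lobe"].notna() if "lobe" in results.columns else pd.Series(False, index=results.index)
    for term in TERMS:
        sel = results[(results["term"] == term) & (results["p_perm"] < alpha) & has_lobe]
        entry: dict = {"n_significant": int(len(sel))}
        if len(sel):
            pct = {
                lobe: round(100.0 * (sel["lobe"] == lobe).sum() / len(sel), 1)
                for lobe in LOBES
            }
            entry["lobe_percent"] = pct
            if "hemisphere" in sel.columns:
                entry["hemisphere_counts"] = {
                    "L": int((sel["hemisphere"] == "L").sum()),
                    "R": int((sel["hemisphere"] == "R").sum()),
                }
        out[term] = entry
    return out
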