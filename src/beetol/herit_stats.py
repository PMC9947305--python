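"""Contingency tests, deviance partitioning and broad-sense heritability.

24-h survival is a Bernoulli trait.  Because colony-mates share one mother
and one environment, the share of phenotypic variation attributable to
patriline (sire) reflects genetic variance, and for haplodiploids broad-sense
heritability is estimated as twice the patriline share.  With a binomial GLM
the natural analogue of variance explained is deviance explained (D²): we fit
the nested sequence {intercept} ⊂ {colony} ⊂ {colony:patriline} and report

    share_colony    = (D0 - D1) / D0
    share_patriline = (D1 - D2) / D0        H² = 2 × share_patriline
    share_residual  =  D2 / D0

For factor-only designs the ML fit is closed form (fitted cell probability =
observed cell proportion), which this module uses directly; an iterative
(IRLS) fit via statsmodels is provided for general designs and agrees with
the closed form to numerical precision on factor-only designs.  Raw
sequential shares sum to 1 exactly; adjusted-D² variants
(1 - [(n-1)/(n-p)](1 - D²)) are available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats
from scipy.special import xlogy

import statsmodels.api as sm

log = logging.getLogger("beetol")

__all__ = [
    "ContingencyResult",
    "DeviancePartition",
    "AnodevRow",
    "CorrelationResult",
    "chisq_test",
    "bernoulli_deviance",
    "binomial_deviance",
    "fit_factor_logit",
    "fit_factor_logit_irls",
    "partition_deviance",
    "h2_from_patriline_share",
    "filter_min_workers",
    "anodev_type2",
    "pearson_cor_test",
    "t_from_r",
]


# ---------------------------------------------------------------------------
# contingency tests


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    pvalue: float
    yates: bool
    monte_carlo_p: float | None = None
    n_replicates: int | None = None


def _pearson_stat(obs: np.ndarray, expected: np.ndarray) -> float:
    return float(((obs - expected) ** 2 / expected).sum())


def _sample_fixed_margins(
    rng: np.random.Generator, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """One table from the null distribution conditional on both margins
    (sequential multivariate hypergeometric; Patefield-equivalent)."""
    remaining = cols.copy()
    table = np.empty((len(rows), len(cols)), dtype=np.int64)
    for i, r in enumerate(rows[:-1]):
        draw = rng.multivariate_hypergeometric(remaining, int(r))
        table[i] = draw
        remaining = remaining - draw
    table[-1] = remaining
    return table


def chisq_test(
    table: Sequence[Sequence[int]] | np.ndarray,
    yates: bool = True,
    monte_carlo_B: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> ContingencyResult:
    """Pearson's chi-squared test of independence on a counts matrix.

    Yates' continuity correction is applied iff ``yates`` and the table is
    2×2 (the convention under which the published colony comparison's 9.510
    is obtained; disable for the uncorrected ≈10.19).  With ``monte_carlo_B``
    the p value is additionally computed by simulation with that many
    replicate tables drawn conditional on both margins, as
    ``(1 + #{stat_rep >= stat_obs}) / (B + 1)`` using the uncorrected
    statistic on both sides.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin")

    apply_yates = yates and obs.shape == (2, 2)
    stat, p, df, expected = stats.chi2_contingency(obs, correction=apply_yates)
    result = ContingencyResult(
        statistic=float(stat), df=int(df), pvalue=float(p), yates=apply_yates
    )

    if monte_carlo_B:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        obs_stat = _pearson_stat(obs, expected)
        B = int(monte_carlo_B)
        if obs.shape == (2, 2):
            a = rng.hypergeometric(cols[0], cols[1], rows[0], size=B)
            rep = np.stack(
                [a, rows[0] - a, cols[0] - a, cols[1] - rows[0] + a], axis=1
            ).reshape(B, 2, 2)
            rep_stats = ((rep - expected) ** 2 / expected).sum(axis=(1, 2))
            exceed = int((rep_stats >= obs_stat - 1e-12).sum())
        else:
            exceed = 0
            for _ in range(B):
                t = _sample_fixed_margins(rng, rows, cols)
                if _pearson_stat(t, expected) >= obs_stat - 1e-12:
                    exceed += 1
        result.monte_carlo_p = (1 + exceed) / (B + 1)
        result.n_replicates = B
    return result


# ---------------------------------------------------------------------------
# deviances


def bernoulli_deviance(y: np.ndarray, p: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Binomial deviance of binary outcomes vs fitted probabilities.

    2·Σ w [y ln(y/p) + (1-y) ln((1-y)/(1-p))] with 0·ln0 := 0; for binary y
    the saturated term vanishes and perfectly fitted cells contribute 0.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    return float(-2.0 * (w * (xlogy(y, p) + xlogy(1 - y, 1 - p))).sum())


def binomial_deviance(successes: np.ndarray, trials: np.ndarray, p: np.ndarray) -> float:
    """Deviance of aggregated binomial rows vs fitted probabilities."""
    s = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xlogy(s, s / (n * p)) + xlogy(n - s, (n - s) / (n * (1 - p)))
    return float(2.0 * np.nansum(term))


@dataclass
class FactorFit:
    deviance: float
    cell_probs: dict
    n: int
    df: int  # number of estimable cell means


def fit_factor_logit(
    outcomes: Sequence[bool] | np.ndarray,
    labels: Sequence,
    weights: Sequence[float] | None = None,
) -> FactorFit:
    """Closed-form ML fit of a single-factor Bernoulli-logit model.

    For a factor-only design the MLE fitted probability in each cell equals
    the cell's (weighted) observed proportion; the deviance follows directly.
    """
    y = np.asarray(outcomes, dtype=float)
    lab = pd.Series(list(labels))
    if len(lab) != len(y):
        raise ValueError("outcomes and labels differ in length")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    df = pd.DataFrame({"y": y, "lab": lab.values, "w": w})
    grouped = df.groupby("lab", sort=True)
    sizes = grouped["w"].sum()
    if (sizes <= 0).any():
        raise ValueError("every factor level needs at least one observation")
    probs = grouped.apply(lambda g: np.average(g["y"], weights=g["w"]), include_groups=False)
    p_hat = df["lab"].map(probs).to_numpy(dtype=float)
    dev = bernoulli_deviance(y, p_hat, w)
    return FactorFit(
        deviance=dev,
        cell_probs=probs.to_dict(),
        n=len(y),
        df=len(probs),
    )


def fit_factor_logit_irls(
    outcomes: Sequence[bool] | np.ndarray,
    labels: Sequence,
    weights: Sequence[float] | None = None,
) -> FactorFit:
    """Iteratively reweighted (statsmodels GLM) fit of the same model.

    Must agree with :func:`fit_factor_logit` to ~1e-8 on factor-only
    designs; exists as the general-design route and as a cross-check.
    """
    y = np.asarray(outcomes, dtype=float)
    X = pd.get_dummies(pd.Series(list(labels)).astype("category")).astype(float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    with warnings.catch_warnings():
        # separated cells are legitimate here: their deviance contribution -> 0
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
    probs = dict(zip(X.columns, np.asarray(res.predict(np.eye(X.shape[1])))))
    return FactorFit(
        deviance=float(res.deviance), cell_probs=probs, n=len(y), df=X.shape[1]
    )


# ---------------------------------------------------------------------------
# heritability via nested deviance partition


@dataclass
class DeviancePartition:
    d0: float
    d1: float
    d2: float
    share_colony: float
    share_patriline: float
    share_residual: float
    h2_raw: float
    h2: float  # clamped to [0, 1]
    n: int
    df_colony: int
    df_patriline: int
    adjusted: dict[str, float] = field(default_factory=dict)
    flagged_h2_gt_1: bool = False

    @property
    def shares(self) -> tuple[float, float, float]:
        return (self.share_colony, self.share_patriline, self.share_residual)


def h2_from_patriline_share(share: float) -> float:
    """Broad-sense heritability from the patriline deviance share (H² = 2·share)."""
    return 2.0 * share


def partition_deviance(
    outcomes: Sequence[bool] | np.ndarray,
    colony: Sequence,
    patriline: Sequence,
    adjusted: bool = False,
) -> DeviancePartition:
    """Nested deviance partition {1} ⊂ {colony} ⊂ {colony:patriline} and H².

    Patrilines must be nested within colony: a patriline label occurring in
    two colonies raises.  Shares are raw proportions of the null deviance
    (they sum to 1 exactly); adjusted-D² variants are attached when
    ``adjusted`` and shares are then the differences of adjusted cumulative
    D² (colony, colony+patriline).
    """
    y = np.asarray(outcomes, dtype=float)
    col = pd.Series(list(colony)).astype(str)
    pat = pd.Series(list(patriline)).astype(str)
    if not (len(col) == len(pat) == len(y)):
        raise ValueError("outcomes, colony and patriline differ in length")
    span = pd.DataFrame({"c": col, "p": pat}).drop_duplicates().groupby("p")["c"].nunique()
    bad = span[span > 1].index.tolist()
    if bad:
        raise ValueError(f"patriline label(s) {bad} span multiple colonies (nesting violated)")

    d0 = fit_factor_logit(y, ["_all_"] * len(y)).deviance
    fit_col = fit_factor_logit(y, col)
    cells = col.str.cat(pat, sep=":")
    fit_cell = fit_factor_logit(y, cells)
    d1, d2 = fit_col.deviance, fit_cell.deviance
    if d0 <= 0:
        raise ValueError("null deviance is zero (constant outcome)")

    share_c = (d0 - d1) / d0
    share_p = (d1 - d2) / d0
    share_r = d2 / d0
    h2_raw = h2_from_patriline_share(share_p)
    part = DeviancePartition(
        d0=d0,
        d1=d1,
        d2=d2,
        share_colony=share_c,
        share_patriline=share_p,
        share_residual=share_r,
        h2_raw=h2_raw,
        h2=float(np.clip(h2_raw, 0.0, 1.0)),
        n=len(y),
        df_colony=fit_col.df,
        df_patriline=fit_cell.df - fit_col.df,
        flagged_h2_gt_1=h2_raw > 1.0,
    )
    if h2_raw > 1.0:
        log.warning("raw H² = %.3f exceeds 1; reported clamped to 1", h2_raw)
    if adjusted:
        n = len(y)

        def adj(d2_cum: float, p: int) -> float:
            return 1.0 - (n - 1) / (n - p) * (1.0 - d2_cum)

        adj_col = adj(share_c, fit_col.df)
        adj_full = adj(share_c + share_p, fit_cell.df)
        part.adjusted = {
            "d2_colony": adj_col,
            "d2_full": adj_full,
            "share_patriline": adj_full - adj_col,
            "h2": h2_from_patriline_share(adj_full - adj_col),
        }
    return part


def filter_min_workers(
    assignment: pd.DataFrame | dict,
    phenotypes: pd.DataFrame,
    min_n: int = 5,
) -> pd.DataFrame:
    """Keep only bees in patrilines with at least ``min_n`` tested bees.

    ``assignment`` maps worker id to patriline (a dict or a DataFrame with
    ``worker_id``/``patriline`` columns); returns the phenotype rows merged
    with their patriline, restricted to the qualifying patrilines.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    if isinstance(assignment, dict):
        assignment = pd.DataFrame(
            {"worker_id": list(assignment), "patriline": list(assignment.values())}
        )
    merged = phenotypes.merge(
        assignment[["worker_id", "patriline"]], on="worker_id", how="inner"
    )
    merged = merged[merged["patriline"] != ""]
    sizes = merged.groupby("patriline")["worker_id"].count()
    keep = sizes[sizes >= min_n].index
    out = merged[merged["patriline"].isin(keep)].copy()
    if out.empty:
        log.warning("min-workers filter (min_n=%d) removed every patriline", min_n)
    return out


# ---------------------------------------------------------------------------
# type-II analysis of deviance


@dataclass
class AnodevRow:
    term: str
    lr_chi2: float
    df: int
    pvalue: float
    flagged: bool = False
    note: str = ""


def _design(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    if not terms:
        return np.ones((len(data), 1))
    formula = "1 + " + " + ".join(f"C(Q('{t}'))" for t in terms)
    return np.asarray(dmatrix(formula, data, return_type="matrix"))


def _fit_deviance(
    data: pd.DataFrame,
    terms: Sequence[str],
    endog: np.ndarray,
    freq_weights: np.ndarray | None,
) -> tuple[float, int]:
    X = _design(data, terms)
    rank = int(np.linalg.matrix_rank(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(
            endog, X, family=sm.families.Binomial(), freq_weights=freq_weights
        ).fit()
    return float(res.deviance), rank


def anodev_type2(
    data: pd.DataFrame,
    terms: Sequence[str],
    response: str = "survived",
    trials: str | None = None,
    weights: str | None = None,
) -> list[AnodevRow]:
    """Type-II analysis of deviance for a binomial GLM with categorical terms.

    For each term the LR χ² is deviance(model with all *other* terms) minus
    deviance(full model), with df the difference in estimable parameters —
    the appropriate per-term test for unbalanced designs.  ``response`` is a
    binary column, or a successes column with ``trials`` naming the trials
    column for aggregated (e.g. per-patriline, bee-count-weighted) rows.
    Aliased terms (df 0) are flagged with LR 0 and p 1.  Tiny negative LRs
    from IRLS convergence are clamped at 0; a materially negative LR (which
    cannot occur for genuinely nested ML fits) is clamped and flagged.
    """
    if trials is not None:
        s = data[response].to_numpy(dtype=float)
        n = data[trials].to_numpy(dtype=float)
        endog = np.column_stack([s, n - s])
        freq_w = None
    else:
        endog = data[response].to_numpy(dtype=float)
        freq_w = data[weights].to_numpy(dtype=float) if weights else None

    dev_full, rank_full = _fit_deviance(data, terms, endog, freq_w)
    rows: list[AnodevRow] = []
    for term in terms:
        others = [t for t in terms if t != term]
        dev_red, rank_red = _fit_deviance(data, others, endog, freq_w)
        df = rank_full - rank_red
        lr = dev_red - dev_full
        flagged = False
        note = ""
        if df <= 0:
            rows.append(
                AnodevRow(term, 0.0, 0, 1.0, flagged=True, note="aliased/inestimable")
            )
            continue
        if lr < -1e-6:
            flagged = True
            note = f"negative LR {lr:.4g} clamped (non-nested or convergence issue)"
            log.warning("term %s: %s", term, note)
        lr = max(lr, 0.0)
        rows.append(
            AnodevRow(
                term,
                float(lr),
                int(df),
                float(stats.chi2.sf(lr, df)),
                flagged=flagged,
                note=note,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    pvalue: float


def t_from_r(r: float, df: int) -> tuple[float, float]:
    """The t statistic and two-sided p implied by a Pearson r with n-2 df."""
    if not -1 < r < 1:
        raise ValueError("r must be strictly inside (-1, 1) for a finite t")
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def pearson_cor_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with the t-based two-sided test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length x and y with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    df = len(x) - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, t=float(np.inf * np.sign(r)), df=df, pvalue=0.0)
    t, p = t_from_r(r, df)
    return CorrelationResult(r=r, t=t, df=df, pvalue=p)
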