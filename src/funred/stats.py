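"""Statistical relationships between redundancy, diversity and environment.

Rank and product-moment correlations (complete cases, two-sided t
approximation), Wilcoxon rank tests (signed-rank for paired samples,
Mann-Whitney U with tie-corrected normal approximation for two groups,
exact enumeration at combined n <= 10), ordinary least squares with
adjusted R-squared, and absolute pairwise metadata deltas for the
between-community analyses.

No multiple-testing correction gates any decision; a Benjamini-Hochberg
q-value column is emitted alongside raw p-values for reference.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .core import (
    NUMERIC_METADATA_FIELDS,
    MetadataRecord,
    UsageError,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """One correlation estimate with its two-sided p-value and n.

    ``estimate`` is NaN when the correlation is undefined (zero variance).
    """

    method: str
    estimate: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: coefficients, R-squared and adjusted R-squared."""

    response: str
    predictors: Tuple[str, ...]
    coefficients: Dict[str, float]
    r2: float
    adjusted_r2: float
    n: int


def _complete_cases(x: Iterable[float], y: Iterable[float]) -> Tuple[np.ndarray, np.ndarray]:
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.shape != yv.shape:
        raise ValidationError(f"length mismatch: {xv.size} vs {yv.size}")
    mask = ~(np.isnan(xv) | np.isnan(yv))
    return xv[mask], yv[mask]


def spearman(x: Iterable[float], y: Iterable[float]) -> CorrelationResult:
    """Tie-corrected Spearman correlation (Pearson on mid-ranks).

    Missing pairs are dropped first; p is the two-sided t approximation
    with n - 2 degrees of freedom.
    """
    xv, yv = _complete_cases(x, y)
    if xv.size < 3:
        raise ValidationError(
            f"need >= 3 complete pairs for a correlation, got {xv.size}"
        )
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("Spearman undefined: a variable is constant")
        return CorrelationResult("spearman", math.nan, math.nan, int(xv.size))
    rho, p = sps.spearmanr(xv, yv)
    return CorrelationResult("spearman", float(rho), float(p), int(xv.size))


def pearson(x: Iterable[float], y: Iterable[float]) -> CorrelationResult:
    """Product-moment correlation with two-sided t-test p-value."""
    xv, yv = _complete_cases(x, y)
    if xv.size < 3:
        raise ValidationError(
            f"need >= 3 complete pairs for a correlation, got {xv.size}"
        )
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("Pearson undefined: a variable is constant")
        return CorrelationResult("pearson", math.nan, math.nan, int(xv.size))
    r, p = sps.pearsonr(xv, yv)
    return CorrelationResult("pearson", float(r), float(p), int(xv.size))


def _mannwhitney_exact(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating group assignments.

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled mid-ranks,
    so the null distribution is exact even with ties.  Intended for
    combined n <= 10.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = a.size
    n = pooled.size
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(n), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0
        us.append(u)
    us = np.asarray(us)
    p_low = (us <= u_obs + 1e-12).mean()
    p_high = (us >= u_obs - 1e-12).mean()
    p = min(1.0, 2.0 * min(p_low, p_high))
    return float(u_obs), float(p)


def rank_test(
    a: Iterable[float], b: Iterable[float], paired: bool
) -> Dict[str, float]:
    """Wilcoxon rank test between two value vectors.

    Paired: Wilcoxon signed-rank, dropping zero differences (p = 1 with a
    warning when every difference is zero).  Unpaired: Mann-Whitney U, by
    exact enumeration when combined n <= 10 and otherwise with the
    tie-corrected normal approximation.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if paired:
        if av.size != bv.size:
            raise ValidationError(
                f"paired test needs equal lengths, got {av.size} and {bv.size}"
            )
        diffs = av - bv
        diffs = diffs[diffs != 0]
        if diffs.size == 0:
            logger.warning("all paired differences are zero; p = 1")
            return {"statistic": 0.0, "p_value": 1.0}
        stat, p = sps.wilcoxon(diffs, zero_method="wilcox")
        return {"statistic": float(stat), "p_value": float(p)}
    if av.size < 1 or bv.size < 1:
        raise ValidationError("both groups must be non-empty")
    if np.ptp(np.concatenate([av, bv])) == 0:
        return {"statistic": float(av.size * bv.size / 2.0), "p_value": 1.0}
    if av.size + bv.size <= 10:
        stat, p = _mannwhitney_exact(av, bv)
        return {"statistic": stat, "p_value": p}
    stat, p = sps.mannwhitneyu(av, bv, method="asymptotic")
    return {"statistic": float(stat), "p_value": float(p)}


def ols_adjusted_r2(
    y: Iterable[float],
    X: pd.DataFrame,
    response_name: str = "y",
) -> RegressionResult:
    """OLS with intercept; reports R-squared and adjusted R-squared.

    ``adjusted = 1 - (1 - R2) (n - 1) / (n - p - 1)``.  Complete cases
    only; a rank-deficient design raises an error naming the collinear
    columns.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    yv = np.asarray(list(y), dtype=float)
    if yv.size != len(X):
        raise ValidationError(
            f"response length {yv.size} != design rows {len(X)}"
        )
    mask = ~np.isnan(yv)
    if X.shape[1]:
        mask &= ~X.isna().any(axis=1).to_numpy()
    yv = yv[mask]
    Xc = X.loc[mask].astype(float)
    n, p = len(Xc), Xc.shape[1]
    if n <= p + 1:
        raise ValidationError(
            f"need n > p + 1 complete cases; got n={n}, p={p}"
        )
    design = sm.add_constant(Xc, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = [
            col
            for col in Xc.columns
            if np.linalg.matrix_rank(design.drop(columns=[col]).to_numpy())
            == rank
        ]
        raise ValidationError(
            f"rank-deficient design; collinear columns: {collinear}"
        )
    fit = sm.OLS(yv, design).fit()
    r2 = float(fit.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return RegressionResult(
        response=response_name,
        predictors=tuple(str(c) for c in Xc.columns),
        coefficients={str(k): float(v) for k, v in fit.params.items()},
        r2=r2,
        adjusted_r2=float(adj),
        n=n,
    )


def pairwise_deltas(
    metadata: Mapping[str, MetadataRecord],
    variable: str,
    pairs: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """Absolute difference of one numeric covariate over sample pairs.

    Pairs where either sample misses the value are excluded (count
    logged).  Returns columns sample_a, sample_b, delta.
    """
    if variable not in NUMERIC_METADATA_FIELDS:
        raise UsageError(
            f"unknown variable {variable!r}; expected one of "
            f"{NUMERIC_METADATA_FIELDS}"
        )
    rows = []
    n_excluded = 0
    for sa, sb in pairs:
        try:
            va = metadata[sa].numeric(variable)
            vb = metadata[sb].numeric(variable)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc}") from None
        if va is None or vb is None:
            n_excluded += 1
            continue
        rows.append(
            {"sample_a": sa, "sample_b": sb, "delta": abs(va - vb)}
        )
    if n_excluded:
        logger.info(
            "pairwise deltas for %r: excluded %d pair(s) with missing values",
            variable,
            n_excluded,
        )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "delta"])


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up), NaNs propagated."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = sps.false_discovery_control(p[ok], method="bh")
    return q


def associate_fr(
    requests: Sequence[Tuple[str, str, str]],
    within: Optional[pd.DataFrame] = None,
    between: Optional[pd.DataFrame] = None,
    diversity: Optional[pd.DataFrame] = None,
    metadata: Optional[Mapping[str, MetadataRecord]] = None,
    beta: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Run a batch of redundancy-vs-covariate correlations.

    Each request is ``(response, covariate, method)`` with response
    ``"fri_a"`` or ``"fri_b"`` and method ``"spearman"`` or ``"pearson"``;
    the request is applied to every function present in the relevant
    table.  Covariates for ``fri_a`` come from the alpha-diversity table
    (by column name) or sample metadata (numeric field name); covariates
    for ``fri_b`` are ``"bray_curtis"`` (from the beta table) or
    ``"delta_<field>"`` (pairwise metadata deltas).  Output columns:
    function, response, covariate, method, estimate, p_value, n, q_value.
    """
    rows: List[Dict[str, object]] = []
    for response, covariate, method in requests:
        corr = {"spearman": spearman, "pearson": pearson}.get(method)
        if corr is None:
            raise UsageError(f"unknown correlation method {method!r}")
        if response == "fri_a":
            if within is None:
                raise UsageError("fri_a requests need the within-FR table")
            table = _join_within(within, covariate, diversity, metadata)
        elif response == "fri_b":
            if between is None:
                raise UsageError("fri_b requests need the between-FR table")
            table = _join_between(between, covariate, metadata, beta)
        else:
            raise UsageError(f"unknown response {response!r}")
        for function, sub in table.groupby("function", sort=True):
            res = corr(sub["value"], sub["covariate"])
            rows.append(
                {
                    "function": function,
                    "response": response,
                    "covariate": covariate,
                    "method": method,
                    "estimate": res.estimate,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "function", "response", "covariate", "method",
            "estimate", "p_value", "n",
        ],
    )
    out["q_value"] = benjamini_hochberg(out["p_value"]) if len(out) else []
    return out


def _join_within(
    within: pd.DataFrame,
    covariate: str,
    diversity: Optional[pd.DataFrame],
    metadata: Optional[Mapping[str, MetadataRecord]],
) -> pd.DataFrame:
    table = within.rename(
        columns={"function_name": "function", "fri_a": "value"}
    )[["sample_id", "function", "value"]].copy()
    if diversity is not None and covariate in diversity.columns:
        cov = diversity.set_index("sample_id")[covariate]
        table["covariate"] = table["sample_id"].map(cov)
    elif metadata is not None and covariate in NUMERIC_METADATA_FIELDS:
        table["covariate"] = [
            _meta_value(metadata, sid, covariate) for sid in table["sample_id"]
        ]
    else:
        raise UsageError(
            f"covariate {covariate!r} not found in diversity table or metadata"
        )
    matched = table["covariate"].notna() | table["value"].notna()
    if not matched.any():
        raise UsageError(
            f"empty join for covariate {covariate!r}: unmatched sample ids "
            f"{sorted(set(table['sample_id']))[:5]}"
        )
    return table


def _join_between(
    between: pd.DataFrame,
    covariate: str,
    metadata: Optional[Mapping[str, MetadataRecord]],
    beta: Optional[pd.DataFrame],
) -> pd.DataFrame:
    table = between.rename(
        columns={"function_name": "function", "fri_b": "value"}
    )[["sample_a", "sample_b", "function", "value"]].copy()
    key = ["sample_a", "sample_b"]
    if covariate == "bray_curtis":
        if beta is None:
            raise UsageError("'bray_curtis' covariate needs the beta table")
        cov = pd.concat(
            [
                beta,
                beta.rename(
                    columns={"sample_a": "sample_b", "sample_b": "sample_a"}
                ),
            ]
        ).set_index(key)["bray_curtis"]
        table["covariate"] = [
            cov.get((a, b), math.nan)
            for a, b in zip(table["sample_a"], table["sample_b"])
        ]
    elif covariate.startswith("delta_"):
        field = covariate[len("delta_"):]
        if metadata is None:
            raise UsageError("delta covariates need sample metadata")
        pairs = sorted(set(zip(table["sample_a"], table["sample_b"])))
        deltas = pairwise_deltas(metadata, field, pairs).set_index(key)["delta"]
        table["covariate"] = [
            deltas.get((a, b), math.nan)
            for a, b in zip(table["sample_a"], table["sample_b"])
        ]
    else:
        raise UsageError(
            f"unknown between-community covariate {covariate!r}; expected "
            "'bray_curtis' or 'delta_<field>'"
        )
    if table["covariate"].isna().all():
        raise UsageError(
            f"empty join for covariate {covariate!r}: no matching sample pairs"
        )
    return table


def _meta_value(
    metadata: Mapping[str, MetadataRecord], sample_id: str, field: str
) -> float:
    rec = metadata.get(sample_id)
    if rec is None:
        return math.nan
    v = rec.numeric(field)
    return math.nan if v is None else v
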