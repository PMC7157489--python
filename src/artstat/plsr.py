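"""Relating image statistics to aesthetic ratings.

Two complementary analyses are run per genre (and on the pooled set):

1. Pearson correlations between ratings and each of the nine
   statistics, summarized as coefficients of determination
   Cd = 100 * r**2 and screened with Benjamini-Hochberg FDR at q = 0.05.
2. Partial least squares regression (PLSR) of ratings on the z-scored
   nine-statistic matrix.  PLSR builds components as linear
   combinations of the predictors chosen to explain rating variance,
   which makes it robust to the strong collinearity among the
   statistics.  The component count is the smallest reaching 85% of
   the asymptotic (maximum-component) fit, and per-predictor VIP
   (variable importance in projection) scores -- whose squares average
   exactly 1 -- flag important statistics at the VIP > 1.25 criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from artstat.errors import (
    DegeneratePredictorError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)
from artstat.stats import STAT_COLUMNS

#: The eight subject-matter categories of the artwork databases.
GENRES = (
    "abstract",
    "landscape",
    "people",
    "still_life",
    "portrait",
    "nude",
    "animals",
    "built",
)

DEFAULT_FDR_Q = 0.05
DEFAULT_VIP_THRESHOLD = 1.25
DEFAULT_ASYMPTOTE_FRACTION = 0.85
MIN_GENRE_N = 10


def rescale_ratings(scores: np.ndarray) -> np.ndarray:
    """Map 7-point ratings in [1, 7] onto the 100-point scale.

    The affine map x -> (x - 1) * 100 / 6 sends the scale endpoints to
    0 and 100, allowing 7-point data to be pooled with natively
    100-point ratings.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size and (np.nanmin(scores) < 1 or np.nanmax(scores) > 7):
        raise InvalidInputError("7-point scores must lie in [1, 7]")
    return (scores - 1.0) * (100.0 / 6.0)


def pearson_cd(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r, Cd = 100 * r**2, and two-sided p for paired data.

    Pairs with a missing value in either variable are dropped
    (pairwise deletion of flagged statistics).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(100.0 * r * r), float(p)


def fdr_adjust(pvals: np.ndarray, q: float = DEFAULT_FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def zscore_predictors(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre and scale columns to mean 0, unit sample sd (ddof = 1).

    Returns the standardized matrix together with the per-column means
    and standard deviations used, so new data can be mapped identically.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("X must be 2-D with at least two rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise DegeneratePredictorError(f"zero-variance predictor column(s) {bad}")
    return (X - mean) / sd, mean, sd


@dataclass(frozen=True)
class PLSRModel:
    """A fitted PLSR model of ratings on nine z-scored statistics."""

    predictors: tuple[str, ...]
    n_comp: int
    x_weights: np.ndarray   # p x k
    x_loadings: np.ndarray  # p x k
    y_loadings: np.ndarray  # k
    x_scores: np.ndarray    # n x k
    cd_fit: float           # percent rating variance explained
    vip: np.ndarray = field(default=None)  # type: ignore[assignment]
    vip_threshold: float = DEFAULT_VIP_THRESHOLD

    @property
    def selected(self) -> tuple[str, ...]:
        """Predictors whose VIP exceeds the selection criterion."""
        return tuple(
            p for p, v in zip(self.predictors, self.vip) if v > self.vip_threshold
        )

    def to_dict(self) -> dict:
        return {
            "n_comp": self.n_comp,
            "cd_fit": self.cd_fit,
            "vip": {p: float(v) for p, v in zip(self.predictors, self.vip)},
            "selected": list(self.selected),
            "vip_threshold": self.vip_threshold,
        }


def vip_scores(model: PLSRModel) -> np.ndarray:
    """Variable-importance-in-projection scores of a fitted model.

    For predictor j over components k = 1..K,

        VIP_j = sqrt( p * sum_k SS_k (w_jk / ||w_k||)^2 / sum_k SS_k )

    where SS_k is the rating variance explained by component k and w_k
    the k-th predictor-weight vector.  The normalization makes the
    mean of the squared scores exactly 1, so scores above 1 mark
    predictors of above-average importance.
    """
    if model.n_comp < 1 or model.x_weights.size == 0:
        raise InvalidInputError("VIP requires a fitted model with >= 1 component")
    W = model.x_weights
    p = W.shape[0]
    ss = model.y_loadings**2 * np.einsum("nk,nk->k", model.x_scores, model.x_scores)
    total = ss.sum()
    if total == 0:
        # components explain no rating variance; importance is uniform
        return np.ones(p)
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ss) / total)


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    predictors: tuple[str, ...] = STAT_COLUMNS,
    vip_threshold: float = DEFAULT_VIP_THRESHOLD,
) -> PLSRModel:
    """Fit a k-component PLSR of ratings on standardized statistics.

    The fit is deterministic given its inputs.  ``cd_fit`` is the
    percent rating variance explained in-sample; with the maximum
    number of components on full-rank predictors it equals the
    ordinary-least-squares R-squared (x100).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise InvalidInputError("X and y must have matching n")
    if not 1 <= k <= min(n - 1, p):
        raise InvalidInputError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, y)
    yhat = pls.predict(X).ravel()
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise InvalidInputError("ratings have zero variance")
    cd_fit = float(100.0 * (1.0 - np.sum((y - yhat) ** 2) / ss_tot))
    model = PLSRModel(
        predictors=tuple(predictors),
        n_comp=k,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_.ravel(),
        x_scores=pls.x_scores_,
        cd_fit=cd_fit,
        vip_threshold=vip_threshold,
    )
    object.__setattr__(model, "vip", vip_scores(model))
    return model


def first_k_reaching(
    cd_curve, fraction: float = DEFAULT_ASYMPTOTE_FRACTION
) -> int:
    """Smallest k whose cd_fit reaches ``fraction`` of the curve's last value.

    ``cd_curve[k-1]`` is the fit with k components; the asymptotic
    value is taken as the final entry (the maximum-component fit).
    """
    curve = list(cd_curve)
    if not curve:
        raise InvalidInputError("empty cd_fit curve")
    target = fraction * curve[-1]
    for k, cd in enumerate(curve, start=1):
        if cd >= target:
            return k
    return len(curve)


def select_ncomp(
    X: np.ndarray,
    y: np.ndarray,
    asymptote_fraction: float = DEFAULT_ASYMPTOTE_FRACTION,
    k_max: int | None = None,
) -> int:
    """Component count by the 85%-of-asymptote rule.

    Models with k = 1..k_max components (k_max = min(n - 1, p)) are fit
    in-sample; the asymptotic value is cd_fit at k_max and the selected
    k is the first reaching ``asymptote_fraction`` of it.  This
    in-sample elbow rule guards against over-fitting without
    cross-validation.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k_max is None:
        k_max = min(n - 1, p)
    curve = [fit_plsr(X, y, k).cd_fit for k in range(1, k_max + 1)]
    return first_k_reaching(curve, asymptote_fraction)


def _records_frame(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("genre", "rating", *STAT_COLUMNS) if c not in records]
    if missing:
        raise InvalidInputError(f"records missing columns {missing}")
    return records


def correlation_table(
    records: pd.DataFrame,
    q: float = DEFAULT_FDR_Q,
    family: str = "table",
    genres: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-(genre, statistic) correlation grid with FDR screening.

    Rows cover the pooled set ("all") plus each genre present; columns
    are genre, statistic, n, r, Cd, p, significant.  With
    ``family="table"`` (default) the Benjamini-Hochberg correction is
    applied jointly over every test in the grid; ``family="genre"``
    corrects each genre's nine tests separately.
    """
    records = _records_frame(records)
    if family not in ("table", "genre"):
        raise InvalidInputError("family must be 'table' or 'genre'")
    if genres is None:
        genres = tuple(g for g in GENRES if g in set(records["genre"]))
        extra = sorted(set(records["genre"]) - set(GENRES))
        genres = genres + tuple(extra)
    rows = []
    for genre in ("all", *genres):
        sub = records if genre == "all" else records[records["genre"] == genre]
        y = sub["rating"].to_numpy(float)
        for stat in STAT_COLUMNS:
            x = sub[stat].to_numpy(float)
            try:
                r, cd, p = pearson_cd(x, y)
            except (InsufficientDataError, UndefinedStatisticError):
                r = cd = p = float("nan")
            rows.append(
                {"genre": genre, "statistic": stat,
                 "n": int(np.isfinite(x).sum()), "r": r, "Cd": cd, "p": p}
            )
    table = pd.DataFrame(rows)
    table["significant"] = False
    if family == "table":
        groups = [table.index]
    else:
        groups = [table.index[table["genre"] == g] for g in ("all", *genres)]
    for idx in groups:
        ok = idx[np.isfinite(table.loc[idx, "p"])]
        if len(ok):
            table.loc[ok, "significant"] = fdr_adjust(
                table.loc[ok, "p"].to_numpy(), q=q
            )
    return table


def run_genre_analysis(
    records: pd.DataFrame,
    genre: str = "all",
    q: float = DEFAULT_FDR_Q,
    vip_threshold: float = DEFAULT_VIP_THRESHOLD,
    asymptote_fraction: float = DEFAULT_ASYMPTOTE_FRACTION,
    min_n: int = MIN_GENRE_N,
) -> tuple[pd.DataFrame, PLSRModel]:
    """One genre's correlation row-set and asymptote-selected PLSR model.

    Correlations drop flagged (NaN) statistics pairwise; PLSR drops
    incomplete records listwise, z-scores the remaining statistics, and
    picks the component count with the 85%-of-asymptote rule.
    """
    records = _records_frame(records)
    sub = records if genre == "all" else records[records["genre"] == genre]
    if len(sub) < min_n:
        raise InsufficientDataError(
            f"genre {genre!r} has {len(sub)} records; need >= {min_n}"
        )
    corr = correlation_table(sub.assign(genre=genre), q=q, family="genre")
    corr = corr[corr["genre"] == genre].reset_index(drop=True)

    stats = sub[list(STAT_COLUMNS)].to_numpy(float)
    y = sub["rating"].to_numpy(float)
    # drop all-missing columns first, then incomplete rows, then any
    # column left without variance (e.g. chroma entropy of greyscale sets)
    usable = ~np.all(~np.isfinite(stats), axis=0)
    complete = np.isfinite(stats[:, usable]).all(axis=1) & np.isfinite(y)
    if complete.sum() < min_n:
        raise InsufficientDataError(
            f"genre {genre!r} has {int(complete.sum())} complete records"
        )
    X = stats[np.ix_(complete, usable)]
    usable[np.flatnonzero(usable)[X.std(axis=0, ddof=1) == 0]] = False
    kept = tuple(c for c, u in zip(STAT_COLUMNS, usable) if u)
    if len(kept) < len(STAT_COLUMNS):
        dropped = sorted(set(STAT_COLUMNS) - set(kept))
        logging.getLogger(__name__).warning(
            "genre %r: degenerate predictor(s) %s excluded from PLSR",
            genre, dropped,
        )
    if len(kept) < 2:
        raise InsufficientDataError(f"genre {genre!r}: too few usable predictors")
    Z, _, _ = zscore_predictors(stats[np.ix_(complete, usable)])
    k = select_ncomp(Z, y[complete], asymptote_fraction=asymptote_fraction)
    model = fit_plsr(Z, y[complete], k, predictors=kept,
                     vip_threshold=vip_threshold)
    return corr, model
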