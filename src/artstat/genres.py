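"""Comparing statistic distributions across genres.

Whether different statistics matter for different genres could simply
reflect genres differing in the statistics themselves.  This module
runs that check: a one-factor fixed-effects ANOVA of each statistic on
genre, Tukey-HSD multiple comparisons over all genre pairs (28 pairs
for the eight genres), and boxplot summaries per genre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import cbook
from scipy import stats as sps

from artstat.errors import InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class GenreANOVA:
    """One-factor ANOVA of a statistic on genre, with pairwise flags."""

    statistic: str
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: tuple[tuple[str, str, bool], ...]


@dataclass(frozen=True)
class BoxplotSummary:
    """Per-genre five-number boxplot summaries of one statistic."""

    statistic: str
    genres: tuple[str, ...]
    median: dict[str, float]
    q1: dict[str, float]
    q3: dict[str, float]
    whisker_low: dict[str, float]
    whisker_high: dict[str, float]
    outliers: dict[str, tuple[float, ...]]


def _groups(records: pd.DataFrame, statistic: str, min_per_group: int,
            min_groups: int = 1):
    if statistic not in records:
        raise InvalidInputError(f"unknown statistic column {statistic!r}")
    if "genre" not in records:
        raise InvalidInputError("records need a 'genre' column")
    out = []
    for genre, sub in records.groupby("genre", sort=True):
        vals = sub[statistic].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_per_group:
            raise InsufficientDataError(
                f"genre {genre!r} has {len(vals)} values; need >= {min_per_group}"
            )
        out.append((str(genre), vals))
    if len(out) < min_groups:
        raise InvalidInputError(f"need >= {min_groups} genres")
    return out


def genre_anova(
    records: pd.DataFrame,
    statistic: str,
    alpha: float = 0.05,
) -> GenreANOVA:
    """One-factor fixed-effects ANOVA of ``statistic`` grouped by genre."""
    groups = _groups(records, statistic, min_per_group=2, min_groups=2)
    values = [v for _, v in groups]
    f_stat, p = sps.f_oneway(*values)
    n = sum(len(v) for v in values)
    return GenreANOVA(
        statistic=statistic,
        F=float(f_stat),
        df_between=len(values) - 1,
        df_within=n - len(values),
        p=float(p),
        pairwise=pairwise_comparisons(records, statistic, alpha=alpha),
    )


def pairwise_comparisons(
    records: pd.DataFrame,
    statistic: str,
    alpha: float = 0.05,
) -> tuple[tuple[str, str, bool], ...]:
    """Tukey HSD flags for every unordered genre pair at family level alpha.

    Returns exactly C(g, 2) entries for g genres (28 for eight).
    """
    groups = _groups(records, statistic, min_per_group=2, min_groups=2)
    names = [g for g, _ in groups]
    res = sps.tukey_hsd(*[v for _, v in groups])
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append((names[i], names[j], bool(res.pvalue[i, j] < alpha)))
    return tuple(out)


def boxplot_summary(
    records: pd.DataFrame,
    statistic: str,
    whis: float = 1.5,
) -> BoxplotSummary:
    """Median, quartiles, whiskers and outliers of a statistic per genre.

    Quartiles use linear interpolation between order statistics;
    whiskers extend to the most extreme points within ``whis`` x IQR of
    the box, and points beyond are reported as outliers.
    """
    groups = _groups(records, statistic, min_per_group=4)
    med, q1, q3, wlo, whi, out = {}, {}, {}, {}, {}, {}
    for genre, vals in groups:
        (bs,) = cbook.boxplot_stats(vals, whis=whis)
        med[genre] = float(bs["med"])
        q1[genre] = float(bs["q1"])
        q3[genre] = float(bs["q3"])
        wlo[genre] = float(bs["whislo"])
        whi[genre] = float(bs["whishi"])
        out[genre] = tuple(float(v) for v in bs["fliers"])
    return BoxplotSummary(
        statistic=statistic,
        genres=tuple(g for g, _ in groups),
        median=med, q1=q1, q3=q3,
        whisker_low=wlo, whisker_high=whi, outliers=out,
    )


def plot_genre_boxes(
    records: pd.DataFrame,
    statistics: tuple[str, ...],
    path,
    whis: float = 1.5,
) -> None:
    """Side-by-side per-genre boxplots of the given statistics (one panel
    each), saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(statistics), figsize=(4 * len(statistics), 4), squeeze=False
    )
    for ax, stat in zip(axes[0], statistics):
        groups = _groups(records, stat, min_per_group=4)
        ax.boxplot([v for _, v in groups], tick_labels=[g for g, _ in groups],
                   whis=whis)
        ax.set_title(stat)
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
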