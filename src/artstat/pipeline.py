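"""End-to-end pipeline: images + metadata -> statistics -> report bundle.

Ties the stages together under one configuration: preprocess every
image, compute the nine statistics, build the correlation grid, fit
per-genre PLSR models with VIP selection, run the genre ANOVAs, and
write boxplots plus a run log with all resolved parameters.  The run
is deterministic under a fixed config, so re-running produces
byte-identical CSV reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from artstat.errors import InsufficientDataError, InvalidInputError
from artstat.genres import genre_anova, plot_genre_boxes
from artstat.plsr import (
    DEFAULT_ASYMPTOTE_FRACTION,
    DEFAULT_FDR_Q,
    DEFAULT_VIP_THRESHOLD,
    GENRES,
    MIN_GENRE_N,
    correlation_table,
    rescale_ratings,
    run_genre_analysis,
)
from artstat.preprocess import DEFAULT_SIDE, load_image, preprocess_image
from artstat.stats import STAT_COLUMNS, compute_statvector

log = logging.getLogger("artstat.pipeline")

#: Float formatting of all CSV reports; fixed so reruns are byte-identical.
CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    image_dir: str = ""
    metadata: str = ""
    out_dir: str = "artstat_out"
    side: int = DEFAULT_SIDE
    fdr_level: float = DEFAULT_FDR_Q
    fdr_family: str = "table"
    vip_threshold: float = DEFAULT_VIP_THRESHOLD
    asymptote_fraction: float = DEFAULT_ASYMPTOTE_FRACTION
    min_genre_n: int = MIN_GENRE_N
    spectral_fit_range: tuple[int, int] | None = None
    box_sizes: tuple[int, ...] | None = None
    anova_planes: tuple[str, ...] = ("L",)
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise InvalidInputError("fdr_level must be in (0, 1)")
        if self.vip_threshold <= 0:
            raise InvalidInputError("vip_threshold must be > 0")
        if not 0.0 < self.asymptote_fraction <= 1.0:
            raise InvalidInputError("asymptote_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise InvalidInputError(f"unknown config keys {sorted(bad)}")
        for key in ("spectral_fit_range", "box_sizes", "anova_planes"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Load the image metadata CSV (image_id, genre, rating[, rating_scale]).

    Ratings with ``rating_scale == "mart7"`` (7-point emotion scores)
    are rescaled onto the 100-point scale so the sets can be pooled;
    ``ja100`` rows are taken as already on 0-100.
    """
    meta = pd.read_csv(path)
    for col in ("image_id", "genre", "rating"):
        if col not in meta:
            raise InvalidInputError(f"metadata is missing column {col!r}")
    if "rating_scale" in meta:
        scales = set(meta["rating_scale"].dropna()) - {"ja100", "mart7"}
        if scales:
            raise InvalidInputError(f"unknown rating_scale values {sorted(scales)}")
        is7 = meta["rating_scale"] == "mart7"
        if is7.any():
            meta.loc[is7, "rating"] = rescale_ratings(
                meta.loc[is7, "rating"].to_numpy(float)
            )
    if ((meta["rating"] < 0) | (meta["rating"] > 100)).any():
        raise InvalidInputError("ratings must lie in [0, 100]")
    return meta


def compute_stats_table(
    image_dir: str | Path,
    meta: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-image nine-statistic table for every image in the metadata.

    Images that fail to load or process are logged and skipped; the
    summary count of failures is logged at the end.
    """
    image_dir = Path(image_dir)
    rows, failures = [], 0
    for rec in meta.itertuples(index=False):
        matches = sorted(image_dir.glob(f"{rec.image_id}.*"))
        try:
            if not matches:
                raise FileNotFoundError(f"no file for image_id {rec.image_id}")
            img = load_image(matches[0])
            stack = preprocess_image(img, side=config.side)
            stats = compute_statvector(
                stack,
                fit_range=config.spectral_fit_range,
                box_sizes=config.box_sizes,
            )
        except Exception as exc:  # per-image failures must not kill the run
            failures += 1
            log.warning("skipping %s: %s", rec.image_id, exc)
            continue
        rows.append(
            {"image_id": rec.image_id, "genre": rec.genre,
             "rating": float(rec.rating), **stats}
        )
    if failures:
        log.warning("%d image(s) skipped", failures)
    return pd.DataFrame(
        rows, columns=["image_id", "genre", "rating", *STAT_COLUMNS]
    )


def plsr_table(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Per-genre PLSR summary: component count, Cd fit, nine VIP scores.

    One row per genre with enough records, plus a pooled "all" row.
    VIP cells above the selection threshold are flagged in companion
    boolean columns (``<stat>_selected``).
    """
    rows = []
    present = [g for g in GENRES if g in set(records["genre"])]
    present += sorted(set(records["genre"]) - set(GENRES))
    for genre in ("all", *present):
        try:
            _, model = run_genre_analysis(
                records, genre,
                q=config.fdr_level,
                vip_threshold=config.vip_threshold,
                asymptote_fraction=config.asymptote_fraction,
                min_n=config.min_genre_n,
            )
        except InsufficientDataError as exc:
            log.warning("PLSR skipped: %s", exc)
            continue
        row = {"genre": genre,
               "n": int(len(records) if genre == "all"
                        else (records["genre"] == genre).sum()),
               "n_comp": model.n_comp, "cd_fit": model.cd_fit}
        for stat, v in zip(model.predictors, model.vip):
            row[stat] = float(v)
            row[f"{stat}_selected"] = bool(v > config.vip_threshold)
        rows.append(row)
    return pd.DataFrame(rows)


def anova_tables(
    records: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA summary and pairwise Tukey flags for each chosen statistic."""
    stats = [f"{s}_{p}" for s in ("SL", "FD", "EN") for p in config.anova_planes]
    main_rows, pair_rows = [], []
    for stat in stats:
        res = genre_anova(records, stat, alpha=0.05)
        main_rows.append(
            {"statistic": stat, "F": res.F, "df_between": res.df_between,
             "df_within": res.df_within, "p": res.p}
        )
        for gi, gj, sig in res.pairwise:
            pair_rows.append(
                {"statistic": stat, "genre_i": gi, "genre_j": gj,
                 "significant": sig}
            )
    return pd.DataFrame(main_rows), pd.DataFrame(pair_rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT,
              lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis and write the report bundle.

    Produces stats.csv, the correlation grid (correlations.csv), the
    PLSR/VIP table (plsr.csv), ANOVA tables (anova.csv, pairwise.csv),
    per-statistic boxplots, and run_log.json with resolved parameters.
    Returns the mapping of report names to paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(config.metadata)
    records = compute_stats_table(config.image_dir, meta, config)
    if records.empty:
        raise InsufficientDataError("no image could be processed")
    paths: dict[str, Path] = {}

    paths["stats"] = out / "stats.csv"
    _write_csv(records, paths["stats"])

    corr = correlation_table(records, q=config.fdr_level,
                             family=config.fdr_family)
    paths["correlations"] = out / "correlations.csv"
    _write_csv(corr, paths["correlations"])

    paths["plsr"] = out / "plsr.csv"
    _write_csv(plsr_table(records, config), paths["plsr"])

    anova, pairwise = anova_tables(records, config)
    paths["anova"] = out / "anova.csv"
    paths["pairwise"] = out / "pairwise.csv"
    _write_csv(anova, paths["anova"])
    _write_csv(pairwise, paths["pairwise"])

    if config.make_plots:
        stats = [f"{s}_{p}" for p in config.anova_planes
                 for s in ("SL", "FD", "EN")]
        try:
            target = out / "boxplots.png"
            plot_genre_boxes(records, tuple(stats), target)
            paths["boxplots"] = target
        except InsufficientDataError as exc:
            log.warning("boxplots skipped: %s", exc)

    cfg = asdict(config)
    paths["run_log"] = out / "run_log.json"
    with open(paths["run_log"], "w") as fh:
        json.dump({"config": cfg, "n_images": int(len(records)),
                   "reports": {k: str(v) for k, v in paths.items()
                               if k != "run_log"}},
                  fh, indent=1, sort_keys=True)
    return paths
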