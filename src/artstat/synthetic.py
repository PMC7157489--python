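"""Synthetic images and rating datasets with known ground truth.

Every stage of the pipeline is testable without artwork databases:

* ``gen_powerlaw_image`` -- spectral synthesis of planes whose
  rotationally averaged amplitude spectrum follows f**beta exactly,
  the oracle for the spectral-slope estimator.
* ``gen_fbm_surface`` -- fractional-Brownian surfaces with Hurst
  exponent H (power spectrum f**-(2H+2)); their theoretical surface
  dimension 3 - H is the oracle for the box-counting estimator.
* ``gen_entropy_image`` -- i.i.d. draws from a 256-symbol distribution
  numerically tuned to a prescribed Shannon entropy.
* ``gen_rating_dataset`` / ``gen_genre_dataset`` -- nine collinear
  statistic columns (a two-latent-factor structure: one factor drives
  the spectral-slope block, the other the fractal-dimension/entropy
  block) with ratings formed as a known linear function of the
  z-scored statistics plus Gaussian noise.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.optimize import brentq

from artstat.errors import InvalidInputError
from artstat.plsr import GENRES
from artstat.stats import N_LEVELS, STAT_COLUMNS

#: Within-block correlation of the two-factor statistic structure.
FACTOR_RHO = 0.5
#: Factor membership: the SL block (columns 0-2) loads on one latent
#: factor, the FD+EN block (columns 3-8) on the other.
FACTOR_BLOCKS = (0, 0, 0, 1, 1, 1, 1, 1, 1)

#: Statistic-like location/scale per column, so synthetic columns live
#: on plausible scales (SL near -1.2, FD near 2.4, EN near 6 bits).
COLUMN_LOC = (-1.2, -1.1, -1.1, 2.4, 2.3, 2.3, 6.0, 4.5, 4.5)
COLUMN_SCALE = (0.35, 0.4, 0.4, 0.25, 0.3, 0.3, 0.8, 1.0, 1.0)


def _radius_grid(size: int) -> np.ndarray:
    k = np.fft.fftfreq(size) * size
    return np.hypot(*np.meshgrid(k, k, indexing="ij"))


def _random_phases(size: int, seed: int) -> np.ndarray:
    """Unit-magnitude Hermitian-symmetric phase field from seeded noise."""
    if size < 4 or size & (size - 1):
        raise InvalidInputError(f"size must be a power of two >= 4, got {size}")
    rng = np.random.default_rng(seed)
    phase = np.fft.fft2(rng.standard_normal((size, size)))
    mag = np.abs(phase)
    mag[mag == 0] = 1.0
    return phase / mag


def _spectral_synthesis(exponent: float, size: int, seed: int) -> np.ndarray:
    """Plane with |FFT| = r**exponent exactly and random phases."""
    r = _radius_grid(size)
    with np.errstate(divide="ignore"):
        amp = np.where(r > 0, r**exponent, 0.0)
    plane = np.fft.ifft2(amp * _random_phases(size, seed)).real
    return plane * size  # arbitrary overall scale; keeps values O(1)


def gen_powerlaw_image(beta: float, size: int, seed: int) -> np.ndarray:
    """Plane whose radial amplitude spectrum is exactly f**beta.

    beta = 0 gives a flat (white-noise-like) spectrum; beta near -1.2
    mimics natural images.  Requires beta in [-3, 0].
    """
    if not -3.0 <= beta <= 0.0:
        raise InvalidInputError(f"beta must be in [-3, 0], got {beta}")
    return _spectral_synthesis(beta, size, seed)


def gen_fbm_surface(
    hurst: float, size: int, seed: int, n_alias: int = 3
) -> np.ndarray:
    """Fractional-Brownian surface with Hurst exponent H in (0, 1).

    Spectral synthesis with power-spectrum exponent -(2H + 2).  The
    power assigned to each lattice frequency is the alias-folded
    continuum spectrum (summed over ``n_alias`` spectral replicas), as
    in a true point-sampled fBm field: plain truncation at the Nyquist
    frequency would leave the surface too smooth at small lags.  The
    theoretical surface fractal dimension is 3 - H; rough surfaces
    (small H) fill more of the (x, y, intensity) volume.
    """
    if not 0.0 < hurst < 1.0:
        raise InvalidInputError(f"hurst must be in (0, 1), got {hurst}")
    phases = _random_phases(size, seed)
    k = np.fft.fftfreq(size) * size
    kx, ky = np.meshgrid(k, k, indexing="ij")
    power = np.zeros((size, size))
    for m1 in range(-n_alias, n_alias + 1):
        for m2 in range(-n_alias, n_alias + 1):
            r2 = (kx + m1 * size) ** 2 + (ky + m2 * size) ** 2
            with np.errstate(divide="ignore"):
                power += np.where(r2 > 0, r2 ** (-(hurst + 1.0)), 0.0)
    amp = np.sqrt(power)
    amp[0, 0] = 0.0
    return np.fft.ifft2(amp * phases).real * size


def _entropy_mixture(target: float) -> tuple[np.ndarray, np.ndarray]:
    """256-symbol distribution with Shannon entropy ``target`` bits.

    A single mixing weight w interpolates between uniform over
    m = 2**ceil(target) symbols (w = 0, entropy ceil(target)) and a
    point mass (w = 1, entropy 0); w is solved numerically to 1e-6 bits.
    Returns (8-bit symbol values, probabilities).
    """
    m = int(2 ** np.ceil(target)) if target > 0 else 1
    levels = np.linspace(0, N_LEVELS - 1, m).round().astype(np.uint8)

    def entropy_at(w: float) -> float:
        p = np.full(m, (1.0 - w) / m)
        p[0] += w
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    if m == 1:
        return levels, np.array([1.0])
    if abs(entropy_at(0.0) - target) < 1e-12:
        w = 0.0
    else:
        w = brentq(lambda w: entropy_at(w) - target, 0.0, 1.0 - 1e-12,
                   xtol=1e-12)
    p = np.full(m, (1.0 - w) / m)
    p[0] += w
    return levels, p


def gen_entropy_image(target_entropy: float, size: int, seed: int) -> np.ndarray:
    """Plane of i.i.d. 8-bit draws with prescribed histogram entropy.

    Pixels are drawn i.i.d. from the tuned 256-symbol distribution, so
    the plane's 256-bin entropy (reference range 0-255) matches
    ``target_entropy`` up to sampling error.  Requires target in [0, 8].
    """
    if not 0.0 <= target_entropy <= 8.0:
        raise InvalidInputError(f"target entropy must be in [0, 8], got {target_entropy}")
    rng = np.random.default_rng(seed)
    levels, probs = _entropy_mixture(target_entropy)
    idx = rng.choice(len(levels), size=size * size, p=probs)
    plane = levels[idx].astype(float)
    return rng.permutation(plane).reshape(size, size)


def factor_covariance(rho: float = FACTOR_RHO) -> np.ndarray:
    """Population correlation matrix of the nine synthetic statistics."""
    blocks = np.asarray(FACTOR_BLOCKS)
    C = rho * (blocks[:, None] == blocks[None, :]).astype(float)
    np.fill_diagonal(C, 1.0)
    return C


def noise_sd_for_r2(weights: np.ndarray, r2: float, rho: float = FACTOR_RHO) -> float:
    """Rating-noise sd giving a target population R**2.

    The signal variance of z(X) @ weights under the factor structure is
    w' C w with C the population correlation matrix; the noise sd is
    chosen so signal / (signal + noise) = r2.
    """
    if not 0.0 < r2 < 1.0:
        raise InvalidInputError("r2 must be in (0, 1)")
    w = np.asarray(weights, dtype=float)
    signal = float(w @ factor_covariance(rho) @ w)
    return float(np.sqrt(signal * (1.0 - r2) / r2))


def _draw_statistics(n: int, rng: np.random.Generator,
                     shift: np.ndarray | None = None) -> np.ndarray:
    blocks = np.asarray(FACTOR_BLOCKS)
    f = rng.standard_normal((n, 2))
    e = rng.standard_normal((n, 9))
    z = np.sqrt(FACTOR_RHO) * f[:, blocks] + np.sqrt(1.0 - FACTOR_RHO) * e
    X = np.asarray(COLUMN_LOC) + np.asarray(COLUMN_SCALE) * z
    if shift is not None:
        X = X + np.asarray(shift, dtype=float)
    return X


def _ratings_from(X: np.ndarray, weights: np.ndarray, noise_sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    raw = Z @ np.asarray(weights, dtype=float)
    raw = raw + rng.normal(0.0, noise_sd, size=len(X))
    span = np.ptp(raw)
    if span == 0:
        return np.full(len(X), 50.0)
    return (raw - raw.min()) * (100.0 / span)


def gen_rating_dataset(
    n: int,
    weights,
    noise_sd: float,
    seed: int,
    genre: str = "all",
) -> tuple[pd.DataFrame, dict]:
    """Synthetic statistic matrix plus ratings with known generative weights.

    Draws n rows of the nine collinear statistic columns, forms
    ratings = z(X) @ weights + N(0, noise_sd) and affinely maps them
    into [0, 100] (an affine map leaves correlations and PLSR fits
    unchanged).  Returns the records frame and a ground-truth dict.
    """
    if n < 20:
        raise InvalidInputError(f"n must be >= 20, got {n}")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (9,):
        raise InvalidInputError("weights must have length 9")
    rng = np.random.default_rng(seed)
    X = _draw_statistics(n, rng)
    ratings = _ratings_from(X, weights, noise_sd, rng)
    df = pd.DataFrame(X, columns=list(STAT_COLUMNS))
    df.insert(0, "image_id", [f"{genre}_{i:05d}" for i in range(n)])
    df.insert(1, "genre", genre)
    df.insert(2, "rating", ratings)
    truth = {
        "weights": weights.tolist(),
        "noise_sd": float(noise_sd),
        "rho": FACTOR_RHO,
        "active": [STAT_COLUMNS[j] for j in np.flatnonzero(weights)],
        "seed": int(seed),
    }
    return df, truth


def gen_genre_dataset(
    genre_specs: dict[str, dict],
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Multi-genre dataset with per-genre shifts and rating weights.

    ``genre_specs`` maps genre name -> {"n": int, "weights": 9-vector,
    "noise_sd": float, "shift": optional 9-vector added to the raw
    statistic columns}.  Ground truth per genre is returned alongside.
    """
    if len(genre_specs) < 2:
        raise InvalidInputError("need >= 2 genres")
    frames, truth = [], {}
    for gi, (genre, spec) in enumerate(sorted(genre_specs.items())):
        rng_seed = (seed * 1009 + gi) % (2**31)
        n = int(spec["n"])
        weights = np.asarray(spec.get("weights", np.zeros(9)), dtype=float)
        noise_sd = float(spec.get("noise_sd", 1.0))
        shift = spec.get("shift")
        rng = np.random.default_rng(rng_seed)
        X = _draw_statistics(n, rng, shift=None if shift is None
                             else np.asarray(shift, dtype=float))
        ratings = _ratings_from(X, weights, noise_sd, rng)
        df = pd.DataFrame(X, columns=list(STAT_COLUMNS))
        df.insert(0, "image_id", [f"{genre}_{i:05d}" for i in range(n)])
        df.insert(1, "genre", genre)
        df.insert(2, "rating", ratings)
        frames.append(df)
        truth[genre] = {
            "n": n,
            "weights": weights.tolist(),
            "noise_sd": noise_sd,
            "shift": None if shift is None else list(map(float, shift)),
            "seed": rng_seed,
        }
    return pd.concat(frames, ignore_index=True), truth


#: Per-genre amplitude-spectrum exponents for the image-set simulator.
#: Abstracts get a distinctly shallower slope than the figurative
#: genres, mirroring the qualitative pattern in which the abstract
#: genre is the statistical outlier among the eight.
GENRE_BETAS = {
    "abstract": -0.7,
    "landscape": -1.3,
    "people": -1.2,
    "still_life": -1.25,
    "portrait": -1.35,
    "nude": -1.4,
    "animals": -1.2,
    "built": -1.15,
}


def simulate_genre_images(
    out_dir: str | Path,
    n_images: int = 200,
    size: int = 256,
    seed: int = 0,
    genres: tuple[str, ...] = GENRES,
) -> tuple[Path, Path]:
    """Write a PNG image set with genre structure plus its metadata CSV.

    Images are 8-bit sRGB power-law textures: the lightness plane has a
    genre-specific spectral exponent plus per-image jitter, and the two
    chroma planes carry independent power-law textures of moderate
    amplitude, so all nine statistics are non-degenerate.  Ratings are
    a linear function of the image's true lightness exponent plus
    noise, mapped to [0, 100].  Returns (images directory, metadata CSV
    path); a ground-truth JSON sidecar is written next to the CSV.
    """
    from skimage.color import lab2rgb

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []

    def _norm(plane: np.ndarray) -> np.ndarray:
        lo, hi = plane.min(), plane.max()
        return np.zeros_like(plane) if hi == lo else (plane - lo) / (hi - lo)

    for i in range(n_images):
        genre = genres[i % len(genres)]
        beta = float(np.clip(GENRE_BETAS[genre] + rng.normal(0.0, 0.1), -3.0, 0.0))
        L = 10.0 + 80.0 * _norm(
            gen_powerlaw_image(beta, size, int(rng.integers(2**31)))
        )
        a = 50.0 * _norm(
            gen_powerlaw_image(-1.0, size, int(rng.integers(2**31)))
        ) - 25.0
        b = 50.0 * _norm(
            gen_powerlaw_image(-1.0, size, int(rng.integers(2**31)))
        ) - 25.0
        rgb = lab2rgb(np.dstack([L, a, b]))
        img = (np.clip(rgb, 0.0, 1.0) * 255).round().astype(np.uint8)
        image_id = f"img_{i:05d}"
        Image.fromarray(img, mode="RGB").save(img_dir / f"{image_id}.png")
        rating_raw = -40.0 * beta + rng.normal(0.0, 8.0)
        rows.append({"image_id": image_id, "genre": genre,
                     "rating": rating_raw, "rating_scale": "ja100"})
        truth_rows.append({"image_id": image_id, "beta": beta})
    meta = pd.DataFrame(rows)
    lo, hi = meta["rating"].min(), meta["rating"].max()
    meta["rating"] = (
        50.0 if hi == lo else (meta["rating"] - lo) * (100.0 / (hi - lo))
    ).round(4)
    meta_path = out_dir / "meta.csv"
    meta.to_csv(meta_path, index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump({"seed": int(seed), "genre_betas": GENRE_BETAS,
                   "images": truth_rows}, fh, indent=1)
    return img_dir, meta_path
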