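"""Per-plane image statistics: spectral slope, fractal dimension, entropy.

Three statistics are estimated on each CIELAB plane:

* **Spectral slope (SL)** -- the slope of log10 amplitude versus log10
  radial spatial frequency of the rotationally averaged 2-D Fourier
  amplitude spectrum.  Natural images sit near -1.2; steeper (more
  negative) slopes mean relatively more coarse-scale tonal variation.
* **Fractal dimension (FD)** -- a 3-D box-counting estimate of how
  thoroughly the intensity surface fills the (x, y, intensity) volume,
  conventioned so a uniform field scores 0 and a space-filling pattern
  scores 3.
* **Entropy (EN)** -- Shannon entropy, in bits, of the plane's 256-bin
  intensity histogram: 0 for a constant field, 8 for an image whose
  8-bit levels are uniformly random.

Applied to the three planes these give the nine-element statistic
vector SL(L), SL(a), SL(b), FD(L), FD(a), FD(b), EN(L), EN(a), EN(b).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from artstat.errors import InvalidInputError, UndefinedStatisticError
from artstat.preprocess import PlaneStack

log = logging.getLogger(__name__)

#: Column order of the nine statistics, statistic-major then plane.
STAT_COLUMNS = (
    "SL_L", "SL_a", "SL_b",
    "FD_L", "FD_a", "FD_b",
    "EN_L", "EN_a", "EN_b",
)

#: Fixed quantization ranges per CIELAB plane, so entropy is comparable
#: across images: L spans [0, 100]; a and b effectively span [-128, 127].
REFERENCE_RANGES = {
    "L": (0.0, 100.0),
    "a": (-128.0, 127.0),
    "b": (-128.0, 127.0),
}

N_LEVELS = 256


def _check_square_plane(plane: np.ndarray, min_side: int = 1) -> np.ndarray:
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2 or plane.shape[0] != plane.shape[1]:
        raise InvalidInputError(f"expected a square plane, got shape {plane.shape}")
    if plane.shape[0] < min_side:
        raise InvalidInputError(f"plane side must be >= {min_side}")
    if not np.all(np.isfinite(plane)):
        raise InvalidInputError("plane contains non-finite values")
    return plane


def radial_amplitude_spectrum(plane: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally averaged Fourier amplitude spectrum.

    The plane mean (DC) is removed, the 2-D FFT amplitude is computed
    (no window; leakage is accepted as part of the estimator), and
    amplitudes are averaged within integer radial-frequency bins
    r = 1 ... side/2 - 1 cycles/image.

    Returns
    -------
    r : ndarray of int
        Radial frequencies, cycles per image.
    amp : ndarray
        Mean amplitude in each radial bin.
    """
    plane = _check_square_plane(plane, min_side=4)
    side = plane.shape[0]
    spec = np.abs(np.fft.fft2(plane - plane.mean()))
    k = np.fft.fftfreq(side) * side
    radius = np.rint(np.hypot(*np.meshgrid(k, k, indexing="ij"))).astype(int)
    rmax = side // 2 - 1
    flat_r = radius.ravel()
    keep = (flat_r >= 1) & (flat_r <= rmax)
    sums = np.bincount(flat_r[keep], weights=spec.ravel()[keep], minlength=rmax + 1)
    counts = np.bincount(flat_r[keep], minlength=rmax + 1)
    r = np.arange(1, rmax + 1)
    return r, sums[1:] / counts[1:]


def spectral_slope(
    plane: np.ndarray,
    fit_range: tuple[int, int] | None = None,
) -> float:
    """Slope of the rotationally averaged amplitude spectrum on log-log axes.

    Parameters
    ----------
    plane : ndarray
        Square plane, side >= 16, not constant.
    fit_range : (int, int), optional
        Inclusive radial-frequency band (cycles/image) for the OLS fit.
        Defaults to (2, side // 4): the DC-adjacent bin and the
        Nyquist-adjacent bins, where discretization artifacts dominate,
        are excluded.

    Raises
    ------
    UndefinedStatisticError
        For a constant plane, where every non-DC amplitude is zero.
    """
    plane = _check_square_plane(plane, min_side=16)
    if np.ptp(plane) == 0:
        raise UndefinedStatisticError("spectral slope undefined for constant plane")
    side = plane.shape[0]
    if fit_range is None:
        fit_range = (2, side // 4)
    lo, hi = fit_range
    if not (1 <= lo < hi <= side // 2 - 1):
        raise InvalidInputError(f"invalid fit range {fit_range} for side {side}")
    r, amp = radial_amplitude_spectrum(plane)
    band = (r >= lo) & (r <= hi) & (amp > 0)
    if band.sum() < 2:
        raise UndefinedStatisticError("too few nonzero spectral bins in fit range")
    slope, _ = np.polyfit(np.log10(r[band]), np.log10(amp[band]), 1)
    return float(slope)


def default_box_sizes(side: int) -> tuple[int, ...]:
    """Default dyadic box-size ladder for a plane of the given side.

    Scales run from side/16 up to side/2 (clipped below at 2).  The
    coarsest partition available (side/2) anchors the top of the
    ladder; scales below side/16 are excluded because band-limited
    (interpolated) images are effectively smooth there, so cell ranges
    reflect the local gradient rather than fractal structure and drag
    the fitted dimension toward the smooth-surface value.
    """
    lo = max(2, side // 16)
    return tuple(s for s in (2 ** e for e in range(1, int(np.log2(side))))
                 if lo <= s <= side // 2)


def box_counts(
    plane: np.ndarray,
    box_sizes: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupied-box counts N(s) of the 3-D box-counting ladder.

    Intensities are affinely rescaled so the occurring range spans
    [0, side], making the (x, y, intensity) volume a cube.  For box
    side s the plane is partitioned into s x s spatial cells; a cell
    whose intensity range is delta occupies ceil(delta / s) boxes, and
    a cell with zero range occupies none -- so a uniform field yields
    N(s) = 0 at every scale.
    """
    plane = _check_square_plane(plane)
    side = plane.shape[0]
    if side & (side - 1) or side < 8:
        raise InvalidInputError(f"plane side must be a power of two >= 8, got {side}")
    if box_sizes is None:
        box_sizes = default_box_sizes(side)
    lo, hi = plane.min(), plane.max()
    if hi > lo:
        z = (plane - lo) * (side / (hi - lo))
    else:
        z = np.zeros_like(plane)
    counts = np.empty(len(box_sizes))
    for i, s in enumerate(box_sizes):
        if side % s:
            raise InvalidInputError(f"box size {s} does not divide side {side}")
        cells = z.reshape(side // s, s, side // s, s)
        span = cells.max(axis=(1, 3)) - cells.min(axis=(1, 3))
        counts[i] = np.ceil(span / s).sum()
    return np.asarray(box_sizes, dtype=int), counts


def fractal_dimension(
    plane: np.ndarray,
    box_sizes: tuple[int, ...] | None = None,
) -> float:
    """3-D box-counting fractal dimension of an intensity surface.

    FD is the least-squares slope of log N(s) against log(1/s) over a
    dyadic ladder of box sizes (s = 2, 4, ..., side/2 by default).  A
    uniform field has no occupied boxes and is defined to have FD = 0;
    regression output is clamped to the theoretical range [0, 3]
    (clamping is logged, since it signals an estimator edge case).
    """
    sizes, counts = box_counts(plane, box_sizes)
    occupied = counts > 0
    if not occupied.any():
        return 0.0
    if occupied.sum() < 2:
        # one usable scale cannot support a slope; treat as degenerate
        return 0.0
    slope, _ = np.polyfit(np.log(1.0 / sizes[occupied]), np.log(counts[occupied]), 1)
    fd = float(slope)
    if fd < -1e-9 or fd > 3.0 + 1e-9:
        log.warning("fractal dimension %.4f outside [0, 3]; clamped", fd)
    return min(max(fd, 0.0), 3.0)


def shannon_entropy(
    plane: np.ndarray,
    reference_range: tuple[float, float] = (0.0, 255.0),
) -> float:
    """Shannon entropy, in bits, of the quantized intensity histogram.

    The plane is quantized to 256 levels by affinely mapping the fixed
    ``reference_range`` onto bins 0...255 (values outside are clipped),
    so entropies are comparable across images sharing a plane type.
    A constant plane returns exactly 0; i.i.d. uniform draws over the
    full range approach the 8-bit maximum.
    """
    plane = np.asarray(plane, dtype=float)
    if not np.all(np.isfinite(plane)):
        raise InvalidInputError("plane contains non-finite values")
    vmin, vmax = reference_range
    if not vmax > vmin:
        raise InvalidInputError("reference range must have vmax > vmin")
    q = np.floor((plane - vmin) * (N_LEVELS / (vmax - vmin)))
    q = np.clip(q, 0, N_LEVELS - 1).astype(np.int64)
    counts = np.bincount(q.ravel(), minlength=N_LEVELS)
    return float(sps.entropy(counts[counts > 0], base=2))


def compute_statvector(
    stack: PlaneStack,
    fit_range: tuple[int, int] | None = None,
    box_sizes: tuple[int, ...] | None = None,
) -> dict[str, float]:
    """All nine statistics of one plane stack, in ``STAT_COLUMNS`` order.

    Spectral slope is undefined on a constant plane; that entry is
    reported as NaN (a flagged missing value that downstream analyses
    drop pairwise or listwise).
    """
    out: dict[str, float] = {}
    for name, plane in stack.planes().items():
        try:
            sl = spectral_slope(plane, fit_range=fit_range)
        except UndefinedStatisticError:
            sl = float("nan")
        out[f"SL_{name}"] = sl
    for name, plane in stack.planes().items():
        out[f"FD_{name}"] = fractal_dimension(plane, box_sizes=box_sizes)
    for name, plane in stack.planes().items():
        out[f"EN_{name}"] = shannon_entropy(plane, REFERENCE_RANGES[name])
    return {k: out[k] for k in STAT_COLUMNS}


@dataclass(frozen=True)
class StatVector:
    """Nine statistics of one image, SL/FD/EN by plane L/a/b."""

    SL_L: float
    SL_a: float
    SL_b: float
    FD_L: float
    FD_a: float
    FD_b: float
    EN_L: float
    EN_a: float
    EN_b: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in STAT_COLUMNS])

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "StatVector":
        return cls(**{c: float(d[c]) for c in STAT_COLUMNS})
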