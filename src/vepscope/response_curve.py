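"""Integrated-power response statistic and Naka-Rushton dynamic-range fits.

The response statistic for a stimulus condition is the averaged trace
squared and integrated in time from stimulus onset to 400 ms after
(units V^2*s).  Power values are normalized within each animal to that
animal's maximum across stimulus intensities, giving a dimensionless
response R in [0, 1], and the normalized power-intensity relation is
fit to the Naka-Rushton equation

    R = I**slope / (I**slope + I50**slope)

where I50 is the flash intensity eliciting a half-maximal response and
the dimensionless ``slope`` exponent measures response heterogeneity.
The saturating response is fixed at 1 by the normalization, so only
(I50, slope) are fit.

The fit minimizes the sum of squared residuals over the unconstrained
internal parameters (log10 I50, log slope) -- positivity is enforced by
the parameterization -- with a multistart over a grid of initial log10
I50 values spanning the data's intensity range crossed with initial
slopes {0.1, 0.3, 1, 3}; the best-RSS solution is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .preprocess import AveragedWaveform

__all__ = [
    "NakaRushtonFit",
    "naka_rushton",
    "vep_power",
    "normalize_by_animal",
    "fit_naka_rushton",
    "fit_response_table",
]

_INITIAL_SLOPES = (0.1, 0.3, 1.0, 3.0)
_N_I50_STARTS = 5
_FTOL = 1e-12


@dataclass(frozen=True)
class NakaRushtonFit:
    """Fitted half-saturation intensity and slope exponent.

    ``converged`` is False for degenerate data (e.g. all responses
    equal); ``reliable`` is False when the data are too sparse for a
    well-posed fit (< 3 points or < 1 decade of intensity span).
    """

    i50: float
    slope: float
    rss: float
    converged: bool
    n_points: int
    reliable: bool = True

    def predict(self, intensity: np.ndarray | float) -> np.ndarray | float:
        return naka_rushton(intensity, self.i50, self.slope)


def naka_rushton(
    intensity: np.ndarray | float, i50: float, slope: float
) -> np.ndarray | float:
    """Evaluate ``I**s / (I**s + I50**s)``; 0 at I = 0, 0.5 at I = I50."""
    if i50 <= 0 or slope <= 0:
        raise ValueError("i50 and slope must be > 0")
    i = np.asarray(intensity, dtype=float)
    out = np.zeros_like(i)
    pos = i > 0
    # log-space form avoids overflow for extreme intensities
    out[pos] = 1.0 / (1.0 + np.exp(slope * (np.log(i50) - np.log(i[pos]))))
    if np.isscalar(intensity):
        return float(out)
    return out


def vep_power(avg: AveragedWaveform, window_s: float = 0.400) -> float:
    """Trapezoidal integral of the squared averaged trace, V^2*s.

    Integrates over ``[onset, onset + window_s]`` on the native sampling
    grid; the record must extend at least ``window_s`` past onset.
    """
    fs = avg.sample_rate_hz
    i0 = int(round(avg.onset_s * fs))
    i1 = i0 + int(round(window_s * fs))
    if i1 >= avg.n_samples:
        raise ValueError(
            f"record ends {avg.n_samples / fs - avg.onset_s:.4f} s after onset; "
            f"need >= {window_s} s for the power window"
        )
    v = avg.trace[i0 : i1 + 1] * 1e-6  # uV -> V
    return float(np.trapezoid(v * v, dx=1.0 / fs))


def normalize_by_animal(
    points: pd.DataFrame,
    animal_col: str = "animal_id",
    power_col: str = "power_v2s",
    out_col: str = "normalized_power",
) -> pd.DataFrame:
    """Fill the normalized response R = power / per-animal max power.

    Returns a copy with ``out_col`` added.  Every animal attains R = 1
    at its maximum (ties all kept at 1).  Animals whose powers are all
    zero (or negative, which cannot arise from a squared integral) get
    NaN and a warning; they are excluded from fitting downstream.
    """
    df = points.copy()
    gmax = df.groupby(animal_col)[power_col].transform("max")
    bad = gmax <= 0
    if bad.any():
        bad_animals = sorted(df.loc[bad, animal_col].unique().tolist())
        warnings.warn(
            f"animals with all-zero power excluded from normalization: {bad_animals}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        df[out_col] = np.where(bad, np.nan, df[power_col] / gmax)
    return df


def _fit_once(
    log_i: np.ndarray, r: np.ndarray, x0: tuple[float, float]
) -> tuple[np.ndarray, float, bool]:
    ln10 = np.log(10.0)

    def resid(x: np.ndarray) -> np.ndarray:
        log10_i50, log_slope = x
        slope = np.exp(min(log_slope, 700.0))
        z = np.clip(slope * (log10_i50 * ln10 - log_i), -700.0, 700.0)
        return 1.0 / (1.0 + np.exp(z)) - r

    res = least_squares(resid, x0=np.asarray(x0), ftol=_FTOL, xtol=1e-14, gtol=None)
    return res.x, float(2.0 * res.cost), bool(res.status > 0)


def fit_naka_rushton(
    intensity: np.ndarray, response: np.ndarray
) -> NakaRushtonFit:
    """Least-squares Naka-Rushton fit of (intensity, normalized response).

    NaN responses are dropped.  Degenerate data (fewer than 2 points, or
    all responses equal) yield a non-converged fit rather than an
    exception.  Fewer than 3 points or less than one decade of intensity
    span flags the fit unreliable.
    """
    i = np.asarray(intensity, dtype=float)
    r = np.asarray(response, dtype=float)
    keep = np.isfinite(i) & np.isfinite(r) & (i > 0)
    i, r = i[keep], r[keep]
    n = i.size
    log10_span = 0.0 if n == 0 else float(np.log10(i.max()) - np.log10(i.min()))
    reliable = n >= 3 and log10_span >= 1.0
    if n < 2 or np.ptp(r) == 0.0:
        center = float(np.exp(np.mean(np.log(i)))) if n else 1.0
        rss = float(np.sum((naka_rushton(i, center, 1.0) - r) ** 2)) if n else 0.0
        return NakaRushtonFit(center, 1.0, rss, converged=False, n_points=n, reliable=False)

    log_i = np.log(i)
    lo, hi = np.log10(i.min()), np.log10(i.max())
    if hi - lo < 1e-9:
        hi = lo + 1.0
    best: tuple[np.ndarray, float, bool] | None = None
    for l10 in np.linspace(lo, hi, _N_I50_STARTS):
        for s0 in _INITIAL_SLOPES:
            x, rss, ok = _fit_once(log_i, r, (float(l10), float(np.log(s0))))
            if best is None or rss < best[1]:
                best = (x, rss, ok)
    assert best is not None
    x, rss, ok = best
    return NakaRushtonFit(
        i50=float(10.0 ** x[0]),
        slope=float(np.exp(x[1])),
        rss=rss,
        converged=ok,
        n_points=n,
        reliable=reliable,
    )


def fit_response_table(
    points: pd.DataFrame,
    mode: str = "pooled",
    intensity_col: str = "dose_photons_um2",
    response_col: str = "normalized_power",
    animal_col: str = "animal_id",
    min_intensities_per_animal: int = 4,
) -> pd.DataFrame:
    """Fit a tidy (animal, intensity, R) table, pooled or per animal.

    ``mode="pooled"`` fits all rows together; ``mode="per_animal"``
    fits each animal separately, flagging animals with fewer than
    ``min_intensities_per_animal`` distinct intensities as unreliable
    (they are reported but should be excluded from group summaries).
    Returns one row per fit with columns
    ``(scope, animal_id, i50, slope, rss, converged, n_points, reliable)``.
    """
    rows = []
    if mode == "pooled":
        fit = fit_naka_rushton(points[intensity_col], points[response_col])
        rows.append(("pooled", "", fit))
    elif mode == "per_animal":
        for animal, grp in points.groupby(animal_col, sort=True):
            fit = fit_naka_rushton(grp[intensity_col], grp[response_col])
            if grp[intensity_col].nunique() < min_intensities_per_animal:
                fit = NakaRushtonFit(
                    fit.i50, fit.slope, fit.rss, fit.converged, fit.n_points, reliable=False
                )
            rows.append(("per_animal", str(animal), fit))
    else:
        raise ValueError(f"mode must be 'pooled' or 'per_animal', got {mode!r}")
    return pd.DataFrame(
        [
            {
                "scope": scope,
                "animal_id": animal,
                "i50": f.i50,
                "slope": f.slope,
                "rss": f.rss,
                "converged": f.converged,
                "n_points": f.n_points,
                "reliable": f.reliable,
            }
            for scope, animal, f in rows
        ]
    )
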