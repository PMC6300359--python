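"""Whole-muscle passive and active mechanics processing.

Covers: physiological cross-sectional area (PCSA) normalization,
sigmoidal force-frequency fitting with extra-sum-of-squares curve
comparison, average passive stiffness over a sarcomere-length window, and
decomposition of skinned-muscle passive tension into a titin-based
(KCl/KI extraction-sensitive) and an ECM-based (extraction-insensitive)
component.

The force-frequency relation is modelled as

    P0(F) = P0min + (P0max - P0min) / (1 + exp((Fhalf - F) / k)),

monotone increasing in stimulation frequency F, with Fhalf the frequency
of half-maximal tension and 1/k the steepness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InvalidInputError
from .stiffness import DEFAULT_WINDOW, window_slope

#: Conventional mammalian skeletal muscle density, g/cm^3.
MUSCLE_DENSITY_G_CM3 = 1.0597

PASSIVE_STATES = ("intact", "skinned", "extracted")


@dataclass(frozen=True)
class PassiveCurve:
    """Ordered (SL um, tension mN/mm^2) points for one preparation state."""

    state: str
    sarcomere_length_um: np.ndarray
    tension_mn_mm2: np.ndarray

    def __post_init__(self) -> None:
        if self.state not in PASSIVE_STATES:
            raise InvalidInputError(
                f"unknown preparation state {self.state!r}; expected {PASSIVE_STATES}"
            )
        sl = np.asarray(self.sarcomere_length_um, dtype=float)
        t = np.asarray(self.tension_mn_mm2, dtype=float)
        if sl.shape != t.shape or sl.ndim != 1:
            raise InvalidInputError("SL and tension must be 1-D arrays of equal length")
        if np.any(np.diff(sl) <= 0):
            raise InvalidInputError("sarcomere lengths must be strictly increasing")
        object.__setattr__(self, "sarcomere_length_um", sl)
        object.__setattr__(self, "tension_mn_mm2", t)


@dataclass(frozen=True)
class SigmoidParams:
    """Force-frequency sigmoid parameters (tensions mN/mm^2, Fhalf, k Hz)."""

    p0_min: float
    p0_max: float
    f_half: float
    k: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise InvalidInputError("k must be positive")
        if self.f_half <= 0:
            raise InvalidInputError("f_half must be positive")
        if self.p0_max < self.p0_min:
            raise InvalidInputError("p0_max must be >= p0_min")


def compute_pcsa(
    muscle_mass_g: float,
    pennation_angle_deg: float,
    fiber_length_cm: float,
    density_g_cm3: float = MUSCLE_DENSITY_G_CM3,
) -> float:
    """PCSA in cm^2: mass * cos(theta) / (density * fiber length)."""
    if muscle_mass_g <= 0 or fiber_length_cm <= 0:
        raise InvalidInputError("muscle mass and fiber length must be positive")
    if not 0 <= pennation_angle_deg < 90:
        raise InvalidInputError("pennation angle must be in [0, 90) degrees")
    if density_g_cm3 <= 0:
        raise InvalidInputError("density must be positive")
    return (
        muscle_mass_g
        * math.cos(math.radians(pennation_angle_deg))
        / (density_g_cm3 * fiber_length_cm)
    )


def sigmoid_eval(params: SigmoidParams, frequency_hz):
    """Evaluate the force-frequency sigmoid at ``frequency_hz``."""
    f = np.asarray(frequency_hz, dtype=float)
    out = params.p0_min + (params.p0_max - params.p0_min) / (
        1.0 + np.exp((params.f_half - f) / params.k)
    )
    return float(out) if np.isscalar(frequency_hz) else out


def _sigmoid(f, p0_min, p0_max, f_half, k):
    return p0_min + (p0_max - p0_min) / (1.0 + np.exp((f_half - f) / k))


def _fit_sigmoid_raw(freq, tension, n_restarts=4, seed=0):
    """Least-squares sigmoid fit; returns (theta, rss) or raises FitError."""
    freq = np.asarray(freq, dtype=float)
    tension = np.asarray(tension, dtype=float)
    span = float(tension.max() - tension.min())
    fspan = float(freq.max() - freq.min())
    if span <= 0 or span < 1e-9 * max(1.0, abs(tension.max())):
        raise FitError("force-frequency data are flat; sigmoid is non-identifiable")
    rng = np.random.default_rng(seed)
    # half-rise frequency guess from the data
    half_level = tension.min() + span / 2
    above = freq[tension >= half_level]
    fhalf0 = float(above.min()) if len(above) else float(np.median(freq))
    best = None
    for attempt in range(n_restarts):
        p0 = [
            float(tension.min()),
            float(tension.max()),
            fhalf0 * (1 + (0.3 * rng.standard_normal() if attempt else 0.0)),
            max(fspan / 8, 1e-3) * (1 + (0.5 * rng.random() if attempt else 0.0)),
        ]
        p0[2] = float(np.clip(p0[2], freq.min() / 2 + 1e-6, 2 * freq.max()))
        try:
            theta, _ = optimize.curve_fit(
                _sigmoid,
                freq,
                tension,
                p0=p0,
                bounds=(
                    [-np.inf, -np.inf, 1e-9, 1e-9],
                    [np.inf, np.inf, 10 * freq.max(), 10 * fspan],
                ),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((tension - _sigmoid(freq, *theta)) ** 2))
        if best is None or rss < best[1]:
            best = (theta, rss)
    if best is None:
        raise FitError("sigmoid fit did not converge after multi-start")
    return best


def fit_force_frequency(
    frequency_hz,
    tension_mn_mm2,
    n_restarts: int = 4,
    seed: int = 0,
) -> tuple[SigmoidParams, dict]:
    """Fit the force-frequency sigmoid by nonlinear least squares.

    Needs >= 5 distinct frequencies spanning the rise.  Returns the fitted
    parameters and a dict with the residual sum of squares and the
    half-maximal frequency (the fitted Fhalf).
    """
    freq = np.asarray(frequency_hz, dtype=float)
    tension = np.asarray(tension_mn_mm2, dtype=float)
    if len(np.unique(freq)) < 5:
        raise InvalidInputError("need >= 5 distinct stimulation frequencies")
    if np.any(freq <= 0):
        raise InvalidInputError("stimulation frequencies must be positive")
    theta, rss = _fit_sigmoid_raw(freq, tension, n_restarts, seed)
    p0_min, p0_max, f_half, k = theta
    if p0_max < p0_min:  # reparameterize the mirror solution
        p0_min, p0_max, k = p0_max, p0_min, -k
    if k <= 0 or f_half <= 0:
        raise FitError("sigmoid fit converged to a non-physical parameter set")
    params = SigmoidParams(p0_min=float(p0_min), p0_max=float(p0_max),
                           f_half=float(f_half), k=float(k))
    return params, {"rss": rss, "half_maximal_frequency_hz": params.f_half,
                    "n_points": len(freq)}


def _log_model(sl, a, b, c):
    return a + b * np.log(sl - c)


def _fit_log_raw(sl, tension):
    sl = np.asarray(sl, dtype=float)
    tension = np.asarray(tension, dtype=float)
    cmax = sl.min() - 1e-6
    p0 = [float(tension.mean()), max(float(np.ptp(tension)), 1e-3), sl.min() - 0.5]
    try:
        theta, _ = optimize.curve_fit(
            _log_model, sl, tension, p0=p0,
            bounds=([-np.inf, -np.inf, -np.inf], [np.inf, np.inf, cmax]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise FitError(f"logarithmic curve fit failed: {exc}") from exc
    rss = float(np.sum((tension - _log_model(sl, *theta)) ** 2))
    return theta, rss


def compare_curves_ftest(
    dataset_a: tuple[np.ndarray, np.ndarray],
    dataset_b: tuple[np.ndarray, np.ndarray],
    model: str = "sigmoid",
    seed: int = 0,
) -> tuple[float, float]:
    """Extra-sum-of-squares F-test: one shared curve vs two separate curves.

    Each dataset is an (x, y) pair — (frequency, tension) for
    ``model="sigmoid"`` or (SL, tension) for ``model="log"`` (tension =
    a + b*ln(SL - c)).  Returns (F statistic, p-value); F = 0, p = 1 when
    the separate fits do not improve on the shared fit.
    """
    if model == "sigmoid":
        fitter, n_params = _fit_sigmoid_raw, 4
        kwargs_a = {"seed": seed}
        kwargs_b = {"seed": seed + 1}
        kwargs_sh = {"seed": seed + 2}
    elif model == "log":
        fitter, n_params = _fit_log_raw, 3
        kwargs_a = kwargs_b = kwargs_sh = {}
    else:
        raise InvalidInputError(f"unknown model {model!r}")
    xa, ya = (np.asarray(v, dtype=float) for v in dataset_a)
    xb, yb = (np.asarray(v, dtype=float) for v in dataset_b)
    _, rss_a = fitter(xa, ya, **kwargs_a)
    _, rss_b = fitter(xb, yb, **kwargs_b)
    rss_sep = rss_a + rss_b
    _, rss_shared = fitter(
        np.concatenate([xa, xb]), np.concatenate([ya, yb]), **kwargs_sh
    )
    n_total = len(xa) + len(xb)
    df_sep = n_total - 2 * n_params
    if df_sep <= 0:
        raise InvalidInputError("not enough points for separate fits")
    num = max(rss_shared - rss_sep, 0.0) / n_params
    if rss_sep <= 0:
        # perfect separate fits: infinitely strong evidence unless shared
        # fit is also perfect
        return (math.inf, 0.0) if num > 0 else (0.0, 1.0)
    f_stat = num / (rss_sep / df_sep)
    p = float(stats.f.sf(f_stat, n_params, df_sep))
    return float(f_stat), p


def window_stiffness(
    curve: PassiveCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
    step: float = 0.01,
) -> float:
    """Average passive stiffness (mN/mm^2 per um) over an SL window.

    Least-squares slope of tension vs SL on a fine interpolation grid;
    the same estimator as for per-titin force curves.
    """
    return window_slope(
        curve.sarcomere_length_um, curve.tension_mn_mm2, window=window, step=step
    )


@dataclass(frozen=True)
class TensionDecomposition:
    """Titin (extraction-sensitive) vs ECM (insensitive) passive tension."""

    sarcomere_length_um: np.ndarray
    titin_tension: np.ndarray
    ecm_tension: np.ndarray
    skinned_tension: np.ndarray
    titin_fraction_percent: float
    n_negative_flagged: int


def decompose_passive_tension(
    skinned: PassiveCurve,
    extracted: PassiveCurve,
    fraction_range: tuple[float, float] | None = None,
) -> TensionDecomposition:
    """Split skinned-muscle passive tension into titin and ECM components.

    titin(SL) = skinned(SL) - extracted(SL) on the common SL support
    (linear interpolation, no extrapolation), floored at 0 with negatives
    counted; ecm(SL) = extracted(SL).  ``titin_fraction_percent`` is
    100 * mean(titin) / mean(skinned) over ``fraction_range`` (default:
    the whole common support).
    """
    lo = max(skinned.sarcomere_length_um[0], extracted.sarcomere_length_um[0])
    hi = min(skinned.sarcomere_length_um[-1], extracted.sarcomere_length_um[-1])
    if lo >= hi:
        raise InvalidInputError("skinned and extracted curves have disjoint SL support")
    grid = np.union1d(skinned.sarcomere_length_um, extracted.sarcomere_length_um)
    grid = grid[(grid >= lo) & (grid <= hi)]
    sk = np.interp(grid, skinned.sarcomere_length_um, skinned.tension_mn_mm2)
    ex = np.interp(grid, extracted.sarcomere_length_um, extracted.tension_mn_mm2)
    titin = sk - ex
    n_neg = int(np.sum(titin < 0))
    titin = np.clip(titin, 0.0, None)

    if fraction_range is None:
        mask = np.ones_like(grid, dtype=bool)
    else:
        flo, fhi = fraction_range
        mask = (grid >= flo) & (grid <= fhi)
        if not mask.any():
            raise InvalidInputError(
                f"fraction_range {fraction_range} has no points on the common support"
            )
    mean_sk = float(np.mean(sk[mask]))
    fraction = 100.0 * float(np.mean(titin[mask])) / mean_sk if mean_sk > 0 else math.nan
    return TensionDecomposition(
        sarcomere_length_um=grid,
        titin_tension=titin,
        ecm_tension=ex,
        skinned_tension=titin + ex,
        titin_fraction_percent=fraction,
        n_negative_flagged=n_neg,
    )
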