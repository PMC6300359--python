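"""Wormlike-chain (WLC) modelling of the titin PEVK spring.

The PEVK segment is treated as an entropic wormlike chain of persistence
length PL and contour length CL = n_residues x 0.38 nm (maximal residue
spacing of an unfolded chain).  The interpolation formula for the
force-extension relation is

    F(x) * PL / (kB*T) = x + 1 / (4 * (1 - x)^2) - 1/4,   x = z / CL,

with z the end-to-end extension.  F(0) = 0, F grows linearly as
(3/2) * (kB*T/PL) * x for small x and diverges as x -> 1.

Extensions come from super-resolution epitope separations between
antibodies flanking the PEVK; because the antibodies do not bind exactly
adjacent to the segment, 15 nm (~4 Ig domains) is subtracted from the
measured separation.  Epitope positions themselves are obtained by
fitting sums of Gaussians to fluorescence intensity line profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .errors import DomainError, FitError, InvalidInputError
from .stiffness import DEFAULT_WINDOW, window_slope

#: nm subtracted from measured epitope separations (antibody offset).
EPITOPE_OFFSET_NM = 15.0

#: Maximal spacing of one residue in an unfolded chain, nm.
RESIDUE_SPACING_NM = 0.38


@dataclass(frozen=True)
class WlcParams:
    """Wormlike-chain parameters.

    persistence_length in nm (default 1.4 for the PEVK), thermal_energy
    kB*T in pN*nm (default 4.11, T = 298 K), residue_spacing in nm.
    """

    persistence_length: float = 1.4
    thermal_energy: float = 4.11
    residue_spacing: float = RESIDUE_SPACING_NM

    def __post_init__(self) -> None:
        for name in ("persistence_length", "thermal_energy", "residue_spacing"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


@dataclass(frozen=True)
class PevkSpring:
    """PEVK segment of one genotype/muscle: residue count and contour length."""

    n_residues: float
    contour_length: float  # nm

    @classmethod
    def from_residues(
        cls, n_residues: float, residue_spacing: float = RESIDUE_SPACING_NM
    ) -> "PevkSpring":
        return cls(n_residues, contour_length(n_residues, residue_spacing))


def contour_length(
    n_residues: float, residue_spacing: float = RESIDUE_SPACING_NM
) -> float:
    """Contour length in nm of an unfolded chain of ``n_residues``."""
    if n_residues < 0:
        raise InvalidInputError("n_residues must be >= 0")
    if residue_spacing <= 0:
        raise InvalidInputError("residue_spacing must be positive")
    return n_residues * residue_spacing


def correct_epitope_separation(measured_separation_nm):
    """Extension z = measured separation - 15 nm antibody offset.

    Vectorized; negative corrected values are returned as-is so callers
    can flag and exclude them (see :func:`correct_epitope_table`).
    """
    sep = np.asarray(measured_separation_nm, dtype=float)
    if np.any(sep < 0):
        raise InvalidInputError("measured separations must be >= 0")
    out = sep - EPITOPE_OFFSET_NM
    return float(out) if np.isscalar(measured_separation_nm) else out


def correct_epitope_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add corrected extension and a flag column to an epitope table.

    Expects columns ``sarcomere_length_um`` and ``separation_nm``; adds
    ``z_nm`` and boolean ``flagged`` (negative extension after correction).
    """
    out = table.copy()
    out["z_nm"] = correct_epitope_separation(out["separation_nm"].to_numpy())
    out["flagged"] = out["z_nm"] < 0
    return out


def wlc_force(z_nm, spring: PevkSpring, params: WlcParams | None = None):
    """WLC force in pN at extension ``z_nm`` (scalar or array)."""
    params = params or WlcParams()
    if spring.contour_length <= 0:
        raise DomainError("contour length must be positive for force evaluation")
    z = np.asarray(z_nm, dtype=float)
    x = z / spring.contour_length
    if np.any(x < 0):
        raise InvalidInputError("extension must be >= 0")
    if np.any(x >= 1):
        bad = np.atleast_1d(z)[np.atleast_1d(x) >= 1]
        raise DomainError(
            f"extension reaches contour length (CL = {spring.contour_length:.2f} nm) "
            f"at z = {np.array2string(bad, precision=2)}; WLC force diverges"
        )
    force = (params.thermal_energy / params.persistence_length) * (
        x + 1.0 / (4.0 * (1.0 - x) ** 2) - 0.25
    )
    return float(force) if np.isscalar(z_nm) else force


def titin_force_curve(
    measurements: pd.DataFrame,
    spring: PevkSpring,
    params: WlcParams | None = None,
    sl_grid: np.ndarray | None = None,
    mode: str = "fit",
) -> pd.DataFrame:
    """Per-titin force vs sarcomere length from epitope measurements.

    ``measurements`` needs columns ``sarcomere_length_um`` and either
    ``z_nm`` or ``separation_nm`` (corrected internally); flagged negative
    extensions are excluded.  A linear least-squares fit of z on SL
    (``mode="fit"``, default) or per-SL group means (``mode="group-mean"``)
    supplies z on the evaluation grid; the WLC map then gives force.

    Returns columns ``sarcomere_length_um, z_nm, force_pn``.
    """
    if mode not in ("fit", "group-mean"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    table = measurements.copy()
    if "z_nm" not in table.columns:
        table = correct_epitope_table(table)
    table = table[table["z_nm"] >= 0]
    sl = table["sarcomere_length_um"].to_numpy(dtype=float)
    z = table["z_nm"].to_numpy(dtype=float)
    if len(np.unique(sl)) < 2:
        raise InvalidInputError("need measurements at >= 2 distinct sarcomere lengths")

    if mode == "fit":
        slope, intercept = np.polyfit(sl, z, 1)
        if sl_grid is None:
            sl_grid = np.arange(sl.min(), sl.max() + 5e-3, 0.01)
        z_grid = intercept + slope * np.asarray(sl_grid, dtype=float)
    else:
        order = np.unique(sl)
        z_grid = np.array([z[sl == s].mean() for s in order])
        sl_grid = order
    z_grid = np.clip(z_grid, 0.0, None)
    force = wlc_force(z_grid, spring, params)
    return pd.DataFrame(
        {"sarcomere_length_um": np.asarray(sl_grid, dtype=float),
         "z_nm": z_grid,
         "force_pn": force}
    )


def average_titin_stiffness(
    curve: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    step: float = 0.01,
) -> float:
    """Average per-titin stiffness (pN/um): window slope of the force curve."""
    return window_slope(
        curve["sarcomere_length_um"].to_numpy(),
        curve["force_pn"].to_numpy(),
        window=window,
        step=step,
    )


def _sum_of_gaussians(x, *theta):
    n = len(theta) // 3
    out = np.zeros_like(x, dtype=float)
    for i in range(n):
        amp, center, width = theta[3 * i : 3 * i + 3]
        out += amp * np.exp(-0.5 * ((x - center) / width) ** 2)
    return out


def fit_epitope_peaks(
    position_nm: np.ndarray,
    intensity: np.ndarray,
    n_peaks: int,
    n_restarts: int = 5,
    seed: int = 0,
):
    """Fit a sum of ``n_peaks`` Gaussians to an intensity line profile.

    Initial centers come from local maxima (randomly perturbed on
    restarts).  Returns ``(centers, result)`` where centers are sorted nm
    positions and ``result`` is a dict with amplitudes, widths and the
    residual sum of squares.  Raises FitError if no restart converges or
    the profile carries no signal.
    """
    x = np.asarray(position_nm, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if n_peaks < 1:
        raise InvalidInputError("n_peaks must be >= 1")
    if len(x) < 5 * n_peaks:
        raise InvalidInputError(
            f"profile has {len(x)} samples; need >= {5 * n_peaks} for {n_peaks} peaks"
        )
    if np.any(np.diff(x) <= 0):
        raise InvalidInputError("positions must be strictly increasing")
    if np.any(y < 0):
        raise InvalidInputError("intensities must be >= 0")
    span = x[-1] - x[0]
    amp_scale = float(y.max() - y.min())
    if amp_scale <= 0 or amp_scale < 1e-9 * max(1.0, y.max()):
        raise FitError("flat intensity profile: no peaks to fit")

    peaks, props = signal.find_peaks(y, prominence=0.1 * amp_scale)
    if len(peaks) >= n_peaks:
        order = np.argsort(props["prominences"])[::-1][:n_peaks]
        centers0 = np.sort(x[peaks[order]])
    else:
        centers0 = np.linspace(x[0] + 0.2 * span, x[-1] - 0.2 * span, n_peaks)
    width0 = span / (6.0 * n_peaks)
    rng = np.random.default_rng(seed)

    best = None
    errors = []
    for attempt in range(n_restarts):
        centers = centers0.copy()
        if attempt > 0:
            centers = centers + rng.normal(0, 0.05 * span, n_peaks)
        theta0 = []
        for c in centers:
            theta0 += [amp_scale, float(np.clip(c, x[0], x[-1])), width0 * (1 + attempt)]
        try:
            import warnings

            with warnings.catch_warnings():
                # covariance estimation can fail on degenerate restarts;
                # only the point estimate is used
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                theta, _ = optimize.curve_fit(
                    _sum_of_gaussians, x, y, p0=theta0, maxfev=20_000
                )
        except RuntimeError as exc:  # no convergence
            errors.append(str(exc))
            continue
        rss = float(np.sum((y - _sum_of_gaussians(x, *theta)) ** 2))
        if best is None or rss < best[1]:
            best = (theta, rss)
    if best is None:
        raise FitError(
            f"Gaussian peak fit failed after {n_restarts} restarts: {errors[-1] if errors else 'no attempts converged'}"
        )
    theta, rss = best
    params = np.array(theta).reshape(n_peaks, 3)
    order = np.argsort(params[:, 1])
    params = params[order]
    centers = params[:, 1]
    if np.any(centers < x[0] - 0.1 * span) or np.any(centers > x[-1] + 0.1 * span):
        raise FitError("fitted peak centers fall outside the profile span")
    result = {
        "amplitudes": params[:, 0],
        "centers": centers,
        "widths": np.abs(params[:, 2]),
        "rss": rss,
    }
    return centers.copy(), result


def halve(spring: PevkSpring) -> PevkSpring:
    """Spring with half the contour length (utility for comparisons)."""
    return replace(spring, contour_length=spring.contour_length / 2)
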