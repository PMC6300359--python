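"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its spec and seed: identical inputs
give identical outputs.  What they emulate (and what they do not) is
documented in docs/methods.md; briefly:

* exon reads — two-isoform exon inclusion mixtures: per exon, inclusion
  events are Bernoulli(pi) over a fixed number of informative reads, and
  raw counts are scaled so that length-normalized PSI estimates have
  expectation 100*pi;
* passive curves — wormlike-chain titin tension (scaled by titins per
  cross-sectional area) plus exponential ECM tension with additive
  Gaussian noise, in the intact/skinned/extracted preparation states;
* force-frequency data — sigmoid responses with Gaussian noise;
* epitope profiles — sums of Gaussians with non-negative-clipped noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidInputError
from .exon_usage import ExonRecord, SampleCounts
from .mechanics import PassiveCurve, SigmoidParams, sigmoid_eval
from .polymer import PevkSpring, WlcParams, wlc_force

#: Default read length (nt) of the emulated paired-end sequencing.
DEFAULT_READ_LENGTH = 100

#: Default stimulation frequencies (Hz) of the force-frequency protocol.
DEFAULT_FREQUENCIES = (1, 10, 20, 40, 60, 80, 100, 120, 150, 200)

#: Titin molecules per mm^2 of muscle cross-section used to scale
#: per-molecule force (pN) to specific tension (mN/mm^2).  ~3e9/mm^2
#: puts simulated tensions on the tens-of-mN/mm^2 scale of measured
#: skeletal muscle curves; only ratios are asserted in tests.
DEFAULT_TITINS_PER_MM2 = 3.0e9

PN_PER_MN = 1.0e9


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class IsoformSpec:
    """Two-isoform mixture spec: per-exon inclusion probabilities."""

    inclusion_probs: np.ndarray  # aligned with the annotation order
    depth: int = 10_000  # informative reads per exon locus
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.inclusion_probs, dtype=float)
        if np.any((probs < 0) | (probs > 1)):
            raise InvalidInputError("inclusion probabilities must lie in [0, 1]")
        if self.depth < 1:
            raise InvalidInputError("depth must be >= 1")
        if self.read_length < 2:
            raise InvalidInputError("read_length must be >= 2")
        object.__setattr__(self, "inclusion_probs", probs)


def simulate_exon_reads(
    spec: IsoformSpec,
    annotation: list[ExonRecord],
    sample_id: str = "sim",
    genotype: str = "WT",
    muscle: str = "diaphragm",
) -> SampleCounts:
    """Simulate per-exon inclusion/exclusion read counts for one sample.

    Reads are assigned uniformly across exon loci (``depth`` informative
    reads each).  Inclusion events are Bernoulli(pi); the inclusion count
    is rescaled by (exon_length + L - 1)/(L - 1) so that the
    length-normalized PSI estimate has expectation 100*pi.
    """
    if not annotation:
        raise InvalidInputError("annotation must be non-empty")
    probs = spec.inclusion_probs
    if len(probs) != len(annotation):
        raise InvalidInputError(
            f"{len(probs)} inclusion probabilities for {len(annotation)} exons"
        )
    rng = _rng(spec.seed)
    length_nt = np.array([e.length_nt for e in annotation])
    included = rng.binomial(spec.depth, probs)
    scale = (length_nt + spec.read_length - 1) / (spec.read_length - 1)
    counts = pd.DataFrame(
        {
            "exon_index": [e.exon_index for e in annotation],
            "inclusion_reads": np.round(included * scale).astype(int),
            "exclusion_reads": (spec.depth - included).astype(int),
        }
    )
    return SampleCounts(
        sample_id=sample_id,
        genotype=genotype,
        muscle=muscle,
        read_length=spec.read_length,
        counts=counts,
    )


@dataclass(frozen=True)
class PassiveCurveSpec:
    """Spec for synthetic passive tension curves.

    Titin tension: WLC force of a spring with ``n_residues`` at extension
    z(SL) = extension_per_um * (SL - slack_sl), scaled by titin density.
    ECM tension: amplitude * (exp(rate * (SL - onset)) - 1), clamped at 0.
    """

    n_residues: float = 1611.0
    titins_per_mm2: float = DEFAULT_TITINS_PER_MM2
    extension_per_um: float = 100.0  # nm of PEVK extension per um of SL
    slack_sl_um: float = 2.0
    ecm_amplitude: float = 0.2  # mN/mm^2
    ecm_rate: float = 2.5  # per um
    ecm_onset_um: float = 2.2
    noise_sd: float = 0.2  # mN/mm^2
    sl_grid: tuple = field(default=tuple(np.round(np.arange(2.0, 3.21, 0.05), 3)))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        grid = np.asarray(self.sl_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise InvalidInputError("sl_grid must be strictly increasing")


def passive_curve_truth(spec: PassiveCurveSpec) -> pd.DataFrame:
    """Noise-free titin and ECM tension components on the spec's SL grid."""
    grid = np.asarray(spec.sl_grid, dtype=float)
    spring = PevkSpring.from_residues(spec.n_residues)
    z = np.clip(spec.extension_per_um * (grid - spec.slack_sl_um), 0.0, None)
    if np.any(z >= spring.contour_length):
        raise DomainError(
            "implied PEVK extension reaches the contour length "
            f"({spring.contour_length:.1f} nm); shorten the SL grid or the spring"
        )
    titin = wlc_force(z, spring, WlcParams()) * spec.titins_per_mm2 / PN_PER_MN
    ecm = np.clip(
        spec.ecm_amplitude * (np.exp(spec.ecm_rate * (grid - spec.ecm_onset_um)) - 1.0),
        0.0,
        None,
    )
    return pd.DataFrame(
        {"sarcomere_length_um": grid, "titin_tension": titin, "ecm_tension": ecm}
    )


def simulate_passive_curve(
    spec: PassiveCurveSpec,
) -> dict[str, PassiveCurve]:
    """Simulate intact, skinned and extracted passive tension curves.

    Intact and skinned both measure titin + ECM (skinning leaves passive
    tension unchanged); extracted measures ECM only.  Independent Gaussian
    noise is added per point and curve, floored at zero tension.
    """
    rng = _rng(spec.seed)
    truth = passive_curve_truth(spec)
    grid = truth["sarcomere_length_um"].to_numpy()
    total = truth["titin_tension"].to_numpy() + truth["ecm_tension"].to_numpy()
    ecm = truth["ecm_tension"].to_numpy()
    curves = {}
    for state, signal_ in (("intact", total), ("skinned", total), ("extracted", ecm)):
        noisy = signal_ + rng.normal(0.0, spec.noise_sd, size=grid.shape)
        curves[state] = PassiveCurve(
            state=state,
            sarcomere_length_um=grid,
            tension_mn_mm2=np.clip(noisy, 0.0, None),
        )
    return curves


def simulate_ff_data(
    params: SigmoidParams,
    frequencies=DEFAULT_FREQUENCIES,
    noise_sd: float = 0.0,
    seed=0,
) -> pd.DataFrame:
    """Sigmoid force-frequency responses with additive Gaussian noise."""
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    freq = np.asarray(frequencies, dtype=float)
    if np.any(freq <= 0) or len(np.unique(freq)) != len(freq):
        raise InvalidInputError("frequencies must be positive and distinct")
    rng = _rng(seed)
    tension = sigmoid_eval(params, freq) + rng.normal(0.0, noise_sd, size=freq.shape)
    return pd.DataFrame({"frequency_hz": freq, "tension_mn_mm2": tension})


def simulate_epitope_profile(
    centers_nm,
    widths_nm,
    amplitudes,
    noise_sd: float = 0.0,
    step_nm: float = 10.0,
    pad_nm: float = 200.0,
    seed=0,
) -> pd.DataFrame:
    """1-D fluorescence intensity profile: sum of Gaussians plus noise.

    Noise is clipped so intensities stay non-negative.  Warns when the
    sampling step exceeds the narrowest peak width (under-sampling).
    """
    import warnings

    centers = np.asarray(centers_nm, dtype=float)
    widths = np.asarray(widths_nm, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if not (len(centers) == len(widths) == len(amps)):
        raise InvalidInputError("centers, widths, amplitudes must have equal length")
    if np.any(widths <= 0) or np.any(amps <= 0):
        raise InvalidInputError("widths and amplitudes must be positive")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    if step_nm > widths.min():
        warnings.warn(
            f"sampling step {step_nm} nm exceeds the narrowest peak width "
            f"{widths.min()} nm; profile is under-sampled",
            stacklevel=2,
        )
    rng = _rng(seed)
    x = np.arange(centers.min() - pad_nm, centers.max() + pad_nm + step_nm / 2, step_nm)
    y = np.zeros_like(x)
    for c, w, a in zip(centers, widths, amps):
        y += a * np.exp(-0.5 * ((x - c) / w) ** 2)
    y = np.clip(y + rng.normal(0.0, noise_sd, size=x.shape), 0.0, None)
    return pd.DataFrame({"position_nm": x, "intensity": y})
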