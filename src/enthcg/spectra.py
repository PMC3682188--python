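"""CW-EPR lineshape primitives shared by the generator and the estimator.

The basis spectrum is a mobile-nitroxide first-derivative lineshape: three
Lorentzian-derivative lines split by the :sup:`14`\\ N hyperfine coupling.
Static dipolar coupling between two nitroxides at interspin distance *r*
is modelled as a Gaussian broadening of the field axis whose standard
deviation follows the point-dipole 1/r^3 law,

    sigma_B(r) = C / r^3   [Gauss, r in Angstrom],

with C fixed once from the nitroxide point-dipole coupling constant
(orientation-averaged) so that r = 13 A produces broadening comparable to
the intrinsic linewidth.  A distribution of distances (Gaussian, center r,
width w) is handled by mixing broadening kernels over the distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: effective dipolar constant, Gauss * A^3 (orientation-averaged point dipole)
DIPOLAR_C = 6.6e3

#: CW dipolar-broadening sensitivity window, Angstrom
R_MIN, R_MAX = 5.0, 25.0

#: default acquisition: 150 G scan width centred on the nitroxide resonance
DEFAULT_CENTER = 3350.0
DEFAULT_SCAN_WIDTH = 150.0
DEFAULT_N_POINTS = 1201

#: default intrinsic parameters (arbitrary but representative): 14N hyperfine
#: splitting and Lorentzian half-width at half-maximum, Gauss
DEFAULT_HYPERFINE = 15.0
DEFAULT_HWHM = 2.0


def field_axis(center: float = DEFAULT_CENTER,
               scan_width: float = DEFAULT_SCAN_WIDTH,
               n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Uniform magnetic-field grid spanning one scan width."""
    return np.linspace(center - scan_width / 2.0, center + scan_width / 2.0,
                       n_points)


def check_uniform(field: np.ndarray) -> float:
    """Return the grid step; raise if the field axis is not uniform."""
    field = np.asarray(field, dtype=float)
    if field.ndim != 1 or field.size < 8:
        raise ValueError("field axis must be a 1-D grid")
    steps = np.diff(field)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
        raise ValueError("field axis must be uniform")
    return float(steps[0])


def nitroxide_derivative(field: np.ndarray,
                         center: float | None = None,
                         hyperfine: float = DEFAULT_HYPERFINE,
                         hwhm: float = DEFAULT_HWHM) -> np.ndarray:
    """Three-line Lorentzian first-derivative nitroxide spectrum."""
    field = np.asarray(field, dtype=float)
    if center is None:
        center = 0.5 * (field[0] + field[-1])
    out = np.zeros_like(field)
    for shift in (-hyperfine, 0.0, hyperfine):
        x = field - (center + shift)
        out += -2.0 * hwhm * x / (np.pi * (x * x + hwhm * hwhm) ** 2)
    return out


def sigma_dipolar(distance: float) -> float:
    """Gaussian broadening width (Gauss) for an interspin distance in A."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    return DIPOLAR_C / distance ** 3


def gaussian_kernel(sigma: float, step: float,
                    max_half: int | None = None) -> np.ndarray:
    """Unit-area discrete Gaussian kernel on a uniform grid."""
    if sigma <= 0:
        return np.array([1.0])
    half = max(int(np.ceil(5.0 * sigma / step)), 1)
    if max_half is not None:
        half = min(half, max_half)
    x = np.arange(-half, half + 1) * step
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def broaden(amplitude: np.ndarray, sigma: float, step: float) -> np.ndarray:
    """Convolve a spectrum with the Gaussian dipolar kernel."""
    if sigma <= 0:
        return np.array(amplitude, dtype=float, copy=True)
    kernel = gaussian_kernel(sigma, step, max_half=(len(amplitude) - 1) // 2)
    return np.convolve(amplitude, kernel, mode="same")


def broaden_distribution(amplitude: np.ndarray, r_center: float,
                         r_width: float, step: float,
                         n_quad: int = 15) -> np.ndarray:
    """Broadened spectrum for a Gaussian distance distribution.

    Distances are sampled on a +/- 3 sigma grid clipped to the sensitivity
    window; each contributes its own 1/r^3 kernel, weighted by the Gaussian
    distance distribution.
    """
    if r_width <= 1e-3:
        return broaden(amplitude, sigma_dipolar(r_center), step)
    r = np.linspace(r_center - 3.0 * r_width, r_center + 3.0 * r_width, n_quad)
    r = np.clip(r, R_MIN, None)   # the distribution's sub-window tail is
    # outside the CW sensitivity model and is folded onto the window edge
    w = np.exp(-0.5 * ((r - r_center) / r_width) ** 2)
    w /= w.sum()
    out = np.zeros_like(np.asarray(amplitude, dtype=float))
    for ri, wi in zip(r, w):
        out += wi * broaden(amplitude, sigma_dipolar(ri), step)
    return out


def mix_full_labeled(diluted: np.ndarray, fraction: float, r_center: float,
                     r_width: float, step: float) -> np.ndarray:
    """Forward model of the fully labelled spectrum.

    A fraction of spin pairs experiences dipolar broadening; the rest keep
    the intrinsic (spin-diluted) lineshape.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return np.array(diluted, dtype=float, copy=True)
    broadened = broaden_distribution(diluted, r_center, r_width, step)
    return (1.0 - fraction) * np.asarray(diluted, float) + fraction * broadened


def remove_linear_baseline(field: np.ndarray,
                           amplitude: np.ndarray) -> np.ndarray:
    """Subtract the straight line through the spectrum's outer wings."""
    field = np.asarray(field, float)
    amplitude = np.asarray(amplitude, float)
    n_edge = max(len(field) // 20, 2)
    idx = np.r_[np.arange(n_edge), np.arange(len(field) - n_edge, len(field))]
    coef = np.polyfit(field[idx], amplitude[idx], 1)
    return amplitude - np.polyval(coef, field)


def double_integral(field: np.ndarray, amplitude: np.ndarray) -> float:
    """Double integral of a first-derivative spectrum (spin count proxy)."""
    step = check_uniform(field)
    absorption = np.cumsum(np.asarray(amplitude, float)) * step
    return float(np.trapezoid(absorption, dx=step))


def normalize_spins(field: np.ndarray, amplitude: np.ndarray,
                    target: float = 1.0) -> np.ndarray:
    """Scale a spectrum so its double integral equals ``target``."""
    di = double_integral(field, amplitude)
    if not np.isfinite(di) or di <= 0:
        raise ValueError("spectrum double integral must be finite and positive")
    return np.asarray(amplitude, float) * (target / di)


@dataclass
class SpectrumPair:
    """A fully labelled / spin-diluted CW spectrum pair on a shared axis."""

    field: np.ndarray
    full_labeled: np.ndarray
    spin_diluted: np.ndarray
    true_distance: float | None = None
    true_width: float | None = None
    interacting_fraction: float | None = None

    def __post_init__(self) -> None:
        check_uniform(self.field)
        if not (len(self.field) == len(self.full_labeled)
                == len(self.spin_diluted)):
            raise ValueError("spectra must share the field axis")
        for amp in (self.full_labeled, self.spin_diluted):
            di = double_integral(self.field, amp)
            if not np.isfinite(di) or di <= 0:
                raise ValueError(
                    "spectrum double integral must be finite and positive")
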