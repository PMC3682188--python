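"""Seeded generators for every synthetic input the analysis chain consumes.

Four families of fixtures:

* Gaussian elastic-network bead trajectories with a known analytic
  covariance (reference input for coarse-graining),
* CW-EPR spectrum pairs with a known interspin distance, width and
  interacting fraction,
* sinusoidal per-residue accessibility (Phi) profiles with the 3.6-residue
  helical period,
* depth-calibration point sets drawn from d = a*Phi + b plus noise.

Every generator is a pure function of its arguments and one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import spectra
from .constants import kt


# ---------------------------------------------------------------------------
# elastic-network reference trajectories
# ---------------------------------------------------------------------------

@dataclass
class ENMSpec:
    """A bead-spring network with harmonic springs at its equilibrium shape.

    stiffness in kcal/(mol nm^2); coordinates in nm.
    """

    coords: np.ndarray                      # (n_beads, 3)
    springs: list = field(default_factory=list)   # (i, j, k)
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        for i, j, k in self.springs:
            if k <= 0:
                raise ValueError(f"spring ({i},{j}) has non-positive "
                                 f"stiffness {k}")
            if not (0 <= i < self.n_beads and 0 <= j < self.n_beads) or i == j:
                raise ValueError(f"spring ({i},{j}) references invalid beads")

    @property
    def n_beads(self) -> int:
        return len(self.coords)


def chain_spec(n_beads: int, spacing: float = 0.5, stiffness: float = 1.0,
               temperature: float = 300.0) -> ENMSpec:
    """Convenience: a linear bead chain with nearest-neighbour springs."""
    coords = np.zeros((n_beads, 3))
    coords[:, 0] = np.arange(n_beads) * spacing
    springs = [(i, i + 1, stiffness) for i in range(n_beads - 1)]
    return ENMSpec(coords, springs, temperature)


def _check_connected(spec: ENMSpec) -> None:
    n = spec.n_beads
    rows = [s[0] for s in spec.springs] + [s[1] for s in spec.springs]
    cols = [s[1] for s in spec.springs] + [s[0] for s in spec.springs]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        comps = [sorted(np.flatnonzero(labels == c).tolist())
                 for c in range(n_comp)]
        raise ValueError(f"spring graph is disconnected; components: {comps}")


def enm_hessian(spec: ENMSpec) -> np.ndarray:
    """Mass-unweighted 3N x 3N Hessian of the harmonic network."""
    n = spec.n_beads
    hess = np.zeros((3 * n, 3 * n))
    for i, j, k in spec.springs:
        d = spec.coords[j] - spec.coords[i]
        r = np.linalg.norm(d)
        if r < 1e-12:
            raise ValueError(f"beads {i} and {j} coincide")
        e = d / r
        block = k * np.outer(e, e)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hess[si, si] += block
        hess[sj, sj] += block
        hess[si, sj] -= block
        hess[sj, si] -= block
    return hess


def enm_covariance(spec: ENMSpec, rigid_tol: float = 1e-8) -> np.ndarray:
    """Analytic fluctuation covariance kB*T * H^+ (rigid modes removed)."""
    hess = enm_hessian(spec)
    evals, evecs = np.linalg.eigh(hess)
    scale = max(evals.max(), 1.0)
    soft = evals < rigid_tol * scale
    inv = np.zeros_like(evals)
    inv[~soft] = 1.0 / evals[~soft]
    return kt(spec.temperature) * (evecs * inv) @ evecs.T


def gen_enm_trajectory(spec: ENMSpec, n_frames: int, seed: int) -> np.ndarray:
    """Draw i.i.d. Gaussian frames with covariance kB*T * H^+.

    Returns an (n_frames, n_beads, 3) array.  Null modes of the Hessian
    (the 6 rigid-body modes, plus any internal mechanisms such as chain
    bending in a nearest-neighbour chain) carry no displacement, so frames
    are already aligned to the reference.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    _check_connected(spec)
    hess = enm_hessian(spec)
    evals, evecs = np.linalg.eigh(hess)
    scale = max(evals.max(), 1.0)
    if evals.min() < -1e-8 * scale:
        raise ValueError("Hessian is not positive semidefinite")
    soft = evals < 1e-8 * scale
    if int(soft.sum()) < 5:
        raise ValueError("fewer than 5 rigid-body modes found; "
                         "degenerate geometry")
    amps = np.zeros_like(evals)
    amps[~soft] = np.sqrt(kt(spec.temperature) / evals[~soft])
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((n_frames, len(evals)))
    disp = (xi * amps) @ evecs.T
    return spec.coords[None, :, :] + disp.reshape(n_frames, spec.n_beads, 3)


# ---------------------------------------------------------------------------
# CW-EPR spectrum pairs
# ---------------------------------------------------------------------------

def gen_pair_spectrum(distance: float, width: float, fraction: float,
                      seed: int, noise_sd: float = 0.0,
                      n_points: int = spectra.DEFAULT_N_POINTS,
                      scan_width: float = spectra.DEFAULT_SCAN_WIDTH,
                      hyperfine: float = spectra.DEFAULT_HYPERFINE,
                      hwhm: float = spectra.DEFAULT_HWHM
                      ) -> spectra.SpectrumPair:
    """Synthesize a fully labelled / spin-diluted spectrum pair.

    The diluted spectrum is the intrinsic three-line nitroxide derivative;
    the fully labelled one mixes in the dipolar-broadened component for the
    interacting fraction.  Both are normalized to the same number of spins
    by double integration.
    """
    if not spectra.R_MIN <= distance <= spectra.R_MAX:
        raise ValueError(
            f"distance {distance} A outside CW sensitivity range "
            f"[{spectra.R_MIN}, {spectra.R_MAX}] A")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    field_ax = spectra.field_axis(scan_width=scan_width, n_points=n_points)
    step = field_ax[1] - field_ax[0]
    diluted = spectra.nitroxide_derivative(field_ax, hyperfine=hyperfine,
                                           hwhm=hwhm)
    diluted = spectra.normalize_spins(field_ax, diluted)
    full = spectra.mix_full_labeled(diluted, fraction, distance, width, step)
    full = spectra.normalize_spins(field_ax, full)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        peak = np.abs(diluted).max()
        full = full + rng.normal(0.0, noise_sd * peak, full.shape)
        diluted = diluted + rng.normal(0.0, noise_sd * peak, diluted.shape)
    return spectra.SpectrumPair(field_ax, full, diluted,
                                true_distance=distance, true_width=width,
                                interacting_fraction=fraction)


# ---------------------------------------------------------------------------
# accessibility profiles
# ---------------------------------------------------------------------------

def gen_accessibility_profile(n_residues: int, period: float = 3.6,
                              phase: float = 0.0, amplitude: float = 1.0,
                              noise_sd: float = 0.0, seed: int = 0,
                              offset: float = 0.0) -> np.ndarray:
    """Per-residue Phi values on residues 1..n with a helical cosine.

    Phi_i = amplitude * cos(2*pi*i/period + phase) + offset + noise.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    if period <= 2.0:
        raise ValueError("period must exceed 2 residues (Nyquist limit)")
    i = np.arange(1, n_residues + 1, dtype=float)
    phi = amplitude * np.cos(2.0 * np.pi * i / period + phase) + offset
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, noise_sd, phi.shape)
    return phi


# ---------------------------------------------------------------------------
# depth calibration point sets
# ---------------------------------------------------------------------------

@dataclass
class CalibrationSet:
    """(Phi, depth) points generated from d = a*Phi + b with known truth."""

    phis: np.ndarray
    depths: np.ndarray
    true_a: float
    true_b: float
    noise_sd: float

    @property
    def points(self) -> list:
        return list(zip(self.phis.tolist(), self.depths.tolist()))


def gen_calibration_points(a: float, b: float, phis, noise_sd: float,
                           seed: int) -> CalibrationSet:
    """Depths in Angstrom from the linear immersion-depth relation."""
    phis = np.asarray(phis, dtype=float)
    if phis.size < 2:
        raise ValueError("need at least 2 calibration points")
    if np.allclose(phis, phis[0]):
        raise ValueError("all Phi values equal; slope unidentifiable")
    depths = a * phis + b
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        depths = depths + rng.normal(0.0, noise_sd, depths.shape)
    return CalibrationSet(phis, depths, a, b, noise_sd)
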