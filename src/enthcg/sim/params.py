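"""Parameter containers for the CG membrane simulator.

The lipid is a single Gay-Berne ellipsoid, aspect ratio 3:1, with the
symmetry along the long axis broken by an extra term odd under a director
flip (heads and tails approach differently).  The exact in-plane potential
of the parent lipid model is not public; the values below are the
package's own "fixture parameter set", calibrated in-repo so that a flat
tensionless bilayer is stable at 300 K (see examples/calibrate_lipids.py).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: membrane-interacting site codes used by the pair kernel
T_LIPID, T_PIP2, T_H0A, T_H0B, T_PATCH, T_R114, T_POCKET, T_GEN = range(8)
N_TYPES = 8

#: pair interaction modes
MODE_NONE, MODE_GB, MODE_LJ, MODE_WCA = 0, 1, 2, 3


@dataclass
class GBParams:
    """Gay-Berne lipid parameters (fixture set).

    aspect_ratio kappa = length/breadth (3:1 lipid shape);
    well_anisotropy kappa' = side-by-side vs end-to-end well ratio;
    head_tail_asymmetry eps_a (kcal/mol) breaks the long-axis symmetry:
    negative values make tail-tail end contact cohesive and head-head
    contact repulsive, the amphiphilic bias that keeps two leaflets
    tail-to-tail.
    """

    sigma0: float = 0.8           # nm, breadth
    epsilon0: float = 2.2         # kcal/mol
    aspect_ratio: float = 3.0
    well_anisotropy: float = 5.0
    head_tail_asymmetry: float = -0.45
    mu: float = 2.0
    nu: float = 1.0
    cutoff: float = 2.8           # nm
    switch_width: float = 0.3     # nm

    def __post_init__(self) -> None:
        if self.epsilon0 <= 0:
            raise ValueError("epsilon0 must be positive")
        if self.aspect_ratio <= 1:
            raise ValueError("aspect ratio must exceed 1")

    @property
    def chi(self) -> float:
        k2 = self.aspect_ratio ** 2
        return (k2 - 1.0) / (k2 + 1.0)

    @property
    def chi_prime(self) -> float:
        kp = self.well_anisotropy ** (1.0 / self.mu)
        return (kp - 1.0) / (kp + 1.0)

    @property
    def lipid_length(self) -> float:
        """Long axis of the ellipsoid, nm."""
        return self.aspect_ratio * self.sigma0

    @property
    def leaflet_offset(self) -> float:
        """Distance of a leaflet's lipid centers from the midplane, nm."""
        return self.lipid_length / 2.0

    def as_tuple(self) -> tuple:
        return (self.sigma0, self.epsilon0, self.chi, self.chi_prime,
                self.head_tail_asymmetry, self.cutoff,
                self.cutoff - self.switch_width)


#: area per lipid implied by the parent model's published system sizes
#: (back-computed; see docs/methods.md), nm^2
FIXTURE_AREA_PER_LIPID = 0.772

#: lipid mass and rotational inertia; reduced values chosen for sampling
#: efficiency (CG dynamics carries no physical time scale)
LIPID_MASS = 100.0        # amu
LIPID_INERTIA = 40.0      # amu nm^2
PROTEIN_SITE_MASS = 150.0  # amu


@dataclass
class InteractionTable:
    """Tabulated protein-lipid and protein-protein LJ channels.

    Five specific attractive channels (kcal/mol): H0-membrane 4 total
    (2 per H0 site), R114-membrane 1.2, PIP2 pocket - PIP2 lipid 2.4,
    inter-protein H0-H0 2, patch-patch 2.  Every other protein pair
    carries a weak generic LJ well (``generic_protein``, sub-kT) or, if
    that is zeroed, plain WCA exclusion; generic protein-lipid pairs are
    always repulsive-only.

    The H0- and R114-membrane depths are *totals over the membrane*: a
    site at its preferred height above the headgroup shell sums LJ wells
    over ``membrane_coordination`` lipids (lattice sum at the fixture
    area/lipid), so each per-lipid pair well is the channel total divided
    by that coordination number.  The pocket-PIP2 well is a specific
    one-to-one headgroup contact and stays per-pair.
    """

    h0_lipid: float = 2.0          # per H0 site; 4 kcal/mol total for H0
    r114_lipid: float = 1.2
    pocket_pip2: float = 2.4
    h0_h0: float = 2.0
    patch_patch: float = 2.0
    #: weak LJ between all other protein site pairs (sub-kT, too weak to
    #: condense domains, following the all-LJ protein cross-interactions
    #: of the parent model); 0 disables and reverts those pairs to WCA
    generic_protein: float = 0.2
    #: lattice-sum of unit LJ wells over a fixture bilayer for a site at
    #: its optimal height (sigma_protein_lipid = 1.0, apl = 0.772)
    membrane_coordination: float = 4.47
    sigma_protein_lipid: float = 1.0
    sigma_protein: float = 0.90
    sigma_h0_pair: float = 0.906
    sigma_patch: float = 0.535
    eps_repulsive: float = 1.0
    lj_cutoff_factor: float = 2.5

    def build_tables(self):
        """(mode, eps, sigma, cutoff) lookup arrays indexed by type codes."""
        mode = np.zeros((N_TYPES, N_TYPES), dtype=np.int64)
        eps = np.zeros((N_TYPES, N_TYPES))
        sig = np.zeros((N_TYPES, N_TYPES))
        lipids = (T_LIPID, T_PIP2)
        proteins = (T_H0A, T_H0B, T_PATCH, T_R114, T_POCKET, T_GEN)

        for a in lipids:
            for b in lipids:
                mode[a, b] = MODE_GB
        for p in proteins:
            for l in lipids:
                mode[p, l] = mode[l, p] = MODE_WCA
                eps[p, l] = eps[l, p] = self.eps_repulsive
                sig[p, l] = sig[l, p] = self.sigma_protein_lipid
            for q in proteins:
                if self.generic_protein > 0.0:
                    mode[p, q] = MODE_LJ
                    eps[p, q] = self.generic_protein
                else:
                    mode[p, q] = MODE_WCA
                    eps[p, q] = self.eps_repulsive
                sig[p, q] = self.sigma_protein
        # the five attractive channels; membrane channels are totals
        # normalized by the lattice-sum coordination number
        eps_h0 = self.h0_lipid / self.membrane_coordination
        eps_r114 = self.r114_lipid / self.membrane_coordination
        for h in (T_H0A, T_H0B):
            for l in lipids:
                mode[h, l] = mode[l, h] = MODE_LJ
                eps[h, l] = eps[l, h] = eps_h0
                sig[h, l] = sig[l, h] = self.sigma_protein_lipid
        for l in lipids:
            mode[T_R114, l] = mode[l, T_R114] = MODE_LJ
            eps[T_R114, l] = eps[l, T_R114] = eps_r114
            sig[T_R114, l] = sig[l, T_R114] = self.sigma_protein_lipid
        mode[T_POCKET, T_PIP2] = mode[T_PIP2, T_POCKET] = MODE_LJ
        eps[T_POCKET, T_PIP2] = eps[T_PIP2, T_POCKET] = self.pocket_pip2
        sig[T_POCKET, T_PIP2] = sig[T_PIP2, T_POCKET] = \
            self.sigma_protein_lipid
        # inter-protein H0-H0 attraction acts between all H0 sites (the
        # antiparallel dimer pairing and the end-to-end inter-dimer
        # contacts seen in the restraint pattern)
        if self.h0_h0 > 0.0:
            for ha in (T_H0A, T_H0B):
                for hb in (T_H0A, T_H0B):
                    mode[ha, hb] = MODE_LJ
                    eps[ha, hb] = self.h0_h0
                    sig[ha, hb] = self.sigma_h0_pair
        mode[T_PATCH, T_PATCH] = MODE_LJ
        eps[T_PATCH, T_PATCH] = self.patch_patch
        sig[T_PATCH, T_PATCH] = self.sigma_patch

        cut = np.where(mode == MODE_LJ, self.lj_cutoff_factor * sig,
                       np.where(mode == MODE_WCA, 2.0 ** (1.0 / 6.0) * sig,
                                0.0))
        return mode, eps, sig, cut


@dataclass
class SimConfig:
    """NVT run configuration (defaults follow the simulation protocol:
    300 K, dt = 0.001 ps, Nose-Hoover thermostat, velocity Verlet)."""

    temperature: float = 300.0
    dt: float = 0.001              # ps
    thermostat_tau: float = 0.1    # ps
    neighbor_skin: float = 0.4     # nm
    seed: int = 0
    box: np.ndarray = field(default_factory=lambda: np.array(
        [50.0, 50.0, 50.0]))
    periodic: np.ndarray = field(default_factory=lambda: np.array(
        [False, False, False]))
    log_stride: int = 500
    snapshot_stride: int = 2000

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
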