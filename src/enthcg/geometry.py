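"""Rigid transforms, Kabsch fitting, and independent anchor measurement.

The anchor-distance routine here is the measurement side of the
EPR-restraint workflow: it never relies on the lattice builder's own
bookkeeping, only on placed site coordinates and the topology's anchor
definitions (best-fit rigid superposition of the reference sites onto the
placed sites, then mapping the local anchor points through that fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgmodel import ENTHTopology
from .constants import NM_TO_ANG


@dataclass
class Placement:
    """A rigid transform x -> R x + t applied to domain-local coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "Placement") -> "Placement":
        """self after other: x -> R_self (R_other x + t_other) + t_self."""
        return Placement(self.rotation @ other.rotation,
                         self.rotation @ other.translation
                         + self.translation)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Placement":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))

    @classmethod
    def identity(cls) -> "Placement":
        return cls(np.eye(3), np.zeros(3))


def rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def c2_z() -> np.ndarray:
    """Two-fold rotation about z (perpendicular to the membrane plane)."""
    return np.diag([-1.0, -1.0, 1.0])


def kabsch(reference: np.ndarray, placed: np.ndarray) -> Placement:
    """Best-fit rigid transform mapping reference points onto placed."""
    ref = np.asarray(reference, float)
    mob = np.asarray(placed, float)
    rc, mc = ref.mean(axis=0), mob.mean(axis=0)
    h = (ref - rc).T @ (mob - mc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return Placement(rot, mc - rot @ rc)


def anchor_positions(topology: ENTHTopology,
                     placed_sites: np.ndarray) -> dict:
    """Label-anchor world positions for one placed (possibly deformed)
    domain, via best-fit superposition of the reference sites."""
    fit = kabsch(topology.site_coords, placed_sites)
    return {res: fit.apply(local)
            for res, (_site, local) in topology.label_anchors.items()}


def anchor_distance(topology: ENTHTopology, sites_a: np.ndarray,
                    sites_b: np.ndarray, residue: int) -> float:
    """Anchor-to-anchor distance (Angstrom) between two placed domains."""
    pa = anchor_positions(topology, sites_a)
    pb = anchor_positions(topology, sites_b)
    if residue not in pa:
        raise KeyError(f"no label anchor for residue {residue}")
    return float(np.linalg.norm(pa[residue] - pb[residue]) * NM_TO_ANG)


def h0_axis_of_sites(sites: np.ndarray) -> np.ndarray:
    """Unit H0 axis: site 1 -> site 2 direction of a placed domain."""
    d = np.asarray(sites, float)[1] - np.asarray(sites, float)[0]
    n = np.linalg.norm(d)
    if n < 1e-10:
        raise ValueError("H0 sites coincide; axis undefined")
    return d / n
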