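"""The CG simulation system: anisotropic lipids plus 16-site proteins."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..cgmodel import (ENTHTopology, ROLE_H0_A, ROLE_H0_B, ROLE_PATCH,
                       ROLE_POCKET, ROLE_R114)
from .params import (FIXTURE_AREA_PER_LIPID, GBParams, InteractionTable,
                     LIPID_MASS, PROTEIN_SITE_MASS, SimConfig, T_GEN, T_H0A,
                     T_H0B, T_LIPID, T_PATCH, T_PIP2, T_POCKET, T_R114)

_ROLE_TO_TYPE = {ROLE_H0_A: T_H0A, ROLE_H0_B: T_H0B, ROLE_PATCH: T_PATCH,
                 ROLE_R114: T_R114, ROLE_POCKET: T_POCKET}


@dataclass
class CGSystem:
    """Lipid membrane plus any number of placed ENTH domains.

    ``geometry`` records what the builder made (kind, axis, center, radii)
    so that analysis and coat construction can work in the membrane's own
    frame.
    """

    lipid_pos: np.ndarray
    lipid_dir: np.ndarray
    lipid_is_pip2: np.ndarray
    gb: GBParams
    interactions: InteractionTable
    config: SimConfig
    geometry: dict = field(default_factory=dict)
    topology: ENTHTopology | None = None
    protein_coords: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lipid_pos = np.asarray(self.lipid_pos, dtype=float)
        self.lipid_dir = np.asarray(self.lipid_dir, dtype=float)
        self.lipid_is_pip2 = np.asarray(self.lipid_is_pip2, dtype=bool)
        norms = np.linalg.norm(self.lipid_dir, axis=1)
        if self.n_lipids and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("lipid directors must be unit vectors")

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_pos)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_coords)

    @property
    def n_particles(self) -> int:
        return self.n_lipids + 16 * self.n_proteins

    def add_protein(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (16, 3):
            raise ValueError("a protein instance is 16 sites")
        if self.topology is None:
            raise ValueError("attach a topology before adding proteins")
        self.protein_coords.append(coords)

    def protein_site_types(self) -> np.ndarray:
        assert self.topology is not None
        return np.array([_ROLE_TO_TYPE.get(self.topology.role_of(s), T_GEN)
                         for s in range(1, 17)], dtype=np.int64)

    def packed(self):
        """(positions, types, protein_id) arrays: lipids first."""
        types = np.where(self.lipid_is_pip2, T_PIP2, T_LIPID).astype(np.int64)
        pid = np.full(self.n_lipids, -1, dtype=np.int64)
        pos = [self.lipid_pos]
        if self.protein_coords:
            site_types = self.protein_site_types()
            for k, coords in enumerate(self.protein_coords):
                pos.append(coords)
                types = np.concatenate([types, site_types])
                pid = np.concatenate([pid, np.full(16, k, dtype=np.int64)])
        allpos = np.concatenate(pos, axis=0) if pos else np.zeros((0, 3))
        return np.ascontiguousarray(allpos), types, pid

    def unpack_proteins(self, allpos: np.ndarray) -> None:
        for k in range(self.n_proteins):
            start = self.n_lipids + 16 * k
            self.protein_coords[k] = allpos[start:start + 16].copy()

    def spring_arrays(self):
        """Global spring index/parameter arrays over all proteins."""
        if not self.protein_coords:
            z = np.zeros(0, dtype=np.int64)
            return z, z, np.zeros(0), np.zeros(0)
        assert self.topology is not None
        si, sj, sk, sr = [], [], [], []
        for k in range(self.n_proteins):
            off = self.n_lipids + 16 * k
            for i, j, kk, r0 in self.topology.springs.springs:
                si.append(off + i - 1)
                sj.append(off + j - 1)
                sk.append(kk)
                sr.append(r0)
        return (np.array(si, dtype=np.int64), np.array(sj, dtype=np.int64),
                np.array(sk, dtype=float), np.array(sr, dtype=float))

    def masses(self) -> np.ndarray:
        m = np.full(self.n_particles, LIPID_MASS)
        m[self.n_lipids:] = PROTEIN_SITE_MASS
        return m

    # -- membrane geometry helpers ----------------------------------------

    def head_positions(self) -> np.ndarray:
        """Headgroup positions: half a lipid length against the director."""
        return self.lipid_pos - 0.5 * self.gb.lipid_length * self.lipid_dir

    def outer_head_shell(self) -> float:
        """Radius (or plane height) of the outer headgroup shell."""
        g = self.geometry
        if g.get("kind") in ("tube", "vesicle"):
            return g["r_mid"] + self.gb.leaflet_offset \
                + 0.5 * self.gb.lipid_length
        return self.gb.leaflet_offset + 0.5 * self.gb.lipid_length

    def rotate(self, rotation: np.ndarray,
               center: np.ndarray | None = None) -> "CGSystem":
        """Rigidly rotate the whole system (and its geometry metadata)."""
        rotation = np.asarray(rotation, dtype=float)
        center = (np.zeros(3) if center is None
                  else np.asarray(center, dtype=float))
        self.lipid_pos = (self.lipid_pos - center) @ rotation.T + center
        self.lipid_dir = self.lipid_dir @ rotation.T
        self.protein_coords = [(c - center) @ rotation.T + center
                               for c in self.protein_coords]
        if "axis" in self.geometry:
            self.geometry["axis"] = rotation @ np.asarray(
                self.geometry["axis"], float)
        if "frame" in self.geometry:
            self.geometry["frame"] = rotation @ np.asarray(
                self.geometry["frame"], float)
        if "center" in self.geometry:
            self.geometry["center"] = rotation @ (np.asarray(
                self.geometry["center"], float) - center) + center
        return self

    def check_overlaps(self, factor: float = 0.5) -> None:
        """Reject configurations with pairs below factor*sigma."""
        allpos, types, pid = self.packed()
        if len(allpos) < 2:
            return
        sigma_ref = max(self.gb.sigma0, self.interactions.sigma_protein_lipid)
        tree = cKDTree(allpos)
        pairs = tree.query_pairs(factor * sigma_ref, output_type="ndarray")
        bad = []
        for i, j in pairs:
            if pid[i] >= 0 and pid[i] == pid[j]:
                continue  # bonded neighbors within one protein
            bad.append((int(i), int(j)))
        if bad:
            raise ValueError(f"{len(bad)} particle pairs overlap below "
                             f"{factor} sigma; first few: {bad[:5]}")


def assign_pip2(n_lipids: int, fraction: float, seed: int) -> np.ndarray:
    """Seeded draw flagging round(fraction*N) lipids as PIP2."""
    n_pip2 = int(round(fraction * n_lipids))
    rng = np.random.default_rng(seed)
    flags = np.zeros(n_lipids, dtype=bool)
    flags[rng.choice(n_lipids, size=n_pip2, replace=False)] = True
    return flags


def default_system(lipid_pos, lipid_dir, is_pip2, geometry,
                   gb: GBParams | None = None,
                   interactions: InteractionTable | None = None,
                   config: SimConfig | None = None) -> CGSystem:
    return CGSystem(lipid_pos=lipid_pos, lipid_dir=lipid_dir,
                    lipid_is_pip2=is_pip2,
                    gb=gb or GBParams(),
                    interactions=interactions or InteractionTable(),
                    config=config or SimConfig(),
                    geometry=geometry)


__all__ = ["CGSystem", "assign_pip2", "default_system",
           "FIXTURE_AREA_PER_LIPID"]
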