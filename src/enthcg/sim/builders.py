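"""Membrane builders: flat bilayer, cylindrical tube, spherical vesicle.

Leaflet populations follow the surface areas at the leaflet radii (lipid
centers sit half a lipid length off the midplane), so curved membranes
get density-balanced leaflets.  PIP2 flags are drawn at 10% of lipids by
a seeded draw, matching the experimental lipid composition.
"""

from __future__ import annotations

import numpy as np

from .params import FIXTURE_AREA_PER_LIPID, GBParams, SimConfig
from .system import CGSystem, assign_pip2, default_system

PIP2_FRACTION = 0.10
_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


def build_bilayer(nx: int, ny: int, gb: GBParams | None = None,
                  area_per_lipid: float = FIXTURE_AREA_PER_LIPID,
                  pip2_fraction: float = PIP2_FRACTION,
                  seed: int = 0, box_height: float = 30.0) -> CGSystem:
    """Flat periodic bilayer of nx x ny lipids per leaflet."""
    if nx < 1 or ny < 1:
        raise ValueError("leaflet dimensions must be positive")
    gb = gb or GBParams()
    s = np.sqrt(area_per_lipid)
    h = gb.leaflet_offset
    xs, ys = np.meshgrid(np.arange(nx) * s, np.arange(ny) * s, indexing="ij")
    leaf = np.column_stack([xs.ravel(), ys.ravel()])
    top = np.column_stack([leaf, np.full(len(leaf), h)])
    bot = np.column_stack([leaf + 0.5 * s, np.full(len(leaf), -h)])
    pos = np.vstack([top, bot])
    dirs = np.zeros_like(pos)
    dirs[:len(top), 2] = -1.0   # heads up (director points head -> tail)
    dirs[len(top):, 2] = 1.0
    flags = assign_pip2(len(pos), pip2_fraction, seed)
    config = SimConfig(box=np.array([nx * s, ny * s, box_height]),
                       periodic=np.array([True, True, False]), seed=seed)
    geometry = {"kind": "bilayer", "normal": np.array([0.0, 0.0, 1.0]),
                "center": np.zeros(3)}
    return default_system(pos, dirs, flags, geometry, gb=gb, config=config)


def _cylinder_leaflet(radius: float, length: float, n: int,
                      phase: float = 0.0) -> np.ndarray:
    """n points quasi-uniform on a cylinder of given radius/length."""
    s = np.sqrt(2.0 * np.pi * radius * length / n)
    rows = max(int(round(length / s)), 1)
    counts = np.full(rows, n // rows)
    counts[:n % rows] += 1
    pts = []
    for irow in range(rows):
        z = (irow + 0.5) * length / rows - 0.5 * length
        m = counts[irow]
        ang = 2.0 * np.pi * np.arange(m) / m + phase + 0.5 * irow
        pts.append(np.column_stack([radius * np.cos(ang),
                                    radius * np.sin(ang),
                                    np.full(m, z)]))
    return np.vstack(pts)


def _fibonacci_sphere(n: int, radius: float,
                      hemisphere: int = 0) -> np.ndarray:
    """n quasi-uniform points on a sphere (or +1/-1 z-hemisphere)."""
    i = np.arange(n) + 0.5
    if hemisphere == 0:
        cz = 1.0 - 2.0 * i / n
    elif hemisphere > 0:
        cz = 1.0 - i / n
    else:
        cz = -1.0 + i / n
    ang = _GOLDEN * np.arange(n)
    sz = np.sqrt(np.clip(1.0 - cz ** 2, 0.0, None))
    return radius * np.column_stack([sz * np.cos(ang), sz * np.sin(ang), cz])


def build_tube(diameter: float, length: float,
               gb: GBParams | None = None,
               area_per_lipid: float = FIXTURE_AREA_PER_LIPID,
               periodic: bool = True, capped: bool = False,
               pip2_fraction: float = PIP2_FRACTION, seed: int = 0,
               box: np.ndarray | None = None,
               margin: float = 12.0) -> CGSystem:
    """Cylindrical bilayer along z, midplane radius = diameter/2.

    ``periodic`` tubes continue across the z boundary; ``capped`` tubes are
    closed with hemispherical caps (total length includes the caps).
    """
    if periodic == capped:
        raise ValueError("choose exactly one of periodic or capped")
    gb = gb or GBParams()
    r_mid = diameter / 2.0
    h = gb.leaflet_offset
    if diameter <= 4.0 * gb.lipid_length:
        raise ValueError("tube too narrow for the lipid length")
    if capped and length <= diameter:
        raise ValueError("capped tube length must exceed its diameter")
    cyl_len = length - (diameter if capped else 0.0)

    pos_list, dir_list = [], []
    for sign, r_leaf in ((+1, r_mid + h), (-1, r_mid - h)):
        n = int(round(2.0 * np.pi * r_leaf * cyl_len / area_per_lipid))
        pts = _cylinder_leaflet(r_leaf, cyl_len, n,
                                phase=0.0 if sign > 0 else 0.3)
        rad = pts.copy()
        rad[:, 2] = 0.0
        rad /= np.linalg.norm(rad[:, :2], axis=1)[:, None] + 1e-300
        pos_list.append(pts)
        dir_list.append(-sign * rad)   # outer leaflet: head out, tail in
        if capped:
            n_cap = int(round(2.0 * np.pi * r_leaf ** 2 / area_per_lipid))
            for end in (+1, -1):
                cap = _fibonacci_sphere(n_cap, r_leaf, hemisphere=end)
                cap[:, 2] += end * cyl_len / 2.0
                rhat = cap - np.array([0.0, 0.0, end * cyl_len / 2.0])
                rhat /= np.linalg.norm(rhat, axis=1)[:, None]
                pos_list.append(cap)
                dir_list.append(-sign * rhat)
    pos = np.vstack(pos_list)
    dirs = np.vstack(dir_list)
    flags = assign_pip2(len(pos), pip2_fraction, seed)

    if periodic:
        if box is not None and not np.isclose(box[2], length):
            raise ValueError(f"periodic tube length {length} does not match "
                             f"the periodic box length {box[2]}")
        width = diameter + 2.0 * margin
        cfg_box = np.array([width, width, length])
        pbc = np.array([False, False, True])
    else:
        width = diameter + 2.0 * margin
        cfg_box = np.array([width, width, length + 2.0 * margin])
        pbc = np.array([False, False, False])
    config = SimConfig(box=cfg_box, periodic=pbc, seed=seed)
    geometry = {"kind": "tube", "axis": np.array([0.0, 0.0, 1.0]),
                "frame": np.eye(3), "center": np.zeros(3), "r_mid": r_mid,
                "length": length, "cyl_length": cyl_len, "capped": capped}
    return default_system(pos, dirs, flags, geometry, gb=gb, config=config)


def build_vesicle(diameter: float, gb: GBParams | None = None,
                  area_per_lipid: float = FIXTURE_AREA_PER_LIPID,
                  pip2_fraction: float = PIP2_FRACTION, seed: int = 0,
                  margin: float = 12.0) -> CGSystem:
    """Spherical bilayer with leaflet counts from the sphere areas."""
    gb = gb or GBParams()
    r_mid = diameter / 2.0
    h = gb.leaflet_offset
    if diameter <= 4.0 * gb.lipid_length:
        raise ValueError("vesicle too small for the lipid length")
    pos_list, dir_list = [], []
    for sign, r_leaf in ((+1, r_mid + h), (-1, r_mid - h)):
        n = int(round(4.0 * np.pi * r_leaf ** 2 / area_per_lipid))
        pts = _fibonacci_sphere(n, r_leaf)
        rhat = pts / np.linalg.norm(pts, axis=1)[:, None]
        pos_list.append(pts)
        dir_list.append(-sign * rhat)
    pos = np.vstack(pos_list)
    dirs = np.vstack(dir_list)
    flags = assign_pip2(len(pos), pip2_fraction, seed)
    width = diameter + 2.0 * margin
    config = SimConfig(box=np.array([width, width, width]),
                       periodic=np.array([False, False, False]), seed=seed)
    geometry = {"kind": "vesicle", "center": np.zeros(3), "r_mid": r_mid}
    return default_system(pos, dirs, flags, geometry, gb=gb, config=config)
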