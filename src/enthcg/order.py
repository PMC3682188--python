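"""Orientational order of ENTH coats.

The local orientational order parameter of domain i is the unsigned dot
product |u_i . u_j| between H0 axis vectors averaged over the neighbors j
within a 5-nm cutoff.  1 means a locally aligned coat; isotropic axes
give 0.5 (the mean of |cos theta| over the sphere).  Utilities cover
convergence traces, axial segment analysis, defect identification and
H0 insertion-depth profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import kendalltau

from .geometry import h0_axis_of_sites
from .sim.system import CGSystem

#: sentinel for domains with no neighbor inside the cutoff
NO_NEIGHBOR = np.nan


def h0_axis(domain_sites: np.ndarray) -> np.ndarray:
    """Unit vector along H0: from CG site 1 to CG site 2."""
    return h0_axis_of_sites(domain_sites)


def domain_axes_positions(system_or_proteins):
    """Per-domain (axes, center positions) from a system or a coord list."""
    if isinstance(system_or_proteins, CGSystem):
        proteins = system_or_proteins.protein_coords
    else:
        proteins = system_or_proteins
    axes = np.array([h0_axis(c) for c in proteins])
    pos = np.array([np.asarray(c).mean(axis=0) for c in proteins])
    return axes, pos


@dataclass
class OrderField:
    """Per-domain axes and local order values for one frame."""

    axes: np.ndarray
    positions: np.ndarray
    local_order: np.ndarray
    cutoff: float
    frame_index: int = 0

    @property
    def global_mean(self) -> float:
        vals = self.local_order[~np.isnan(self.local_order)]
        return float(vals.mean()) if len(vals) else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "domain": np.arange(len(self.axes)),
            "s_local": self.local_order,
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2]})


def local_order(axes: np.ndarray, positions: np.ndarray,
                cutoff: float = 5.0, frame_index: int = 0,
                method: str = "tree") -> OrderField:
    """S_i = mean_j |u_i . u_j| over neighbors within the cutoff (j != i).

    Domains without neighbors carry NaN and are excluded from the global
    mean.  ``method='brute'`` forces the O(N^2) reference search.
    """
    axes = np.asarray(axes, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = len(axes)
    if n < 1:
        raise ValueError("need at least one domain")
    norms = np.linalg.norm(axes, axis=1)
    axes = axes / norms[:, None]
    s = np.full(n, NO_NEIGHBOR)
    if method == "brute" or not np.isfinite(cutoff):
        d = np.linalg.norm(positions[:, None, :] - positions[None, :, :],
                           axis=2)
        mask = (d <= cutoff) & ~np.eye(n, dtype=bool)
        dots = np.abs(axes @ axes.T)
        for i in range(n):
            if mask[i].any():
                s[i] = dots[i, mask[i]].mean()
    else:
        tree = cKDTree(positions)
        neighbor_lists = tree.query_ball_tree(tree, cutoff)
        for i, nbrs in enumerate(neighbor_lists):
            nbrs = [j for j in nbrs if j != i]
            if nbrs:
                s[i] = np.abs(axes[nbrs] @ axes[i]).mean()
    return OrderField(axes=axes, positions=positions, local_order=s,
                      cutoff=cutoff, frame_index=frame_index)


def order_trace(frames, cutoff: float = 5.0,
                tail_fraction: float = 0.25, alpha: float = 0.05):
    """Global mean local order per frame plus a convergence flag.

    ``frames`` is a sequence of (axes, positions) pairs, protein coord
    lists, or simulator snapshots.  Convergence: no significant
    Mann-Kendall trend over the trailing window.
    """
    series = []
    for k, frame in enumerate(frames):
        if isinstance(frame, dict):        # simulator snapshot
            axes, pos = domain_axes_positions(frame["proteins"])
        elif (isinstance(frame, tuple) and len(frame) == 2
                and np.asarray(frame[0]).ndim == 2):
            axes, pos = frame
        else:
            axes, pos = domain_axes_positions(frame)
        series.append(local_order(axes, pos, cutoff,
                                  frame_index=k).global_mean)
    series = np.asarray(series)
    n_tail = max(int(np.ceil(len(series) * tail_fraction)), 2)
    tail = series[-n_tail:]
    if len(tail) < 4 or np.allclose(tail, tail[0]):
        converged = True
    else:
        _tau, p = kendalltau(np.arange(len(tail)), tail)
        converged = bool(p > alpha)
    return series, converged


@dataclass
class SegmentReport:
    """Per-axial-segment mean order for one segmentation choice."""

    edges: np.ndarray
    means: np.ndarray
    counts: np.ndarray
    choice_id: str
    cap_mean: float = np.nan


def segment_order(field: OrderField, tube_axis: np.ndarray,
                  n_segments: int, choice: str = "aligned",
                  axial_range: tuple | None = None,
                  cap_mask: np.ndarray | None = None) -> SegmentReport:
    """Axial binning of local order along the tube.

    ``choice`` selects one of two segmentations: 'aligned' bins span the
    axial range; 'offset' shifts the edges by half a bin (boundary
    segments clipped).  Cap domains (``cap_mask``) are excluded from the
    axial bins and reported separately.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    axis = np.asarray(tube_axis, float)
    axis = axis / np.linalg.norm(axis)
    t = field.positions @ axis
    s = field.local_order
    ok = ~np.isnan(s)
    cap_mean = np.nan
    if cap_mask is not None:
        cap_mask = np.asarray(cap_mask, bool)
        cap_vals = s[cap_mask & ok]
        cap_mean = float(cap_vals.mean()) if len(cap_vals) else np.nan
        ok = ok & ~cap_mask
    lo, hi = (t[ok].min(), t[ok].max()) if axial_range is None \
        else axial_range
    edges = np.linspace(lo, hi, n_segments + 1)
    if choice == "offset":
        half = 0.5 * (edges[1] - edges[0])
        edges = edges + half
        edges = np.concatenate([[lo], edges[edges < hi], [hi]])
    elif choice != "aligned":
        raise ValueError("choice must be 'aligned' or 'offset'")
    means = np.full(len(edges) - 1, np.nan)
    counts = np.zeros(len(edges) - 1, dtype=int)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                  len(edges) - 2)
    for b in range(len(edges) - 1):
        vals = s[ok & (idx == b)]
        counts[b] = len(vals)
        if len(vals):
            means[b] = vals.mean()
    return SegmentReport(edges=edges, means=means, counts=counts,
                         choice_id=choice, cap_mean=cap_mean)


@dataclass
class DefectList:
    indices: np.ndarray
    threshold: float


def find_defects(field: OrderField, threshold: float = 0.8) -> DefectList:
    """Domains whose local order falls below the threshold."""
    s = field.local_order
    idx = np.flatnonzero(~np.isnan(s) & (s < threshold))
    return DefectList(indices=idx, threshold=threshold)


# ---------------------------------------------------------------------------
# insertion depth
# ---------------------------------------------------------------------------

def fit_shell(head_positions: np.ndarray, model: str,
              axis: np.ndarray | None = None,
              center: np.ndarray | None = None):
    """Least-squares headgroup-shell fit.

    'planar': mean height along the normal; 'cylinder': mean radius about
    the axis; 'sphere': mean radius about the center.  Returns the scalar
    shell coordinate (height or radius).
    """
    pts = np.asarray(head_positions, float)
    if model == "planar":
        normal = np.array([0.0, 0.0, 1.0]) if axis is None else \
            np.asarray(axis, float)
        normal = normal / np.linalg.norm(normal)
        return float((pts @ normal).mean())
    center = np.zeros(3) if center is None else np.asarray(center, float)
    rel = pts - center
    if model == "cylinder":
        ax = np.array([0.0, 0.0, 1.0]) if axis is None else \
            np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)
        rel = rel - np.outer(rel @ ax, ax)
        return float(np.linalg.norm(rel, axis=1).mean())
    if model == "sphere":
        return float(np.linalg.norm(rel, axis=1).mean())
    raise ValueError("model must be 'planar', 'cylinder' or 'sphere'")


def insertion_depth_profile(frames, system: CGSystem,
                            model: str | None = None,
                            outer_only: bool = True):
    """Signed H0-site depths relative to the headgroup shell.

    Positive = below the headgroup shell (inserted); a domain standing
    ``d`` nm above the shell reports -d.  ``frames`` is a sequence of
    simulator snapshots (or one system state if None).  Returns (depths
    array, mean).
    """
    geom = system.geometry
    if model is None:
        model = {"bilayer": "planar", "tube": "cylinder",
                 "vesicle": "sphere"}[geom.get("kind", "bilayer")]
    axis = np.asarray(geom.get("axis", [0.0, 0.0, 1.0]), float)
    center = np.asarray(geom.get("center", np.zeros(3)), float)
    half_len = 0.5 * system.gb.lipid_length
    depths = []
    if frames is None:
        frames = [{"lipid_pos": system.lipid_pos,
                   "lipid_dir": system.lipid_dir,
                   "proteins": system.protein_coords}]
    for frame in frames:
        heads = frame["lipid_pos"] - half_len * frame["lipid_dir"]
        if outer_only and model in ("cylinder", "sphere"):
            rel = frame["lipid_pos"] - center
            if model == "cylinder":
                rel = rel - np.outer(rel @ axis, axis)
            outer = np.einsum("ij,ij->i", rel, frame["lipid_dir"]) < 0
            heads = heads[outer]
        elif outer_only and model == "planar":
            heads = heads[frame["lipid_dir"][:, 2] < 0]
        shell = fit_shell(heads, model, axis=axis, center=center)
        for coords in frame["proteins"]:
            h0 = np.asarray(coords)[:2]
            if model == "planar":
                coord = h0[:, 2]
            elif model == "cylinder":
                rel = h0 - center
                rel = rel - np.outer(rel @ axis, axis)
                coord = np.linalg.norm(rel, axis=1)
            else:
                coord = np.linalg.norm(h0 - center, axis=1)
            # positive depth = inside the membrane (below the outer shell)
            depths.extend(shell - coord if model != "planar"
                          else shell - coord)
    depths = np.asarray(depths)
    return depths, float(depths.mean())
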