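"""Building the 16-site coarse-grained ENTH model.

Four ingredients:

* essential-dynamics coarse-graining (EDCG): variational placement of
  contiguous residue segments so that CG sites optimally represent the
  low-frequency (essential) collective motions of a reference trajectory,
  solved exactly by dynamic programming;
* center-of-geometry mapping of a residue trajectory onto CG sites;
* heteroENM: iterative fluctuation matching that assigns each intra-protein
  spring the stiffness reproducing the reference pair-distance variances;
* Boltzmann inversion of a radial distribution function into a PMF (used
  for the R114-loop/headgroup interaction well).

The 16-site ENTH topology itself (site coordinates, roles, spin-label
anchor points) ships as an idealized synthetic fixture -- the shape and
role layout of the domain, not a crystal-structure derivation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import kt
from .synthetic import ENMSpec, enm_covariance

# ---------------------------------------------------------------------------
# EDCG
# ---------------------------------------------------------------------------


@dataclass
class SitePartition:
    """Contiguous residue segments defining CG sites.

    ``boundaries`` are 1-based inclusive segment starts; the first is 1.
    ``residual`` is the essential-subspace fluctuation mismatch of the
    optimal partition.
    """

    boundaries: list
    n_sites: int
    residual: float

    def __post_init__(self) -> None:
        if self.boundaries[0] != 1:
            raise ValueError("first boundary must be 1")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries,
                                          self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.boundaries) != self.n_sites:
            raise ValueError("n_sites must equal the number of segments")

    def segments(self, n_residues: int):
        """Yield (start, stop) 0-based half-open residue ranges."""
        edges = [b - 1 for b in self.boundaries] + [n_residues]
        return list(zip(edges[:-1], edges[1:]))


def align_trajectory(frames: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Remove rigid-body motion: center frames and Kabsch-align them to
    their running mean structure (the EDCG precondition)."""
    frames = np.asarray(frames, dtype=float)
    frames = frames - frames.mean(axis=1, keepdims=True)
    ref = frames[0]
    for _ in range(n_iter):
        out = np.empty_like(frames)
        for k, f in enumerate(frames):
            h = ref.T @ f
            u, _s, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
            out[k] = f @ rot.T
        frames = out
        ref = frames.mean(axis=0)
    return frames


def essential_projection(frames: np.ndarray, n_modes: int | None = None,
                         variance_goal: float = 0.90):
    """Project a trajectory onto its top PCA (essential) modes.

    Returns (projected displacement trajectory (F,N,3), n_modes used).
    Frames must already be free of rigid-body motion.
    """
    frames = np.asarray(frames, dtype=float)
    n_frames, n_res, _ = frames.shape
    if n_frames < 3:
        raise ValueError("too few frames for a covariance estimate")
    disp = (frames - frames.mean(axis=0)).reshape(n_frames, 3 * n_res)
    u, s, vt = np.linalg.svd(disp, full_matrices=False)
    var = s ** 2
    if var[0] <= 0:
        raise ValueError("degenerate covariance: trajectory has no motion")
    if n_modes is None:
        frac = np.cumsum(var) / var.sum()
        n_modes = int(np.searchsorted(frac, variance_goal) + 1)
    n_modes = min(n_modes, len(s))
    ess = (u[:, :n_modes] * s[:n_modes]) @ vt[:n_modes]
    return ess.reshape(n_frames, n_res, 3), n_modes


def _segment_costs(ess: np.ndarray) -> np.ndarray:
    """cost[a, b] = essential fluctuation variance about the segment-mean
    motion for residues a..b-1 (0-based half-open)."""
    n_frames, n_res, _ = ess.shape
    per_bead = (ess ** 2).sum(axis=2).mean(axis=0)            # (N,)
    m_prefix = np.concatenate([[0.0], np.cumsum(per_bead)])
    p_prefix = np.concatenate([np.zeros((n_frames, 1, 3)),
                               np.cumsum(ess, axis=1)], axis=1)
    cost = np.full((n_res + 1, n_res + 1), np.inf)
    for a in range(n_res):
        seg_sum = p_prefix[:, a + 1:, :] - p_prefix[:, a:a + 1, :]
        cross = (seg_sum ** 2).sum(axis=2).mean(axis=0)       # (N-a,)
        ns = np.arange(1, n_res - a + 1)
        cost[a, a + 1:] = (m_prefix[a + 1:] - m_prefix[a]) - cross / ns
    return cost


def edcg_partition(frames: np.ndarray, n_sites: int,
                   n_modes: int | None = None) -> SitePartition:
    """Optimal contiguous partition of residues into CG sites.

    Minimizes the summed within-segment fluctuation mismatch in the
    essential subspace.  Dynamic programming makes the optimum exact and
    deterministic; cost ties break toward the earlier boundary.
    """
    frames = np.asarray(frames, dtype=float)
    n_res = frames.shape[1]
    if n_sites > n_res:
        raise ValueError(f"n_sites={n_sites} exceeds n_residues={n_res}")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    ess, _ = essential_projection(frames, n_modes)
    cost = _segment_costs(ess)

    dp = np.full((n_sites + 1, n_res + 1), np.inf)
    back = np.zeros((n_sites + 1, n_res + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, n_sites + 1):
        for b in range(k, n_res + 1):
            for a in range(k - 1, b):
                c = dp[k - 1, a] + cost[a, b]
                if c < dp[k, b]:          # strict: ties keep earliest split
                    dp[k, b] = c
                    back[k, b] = a
    bounds = []
    b = n_res
    for k in range(n_sites, 0, -1):
        a = back[k, b]
        bounds.append(a + 1)
        b = a
    bounds.reverse()
    return SitePartition(boundaries=bounds, n_sites=n_sites,
                         residual=float(dp[n_sites, n_res]))


def map_to_sites(frames: np.ndarray, partition: SitePartition) -> np.ndarray:
    """Center-of-geometry mapping of a residue trajectory onto CG sites."""
    frames = np.asarray(frames, dtype=float)
    n_res = frames.shape[1]
    segs = partition.segments(n_res)
    if segs[-1][1] != n_res:
        raise ValueError("partition does not cover all residues")
    return np.stack([frames[:, a:b, :].mean(axis=1) for a, b in segs],
                    axis=1)


# ---------------------------------------------------------------------------
# heteroENM fluctuation matching
# ---------------------------------------------------------------------------

@dataclass
class SpringNetwork:
    """Harmonic springs (site_i, site_j, k kcal/(mol nm^2), r0 nm)."""

    springs: list
    cutoff: float
    converged: bool = True
    n_iterations: int = 0
    max_mismatch: float = 0.0
    mismatch_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for i, j, k, r0 in self.springs:
            if i >= j:
                raise ValueError(f"spring ({i},{j}) must have i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate spring ({i},{j})")
            seen.add((i, j))
            if k < 0 or r0 <= 0:
                raise ValueError(f"invalid spring ({i},{j}): k={k}, r0={r0}")

    @property
    def pairs(self):
        return [(i, j) for i, j, _, _ in self.springs]

    def to_enm_spec(self, coords: np.ndarray,
                    temperature: float = 300.0) -> ENMSpec:
        return ENMSpec(coords, [(i, j, k) for i, j, k, _ in self.springs],
                       temperature)


def pair_distance_variances(frames: np.ndarray, pairs) -> np.ndarray:
    """Sample variances of the listed pair distances along a trajectory."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty(len(pairs))
    for n, (i, j) in enumerate(pairs):
        d = np.linalg.norm(frames[:, j] - frames[:, i], axis=1)
        out[n] = d.var(ddof=1)
    return out


def model_distance_variances(coords: np.ndarray, springs,
                             temperature: float) -> np.ndarray:
    """Pair-distance variances of an ENM at its mean structure.

    Linearized along the pair direction: var(d_ij) = e^T (C_ii + C_jj -
    2 C_ij) e with C the fluctuation covariance kB*T*H^+.
    """
    spec = ENMSpec(coords, [(i, j, k) for i, j, k, _ in springs], temperature)
    cov = enm_covariance(spec)
    out = np.empty(len(springs))
    for n, (i, j, _, _) in enumerate(springs):
        d = coords[j] - coords[i]
        e = d / np.linalg.norm(d)
        ci, cj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        block = cov[ci, ci] + cov[cj, cj] - cov[ci, cj] - cov[cj, ci]
        out[n] = e @ block @ e
    return out


def heteroenm_fit(site_frames: np.ndarray | None = None, *,
                  coords: np.ndarray | None = None,
                  target_variances: np.ndarray | None = None,
                  cutoff: float = 1.2, tolerance: float = 0.03,
                  max_iter: int = 200, k_init: float = 10.0,
                  gamma: float = 0.5, k_floor: float = 1e-3,
                  temperature: float = 300.0) -> SpringNetwork:
    """Fit heterogeneous spring constants by fluctuation matching.

    Every pair within ``cutoff`` at the mean structure receives a spring.
    Each iteration rescales k_ij by (model_var/target_var)**gamma until the
    worst relative mismatch drops below ``tolerance``.  Targets come either
    from a mapped site trajectory or explicitly (``coords`` +
    ``target_variances`` aligned with the cutoff pair list).
    """
    if site_frames is not None:
        site_frames = np.asarray(site_frames, dtype=float)
        coords = site_frames.mean(axis=0)
    elif coords is None:
        raise ValueError("provide site_frames or coords+target_variances")
    coords = np.asarray(coords, dtype=float)
    n_sites = len(coords)
    pairs = [(i, j) for i in range(n_sites) for j in range(i + 1, n_sites)
             if np.linalg.norm(coords[j] - coords[i]) <= cutoff]
    if not pairs:
        raise ValueError("no pairs within cutoff; increase cutoff")
    if site_frames is not None:
        targets = pair_distance_variances(site_frames, pairs)
    else:
        targets = np.asarray(target_variances, dtype=float)
        if len(targets) != len(pairs):
            raise ValueError(f"expected {len(pairs)} target variances for "
                             f"the cutoff pair list, got {len(targets)}")
    if np.any(targets <= 0):
        bad = [pairs[i] for i in np.flatnonzero(targets <= 0)]
        raise ValueError(f"non-positive target variances for pairs {bad}")

    r0 = np.array([np.linalg.norm(coords[j] - coords[i]) for i, j in pairs])
    k = np.full(len(pairs), float(k_init))
    springs = [(i, j, float(kk), float(rr))
               for (i, j), kk, rr in zip(pairs, k, r0)]
    history = []
    n_done = 0
    if np.isfinite(tolerance):
        for n_done in range(1, max_iter + 1):
            model = model_distance_variances(coords, springs, temperature)
            mismatch = float(np.abs(model / targets - 1.0).max())
            history.append(mismatch)
            if mismatch < tolerance:
                break
            k = np.maximum(k * (model / targets) ** gamma, k_floor)
            springs = [(i, j, float(kk), float(rr))
                       for (i, j), kk, rr in zip(pairs, k, r0)]
        else:
            n_done = max_iter
    final = (np.abs(model_distance_variances(coords, springs, temperature)
                    / targets - 1.0).max() if np.isfinite(tolerance) else
             np.inf)
    return SpringNetwork(springs=springs, cutoff=cutoff,
                         converged=bool(final < tolerance),
                         n_iterations=0 if not np.isfinite(tolerance)
                         else n_done,
                         max_mismatch=float(final) if np.isfinite(final)
                         else 0.0,
                         mismatch_history=history)


# ---------------------------------------------------------------------------
# Boltzmann inversion
# ---------------------------------------------------------------------------

def pmf_from_rdf(r: np.ndarray, g_of_r: np.ndarray,
                 temperature: float = 300.0):
    """PMF(r) = -kB*T*ln g(r), zeroed at the largest r with g > 0.

    Bins with g = 0 are masked (NaN).  Returns (r, pmf) arrays.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g_of_r, dtype=float)
    if np.any(np.diff(r) <= 0):
        raise ValueError("r grid must be strictly increasing")
    if np.any(g < 0):
        raise ValueError("g(r) must be non-negative")
    if not np.any(g > 0):
        raise ValueError("g(r) is zero everywhere; PMF undefined")
    pmf = np.full_like(g, np.nan)
    ok = g > 0
    pmf[ok] = -kt(temperature) * np.log(g[ok])
    ref = pmf[np.flatnonzero(ok)[-1]]
    return r, pmf - ref


# ---------------------------------------------------------------------------
# the 16-site ENTH topology
# ---------------------------------------------------------------------------

#: synthetic fixture: idealized domain-local site coordinates (nm).
#: Frame: z = outward membrane normal (membrane surface near z = 0), the
#: H0 amphipathic helix lies along +x at y = z = 0, the globular body sits
#: above it.  Not derived from a deposited structure.
ENTH16_COORDS = np.array([
    [-0.4125, 0.000, 0.00],    # 1  H0 N-terminal half (H0_A)
    [0.6000, 0.000, 0.00],     # 2  H0 C-terminal half (H0_B)
    [1.0500, 0.950, 0.90],     # 3   body, lower shell
    [0.3630, 1.658, 0.80],     # 4
    [0.8150, 0.125, 0.585],    # 5  V50/V51 hydrophobic patch
    [-0.5880, 1.350, 0.80],    # 6
    [0.1500, 0.450, 0.10],     # 7  PIP2 pocket (default assignment)
    [-0.5880, 0.350, 0.80],    # 8
    [0.3630, 0.042, 0.80],     # 9
    [-0.3000, 0.000, 0.00],    # 10 R114 loop
    [0.5850, 1.203, 1.75],     # 11  body, upper shell
    [-0.0850, 1.421, 1.75],    # 12
    [-0.5000, 0.850, 1.75],    # 13
    [-0.0850, 0.279, 1.75],    # 14
    [0.5850, 0.497, 1.75],     # 15
    [0.1000, 0.850, 2.30],     # 16  apex
])

#: spin-label anchor points (nitroxide stand-ins) in the same local frame,
#: offset 0.7-1.0 nm from the H0 axis along the side-chain directions;
#: hydrophobic-face residues point toward the membrane (-z).
LABEL_ANCHORS_LOCAL = {
    4: np.array([-0.4875, 0.430, 0.550]),
    5: np.array([-0.3375, -0.798, 0.000]),
    6: np.array([-0.1875, 0.122, -0.690]),
    10: np.array([0.4125, 0.002, -0.700]),
    13: np.array([0.8625, -0.581, -0.410]),
    14: np.array([1.0125, -0.3644, -0.450]),
}

#: residue -> owning H0 site (residues 1-8 on site 1, 9-15 on site 2)
ANCHOR_OWNERS = {4: 1, 5: 1, 6: 1, 10: 2, 13: 2, 14: 2}

ROLE_H0_A = "H0_A"
ROLE_H0_B = "H0_B"
ROLE_PATCH = "hydrophobic_patch"
ROLE_R114 = "R114_loop"
ROLE_POCKET = "PIP2_pocket"
ROLE_GENERIC = "generic"


@dataclass
class ENTHTopology:
    """The 16-site CG ENTH domain: coordinates, roles, springs, anchors."""

    site_coords: np.ndarray
    roles: dict
    springs: SpringNetwork
    label_anchors: dict       # residue -> (owning site 1-based, local coords)
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_coords = np.asarray(self.site_coords, dtype=float)
        if self.site_coords.shape != (16, 3):
            raise ValueError("ENTH topology requires exactly 16 sites")
        for i, j, *_ in self.springs.springs:
            if not (1 <= i <= 16 and 1 <= j <= 16):
                raise ValueError(f"spring references site outside 1..16: "
                                 f"({i},{j})")
        required = {1: ROLE_H0_A, 2: ROLE_H0_B, 5: ROLE_PATCH, 10: ROLE_R114}
        for site, role in required.items():
            if self.roles.get(site) != role:
                raise ValueError(f"site {site} must carry role {role}")
        if sum(1 for r in self.roles.values() if r == ROLE_POCKET) != 1:
            raise ValueError("exactly one PIP2-pocket site required")
        if self.masses is None:
            self.masses = np.full(16, 150.0)
        # every site reachable through the spring network
        adj = {i: set() for i in range(1, 17)}
        for i, j, *_ in self.springs.springs:
            adj[i].add(j)
            adj[j].add(i)
        seen, stack = set(), [1]
        while stack:
            s = stack.pop()
            if s in seen:
                continue
            seen.add(s)
            stack.extend(adj[s] - seen)
        if len(seen) != 16:
            raise ValueError("spring network is not connected over the "
                             "16 sites")

    @property
    def h0_sites(self):
        return (1, 2)

    def role_of(self, site: int) -> str:
        return self.roles.get(site, ROLE_GENERIC)

    def to_json(self) -> str:
        payload = {
            "site_coords": self.site_coords.tolist(),
            "roles": {str(k): v for k, v in self.roles.items()},
            "springs": {"cutoff": self.springs.cutoff,
                        "entries": [list(s) for s in self.springs.springs]},
            "label_anchors": {str(res): {"site": int(site),
                                         "local": local.tolist()}
                              for res, (site, local)
                              in self.label_anchors.items()},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ENTHTopology":
        data = json.loads(text)
        springs = SpringNetwork(
            springs=[tuple(s) for s in data["springs"]["entries"]],
            cutoff=data["springs"]["cutoff"])
        anchors = {int(res): (entry["site"], np.asarray(entry["local"]))
                   for res, entry in data["label_anchors"].items()}
        return cls(site_coords=np.asarray(data["site_coords"]),
                   roles={int(k): v for k, v in data["roles"].items()},
                   springs=springs, label_anchors=anchors)


def default_spring_network(coords: np.ndarray | None = None,
                           cutoff: float = 1.3,
                           stiffness: float = 50.0) -> SpringNetwork:
    """Uniform-stiffness network over all site pairs within the cutoff."""
    if coords is None:
        coords = ENTH16_COORDS
    springs = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            r0 = float(np.linalg.norm(coords[j] - coords[i]))
            if r0 <= cutoff:
                springs.append((i + 1, j + 1, stiffness, r0))
    return SpringNetwork(springs=springs, cutoff=cutoff)


def build_enth16(reference_coords: np.ndarray | None = None,
                 springs: SpringNetwork | None = None,
                 pocket_site: int = 7) -> ENTHTopology:
    """Assemble the 16-site topology with roles and label anchors.

    ``reference_coords`` may supply user 16-site coordinates (e.g. mapped
    from a crystal structure); by default the packaged idealized fixture is
    used.  The PIP2 pocket defaults to site 7 but is configurable.
    """
    coords = (ENTH16_COORDS if reference_coords is None
              else np.asarray(reference_coords, dtype=float))
    if coords.shape != (16, 3):
        raise ValueError(f"expected 16 sites, got {coords.shape[0]}")
    if springs is None:
        springs = default_spring_network(coords)
    roles = {1: ROLE_H0_A, 2: ROLE_H0_B, 5: ROLE_PATCH, 10: ROLE_R114,
             pocket_site: ROLE_POCKET}
    if pocket_site in (1, 2, 5, 10):
        raise ValueError("pocket site collides with a reserved role site")
    anchors = {res: (ANCHOR_OWNERS[res], LABEL_ANCHORS_LOCAL[res].copy())
               for res in sorted(LABEL_ANCHORS_LOCAL)}
    return ENTHTopology(site_coords=coords, roles=roles, springs=springs,
                        label_anchors=anchors)
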