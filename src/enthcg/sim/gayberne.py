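"""Gay-Berne pair energy, force and director gradients.

One numba kernel implements the pair math used everywhere (scalar API and
the MD force loop).  The potential is the standard Gay-Berne form with
orientation-dependent contact distance sigma(u1,u2,rhat) and well depth
eps(u1,u2,rhat) (exponents nu=1, mu=2), plus a head-tail asymmetry term

    U_a = eps_a * (u1.rhat - u2.rhat) * h^-6,

odd under flipping a single director, evaluated at the same shifted
anisotropic distance h = (r - sigma + sigma0)/sigma0.  The total pair
energy is smoothly switched to zero over the last ``switch_width`` nm
before the cutoff (quintic smoothstep, C2).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import GBParams

_H_CLAMP = 0.2  # minimum shifted distance; below this the pair is deep in
                # overlap and energies are evaluated at the clamp


@njit(cache=True, fastmath=True)
def _switch(s, ron, rc):
    """Quintic smoothstep 1 -> 0 on [ron, rc]; returns (S, dS/ds)."""
    if s <= ron:
        return 1.0, 0.0
    if s >= rc:
        return 0.0, 0.0
    t = (s - ron) / (rc - ron)
    sw = 1.0 + t * t * t * (-10.0 + t * (15.0 - 6.0 * t))
    dsw = t * t * (-30.0 + t * (60.0 - 30.0 * t)) / (rc - ron)
    return sw, dsw


@njit(cache=True, fastmath=True)
def gb_pair(dx, dy, dz, u1x, u1y, u1z, u2x, u2y, u2z,
            sigma0, eps0, chi, chip, eps_a, rc, ron):
    """Energy, force and director gradients for one lipid pair.

    ``d`` is r_j - r_i.  Returns (U, fx, fy, fz, g1x, g1y, g1z, g2x, g2y,
    g2z) where f is the force on particle j and g_k = dU/du_k (the caller
    projects out the radial component).
    """
    r2 = dx * dx + dy * dy + dz * dz
    s = np.sqrt(r2)
    if s >= rc:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    inv_s = 1.0 / s
    rhx, rhy, rhz = dx * inv_s, dy * inv_s, dz * inv_s
    a = u1x * rhx + u1y * rhy + u1z * rhz
    b = u2x * rhx + u2y * rhy + u2z * rhz
    c = u1x * u2x + u1y * u2y + u1z * u2z

    gp = a + b
    gm = a - b
    dp = 1.0 + chi * c
    dm = 1.0 - chi * c
    A = gp * gp / dp
    B = gm * gm / dm
    gsig = 1.0 - 0.5 * chi * (A + B)
    if gsig < 1e-10:
        gsig = 1e-10
    sig = sigma0 / np.sqrt(gsig)

    ep = 1.0 + chip * c
    em = 1.0 - chip * c
    Ae = gp * gp / ep
    Be = gm * gm / em
    eps2 = 1.0 - 0.5 * chip * (Ae + Be)
    e1arg = 1.0 - chi * chi * c * c
    if e1arg < 1e-10:
        e1arg = 1e-10
    eps1 = 1.0 / np.sqrt(e1arg)
    eps = eps0 * eps1 * eps2 * eps2

    h = (s - sig + sigma0) / sigma0
    clamped = h < _H_CLAMP
    if clamped:
        h = _H_CLAMP
    hi = 1.0 / h
    hi2 = hi * hi
    hi6 = hi2 * hi2 * hi2
    hi12 = hi6 * hi6

    U0 = 4.0 * eps * (hi12 - hi6)
    Ua = eps_a * gm * hi6
    U = U0 + Ua

    # dU/dh
    dU0h = 4.0 * eps * (-12.0 * hi12 + 6.0 * hi6) * hi
    dUah = -6.0 * eps_a * gm * hi6 * hi
    dUh = dU0h + dUah
    if clamped:
        dUh = 0.0

    # sigma partials
    dA_da = 2.0 * gp / dp
    dB_da = 2.0 * gm / dm
    dA_db = dA_da
    dB_db = -dB_da
    dA_dc = -chi * gp * gp / (dp * dp)
    dB_dc = chi * gm * gm / (dm * dm)
    fac_sig = -0.5 * sig / gsig          # dsig/dg * ... (sig = s0 g^-1/2)
    dsig_da = fac_sig * (-0.5 * chi) * (dA_da + dB_da)
    dsig_db = fac_sig * (-0.5 * chi) * (dA_db + dB_db)
    dsig_dc = fac_sig * (-0.5 * chi) * (dA_dc + dB_dc)

    # eps partials
    dAe_da = 2.0 * gp / ep
    dBe_da = 2.0 * gm / em
    dAe_db = dAe_da
    dBe_db = -dBe_da
    dAe_dc = -chip * gp * gp / (ep * ep)
    dBe_dc = chip * gm * gm / (em * em)
    deps2_da = -0.5 * chip * (dAe_da + dBe_da)
    deps2_db = -0.5 * chip * (dAe_db + dBe_db)
    deps2_dc = -0.5 * chip * (dAe_dc + dBe_dc)
    U0_over_eps = 4.0 * (hi12 - hi6)
    deps_da = eps0 * eps1 * 2.0 * eps2 * deps2_da
    deps_db = eps0 * eps1 * 2.0 * eps2 * deps2_db
    deps1_dc = chi * chi * c * eps1 * eps1 * eps1
    deps_dc = eps0 * (deps1_dc * eps2 * eps2
                      + eps1 * 2.0 * eps2 * deps2_dc)

    Pa = U0_over_eps * deps_da + dUh * (-dsig_da / sigma0) + eps_a * hi6
    Pb = U0_over_eps * deps_db + dUh * (-dsig_db / sigma0) - eps_a * hi6
    Pc = U0_over_eps * deps_dc + dUh * (-dsig_dc / sigma0)
    Ps = dUh / sigma0

    sw, dsw = _switch(s, ron, rc)

    # Cartesian gradient wrt r (= r_j - r_i)
    ca = Pa * inv_s
    cb = Pb * inv_s
    crad = Ps - (Pa * a + Pb * b) * inv_s
    gx = crad * rhx + ca * u1x + cb * u2x
    gy = crad * rhy + ca * u1y + cb * u2y
    gz = crad * rhz + ca * u1z + cb * u2z
    # switched totals
    fx = -(sw * gx + dsw * U * rhx)
    fy = -(sw * gy + dsw * U * rhy)
    fz = -(sw * gz + dsw * U * rhz)

    g1x = sw * (Pa * rhx + Pc * u2x)
    g1y = sw * (Pa * rhy + Pc * u2y)
    g1z = sw * (Pa * rhz + Pc * u2z)
    g2x = sw * (Pb * rhx + Pc * u1x)
    g2y = sw * (Pb * rhy + Pc * u1y)
    g2z = sw * (Pb * rhz + Pc * u1z)

    return sw * U, fx, fy, fz, g1x, g1y, g1z, g2x, g2y, g2z


def gb_pair_energy(pos_i, dir_i, pos_j, dir_j,
                   params: GBParams | None = None) -> float:
    """Pair energy (kcal/mol) of two lipids at given positions/directors."""
    if params is None:
        params = GBParams()
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    d = pos_j - pos_i
    if np.dot(d, d) < 1e-20:
        raise ValueError("zero separation between lipids (overlap)")
    u1 = np.asarray(dir_i, dtype=float)
    u2 = np.asarray(dir_j, dtype=float)
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    s0, e0, chi, chip, ea, rc, ron = params.as_tuple()
    out = gb_pair(d[0], d[1], d[2], u1[0], u1[1], u1[2],
                  u2[0], u2[1], u2[2], s0, e0, chi, chip, ea, rc, ron)
    return float(out[0])


def gb_pair_gradients(pos_i, dir_i, pos_j, dir_j,
                      params: GBParams | None = None):
    """(U, force_on_j, dU/du1, dU/du2) for finite-difference checks."""
    if params is None:
        params = GBParams()
    d = np.asarray(pos_j, float) - np.asarray(pos_i, float)
    u1 = np.asarray(dir_i, float)
    u2 = np.asarray(dir_j, float)
    s0, e0, chi, chip, ea, rc, ron = params.as_tuple()
    out = gb_pair(d[0], d[1], d[2], u1[0], u1[1], u1[2],
                  u2[0], u2[1], u2[2], s0, e0, chi, chip, ea, rc, ron)
    return (out[0], np.array(out[1:4]), np.array(out[4:7]),
            np.array(out[7:10]))
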