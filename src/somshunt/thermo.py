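"""Seawater thermodynamics: potential density anomaly and oxygen solubility.

A compact port of the published coefficient sets needed by the CTD pipeline:

* density of seawater at atmospheric pressure and the adiabatic lapse rate
  from the UNESCO 1983 (EOS-80) polynomials (Millero & Poisson 1981;
  Fofonoff 1977), giving the potential density anomaly sigma-theta
  referenced to 0 db;
* oxygen solubility from the Garcia & Gordon (1992) combined fit to the
  Benson & Krause data, in umol/kg.

Each routine is pinned to the published check values in the test suite.
Inputs are practical salinity (PSS-78), in-situ temperature (deg C, ITS-90
treated as IPTS-68-compatible at the precision needed here) and pressure (db).
"""

from __future__ import annotations

import numpy as np

__all__ = ["density_at_surface", "potential_temperature", "sigma_theta", "o2_solubility"]


def density_at_surface(s, t):
    """Seawater density (kg/m^3) at 0 db, UNESCO 1983 polynomial."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    # density of Standard Mean Ocean Water
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    b = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    c = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    d = 4.8314e-4
    return rho_w + b * s + c * s**1.5 + d * s**2


def _adiabatic_lapse(s, t, p):
    """Adiabatic temperature gradient (deg C / db), Fofonoff 1977 / UNESCO."""
    ds = s - 35.0
    return (
        (((-2.1687e-16 * t + 1.8676e-14) * t - 4.6206e-13) * p
         + ((2.7759e-12 * t - 1.1351e-10) * ds
            + ((-5.4481e-14 * t + 8.733e-12) * t - 6.7795e-10) * t
            + 1.8741e-8)) * p
        + (-4.2393e-8 * t + 1.8932e-6) * ds
        + ((6.6228e-10 * t - 6.836e-8) * t + 8.5258e-6) * t
        + 3.5803e-5
    )


def potential_temperature(s, t, p, p_ref=0.0):
    """Potential temperature (deg C) by the standard 4th-order RK scheme."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    h = p_ref - p
    xk = h * _adiabatic_lapse(s, t, p)
    t = t + 0.5 * xk
    q = xk
    p = p + 0.5 * h
    xk = h * _adiabatic_lapse(s, t, p)
    t = t + 0.29289322 * (xk - q)
    q = 0.58578644 * xk + 0.121320344 * q
    xk = h * _adiabatic_lapse(s, t, p)
    t = t + 1.707106781 * (xk - q)
    q = 3.414213562 * xk - 4.121320344 * q
    p = p + 0.5 * h
    xk = h * _adiabatic_lapse(s, t, p)
    return t + (xk - 2.0 * q) / 6.0


def sigma_theta(s, t, p):
    """Potential density anomaly (kg/m^3) referenced to the surface (0 db)."""
    theta = potential_temperature(s, t, p, 0.0)
    return density_at_surface(s, theta) - 1000.0


# Garcia & Gordon (1992) combined fit, umol/kg
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def o2_solubility(s, t):
    """Oxygen solubility (umol/kg) at in-situ T and S, Garcia-Gordon fit.

    Scaled temperature ts = ln((298.15 - t)/(273.15 + t)); check value
    O2sol(S=35, t=10) = 274.61 umol/kg.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    ts = np.log((298.15 - t) / (273.15 + t))
    a0, a1, a2, a3, a4, a5 = _GG_A
    b0, b1, b2, b3 = _GG_B
    ln_c = (
        a0 + a1 * ts + a2 * ts**2 + a3 * ts**3 + a4 * ts**4 + a5 * ts**5
        + s * (b0 + b1 * ts + b2 * ts**2 + b3 * ts**3)
        + _GG_C0 * s**2
    )
    return np.exp(ln_c)
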