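"""Independent reference computations used to check the package.

These deliberately avoid the code paths they validate: the homogeneous
sphere potential is a closed form obtained by summing the Legendre series
with generating-function identities, and the MEG oracle integrates the
volume-current contribution over the conductor surface (Geselowitz)
instead of using the Sarvas closed form.
"""

import numpy as np

MU0 = 4e-7 * np.pi


def homogeneous_sphere_potential(R_mm, sigma, r0_mm, q_nam, elec_mm):
    """Surface potential (µV) of a dipole in a homogeneous conducting sphere.

    Closed form: with x = b/R, u = cos(angle electrode-dipole),
    d = sqrt(1 - 2xu + x²), the radial Legendre sum is
    2(u - x)/d³ + (1/x)(1/d − 1) and the tangential sum (against P_n')
    2/d³ + (d + 1)/(d·(1 − xu + d)).
    """
    R = R_mm * 1e-3
    r0 = np.asarray(r0_mm, float) * 1e-3
    q = np.asarray(q_nam, float) * 1e-9
    re = np.atleast_2d(np.asarray(elec_mm, float)) * 1e-3
    b = np.linalg.norm(r0)
    er = r0 / b
    ee = re / np.linalg.norm(re, axis=1, keepdims=True)
    u = ee @ er
    x = b / R
    d = np.sqrt(1 - 2 * x * u + x * x)
    qr = q @ er
    qt = (ee - u[:, None] * er) @ q
    s_rad = 2 * (u - x) / d**3 + (1 / x) * (1 / d - 1)
    s_tan = 2 / d**3 + (d + 1) / (d * (1 - x * u + d))
    v = (qr * s_rad + qt * s_tan) / (4 * np.pi * sigma * R**2)
    return v * 1e6


def geselowitz_meg_field(sensor_mm, r0_mm, q_nam, R_mm, sigma,
                         n_surf=200000):
    """Magnetic field (fT, 3-vector) at one point outside a conducting sphere.

    B = B_primary − (µ0/4π)·σ·∮ V(r') n̂ × (r − r')/|r − r'|³ dS' with the
    surface potential V from the homogeneous closed form, integrated over a
    Fibonacci point set on the sphere.
    """
    i = np.arange(n_surf) + 0.5
    z = 1 - 2 * i / n_surf
    phi = np.pi * (3 - np.sqrt(5)) * i
    rho = np.sqrt(1 - z**2)
    nhat = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    rp = R_mm * 1e-3 * nhat
    v_surf = homogeneous_sphere_potential(R_mm, sigma, r0_mm, q_nam,
                                          rp * 1e3) * 1e-6
    r = np.asarray(sensor_mm, float) * 1e-3
    r0 = np.asarray(r0_mm, float) * 1e-3
    q = np.asarray(q_nam, float) * 1e-9
    dvec = r - r0
    b_primary = MU0 / (4 * np.pi) * np.cross(q, dvec) / np.linalg.norm(dvec)**3
    diff = r[None, :] - rp
    dist3 = np.linalg.norm(diff, axis=1)**3
    integrand = np.cross(nhat, diff) / dist3[:, None]
    area = 4 * np.pi * (R_mm * 1e-3)**2 / n_surf
    b_volume = -MU0 / (4 * np.pi) * sigma * (integrand * v_surf[:, None]
                                             ).sum(axis=0) * area
    return (b_primary + b_volume) * 1e15


def grid_search_orientation(L, C, step_deg=1.0, refine=True):
    """Brute-force beamformer orientation: maximize the output ratio
    (φᵀ LᵀC⁻¹L φ)/(φᵀ LᵀC⁻²L φ) over a spherical angle grid.

    A global ``step_deg`` grid is followed by one local refinement pass
    (±2 steps at 1/50 of the step) so that ridges narrower than the global
    grid are still resolved; both stages are plain exhaustive evaluation.
    """
    Cinv = np.linalg.inv(C)
    B = L.T @ Cinv @ L
    A = L.T @ Cinv @ Cinv @ L

    def best(th, ps):
        T, P = np.meshgrid(th, ps, indexing="ij")
        dirs = np.stack([np.sin(T) * np.cos(P), np.sin(T) * np.sin(P),
                         np.cos(T)], axis=-1).reshape(-1, 3)
        num = np.einsum("ni,ij,nj->n", dirs, B, dirs)
        den = np.einsum("ni,ij,nj->n", dirs, A, dirs)
        i = np.argmax(num / den)
        return dirs[i], T.ravel()[i], P.ravel()[i]

    th = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    ps = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    d, t0, p0 = best(th, ps)
    if refine:
        half = np.deg2rad(2 * step_deg)
        fine = np.deg2rad(step_deg / 50.0)
        th2 = np.arange(t0 - half, t0 + half, fine)
        ps2 = np.arange(p0 - half, p0 + half, fine)
        d, _, _ = best(th2, ps2)
    return d
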