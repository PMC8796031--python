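"""Analytic concentric-sphere EEG/MEG forward models.

Geometry lives in a right-handed, head-centered coordinate frame with
positions in mm. Dipole moments are expressed in nA·m; EEG leadfields map
to µV and MEG leadfields to fT per unit moment.

The EEG solution is the spherical-harmonic series for a current dipole
inside a layered isotropic conductor sphere, solved per harmonic order with
a small linear system over the shell coefficients. The MEG solution is the
closed-form magnetic field of a dipole in a spherically symmetric conductor
(Sarvas formula), which is independent of the conductivity profile and
silent for radially oriented moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HeadModel",
    "SensorArray",
    "SourceSpace",
    "Leadfield",
    "build_sphere_head",
    "place_sensors",
    "build_source_grid",
    "eeg_sphere_leadfield",
    "meg_sphere_leadfield",
    "reduce_leadfield_tsvd",
    "reduce_meg_leadfield",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T·m/A

# unit bookkeeping: geometry in mm, moments in nA·m, EEG in µV, MEG in fT
_MM = 1e-3          # mm -> m
_NAM = 1e-9         # nA·m -> A·m
_UV = 1e6           # V -> µV
_FT = 1e15          # T -> fT


@dataclass(frozen=True)
class HeadModel:
    """Concentric-sphere volume conductor.

    Shells are ordered innermost to outermost; ``shell_radii`` are the outer
    radii of each shell in mm and ``shell_conductivities`` the isotropic
    conductivities in S/m.
    """

    shell_radii: np.ndarray
    shell_conductivities: np.ndarray
    label: str = ""

    def __post_init__(self):
        radii = np.asarray(self.shell_radii, dtype=float)
        cond = np.asarray(self.shell_conductivities, dtype=float)
        if radii.ndim != 1 or radii.size == 0:
            raise ValueError("at least one shell is required")
        if radii.size != cond.size:
            raise ValueError("radii and conductivities must have equal length")
        if not np.all(np.diff(radii) > 0):
            raise ValueError("shell radii must be strictly increasing")
        if not np.all(radii > 0):
            raise ValueError("shell radii must be positive")
        if not np.all(cond > 0):
            raise ValueError("shell conductivities must be positive")
        object.__setattr__(self, "shell_radii", radii)
        object.__setattr__(self, "shell_conductivities", cond)

    @property
    def n_shells(self) -> int:
        return self.shell_radii.size

    @property
    def brain_radius(self) -> float:
        """Outer radius of the innermost (brain) shell, mm."""
        return float(self.shell_radii[0])

    @property
    def scalp_radius(self) -> float:
        """Radius of the outermost shell surface, mm."""
        return float(self.shell_radii[-1])

    @property
    def skull_shell(self) -> int:
        """Index of the least conductive shell (the skull by convention)."""
        return int(np.argmin(self.shell_conductivities))

    def with_shell_conductivity(self, shell: int, sigma: float,
                                label: str | None = None) -> "HeadModel":
        """Return a copy with one shell's conductivity replaced."""
        if sigma <= 0:
            raise ValueError("conductivity must be positive")
        cond = self.shell_conductivities.copy()
        cond[shell] = sigma
        return replace(self, shell_conductivities=cond,
                       label=self.label if label is None else label)


def build_sphere_head(radii, conductivities, label: str = "") -> HeadModel:
    """Validate and build a concentric-sphere head model.

    Parameters
    ----------
    radii : sequence of float
        Outer shell radii in mm, innermost (brain) first, strictly increasing.
    conductivities : sequence of float
        Shell conductivities in S/m, same order.
    """
    return HeadModel(np.asarray(radii, float), np.asarray(conductivities, float),
                     label=label)


@dataclass(frozen=True)
class SensorArray:
    """EEG electrode or MEG magnetometer geometry."""

    positions: np.ndarray          # (S, 3) mm
    orientations: np.ndarray | None  # (S, 3) unit vectors, MEG only
    modality: str                  # "eeg" | "meg"
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 3:
            raise ValueError("positions must be (S, 3) with S >= 3")
        object.__setattr__(self, "positions", pos)
        if self.modality not in ("eeg", "meg"):
            raise ValueError("modality must be 'eeg' or 'meg'")
        if self.orientations is not None:
            ori = np.asarray(self.orientations, dtype=float)
            norms = np.linalg.norm(ori, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("orientations must be unit vectors")
            object.__setattr__(self, "orientations", ori)
        if not self.channel_names:
            prefix = self.modality.upper()
            object.__setattr__(
                self, "channel_names",
                [f"{prefix}{i + 1:03d}" for i in range(pos.shape[0])])

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


def _fibonacci_directions(n: int, coverage: str) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    if coverage == "hemisphere":
        # z from just below the pole down to slightly above the equator
        z = 1.0 - (i + 0.5) / n
    elif coverage == "full":
        z = 1.0 - 2.0 * (i + 0.5) / n
    else:
        raise ValueError("coverage must be 'hemisphere' or 'full'")
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = golden * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def place_sensors(head: HeadModel, modality: str, n: int,
                  offset_mm: float = 0.0,
                  coverage: str = "hemisphere") -> SensorArray:
    """Place sensors quasi-uniformly on a sphere around the head.

    EEG electrodes sit exactly on the scalp (``offset_mm`` must be 0); MEG
    magnetometer proxies sit ``offset_mm`` above it with radial pickup
    orientations.
    """
    if n < 3:
        raise ValueError("need at least 3 sensors")
    if offset_mm < 0:
        raise ValueError("offset_mm must be >= 0")
    modality = modality.lower()
    if modality == "eeg" and offset_mm != 0:
        raise ValueError("EEG electrodes must lie on the scalp (offset_mm=0)")
    radius = head.scalp_radius + offset_mm
    dirs = _fibonacci_directions(n, coverage)
    positions = radius * dirs
    orientations = dirs.copy() if modality == "meg" else None
    return SensorArray(positions=positions, orientations=orientations,
                       modality=modality)


@dataclass(frozen=True)
class SourceSpace:
    """Regular grid of candidate dipole positions inside the brain shell."""

    points: np.ndarray   # (P, 3) mm
    spacing: float       # nominal grid resolution, mm
    indices: np.ndarray = None  # stable integer identifiers

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
            raise ValueError("points must be a nonempty (P, 3) array")
        object.__setattr__(self, "points", pts)
        if self.indices is None:
            object.__setattr__(self, "indices", np.arange(pts.shape[0]))
        else:
            object.__setattr__(self, "indices",
                               np.asarray(self.indices, dtype=int))

    @property
    def n_sources(self) -> int:
        return self.points.shape[0]

    def nearest_index(self, point) -> int:
        """Index of the grid point closest to ``point`` (mm)."""
        d = np.linalg.norm(self.points - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


def build_source_grid(head: HeadModel, spacing: float,
                      margin: float = 2.0) -> SourceSpace:
    """Cartesian source grid clipped to a ball inside the brain shell.

    Points are lattice sites ``k * spacing`` (k integer, centered on the
    origin) with radius at most ``brain_radius - margin``, in lexicographic
    (x, y, z) order.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    r_max = head.brain_radius - margin
    if spacing > head.brain_radius:
        raise ValueError("spacing exceeds the brain radius")
    k_max = int(np.floor(r_max / spacing))
    axis = np.arange(-k_max, k_max + 1, dtype=float) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= r_max + 1e-12
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise ValueError("grid is empty; decrease spacing or margin")
    return SourceSpace(points=pts, spacing=float(spacing))


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix mapping dipole moments to sensor readings.

    ``gain`` has shape (S, P·k) with k = 3 free-orientation columns per
    source, or k = 2 after tSVD reduction (``per_source_basis`` then holds
    the retained orientation vectors, shape (P, 3, 2)).
    """

    gain: np.ndarray
    modality: str                 # "eeg" | "meg" | "meeg"
    n_sources: int
    k: int = 3
    reference: str = "none"       # "average" | "none"
    per_source_basis: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        g = np.asarray(self.gain, dtype=float)
        if g.shape[1] != self.n_sources * self.k:
            raise ValueError("gain shape inconsistent with n_sources and k")
        if not np.all(np.isfinite(g)):
            raise ValueError("gain contains non-finite entries")
        object.__setattr__(self, "gain", g)

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    def point(self, p: int) -> np.ndarray:
        """Per-source gain block, shape (S, k)."""
        return self.gain[:, self.k * p:self.k * (p + 1)]


def _legendre_sums(u: np.ndarray, x: np.ndarray, coeff: np.ndarray):
    """Accumulate radial/tangential Legendre series.

    Returns ``sum_n coeff[n] x^(n-1) n P_n(u)`` and
    ``sum_n coeff[n] x^(n-1) P_n'(u)`` for n = 1..len(coeff); ``u`` is the
    cosine between source and sensor directions (broadcast P×S), ``x`` the
    relative source eccentricity per source (P×1).
    """
    n_terms = coeff.size
    p_prev = np.ones_like(u)        # P_0
    p_cur = u.copy()                # P_1
    dp_prev = np.zeros_like(u)      # P_0'
    dp_cur = np.ones_like(u)        # P_1'
    xpow = np.ones_like(x)          # x^(n-1), n = 1
    s_rad = coeff[0] * xpow * 1.0 * p_cur
    s_tan = coeff[0] * xpow * dp_cur
    for n in range(1, n_terms):
        # advance P_n, P_n' from order n to n+1
        p_next = ((2 * n + 1) * u * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        xpow = xpow * x
        order = n + 1
        s_rad += coeff[n] * xpow * order * p_cur
        s_tan += coeff[n] * xpow * dp_cur
    return s_rad, s_tan


def _multishell_coefficients(head: HeadModel, n_terms: int) -> np.ndarray:
    """Surface-potential expansion coefficients G_n of the layered sphere.

    For a dipole source whose infinite-medium expansion in the innermost
    shell is (1/(4πσ₁R²)) Σ x^(n-1) ρ^-(n+1) [...], the scalp potential is
    (1/(4πσ₁R²)) Σ G_n x^(n-1) [...]; for a homogeneous sphere
    G_n = (2n+1)/n.
    """
    radii = head.shell_radii / head.scalp_radius  # normalized, last = 1
    sigma = head.shell_conductivities
    n_shells = radii.size
    coeffs = np.empty(n_terms)
    for order in range(1, n_terms + 1):
        n = float(order)
        if n_shells == 1:
            coeffs[order - 1] = (2 * n + 1) / n
            continue
        # unknowns: A_1, (A_j, B_j) for j = 2..L
        m = 2 * n_shells - 1
        A = np.zeros((m, m))
        b = np.zeros(m)

        def col_A(j):  # column index of A_j
            return 0 if j == 0 else 2 * j - 1

        def col_B(j):  # column of B_j, j >= 1
            return 2 * j

        for j in range(n_shells - 1):  # interface between shell j and j+1
            rho = radii[j]
            pn, qn = rho**n, rho**(-(n + 1))
            dpn, dqn = n * rho**(n - 1), -(n + 1) * rho**(-(n + 2))
            row_v, row_s = 2 * j, 2 * j + 1
            A[row_v, col_A(j)] += pn
            A[row_s, col_A(j)] += sigma[j] * dpn
            if j >= 1:
                A[row_v, col_B(j)] += qn
                A[row_s, col_B(j)] += sigma[j] * dqn
            A[row_v, col_A(j + 1)] -= pn
            A[row_v, col_B(j + 1)] -= qn
            A[row_s, col_A(j + 1)] -= sigma[j + 1] * dpn
            A[row_s, col_B(j + 1)] -= sigma[j + 1] * dqn
            if j == 0:  # move the source term to the right-hand side
                b[row_v] = -qn
                b[row_s] = -sigma[0] * dqn
        # outer boundary: radial current vanishes at rho = 1
        last = n_shells - 1
        A[m - 1, col_A(last)] = n
        A[m - 1, col_B(last)] = -(n + 1)
        if last == 0:
            b[m - 1] = (n + 1)  # source contributes -(n+1) to dV/drho
        sol = np.linalg.solve(A, b)
        coeffs[order - 1] = sol[col_A(last)] + sol[col_B(last)]
    return coeffs


def eeg_sphere_leadfield(head: HeadModel, sensors: SensorArray,
                         sources: SourceSpace, n_terms: int = 60) -> Leadfield:
    """EEG leadfield of the layered sphere, average-referenced.

    Returns scalp potentials in µV per nA·m of dipole moment. The series is
    truncated at ``n_terms`` harmonic orders; raise it for sources very
    close to the brain surface.
    """
    if sensors.modality != "eeg":
        raise ValueError("sensors must be an EEG array")
    R = head.scalp_radius
    if not np.allclose(np.linalg.norm(sensors.positions, axis=1), R,
                       atol=1e-6):
        raise ValueError("EEG electrodes must lie on the outermost shell")
    r_src = np.linalg.norm(sources.points, axis=1)
    if np.any(r_src >= head.brain_radius):
        raise ValueError("all sources must lie strictly inside the brain shell")

    coeffs = _multishell_coefficients(head, n_terms)
    sigma1 = head.shell_conductivities[0]
    # prefactor: SI potential 1/(4π σ R_m²), then A·m -> nA·m, V -> µV
    K = _UV * _NAM / (4 * np.pi * sigma1 * (R * _MM) ** 2)

    S = sensors.n_sensors
    P = sources.n_sources
    e_dirs = sensors.positions / R                       # (S, 3) unit
    x = (r_src / R)[:, None]                             # (P, 1)
    deep = r_src < 1e-9
    src_dirs = np.where(deep[:, None], np.array([0.0, 0.0, 1.0]),
                        sources.points / np.where(deep, 1.0, r_src)[:, None])
    u = src_dirs @ e_dirs.T                              # (P, S)
    s_rad, s_tan = _legendre_sums(u, x, coeffs)
    # tangent helper: e_hat - u * r_hat (unnormalized; absorbs sin(gamma))
    tang = e_dirs[None, :, :] - u[:, :, None] * src_dirs[:, None, :]
    gain_psk = K * (s_rad[:, :, None] * src_dirs[:, None, :]
                    + s_tan[:, :, None] * tang)          # (P, S, 3)
    if np.any(deep):
        # dipole at the center: only the n=1 term survives
        gain_psk[deep] = K * coeffs[0] * e_dirs[None, :, :]
    gain = gain_psk.transpose(1, 0, 2).reshape(S, 3 * P)
    gain = gain - gain.mean(axis=0, keepdims=True)       # average reference
    return Leadfield(gain=gain, modality="eeg", n_sources=P, k=3,
                     reference="average", channel_names=list(sensors.channel_names))


def meg_sphere_leadfield(sensors: SensorArray, sources: SourceSpace,
                         sphere_center=(0.0, 0.0, 0.0)) -> Leadfield:
    """MEG leadfield of the spherically symmetric conductor (Sarvas).

    Returns the field component along each sensor orientation in fT per
    nA·m. Exact for any radial conductivity profile, hence independent of
    the head model's conductivities; radial dipole moments are silent.
    Sources at the sphere center are magnetically silent and produce
    all-zero columns (a warning is emitted).
    """
    if sensors.modality != "meg":
        raise ValueError("sensors must be an MEG array")
    if sensors.orientations is None:
        raise ValueError("MEG sensors need pickup orientations")
    center = np.asarray(sphere_center, float)
    r_sens = (sensors.positions - center) * _MM          # (S, 3) m
    r_src = (sources.points - center) * _MM              # (P, 3) m

    at_center = np.linalg.norm(r_src, axis=1) < 1e-12
    if np.any(at_center):
        warnings.warn("source(s) at the sphere center are magnetically "
                      "silent; their leadfield columns are zero")

    r0 = r_src[:, None, :]                               # (P, 1, 3)
    r = r_sens[None, :, :]                               # (1, S, 3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)                   # (P, S)
    rn = np.linalg.norm(r_sens, axis=-1)[None, :]        # (1, S)
    ar = np.einsum("psk,psk->ps", a_vec, np.broadcast_to(r, a_vec.shape))
    F = a * (rn * a + rn**2 - np.einsum("pok,psk->ps", r0, np.broadcast_to(r, a_vec.shape)))
    c1 = a**2 / rn + ar / a + 2 * a + 2 * rn             # (P, S)
    c2 = a + 2 * rn + ar / a
    gradF = c1[:, :, None] * r - c2[:, :, None] * r0     # (P, S, 3)

    o = sensors.orientations[None, :, :]                 # (1, S, 3)
    o_dot_gradF = np.einsum("psk,osk->ps", gradF, o)
    r0_x_o = np.cross(np.broadcast_to(r0, gradF.shape), np.broadcast_to(o, gradF.shape))
    r0_x_r = np.cross(np.broadcast_to(r0, gradF.shape), np.broadcast_to(r, gradF.shape))
    gain_psk = (MU0 / (4 * np.pi * F**2))[:, :, None] * (
        F[:, :, None] * r0_x_o - o_dot_gradF[:, :, None] * r0_x_r)
    gain_psk *= _FT * _NAM
    gain_psk[at_center] = 0.0
    S, P = sensors.n_sensors, sources.n_sources
    gain = gain_psk.transpose(1, 0, 2).reshape(S, 3 * P)
    return Leadfield(gain=gain, modality="meg", n_sources=P, k=3,
                     reference="none", channel_names=list(sensors.channel_names))


def reduce_leadfield_tsvd(L_point: np.ndarray):
    """Drop the weakest singular direction of a per-source S×3 gain.

    For spherical MEG the discarded right-singular vector is the
    quasi-radial orientation, which carries (numerically) no signal. Ties
    between the two smallest singular values are broken by keeping the first
    two columns of V in the SVD's descending order.

    Returns
    -------
    L2 : (S, 2) array
        Gain restricted to the two strongest orientation directions.
    basis : (3, 2) array
        The retained right-singular vectors (columns).
    """
    L_point = np.asarray(L_point, float)
    if L_point.ndim != 2 or L_point.shape[1] != 3:
        raise ValueError("expected an S×3 point leadfield")
    if not np.all(np.isfinite(L_point)) or not np.any(L_point):
        raise ValueError("point leadfield must be finite and nonzero")
    _, _, vt = np.linalg.svd(L_point, full_matrices=False)
    basis = vt[:2].T                                     # (3, 2)
    return L_point @ basis, basis


def reduce_meg_leadfield(leadfield: Leadfield) -> Leadfield:
    """Apply the tSVD reduction to every source of a free-orientation leadfield."""
    if leadfield.k != 3:
        raise ValueError("leadfield is already reduced")
    S, P = leadfield.n_sensors, leadfield.n_sources
    gain2 = np.empty((S, 2 * P))
    basis = np.empty((P, 3, 2))
    for p in range(P):
        Lp = leadfield.point(p)
        if not np.any(Lp):
            # magnetically silent point (e.g. the sphere center): keep an
            # arbitrary tangential basis and a zero gain
            gain2[:, 2 * p:2 * p + 2] = 0.0
            basis[p] = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
            continue
        gain2[:, 2 * p:2 * p + 2], basis[p] = reduce_leadfield_tsvd(Lp)
    return Leadfield(gain=gain2, modality=leadfield.modality, n_sources=P,
                     k=2, reference=leadfield.reference,
                     per_source_basis=basis,
                     channel_names=list(leadfield.channel_names))
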