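"""Covariance estimation, regularization, LCMV beamforming and dipole scanning.

The beamformer is the linearly constrained minimum-variance spatial filter
with a unit-norm weight constraint (unit-noise-gain form): for a source
with gain L and orientation φ,

    W_φ = argmax_φ argmin_W  Wᵀ C W   s.t.  Wᵀ L φ > 0, ‖W‖ = 1,

whose solution is W ∝ C⁻¹ L φ with φ the generalized eigenvector of
(Lᵀ C⁻² L, Lᵀ C⁻¹ L) belonging to the smallest generalized eigenvalue.
Two weight normalizations are kept side by side: ``unit_norm`` (default)
divides by ‖C⁻¹Lφ‖ and satisfies the ‖W‖ = 1 constraint; ``as_printed``
divides by the scalar Lφᵀ C⁻² Lφ, a form that circulates in the literature
but does *not* have unit norm (it differs by the factor √(LφᵀC⁻²Lφ)).
Both are reported separately and never mixed.

The covariance can be estimated from the trial average ("average-based")
or from the concatenated single trials ("event-related"); regularization is
diagonal loading scaled by trace(C)/S so that a given α is comparable
across sensor counts, C_reg = C + α·I·trace(C)/S.

The dipole scan evaluates a single-dipole least-squares fit at every source
point and reports goodness of fit gof = 1 − ‖D − LL⁺D‖²/‖D‖².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .forward import Leadfield, reduce_meg_leadfield
from .simulate import SpikeDataset

__all__ = [
    "Covariance",
    "BeamformerFilter",
    "SourceMap",
    "estimate_covariance",
    "regularize_covariance",
    "optimal_orientation",
    "beamformer_filter",
    "beamformer_power_map",
    "dipole_scan",
]

# relative eigenvalue floor below which a covariance counts as singular
_EIG_FLOOR = 1e-12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when a rank-deficient covariance is inverted without loading."""


@dataclass(frozen=True)
class Covariance:
    """Sensor covariance with its estimation mode and loading metadata."""

    C: np.ndarray
    mode: str                    # "average_based" | "event_related"
    n_samples: int
    alpha: float = 0.0

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if not np.allclose(C, C.T, atol=1e-12 * max(1.0, np.abs(C).max())):
            raise ValueError("C must be symmetric")
        object.__setattr__(self, "C", 0.5 * (C + C.T))

    @property
    def n_sensors(self) -> int:
        return self.C.shape[0]

    def eigendecomposition(self):
        """Eigenvalues (ascending) and eigenvectors of the symmetric C."""
        return np.linalg.eigh(self.C)

    def inverse(self) -> np.ndarray:
        """Symmetric inverse; raises if numerically rank deficient."""
        vals, vecs = self.eigendecomposition()
        if vals[-1] <= 0 or vals[0] <= _EIG_FLOOR * vals[-1]:
            raise SingularCovarianceError(
                "covariance matrix is numerically singular; apply diagonal "
                "loading with regularize_covariance(C, alpha > 0) before "
                "inverting")
        return (vecs / vals) @ vecs.T


def estimate_covariance(dataset: SpikeDataset, mode: str = "average_based",
                        window_ms: tuple[float, float] | None = None
                        ) -> Covariance:
    """Sensor covariance from the trial average or the concatenated trials.

    ``window_ms`` restricts the estimate to an epoch sub-window (relative to
    the event peak); the default is the full epoch. Both modes use the same
    window; with a single trial they coincide.
    """
    if window_ms is None:
        lo, hi = 0, dataset.n_times
    else:
        lo = int(round(dataset.peak_index + window_ms[0] * 1e-3 * dataset.srate))
        hi = int(round(dataset.peak_index + window_ms[1] * 1e-3 * dataset.srate))
        if not 0 <= lo < hi <= dataset.n_times:
            raise ValueError("covariance window outside the epoch")
    if hi - lo < 1:
        raise ValueError("empty covariance window")
    if mode == "average_based":
        d = dataset.trials.mean(axis=0)[:, lo:hi]
        C = d @ d.T / (hi - lo)
        n = hi - lo
    elif mode == "event_related":
        seg = dataset.trials[:, :, lo:hi]
        n = dataset.n_trials * (hi - lo)
        d = seg.transpose(1, 0, 2).reshape(dataset.n_channels, n)
        C = d @ d.T / n
    else:
        raise ValueError("mode must be 'average_based' or 'event_related'")
    return Covariance(C=C, mode=mode, n_samples=n)


def regularize_covariance(cov: Covariance, alpha: float) -> Covariance:
    """Diagonal loading C_reg = C + α·I·trace(C)/S.

    The trace scaling makes a given α comparable between sensor arrays of
    different size and unit; trace(C_reg) = (1 + α)·trace(C).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return cov
    S = cov.n_sensors
    C_reg = cov.C + alpha * np.trace(cov.C) / S * np.eye(S)
    return Covariance(C=C_reg, mode=cov.mode, n_samples=cov.n_samples,
                      alpha=cov.alpha + alpha)


@dataclass(frozen=True)
class BeamformerFilter:
    """Spatial filter weights and source orientation for one source point."""

    W: np.ndarray          # (S,)
    phi: np.ndarray        # unit orientation, length 3 (or 2 in reduced basis)
    variant: str           # "unit_norm" | "as_printed"


def _degenerate_orientation(L: np.ndarray) -> np.ndarray:
    # dominant right-singular vector: the matched-filter orientation
    _, _, vt = np.linalg.svd(L, full_matrices=False)
    return vt[0]


def _fix_sign(v: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _min_gen_eigvec(A: np.ndarray, B: np.ndarray) -> np.ndarray | None:
    """Eigenvector of the smallest generalized eigenvalue of (A, B).

    B = LᵀC⁻¹L may be rank deficient (for the exactly spherical MEG forward
    the radial orientation is silent): the problem is then solved on
    range(B) and the silent directions never enter the orientation. Returns
    None when B vanishes (fully silent source) or when the spectrum is
    degenerate (every orientation equivalent).
    """
    bvals, bvecs = np.linalg.eigh(B)
    keep = bvals > max(bvals[-1], 0.0) * 1e-10
    if not np.any(keep):
        return None
    V = bvecs[:, keep]
    A_r = V.T @ A @ V
    B_r = V.T @ B @ V
    evals, evecs = sla.eigh(A_r, B_r)
    if evals[-1] - evals[0] <= 1e-10 * max(abs(evals[0]), abs(evals[-1])):
        return None
    phi = V @ evecs[:, 0]
    return phi / np.linalg.norm(phi)


def optimal_orientation(L: np.ndarray, cov: Covariance) -> np.ndarray:
    """Beamformer-optimal source orientation at one source point.

    Solves the generalized eigenvalue problem (Lᵀ C⁻² L, Lᵀ C⁻¹ L) and
    returns the unit eigenvector of the smallest eigenvalue — the
    orientation maximizing the filter's output ratio. When C is a scaled
    identity every orientation is equivalent; the deterministic fallback is
    then the dominant right-singular vector of L. Scale-invariant in L.
    """
    L = np.asarray(L, float)
    Cinv = cov.inverse()
    A = L.T @ Cinv @ Cinv @ L
    B = L.T @ Cinv @ L
    phi = _min_gen_eigvec(A, B)
    if phi is None:
        phi = _degenerate_orientation(L)
    return _fix_sign(phi)


def beamformer_filter(L: np.ndarray, cov: Covariance,
                      variant: str = "unit_norm",
                      orientation: np.ndarray | None = None
                      ) -> BeamformerFilter:
    """LCMV filter weights for one source point.

    ``unit_norm`` enforces the ‖W‖ = 1 constraint; ``as_printed`` uses the
    scalar denominator Lφᵀ C⁻² Lφ instead. The two weight vectors are
    parallel and satisfy Wᵀ Lφ > 0.
    """
    if variant not in ("unit_norm", "as_printed"):
        raise ValueError("variant must be 'unit_norm' or 'as_printed'")
    L = np.asarray(L, float)
    phi = optimal_orientation(L, cov) if orientation is None \
        else np.asarray(orientation, float)
    l_phi = L @ phi
    Cinv = cov.inverse()
    w_raw = Cinv @ l_phi
    if variant == "unit_norm":
        W = w_raw / np.linalg.norm(w_raw)
    else:
        W = w_raw / (l_phi @ Cinv @ Cinv @ l_phi)
    if W @ l_phi < 0:
        W, phi = -W, -phi
    return BeamformerFilter(W=W, phi=phi, variant=variant)


@dataclass
class SourceMap:
    """Per-source scalar field (beamformer power or goodness of fit)."""

    values: np.ndarray
    kind: str                     # "beamformer_power" | "gof"
    method: str = ""              # "bf-avg" | "bf-evt" | "dip"
    modality: str = ""
    model: str = ""
    alpha: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("source map contains non-finite values")
        if self.kind == "gof" and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("gof values must lie in [0, 1]")
        self.values = v

    @property
    def argmax_index(self) -> int:
        """Index of the map maximum; ties resolve to the lowest index."""
        return int(np.argmax(self.values))


def beamformer_power_map(leadfield: Leadfield, cov: Covariance,
                         d_avg: np.ndarray, analysis_index,
                         variant: str = "unit_norm") -> SourceMap:
    """Beamformer output power at every source point.

    power(p) = W_{p,φ}ᵀ D D ᵀ W_{p,φ} with D the averaged-data column(s) at
    ``analysis_index`` (one sample by default; a sequence of indices selects
    a window). The per-source orientation is the generalized-eigenvector
    optimum; filters use the covariance passed in (regularize it first).
    """
    if variant not in ("unit_norm", "as_printed"):
        raise ValueError("variant must be 'unit_norm' or 'as_printed'")
    d_avg = np.asarray(d_avg, float)
    cols = np.atleast_1d(np.asarray(analysis_index, int))
    D = d_avg[:, cols]                                    # (S, m)

    vals, vecs = cov.eigendecomposition()
    if vals[-1] <= 0 or vals[0] <= _EIG_FLOOR * vals[-1]:
        raise SingularCovarianceError(
            "covariance matrix is numerically singular; apply diagonal "
            "loading with regularize_covariance(C, alpha > 0)")
    w1 = 1.0 / vals                                       # C^-1 spectrum
    P, k = leadfield.n_sources, leadfield.k
    Lt = vecs.T @ leadfield.gain                          # rotated leadfield
    Lt3 = Lt.reshape(cov.n_sensors, P, k)
    G1 = np.einsum("spi,s,spj->pij", Lt3, w1, Lt3)        # Lᵀ C⁻¹ L
    G2 = np.einsum("spi,s,spj->pij", Lt3, w1**2, Lt3)     # Lᵀ C⁻² L
    Dt = vecs.T @ D                                       # (S, m)

    degenerate_cov = vals[-1] - vals[0] <= 1e-12 * vals[-1]
    power = np.empty(P)
    for p in range(P):
        if not np.any(Lt3[:, p, :]):
            power[p] = 0.0                                # silent source
            continue
        if degenerate_cov:
            phi = _degenerate_orientation(leadfield.point(p))
        else:
            phi = _min_gen_eigvec(G2[p], G1[p])
            if phi is None:
                phi = _degenerate_orientation(leadfield.point(p))
        l_rot = Lt3[:, p, :] @ phi                        # Uᵀ L φ
        wd = (w1 * l_rot) @ Dt                            # (C⁻¹Lφ)ᵀ D, (m,)
        if variant == "unit_norm":
            denom = np.sqrt(l_rot @ (w1**2 * l_rot))      # ‖C⁻¹Lφ‖
        else:
            denom = l_rot @ (w1**2 * l_rot)               # LφᵀC⁻²Lφ
        power[p] = np.sum((wd / denom) ** 2)
    return SourceMap(values=power, kind="beamformer_power",
                     modality=leadfield.modality, alpha=cov.alpha)


def dipole_scan(leadfield: Leadfield, d: np.ndarray,
                meg_tsvd: bool = False) -> SourceMap:
    """Single-dipole deviation scan over the source grid.

    At each point the data column(s) are projected onto the span of the
    local gain via the pseudoinverse; the score is the goodness of fit
    gof(p) = 1 − ‖D − L_p L_p⁺ D‖²/‖D‖². With ``meg_tsvd`` the per-source
    gain is first reduced to its two strongest orientation directions
    (discarding the quasi-radial one), the truncated-SVD regularization used
    for MEG scans. No covariance regularization is involved.
    """
    d = np.asarray(d, float)
    D = d[:, None] if d.ndim == 1 else d
    total = np.sum(D**2)
    if total == 0:
        raise ValueError("cannot scan an all-zero data vector")
    if meg_tsvd and leadfield.k == 3:
        leadfield = reduce_meg_leadfield(leadfield)
    P = leadfield.n_sources
    gof = np.empty(P)
    for p in range(P):
        L = leadfield.point(p)
        u, s, _ = np.linalg.svd(L, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s[0] > 0 else 0
        proj = u[:, :rank].T @ D if rank else np.zeros((0, D.shape[1]))
        resid = total - np.sum(proj**2)
        gof[p] = 1.0 - resid / total
    gof = np.clip(gof, 0.0, 1.0)
    return SourceMap(values=gof, kind="gof", method="dip",
                     modality=leadfield.modality)
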