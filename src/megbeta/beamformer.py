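"""Scalar LCMV beamformer and network-weighted time-course extraction.

Source activity at a voxel is estimated with a linearly constrained
minimum-variance (LCMV) spatial filter: weights have unit gain to the
voxel's oriented leadfield and minimum output variance under the measured
data covariance.  The dipole orientation at each voxel is the one that
maximizes the beamformer output signal-to-noise ratio (pseudo-Z), obtained
analytically from a generalized eigendecomposition of the reduced 3x3
problem.  Voxel time-courses are sign-aligned (beamformer polarity is
arbitrary) and combined into a single network time-course as the
map-weighted sum  Q_R(t) = sum_i W_i Q_i(t)  over the voxels of a
thresholded network map.

The forward model is the Sarvas closed form for a current dipole in a
homogeneous conducting sphere: a simplification of per-channel local-spheres
head models that preserves every algorithmic contract exercised here, since
all synthetic data are generated with the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as spl

from .spectral import bandpass
from .weibull import FS

__all__ = [
    "MU0",
    "sarvas_leadfield",
    "compute_covariance",
    "tikhonov",
    "lcmv_scalar_weights",
    "sign_align",
    "NetworkMap",
    "network_timecourse",
    "scan_voxels",
]

MU0 = 4e-7 * np.pi  # vacuum permeability (T*m/A)

MAP_THRESHOLD = 0.3


def sarvas_leadfield(dipole_pos, dipole_ori, sensor_pos, sensor_ori,
                     sphere_center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Magnetometer outputs for a unit current dipole in a conducting sphere.

    Uses the Sarvas closed form for the external magnetic field
    B(r) = mu0/(4 pi F^2) (F (Q x r0) - ((Q x r0) . r) grad F); each sensor
    measures B projected on its orientation.  Linear in the dipole moment;
    a purely radial dipole produces an identically zero field.
    """
    center = np.asarray(sphere_center, dtype=float)
    r0 = np.asarray(dipole_pos, dtype=float) - center
    if np.linalg.norm(r0) < 1e-12:
        raise ValueError("dipole at the sphere center has no defined field")
    q = np.asarray(dipole_ori, dtype=float)
    pos = np.atleast_2d(np.asarray(sensor_pos, dtype=float)) - center
    ori = np.atleast_2d(np.asarray(sensor_ori, dtype=float))

    a_vec = pos - r0  # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    r = np.linalg.norm(pos, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("sensor coincides with the dipole")
    ar = np.einsum("ij,ij->i", a_vec, pos)
    F = a * (r * a + r**2 - pos @ r0)
    gradF = (
        (a**2 / r + ar / a + 2.0 * a + 2.0 * r)[:, None] * pos
        - (a + 2.0 * r + ar / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    B = MU0 / (4.0 * np.pi * F[:, None] ** 2) * (
        F[:, None] * qxr0 - (pos @ qxr0)[:, None] * gradF
    )
    return np.einsum("ij,ij->i", B, ori)


def compute_covariance(data: np.ndarray, band: tuple[float, float] = (1.0, 150.0),
                       fs: float = FS) -> np.ndarray:
    """Channel covariance over the whole recording in a wide frequency band.

    Computed within 1-150 Hz by default, over all samples, to minimize
    covariance estimation error.
    """
    x = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("data contain non-finite values")
    n_chan, n_times = x.shape
    if n_times <= n_chan:
        raise ValueError(
            f"covariance needs more samples ({n_times}) than channels ({n_chan})"
        )
    if band is not None:
        x = np.stack([bandpass(row, band, fs) for row in x])
    return np.cov(x)


def tikhonov(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Regularize: C + lambda*I with lambda = 4 x min eigenvalue of C.

    lambda is always taken from the *original* covariance; regularizing an
    already-regularized matrix would compound lambda.  Returns the
    regularized matrix and lambda.
    """
    C = np.asarray(cov, dtype=float)
    eigs = np.linalg.eigvalsh(C)
    if eigs[0] < -1e-10 * max(abs(eigs[-1]), 1e-300):
        raise ValueError("covariance has a negative eigenvalue")
    lam = 4.0 * float(max(eigs[0], 0.0))
    return C + lam * np.eye(C.shape[0]), lam


class _RegularizedInverse:
    """Symmetric inverse through eigendecomposition (stable at high cond)."""

    def __init__(self, C_reg: np.ndarray):
        w, V = np.linalg.eigh(np.asarray(C_reg, dtype=float))
        if w[-1] <= 0:
            raise ValueError("regularized covariance must be positive definite")
        # cap the applied inverse's condition number at 1e6: keeps the
        # orientation eigenproblem factorizable even for noiseless
        # rank-deficient data, and is exact in the signal subspace
        self.w = np.maximum(w, w[-1] * 1e-6)
        self.V = V

    def apply(self, M: np.ndarray, power: int = 1) -> np.ndarray:
        return self.V @ ((self.V.T @ M).T / self.w**power).T


def lcmv_scalar_weights(C_reg: np.ndarray, leadfields: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """SNR-optimal scalar LCMV weights at one voxel.

    Parameters
    ----------
    C_reg : (n_chan, n_chan)
        Regularized data covariance.
    leadfields : (n_chan, 3)
        Leadfields for three orthogonal unit dipole orientations.

    Returns ``(weights, orientation)``.  The orientation maximizes the
    beamformer output SNR (pseudo-Z), i.e. the top generalized eigenvector
    of (L' C^-1 L, L' C^-2 L); degenerate directions (e.g. the radial
    direction in a spherical conductor) are projected out first.  Weights
    satisfy the unit-gain constraint w' l = 1.
    """
    L = np.asarray(leadfields, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError("leadfields must be (n_channels, 3)")
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("all leadfields are zero at this voxel")
    keep = s > 1e-8 * s[0]
    K = Vt[keep].T  # (3, r): orthonormal basis of the non-degenerate subspace
    inv = _RegularizedInverse(C_reg)
    # scale out physical units (T, T^2/Hz): the optimal orientation is
    # invariant to scalar rescaling of both L and C
    Ls = (L / s[0]) @ K
    CiLs = inv.apply(Ls) * inv.w[-1]
    A = Ls.T @ CiLs  # ~ L' C^-1 L, symmetric PSD
    B = CiLs.T @ CiLs  # ~ L' C^-2 L, PSD by construction
    try:
        evals, evecs = spl.eigh(A, B)
        top = evecs[:, -1]
    except np.linalg.LinAlgError:
        # near-singular B: whiten through B's eigendecomposition instead
        eB, VB = np.linalg.eigh(B)
        keepB = eB > eB[-1] * 1e-14
        Wh = VB[:, keepB] / np.sqrt(eB[keepB])
        ev, evec = np.linalg.eigh(Wh.T @ A @ Wh)
        top = Wh @ evec[:, -1]
    u = K @ top
    u = u / np.linalg.norm(u)
    # fixed (arbitrary) polarity convention; sign_align resolves it later
    j = int(np.argmax(np.abs(u)))
    if u[j] < 0:
        u = -u
    l_opt = L @ u
    Cil = inv.apply(l_opt)
    denom = float(l_opt @ Cil)
    if denom <= 0 or np.linalg.norm(l_opt) < 1e-300:
        raise ValueError("degenerate oriented leadfield")
    w = Cil / denom
    return w, u


def scan_voxels(C_reg: np.ndarray, leadfields_per_voxel: np.ndarray,
                data: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Run the scalar beamformer at each voxel.

    ``leadfields_per_voxel`` is (n_voxels, n_chan, 3).  Returns the weight
    matrix (n_voxels, n_chan), the noise-normalized output power
    w'Cw / w'w per voxel (its argmax localizes a single source), and, if
    ``data`` is given, the voxel time-courses W @ data.
    """
    C_reg = np.asarray(C_reg, dtype=float)
    W, power = [], []
    for L in leadfields_per_voxel:
        w, _ = lcmv_scalar_weights(C_reg, L)
        W.append(w)
        power.append(float(w @ C_reg @ w) / float(w @ w))
    W = np.stack(W)
    tcs = W @ np.asarray(data, dtype=float) if data is not None else None
    return W, np.asarray(power), tcs


def sign_align(voxel_timecourses: np.ndarray, weights: np.ndarray | None = None,
               max_iter: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Resolve arbitrary per-voxel polarity before summing over the map.

    Iteratively flips voxels whose series correlates negatively with the
    current (map-weighted) mean series, until a fixed point or ``max_iter``
    passes.  Zero-variance voxels are left unflipped.  Returns the aligned
    series and the sign vector.
    """
    X = np.asarray(voxel_timecourses, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a voxels x time array")
    wmap = np.ones(X.shape[0]) if weights is None else np.asarray(weights, float)
    signs = np.ones(X.shape[0])
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    live = sd > 0
    for _ in range(max_iter):
        ref = (wmap * signs) @ Xc
        if ref @ ref <= 1e-24 * float(np.max(sd, initial=0.0)) ** 2 * X.shape[1]:
            # perfectly cancelling polarities: seed with the strongest voxel
            ref = Xc[int(np.argmax(sd))]
        cov = Xc @ ref
        new = np.where(live & (cov < 0), -1.0, 1.0)
        if np.array_equal(new, signs):
            break
        signs = new
    return X * signs[:, None], signs


@dataclass(frozen=True)
class NetworkMap:
    """Thresholded weighted voxel map defining one functional network."""

    voxels_mm: np.ndarray  # (n, 3) coordinates on the 8 mm grid
    weights: np.ndarray  # (n,) map values, all >= threshold
    name: str = ""
    threshold: float = MAP_THRESHOLD

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.size < 1:
            raise ValueError("network map needs at least one voxel")
        if np.any(w < self.threshold):
            raise ValueError(
                f"all retained map weights must be >= {self.threshold}"
            )


def network_timecourse(voxel_timecourses: np.ndarray, net_map: NetworkMap
                       ) -> np.ndarray:
    """Map-weighted sum of (sign-aligned) voxel series: sum_i W_i Q_i(t)."""
    X = np.asarray(voxel_timecourses, dtype=float)
    w = np.asarray(net_map.weights, dtype=float)
    if X.shape[0] != w.size:
        raise ValueError(
            f"voxel count {X.shape[0]} does not match map size {w.size}"
        )
    return w @ X
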