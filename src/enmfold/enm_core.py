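"""Gaussian and anisotropic network models.

The GNM treats a protein as a network of CA nodes joined by identical
harmonic springs whenever two nodes lie within a cutoff distance
(default 7.0 A, the radius of the first coordination shell).  All
fluctuation quantities derive from the pseudoinverse of the network's
Kirchhoff (connectivity) matrix:

    Gamma_ij = -gamma                   (i != j, contact)
             = 0                        (i != j, no contact)
    Gamma_ii = -sum_{j != i} Gamma_ij

    <dR_i . dR_j> = (3 kB T / gamma) [Gamma^+]_ij

The ANM extends this to a 3N Hessian built from rank-1 blocks along the
native separation vectors, yielding directional normal modes with six
rigid-body zero modes.

Internal units: kB*T = gamma = 1 by default, so fluctuations are in
arbitrary units until :func:`fit_gamma` calibrates the scale against
experimental B-factors; after calibration they are in A^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr

__all__ = [
    "ENMParams",
    "KirchhoffMatrix",
    "HessianMatrix",
    "ModeSpectrum",
    "Covariance",
    "DisconnectedNetworkError",
    "build_kirchhoff",
    "pseudo_inverse",
    "mode_fluctuations",
    "b_factors",
    "fit_gamma",
    "cross_correlation",
    "mode_mass_fraction",
    "build_hessian",
    "anm_slow_mode_field",
]

# |lambda| < rtol * lambda_max counts as a zero mode.  Numerically exact
# zero modes (rigid-body / disconnection) land near N*eps*lambda_max
# (~1e-12), while genuinely soft internal modes (e.g. torsion of a
# cluster about a thin linker) can be as low as ~1e-9; 1e-11 separates
# the two with about an order of magnitude of margin on either side.
ZERO_MODE_RTOL = 1e-11


class DisconnectedNetworkError(ValueError):
    """GNM network with more than one connected component."""

    def __init__(self, components):
        self.components = components
        sizes = [len(c) for c in components]
        super().__init__(
            f"network has {len(components)} connected components (sizes {sizes})"
        )


@dataclass(frozen=True)
class ENMParams:
    """Spring constant, thermal energy and contact cutoffs.

    gamma and kBT are in arbitrary consistent energy units; cutoffs in A.
    """

    gamma: float = 1.0
    kBT: float = 1.0
    cutoff_gnm: float = 7.0
    cutoff_anm: float = 13.0

    def __post_init__(self):
        for name in ("gamma", "kBT", "cutoff_gnm", "cutoff_anm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class KirchhoffMatrix:
    matrix: np.ndarray
    params: ENMParams
    contact_list: list  # (i, j) with i < j

    @property
    def n(self):
        return self.matrix.shape[0]


@dataclass
class HessianMatrix:
    matrix: np.ndarray  # 3N x 3N
    params: ENMParams
    contact_list: list

    @property
    def n(self):
        return self.matrix.shape[0] // 3


@dataclass
class ModeSpectrum:
    """Eigen-decomposition with zero modes flagged.

    ``eigenvalues`` ascending over *all* modes; the first
    ``zero_mode_count`` are the (numerically) zero ones.  ``kind`` is
    "gnm" or "anm" and fixes the covariance scaling.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns
    zero_mode_count: int
    kind: str
    params: ENMParams

    @property
    def nonzero_values(self):
        return self.eigenvalues[self.zero_mode_count:]

    @property
    def nonzero_vectors(self):
        return self.eigenvectors[:, self.zero_mode_count:]

    @property
    def n_nonzero(self):
        return len(self.eigenvalues) - self.zero_mode_count

    @property
    def scale(self):
        """Covariance prefactor: 3kBT (GNM) or kBT (ANM).

        The spring constant gamma lives inside the matrix (its
        eigenvalues are proportional to gamma), so fluctuations scale
        as kBT/gamma overall.
        """
        p = self.params
        return (3.0 if self.kind == "gnm" else 1.0) * p.kBT


@dataclass
class Covariance:
    """<dR_i . dR_j> matrix (GNM: N x N; ANM: 3N x 3N)."""

    matrix: np.ndarray
    kind: str = "gnm"

    @property
    def diagonal(self):
        return np.diag(self.matrix).copy()

    def residue_msf(self):
        """Per-residue mean-square fluctuations.

        For the GNM this is the diagonal; for the ANM, the trace of each
        residue's 3x3 diagonal block.
        """
        if self.kind == "gnm":
            return self.diagonal
        d = np.diag(self.matrix)
        return d.reshape(-1, 3).sum(axis=1)


def _contact_pairs(coords: np.ndarray, cutoff: float):
    """All i<j pairs with CA distance <= cutoff (sequence neighbors included)."""
    d = squareform(pdist(coords))
    ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
    return list(zip(ii.tolist(), jj.tolist())), d


def build_kirchhoff(model, params: ENMParams | None = None) -> KirchhoffMatrix:
    """GNM Kirchhoff matrix of a CA model (or raw (N,3) coordinates)."""
    params = params or ENMParams()
    coords = model if isinstance(model, np.ndarray) else model.coords
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 residues")
    pairs, _ = _contact_pairs(coords, params.cutoff_gnm)
    k = np.zeros((n, n))
    for i, j in pairs:
        k[i, j] = k[j, i] = -params.gamma
    np.fill_diagonal(k, -k.sum(axis=1))
    return KirchhoffMatrix(matrix=k, params=params, contact_list=pairs)


def _components_from_matrix(matrix):
    adj = (matrix != 0).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(adj, directed=False)
    return [np.nonzero(labels == c)[0].tolist() for c in range(n_comp)]


def pseudo_inverse(k, strict: bool = True):
    """Decompose a Kirchhoff/Hessian matrix; return (ModeSpectrum, Covariance).

    Zero modes are identified by |lambda| < 1e-10 * lambda_max and
    excluded from the pseudoinverse.  In strict mode a GNM with more
    than one zero mode raises :class:`DisconnectedNetworkError` naming
    the components, and an ANM with more than six raises a degeneracy
    error; ``strict=False`` simply excludes however many zero modes are
    found (used for fragmented late-unfolding topologies).
    """
    if isinstance(k, KirchhoffMatrix):
        kind, expected = "gnm", 1
    elif isinstance(k, HessianMatrix):
        kind, expected = "anm", 6
    else:
        raise TypeError("expected KirchhoffMatrix or HessianMatrix")
    w, v = eigh(k.matrix)
    lam_max = float(w[-1])
    if lam_max <= 0:
        raise ValueError("matrix has no positive eigenvalue")
    tol = ZERO_MODE_RTOL * lam_max
    nzero = int(np.sum(np.abs(w) < tol))
    if np.any(w < -tol):
        raise ValueError("matrix is not positive semidefinite")
    if strict and nzero > expected:
        if kind == "gnm":
            raise DisconnectedNetworkError(_components_from_matrix(k.matrix))
        raise ValueError(f"ANM degeneracy: {nzero} zero modes (expected 6)")
    spec = ModeSpectrum(
        eigenvalues=w, eigenvectors=v, zero_mode_count=nzero,
        kind=kind, params=k.params,
    )
    inv = spec.nonzero_vectors * (1.0 / spec.nonzero_values)
    cov = spec.scale * (inv @ spec.nonzero_vectors.T)
    return spec, Covariance(matrix=cov, kind=kind)


def mode_fluctuations(spec: ModeSpectrum, mode_set) -> np.ndarray:
    """Per-residue square fluctuations from a subset of nonzero modes.

    ``mode_set`` indexes the nonzero modes (0 = slowest).  Summing over
    all nonzero modes reproduces the covariance diagonal.
    """
    idx = np.asarray(sorted(set(int(m) for m in mode_set)), dtype=int)
    if idx.size == 0:
        raise ValueError("mode_set is empty")
    if idx.min() < 0 or idx.max() >= spec.n_nonzero:
        raise IndexError("mode index out of range of nonzero modes")
    u = spec.nonzero_vectors[:, idx]
    lam = spec.nonzero_values[idx]
    per_coord = spec.scale * (u ** 2 / lam).sum(axis=1)
    if spec.kind == "anm":
        return per_coord.reshape(-1, 3).sum(axis=1)
    return per_coord


def b_factors(cov: Covariance) -> np.ndarray:
    """Debye-Waller factors B_i = (8 pi^2 / 3) <dR_i^2>."""
    return (8.0 * np.pi ** 2 / 3.0) * cov.residue_msf()


def fit_gamma(model, cov_unit_gamma: Covariance):
    """Calibrate the spring constant against experimental B-factors.

    Fits the least-squares scale ``s`` with ``B_exp ~ s * B_pred(gamma=1)``;
    the returned gamma is ``1/s`` (B scales as 1/gamma).  Returns
    ``(gamma, scale, pearson_r)``.
    """
    b_exp = model.bfactors
    if np.allclose(b_exp, b_exp[0]):
        raise ValueError("experimental B-factors are constant; fit is degenerate")
    b_pred = b_factors(cov_unit_gamma)
    scale = float(np.dot(b_pred, b_exp) / np.dot(b_pred, b_pred))
    if scale <= 0:
        raise ValueError("non-positive fitted scale")
    r = float(pearsonr(b_pred, b_exp)[0])
    return 1.0 / scale, scale, r


def cross_correlation(spec: ModeSpectrum, mode_set) -> np.ndarray:
    """Normalized cross-correlation map over a mode subset.

    C_ij = <dR_i.dR_j> / sqrt(<dR_i^2><dR_j^2>), computed from the
    selected modes only; diagonal exactly 1, entries in [-1, 1].
    """
    idx = np.asarray(sorted(set(int(m) for m in mode_set)), dtype=int)
    if idx.size == 0:
        raise ValueError("mode_set is empty")
    if idx.min() < 0 or idx.max() >= spec.n_nonzero:
        raise IndexError("mode index out of range of nonzero modes")
    u = spec.nonzero_vectors[:, idx]
    lam = spec.nonzero_values[idx]
    cov = (u / lam) @ u.T
    if spec.kind == "anm":
        n = cov.shape[0] // 3
        cov = cov.reshape(n, 3, n, 3)
        cov = np.einsum("iaja->ij", cov)
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise ValueError("zero self-fluctuation in the selected mode subset")
    c = cov / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def mode_mass_fraction(spec: ModeSpectrum, first_m: int) -> float:
    """Fraction of total motion carried by the ``first_m`` slowest modes.

    Mode weights are 1/lambda (a mode's contribution to the total
    mean-square fluctuation), so the fraction is
    sum_{k<=m} 1/lambda_k / sum_all 1/lambda_k.
    """
    if not 1 <= first_m <= spec.n_nonzero:
        raise ValueError("first_m out of range")
    inv = 1.0 / spec.nonzero_values
    return float(inv[:first_m].sum() / inv.sum())


def build_hessian(model, params: ENMParams | None = None) -> HessianMatrix:
    """ANM Hessian: rank-1 blocks -(gamma/d^2) dx dx^T for contacting pairs."""
    params = params or ENMParams()
    coords = model if isinstance(model, np.ndarray) else model.coords
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 residues for an ANM")
    pairs, dmat = _contact_pairs(coords, params.cutoff_anm)
    h = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        dx = coords[j] - coords[i]
        d2 = float(dmat[i, j]) ** 2
        if d2 == 0.0:
            raise ValueError(f"coincident nodes {i} and {j}")
        block = -(params.gamma / d2) * np.outer(dx, dx)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return HessianMatrix(matrix=h, params=params, contact_list=pairs)


def anm_slow_mode_field(spec: ModeSpectrum, mode_rank: int = 1) -> np.ndarray:
    """Displacement field of the ``mode_rank``-th slowest internal ANM mode.

    Returns an (N, 3) unit-norm field (overall 3N vector normalized).
    Sign convention: the largest-magnitude component is positive, so a
    global sign flip of the eigenvector yields the same field.
    """
    if spec.kind != "anm":
        raise ValueError("slow-mode fields require an ANM spectrum")
    if not 1 <= mode_rank <= spec.n_nonzero:
        raise IndexError("mode rank beyond spectrum")
    vec = spec.nonzero_vectors[:, mode_rank - 1].copy()
    k = int(np.argmax(np.abs(vec)))
    if vec[k] < 0:
        vec = -vec
    vec /= np.linalg.norm(vec)
    return vec.reshape(-1, 3)
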