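"""Regular spherical-harmonic interference bases.

External interference fields measured inside a source-free sensor volume are
gradients of harmonic potentials that are finite at the expansion origin, so
the field is modelled as a linear combination of the Cartesian gradients of
the *regular* real solid harmonics

    R_lm(r) = r^l Y_lm(theta, phi),   l = 1..L,  m = -l..l,

projected onto each channel's sensitive axis.  The basis matrix S then has
M rows (channels) and N = L^2 + 2L columns; its column space is the modelled
interference subspace.  Order L = 1 spans exactly the three spatially uniform
fields (homogeneous field correction).

Convention: real spherical harmonics in the orthonormal (fully normalised)
convention *without* the Condon-Shortley phase; m > 0 are the cosine branch,
m < 0 the sine branch of |m|.  Any fixed convention spans the same subspace,
and columns are unit-normalised by default, so downstream results do not
depend on this choice beyond reproducibility.

Gradients are evaluated in closed form: R_lm factorises into a polynomial in
(x, y) times a polynomial in (z, r^2), both differentiated analytically, so
the basis is exact to machine precision (no numerical differentiation).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from numpy.polynomial import legendre as npleg
from numpy.polynomial import polynomial as nppoly

from .geometry import SensorArray

__all__ = ["HarmonicBasis", "InvalidOrderError", "regular_harmonic_basis", "n_basis"]


class InvalidOrderError(ValueError):
    """Raised for harmonic orders outside the supported range."""


def n_basis(order: int) -> int:
    """Number of interference basis vectors at harmonic order L: L^2 + 2L."""
    return order * order + 2 * order


@dataclass(frozen=True)
class HarmonicBasis:
    """Interference subspace basis evaluated on a sensor array.

    Attributes
    ----------
    S : (M, N) array
        Basis matrix; column (l, m) is grad(r^l Y_lm) dotted with each
        channel's orientation at its position (relative to the origin).
    order : int
        Maximum harmonic degree L; N = L^2 + 2L.
    column_labels : tuple of (l, m)
        Degree/order pair per column, l = 1..L, m = -l..l.
    normalized : bool
        True if columns were scaled to unit Euclidean norm.
    """

    S: np.ndarray
    order: int
    column_labels: tuple[tuple[int, int], ...]
    normalized: bool

    @property
    def n_channels(self) -> int:
        return self.S.shape[0]

    @property
    def n_components(self) -> int:
        return self.S.shape[1]

    def restrict(self, mask: np.ndarray) -> "HarmonicBasis":
        """Basis restricted to the channels where ``mask`` is True."""
        return HarmonicBasis(self.S[np.asarray(mask, bool)], self.order,
                             self.column_labels, self.normalized)


def _assoc_legendre_poly(l: int, m: int) -> np.ndarray:
    """Power coefficients of d^m/du^m P_l(u) (no Condon-Shortley phase)."""
    c = np.zeros(l + 1)
    c[l] = 1.0
    p = npleg.leg2poly(c)
    for _ in range(m):
        p = nppoly.polyder(p)
    return p


def _solid_harmonic_gradient(l: int, m: int, xyz: np.ndarray) -> np.ndarray:
    """Cartesian gradient of the real regular solid harmonic r^l Y_lm.

    Uses the factorisation r^l Y_lm = N_lm * A_|m|(x, y) * Q(z, r^2) with
    A_m = Re/Im[(x+iy)^m] and Q(z, r^2) = sum_j q_j z^j (r^2)^{(l-|m|-j)/2}
    (the parity of d^|m|P_l makes every exponent of r^2 a nonnegative
    integer).  Returns an (n_points, 3) array.
    """
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    r2 = x * x + y * y + z * z
    am = abs(m)

    norm = np.sqrt((2 * l + 1) / (4 * np.pi))
    if am > 0:
        norm *= np.sqrt(2.0 * factorial(l - am) / factorial(l + am))

    # A_|m| and A_|m|-1 (cosine branch) / B (sine branch) via complex powers
    w = x + 1j * y
    wm = w**am
    A_m = wm.real if m >= 0 else wm.imag
    if am >= 1:
        wm1 = w ** (am - 1)
        # d/dx, d/dy of the angular factor
        if m >= 0:
            dA_dx, dA_dy = am * wm1.real, -am * wm1.imag
        else:
            dA_dx, dA_dy = am * wm1.imag, am * wm1.real
    else:
        dA_dx = dA_dy = np.zeros_like(x)

    q = _assoc_legendre_poly(l, am)
    Q = np.zeros_like(x)
    dQ_dz = np.zeros_like(x)
    dQ_dr2 = np.zeros_like(x)
    for j, qj in enumerate(q):
        if qj == 0.0:
            continue
        p = (l - am - j) // 2  # exponent of r^2; integer by parity
        zj = z**j
        r2p = r2**p
        Q += qj * zj * r2p
        if j >= 1:
            dQ_dz += qj * j * z ** (j - 1) * r2p
        if p >= 1:
            dQ_dr2 += qj * p * zj * r2 ** (p - 1)

    grad = np.empty((x.shape[0], 3))
    grad[:, 0] = dA_dx * Q + A_m * 2.0 * x * dQ_dr2
    grad[:, 1] = dA_dy * Q + A_m * 2.0 * y * dQ_dr2
    grad[:, 2] = A_m * (dQ_dz + 2.0 * z * dQ_dr2)
    return norm * grad


def regular_harmonic_basis(
    array: SensorArray, order: int, normalize: bool = True
) -> HarmonicBasis:
    """Build the regular spherical-harmonic interference basis on an array.

    Parameters
    ----------
    array : SensorArray
        Channel positions/orientations and expansion origin.
    order : int
        Maximum harmonic degree L >= 1; yields N = L^2 + 2L columns ordered
        l = 1..L, m = -l..l.
    normalize : bool
        Scale each column to unit Euclidean norm (default).  Projection is
        invariant to column scaling, but the VB gain model's unit-variance
        amplitude prior makes normalised columns the natural choice.
    """
    if order < 1:
        raise InvalidOrderError(f"harmonic order must be >= 1, got {order}")
    xyz = array.centered_positions()
    cols = []
    labels = []
    for l in range(1, order + 1):
        for m in range(-l, l + 1):
            field = _solid_harmonic_gradient(l, m, xyz)
            cols.append(np.einsum("ij,ij->i", field, array.orientations))
            labels.append((l, m))
    S = np.column_stack(cols)
    if not np.isfinite(S).all():
        raise InvalidOrderError("non-finite basis entries (check geometry)")
    if normalize:
        norms = np.linalg.norm(S, axis=0)
        if np.any(norms == 0):
            raise InvalidOrderError("zero-norm basis column; degenerate geometry")
        S = S / norms
    return HarmonicBasis(S, order, tuple(labels), bool(normalize))
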