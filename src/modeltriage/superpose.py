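"""CA-RMSD between paired traces, in a fixed frame or after Kabsch superposition.

All solutions of one reconstruction puzzle live in the same crystal/map
frame, so the fixed-frame (raw coordinate) RMSD is the default metric;
optimal rigid superposition is provided for ensembles from heterogeneous
frames and always yields an RMSD no larger than the fixed-frame value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InputError
from .structio import CATrace, match_residues

__all__ = ["SuperpositionResult", "kabsch_superpose", "ca_rmsd", "paired_rmsd"]

# relative threshold on the second singular value of the cross-covariance;
# below it the point sets are effectively collinear/coincident and the
# optimal rotation is not unique
_DEGENERACY_RTOL = 1e-9


@dataclass
class SuperpositionResult:
    """Optimal rigid map  b -> rotation @ b + translation  onto a."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,) Angstrom
    rmsd: float  # minimized RMSD, Angstrom


def paired_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Fixed-frame RMSD of two already-paired (N, 3) coordinate arrays."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InputError(f"paired coordinate shapes differ: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def kabsch_superpose(
    a: np.ndarray, b: np.ndarray, pairing: tuple[np.ndarray, np.ndarray] | None = None
) -> SuperpositionResult:
    """Least-squares rigid superposition of point set b onto a (Kabsch, SVD).

    ``pairing`` is an optional (indices_into_a, indices_into_b) pair; by
    default points correspond positionally. Requires at least three
    non-collinear pairs; a degenerate configuration raises
    :class:`DegenerateGeometryError`.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if pairing is not None:
        ia, ib = pairing
        a = a[np.asarray(ia, dtype=np.intp)]
        b = b[np.asarray(ib, dtype=np.intp)]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError(f"point sets must be matching (N, 3) arrays, got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise InputError(f"superposition needs at least 3 pairs, got {n}")

    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    pa = a - centroid_a
    pb = b - centroid_b

    cov = pb.T @ pa  # 3x3 cross-covariance
    u, s, vt = np.linalg.svd(cov)
    if s[0] <= 0 or s[1] <= _DEGENERACY_RTOL * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "point set is collinear or coincident; optimal rotation is not unique"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = centroid_a - rotation @ centroid_b
    rmsd = paired_rmsd(a, (rotation @ b.T).T + translation)
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def ca_rmsd(
    a: CATrace,
    b: CATrace,
    mode: str = "fixed_frame",
    match_mode: str = "strict",
) -> float:
    """CA-RMSD between two traces over the residue-key pairing.

    ``fixed_frame`` computes sqrt(sum ||a_i - b_i||^2 / N) on raw
    coordinates; ``superposed`` first applies the optimal rigid
    superposition and reports the minimized RMSD.
    """
    if mode not in ("fixed_frame", "superposed"):
        raise InputError(f"unknown RMSD mode: {mode!r}")
    ia, ib = match_residues(a, b, mode=match_mode)
    xa = a.coords[ia]
    xb = b.coords[ib]
    if mode == "fixed_frame":
        return paired_rmsd(xa, xb)
    return kabsch_superpose(xa, xb).rmsd
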