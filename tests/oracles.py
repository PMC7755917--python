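"""Independent reference computations used only by tests.

These deliberately share no code with the package: superposition via Horn's
quaternion-eigenvalue method (vs the package's SVD-based Kabsch), and the
closed-form spherical-cap area for two intersecting spheres (vs the package's
point-sampling SASA).
"""

import numpy as np


def quaternion_superpose_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Optimal-superposition RMSD via the largest eigenvalue of Horn's 4x4
    key matrix; never constructs the rotation explicitly."""
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    n = len(moving)
    P = moving - moving.mean(axis=0)
    Q = fixed - fixed.mean(axis=0)
    M = P.T @ Q  # correlation matrix
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    g = (P * P).sum() + (Q * Q).sum()
    return float(np.sqrt(max(g - 2.0 * lam, 0.0) / n))


def two_sphere_sasa(radius: float, separation: float) -> float:
    """Exposed area of one of two equal probe-expanded spheres of ``radius``
    whose centres are ``separation`` apart: the full sphere minus the
    spherical cap hidden inside the partner (cap height h = R - d/2,
    cap area 2 pi R h)."""
    if separation >= 2 * radius:
        return 4.0 * np.pi * radius**2
    h = radius - separation / 2.0
    return 4.0 * np.pi * radius**2 - 2.0 * np.pi * radius * h
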