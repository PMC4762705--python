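"""Independent oracles used only by the tests.

These deliberately avoid the package's own solvers: the rigid fit is Horn's
closed-form quaternion method, rotations are built from the axis-angle
formula directly.
"""

from __future__ import annotations

import numpy as np


def axis_angle_matrix(axis, degrees: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (unit) axis."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    th = np.radians(degrees)
    kx = np.array([[0, -k[2], k[1]],
                   [k[2], 0, -k[0]],
                   [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * kx + (1 - np.cos(th)) * (kx @ kx)


def horn_quaternion_fit(source: np.ndarray, target: np.ndarray):
    """Closed-form least-squares rigid fit (Horn 1987, unit quaternions).

    Returns (rotation, translation) minimising sum ||R s + t - g||^2.
    """
    s = np.asarray(source, dtype=float)
    g = np.asarray(target, dtype=float)
    cs, cg = s.mean(axis=0), g.mean(axis=0)
    a = s - cs
    b = g - cg
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    w, v = np.linalg.eigh(n)
    q = v[:, np.argmax(w)]  # w of largest eigenvalue
    q0, q1, q2, q3 = q
    rot = np.array([
        [q0*q0 + q1*q1 - q2*q2 - q3*q3, 2*(q1*q2 - q0*q3), 2*(q1*q3 + q0*q2)],
        [2*(q2*q1 + q0*q3), q0*q0 - q1*q1 + q2*q2 - q3*q3, 2*(q2*q3 - q0*q1)],
        [2*(q3*q1 - q0*q2), 2*(q3*q2 + q0*q1), q0*q0 - q1*q1 - q2*q2 + q3*q3],
    ])
    return rot, cg - rot @ cs


def random_proper_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR with determinant fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def icc_2_1_anova(matrix: np.ndarray) -> float:
    """ICC(2,1) from two-way ANOVA mean squares, written out by hand."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
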