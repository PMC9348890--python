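"""Unit-quaternion rotations, (w, x, y, z) convention.

Quaternions q and -q act identically on vectors (double cover of SO(3)).
Uniform random orientations use Shoemake's subgroup-algorithm construction,
which is exactly uniform over SO(3).
"""

from __future__ import annotations

import numpy as np

__all__ = ["random_quaternion", "quat_to_matrix", "quat_multiply", "normalize_quaternion"]


def normalize_quaternion(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("zero quaternion")
    return q / n


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion (w, x, y, z) over SO(3)."""
    u1, u2, u3 = rng.uniform(size=3)
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    return np.array(
        [
            b * np.cos(2 * np.pi * u3),
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
        ]
    )


def quat_multiply(q1, q2) -> np.ndarray:
    """Hamilton product q1 * q2; rotation q1∘q2 (q2 applied first)."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_to_matrix(q) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = normalize_quaternion(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
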