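"""Rigid-body fitting utilities (Kabsch superposition)."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "superpose", "superpose_frames", "rotation_angle_axis"]


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation R and translation t mapping mobile → reference.

    Least-squares over paired points; returns (R, t) with
    ``reference ≈ mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Mobile coordinates after least-squares fit onto the reference."""
    R, t = kabsch(mobile, reference)
    return mobile @ R.T + t


def superpose_frames(frames: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Superpose every frame onto the ensemble mean, iterated.

    The mean structure is recomputed after each pass so the fitting frame
    converges toward the ensemble average rather than an arbitrary frame.
    ``iterations=0`` disables fitting (for ensembles already expressed in a
    common laboratory frame, where removing the mean displacement would
    distort genuine collective motion).
    """
    out = np.array(frames, dtype=float, copy=True)
    if iterations <= 0:
        return out
    ref = out.mean(axis=0)
    for _ in range(iterations):
        for t in range(out.shape[0]):
            out[t] = superpose(out[t], ref)
        ref = out.mean(axis=0)
    return out


def rotation_angle_axis(R: np.ndarray):
    """Rotation angle (degrees) and unit axis of a 3×3 rotation matrix."""
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_theta)))
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(w)
    axis = w / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
    return theta, axis
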