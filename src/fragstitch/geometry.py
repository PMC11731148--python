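"""Small geometric utilities: Kabsch superposition and RMSD."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimises the RMSD to
    ``target``.  Both arrays are (n, 3) with matched rows.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch requires matched (n, 3) arrays")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ct - rot @ cm
    return rot, trans


def apply_rigid(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain paired RMSD (no superposition)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rmsd requires matched arrays")
    if a.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    rot, trans = kabsch(mobile, target)
    return rmsd(apply_rigid(mobile, rot, trans), target)
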