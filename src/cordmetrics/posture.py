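"""Postural alignment angles from body landmarks.

Two angles index whole-body alignment in a lateral view (image
coordinates, y increasing downward):

- the cervico-thoraco-lumbar (CTL) angle: the interior angle at the
  shoulder between the shoulder-eye and shoulder-hip lines, indexing
  upper-body posture above a thoracic lesion;
- the trunk alignment angle: the unsigned angle between the shoulder-hip
  line and the ground direction, indexing pelvis/hindlimb alignment below
  the lesion.

The ground direction is supplied per scene rather than assumed horizontal
so camera tilt can be corrected.  Both angles are invariant under
translation, rotation (with the ground vector co-rotated) and uniform
scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError

_EPS = 1e-12


def _vec(p, q) -> np.ndarray:
    v = np.asarray(q, dtype=np.float64) - np.asarray(p, dtype=np.float64)
    if np.linalg.norm(v) < _EPS:
        raise GeometryError("coincident landmark points")
    return v


def ctl_angle(eye, shoulder, hip) -> float:
    """Interior angle (degrees, in (0, 180]) at the shoulder."""
    u = _vec(shoulder, eye)
    v = _vec(shoulder, hip)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def trunk_angle(shoulder, hip, ground_direction=(1.0, 0.0)) -> float:
    """Unsigned angle (degrees, in [0, 90]) between trunk line and ground."""
    g = np.asarray(ground_direction, dtype=np.float64)
    if np.linalg.norm(g) < _EPS:
        raise GeometryError("zero ground direction vector")
    u = _vec(shoulder, hip)
    cosang = abs(np.dot(u, g)) / (np.linalg.norm(u) * np.linalg.norm(g))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def scene_angles(scene) -> tuple[float, float]:
    """(CTL, trunk) angles of a :class:`~cordmetrics.simulate.LandmarkScene`."""
    return (ctl_angle(scene.eye, scene.shoulder, scene.hip),
            trunk_angle(scene.shoulder, scene.hip, scene.ground_direction))


def angle_range(measures: pd.DataFrame, min_frames: int = 3) -> dict[str, dict[str, float]]:
    """Per-animal movement range of each angle over selected frames.

    ``measures`` has columns ``ctl_angle`` and ``trunk_angle`` with one
    row per frame; at least ``min_frames`` frames are required.
    """
    if len(measures) < min_frames:
        raise ParameterError(f"need at least {min_frames} frames")
    out = {}
    for col in ("ctl_angle", "trunk_angle"):
        if col not in measures:
            raise ParameterError(f"missing column '{col}'")
        v = measures[col].to_numpy(dtype=float)
        out[col] = {"min": float(v.min()), "max": float(v.max()),
                    "range": float(v.max() - v.min())}
    return out


def prevalence(flags_by_group: dict[str, "list[bool] | np.ndarray"]
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group prevalence of a dichotomous trait (e.g. trunk instability).

    Returns ``(summary, contingency)``: the summary has per-group counts
    and percentages; the 2 x k contingency table (flagged / not flagged
    per group) is exported for external chi-square testing.
    """
    if not flags_by_group:
        raise ParameterError("no groups supplied")
    rows = {}
    summary = []
    for group, flags in flags_by_group.items():
        flags = np.asarray(flags, dtype=bool)
        n = flags.size
        n_flagged = int(flags.sum())
        summary.append({
            "group": group, "n": n, "n_flagged": n_flagged,
            "percent": 100.0 * n_flagged / n if n else float("nan"),
            "empty": n == 0,
        })
        rows[group] = [n_flagged, n - n_flagged]
    contingency = pd.DataFrame(rows, index=["flagged", "not_flagged"])
    return pd.DataFrame(summary), contingency


def read_landmarks(path) -> pd.DataFrame:
    """Read a landmark CSV with columns frame, point, x, y."""
    df = pd.read_csv(path)
    missing = {"frame", "point", "x", "y"} - set(df.columns)
    if missing:
        raise ParameterError(f"landmark CSV missing columns: {sorted(missing)}")
    return df


def angles_from_landmarks(df: pd.DataFrame) -> pd.DataFrame:
    """Per-frame CTL and trunk angles from a long-format landmark table.

    Each frame must provide ``eye``, ``shoulder`` and ``hip`` points; a
    ``ground`` row gives the ground direction (default horizontal).
    """
    rows = []
    for frame, sub in df.groupby("frame", sort=True):
        pts = {str(r["point"]): np.array([r["x"], r["y"]], dtype=float)
               for _, r in sub.iterrows()}
        for need in ("eye", "shoulder", "hip"):
            if need not in pts:
                raise ParameterError(f"frame {frame} missing landmark '{need}'")
        ground = pts.get("ground", np.array([1.0, 0.0]))
        rows.append({
            "frame": frame,
            "ctl_angle": ctl_angle(pts["eye"], pts["shoulder"], pts["hip"]),
            "trunk_angle": trunk_angle(pts["shoulder"], pts["hip"], ground),
        })
    return pd.DataFrame(rows)
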