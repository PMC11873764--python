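"""Volume censoring ("scrubbing") of network time courses.

Motion-contaminated volumes are flagged on two criteria — framewise
displacement (FD) above 0.5 mm or a DVARS signal-change rate above 3 %
of the mean signal — and each flagged volume is removed together with
the volume before it and the two after it.  A session is kept for
analysis only if at least half of its volumes survive.

FD follows the Power convention: the sum of absolute backward
differences of the six rigid-body parameters, with rotations converted
to arc length on a 50 mm sphere.  DVARS is computed here on network
time courses (the voxel-level data are upstream of this pipeline), as
the root-mean-square backward difference across networks expressed as a
percentage of the grand-mean signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MotionTrace, NetworkTimeCourses

__all__ = [
    "QCParams",
    "QCTrace",
    "compute_fd",
    "compute_dvars",
    "build_scrub_mask",
    "apply_scrub",
    "check_inclusion",
    "run_qc",
]


@dataclass(frozen=True)
class QCParams:
    """Censoring thresholds and the retention rule.

    fd_threshold
        Flag volumes with FD strictly above this, in mm.
    dvars_threshold
        Flag volumes with DVARS strictly above this, in % of mean signal.
    n_before / n_after
        Neighbours removed around each flagged volume (1 before, 2 after).
    min_retained_fraction
        A session is included iff at least this fraction of volumes is kept.
    head_radius
        Sphere radius (mm) converting rotations to displacement.
    """

    fd_threshold: float = 0.5
    dvars_threshold: float = 3.0
    n_before: int = 1
    n_after: int = 2
    min_retained_fraction: float = 0.5
    head_radius: float = 50.0

    def __post_init__(self) -> None:
        if self.fd_threshold <= 0 or self.dvars_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.min_retained_fraction <= 1:
            raise ValueError("min_retained_fraction must lie in (0, 1]")
        if self.n_before < 0 or self.n_after < 0:
            raise ValueError("neighbour counts must be non-negative")
        if self.head_radius <= 0:
            raise ValueError("head_radius must be positive")


@dataclass
class QCTrace:
    """Per-volume FD/DVARS values and the derived keep/remove mask."""

    fd: np.ndarray
    dvars_pct: np.ndarray
    keep_mask: np.ndarray
    retained_fraction: float

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars_pct = np.asarray(self.dvars_pct, dtype=float)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        t = self.keep_mask.size
        if self.fd.size != t or self.dvars_pct.size != t:
            raise ValueError("fd, dvars_pct and keep_mask must share one length")
        if np.any(self.fd < 0) or np.any(self.dvars_pct < 0):
            raise ValueError("fd and dvars_pct must be non-negative")
        expected = self.keep_mask.sum() / t
        if abs(expected - self.retained_fraction) > 1e-9:
            raise ValueError("retained_fraction inconsistent with keep_mask")


def compute_fd(motion: MotionTrace, head_radius: float = 50.0) -> np.ndarray:
    """Framewise displacement per volume, in mm.

    fd[0] = 0 by convention (no predecessor); fd[t] sums the absolute
    backward differences of the three translations plus ``head_radius``
    times those of the three rotations.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_dvars(tc: NetworkTimeCourses) -> np.ndarray:
    """DVARS per volume, as a percentage of the grand-mean signal.

    dvars[0] = 0; dvars[t] = 100 * RMS over networks of the backward
    signal difference, divided by the grand mean of the whole matrix.
    Signals must therefore be un-demeaned (raw BOLD-like scale).
    """
    if tc.n_volumes < 2:
        raise ValueError("need at least 2 volumes to compute DVARS")
    grand_mean = float(tc.values.mean())
    scale = float(np.abs(tc.values).mean())
    if abs(grand_mean) < 1e-9 * max(scale, 1.0):
        raise ValueError(
            "grand-mean signal is ~0; DVARS needs un-demeaned time courses"
        )
    rms = np.sqrt(np.mean(np.diff(tc.values, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], 100.0 * rms / grand_mean])


def build_scrub_mask(
    fd: np.ndarray, dvars_pct: np.ndarray, params: QCParams = QCParams()
) -> np.ndarray:
    """Boolean keep-mask after flagging and neighbour removal.

    A volume is flagged when FD or DVARS strictly exceeds its threshold;
    the removed set is the union over flagged volumes t of
    {t - n_before, ..., t + n_after}, clipped to the series.
    """
    fd = np.asarray(fd, dtype=float)
    dvars_pct = np.asarray(dvars_pct, dtype=float)
    if fd.shape != dvars_pct.shape:
        raise ValueError("fd and dvars_pct must have the same length")
    t = fd.size
    flagged = (fd > params.fd_threshold) | (dvars_pct > params.dvars_threshold)
    remove = np.zeros(t, dtype=bool)
    for offset in range(-params.n_before, params.n_after + 1):
        shifted = np.flatnonzero(flagged) + offset
        shifted = shifted[(shifted >= 0) & (shifted < t)]
        remove[shifted] = True
    return ~remove


def apply_scrub(tc: NetworkTimeCourses, keep_mask: np.ndarray) -> NetworkTimeCourses:
    """Row-subset of the time courses at kept volumes, in original order."""
    keep_mask = np.asarray(keep_mask, dtype=bool)
    if keep_mask.size != tc.n_volumes:
        raise ValueError(
            f"mask length {keep_mask.size} != {tc.n_volumes} volumes"
        )
    kept = int(keep_mask.sum())
    if kept < 2:
        raise ValueError(
            f"only {kept} volumes retained; downstream statistics are undefined"
        )
    return tc.with_values(tc.values[keep_mask])


def check_inclusion(retained_fraction: float, params: QCParams = QCParams()) -> bool:
    """Session inclusion rule: keep iff the retained fraction is at least
    ``min_retained_fraction`` (boundary inclusive: a 50 % minimum)."""
    if not 0 <= retained_fraction <= 1:
        raise ValueError("retained_fraction must lie in [0, 1]")
    return retained_fraction >= params.min_retained_fraction


def run_qc(
    tc: NetworkTimeCourses, motion: MotionTrace, params: QCParams = QCParams()
) -> QCTrace:
    """FD + DVARS + scrub mask for one session in one call."""
    if motion.n_volumes != tc.n_volumes:
        raise ValueError(
            f"motion trace length {motion.n_volumes} != time-course length "
            f"{tc.n_volumes}"
        )
    fd = compute_fd(motion, params.head_radius)
    dvars = compute_dvars(tc)
    keep = build_scrub_mask(fd, dvars, params)
    return QCTrace(
        fd=fd,
        dvars_pct=dvars,
        keep_mask=keep,
        retained_fraction=keep.sum() / keep.size,
    )
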