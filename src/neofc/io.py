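"""Reading and writing the pipeline's plain-text artifacts.

All tabular artifacts are UTF-8 TSV with a header row and '.' decimals
('NA' marks undefined entries); the one exception is the motion file,
which follows the headerless six-column SPM ``rp_*.txt`` dialect
(3 translations in mm, 3 rotations in radians).  Floats are written
with ``%.17g`` so every write -> read round-trip is lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Connectome, MotionTrace, NetworkTimeCourses

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_motion",
    "write_motion",
    "read_connectome",
    "write_connectome",
    "read_manifest",
    "write_mask",
    "read_mask",
]

_FLOAT_FMT = "%.17g"


def _parse_numeric_table(path: Path, sep: str = "\t") -> pd.DataFrame:
    """TSV with header -> all-float DataFrame, with line-numbered errors."""
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty file") from err
    except pd.errors.ParserError as err:
        # pandas reports the offending line number in its message
        raise ValueError(f"{path}: ragged or malformed row ({err})") from err
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: non-numeric cell in column {col!r} at line {line}"
            )
        df[col] = converted
    return df


def read_timecourses(
    path: str | Path, subject_id: str | None = None, session: str | None = None
) -> NetworkTimeCourses:
    """Parse a time-course TSV (header = network labels, rows = volumes)."""
    path = Path(path)
    df = _parse_numeric_table(path)
    return NetworkTimeCourses(
        values=df.to_numpy(dtype=float),
        network_labels=[str(c) for c in df.columns],
        subject_id=subject_id,
        session=session,
    )


def write_timecourses(tc: NetworkTimeCourses, path: str | Path) -> None:
    pd.DataFrame(tc.values, columns=tc.network_labels).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_motion(path: str | Path) -> MotionTrace:
    """Parse an SPM-style rp file: 6 whitespace-separated numeric columns."""
    path = Path(path)
    try:
        params = np.loadtxt(path, ndmin=2)
    except ValueError as err:
        raise ValueError(f"{path}: malformed motion file ({err})") from err
    if params.size == 0:
        raise ValueError(f"{path}: empty motion file")
    if params.shape[1] != 6:
        raise ValueError(
            f"{path}: expected 6 motion columns, found {params.shape[1]}"
        )
    return MotionTrace(params=params)


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    np.savetxt(path, motion.params, fmt=_FLOAT_FMT)


def read_connectome(
    path: str | Path, subject_id: str | None = None, session: str | None = None
) -> Connectome:
    """Parse a labeled square accordance-matrix TSV ('NA' diagonal)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    labels = [str(c) for c in df.columns]
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: connectome must be square, got {df.shape[0]}x{df.shape[1]}"
        )
    return Connectome(
        matrix=df.to_numpy(dtype=float),
        network_labels=labels,
        subject_id=subject_id,
        session=session,
    )


def write_connectome(connectome: Connectome, path: str | Path) -> None:
    pd.DataFrame(connectome.matrix, columns=connectome.network_labels).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA"
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest TSV; file paths are resolved relative to its folder."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "group", "session", "timecourse_path", "motion_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    root = path.parent
    for col in ("timecourse_path", "motion_path"):
        df[col] = [
            str(p) if Path(p).is_absolute() else str(root / p) for p in df[col]
        ]
    return df


def write_mask(keep_mask: np.ndarray, path: str | Path) -> None:
    """Per-session keep mask: one 0/1 per line."""
    np.savetxt(path, np.asarray(keep_mask, dtype=int), fmt="%d")


def read_mask(path: str | Path) -> np.ndarray:
    vals = np.loadtxt(path, dtype=int, ndmin=1)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: mask entries must be 0 or 1")
    return vals.astype(bool)
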