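"""Core in-memory containers shared across the pipeline stages.

The pipeline operates on per-subject, per-session objects: a matrix of
resting-state network (RSN) time courses, the rigid-body motion trace
recorded alongside it, and the accordance connectome estimated from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NetworkTimeCourses", "MotionTrace", "Connectome", "edge_pairs"]


def edge_pairs(n: int) -> list[tuple[int, int]]:
    """Upper-triangle index pairs (i < j) enumerating the n*(n-1)/2 edges."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass
class NetworkTimeCourses:
    """T x N matrix of BOLD network signals for one subject-session.

    Rows are volumes (time), columns are networks.  ``network_labels``
    names the columns; labels must be unique because edges are reported
    by label pairs downstream.
    """

    values: np.ndarray
    network_labels: list[str]
    subject_id: str | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.network_labels = list(self.network_labels)
        if self.values.ndim != 2:
            raise ValueError(f"time courses must be 2-D, got shape {self.values.shape}")
        t, n = self.values.shape
        if t < 2:
            raise ValueError(f"need at least 2 volumes, got {t}")
        if n < 1:
            raise ValueError("need at least one network column")
        if len(self.network_labels) != n:
            raise ValueError(
                f"{len(self.network_labels)} labels for {n} columns"
            )
        if len(set(self.network_labels)) != n:
            raise ValueError("network labels must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValueError(
                f"non-finite signal at (volume, network) {tuple(bad[0])}"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_networks(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "NetworkTimeCourses":
        """Copy carrying the same labels/identity but new signal values."""
        return NetworkTimeCourses(
            values=values,
            network_labels=list(self.network_labels),
            subject_id=self.subject_id,
            session=self.session,
        )


@dataclass
class MotionTrace:
    """T x 6 rigid-body realignment parameters.

    Columns 0-2 are translations in mm, columns 3-5 rotations in radians
    (the SPM ``rp_*.txt`` convention).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion trace must be T x 6, got shape {self.params.shape}"
            )
        if not np.all(np.isfinite(self.params)):
            bad = int(np.argwhere(~np.isfinite(self.params))[0, 0])
            raise ValueError(f"non-finite motion parameter at volume {bad}")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class Connectome:
    """N x N symmetric accordance matrix for one subject-session.

    The diagonal carries NaN (self-coupling is trivially 1 and excluded
    from every edge enumeration); off-diagonal entries lie in [0, 1] or
    are NaN where an edge is undefined (zero thresholded energy).
    """

    matrix: np.ndarray
    network_labels: list[str]
    subject_id: str | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.network_labels = list(self.network_labels)
        n = len(self.network_labels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        off = ~np.eye(n, dtype=bool)
        vals = self.matrix[off]
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("off-diagonal accordance values must lie in [0, 1]")
        if not np.allclose(
            np.nan_to_num(self.matrix), np.nan_to_num(self.matrix.T), atol=1e-12
        ):
            raise ValueError("connectome matrix must be symmetric")

    @property
    def n_networks(self) -> int:
        return len(self.network_labels)

    def edge_value(self, a: str, b: str) -> float:
        i = self.network_labels.index(a)
        j = self.network_labels.index(b)
        if i == j:
            raise ValueError("self-edges are undefined")
        return float(self.matrix[i, j])

    def edge_table(self) -> pd.DataFrame:
        """Long-format edge listing (region_1, region_2, accordance)."""
        rows = [
            {
                "subject_id": self.subject_id,
                "session": self.session,
                "region_1": self.network_labels[i],
                "region_2": self.network_labels[j],
                "accordance": self.matrix[i, j],
            }
            for i, j in edge_pairs(self.n_networks)
        ]
        return pd.DataFrame(rows)
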