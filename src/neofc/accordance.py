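"""Accordance functional-connectivity estimation.

Accordance is a nonparametric coupling statistic between two
standardized time courses.  Each z-scored signal is split at a positive
threshold u (here the 80 % standard-normal quantile, u ~ 0.8416) into a
suprathreshold part x+ (activation) and a subthreshold part x-
(deactivation).  Accordance counts coactivation and codeactivation:

    a_ij = ( <x_i+, x_j+> + <x_i-, x_j-> ) / (sigma_i * sigma_j)

with sigma^2 = <x+, x+> + <x-, x->, so self-coupling is exactly 1 and
every edge lies in [0, 1] (Cauchy-Schwarz on same-sign inner products).
Discordance is the complementary anti-coupling statistic over the
cross-sign products.  Compared with Pearson correlation, the statistic
only credits coherent excursions beyond the threshold, which makes it
robust to small fluctuations around baseline.

Two variants are provided: ``magnitude`` (default) keeps the thresholded
signal values, ``binary`` replaces them with +/-1 indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import Connectome, NetworkTimeCourses, edge_pairs

__all__ = [
    "AccordanceParams",
    "ThresholdedSignal",
    "znormalize",
    "threshold_signal",
    "accordance",
    "discordance",
    "build_connectome",
    "group_average_connectome",
]


@dataclass(frozen=True)
class AccordanceParams:
    """Threshold choice for the accordance estimator.

    quantile_prob
        Probability defining the threshold u as the standard-normal
        quantile; the default 0.8 gives u ~ 0.8416.
    variant
        'magnitude' keeps thresholded signal values; 'binary' uses
        +/-1 indicators on the same supports.
    """

    quantile_prob: float = 0.8
    variant: str = "magnitude"

    def __post_init__(self) -> None:
        if not 0.5 < self.quantile_prob < 1:
            raise ValueError("quantile_prob must lie in (0.5, 1)")
        if self.variant not in ("magnitude", "binary"):
            raise ValueError("variant must be 'magnitude' or 'binary'")

    @property
    def threshold(self) -> float:
        """u = standard-normal quantile of quantile_prob (> 0)."""
        return float(sps.norm.ppf(self.quantile_prob))


@dataclass
class ThresholdedSignal:
    """Supra/sub-threshold parts of a standardized signal.

    x_plus is non-negative, x_minus non-positive, their supports are
    disjoint, and sigma is the thresholded energy
    sqrt(<x+, x+> + <x-, x->).
    """

    x_plus: np.ndarray
    x_minus: np.ndarray

    def __post_init__(self) -> None:
        self.x_plus = np.asarray(self.x_plus, dtype=float)
        self.x_minus = np.asarray(self.x_minus, dtype=float)
        if self.x_plus.shape != self.x_minus.shape:
            raise ValueError("x_plus and x_minus must share one shape")
        if np.any(self.x_plus < 0) or np.any(self.x_minus > 0):
            raise ValueError("x_plus must be >= 0 and x_minus <= 0 elementwise")
        if np.any((self.x_plus != 0) & (self.x_minus != 0)):
            raise ValueError("x_plus and x_minus supports must be disjoint")

    @property
    def sigma(self) -> float:
        return float(
            np.sqrt(self.x_plus @ self.x_plus + self.x_minus @ self.x_minus)
        )


def znormalize(tc: NetworkTimeCourses) -> NetworkTimeCourses:
    """Column-wise z-scoring: mean 0, unit sample standard deviation (ddof=1)."""
    sd = tc.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(np.isclose(sd, 0.0))
    if bad.size:
        names = ", ".join(tc.network_labels[i] for i in bad)
        raise ValueError(f"zero-variance network column(s): {names}")
    return tc.with_values((tc.values - tc.values.mean(axis=0)) / sd)


def threshold_signal(
    z: np.ndarray, params: AccordanceParams = AccordanceParams()
) -> ThresholdedSignal:
    """Split a standardized vector at +/-u into activation parts.

    magnitude variant: x+[t] = z[t] if z[t] >= u else 0, and
    x-[t] = z[t] if z[t] <= -u else 0.  binary variant: +/-1 on the same
    supports.
    """
    z = np.asarray(z, dtype=float)
    u = params.threshold
    up = z >= u
    dn = z <= -u
    if params.variant == "magnitude":
        return ThresholdedSignal(np.where(up, z, 0.0), np.where(dn, z, 0.0))
    return ThresholdedSignal(up.astype(float), -dn.astype(float))


def _edge_value(si: ThresholdedSignal, sj: ThresholdedSignal, cross: bool) -> float:
    den = si.sigma * sj.sigma
    if den == 0.0:
        warnings.warn(
            "zero thresholded energy: edge undefined (NaN)", stacklevel=3
        )
        return float("nan")
    if cross:
        num = -(si.x_plus @ sj.x_minus + si.x_minus @ sj.x_plus)
    else:
        num = si.x_plus @ sj.x_plus + si.x_minus @ sj.x_minus
    return float(num / den)


def accordance(si: ThresholdedSignal, sj: ThresholdedSignal) -> float:
    """Coactivation/codeactivation coupling in [0, 1]; NaN if either
    signal never crosses the threshold (zero energy)."""
    return _edge_value(si, sj, cross=False)


def discordance(si: ThresholdedSignal, sj: ThresholdedSignal) -> float:
    """Anti-coupling (activation of one with deactivation of the other)
    in [0, 1]; NaN on zero energy."""
    return _edge_value(si, sj, cross=True)


def build_connectome(
    tc: NetworkTimeCourses, params: AccordanceParams = AccordanceParams()
) -> Connectome:
    """Accordance matrix over all network pairs of one session.

    The signals are z-scored, thresholded at +/-u and every one of the
    N(N-1)/2 edges is filled in; the diagonal is left NaN (self-coupling
    is trivially 1 and excluded from all edge statistics).
    """
    z = znormalize(tc)
    thresholded = [threshold_signal(z.values[:, k], params) for k in range(z.n_networks)]
    n = z.n_networks
    mat = np.full((n, n), np.nan)
    for i, j in edge_pairs(n):
        mat[i, j] = mat[j, i] = accordance(thresholded[i], thresholded[j])
    return Connectome(
        matrix=mat,
        network_labels=tc.network_labels,
        subject_id=tc.subject_id,
        session=tc.session,
    )


def group_average_connectome(connectomes: list[Connectome]) -> Connectome:
    """Elementwise mean connectome across subjects (NaN edges excluded
    per entry); all inputs must share the same label order."""
    if not connectomes:
        raise ValueError("need at least one connectome")
    labels = connectomes[0].network_labels
    for c in connectomes[1:]:
        if c.network_labels != labels:
            raise ValueError(
                "network label mismatch across connectomes; reorder inputs "
                "explicitly rather than relying on silent alignment"
            )
    stack = np.stack([c.matrix for c in connectomes])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return Connectome(matrix=mean, network_labels=labels, session="group-mean")
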