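"""Longitudinal edge statistics: maturating COI and intervention effect.

Two stages operate on per-subject accordance connectomes from two
sessions (33 and 40 weeks gestational age):

1. *COI definition.*  For every network pair, a paired t-test compares
   session-2 against session-1 accordance across the pooled cohort; the
   raw p-values are corrected with the Benjamini-Hochberg step-up over
   all m = N(N-1)/2 edges, and edges with adjusted p <= alpha form the
   maturating circuitry of interest (COI).  The edge-weight difference
   (EWD) is the mean per-subject accordance change.

2. *Intervention-effect test.*  On the COI edges only, each group's
   within-group paired t-test (one-sided, increase) yields a p-value
   that is converted to a z-score via the standard-normal quantile.
   The group contrast z_diff = (z_music - z_control) / sqrt(2) is
   standard normal under the null of equal maturation (variance-sum
   law with independent groups), and edges with z_diff >= 1.3
   (p <= 0.1, one-sided) are called significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import Connectome, edge_pairs

__all__ = [
    "StatsConfig",
    "GroupDiffConfig",
    "paired_edge_ttest",
    "bh_fdr",
    "define_coi",
    "pval_to_z",
    "group_z_difference",
    "music_effect_test",
]

logger = logging.getLogger(__name__)

_P_CLAMP = 1e-15


@dataclass(frozen=True)
class StatsConfig:
    """COI-definition settings.

    alpha
        FDR level for the Benjamini-Hochberg correction.
    n_edges
        Number m of tests in the BH family; None means all N(N-1)/2
        edges of the connectome (55 for 11 networks).
    coi_test_sides
        'two_sided' (default) or 'one_sided_increase' for the paired
        t-tests defining the COI.
    """

    alpha: float = 0.05
    n_edges: int | None = None
    coi_test_sides: str = "two_sided"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.coi_test_sides not in ("two_sided", "one_sided_increase"):
            raise ValueError(
                "coi_test_sides must be 'two_sided' or 'one_sided_increase'"
            )
        if self.n_edges is not None and self.n_edges < 1:
            raise ValueError("n_edges must be positive")


@dataclass(frozen=True)
class GroupDiffConfig:
    """Thresholding of the standardized group difference.

    z_threshold 1.3 corresponds (to rounding) to a one-sided p of 0.1:
    the standard-normal quantile at 0.9 is 1.2816.
    """

    z_threshold: float = 1.3
    p_threshold: float = 0.1

    def __post_init__(self) -> None:
        implied = float(sps.norm.isf(self.p_threshold))
        if abs(self.z_threshold - implied) > 0.05:
            raise ValueError(
                f"z_threshold {self.z_threshold} inconsistent with "
                f"p_threshold {self.p_threshold} (implied z {implied:.4f})"
            )


def _edge_matrix(
    connectomes: dict[str, Connectome], labels: list[str]
) -> np.ndarray:
    """Stack upper-triangle edges into a (n_subjects, n_edges) array,
    rows in sorted-subject order."""
    pairs = edge_pairs(len(labels))
    out = np.empty((len(connectomes), len(pairs)))
    for r, sid in enumerate(sorted(connectomes)):
        c = connectomes[sid]
        if c.network_labels != labels:
            raise ValueError(f"network label mismatch for subject {sid}")
        out[r] = [c.matrix[i, j] for i, j in pairs]
    return out


def _check_paired(t1: dict[str, Connectome], t2: dict[str, Connectome]) -> list[str]:
    unpaired = sorted(set(t1) ^ set(t2))
    if unpaired:
        raise ValueError(f"subjects without both sessions: {', '.join(unpaired)}")
    if len(t1) < 3:
        raise ValueError("need at least 3 paired subjects")
    return sorted(t1)


def paired_edge_ttest(
    connectomes_t1: dict[str, Connectome],
    connectomes_t2: dict[str, Connectome],
    config: StatsConfig = StatsConfig(),
) -> pd.DataFrame:
    """Edge-wise paired t-tests of session-2 vs session-1 accordance.

    Returns one row per edge with t_statistic, p_raw, BH-adjusted p_fdr,
    ewd (mean session-2 minus session-1 accordance), the number of
    complete pairs used, and the in_coi flag (p_fdr <= alpha).  Edges
    with an undefined accordance in any subject are dropped from testing
    (logged); the BH family size m stays at ``config.n_edges``.
    """
    _check_paired(connectomes_t1, connectomes_t2)
    labels = next(iter(connectomes_t1.values())).network_labels
    a1 = _edge_matrix(connectomes_t1, labels)
    a2 = _edge_matrix(connectomes_t2, labels)
    pairs = edge_pairs(len(labels))
    m = config.n_edges if config.n_edges is not None else len(pairs)

    d = a2 - a1
    defined = np.all(np.isfinite(d), axis=0)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.warning("dropping %d edge(s) with undefined accordance", n_dropped)

    alternative = (
        "greater" if config.coi_test_sides == "one_sided_increase" else "two-sided"
    )
    t_stat = np.full(len(pairs), np.nan)
    p_raw = np.full(len(pairs), np.nan)
    with warnings.catch_warnings():
        # zero-variance difference columns yield nan t with a RuntimeWarning
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if defined.any():
            res = sps.ttest_rel(
                a2[:, defined], a1[:, defined], alternative=alternative
            )
            t_stat[defined] = res.statistic
            p_raw[defined] = res.pvalue
    # zero-variance difference vectors have no defined t: mark, don't infer
    degenerate = defined & (np.std(d, axis=0, ddof=1) == 0)
    t_stat[degenerate] = np.nan
    p_raw[degenerate] = np.nan

    testable = np.isfinite(p_raw)
    p_fdr = np.full(len(pairs), np.nan)
    if testable.any():
        p_fdr[testable], _ = bh_fdr(p_raw[testable], m=m, alpha=config.alpha)

    table = pd.DataFrame(
        {
            "region_1": [labels[i] for i, j in pairs],
            "region_2": [labels[j] for i, j in pairs],
            "t_statistic": t_stat,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "ewd": np.where(defined, d.mean(axis=0), np.nan),
            "n_pairs": d.shape[0],
        }
    )
    table["in_coi"] = table["p_fdr"] <= config.alpha
    return table


def bh_fdr(
    p_raw: np.ndarray, m: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    ``m`` may exceed ``len(p_raw)``: the unobserved tests are then taken
    to have larger p-values than every observed one (they occupy the top
    ranks and never lower the running minimum), which supports
    recomputing adjusted values from a partial table of the smallest
    p-values.  Returns the adjusted p-values in input order and the
    indices of survivors (p_fdr <= alpha).
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be a 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m = {m} smaller than the number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate((m * p[order] / ranks)[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    p_fdr = np.empty(n)
    p_fdr[order] = adjusted_sorted
    survivors = np.flatnonzero(p_fdr <= alpha)
    return p_fdr, survivors


def define_coi(
    stats_table: pd.DataFrame, config: StatsConfig = StatsConfig()
) -> pd.DataFrame:
    """Edges surviving FDR correction, as a Table-1-style report.

    Returns columns region_1, region_2, p_fdr, p_raw, ewd sorted by
    region labels; an empty COI is allowed (with a warning).
    """
    coi = stats_table.loc[
        stats_table["p_fdr"] <= config.alpha,
        ["region_1", "region_2", "p_fdr", "p_raw", "ewd"],
    ].sort_values(["region_1", "region_2"], kind="stable", ignore_index=True)
    if coi.empty:
        warnings.warn("no edges survive FDR correction: empty COI", stacklevel=2)
    return coi


def pval_to_z(p: float, tail: str = "one_sided") -> float:
    """Standard-normal quantile at 1 - p (strictly decreasing in p).

    p is clamped to [1e-15, 1 - 1e-15] with a warning, so extremely
    small p-values map to large finite z rather than infinity.
    """
    if tail != "one_sided":
        raise ValueError("only one-sided conversion is defined")
    p = float(p)
    if not 0 <= p <= 1 or not np.isfinite(p):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < _P_CLAMP or p > 1 - _P_CLAMP:
        warnings.warn(
            f"p-value {p:.3g} clamped to [{_P_CLAMP:.0e}, 1-{_P_CLAMP:.0e}] "
            "before z-conversion",
            stacklevel=2,
        )
        p = min(max(p, _P_CLAMP), 1 - _P_CLAMP)
    return float(sps.norm.isf(p))


def group_z_difference(z_pm: float, z_pc: float) -> tuple[float, float]:
    """Standardized group contrast and its upper-tail probability.

    z_diff = (z_pm - z_pc) / sqrt(2) is standard normal under the null
    (variance-sum law, cov(Z_PM, Z_PC) = 0 across independent groups);
    p_diff is its one-sided upper-tail probability.
    """
    if not (np.isfinite(z_pm) and np.isfinite(z_pc)):
        raise ValueError("z-scores must be finite")
    z_diff = (z_pm - z_pc) / np.sqrt(2.0)
    return float(z_diff), float(sps.norm.sf(z_diff))


def music_effect_test(
    music_t1: dict[str, Connectome],
    music_t2: dict[str, Connectome],
    control_t1: dict[str, Connectome],
    control_t2: dict[str, Connectome],
    coi: pd.DataFrame | list[tuple[str, str]],
    config: GroupDiffConfig = GroupDiffConfig(),
) -> pd.DataFrame:
    """Intervention-effect test on the COI edges.

    For each COI edge, both groups' within-group paired t-tests
    (session 2 > session 1, one-sided) are converted to z-scores and
    contrasted as z_diff = (z_music - z_control)/sqrt(2); edges with
    z_diff >= z_threshold are flagged significant.  Returns a
    Table-2-style report (region_1, region_2, z_pm, z_pc, z_diff,
    p_diff, significant).
    """
    if isinstance(coi, pd.DataFrame):
        edges = list(zip(coi["region_1"], coi["region_2"]))
    else:
        edges = list(coi)
    if not edges:
        raise ValueError("COI is empty: nothing to test")

    _check_paired(music_t1, music_t2)
    _check_paired(control_t1, control_t2)
    labels = next(iter(music_t1.values())).network_labels

    def edge_index(r1: str, r2: str) -> int:
        try:
            i, j = labels.index(r1), labels.index(r2)
        except ValueError as err:
            raise ValueError(f"unknown region in COI edge ({r1}, {r2})") from err
        return edge_pairs(len(labels)).index((min(i, j), max(i, j)))

    idx = [edge_index(r1, r2) for r1, r2 in edges]
    rows = []
    group_arrays = {
        "music": (_edge_matrix(music_t1, labels), _edge_matrix(music_t2, labels)),
        "control": (
            _edge_matrix(control_t1, labels),
            _edge_matrix(control_t2, labels),
        ),
    }
    z_by_group: dict[str, list[float]] = {}
    for group, (a1, a2) in group_arrays.items():
        res = sps.ttest_rel(a2[:, idx], a1[:, idx], alternative="greater")
        pvals = np.atleast_1d(res.pvalue)
        z_by_group[group] = [pval_to_z(p) for p in pvals]

    for k, (r1, r2) in enumerate(edges):
        z_pm = z_by_group["music"][k]
        z_pc = z_by_group["control"][k]
        z_diff, p_diff = group_z_difference(z_pm, z_pc)
        rows.append(
            {
                "region_1": r1,
                "region_2": r2,
                "z_pm": z_pm,
                "z_pc": z_pc,
                "z_diff": z_diff,
                "p_diff": p_diff,
                "significant": z_diff >= config.z_threshold,
            }
        )
    return pd.DataFrame(rows)
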