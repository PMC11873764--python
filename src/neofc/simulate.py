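"""Synthetic longitudinal two-group cohort generator.

Stands in for the cohort the pipeline was designed around: preterm
infants scanned twice (33 and 40 weeks gestational age), a music
intervention group of 24 and a control group of 19, with 11 ICA network
time courses of 590 volumes at TR = 0.7 s per session.  Each session is
sampled as an AR(1)-filtered multivariate normal whose stationary
cross-network correlation equals a known target matrix, so every
downstream stage (scrubbing, accordance, COI, group contrast) can be
tested against ground truth.

Maturation is modelled as additive correlation increments applied at
session 2 in both groups; the intervention effect as an extra increment
on designated edges in the music group only.  Motion spikes are planted
jointly in the signal (a decaying global pulse that trips the DVARS
criterion at one volume) and the motion parameters (a sustained step
that trips the FD criterion at the same volume).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import MotionTrace, NetworkTimeCourses

__all__ = [
    "SimulationConfig",
    "CohortManifest",
    "DEFAULT_NETWORK_LABELS",
    "default_baseline_coupling",
    "default_maturation_delta",
    "default_group_delta",
    "simulate_session",
    "inject_motion_artifacts",
    "simulate_cohort",
    "subject_seed",
]

logger = logging.getLogger(__name__)

GROUPS = ("music", "control")
SESSIONS = ("t33", "t40")

#: The 11 resting-state networks used as connectome nodes.
DEFAULT_NETWORK_LABELS = [
    "PrefrontalLimbic",
    "Cerebellum",
    "ThalamiBrainstem",
    "Salience",
    "Prefrontal",
    "Visual",
    "BilateralPCC",
    "Auditory",
    "Sensorimotor",
    "RPrecuneus",
    "LPrecuneus",
]

#: Edges whose coupling increases from session 1 to session 2 in both
#: groups (the planted "maturating" circuitry).
DEFAULT_MATURATION_EDGES = [
    ("ThalamiBrainstem", "Salience"),
    ("ThalamiBrainstem", "Sensorimotor"),
    ("ThalamiBrainstem", "Auditory"),
    ("ThalamiBrainstem", "Prefrontal"),
    ("ThalamiBrainstem", "PrefrontalLimbic"),
    ("PrefrontalLimbic", "Visual"),
    ("PrefrontalLimbic", "Cerebellum"),
    ("PrefrontalLimbic", "LPrecuneus"),
    ("Salience", "Visual"),
    ("Salience", "Cerebellum"),
    ("Sensorimotor", "Auditory"),
    ("Sensorimotor", "BilateralPCC"),
]

# Generator conventions (see docs/methods.md): BOLD-like baseline so
# DVARS percentages are meaningful, unit fluctuation scale, and spike
# magnitudes comfortably beyond the censoring thresholds.
SIGNAL_BASELINE = 100.0
SIGNAL_SCALE = 1.0
SIGNAL_SPIKE_MAGNITUDE = 6.0  # signal units = % of baseline
SIGNAL_SPIKE_DECAY = 0.65
MOTION_SPIKE_MM = 1.0
BASELINE_JITTER_MM = 0.02
BASELINE_JITTER_RAD = 4e-4


def default_baseline_coupling(n_networks: int = 11, rho: float = 0.25) -> np.ndarray:
    """Equicorrelation baseline: rho off-diagonal, 1 on the diagonal."""
    m = np.full((n_networks, n_networks), rho)
    np.fill_diagonal(m, 1.0)
    return m


def default_maturation_delta(labels: list[str] | None = None) -> dict:
    """Planted maturation: +0.12 coupling on 12 thalamo-cortical /
    limbic / sensory edges at session 2 in both groups."""
    labels = labels or DEFAULT_NETWORK_LABELS
    out = {}
    for a, b in DEFAULT_MATURATION_EDGES:
        if a in labels and b in labels:
            out[(labels.index(a), labels.index(b))] = 0.12
    return out


def default_group_delta(labels: list[str] | None = None) -> dict:
    """Planted intervention effect: an extra +0.15 on the
    thalamic/brainstem - salience edge in the music group only."""
    labels = labels or DEFAULT_NETWORK_LABELS
    i = labels.index("ThalamiBrainstem") if "ThalamiBrainstem" in labels else 0
    j = labels.index("Salience") if "Salience" in labels else 1
    return {(min(i, j), max(i, j)): 0.15}


def _validate_correlation(matrix: np.ndarray, name: str) -> None:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have a unit diagonal")
    if np.any(np.abs(m) > 1 + 1e-10):
        raise ValueError(f"{name} entries must lie in [-1, 1]")
    eigmin = float(np.linalg.eigvalsh(m).min())
    if eigmin < -1e-8:
        raise ValueError(
            f"{name} is not positive semi-definite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )


@dataclass
class SimulationConfig:
    """The stated world of the synthetic cohort.

    Defaults follow the target study design: 24 music / 19 control
    subjects, 11 networks, 590 volumes at TR 0.7 s, with a plausible
    AR(1) temporal autocorrelation of 0.4 and ~2 % motion-spike volumes
    per session.
    """

    n_music: int = 24
    n_control: int = 19
    n_networks: int = 11
    n_volumes: int = 590
    tr_seconds: float = 0.7
    network_labels: list[str] = field(default_factory=lambda: list(DEFAULT_NETWORK_LABELS))
    baseline_coupling: np.ndarray = None  # type: ignore[assignment]
    maturation_delta: dict = field(default_factory=default_maturation_delta)
    group_delta: dict = field(default_factory=default_group_delta)
    ar1_coefficient: float = 0.4
    spike_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_music < 1 or self.n_control < 1:
            raise ValueError("group sizes must be at least 1")
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if not 0 <= self.spike_rate < 0.5:
            raise ValueError("spike_rate must lie in [0, 0.5)")
        if self.baseline_coupling is None:
            self.baseline_coupling = default_baseline_coupling(self.n_networks)
        self.baseline_coupling = np.asarray(self.baseline_coupling, dtype=float)
        if self.baseline_coupling.shape != (self.n_networks, self.n_networks):
            raise ValueError("baseline_coupling shape must match n_networks")
        if len(self.network_labels) != self.n_networks:
            # regenerate generic labels when n_networks deviates from 11
            if self.network_labels == DEFAULT_NETWORK_LABELS:
                self.network_labels = [f"net{k:02d}" for k in range(self.n_networks)]
            else:
                raise ValueError("network_labels length must match n_networks")
        _validate_correlation(self.baseline_coupling, "baseline_coupling")
        for group in GROUPS:
            for session in SESSIONS:
                _validate_correlation(
                    self.coupling_for(group, session),
                    f"coupling for ({group}, {session})",
                )

    def _apply_delta(self, matrix: np.ndarray, delta: dict) -> np.ndarray:
        out = matrix.copy()
        for (i, j), inc in delta.items():
            if i == j:
                raise ValueError("coupling increments must be off-diagonal")
            out[i, j] += inc
            out[j, i] += inc
        return out

    def coupling_for(self, group: str, session: str) -> np.ndarray:
        """Ground-truth correlation target for one (group, session) cell."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        if session not in SESSIONS:
            raise ValueError(f"unknown session {session!r}")
        m = self.baseline_coupling.copy()
        if session == "t40":
            m = self._apply_delta(m, self.maturation_delta)
            if group == "music":
                m = self._apply_delta(m, self.group_delta)
        return m


@dataclass
class CohortManifest:
    """Index of all generated subject-session artifacts plus the
    ground-truth coupling matrices retained for recovery tests."""

    records: pd.DataFrame
    true_coupling: dict[tuple[str, str], np.ndarray]
    network_labels: list[str]

    def __post_init__(self) -> None:
        per_subject = self.records.groupby("subject_id")
        if not (per_subject["session"].nunique() == 2).all():
            raise ValueError("every subject needs exactly two sessions")
        if not (per_subject["group"].nunique() == 1).all():
            raise ValueError("group labels must be constant within subject")


def subject_seed(master_seed: int, *counters: int) -> int:
    """Counter-based per-subject/session seed derivation (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, counters)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def simulate_session(
    config: SimulationConfig, group: str, session: str, subject_seed: int
) -> NetworkTimeCourses:
    """One session's T x N network time courses.

    The N channels follow x_t = phi * x_{t-1} + e_t with innovations
    e_t ~ N(0, (1 - phi^2) * C), where C is the target correlation
    matrix, so the stationary cross-network correlation equals C
    exactly (the shared phi leaves cross-correlations untouched).
    The latent process is then placed on a BOLD-like scale
    (baseline 100, unit fluctuation sd).
    """
    target = config.coupling_for(group, session)
    _validate_correlation(target, f"coupling for ({group}, {session})")
    t, n = config.n_volumes, config.n_networks
    phi = config.ar1_coefficient
    rng = np.random.default_rng(subject_seed)
    # method="eigh" tolerates the PSD-but-singular case (coupling == 1)
    innovations = rng.multivariate_normal(
        np.zeros(n), target, size=t, method="eigh"
    )
    x = np.empty((t, n))
    x[0] = innovations[0]  # stationary start: full variance
    scale = np.sqrt(1.0 - phi**2)
    if t > 1:
        x[1:], _ = lfilter(
            [1.0], [1.0, -phi], scale * innovations[1:], axis=0, zi=phi * x[:1]
        )
    values = SIGNAL_BASELINE + SIGNAL_SCALE * x
    return NetworkTimeCourses(
        values=values,
        network_labels=config.network_labels,
        session=session,
    )


def inject_motion_artifacts(
    tc: NetworkTimeCourses,
    spike_rate: float,
    spike_magnitude: float = SIGNAL_SPIKE_MAGNITUDE,
    seed: int = 0,
) -> tuple[NetworkTimeCourses, MotionTrace]:
    """Plant motion spikes in the signal and a matching motion trace.

    Spike volumes are drawn Bernoulli(spike_rate).  At each spike the
    motion parameters take a sustained +/-1 mm translation step (FD
    exceeds 0.5 mm at that volume only; baseline jitter keeps FD below
    0.2 mm elsewhere) and the signal receives a global decaying pulse
    (first step ``spike_magnitude`` signal units, decay 0.6) so DVARS
    exceeds 3 % at the spike onset and nowhere else.  With
    spike_rate = 0 the time courses are returned unchanged alongside a
    quiet motion trace.
    """
    if not 0 <= spike_rate < 0.5:
        raise ValueError("spike_rate must lie in [0, 0.5)")
    t = tc.n_volumes
    rng = np.random.default_rng(seed)

    increments = np.zeros((t, 6))
    increments[1:, :3] = rng.uniform(-BASELINE_JITTER_MM, BASELINE_JITTER_MM, (t - 1, 3))
    increments[1:, 3:] = rng.uniform(-BASELINE_JITTER_RAD, BASELINE_JITTER_RAD, (t - 1, 3))
    params = np.cumsum(increments, axis=0)

    spikes = np.flatnonzero(rng.random(t) < spike_rate)
    values = tc.values.copy()
    for s in spikes:
        axis = int(rng.integers(0, 3))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        params[s:, axis] += sign * MOTION_SPIKE_MM  # sustained step
        pulse_sign = 1.0 if rng.random() < 0.5 else -1.0
        k = np.arange(min(8, t - s))
        values[s : s + k.size] += (
            pulse_sign * spike_magnitude * SIGNAL_SPIKE_DECAY**k
        )[:, None]
    out = tc.with_values(values) if spikes.size else tc.with_values(tc.values.copy())
    return out, MotionTrace(params=params)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def simulate_cohort(config: SimulationConfig, output_dir: str | Path) -> CohortManifest:
    """Generate and write the full two-group, two-session cohort.

    Writes one time-course TSV and one SPM-style motion file per
    subject-session, the manifest TSV, and the ground-truth coupling
    matrices under ``truth/``.  Deterministic given (config, seed):
    per-subject seeds are derived from the master seed by counters, so
    outputs are byte-identical across reruns and distinct across
    subjects.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {out}: {err}") from err

    subjects = [("music", f"M{k + 1:02d}", k) for k in range(config.n_music)] + [
        ("control", f"C{k + 1:02d}", config.n_music + k)
        for k in range(config.n_control)
    ]
    rows = []
    for group, sid, s_idx in subjects:
        for t_idx, session in enumerate(SESSIONS):
            tc_seed = subject_seed(config.seed, s_idx, t_idx, 0)
            motion_seed = subject_seed(config.seed, s_idx, t_idx, 1)
            clean = simulate_session(config, group, session, tc_seed)
            noisy, motion = inject_motion_artifacts(
                clean, config.spike_rate, seed=motion_seed
            )
            tc_name = f"sub-{sid}_ses-{session}_timecourses.tsv"
            rp_name = f"sub-{sid}_ses-{session}_rp.txt"
            try:
                _write_tsv(
                    pd.DataFrame(noisy.values, columns=config.network_labels),
                    out / tc_name,
                )
                np.savetxt(out / rp_name, motion.params, fmt="%.17g")
            except OSError as err:
                raise OSError(f"failed writing {out / tc_name}: {err}") from err
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "session": session,
                    "timecourse_path": tc_name,
                    "motion_path": rp_name,
                }
            )
    records = pd.DataFrame(rows)
    _write_tsv(records, out / "manifest.tsv")

    truth = {}
    for group in GROUPS:
        for session in SESSIONS:
            m = config.coupling_for(group, session)
            truth[(group, session)] = m
            _write_tsv(
                pd.DataFrame(m, columns=config.network_labels),
                out / "truth" / f"coupling_{group}_{session}.tsv",
            )
    logger.info(
        "wrote synthetic cohort: %d subjects, %d files, under %s",
        len(subjects),
        2 * len(subjects) * 2 + 5,
        out,
    )
    return CohortManifest(
        records=records,
        true_coupling=truth,
        network_labels=list(config.network_labels),
    )
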