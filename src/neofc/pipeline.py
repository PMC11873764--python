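"""End-to-end orchestration of the longitudinal connectome analysis.

Stage order: (optional) cohort simulation -> motion scrubbing ->
accordance connectome estimation -> COI definition (edge-wise paired
tests + FDR) -> intervention-effect test on the COI.  Every stage is
disk-mediated (reads the previous stage's TSV artifacts, writes its
own), so running stages individually produces byte-identical results to
the end-to-end run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accordance import AccordanceParams, build_connectome
from .containers import Connectome
from .io import (
    read_manifest,
    read_mask,
    read_motion,
    read_timecourses,
    write_connectome,
    write_mask,
)
from .qc import QCParams, apply_scrub, check_inclusion, run_qc
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    GroupDiffConfig,
    StatsConfig,
    define_coi,
    music_effect_test,
    paired_edge_ttest,
)

__all__ = [
    "PipelineConfig",
    "RunRecord",
    "stage_simulate",
    "stage_scrub",
    "stage_connectome",
    "stage_coi",
    "stage_group_diff",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_COI_COLUMNS = {
    "region_1": "Region1",
    "region_2": "Region2",
    "p_fdr": "p_value_FDR",
    "p_raw": "p_value_original",
    "ewd": "EWD",
}
_GDIFF_COLUMNS = {
    "region_1": "Region1",
    "region_2": "Region2",
    "z_pm": "Z_PM",
    "z_pc": "Z_PC",
    "z_diff": "Z_diff",
    "p_diff": "p",
}


@dataclass
class PipelineConfig:
    """All run settings in one validated object.

    Either ``manifest`` points at an existing cohort, or ``simulation``
    describes one to generate under ``output_root/synthetic``.
    """

    output_root: str | Path = "neofc_out"
    manifest: str | Path | None = None
    simulation: SimulationConfig | None = None
    qc: QCParams = field(default_factory=QCParams)
    accordance: AccordanceParams = field(default_factory=AccordanceParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    group_diff: GroupDiffConfig = field(default_factory=GroupDiffConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.manifest is None and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.simulation is not None:
            self.simulation.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("output_root", "manifest", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "simulation" in raw:
            kwargs["simulation"] = _sim_config_from_dict(raw["simulation"] or {})
        for key, klass in (
            ("qc", QCParams),
            ("accordance", AccordanceParams),
            ("stats", StatsConfig),
            ("group_diff", GroupDiffConfig),
        ):
            if key in raw:
                kwargs[key] = klass(**(raw[key] or {}))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            "output_root": str(self.output_root),
            "manifest": None if self.manifest is None else str(self.manifest),
            "seed": self.seed,
            "log_level": self.log_level,
            "qc": asdict(self.qc),
            "accordance": asdict(self.accordance),
            "stats": asdict(self.stats),
            "group_diff": asdict(self.group_diff),
        }
        if self.simulation is not None:
            sim = asdict(self.simulation)
            sim["baseline_coupling"] = np.asarray(
                sim["baseline_coupling"]
            ).tolist()
            sim["maturation_delta"] = sorted(
                [list(k) + [v] for k, v in sim["maturation_delta"].items()]
            )
            sim["group_delta"] = sorted(
                [list(k) + [v] for k, v in sim["group_delta"].items()]
            )
            out["simulation"] = sim
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config_from_dict(raw: dict) -> SimulationConfig:
    raw = dict(raw)
    labels = raw.get("network_labels")
    for key in ("maturation_delta", "group_delta"):
        if key in raw and isinstance(raw[key], list):
            delta = {}
            for r1, r2, inc in raw[key]:
                if isinstance(r1, str):
                    if labels is None:
                        raise ValueError(
                            f"{key} uses labels but network_labels is unset"
                        )
                    r1, r2 = labels.index(r1), labels.index(r2)
                delta[(min(r1, r2), max(r1, r2))] = float(inc)
            raw[key] = delta
    if "baseline_rho" in raw:
        from .simulate import default_baseline_coupling

        raw["baseline_coupling"] = default_baseline_coupling(
            raw.get("n_networks", 11), raw.pop("baseline_rho")
        )
    return SimulationConfig(**raw)


@dataclass
class RunRecord:
    """Provenance of one pipeline run: version, config hash, timestamps
    and per-stage counts (every exclusion traceable to a rule)."""

    version: str
    config_hash: str
    seed: int
    started: str
    finished: str = ""
    counts: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_report(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def stage_simulate(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Generate the synthetic cohort; returns the manifest path."""
    simulate_cohort(config, out_dir)
    return Path(out_dir) / "manifest.tsv"


def stage_scrub(
    manifest_path: str | Path, params: QCParams, out_dir: str | Path
) -> pd.DataFrame:
    """Motion QC for every session: write per-session keep masks and the
    QC report (subject, session, retained_fraction, included)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    rows = []
    for rec in manifest.itertuples():
        tc = read_timecourses(rec.timecourse_path, rec.subject_id, rec.session)
        motion = read_motion(rec.motion_path)
        qc = run_qc(tc, motion, params)
        write_mask(qc.keep_mask, out / f"sub-{rec.subject_id}_ses-{rec.session}_mask.txt")
        included = check_inclusion(qc.retained_fraction, params)
        if not included:
            logger.info(
                "excluding %s %s: retained fraction %.3f < %.2f",
                rec.subject_id,
                rec.session,
                qc.retained_fraction,
                params.min_retained_fraction,
            )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "session": rec.session,
                "retained_fraction": qc.retained_fraction,
                "included": included,
            }
        )
    report = pd.DataFrame(rows)
    _write_report(report, out / "qc_report.tsv")
    return report


def _included_records(manifest: pd.DataFrame, qc_report: pd.DataFrame) -> pd.DataFrame:
    merged = manifest.merge(
        qc_report[["subject_id", "session", "included"]],
        on=["subject_id", "session"],
        how="left",
    )
    missing = merged["included"].isna()
    if missing.any():
        bad = merged.loc[missing, "subject_id"].tolist()
        raise ValueError(f"sessions missing from QC report: {bad}")
    if merged["included"].dtype == object:
        merged["included"] = merged["included"].astype(str) == "True"
    return merged[merged["included"].astype(bool)]


def stage_connectome(
    manifest_path: str | Path,
    qc_dir: str | Path,
    params: AccordanceParams,
    out_dir: str | Path,
) -> dict[tuple[str, str], Connectome]:
    """Accordance connectomes for all QC-included sessions.

    Reads the scrub masks written by the QC stage, drops censored
    volumes, estimates the accordance matrix and writes one labeled
    square TSV per session plus a combined long-format edge table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc_dir = Path(qc_dir)
    manifest = read_manifest(manifest_path)
    qc_report = pd.read_csv(qc_dir / "qc_report.tsv", sep="\t")
    qc_report["subject_id"] = qc_report["subject_id"].astype(str)
    connectomes: dict[tuple[str, str], Connectome] = {}
    edge_frames = []
    for rec in _included_records(manifest, qc_report).itertuples():
        tc = read_timecourses(rec.timecourse_path, rec.subject_id, rec.session)
        mask = read_mask(qc_dir / f"sub-{rec.subject_id}_ses-{rec.session}_mask.txt")
        scrubbed = apply_scrub(tc, mask)
        conn = build_connectome(scrubbed, params)
        conn.subject_id = rec.subject_id
        connectomes[(rec.subject_id, rec.session)] = conn
        write_connectome(
            conn, out / f"sub-{rec.subject_id}_ses-{rec.session}_connectome.tsv"
        )
        edge_frames.append(conn.edge_table())
    if edge_frames:
        _write_report(pd.concat(edge_frames, ignore_index=True), out / "edges.tsv")
    return connectomes


def _paired_connectomes(
    manifest: pd.DataFrame,
    qc_report: pd.DataFrame,
    conn_dir: Path,
    groups: tuple[str, ...] | None = None,
) -> tuple[dict[str, Connectome], dict[str, Connectome]]:
    """Connectomes of subjects with *both* sessions QC-included,
    optionally restricted to the given groups; keyed by subject."""
    from .io import read_connectome

    included = _included_records(manifest, qc_report)
    if groups is not None:
        included = included[included["group"].isin(groups)]
    sessions_per_subject = included.groupby("subject_id")["session"].nunique()
    paired = set(sessions_per_subject[sessions_per_subject == 2].index)
    dropped = sorted(set(included["subject_id"]) - paired)
    if dropped:
        logger.info("excluding unpaired subject(s): %s", ", ".join(dropped))
    t1: dict[str, Connectome] = {}
    t2: dict[str, Connectome] = {}
    sessions = sorted(included["session"].unique())
    if len(sessions) != 2:
        raise ValueError(f"expected exactly 2 session labels, got {sessions}")
    for rec in included.itertuples():
        if rec.subject_id not in paired:
            continue
        conn = read_connectome(
            conn_dir / f"sub-{rec.subject_id}_ses-{rec.session}_connectome.tsv",
            rec.subject_id,
            rec.session,
        )
        (t1 if rec.session == sessions[0] else t2)[rec.subject_id] = conn
    return t1, t2


def stage_coi(
    manifest_path: str | Path,
    qc_dir: str | Path,
    conn_dir: str | Path,
    config: StatsConfig,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maturating-COI definition over the pooled paired cohort.

    Writes the full edge statistics table and the Table-1-style
    ``coi_table.tsv``; returns (edge_stats, coi_table) with internal
    column names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    qc_report = pd.read_csv(Path(qc_dir) / "qc_report.tsv", sep="\t")
    qc_report["subject_id"] = qc_report["subject_id"].astype(str)
    t1, t2 = _paired_connectomes(manifest, qc_report, Path(conn_dir))
    edge_stats = paired_edge_ttest(t1, t2, config)
    coi = define_coi(edge_stats, config)
    _write_report(edge_stats, out / "edge_stats.tsv")
    _write_report(coi.rename(columns=_COI_COLUMNS), out / "coi_table.tsv")
    return edge_stats, coi


def stage_group_diff(
    manifest_path: str | Path,
    qc_dir: str | Path,
    conn_dir: str | Path,
    coi_table_path: str | Path,
    config: GroupDiffConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Intervention-effect test on the COI edges.

    Writes the Table-2-style ``group_diff_table.tsv`` and returns the
    result with internal column names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    qc_report = pd.read_csv(Path(qc_dir) / "qc_report.tsv", sep="\t")
    qc_report["subject_id"] = qc_report["subject_id"].astype(str)
    coi = pd.read_csv(coi_table_path, sep="\t").rename(
        columns={v: k for k, v in _COI_COLUMNS.items()}
    )
    conn_dir = Path(conn_dir)
    m1, m2 = _paired_connectomes(manifest, qc_report, conn_dir, groups=("music",))
    c1, c2 = _paired_connectomes(manifest, qc_report, conn_dir, groups=("control",))
    result = music_effect_test(m1, m2, c1, c2, coi, config)
    out_table = result.rename(columns=_GDIFF_COLUMNS).drop(columns=["significant"])
    _write_report(out_table, out / "group_diff_table.tsv")
    return result


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """All stages in order under ``config.output_root``.

    Deterministic given (config, seed); equivalent to invoking the
    stages one by one on the same directories.
    """
    logging.basicConfig(level=config.log_level)
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    record = RunRecord(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        started=datetime.now(timezone.utc).isoformat(),
    )

    if config.manifest is not None:
        manifest_path = Path(config.manifest)
    else:
        manifest_path = stage_simulate(config.simulation, root / "synthetic")
    manifest = read_manifest(manifest_path)
    record.counts["sessions_total"] = len(manifest)

    qc_dir = root / "qc"
    qc_report = stage_scrub(manifest_path, config.qc, qc_dir)
    record.counts["sessions_included"] = int(qc_report["included"].sum())
    record.counts["sessions_excluded_motion"] = int((~qc_report["included"]).sum())

    conn_dir = root / "connectomes"
    stage_connectome(manifest_path, qc_dir, config.accordance, conn_dir)

    stats_dir = root / "stats"
    edge_stats, coi = stage_coi(
        manifest_path, qc_dir, conn_dir, config.stats, stats_dir
    )
    record.counts["edges_tested"] = int(edge_stats["p_raw"].notna().sum())
    record.counts["edges_dropped"] = int(edge_stats["p_raw"].isna().sum())
    record.counts["coi_edges"] = len(coi)

    if not coi.empty:
        gdiff = stage_group_diff(
            manifest_path,
            qc_dir,
            conn_dir,
            stats_dir / "coi_table.tsv",
            config.group_diff,
            stats_dir,
        )
        record.counts["significant_group_edges"] = int(gdiff["significant"].sum())
    else:
        logger.warning("empty COI: skipping the intervention-effect stage")
        record.counts["significant_group_edges"] = 0

    record.finished = datetime.now(timezone.utc).isoformat()
    record.write(root / "run_record.json")
    return record
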