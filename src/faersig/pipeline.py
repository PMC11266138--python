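"""End-to-end orchestration: ingest → dedup → cohort → screen → subgroups → SOC.

The pipeline is driven by a single declarative configuration (YAML or
constructed in code) and writes every stage's table as TSV together with
a per-stage record-count log and a machine-readable run manifest, so the
flow of reports through the filters is reproducible as text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from .cohort import CohortSpec, concomitant_summary, descriptive_summary, select_cohort
from .dedup import clean_snapshot
from .signals import DisproportionalityScreen, SignalCriteria
from .soc import PtSocMap, load_pt_soc_map, soc_summary
from .subgroup import subgroup_signals
from .synth import default_config, generate_snapshot

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    Exactly one input source applies: FAERS-format files on disk
    (``demo_files``/``drug_files``/``reac_files`` plus optional
    ``deleted_files``) or the synthetic generator (``synth_n_cases`` > 0).
    """

    drug_name_patterns: list[str] = field(default_factory=lambda: ["OSELTAMIVIR", "TAMIFLU"])
    drug_label: str = "target"
    age_min_years: float = 0.0
    age_max_years: float = 18.0
    ps_exclusive: bool = True
    background_scope: str = "stratum"
    ic_shrinkage: bool = False
    zero_cell_correction: float = 0.0
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    seed: int = 0
    # file inputs
    demo_files: list[str] = field(default_factory=list)
    drug_files: list[str] = field(default_factory=list)
    reac_files: list[str] = field(default_factory=list)
    outc_files: list[str] = field(default_factory=list)
    deleted_files: list[str] = field(default_factory=list)
    pt_soc_map_file: str | None = None
    # synthetic input
    synth_n_cases: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        crit = SignalCriteria(**raw.pop("criteria", {}))
        return cls(criteria=crit, **raw)


def _log_stage(log: list[dict], stage: str, rows_in: int, rows_out: int, reason: str) -> None:
    log.append({"stage": stage, "rows_in": rows_in, "rows_out": rows_out, "reason": reason})
    logger.info("%s: %d -> %d (%s)", stage, rows_in, rows_out, reason)


def _ingest(cfg: RunConfig):
    if cfg.synth_n_cases > 0:
        snapshot, _ = generate_snapshot(default_config(cfg.synth_n_cases, cfg.seed))
        pt_soc = default_config(cfg.synth_n_cases, cfg.seed).pt_soc_map()
        return snapshot, pt_soc
    if not cfg.demo_files:
        raise ValueError("config provides neither input files nor a synthetic size")
    n = len(cfg.demo_files)
    if not (len(cfg.drug_files) == len(cfg.reac_files) == n):
        raise ValueError("demo/drug/reac file lists must have equal length")
    quarters = []
    for i in range(n):
        q = {
            "demo": fio.read_table(cfg.demo_files[i], "demo"),
            "drug": fio.read_table(cfg.drug_files[i], "drug"),
            "reac": fio.read_table(cfg.reac_files[i], "reac"),
            "source": str(cfg.demo_files[i]),
        }
        if cfg.outc_files:
            q["outc"] = fio.read_table(cfg.outc_files[i], "outc")
        quarters.append(q)
    deleted = fio.read_deleted_cases(cfg.deleted_files)
    snapshot = fio.assemble_snapshot(quarters, deleted)
    pt_soc = load_pt_soc_map(cfg.pt_soc_map_file) if cfg.pt_soc_map_file else PtSocMap({})
    return snapshot, pt_soc


def render_forest_data(signal_frame: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (pt, soc, a, ror, l95, u95) rows, by SOC then descending a."""
    cols = ["pt", "soc", "a", "ror", "ror_l95", "ror_u95"]
    if "soc" not in signal_frame.columns:
        signal_frame = signal_frame.assign(soc="UNMAPPED")
    out = signal_frame[cols].copy()
    return out.sort_values(["soc", "a", "pt"], ascending=[True, False, True],
                           kind="mergesort").reset_index(drop=True)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage in order and write all outputs under ``outdir``.

    A stage failure aborts with the stage name in the exception message.
    Outputs: stage_log.tsv, demographics.tsv, concomitants.tsv,
    signals.tsv, signals_F.tsv, signals_M.tsv, discordance.tsv,
    soc_summary.tsv, forest.tsv, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    stage = "ingest"
    try:
        snapshot, pt_soc = _ingest(config)
        _log_stage(log, "ingest", 0, snapshot.n_reports, "reports loaded")

        stage = "dedup"
        n_in = snapshot.n_reports
        snapshot, audit = clean_snapshot(snapshot)
        _log_stage(log, "deletions", n_in, n_in - audit.n_deleted_reports, "deleted cases removed")
        _log_stage(log, "dedup", n_in - audit.n_deleted_reports, audit.n_reports_out,
                   "one version per case")

        stage = "cohort"
        spec = CohortSpec(
            drug_name_patterns=config.drug_name_patterns,
            age_min_years=config.age_min_years,
            age_max_years=config.age_max_years,
            ps_exclusive=config.ps_exclusive,
            background_scope=config.background_scope,
        )
        cohort = select_cohort(snapshot, spec)
        _log_stage(log, "cohort", audit.n_reports_out, cohort.n_members,
                   "pediatric primary-suspect reports")
        descriptive_summary(cohort, snapshot).to_csv(outdir / "demographics.tsv", sep="\t", index=False)
        concomitant_summary(cohort).to_csv(outdir / "concomitants.tsv", sep="\t", index=False)

        stage = "signals"
        screen = DisproportionalityScreen.from_cohort(
            cohort,
            drug=config.drug_label,
            criteria=config.criteria,
            ic_shrinkage=config.ic_shrinkage,
            zero_cell_correction=config.zero_cell_correction,
        )
        results = screen.fit()
        sig_frame = results.with_soc(pt_soc)
        sig_frame.to_csv(outdir / "signals.tsv", sep="\t", index=False)
        _log_stage(log, "signals", cohort.n_member_pairs, len(sig_frame), "PTs screened")

        stage = "subgroup"
        strata, discordance = subgroup_signals(
            cohort,
            criteria=config.criteria,
            ic_shrinkage=config.ic_shrinkage,
            zero_cell_correction=config.zero_cell_correction,
        )
        for sex, res in strata.items():
            res.frame.to_csv(outdir / f"signals_{sex}.tsv", sep="\t", index=False)
        discordance.to_csv(outdir / "discordance.tsv", sep="\t", index=False)
        _log_stage(log, "subgroup", len(sig_frame),
                   sum(len(r.frame) for r in strata.values()), "per-sex screens")

        stage = "soc"
        soc_tab = soc_summary(sig_frame, pt_soc)
        soc_tab.to_csv(outdir / "soc_summary.tsv", sep="\t", index=False)
        _log_stage(log, "soc", len(sig_frame), len(soc_tab), "SOC aggregation")

        render_forest_data(sig_frame).to_csv(outdir / "forest.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - context then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    pd.DataFrame(log).to_csv(outdir / "stage_log.tsv", sep="\t", index=False)
    manifest = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "criteria"},
            "criteria": asdict(config.criteria),
        },
        "provenance": snapshot.provenance,
        "n_reports": snapshot.n_reports,
        "n_members": cohort.n_members,
        "n_member_pairs": cohort.n_member_pairs,
        "n_signals": int(sig_frame["signal"].sum()),
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
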