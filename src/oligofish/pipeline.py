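"""End-to-end orchestration: cells + patients in, report out.

Runs the full analysis a FISH polysomy study performs: per-sample
deletion/polysomy/CDKN2A calls, combined codeletion status with
polysomy subgroup and ploidy extrapolation, signature profiles with
cohort summaries, an emulated 100-nucleus manual rater with
manual-vs-automated concordance, contingency associations of polysomy
with clinico-histological covariates, and Kaplan-Meier / log-rank / Cox
survival analysis.  Deterministic given inputs and the seed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, concordance, io_formats, sample_caller, signature_profile
from .io_formats import CellSignal, PatientRecord, ProbeAssay

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "group_cells", "call_samples"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage name and sample id."""


@dataclass(frozen=True)
class PipelineConfig:
    cells_path: str
    patients_path: str | None = None
    out_dir: str = "."
    deletion_cutoff: float = sample_caller.DELETION_CUTOFF
    polysomy_cutoff: float = sample_caller.POLYSOMY_CUTOFF
    cdkn2a_hemi_cutoff: float = sample_caller.CDKN2A_HEMI_CUTOFF
    cdkn2a_homo_cutoff: float = sample_caller.CDKN2A_HOMO_CUTOFF
    strict_deletion_boundary: bool = True
    yates: bool = False
    manual_n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deletion_cutoff", "polysomy_cutoff", "cdkn2a_hemi_cutoff",
                     "cdkn2a_homo_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def group_cells(cells: list[CellSignal]) -> dict[tuple[str, ProbeAssay], list[CellSignal]]:
    grouped: dict[tuple[str, ProbeAssay], list[CellSignal]] = defaultdict(list)
    for c in cells:
        grouped[(c.sample_id, c.assay)].append(c)
    return dict(grouped)


def call_samples(
    cells: list[CellSignal], config: PipelineConfig | None = None
) -> dict[str, dict]:
    """Per-sample calls for every assay present, plus combined status."""
    config = config or PipelineConfig(cells_path="")
    grouped = group_cells(cells)
    sample_ids = sorted({sid for sid, _ in grouped})
    out: dict[str, dict] = {}
    for sid in sample_ids:
        entry: dict = {}
        try:
            for assay in (ProbeAssay.CHR1, ProbeAssay.CHR19):
                if (sid, assay) in grouped:
                    entry[assay.name] = sample_caller.call_assay(
                        grouped[(sid, assay)],
                        config.deletion_cutoff,
                        config.polysomy_cutoff,
                        strict_deletion_boundary=config.strict_deletion_boundary,
                    )
            if (sid, ProbeAssay.CDKN2A) in grouped:
                entry["CDKN2A"] = sample_caller.call_cdkn2a(
                    grouped[(sid, ProbeAssay.CDKN2A)],
                    config.cdkn2a_hemi_cutoff,
                    config.cdkn2a_homo_cutoff,
                )
            if "CHR1" in entry and "CHR19" in entry:
                combined = sample_caller.combine_assays(entry["CHR1"], entry["CHR19"])
                ploidy = sample_caller.infer_ploidy(
                    grouped[(sid, ProbeAssay.CHR1)],
                    grouped[(sid, ProbeAssay.CHR19)],
                    config.polysomy_cutoff,
                )
                entry["combined"] = sample_caller.CombinedStatus(
                    sid, combined.codeleted, combined.polysomy_subgroup, ploidy
                )
        except Exception as exc:
            raise PipelineError(f"calling stage failed for sample {sid}: {exc}") from exc
        out[sid] = entry
    return out


def _concordance_block(
    grouped: dict[tuple[str, ProbeAssay], list[CellSignal]],
    calls: dict[str, dict],
    config: PipelineConfig,
) -> dict:
    rng = np.random.default_rng(config.seed)
    block: dict = {}
    for assay in (ProbeAssay.CHR1, ProbeAssay.CHR19):
        auto: dict[str, bool] = {}
        manual: dict[str, bool] = {}
        for sid, entry in calls.items():
            if assay.name not in entry or (sid, assay) not in grouped:
                continue
            auto[sid] = entry[assay.name].polysomy_called
            cells = grouped[(sid, assay)]
            n_eligible = sum(1 for c in cells if c.green_count >= 1)
            sub = concordance.manual_subsample(
                cells, min(config.manual_n, n_eligible), rng
            )
            manual[sid] = sample_caller.call_assay(
                sub, config.deletion_cutoff, config.polysomy_cutoff,
                strict_deletion_boundary=config.strict_deletion_boundary,
            ).polysomy_called
        if not auto:
            continue
        table = concordance.agreement_table(manual, auto)
        block[assay.name] = {
            "table": table,
            "kappa": concordance.cohen_kappa(table),
            "percent_agreement": concordance.percent_agreement(table),
        }
    return block


_ASSOCIATION_FIELDS = (
    ("grade", lambda r: r.grade == "O3"),
    ("mitoses_gt5", lambda r: None if r.mitoses_class is None else r.mitoses_class == "gt5"),
    ("mvp_glomeruloid", lambda r: None if r.mvp is None else r.mvp == "glomeruloid"),
    ("mib1_gt17", lambda r: None if r.mib1_class is None else r.mib1_class == "gt17"),
    ("necrosis", lambda r: r.necrosis),
    ("calcification", lambda r: r.calcification),
    ("recurrent", lambda r: r.recurrent_flag),
)


def _association_block(
    records: list[PatientRecord], polysomy: dict[str, bool], config: PipelineConfig
) -> dict:
    block = {}
    for name, getter in _ASSOCIATION_FIELDS:
        table = np.zeros((2, 2), dtype=int)
        for r in records:
            if r.patient_id not in polysomy:
                continue
            v = getter(r)
            if v is None:
                continue
            table[int(v), int(polysomy[r.patient_id])] += 1
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        block[name] = cohort_stats.chisq_test(table.tolist(), yates=config.yates)
    return block


_COX_COVARIATES = (
    "grade_O3", "polysomy", "mitoses_gt5", "mvp_glomeruloid",
    "mib1_gt17", "necrosis", "calcification", "recurrent",
)


def _survival_block(records: list[PatientRecord], polysomy: dict[str, bool]) -> dict:
    df = cohort_stats.records_to_frame(
        records, extra={"polysomy": {k: float(v) for k, v in polysomy.items()}}
    )
    block: dict = {}
    for endpoint, (dur, ev) in {
        "efs": ("efs_months", "efs_event"),
        "os": ("os_months", "os_event"),
    }.items():
        sub = df.dropna(subset=["polysomy"])
        table = cohort_stats.survival_table(sub, "polysomy", duration_col=dur, event_col=ev)
        logrank_p = cohort_stats.logrank_test(
            sub["polysomy"].to_numpy(), sub[dur].to_numpy(), sub[ev].to_numpy(dtype=bool)
        )
        covs = [c for c in _COX_COVARIATES if c in df.columns and df[c].dropna().nunique() > 1]
        uni = cohort_stats.cox_fit(df, covs, duration_col=dur, event_col=ev,
                                   scope=cohort_stats.ModelScope.UNIVARIATE)
        try:
            multi = cohort_stats.cox_fit(df, covs, duration_col=dur, event_col=ev,
                                         scope=cohort_stats.ModelScope.MULTIVARIATE)
        except ValueError:
            multi = []
        block[endpoint] = {
            "by_polysomy": {
                str(k): v for k, v in table.to_dict(orient="index").items()
            },
            "logrank_p": logrank_p,
            "cox_univariate": uni,
            "cox_multivariate": multi,
        }
    return block


def _write_signature_tsv(profiles_by_assay: dict, polysomy: dict[str, bool], out_dir: Path) -> None:
    for assay_name, profiles in profiles_by_assay.items():
        rows = []
        for p in profiles:
            group = "polysomic" if polysomy.get(p.sample_id) else "non_polysomic"
            for sig, frac in p.binned_signature_fractions().items():
                rows.append((sig, group, p.sample_id, frac))
        df = pd.DataFrame(rows, columns=["signature", "group", "sample_id", "fraction"])
        summary = (
            df.groupby(["signature", "group"])["fraction"].mean().reset_index()
            .rename(columns={"fraction": "mean_fraction"})
        )
        summary.to_csv(out_dir / f"signatures_{assay_name}.tsv", sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write ``report.json`` plus TSV tables.

    Returns the report document.  Raises :class:`PipelineError` with the
    failing stage and sample on any stage error.
    """
    cells_path = Path(config.cells_path)
    if not cells_path.exists():
        raise PipelineError(f"input cells table not found: {cells_path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cells = io_formats.read_cell_table(cells_path)
    grouped = group_cells(cells)
    calls = call_samples(cells, config)

    polysomy = {
        sid: entry["combined"].polysomy_subgroup is not sample_caller.PolysomySubgroup.NONE
        for sid, entry in calls.items()
        if "combined" in entry
    }

    profiles_by_assay: dict[str, list] = {}
    groups_by_assay: dict[str, dict] = {}
    for assay in (ProbeAssay.CHR1, ProbeAssay.CHR19):
        profiles = []
        for sid in sorted(polysomy):
            if (sid, assay) in grouped:
                profiles.append(signature_profile.profile_sample(grouped[(sid, assay)]))
        if not profiles:
            continue
        profiles_by_assay[assay.name] = profiles
        groups = {"polysomic": [], "non_polysomic": []}
        for p in profiles:
            groups["polysomic" if polysomy[p.sample_id] else "non_polysomic"].append(p)
        if all(groups.values()):
            groups_by_assay[assay.name] = signature_profile.cohort_band_summary(groups)

    concordance_block = _concordance_block(grouped, calls, config)

    stats: dict = {"cohort_summary": groups_by_assay, "concordance": concordance_block}

    if config.patients_path:
        records = io_formats.read_patient_table(config.patients_path)
        stats["associations"] = _association_block(records, polysomy, config)
        stats["survival"] = _survival_block(records, polysomy)

    _write_signature_tsv(profiles_by_assay, polysomy, out_dir)
    report = io_formats.write_report(calls, stats, out_dir / "report.json")
    return report
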