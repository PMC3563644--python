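"""Signature validation against an independent cohort, and pipeline orchestration.

A discovery signature (genes plus directions from the meta-analysis) is
scored against a validation cohort that never contributed to the
combination: a signature gene is *verified* when its validation-side fold
change points the same way and its validation BH-adjusted p falls below the
configured cutoff. Genes not measured on the validation platform are
excluded from the denominator and counted separately. The array-wide rate —
the fraction of ALL validation-platform genes meeting the same criterion —
is the background against which signature enrichment is judged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_core import (
    ErgMetaError,
    LOG,
    GroupAssignment,
    ProbeGeneMap,
    RunConfig,
    StudyMatrix,
    read_probe_gene_map,
    read_study_matrix,
    stage,
    write_group_assignment,
    write_results_table,
)
from .harmonize import build_gene_universe, collapse_probes
from .metastats import (
    PerStudyStats,
    Signature,
    add_permutation_p,
    bh_adjust,
    combine_studies,
    filter_signature,
    two_group_stats,
    volcano_table,
)
from .subgroups import assign_by_marker_tertiles, assignment_from_annotation

REPORT_COLUMNS = [
    "fc_threshold",
    "n_signature",
    "n_excluded",
    "n_verified",
    "percent_verified",
    "array_wide_rate",
]


@dataclass
class ConcordanceReport:
    """Verification counts and background rates, one row per FC threshold."""

    table: pd.DataFrame  # columns REPORT_COLUMNS

    def row(self, fc_threshold: float) -> pd.Series:
        hit = self.table[self.table["fc_threshold"] == fc_threshold]
        if hit.empty:
            raise ErgMetaError(f"no report row for fc_threshold={fc_threshold}")
        return hit.iloc[0]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _with_adjusted_p(validation_stats: PerStudyStats) -> pd.DataFrame:
    """Validation table with a BH-adjusted p across all measured genes."""
    tab = validation_stats.table.copy()
    if "p_adj" not in tab.columns:
        tab["p_adj"] = bh_adjust(tab["p_value"].to_numpy())
    return tab


def validate_signature(
    signature: Signature,
    validation_stats: PerStudyStats,
    config: RunConfig,
    validation_table: pd.DataFrame | None = None,
) -> dict:
    """Score one signature against the validation cohort.

    Returns a dict with n_signature (genes entering validation after
    platform exclusions), n_excluded (unmeasured on the validation
    platform), n_verified (direction concordant and validation adjusted
    p < ``config.validation_p_threshold``) and percent_verified (rounded to
    the nearest integer).
    """
    tab = _with_adjusted_p(validation_stats) if validation_table is None else validation_table
    genes = signature.genes
    measured = [g for g in genes if g in tab.index]
    n_excluded = len(genes) - len(measured)
    if not measured:
        raise ErgMetaError("signature empty after validation-platform exclusions")
    sub = tab.loc[measured]
    dirs = signature.table.loc[measured, "direction"].to_numpy()
    concordant = np.sign(sub["log2fc"].to_numpy()) == dirs
    significant = sub["p_adj"].to_numpy() < config.validation_p_threshold
    n_verified = int(np.sum(concordant & significant))
    return {
        "n_signature": len(measured),
        "n_excluded": n_excluded,
        "n_verified": n_verified,
        "percent_verified": int(round(100.0 * n_verified / len(measured))),
    }


def array_wide_rate(
    validation_stats: PerStudyStats,
    config: RunConfig,
    validation_table: pd.DataFrame | None = None,
) -> dict[float, float]:
    """Fraction of ALL measured validation genes passing each FC/adjusted-p
    criterion — the background rate for judging signature enrichment."""
    tab = _with_adjusted_p(validation_stats) if validation_table is None else validation_table
    if tab.empty:
        raise ErgMetaError("validation statistics are empty")
    linear = 2.0 ** np.abs(tab["log2fc"].to_numpy())
    sig = tab["p_adj"].to_numpy() < config.validation_p_threshold
    return {
        thr: float(np.mean((linear > thr) & sig)) for thr in config.fc_thresholds
    }


def concordance_report(
    meta: pd.DataFrame,
    validation_stats: PerStudyStats,
    config: RunConfig,
) -> ConcordanceReport:
    """validate_signature + array_wide_rate at every configured threshold."""
    tab = _with_adjusted_p(validation_stats)
    background = array_wide_rate(validation_stats, config, validation_table=tab)
    rows = []
    for thr in config.fc_thresholds:
        sig = filter_signature(meta, thr, config.adj_p_threshold)
        row: dict = {"fc_threshold": thr}
        row.update(
            validate_signature(sig, validation_stats, config, validation_table=tab)
        )
        row["array_wide_rate"] = background[thr]
        rows.append(row)
    return ConcordanceReport(table=pd.DataFrame(rows, columns=REPORT_COLUMNS))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    """File-system layout consumed by :func:`run_pipeline`.

    ``meta_dir`` (and optionally ``validation_dir``) contain
    ``matrix_<study>.tsv``, ``probemap_<study>.tsv`` and a shared
    ``annotation.tsv`` — the layout written by
    :func:`ergmeta.synthio.write_study_set`.
    """

    meta_dir: Path
    validation_dir: Path | None = None
    marker: str = "ERG"
    cancer_label: str = "cancer"
    benign_label: str = "benign"
    validation_positive: str = "cancer_pos"
    validation_negative: str = "cancer_neg"

    def __post_init__(self) -> None:
        self.meta_dir = Path(self.meta_dir)
        if self.validation_dir is not None:
            self.validation_dir = Path(self.validation_dir)


@dataclass
class PipelineResult:
    meta_cancer: pd.DataFrame | None
    meta_subgroup: pd.DataFrame | None
    signatures: dict[str, dict[float, Signature]]
    report: ConcordanceReport | None
    manifest: dict


def _load_bundle(directory: Path) -> tuple[list[StudyMatrix], dict[str, ProbeGeneMap]]:
    matrices = sorted(directory.glob("matrix_*.tsv"))
    if not matrices:
        raise ErgMetaError(f"no matrix_*.tsv files under {directory}")
    annotation = directory / "annotation.tsv"
    studies, maps = [], {}
    for mpath in matrices:
        sid = mpath.stem.removeprefix("matrix_")
        study = read_study_matrix(mpath, annotation, study_id=sid)
        pmap = read_probe_gene_map(directory / f"probemap_{sid}.tsv")
        studies.append(study)
        maps[sid] = pmap
    return studies, maps


def _contrast(
    gene_studies: list[StudyMatrix],
    assignments: dict[str, GroupAssignment],
    config: RunConfig,
    label: str,
) -> pd.DataFrame:
    stats_list = [
        two_group_stats(s, assignments[s.study_id])
        for s in gene_studies
        if s.study_id in assignments
    ]
    if len(stats_list) < 2:
        raise ErgMetaError(f"contrast {label!r}: fewer than 2 usable studies")
    meta = combine_studies(stats_list, min_studies=config.min_studies_per_gene)
    if config.permutations > 0:
        pairs = [
            (s, assignments[s.study_id])
            for s in gene_studies
            if s.study_id in assignments
        ]
        meta = add_permutation_p(
            meta, pairs, B=config.permutations, seed=config.seed
        )
    return meta


def run_pipeline(
    config: RunConfig, inputs: PipelineInputs, out_dir: str | Path
) -> PipelineResult:
    """Execute collapse -> assignment -> per-study stats -> combination ->
    filtering -> optional validation, writing TSV results and a manifest.

    Two contrasts are run when the annotation supports them: cancer vs
    benign (annotation labels) and subgroup positive vs negative
    (marker-expression tertiles among cancer samples). Outputs are byte
    deterministic for a fixed config and input bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": {},
    }

    with stage("load"):
        studies, maps = _load_bundle(inputs.meta_dir)
    manifest["stages"]["load"] = {"n_studies": len(studies)}

    with stage("collapse"):
        gene_studies = [collapse_probes(s, maps[s.study_id]) for s in studies]
        coverage = build_gene_universe(
            gene_studies, min_studies=config.min_studies_per_gene
        )
    manifest["stages"]["collapse"] = {
        "n_genes_universe": int(len(coverage.table)),
        "n_genes_combinable": len(coverage.combination_genes),
    }

    with stage("assign"):
        cancer_assign: dict[str, GroupAssignment] = {}
        subgroup_assign: dict[str, GroupAssignment] = {}
        for s in gene_studies:
            phenos = set(s.sample_phenotypes.values())
            if inputs.cancer_label in phenos and inputs.benign_label in phenos:
                try:
                    cancer_assign[s.study_id] = assignment_from_annotation(
                        s, inputs.cancer_label, inputs.benign_label
                    )
                except ErgMetaError as e:
                    LOG.warning("cancer-vs-benign skip %s: %s", s.study_id, e)
            if inputs.cancer_label in phenos:
                try:
                    subgroup_assign[s.study_id] = assign_by_marker_tertiles(
                        s, inputs.marker, restrict_to=inputs.cancer_label
                    )
                    write_group_assignment(
                        subgroup_assign[s.study_id],
                        out / f"groups_subgroup_{s.study_id}.tsv",
                    )
                except ErgMetaError as e:
                    LOG.warning("subgroup skip %s: %s", s.study_id, e)
    manifest["stages"]["assign"] = {
        "n_studies_cancer_contrast": len(cancer_assign),
        "n_studies_subgroup_contrast": len(subgroup_assign),
    }

    meta_cancer = meta_subgroup = None
    signatures: dict[str, dict[float, Signature]] = {}
    with stage("combine"):
        if len(cancer_assign) >= 2:
            meta_cancer = _contrast(
                gene_studies, cancer_assign, config, "cancer_vs_benign"
            )
            write_results_table(meta_cancer, out / "results_cancer_vs_benign.tsv")
        if len(subgroup_assign) >= 2:
            meta_subgroup = _contrast(
                gene_studies, subgroup_assign, config, "subgroup_pos_vs_neg"
            )
            write_results_table(meta_subgroup, out / "results_subgroup.tsv")
    if meta_cancer is None and meta_subgroup is None:
        raise ErgMetaError("no contrast had >= 2 usable studies")

    with stage("filter"):
        for name, meta in (("cancer", meta_cancer), ("subgroup", meta_subgroup)):
            if meta is None:
                continue
            signatures[name] = {}
            for thr in config.fc_thresholds:
                sig = filter_signature(meta, thr, config.adj_p_threshold)
                signatures[name][thr] = sig
                manifest["stages"].setdefault("filter", {})[
                    f"{name}_fc{thr:g}"
                ] = {"n_up": sig.n_up, "n_down": sig.n_down}
            volcano_table(meta, signatures[name][config.fc_thresholds[0]]).to_csv(
                out / f"volcano_{name}.tsv", sep="\t", float_format="%.6g"
            )

    report = None
    if inputs.validation_dir is not None and meta_subgroup is not None:
        with stage("validate"):
            vstudies, vmaps = _load_bundle(inputs.validation_dir)
            if len(vstudies) != 1:
                raise ErgMetaError(
                    f"validation bundle must hold exactly 1 study, "
                    f"found {len(vstudies)}"
                )
            vgene = collapse_probes(vstudies[0], vmaps[vstudies[0].study_id])
            vassign = assignment_from_annotation(
                vgene, inputs.validation_positive, inputs.validation_negative
            )
            vstats = two_group_stats(vgene, vassign)
            report = concordance_report(meta_subgroup, vstats, config)
            report.write(out / "report.tsv")
        manifest["stages"]["validate"] = {
            "n_validation_genes": int(vstats.n_genes)
        }

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(
        meta_cancer=meta_cancer,
        meta_subgroup=meta_subgroup,
        signatures=signatures,
        report=report,
        manifest=manifest,
    )
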