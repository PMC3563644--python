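"""Probe-to-gene collapse and the cross-study gene universe.

Array platforms interrogate a gene with one or several probe sets. For
cross-study comparison each study is collapsed to one row per gene by
keeping, for multi-probe genes, the probe set with the highest sample
variance across all samples of the study (pooled over phenotype groups,
denominator n-1). Genes must be measured in a minimum number of studies to
enter the combination step; sparsely measured genes show high background
variation and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_core import (
    ErgMetaError,
    GENE_LEVEL,
    LOG,
    ProbeGeneMap,
    StudyMatrix,
)


@dataclass
class GeneCoverage:
    """Which studies measure each gene, and the resulting combination set."""

    table: pd.DataFrame  # index gene_id, column n_studies
    studies_present: dict[str, list[str]]
    min_studies: int

    @property
    def combination_genes(self) -> list[str]:
        """Genes measured in at least ``min_studies`` studies, sorted."""
        ok = self.table.index[self.table["n_studies"] >= self.min_studies]
        return sorted(ok)


def collapse_probes(study: StudyMatrix, pmap: ProbeGeneMap) -> StudyMatrix:
    """Collapse a probe-level matrix to gene level by highest-variance probe.

    For every gene with several mapped probes the probe whose across-all-
    samples variance (ddof=1, NaN-aware) is largest is retained; variance
    ties break to the lexicographically smallest probe ID. Probes absent
    from the map are dropped. The returned matrix records the chosen probe
    per gene and has rows sorted by gene ID.
    """
    if len(pmap) == 0:
        raise ErgMetaError("probe-gene map is empty")
    mapped = [p for p in study.values.index if p in pmap.entries]
    if not mapped:
        raise ErgMetaError(
            f"study {study.study_id!r}: no probe maps to any gene"
        )
    n_dropped = study.values.shape[0] - len(mapped)
    if n_dropped:
        LOG.info(
            "study %s: dropping %d unmapped probe(s)", study.study_id, n_dropped
        )

    sub = study.values.loc[mapped]
    sel = pd.DataFrame(
        {
            "probe": mapped,
            "gene": [pmap.entries[p] for p in mapped],
            "var": sub.var(axis=1, ddof=1).to_numpy(),
        }
    )
    # highest variance first, ties to lexicographically smallest probe ID
    sel = sel.sort_values(["var", "probe"], ascending=[False, True], kind="stable")
    chosen = sel.drop_duplicates("gene", keep="first").sort_values("gene")

    out = sub.loc[chosen["probe"]].copy()
    out.index = pd.Index(chosen["gene"].to_numpy(), name="gene_id")
    return StudyMatrix(
        study_id=study.study_id,
        values=out,
        feature_level=GENE_LEVEL,
        sample_phenotypes=dict(study.sample_phenotypes),
        chosen_probes=dict(zip(chosen["gene"], chosen["probe"])),
    )


def build_gene_universe(
    studies: list[StudyMatrix], min_studies: int = 2
) -> GeneCoverage:
    """Per-gene study coverage across gene-level matrices.

    Every gene appearing anywhere is covered; the combination set consists
    of genes measured in at least ``min_studies`` studies (>= 2).
    """
    if min_studies < 2:
        raise ErgMetaError(f"min_studies must be >= 2, got {min_studies}")
    if len(studies) < 2:
        raise ErgMetaError("need at least 2 studies to build a gene universe")
    present: dict[str, list[str]] = {}
    for study in studies:
        for g in study.values.index:
            present.setdefault(g, []).append(study.study_id)
    genes = sorted(present)
    table = pd.DataFrame(
        {"n_studies": [len(present[g]) for g in genes]},
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneCoverage(table=table, studies_present=present, min_studies=min_studies)
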