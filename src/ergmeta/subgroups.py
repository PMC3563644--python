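"""Tumor subgroup assignment: marker-expression tertiles or external labels.

When the rearrangement status of a tumor is not annotated, the expression of
its downstream marker gene (ERG for the TMPRSS2-ERG fusion) serves as a
surrogate: within each study the cancer samples are split into expression
tertiles, the top third is called positive, the bottom third negative, and
the intermediate third is excluded from all downstream statistics. With a
bimodal marker this recovers the latent status with high accuracy, which
:func:`surrogate_concordance` quantifies on synthetic data.
"""

from __future__ import annotations

import math

from .io_core import (
    ErgMetaError,
    EXCLUDED,
    NEGATIVE,
    POSITIVE,
    GroupAssignment,
    StudyMatrix,
)
from .synthio import TruthTable


def assign_by_marker_tertiles(
    study: StudyMatrix, marker: str, restrict_to: str = "cancer"
) -> GroupAssignment:
    """Split the samples of one phenotype into marker-expression tertiles.

    Samples with phenotype ``restrict_to`` are sorted by marker expression
    descending (ties broken by sample ID ascending, so assignment is
    deterministic); the top ceil(n/3) are labeled positive, the bottom
    floor(n/3) negative, and the middle remainder excluded. Samples of other
    phenotypes are left unlabeled.
    """
    if marker not in study.values.index:
        raise ErgMetaError(
            f"study {study.study_id!r}: marker gene {marker!r} not measured"
        )
    eligible = study.samples_with_phenotype(restrict_to)
    n = len(eligible)
    if n < 3:
        raise ErgMetaError(
            f"study {study.study_id!r}: only {n} sample(s) with phenotype "
            f"{restrict_to!r}; need >= 3 for tertiles"
        )
    expr = study.values.loc[marker]
    ranked = sorted(eligible, key=lambda s: (-expr[s], s))
    n_pos = math.ceil(n / 3)
    n_neg = math.floor(n / 3)
    labels: dict[str, str] = {}
    for i, s in enumerate(ranked):
        if i < n_pos:
            labels[s] = POSITIVE
        elif i >= n - n_neg:
            labels[s] = NEGATIVE
        else:
            labels[s] = EXCLUDED
    return GroupAssignment(labels=labels, marker_gene=marker)


def assignment_from_annotation(
    study: StudyMatrix, positive_label: str, negative_label: str
) -> GroupAssignment:
    """Two-group assignment from externally annotated phenotypes.

    Samples whose phenotype equals ``positive_label`` / ``negative_label``
    become positive / negative; all other samples are excluded. Used both
    for cancer-vs-benign contrasts and for validation cohorts whose
    subgroup status was determined by an external assay.
    """
    labels: dict[str, str] = {}
    counts = {positive_label: 0, negative_label: 0}
    for s in study.samples:
        ph = study.sample_phenotypes[s]
        if ph == positive_label:
            labels[s] = POSITIVE
            counts[positive_label] += 1
        elif ph == negative_label:
            labels[s] = NEGATIVE
            counts[negative_label] += 1
        else:
            labels[s] = EXCLUDED
    for lab, c in counts.items():
        if c == 0:
            raise ErgMetaError(
                f"study {study.study_id!r}: phenotype label {lab!r} matches no sample"
            )
    return GroupAssignment(labels=labels, marker_gene="")


def surrogate_concordance(
    surrogate: GroupAssignment, truth: TruthTable, study_id: str
) -> float:
    """Fraction of non-excluded samples whose surrogate label matches the
    true latent subgroup of a synthetic study."""
    hits = 0
    total = 0
    for s, lab in surrogate.labels.items():
        if lab == EXCLUDED:
            continue
        true_lab = truth.subgroup_membership.get((study_id, s))
        if true_lab is None:
            continue
        total += 1
        hits += lab == true_lab
    if total == 0:
        raise ErgMetaError(
            f"no overlap between assignment and truth for study {study_id!r}"
        )
    return hits / total
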