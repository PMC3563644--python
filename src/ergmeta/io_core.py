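"""Domain types, tab-separated I/O, run configuration and logging.

All expression values are log2-scale intensities as produced by standard
array normalization (gcRMA-style pipelines); fold changes are therefore
differences on the log2 scale, reported linearly as ``2**|log2fc|`` with a
separate direction flag. Files are plain TSV with '.' decimals, no quoting,
and the cell token ``NA`` for missing values.
"""

from __future__ import annotations

import logging
import math
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

LOG = logging.getLogger("ergmeta")

NA_TOKEN = "NA"
#: float format giving exact binary round trips (17 significant digits)
FLOAT_FMT = "%.17g"

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"

PROBE_LEVEL = "probe"
GENE_LEVEL = "gene"

#: column order of a written results table
RESULTS_COLUMNS = [
    "gene_id",
    "n_studies",
    "weighted_log2fc",
    "linear_fc",
    "direction",
    "fisher_stat",
    "p_chisq",
    "p_perm",
    "p_adj",
]


class ErgMetaError(ValueError):
    """Raised for malformed inputs or invalid configuration; never repaired silently."""


@contextmanager
def stage(name: str) -> Iterator[None]:
    """Log entry/exit and wall time of a pipeline stage."""
    t0 = time.perf_counter()
    LOG.info("stage %-24s start", name)
    yield
    LOG.info("stage %-24s done in %.2fs", name, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class StudyMatrix:
    """One study's normalized log2 expression matrix (features x samples).

    Parameters
    ----------
    study_id
        Free-text study label.
    values
        DataFrame of log2 intensities; rows are feature IDs (probe sets or
        genes), columns are sample IDs. NaN marks a missing measurement;
        infinities are rejected.
    feature_level
        ``"probe"`` or ``"gene"``.
    sample_phenotypes
        Maps every sample ID to its phenotype label (e.g. ``"cancer"``,
        ``"benign"``).
    chosen_probes
        After probe collapse: the probe set retained for each gene row.
    """

    study_id: str
    values: pd.DataFrame
    feature_level: str
    sample_phenotypes: dict[str, str]
    chosen_probes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.feature_level not in (PROBE_LEVEL, GENE_LEVEL):
            raise ErgMetaError(
                f"study {self.study_id!r}: feature_level must be "
                f"'{PROBE_LEVEL}' or '{GENE_LEVEL}', got {self.feature_level!r}"
            )
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ErgMetaError(f"study {self.study_id!r}: duplicate feature ID {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ErgMetaError(f"study {self.study_id!r}: duplicate sample ID {dup!r}")
        missing = [s for s in cols if s not in self.sample_phenotypes]
        if missing:
            raise ErgMetaError(
                f"study {self.study_id!r}: sample {missing[0]!r} has no phenotype annotation"
            )
        arr = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(arr).any():
            raise ErgMetaError(f"study {self.study_id!r}: non-finite expression value")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_with_phenotype(self, phenotype: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_phenotypes[s] == phenotype]


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene identifier map (a probe maps to at most one gene)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.entries.items():
            if not gene:
                raise ErgMetaError(f"probe {probe!r} maps to an empty gene ID")

    def __len__(self) -> int:
        return len(self.entries)

    def gene_of(self, probe: str) -> str | None:
        return self.entries.get(probe)


@dataclass
class GroupAssignment:
    """Per-sample two-group labels, with a middle/unused class ``excluded``.

    ``marker_gene`` records the surrogate marker when the assignment came from
    expression tertiles; it is empty for externally annotated assignments
    (FISH status, cancer vs benign).
    """

    labels: dict[str, str]
    marker_gene: str = ""

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {POSITIVE, NEGATIVE, EXCLUDED}
        if bad:
            raise ErgMetaError(f"invalid group label(s): {sorted(bad)}")

    def group(self, which: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == which]

    @property
    def positives(self) -> list[str]:
        return self.group(POSITIVE)

    @property
    def negatives(self) -> list[str]:
        return self.group(NEGATIVE)

    @property
    def excluded(self) -> list[str]:
        return self.group(EXCLUDED)


@dataclass
class RunConfig:
    """Analysis-wide thresholds and reproducibility knobs.

    Attributes
    ----------
    fc_thresholds
        Linear fold-change cutoffs for signature filtering (strict ``>``).
    adj_p_threshold
        BH-adjusted p cutoff for signature filtering (strict ``<``).
    permutations
        Number of label permutations B for the permutational summary p
        (0 disables it).
    seed
        Master seed for every stochastic step.
    min_studies_per_gene
        Minimum number of contributing studies for a gene to be combined.
    validation_p_threshold
        Adjusted-p cutoff on the validation side of the concordance check.
    """

    fc_thresholds: tuple[float, ...] = (1.5, 2.0)
    adj_p_threshold: float = 0.1
    permutations: int = 0
    seed: int = 0
    min_studies_per_gene: int = 2
    validation_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        self.fc_thresholds = tuple(float(t) for t in self.fc_thresholds)
        if any(t <= 1 for t in self.fc_thresholds):
            raise ErgMetaError("fold-change thresholds must be > 1 (linear scale)")
        for name in ("adj_p_threshold", "validation_p_threshold"):
            p = getattr(self, name)
            if not (0 < p <= 1):
                raise ErgMetaError(f"{name} must lie in (0, 1], got {p}")
        if self.permutations < 0:
            raise ErgMetaError("permutations must be non-negative")
        if self.min_studies_per_gene < 2:
            raise ErgMetaError("min_studies_per_gene must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML key-value file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ErgMetaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "fc_thresholds": list(self.fc_thresholds),
            "adj_p_threshold": self.adj_p_threshold,
            "permutations": self.permutations,
            "seed": self.seed,
            "min_studies_per_gene": self.min_studies_per_gene,
            "validation_p_threshold": self.validation_p_threshold,
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_header_ids(path: Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    return header[1:]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV with columns sample_id, [study_id,] phenotype."""
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "phenotype"):
        if col not in ann.columns:
            raise ErgMetaError(f"annotation {path}: missing required column {col!r}")
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ErgMetaError(f"annotation {path}: duplicate sample_id {dup!r}")
    return ann


def read_study_matrix(
    path: str | Path,
    annotation_path: str | Path,
    study_id: str | None = None,
    feature_level: str = PROBE_LEVEL,
) -> StudyMatrix:
    """Read an expression matrix TSV plus its sample annotation.

    The matrix has a header row of sample IDs and feature IDs in the first
    column; ``NA`` cells become missing values. Duplicate feature or sample
    IDs, non-numeric cells and samples absent from the annotation are hard
    errors naming the offending ID.
    """
    path = Path(path)
    sample_ids = _read_header_ids(path)
    dup_samples = pd.Index(sample_ids)
    if dup_samples.has_duplicates:
        dup = dup_samples[dup_samples.duplicated()][0]
        raise ErgMetaError(f"{path}: duplicate sample ID {dup!r} in header")

    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
    )
    df.columns = sample_ids  # undo pandas' silent dedup of repeated headers
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ErgMetaError(f"{path}: duplicate feature ID {dup!r}")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[bad][0]
                raise ErgMetaError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at feature {row!r}, sample {col!r}"
                )
            df[col] = coerced
    df = df.astype(float)
    df.index = df.index.astype(str)

    ann = read_annotation(annotation_path)
    pheno = dict(zip(ann["sample_id"], ann["phenotype"]))
    for s in df.columns:
        if s not in pheno:
            raise ErgMetaError(f"{path}: sample {s!r} missing from annotation")

    if study_id is None:
        if "study_id" in ann.columns:
            here = set(ann.loc[ann["sample_id"].isin(df.columns), "study_id"])
            study_id = here.pop() if len(here) == 1 else path.stem
        else:
            study_id = path.stem
    return StudyMatrix(
        study_id=study_id,
        values=df,
        feature_level=feature_level,
        sample_phenotypes={s: pheno[s] for s in df.columns},
    )


def write_study_matrix(study: StudyMatrix, path: str | Path) -> None:
    """Write the expression matrix as TSV (row/column order preserved)."""
    study.values.to_csv(
        path, sep="\t", index_label="feature_id", float_format=FLOAT_FMT, na_rep=NA_TOKEN
    )


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read a probe -> gene TSV (columns probe_id, gene_id).

    A probe ID appearing more than once would map to multiple genes; such
    redundant probes are dropped with a logged warning so the many-to-one
    invariant holds.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_id"):
        if col not in df.columns:
            raise ErgMetaError(f"probe map {path}: missing required column {col!r}")
    empties = df["gene_id"] == ""
    if empties.any():
        probe = df.loc[empties, "probe_id"].iloc[0]
        raise ErgMetaError(f"probe map {path}: probe {probe!r} has empty gene ID")
    dup_mask = df["probe_id"].duplicated(keep=False)
    if dup_mask.any():
        dropped = sorted(set(df.loc[dup_mask, "probe_id"]))
        LOG.warning(
            "probe map %s: dropping %d redundant probe(s) mapping to multiple rows: %s",
            path,
            len(dropped),
            ", ".join(dropped[:5]) + ("..." if len(dropped) > 5 else ""),
        )
        df = df[~dup_mask]
    return ProbeGeneMap(entries=dict(zip(df["probe_id"], df["gene_id"])))


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(pmap.entries), "gene_id": list(pmap.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a combined results table as TSV.

    One row per gene, fixed column order (:data:`RESULTS_COLUMNS`), genes
    sorted by adjusted p then gene ID; byte-deterministic for a given table.
    """
    if table.empty:
        raise ErgMetaError("refusing to write an empty results table")
    out = table.copy()
    out.index.name = "gene_id"
    out = out.reset_index()
    missing = [c for c in RESULTS_COLUMNS if c not in out.columns]
    if missing:
        raise ErgMetaError(f"results table missing column(s): {missing}")
    out = out[RESULTS_COLUMNS].sort_values(
        ["p_adj", "gene_id"], kind="stable", ignore_index=True
    )
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=NA_TOKEN)


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False, dtype={"gene_id": str}
    )
    return df.set_index("gene_id")


def write_group_assignment(groups: GroupAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.labels), "label": list(groups.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_group_assignment(path: str | Path, marker_gene: str = "") -> GroupAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return GroupAssignment(
        labels=dict(zip(df["sample_id"], df["label"])), marker_gene=marker_gene
    )
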