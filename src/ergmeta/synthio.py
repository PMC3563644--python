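"""Synthetic multi-study expression cohorts with known ground truth.

Emulates the statistical structure a cross-study microarray meta-analysis
assumes: several independent studies on distinct platforms (each with its own
probe namespace and probe->gene map, one to a few probe sets per gene),
study-specific additive baselines, cancer and benign samples, a latent
binary tumor subgroup (ERG rearrangement-like, ~50% prevalence) driven by a
bimodal marker gene, subgroup- and cancer-linked differentially expressed
genes with configurable log2 effects, and i.i.d. Gaussian noise on the log2
scale (the variance-stabilized regime post-normalization).

Defaults mirror an eight-study prostate cohort design: per-study
(cancer, benign) sample counts of (21,8), (57,15), (41,13), (50,48),
(23,49), (7,6), (68,14), (138,3) — 405 cancer + 156 benign = 561 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    ErgMetaError,
    GENE_LEVEL,
    PROBE_LEVEL,
    LOG,
    ProbeGeneMap,
    StudyMatrix,
    write_probe_gene_map,
    write_study_matrix,
)

#: gene ID reserved for the bimodal subgroup marker
MARKER_GENE = "ERG"

#: Table-style default per-study (cancer, benign) sample counts
DEFAULT_SAMPLES = (
    (21, 8),
    (57, 15),
    (41, 13),
    (50, 48),
    (23, 49),
    (7, 6),
    (68, 14),
    (138, 3),
)

_BASE_MEAN = 8.0       # grand mean of log2 intensities
_BASE_SD = 1.5         # between-gene spread of baseline expression
_PROBE_OFFSET_SD = 0.3  # constant per-probe shift (affinity differences)
_POSITIVE_RATE = 0.5    # prevalence of the subgroup among cancer samples


@dataclass
class SimConfig:
    """Parameters of the synthetic study set.

    Attributes
    ----------
    n_studies
        Number of independent studies.
    genes
        Genes per study (all platforms cover all genes; the marker is one
        of them).
    probes_per_gene
        Inclusive (low, high) range for the number of probe sets per gene,
        drawn per gene per study.
    samples_per_study
        One (n_cancer, n_benign) pair per study.
    de_fraction_cancer
        Fraction of genes truly differential cancer vs benign.
    de_fraction_subgroup
        Fraction truly differential between subgroup-positive and -negative
        cancer samples (disjoint from the cancer-DE set and the marker).
    effect_log2
        Magnitude of every true log2 difference (sign drawn per gene).
    noise_sd
        Within-group SD per measurement on the log2 scale.
    study_shift_sd
        SD of the additive per-study-per-gene baseline shift.
    marker_gap_log2
        Mean separation of the marker gene between subgroup-positive and
        -negative cancer samples (>= 0; the source of marker bimodality).
    seed
        Reproducibility seed.
    """

    n_studies: int = 8
    genes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 3)
    samples_per_study: tuple[tuple[int, int], ...] = DEFAULT_SAMPLES
    de_fraction_cancer: float = 0.10
    de_fraction_subgroup: float = 0.05
    effect_log2: float = 1.0
    noise_sd: float = 0.5
    study_shift_sd: float = 0.5
    marker_gap_log2: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples_per_study = tuple(tuple(p) for p in self.samples_per_study)
        if self.n_studies < 1 or self.genes < 2:
            raise ErgMetaError("need at least 1 study and 2 genes")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ErgMetaError(f"invalid probes_per_gene range {self.probes_per_gene}")
        if len(self.samples_per_study) != self.n_studies:
            raise ErgMetaError(
                f"samples_per_study has {len(self.samples_per_study)} entries "
                f"for n_studies={self.n_studies}"
            )
        if any(nc < 1 or nb < 0 for nc, nb in self.samples_per_study):
            raise ErgMetaError("per-study sample counts must be positive")
        for name in ("de_fraction_cancer", "de_fraction_subgroup"):
            f = getattr(self, name)
            if not (0 <= f <= 1):
                raise ErgMetaError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.study_shift_sd < 0 or self.marker_gap_log2 < 0:
            raise ErgMetaError("SDs and marker_gap_log2 must be non-negative")


@dataclass
class TruthTable:
    """Ground truth of a synthetic study set.

    ``genes`` is indexed by gene ID with columns ``is_de_cancer``,
    ``is_de_subgroup`` (bool) and ``true_log2fc`` (signed; 0 for null genes).
    ``subgroup_membership`` maps (study_id, sample_id) of every cancer sample
    to ``"positive"`` or ``"negative"``.
    """

    genes: pd.DataFrame
    subgroup_membership: dict[tuple[str, str], str] = field(default_factory=dict)
    marker_gene: str = MARKER_GENE

    def __post_init__(self) -> None:
        g = self.genes
        flagged = g["is_de_cancer"] | g["is_de_subgroup"]
        if (flagged != (g["true_log2fc"] != 0)).any():
            raise ErgMetaError("truth flags inconsistent with true_log2fc")

    def de_subgroup_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_de_subgroup"]])

    def de_cancer_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_de_cancer"]])


def _gene_ids(n: int) -> list[str]:
    return [MARKER_GENE] + [f"G{i:05d}" for i in range(1, n)]


def _make_truth(cfg: SimConfig, rng: np.random.Generator) -> TruthTable:
    ids = _gene_ids(cfg.genes)
    n = cfg.genes
    n_ca = int(round(cfg.de_fraction_cancer * n))
    n_sub = int(round(cfg.de_fraction_subgroup * n))
    if n_ca + n_sub > n - 1:
        raise ErgMetaError("DE fractions leave no null genes")
    # draw disjoint DE sets, never touching the marker gene
    pool = rng.permutation(np.arange(1, n))
    ca_idx = set(pool[:n_ca].tolist())
    sub_idx = set(pool[n_ca : n_ca + n_sub].tolist())
    signs = rng.choice([-1.0, 1.0], size=n)  # fair coin per gene
    rows = {
        "is_de_cancer": np.array([i in ca_idx for i in range(n)]),
        "is_de_subgroup": np.array([i in sub_idx for i in range(n)]),
    }
    flagged = rows["is_de_cancer"] | rows["is_de_subgroup"]
    rows["true_log2fc"] = np.where(flagged, signs * cfg.effect_log2, 0.0)
    return TruthTable(genes=pd.DataFrame(rows, index=pd.Index(ids, name="gene_id")))


def _simulate_study(
    cfg: SimConfig,
    truth: TruthTable,
    study_id: str,
    n_cancer: int,
    n_benign: int,
    base_means: np.ndarray,
    rng: np.random.Generator,
    membership: np.ndarray | None = None,
) -> tuple[StudyMatrix, ProbeGeneMap]:
    """One study at probe level; records cancer-sample subgroup membership in truth."""
    ids = list(truth.genes.index)
    n_genes = len(ids)
    lo, hi = cfg.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=n_genes)

    sample_ids = [f"{study_id}_ca{i:03d}" for i in range(n_cancer)] + [
        f"{study_id}_be{i:03d}" for i in range(n_benign)
    ]
    is_cancer = np.array([True] * n_cancer + [False] * n_benign)
    if membership is None:
        membership = rng.random(n_cancer) < _POSITIVE_RATE
    is_positive = np.concatenate([membership, np.zeros(n_benign, dtype=bool)])

    for i in range(n_cancer):
        truth.subgroup_membership[(study_id, sample_ids[i])] = (
            "positive" if membership[i] else "negative"
        )

    study_shift = rng.normal(0.0, cfg.study_shift_sd, size=n_genes)
    fc = truth.genes["true_log2fc"].to_numpy()
    de_ca = truth.genes["is_de_cancer"].to_numpy()
    de_sub = truth.genes["is_de_subgroup"].to_numpy()
    marker = np.asarray([g == truth.marker_gene for g in ids])

    # gene-level signal per (gene, sample)
    signal = (base_means + study_shift)[:, None] + np.zeros((n_genes, len(sample_ids)))
    signal += np.where(de_ca, fc, 0.0)[:, None] * is_cancer[None, :]
    signal += np.where(de_sub, fc, 0.0)[:, None] * is_positive[None, :]
    signal += (marker[:, None] * cfg.marker_gap_log2) * is_positive[None, :]

    # expand to probes: constant per-probe offsets plus i.i.d. noise
    probe_gene_idx = np.repeat(np.arange(n_genes), n_probes_per_gene)
    n_probes = len(probe_gene_idx)
    probe_ids = [f"{study_id}_p{j:06d}" for j in range(n_probes)]
    offsets = rng.normal(0.0, _PROBE_OFFSET_SD, size=n_probes)
    values = (
        signal[probe_gene_idx]
        + offsets[:, None]
        + rng.normal(0.0, cfg.noise_sd, size=(n_probes, len(sample_ids)))
    )

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids), columns=sample_ids)
    phenos = {
        s: ("cancer" if c else "benign") for s, c in zip(sample_ids, is_cancer)
    }
    pmap = ProbeGeneMap(
        entries={p: ids[g] for p, g in zip(probe_ids, probe_gene_idx)}
    )
    study = StudyMatrix(
        study_id=study_id,
        values=matrix,
        feature_level=PROBE_LEVEL,
        sample_phenotypes=phenos,
    )
    return study, pmap


def generate_study_set(
    cfg: SimConfig,
) -> tuple[list[StudyMatrix], dict[str, ProbeGeneMap], TruthTable]:
    """Generate the full multi-study set: probe-level matrices, per-study
    probe maps and the ground-truth table. Bit-reproducible for a fixed seed."""
    master = np.random.SeedSequence(cfg.seed)
    truth_ss, base_ss, *study_ss = master.spawn(cfg.n_studies + 2)
    truth = _make_truth(cfg, np.random.default_rng(truth_ss))
    base_means = np.random.default_rng(base_ss).normal(
        _BASE_MEAN, _BASE_SD, size=cfg.genes
    )

    studies: list[StudyMatrix] = []
    maps: dict[str, ProbeGeneMap] = {}
    for k, ((n_ca, n_be), ss) in enumerate(zip(cfg.samples_per_study, study_ss), 1):
        sid = f"study{k}"
        study, pmap = _simulate_study(
            cfg, truth, sid, n_ca, n_be, base_means, np.random.default_rng(ss)
        )
        studies.append(study)
        maps[sid] = pmap
    LOG.info(
        "simulated %d studies, %d genes, %d DE(cancer), %d DE(subgroup)",
        cfg.n_studies,
        cfg.genes,
        len(truth.de_cancer_genes()),
        len(truth.de_subgroup_genes()),
    )
    return studies, maps, truth


def generate_validation_study(
    cfg: SimConfig,
    truth: TruthTable,
    study_id: str = "validation",
    n_samples: int = 57,
    seed: int | None = None,
) -> tuple[StudyMatrix, ProbeGeneMap]:
    """An independent all-cancer cohort drawn from the SAME truth table.

    Emulates a validation study whose subgroup status is known externally
    (FISH-style): sample phenotypes are ``cancer_pos`` / ``cancer_neg``
    rather than a surrogate marker call. Membership is recorded in ``truth``.
    """
    ss = np.random.SeedSequence(cfg.seed + 1 if seed is None else seed).spawn(2)
    rng = np.random.default_rng(ss[0])
    base_means = rng.normal(_BASE_MEAN, _BASE_SD, size=len(truth.genes))
    membership = rng.random(n_samples) < _POSITIVE_RATE
    study, pmap = _simulate_study(
        cfg,
        truth,
        study_id,
        n_cancer=n_samples,
        n_benign=0,
        base_means=base_means,
        rng=np.random.default_rng(ss[1]),
        membership=membership,
    )
    # externally annotated subgroup status replaces the generic cancer label
    study.sample_phenotypes = {
        s: ("cancer_pos" if truth.subgroup_membership[(study_id, s)] == "positive"
            else "cancer_neg")
        for s in study.samples
    }
    return study, pmap


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def export_truth(truth: TruthTable, path: str | Path) -> None:
    """Write the per-gene truth table as TSV (one row per gene, input order)."""
    out = truth.genes.copy()
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["is_de_cancer"] = df["is_de_cancer"].astype(bool)
    df["is_de_subgroup"] = df["is_de_subgroup"].astype(bool)
    return TruthTable(genes=df)


def export_membership(truth: TruthTable, path: str | Path) -> None:
    rows = [
        {"study_id": st, "sample_id": sa, "subgroup": lab}
        for (st, sa), lab in sorted(truth.subgroup_membership.items())
    ]
    pd.DataFrame(rows, columns=["study_id", "sample_id", "subgroup"]).to_csv(
        path, sep="\t", index=False
    )


def write_study_set(
    studies: list[StudyMatrix],
    maps: dict[str, ProbeGeneMap],
    truth: TruthTable | None,
    out_dir: str | Path,
) -> None:
    """Write matrix_<study>.tsv, probemap_<study>.tsv, annotation.tsv and
    (when truth is given) truth.tsv + truth_subgroups.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann_rows = []
    for study in studies:
        write_study_matrix(study, out / f"matrix_{study.study_id}.tsv")
        write_probe_gene_map(maps[study.study_id], out / f"probemap_{study.study_id}.tsv")
        for s in study.samples:
            ann_rows.append(
                {
                    "sample_id": s,
                    "study_id": study.study_id,
                    "phenotype": study.sample_phenotypes[s],
                }
            )
    pd.DataFrame(ann_rows).to_csv(out / "annotation.tsv", sep="\t", index=False)
    if truth is not None:
        export_truth(truth, out / "truth.tsv")
        export_membership(truth, out / "truth_subgroups.tsv")
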