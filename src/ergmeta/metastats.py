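"""Per-study two-group statistics and their cross-study combination.

The meta-analytic engine: per study a two-sided Welch unequal-variance
t-test and a mean-difference log2 fold change per gene; across studies
Fisher's inverse chi-squared combination (X = -2 * sum(ln p_i), referred to
a chi-squared distribution with 2k degrees of freedom), an optional
permutational summary p-value obtained by within-study group-label
shuffling, sample-size-weighted combined fold changes, Benjamini-Hochberg
FDR adjustment, and threshold filtering into up/down signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import (
    ErgMetaError,
    LOG,
    GroupAssignment,
    StudyMatrix,
)

#: floor applied to p-values before taking logs (finite Fisher statistic)
P_FLOOR = 1e-300
#: p-value reported when both groups are constant but their means differ
P_DEGENERATE = np.finfo(float).tiny
#: slack when counting permuted statistics >= the observed one
_PERM_EPS = 1e-9


@dataclass
class PerStudyStats:
    """Per-gene two-group statistics of one study.

    ``table`` is indexed by gene ID with columns ``log2fc`` (positive-group
    mean minus negative-group mean), ``p_value`` (two-sided), ``n_pos`` and
    ``n_neg`` (per-gene effective group sizes after missing-value removal).
    """

    study_id: str
    table: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.table)


@dataclass
class Signature:
    """Genes passing a fold-change / adjusted-p filter, with directions."""

    fc_threshold: float
    adj_p_threshold: float
    table: pd.DataFrame  # index gene_id; columns direction, weighted_log2fc, linear_fc, p_adj

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] > 0).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] < 0).sum())

    def directions(self) -> dict[str, int]:
        return {g: int(d) for g, d in self.table["direction"].items()}


# ---------------------------------------------------------------------------
# per-study test
# ---------------------------------------------------------------------------


def _welch_from_moments(
    m1: np.ndarray,
    v1: np.ndarray,
    n1: np.ndarray,
    m2: np.ndarray,
    v2: np.ndarray,
    n2: np.ndarray,
) -> np.ndarray:
    """Vectorized two-sided Welch p from group moments.

    Degenerate-variance convention: when both groups are constant the p is 1
    for equal means and the smallest positive float otherwise, so the value
    stays usable inside logarithms.
    """
    m1, v1, m2, v2 = map(np.asarray, (m1, v1, m2, v2))
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), m1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), m2.shape)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(m1 == m2, 1.0, P_DEGENERATE), p)
    return np.clip(p, P_DEGENERATE, 1.0)


def two_group_stats(study: StudyMatrix, groups: GroupAssignment) -> PerStudyStats:
    """Welch t-test and log2 fold change per gene for one study.

    log2fc is mean(positive) - mean(negative) on the log2 scale. Missing
    values are dropped per gene; genes missing in more than half of either
    group (or with fewer than 2 usable values in a group) are dropped with
    a logged warning.
    """
    pos = [s for s in groups.positives if s in study.values.columns]
    neg = [s for s in groups.negatives if s in study.values.columns]
    if len(pos) < 2 or len(neg) < 2:
        raise ErgMetaError(
            f"study {study.study_id!r}: need >= 2 samples per group "
            f"(got {len(pos)} positive, {len(neg)} negative)"
        )
    P = study.values[pos].to_numpy(dtype=float)
    N = study.values[neg].to_numpy(dtype=float)
    n_pos_eff = np.sum(~np.isnan(P), axis=1)
    n_neg_eff = np.sum(~np.isnan(N), axis=1)
    keep = (
        (n_pos_eff >= 2)
        & (n_neg_eff >= 2)
        & (n_pos_eff > len(pos) / 2)
        & (n_neg_eff > len(neg) / 2)
    )
    if not keep.all():
        LOG.warning(
            "study %s: dropping %d gene(s) with too many missing values",
            study.study_id,
            int((~keep).sum()),
        )
    P, N = P[keep], N[keep]
    n1, n2 = n_pos_eff[keep], n_neg_eff[keep]
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(P, axis=1)
        m2 = np.nanmean(N, axis=1)
        v1 = np.nanvar(P, axis=1, ddof=1)
        v2 = np.nanvar(N, axis=1, ddof=1)
    p = _welch_from_moments(m1, v1, n1, m2, v2, n2)
    table = pd.DataFrame(
        {
            "log2fc": m1 - m2,
            "p_value": p,
            "n_pos": n1.astype(int),
            "n_neg": n2.astype(int),
        },
        index=study.values.index[keep],
    )
    table.index.name = "gene_id"
    return PerStudyStats(study_id=study.study_id, table=table)


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------


def fisher_combined_p(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's inverse chi-squared combination of k independent p-values.

    Returns ``(X, p)`` with X = -2 * sum(ln p_i) and p the upper-tail
    probability of X under chi-squared with 2k degrees of freedom. p-values
    are clipped below at 1e-300 before the log.
    """
    p_arr = np.asarray(list(p_values), dtype=float)
    if p_arr.size == 0:
        raise ErgMetaError("fisher_combined_p: empty p-value list")
    if np.any((p_arr <= 0) | (p_arr > 1)) or np.any(np.isnan(p_arr)):
        raise ErgMetaError("fisher_combined_p: p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(np.clip(p_arr, P_FLOOR, None)))
    return float(x), float(stats.chi2.sf(x, 2 * p_arr.size))


def weighted_combined_fc(per_study: Sequence[tuple[float, float]]) -> float:
    """Weighted mean of per-study log2 fold changes: sum(w*fc)/sum(w)."""
    if len(per_study) == 0:
        raise ErgMetaError("weighted_combined_fc: empty input")
    fcs = np.array([f for f, _ in per_study], dtype=float)
    ws = np.array([w for _, w in per_study], dtype=float)
    if np.any(ws <= 0):
        raise ErgMetaError("weighted_combined_fc: weights must be positive")
    return float(np.sum(ws * fcs) / np.sum(ws))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p_arr = np.asarray(list(p_values), dtype=float)
    if p_arr.size == 0:
        return p_arr
    if np.any((p_arr <= 0) | (p_arr > 1)) or np.any(np.isnan(p_arr)):
        raise ErgMetaError("bh_adjust: p-values must lie in (0, 1]")
    return multipletests(p_arr, method="fdr_bh")[1]


def combine_studies(
    stats_list: Sequence[PerStudyStats],
    min_studies: int = 2,
    equal_weights: bool = False,
) -> pd.DataFrame:
    """Combine per-study statistics into the meta-analysis table.

    For every gene measured in at least ``min_studies`` studies: the number
    of contributing studies k, Fisher statistic and chi-squared combined p,
    BH-adjusted p (across all combined genes of this contrast), combined
    log2 fold change weighted by per-study sample size n_pos + n_neg
    (or equally when ``equal_weights``), the linear fold change
    2**|weighted_log2fc| and the direction sign. ``p_perm`` is NaN until
    :func:`add_permutation_p` fills it.
    """
    if len(stats_list) < 2:
        raise ErgMetaError("combine_studies: need >= 2 studies")
    if min_studies < 2:
        raise ErgMetaError("combine_studies: min_studies must be >= 2")
    pmat = pd.DataFrame({s.study_id: s.table["p_value"] for s in stats_list})
    fcmat = pd.DataFrame({s.study_id: s.table["log2fc"] for s in stats_list})
    wmat = pd.DataFrame(
        {s.study_id: s.table["n_pos"] + s.table["n_neg"] for s in stats_list}
    ).astype(float)
    if equal_weights:
        wmat = wmat.where(wmat.isna(), 1.0)

    k = pmat.notna().sum(axis=1)
    keep = k >= min_studies
    pmat, fcmat, wmat, k = pmat[keep], fcmat[keep], wmat[keep], k[keep]
    if pmat.empty:
        raise ErgMetaError(
            f"combine_studies: no gene measured in >= {min_studies} studies"
        )

    logp = np.log(np.clip(pmat.to_numpy(dtype=float), P_FLOOR, None))
    x = -2.0 * np.nansum(logp, axis=1)
    p_chisq = stats.chi2.sf(x, 2 * k.to_numpy())
    p_chisq = np.clip(p_chisq, P_DEGENERATE, 1.0)

    w = wmat.to_numpy(dtype=float)
    f = fcmat.to_numpy(dtype=float)
    wsum = np.nansum(w, axis=1)
    wfc = np.nansum(w * f, axis=1) / wsum

    out = pd.DataFrame(
        {
            "n_studies": k.astype(int),
            "weighted_log2fc": wfc,
            "linear_fc": 2.0 ** np.abs(wfc),
            "direction": np.sign(wfc).astype(int),
            "fisher_stat": x,
            "p_chisq": p_chisq,
            "p_perm": np.nan,
            "p_adj": bh_adjust(p_chisq),
        },
        index=pmat.index,
    )
    out.index.name = "gene_id"
    return out.sort_index()


# ---------------------------------------------------------------------------
# permutational summary p
# ---------------------------------------------------------------------------


def _gene_groups(
    studies: Sequence[tuple[StudyMatrix, GroupAssignment]], gene: str
) -> list[tuple[np.ndarray, int]]:
    """Per study: the pooled non-missing values (positive first) and n_pos."""
    out = []
    for study, groups in studies:
        if gene not in study.values.index:
            continue
        row = study.values.loc[gene]
        pos = row[[s for s in groups.positives if s in row.index]].dropna()
        neg = row[[s for s in groups.negatives if s in row.index]].dropna()
        if len(pos) < 2 or len(neg) < 2:
            raise ErgMetaError(
                f"study {study.study_id!r}, gene {gene!r}: degenerate groups "
                f"({len(pos)} vs {len(neg)} usable values)"
            )
        out.append((np.concatenate([pos.to_numpy(), neg.to_numpy()]), len(pos)))
    if not out:
        raise ErgMetaError(f"gene {gene!r} measured in no study")
    return out


def _welch_p_rows(values: np.ndarray, n_pos: int) -> np.ndarray:
    """Welch p per row of a (B, n) matrix split at column n_pos."""
    a, b = values[:, :n_pos], values[:, n_pos:]
    return _welch_from_moments(
        a.mean(axis=1),
        a.var(axis=1, ddof=1),
        a.shape[1],
        b.mean(axis=1),
        b.var(axis=1, ddof=1),
        b.shape[1],
    )


def _count_splits(groups: list[tuple[np.ndarray, int]]) -> float:
    total = 1.0
    for vals, n_pos in groups:
        total *= math.comb(len(vals), n_pos)
    return total


def permutation_combined_p(
    studies: Sequence[tuple[StudyMatrix, GroupAssignment]],
    gene: str,
    B: int,
    seed: int,
    method: str = "auto",
    max_exhaustive: int = 250_000,
) -> float:
    """Permutational summary p-value for one gene.

    Group labels are permuted independently within each study (preserving
    group sizes); per-study Welch p-values and the Fisher statistic X_b are
    recomputed for each of B permutations, and

        p_perm = (1 + #{X_b >= X_obs}) / (B + 1).

    When ``method="auto"`` and the number of distinct within-study label
    splits is at most B, all splits are enumerated instead and the p-value
    is the exact fraction #{X_b >= X_obs} / N (the observed split included).
    One master seed spawns a per-study stream, so results are reproducible.
    """
    if B < 1:
        raise ErgMetaError("permutation_combined_p: B must be >= 1")
    if method not in ("auto", "sample", "exhaustive"):
        raise ErgMetaError(f"unknown permutation method {method!r}")
    groups = _gene_groups(studies, gene)

    # observed Fisher statistic from the unpermuted split
    x_obs = 0.0
    for vals, n_pos in groups:
        p = _welch_p_rows(vals[None, :], n_pos)[0]
        x_obs += -2.0 * math.log(max(p, P_FLOOR))

    n_splits = _count_splits(groups)
    if method == "exhaustive" or (method == "auto" and n_splits <= B):
        if n_splits > max_exhaustive:
            raise ErgMetaError(
                f"exhaustive enumeration over {n_splits:.3g} splits exceeds "
                f"the cap of {max_exhaustive}"
            )
        x_all = np.zeros(1)
        for vals, n_pos in groups:
            idx_all = np.array(
                list(combinations(range(len(vals)), n_pos)), dtype=int
            )
            rest = np.array(
                [sorted(set(range(len(vals))) - set(c)) for c in idx_all], dtype=int
            )
            arranged = np.concatenate([vals[idx_all], vals[rest]], axis=1)
            p = _welch_p_rows(arranged, n_pos)
            contrib = -2.0 * np.log(np.clip(p, P_FLOOR, None))
            x_all = (x_all[:, None] + contrib[None, :]).ravel()
        count = int(np.sum(x_all >= x_obs - _PERM_EPS))
        return count / len(x_all)

    ss = np.random.SeedSequence(seed).spawn(len(groups))
    x_b = np.zeros(B)
    for (vals, n_pos), s in zip(groups, ss):
        rng = np.random.default_rng(s)
        perm = rng.permuted(np.tile(vals, (B, 1)), axis=1)
        p = _welch_p_rows(perm, n_pos)
        x_b += -2.0 * np.log(np.clip(p, P_FLOOR, None))
    count = int(np.sum(x_b >= x_obs - _PERM_EPS))
    return (1 + count) / (B + 1)


def add_permutation_p(
    meta: pd.DataFrame,
    studies: Sequence[tuple[StudyMatrix, GroupAssignment]],
    B: int,
    seed: int,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fill the ``p_perm`` column of a meta table (all genes, or a subset).

    Per-gene seeds are derived from the master seed so the result does not
    depend on the order or choice of genes.
    """
    target = list(meta.index if genes is None else genes)
    out = meta.copy()
    base = np.random.SeedSequence(seed)
    for g in target:
        # stable per-gene substream keyed by the gene's position in the table
        gene_seed = np.random.SeedSequence(
            entropy=base.entropy, spawn_key=(int(meta.index.get_loc(g)),)
        )
        child = np.random.default_rng(gene_seed).integers(0, 2**31 - 1)
        out.loc[g, "p_perm"] = permutation_combined_p(
            studies, g, B=B, seed=int(child)
        )
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_signature(
    meta: pd.DataFrame, fc_threshold: float, adj_p_threshold: float
) -> Signature:
    """Genes with linear_fc strictly above ``fc_threshold`` and p_adj
    strictly below ``adj_p_threshold``, split into up/down by direction."""
    if fc_threshold <= 1:
        raise ErgMetaError("fc_threshold must be > 1")
    if not (0 < adj_p_threshold <= 1):
        raise ErgMetaError("adj_p_threshold must lie in (0, 1]")
    if meta.empty:
        sub = meta
    else:
        sub = meta[
            (meta["linear_fc"] > fc_threshold) & (meta["p_adj"] < adj_p_threshold)
        ]
    table = sub[["direction", "weighted_log2fc", "linear_fc", "p_adj"]].copy()
    return Signature(
        fc_threshold=fc_threshold, adj_p_threshold=adj_p_threshold, table=table
    )


def volcano_table(meta: pd.DataFrame, signature: Signature) -> pd.DataFrame:
    """Per-gene volcano-plot export: log2fc, -log10 adjusted p, membership flag."""
    out = pd.DataFrame(
        {
            "weighted_log2fc": meta["weighted_log2fc"],
            "neg_log10_p_adj": -np.log10(meta["p_adj"]),
            "in_signature": meta.index.isin(signature.table.index),
        },
        index=meta.index,
    )
    out.index.name = "gene_id"
    return out
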