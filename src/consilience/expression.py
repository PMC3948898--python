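"""Two-class differential expression with permutation FDR, and enrichment filters.

Implements a SAM-style (significance-analysis-of-microarrays) workflow for a
two-class unpaired design on log2 expression data:

* per-gene moderated statistic d_i = (mean2 - mean1) / (s_i + s0), where s_i
  is the pooled standard error of the mean difference and s0 is a fudge
  constant (here the median of all s_i) stabilising small variances;
* permutation null over class-label reassignments; the FDR at a threshold
  delta is estimated as the median number of null exceedances divided by the
  observed number of exceedances;
* delta is the smallest value on the observed |d| grid whose estimated FDR
  is within the bound (default 5%), and flagged genes must additionally
  change at least ``min_fold``-fold (default 2.0) in either direction.

Downstream context filtering intersects gene sets with the union of
differential gene sets, and annotation terms are kept when the
hypergeometric upper-tail p-value is below 0.05 and the fold enrichment is
at least 2.0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .mti import normalize_gene

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DeResult",
    "EnrichmentResult",
    "normalize_log2",
    "sam_statistics",
    "de_filter",
    "context_filter",
    "enrichment_test",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples matrix of log2 intensities with two-class labels.

    ``classes`` maps each sample (column) to its class label; class order is
    the order of first appearance, and fold changes are class2 / class1.
    """

    data: pd.DataFrame
    classes: pd.Series

    def __post_init__(self):
        classes = pd.Series(self.classes)
        object.__setattr__(self, "classes", classes)
        if list(classes.index) != list(self.data.columns):
            raise ValueError("class labels must be indexed by the sample columns")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")
        counts = classes.value_counts()
        if (counts < 2).any():
            raise ValueError("each class needs at least 2 samples")

    @property
    def class_order(self) -> tuple:
        seen = []
        for c in self.classes:
            if c not in seen:
                seen.append(c)
        return tuple(seen)


def normalize_log2(raw: pd.DataFrame, classes: pd.Series) -> ExpressionMatrix:
    """Log2-transform a positive raw matrix and median-center each sample.

    Per-sample median centering is the minimal normalisation removing
    array-level intensity shifts; a sample scaled by a constant factor has
    that factor removed exactly.
    """
    values = raw.to_numpy(dtype=float)
    if not np.all(values > 0):
        raise ValueError("raw intensities must be strictly positive")
    logged = np.log2(values)
    centered = logged - np.median(logged, axis=0, keepdims=True)
    return ExpressionMatrix(
        data=pd.DataFrame(centered, index=raw.index, columns=raw.columns),
        classes=classes,
    )


def _class_indices(em: ExpressionMatrix) -> tuple:
    order = em.class_order
    if len(order) != 2:
        raise ValueError(f"expected exactly two classes, got {order}")
    labels = em.classes.to_numpy()
    idx1 = np.flatnonzero(labels == order[0])
    idx2 = np.flatnonzero(labels == order[1])
    return idx1, idx2


def _d_stat(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, s0: float):
    """Vectorised d statistic and components for one label assignment."""
    n1, n2 = idx1.size, idx2.size
    m1 = x[:, idx1].mean(axis=1)
    m2 = x[:, idx2].mean(axis=1)
    ss = ((x[:, idx1] - m1[:, None]) ** 2).sum(axis=1) + (
        (x[:, idx2] - m2[:, None]) ** 2
    ).sum(axis=1)
    pooled_var = ss / (n1 + n2 - 2)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m2 - m1) / (s + s0)
    return d, m2 - m1, s


def sam_statistics(em: ExpressionMatrix, s0: Optional[float] = None) -> pd.DataFrame:
    """Per-gene moderated d statistic and linear fold change.

    d_i = (mean2 - mean1)/(s_i + s0) with s_i the pooled standard error of
    the mean difference; s0 defaults to the median of all s_i.  Fold change
    is 2^(mean2 - mean1) since the data are log2.
    """
    idx1, idx2 = _class_indices(em)
    x = em.data.to_numpy(dtype=float)
    _, diff, s = _d_stat(x, idx1, idx2, 0.0)
    if s0 is None:
        s0 = float(np.median(s))
    d = diff / (s + s0)
    return pd.DataFrame(
        {"d": d, "fold_change": 2.0 ** diff, "s": s},
        index=em.data.index,
    ).assign(s0=s0)


def _label_permutations(n: int, n1: int, n_perm: int, rng: np.random.Generator):
    """Distinct two-class label assignments: exhaustive if few, sampled otherwise."""
    total = math.comb(n, n1)
    if total <= n_perm:
        return [np.array(c) for c in itertools.combinations(range(n), n1)]
    cols = np.arange(n)
    return [np.sort(rng.permutation(cols)[:n1]) for _ in range(n_perm)]


@dataclass(frozen=True)
class DeResult:
    """Differential-expression call: per-gene table plus the fitted threshold.

    ``table`` has columns d, fold_change, significant; ``delta`` is the
    chosen |d| threshold (None when no grid value met the FDR bound),
    ``fdr`` its estimated false discovery rate, ``s0`` the fudge constant.
    """

    table: pd.DataFrame
    delta: Optional[float]
    fdr: Optional[float]
    s0: float
    n_permutations: int

    @property
    def significant_genes(self) -> frozenset:
        return frozenset(self.table.index[self.table["significant"]])


def de_filter(
    em: ExpressionMatrix,
    min_fold: float = 2.0,
    fdr_max: float = 0.05,
    n_perm: int = 200,
    seed: Optional[int] = None,
) -> DeResult:
    """Flag differential genes at a permutation-estimated FDR with a fold floor.

    The delta grid is the sorted unique |d| values; the chosen delta is the
    smallest one whose estimated FDR (median null exceedances / observed
    exceedances) is <= ``fdr_max``.  Genes are flagged when |d| >= delta AND
    the fold change is >= ``min_fold`` or <= 1/``min_fold``; ``min_fold`` of
    1.0 disables the fold criterion.  When <= ``n_perm`` distinct label
    assignments exist they are enumerated exhaustively, otherwise ``n_perm``
    are sampled with the given seed.  If no delta meets the bound the
    significant set is empty (logged, not an error).
    """
    if n_perm < 50:
        raise ValueError("need at least 50 permutations for a stable FDR estimate")
    idx1, idx2 = _class_indices(em)
    x = em.data.to_numpy(dtype=float)
    stats = sam_statistics(em)
    s0 = float(stats["s0"].iloc[0])
    d_obs = stats["d"].to_numpy()
    abs_obs = np.sort(np.abs(d_obs))

    rng = np.random.default_rng(seed)
    n = x.shape[1]
    all_cols = np.arange(n)
    perms = _label_permutations(n, idx1.size, n_perm, rng)
    null_sorted = []
    for p1 in perms:
        p2 = np.setdiff1d(all_cols, p1)
        d_null, _, _ = _d_stat(x, p1, p2, s0)
        null_sorted.append(np.sort(np.abs(d_null)))
    null_sorted = np.asarray(null_sorted)  # (P, G), each row sorted

    n_genes = d_obs.size
    grid = np.unique(abs_obs)
    # counts of exceedances |d| >= delta for observed and each permutation
    obs_counts = n_genes - np.searchsorted(abs_obs, grid, side="left")
    null_counts = n_genes - np.vstack(
        [np.searchsorted(row, grid, side="left") for row in null_sorted]
    )
    med_null = np.median(null_counts, axis=0)
    fdr_est = med_null / obs_counts  # obs_counts >= 1 on the grid by construction

    ok = np.flatnonzero(fdr_est <= fdr_max)
    if ok.size == 0:
        logger.info("no delta met the FDR bound %.3g; significant set empty", fdr_max)
        delta, fdr = None, None
        flagged = np.zeros(n_genes, dtype=bool)
    else:
        i = ok[0]
        delta, fdr = float(grid[i]), float(fdr_est[i])
        flagged = np.abs(d_obs) >= delta
    fc = stats["fold_change"].to_numpy()
    if min_fold > 1.0:
        flagged = flagged & ((fc >= min_fold) | (fc <= 1.0 / min_fold))
    table = stats[["d", "fold_change"]].assign(significant=flagged)
    return DeResult(table=table, delta=delta, fdr=fdr, s0=s0, n_permutations=len(perms))


def context_filter(gene_set: Iterable, differential_sets: Sequence[Iterable]) -> frozenset:
    """Keep only genes appearing in at least one differential gene set.

    Implements the tissue-context confirmation step: candidate targets absent
    from every differential set are excluded.  Symbols are normalised before
    intersection; the operation is idempotent and monotone in both arguments.
    """
    genes = {normalize_gene(g) for g in gene_set}
    union: set = set()
    for s in differential_sets:
        union |= {normalize_gene(g) for g in s}
    return frozenset(genes & union)


@dataclass(frozen=True)
class EnrichmentResult:
    """One annotation term's over-representation in a study set."""

    term: str
    k: int  # term hits in the study set
    n: int  # study-set size
    K: int  # term hits in the universe
    N: int  # universe size
    fold_enrichment: float
    p_value: float

    def __post_init__(self):
        if self.k > min(self.n, self.K):
            raise ValueError("term hits exceed study or universe membership")


def enrichment_test(
    study_set: Iterable,
    term_map: Mapping[str, Iterable],
    universe: Iterable,
    alpha: float = 0.05,
    min_fold_enrichment: float = 2.0,
    filtered: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test with a fold-enrichment floor.

    For each term with K genes in the N-gene universe and k hits in the
    n-gene study set, p = P(X >= k) under sampling without replacement and
    fold enrichment = (k/n)/(K/N).  With ``filtered`` (default) only terms
    with p < ``alpha`` AND fold enrichment >= ``min_fold_enrichment`` are
    returned; otherwise all terms are, sorted by p.
    """
    uni = {normalize_gene(g) for g in universe}
    study = {normalize_gene(g) for g in study_set}
    if not study:
        raise ValueError("study set is empty")
    if not study <= uni:
        raise ValueError("study set is not a subset of the universe")
    N, n = len(uni), len(study)
    results = []
    for term, genes in term_map.items():
        members = {normalize_gene(g) for g in genes} & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fe = (k / n) / (K / N)
        results.append(
            EnrichmentResult(
                term=str(term), k=k, n=n, K=K, N=N,
                fold_enrichment=fe, p_value=p,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if filtered:
        results = [
            r for r in results
            if r.p_value < alpha and r.fold_enrichment >= min_fold_enrichment
        ]
    return results
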