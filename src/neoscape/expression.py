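"""Single-sample GSEA with permutation significance and outlier calling.

Per-sample enrichment scores follow the single-sample GSEA statistic: for
each sample, genes are ranked by expression; the score of a gene set is the
summed difference between the weighted in-set empirical CDF (rank weights
raised to ``tau``, default 0.25) and the uniform out-of-set ECDF over the
descending-expression ordering.  Scores are normalized across the whole
matrix by the global score range (conventional absolute-range ssGSEA
normalization).

Significance of a set in a sample is empirical: its score is compared with
the scores of randomly drawn gene sets of identical size (10,000 draws at
production settings) taken from the full expression universe, with an
add-one upper-tail p and Benjamini-Hochberg correction across sets per
sample.  A sample is an outlier for a set when q < 0.05 and its enrichment
score shows at least a +/-1 log2 change relative to the median score of the
other samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .immune_assoc import bh_adjust

DEFAULT_TAU = 0.25
DEFAULT_N_PERM = 10_000
Q_MAX = 0.05
MIN_ABS_DELTA = 1.0


class ExpressionError(ValueError):
    pass


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (set name, description, genes...)."""
    import gseapy

    return gseapy.read_gmt(str(path))


def filter_gene_sets(
    gene_sets: dict[str, list[str]], universe, min_size: int = 2
) -> dict[str, list[str]]:
    """Intersect sets with the expression universe; drop undersized sets."""
    universe = set(universe)
    out = {}
    for name, genes in gene_sets.items():
        kept = [g for g in genes if g in universe]
        if len(kept) >= min_size:
            out[name] = kept
        else:
            warnings.warn(f"gene set {name!r} has < {min_size} genes on the array",
                          stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Enrichment scores
# ---------------------------------------------------------------------------

def _sample_rank_arrays(x: np.ndarray, tau: float):
    """Per-sample precomputation for the running-sum statistic.

    Returns (weights, coverage) per gene, where coverage[g] is the number
    of positions of the descending-expression ordering at which gene g has
    already been passed (N - 0-based position), and weights are expression
    ranks raised to tau.  Ties in expression are broken by gene index so
    scores are deterministic.
    """
    n = x.size
    ranks = stats.rankdata(x, method="average")
    order = np.lexsort((np.arange(n), -x))  # descending x, stable in gene index
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    coverage = (n - pos).astype(np.float64)
    weights = ranks.astype(np.float64) ** tau
    return weights, coverage


def _es_from_indices(
    idx: np.ndarray, weights: np.ndarray, coverage: np.ndarray, n_genes: int
) -> np.ndarray:
    """Enrichment scores for one or many gene sets given as index arrays.

    ``idx`` has shape (..., set_size).  The value equals the sum over all
    ordering positions of (weighted in-set ECDF - uniform out-of-set ECDF);
    summing each gene's contribution over the positions that include it
    collapses the running sum to an O(set size) expression.
    """
    idx = np.atleast_2d(idx)
    k = idx.shape[-1]
    if k >= n_genes:
        raise ExpressionError("gene set size must be smaller than the universe")
    w = weights[idx]
    cov = coverage[idx]
    w_total = w.sum(axis=-1)
    sum_pin = (w * cov).sum(axis=-1) / w_total
    t_all = n_genes * (n_genes + 1) / 2.0
    sum_pout = (t_all - cov.sum(axis=-1)) / (n_genes - k)
    return sum_pin - sum_pout


def ssgsea_scores(
    expr: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    tau: float = DEFAULT_TAU,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-set, per-sample single-sample GSEA enrichment scores.

    ``expr`` is genes x samples (log-scale expression, one row per gene).
    Sets are intersected with the gene universe; an empty intersection
    skips the set with a warning.  With ``normalize`` the score matrix is
    divided by its global range (max - min over all sets and samples).
    """
    gene_index = {g: i for i, g in enumerate(expr.index)}
    x = expr.to_numpy(dtype=float)
    n_genes = x.shape[0]
    per_sample = [_sample_rank_arrays(x[:, j], tau) for j in range(x.shape[1])]
    rows = {}
    for name, genes in gene_sets.items():
        idx = np.array([gene_index[g] for g in set(genes) if g in gene_index])
        if idx.size == 0:
            warnings.warn(f"gene set {name!r} has no genes on the array; skipped",
                          stacklevel=2)
            continue
        rows[name] = [
            float(_es_from_indices(idx, w, cov, n_genes)[0])
            for (w, cov) in per_sample
        ]
    es = pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)
    if normalize and es.size:
        rng_ = es.to_numpy().max() - es.to_numpy().min()
        if rng_ > 0:
            es = es / rng_
    return es


def running_sum_es(
    expr_col: pd.Series, genes, tau: float = DEFAULT_TAU
) -> float:
    """Explicit running-sum evaluation of the enrichment score (one sample).

    Readable O(N) reference path for the same statistic as
    :func:`ssgsea_scores`; useful for audit.
    """
    x = expr_col.to_numpy(dtype=float)
    n = x.size
    in_set = np.array([g in set(genes) for g in expr_col.index])
    weights, _ = _sample_rank_arrays(x, tau)
    order = np.lexsort((np.arange(n), -x))
    w_sorted = np.where(in_set[order], weights[order], 0.0)
    p_in = np.cumsum(w_sorted) / w_sorted.sum()
    out_sorted = (~in_set[order]).astype(float)
    p_out = np.cumsum(out_sorted) / out_sorted.sum()
    return float(np.sum(p_in - p_out))


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def permutation_gene_set_p(
    expr: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    tau: float = DEFAULT_TAU,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Empirical significance of enrichment scores via random same-size sets.

    For each real set, ``n_perm`` gene sets of identical size are drawn
    uniformly from all genes on the array and scored; the upper-tail
    (``alternative="greater"``, matching an upregulation analysis) or
    two-sided empirical p uses the add-one convention
    ``(1 + #{null >= obs}) / (n_perm + 1)``.  BH correction runs across
    sets within each sample.

    Returns (raw ES, p, q) DataFrames, sets x samples.
    """
    if n_perm < 100:
        raise ExpressionError("n_perm must be >= 100")
    if alternative not in ("greater", "two-sided"):
        raise ExpressionError("alternative must be 'greater' or 'two-sided'")
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(expr.index)}
    x = expr.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    per_sample = [_sample_rank_arrays(x[:, j], tau) for j in range(n_samples)]

    es = ssgsea_scores(expr, gene_sets, tau=tau, normalize=False)
    p = pd.DataFrame(index=es.index, columns=es.columns, dtype=float)
    for name in es.index:
        genes = [g for g in set(gene_sets[name]) if g in gene_index]
        k = len(genes)
        if k > n_genes:
            raise ExpressionError(f"gene set {name!r} larger than the universe")
        perm_idx = np.array(
            [rng.choice(n_genes, size=k, replace=False) for _ in range(n_perm)]
        )
        for j, col in enumerate(es.columns):
            w, cov = per_sample[j]
            null = _es_from_indices(perm_idx, w, cov, n_genes)
            obs = es.loc[name, col]
            if alternative == "greater":
                exceed = int(np.sum(null >= obs))
            else:
                exceed = 2 * min(int(np.sum(null >= obs)), int(np.sum(null <= obs)))
            p.loc[name, col] = min(1.0, (exceed + 1) / (n_perm + 1))
    q = p.copy()
    for col in q.columns:
        q[col] = bh_adjust(p[col].to_numpy())
    return es, p, q


# ---------------------------------------------------------------------------
# Outlier rule
# ---------------------------------------------------------------------------

def delta_log2_vs_median(es: pd.DataFrame) -> pd.DataFrame:
    """Per (set, sample) log2 change of the score vs the median of the
    other samples.

    Sign changes are unbounded fold changes: score > 0 with median <= 0
    maps to +inf, score <= 0 with median > 0 to -inf; both non-positive is
    undefined (NaN).
    """
    if es.shape[1] < 3:
        raise ExpressionError("need >= 3 samples (median of the others undefined)")
    out = pd.DataFrame(index=es.index, columns=es.columns, dtype=float)
    values = es.to_numpy(dtype=float)
    for j, col in enumerate(es.columns):
        others = np.delete(values, j, axis=1)
        med = np.median(others, axis=1)
        cur = values[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(
                (cur > 0) & (med > 0),
                np.log2(np.where((cur > 0) & (med > 0), cur / med, 1.0)),
                np.where(
                    (cur > 0) & (med <= 0),
                    np.inf,
                    np.where((cur <= 0) & (med > 0), -np.inf, np.nan),
                ),
            )
        out[col] = delta
    return out


def call_outliers(
    es: pd.DataFrame,
    q: pd.DataFrame,
    q_max: float = Q_MAX,
    min_abs_delta: float = MIN_ABS_DELTA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag (set, sample) outliers: significant AND strongly deviating.

    A sample is flagged for a set when its BH q-value is below ``q_max``
    and the absolute log2 change of its enrichment score relative to the
    median of the other samples is at least ``min_abs_delta``.

    Returns (boolean flags, delta) DataFrames.
    """
    if not es.index.equals(q.index) or not es.columns.equals(q.columns):
        raise ExpressionError("ES and q matrices must be aligned")
    delta = delta_log2_vs_median(es)
    flags = (q < q_max) & (delta.abs() >= min_abs_delta)
    return flags.fillna(False).astype(bool), delta


# ---------------------------------------------------------------------------
# Coefficient-of-variation gene ranking
# ---------------------------------------------------------------------------

def cv_rank_genes(expr: pd.DataFrame, top_n: int = 50) -> pd.DataFrame:
    """Rank genes by coefficient of variation across samples.

    CV = sample standard deviation / mean per gene; zero-mean genes are
    excluded with a warning.  Descending CV with stable tie-break by gene
    id; requesting more genes than available returns the full ranking with
    a warning.
    """
    mean = expr.mean(axis=1)
    zero = mean == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-mean genes excluded from CV ranking",
            stacklevel=2,
        )
    sub = expr.loc[~zero]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    ranked = (
        pd.DataFrame({"gene": cv.index, "cv": cv.to_numpy()})
        .sort_values(["cv", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    if top_n > len(ranked):
        warnings.warn(
            f"top_n={top_n} exceeds {len(ranked)} rankable genes; returning all",
            stacklevel=2,
        )
        return ranked
    return ranked.head(top_n).reset_index(drop=True)
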