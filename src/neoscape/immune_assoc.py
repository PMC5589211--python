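"""Clonality-immunogenicity association and TCR differential abundance.

Statistical comparisons used downstream of the neoepitope pipeline:

* a binomial GLM ``immunogenic ~ clonality + hla_binding`` relating the
  sign rule on immunogenicity scores (score >= 0) to neoepitope clonality
  and HLA binding affinity (no interaction term: none was detectable),
* Pearson chi-square (no continuity correction) on 2x2 immunogenicity
  contingency tables,
* two-sided Mann-Whitney rank comparisons of absolute scores,
* per-clonotype two-sided exact binomial tests of TCR abundance between
  two repertoires with Benjamini-Hochberg correction (q < 0.01
  significance threshold by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

TCR_Q_THRESHOLD = 0.01


class AssociationError(ValueError):
    pass


@dataclass
class GlmResult:
    converged: bool
    n: int
    coefficients: dict[str, float] | None = None
    std_errors: dict[str, float] | None = None
    p_values: dict[str, float] | None = None


def fit_binomial_glm(
    observations: pd.DataFrame,
    log10_binding: bool = False,
    min_per_level: int = 10,
) -> GlmResult:
    """Logistic model of immunogenicity on clonality and HLA binding.

    ``observations`` needs columns ``immunogenic`` (bool; the score >= 0
    sign rule applied upstream), ``clonal`` (bool/0-1) and ``hla_binding``
    (IC50 in nM; set ``log10_binding`` to model log10 nM instead).  Fitted
    by iteratively reweighted least squares.  Complete separation or other
    non-convergence returns a flagged result without coefficients.
    """
    df = observations.copy()
    for col in ("immunogenic", "clonal", "hla_binding"):
        if col not in df.columns:
            raise AssociationError(f"observations missing column {col!r}")
    y = df["immunogenic"].astype(float).to_numpy()
    clonal = df["clonal"].astype(float).to_numpy()
    for level in (0.0, 1.0):
        if np.sum(clonal == level) < min_per_level:
            raise AssociationError(
                f"need >= {min_per_level} observations per clonality level"
            )
    if y.min() == y.max():
        return GlmResult(converged=False, n=len(y))
    binding = df["hla_binding"].astype(float).to_numpy()
    if log10_binding:
        binding = np.log10(binding)
    X = sm.add_constant(
        pd.DataFrame({"clonality": clonal, "hla_binding": binding})
    )
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception:
        return GlmResult(converged=False, n=len(y))
    if not fit.converged or np.abs(fit.params).max() > 1e6:
        return GlmResult(converged=False, n=len(y))
    names = {"const": "intercept", "clonality": "clonality", "hla_binding": "hla_binding"}
    return GlmResult(
        converged=True,
        n=len(y),
        coefficients={names[k]: float(v) for k, v in fit.params.items()},
        std_errors={names[k]: float(v) for k, v in fit.bse.items()},
        p_values={names[k]: float(v) for k, v in fit.pvalues.items()},
    )


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no Yates correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise AssociationError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise AssociationError("zero marginal in contingency table")
    stat, p, _, expected = stats.chi2_contingency(t, correction=False)
    if (expected <= 0).any():
        raise AssociationError("zero expected cell count")
    return float(stat), float(p)


def mannwhitney(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have <= ``exact_max_n`` observations
    and no cross-group ties; tie-corrected normal approximation otherwise.
    All values tied across both groups gives p = 1 with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise AssociationError("both groups must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if max(x.size, y.size) <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise AssociationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def tcr_differential_abundance(
    table: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    q_threshold: float = TCR_Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-clonotype differential abundance between two repertoires.

    ``table`` has columns ``clonotype``, ``sample``, ``count``.  For each
    clonotype present in either sample, a two-sided exact binomial test of
    ``count_a`` out of ``total_a`` against the clonotype's frequency in
    sample b; clonotypes absent from b are assigned a pseudo-frequency of
    ``0.5 / total_b`` (the reference frequency convention is stated openly
    since the original tool's internals are proprietary).  BH correction
    runs over all tested clonotypes of this pair.
    """
    for col in ("clonotype", "sample", "count"):
        if col not in table.columns:
            raise AssociationError(f"clonotype table missing column {col!r}")
    counts = (
        table.groupby(["clonotype", "sample"])["count"].sum().unstack(fill_value=0)
    )
    for s in (sample_a, sample_b):
        if s not in counts.columns:
            raise AssociationError(f"sample {s!r} not in clonotype table")
    ca = counts[sample_a]
    cb = counts[sample_b]
    total_a = int(ca.sum())
    total_b = int(cb.sum())
    if total_a == 0 or total_b == 0:
        raise AssociationError("both samples need nonzero totals")
    present = (ca > 0) | (cb > 0)
    rows = []
    for clone in counts.index[present]:
        na = int(ca[clone])
        nb = int(cb[clone])
        ref_freq = nb / total_b if nb > 0 else 0.5 / total_b
        p = stats.binomtest(na, total_a, ref_freq, alternative="two-sided").pvalue
        rows.append((clone, na, nb, na / total_a, nb / total_b, p))
    out = pd.DataFrame(
        rows,
        columns=["clonotype", "count_a", "count_b", "freq_a", "freq_b", "p"],
    )
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < q_threshold
    return out
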