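"""Neoepitope depletion statistic with cohort and permutation nulls.

The statistic asks whether a tumor sample carries fewer predicted
neoepitopes than its silent-mutation spectrum predicts.  Silent mutations
are assumed neutral to immune selection, so the per-class silent counts
``Ss`` (192 trinucleotide-substitution classes) anchor the expectation:

* ``Ns[m]`` — missense mutations per silent mutation in class ``m``,
* ``Bs[m]`` — predicted neoepitopes per missense mutation in class ``m``,

both fitted on the pooled cohort.  For a sample with silent spectrum
``Ss``::

    Npred = sum_m Ss[m] * Ns[m]
    Bpred = sum_m Ss[m] * Ns[m] * Bs[m]
    Expected = Bpred / Npred        Observed = Bobs / Nobs
    R = Observed / Expected         (R < 1 indicates depletion)

Note on ``Bpred``: the source method's printed formula repeats the
``Npred`` summand without the ``Bs`` factor, which is dimensionally
inconsistent (it would predict missense counts, not neoepitope counts);
the ``Bs``-weighted form above is the one implemented.

Classes with a zero denominator (no silent mutations pooled) carry no rate
information and are excluded from all sums rather than smoothed —
pseudo-counts would bias ``R`` on small cohorts.

Significance comes from empirical two-sided p-values (the log2 ratios are
not normally distributed), against either a cohort of reference samples or
sample-specific permutation nulls: mutation-to-sample assignments are
shuffled preserving each sample's total mutation count, 150 pairwise
distinct permutations by default, and each real sample is compared against
its own permutation distribution to control for mutation number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import N_CLASSES

DEFAULT_N_PERM = 150

#: sentinel reported for log2(R) when Bobs == 0 (R == 0)
LOG2R_SENTINEL = -np.inf


class DepletionError(ValueError):
    """Raised on inputs that make the statistic undefined."""


@dataclass
class NullRates:
    """Per-class missense-per-silent (Ns) and neoepitope-per-missense (Bs)."""

    ns: np.ndarray
    bs: np.ndarray
    supported: np.ndarray  # classes with a nonzero silent denominator

    def __post_init__(self) -> None:
        for name in ("ns", "bs", "supported"):
            v = getattr(self, name)
            if len(v) != N_CLASSES:
                raise DepletionError(f"{name} must have length {N_CLASSES}")


@dataclass
class DepletionResult:
    sample: str
    npred: float
    bpred: float
    expected: float
    observed: float
    r: float
    log2r: float
    nobs: int
    bobs: int
    p_empirical: float | None = None


def fit_null_rates(
    silent_counts: np.ndarray,
    missense_counts: np.ndarray,
    neoepitope_counts: np.ndarray,
) -> NullRates:
    """Fit Ns and Bs from pooled per-class counts across all samples.

    ``neoepitope_counts[m]`` is the number of neoepitope-yielding missense
    mutations of class ``m`` (or any per-mutation binder tally applied
    consistently across the cohort).  Classes with zero silent count are
    flagged unsupported; classes with missense but no neoepitopes get a
    valid ``Bs = 0``.
    """
    silent = np.asarray(silent_counts, dtype=float)
    missense = np.asarray(missense_counts, dtype=float)
    neo = np.asarray(neoepitope_counts, dtype=float)
    if not (len(silent) == len(missense) == len(neo) == N_CLASSES):
        raise DepletionError(f"count vectors must have length {N_CLASSES}")
    if (silent < 0).any() or (missense < 0).any() or (neo < 0).any():
        raise DepletionError("counts must be nonnegative")
    supported = silent > 0
    if not supported.any():
        raise DepletionError("no class has a nonzero silent count")
    ns = np.full(N_CLASSES, np.nan)
    bs = np.full(N_CLASSES, np.nan)
    ns[supported] = missense[supported] / silent[supported]
    has_missense = supported & (missense > 0)
    bs[has_missense] = neo[has_missense] / missense[has_missense]
    # no missense in class => the Ss*Ns*Bs term vanishes; set Bs=0 explicitly
    bs[supported & (missense == 0)] = 0.0
    return NullRates(ns=ns, bs=bs, supported=supported)


def predict_expected(
    ss: np.ndarray, rates: NullRates
) -> tuple[float, float, float]:
    """Expected missense (Npred) and neoepitope (Bpred) yield from a silent
    spectrum, and the expected neoepitopes-per-missense rate.

    Sums run over supported classes only.  ``Npred == 0`` (no informative
    silent mutations) is an error.
    """
    ss = np.asarray(ss, dtype=float)
    if len(ss) != N_CLASSES:
        raise DepletionError(f"Ss must have length {N_CLASSES}")
    m = rates.supported
    npred = float(np.sum(ss[m] * rates.ns[m]))
    bpred = float(np.sum(ss[m] * rates.ns[m] * rates.bs[m]))
    if npred == 0:
        raise DepletionError("Npred is zero: no informative silent mutations")
    return npred, bpred, bpred / npred


def depletion_ratio(
    sample: str,
    ss: np.ndarray,
    nobs: int,
    bobs: int,
    rates: NullRates,
) -> DepletionResult:
    """Observed/expected neoepitope-per-missense ratio R for one sample."""
    if nobs <= 0:
        raise DepletionError(f"{sample}: Nobs must be > 0")
    if bobs < 0:
        raise DepletionError(f"{sample}: Bobs must be >= 0")
    npred, bpred, expected = predict_expected(ss, rates)
    if expected == 0:
        raise DepletionError(f"{sample}: expected rate is zero; R undefined")
    observed = bobs / nobs
    r = observed / expected
    if r == 0:
        warnings.warn(
            f"{sample}: Bobs == 0; log2(R) reported as -inf sentinel",
            stacklevel=2,
        )
        log2r = LOG2R_SENTINEL
    else:
        log2r = float(np.log2(r))
    return DepletionResult(
        sample=sample, npred=npred, bpred=bpred, expected=expected,
        observed=observed, r=r, log2r=log2r, nobs=int(nobs), bobs=int(bobs),
    )


def empirical_p(observed_log2r: float, null_log2r) -> float:
    """Two-sided empirical p-value with add-one correction.

    With ``r_le`` null values <= the observation, ``r_ge`` >= it, and ``N``
    null values: ``p = min(1, 2 * (min(r_le, r_ge) + 1) / (N + 1))``.  The
    add-one convention avoids p = 0 from finite nulls.
    """
    null = np.asarray(list(null_log2r), dtype=float)
    if null.size == 0:
        raise DepletionError("empty null distribution")
    if not np.isfinite(null).all():
        raise DepletionError("null distribution contains non-finite values")
    r_le = int(np.sum(null <= observed_log2r))
    r_ge = int(np.sum(null >= observed_log2r))
    return min(1.0, 2.0 * (min(r_le, r_ge) + 1) / (null.size + 1))


# ---------------------------------------------------------------------------
# Cohort-level machinery on occurrence tables
# ---------------------------------------------------------------------------
# The exchange format is an occurrence table: one row per (mutation, sample)
# occurrence with columns sample, class_idx, mclass, is_neoepitope.

def _per_sample_inputs(occ: pd.DataFrame, samples: list[str]):
    """Vectorized per-sample (Ss, Nobs, Bobs) from an occurrence table."""
    sample_codes = pd.Categorical(occ["sample"], categories=samples).codes.astype(
        np.int64
    )
    cls = occ["class_idx"].to_numpy(dtype=np.int64)
    silent = (occ["mclass"] == "silent").to_numpy()
    missense = (occ["mclass"] == "missense").to_numpy()
    neo = missense & occ["is_neoepitope"].to_numpy(dtype=bool)
    n = len(samples)
    flat = sample_codes * N_CLASSES + cls
    ss = np.bincount(flat[silent], minlength=n * N_CLASSES).reshape(n, N_CLASSES)
    nobs = np.bincount(sample_codes[missense], minlength=n)
    bobs = np.bincount(sample_codes[neo], minlength=n)
    return ss, nobs, bobs


def pooled_class_counts(occ: pd.DataFrame):
    """Pooled per-class (silent, missense, neoepitope) occurrence counts."""
    cls = occ["class_idx"].to_numpy(dtype=np.int64)
    silent = (occ["mclass"] == "silent").to_numpy()
    missense = (occ["mclass"] == "missense").to_numpy()
    neo = missense & occ["is_neoepitope"].to_numpy(dtype=bool)
    return (
        np.bincount(cls[silent], minlength=N_CLASSES),
        np.bincount(cls[missense], minlength=N_CLASSES),
        np.bincount(cls[neo], minlength=N_CLASSES),
    )


def cohort_depletion(
    occ: pd.DataFrame, rates: NullRates | None = None
) -> list[DepletionResult]:
    """Depletion ratios for every sample of an occurrence table.

    When ``rates`` is ``None`` the null rates are fitted on the table's own
    pooled counts (the cohort null); supply rates fitted on an external
    reference cohort to measure depletion relative to that reference.
    """
    if rates is None:
        rates = fit_null_rates(*pooled_class_counts(occ))
    samples = sorted(occ["sample"].unique())
    ss, nobs, bobs = _per_sample_inputs(occ, samples)
    return [
        depletion_ratio(s, ss[i], int(nobs[i]), int(bobs[i]), rates)
        for i, s in enumerate(samples)
    ]


def cohort_empirical_p(
    results: list[DepletionResult],
) -> list[DepletionResult]:
    """Cohort null: each sample's log2R tested against all other samples'."""
    log2rs = np.array([r.log2r for r in results])
    for i, res in enumerate(results):
        null = np.delete(log2rs, i)
        null = null[np.isfinite(null)]
        if null.size:
            res.p_empirical = empirical_p(res.log2r, null)
    return results


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def _permutation_key(perm: np.ndarray, boundaries: np.ndarray) -> tuple:
    """Canonical form of an assignment: occurrence ids sorted within each
    sample block (order within a sample is irrelevant)."""
    parts = []
    start = 0
    for end in boundaries:
        block = np.sort(perm[start:end])
        parts.append(tuple(block.tolist()))
        start = end
    return tuple(parts)


def permutation_null(
    occ: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    rates: NullRates | None = None,
    max_draw_factor: int = 50,
    return_keys: bool = False,
) -> tuple[list[DepletionResult], pd.DataFrame] | tuple[
    list[DepletionResult], pd.DataFrame, list[tuple]
]:
    """Sample-specific permutation nulls for the depletion ratio.

    Mutation-to-sample assignments are shuffled preserving each sample's
    total occurrence count; redundant (duplicate) permutations are rejected
    and redrawn until ``n_perm`` pairwise-distinct permutations are
    collected (the identity assignment is a valid draw).  Pooled class
    counts are invariant under reassignment, so the null rates are fitted
    once on the real pooled cohort.  Each real sample's two-sided empirical
    p is computed against its own permutation distribution, controlling for
    its mutation count.

    Returns the per-sample results (with ``p_empirical`` set) and the null
    log2R distributions as a samples x permutations DataFrame for audit;
    with ``return_keys`` the canonical assignment keys are returned as well
    so distinctness can be verified externally.
    """
    samples = sorted(occ["sample"].unique())
    if len(samples) < 2:
        raise DepletionError("permutation null needs >= 2 samples")
    if n_perm < 1:
        raise DepletionError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = fit_null_rates(*pooled_class_counts(occ))

    # occurrence arrays, ordered by sample so blocks are contiguous
    order = np.argsort(
        pd.Categorical(occ["sample"], categories=samples).codes, kind="stable"
    )
    occ_sorted = occ.iloc[order].reset_index(drop=True)
    cls = occ_sorted["class_idx"].to_numpy(dtype=np.int64)
    is_silent = (occ_sorted["mclass"] == "silent").to_numpy()
    is_missense = (occ_sorted["mclass"] == "missense").to_numpy()
    is_neo = is_missense & occ_sorted["is_neoepitope"].to_numpy(dtype=bool)
    totals = occ_sorted["sample"].value_counts().reindex(samples).to_numpy()
    boundaries = np.cumsum(totals)
    n_occ = len(occ_sorted)
    n_samp = len(samples)

    seen: set[tuple] = set()
    keys: list[tuple] = []
    null = np.empty((n_samp, n_perm))
    supported = rates.supported
    ns_bs = rates.ns[supported] * rates.bs[supported]
    ns_only = rates.ns[supported]

    collected = 0
    attempts = 0
    max_attempts = max_draw_factor * n_perm
    while collected < n_perm and attempts < max_attempts:
        attempts += 1
        perm = rng.permutation(n_occ)
        key = _permutation_key(perm, boundaries)
        if key in seen:
            continue
        seen.add(key)
        keys.append(key)
        # per-sample stats under this assignment
        sample_of = np.empty(n_occ, dtype=np.int64)
        start = 0
        for i, end in enumerate(boundaries):
            sample_of[perm[start:end]] = i
            start = end
        flat = sample_of * N_CLASSES + cls
        ss = np.bincount(flat[is_silent], minlength=n_samp * N_CLASSES)
        ss = ss.reshape(n_samp, N_CLASSES)[:, supported]
        nobs = np.bincount(sample_of[is_missense], minlength=n_samp)
        bobs = np.bincount(sample_of[is_neo], minlength=n_samp)
        npred = ss @ ns_only
        bpred = ss @ ns_bs
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = bpred / npred
            observed = bobs / np.maximum(nobs, 1)
            r = observed / expected
            null[:, collected] = np.where(r > 0, np.log2(r), LOG2R_SENTINEL)
        collected += 1

    if collected < n_perm:
        warnings.warn(
            f"only {collected} distinct permutations found (requested {n_perm}); "
            "using all distinct permutations",
            stacklevel=2,
        )
        null = null[:, :collected]

    results = cohort_depletion(occ, rates=rates)
    null_df = pd.DataFrame(null, index=samples)
    for res in results:
        dist = null_df.loc[res.sample].to_numpy()
        finite = dist[np.isfinite(dist)]
        res.p_empirical = empirical_p(res.log2r, finite)
    if return_keys:
        return results, null_df, keys
    return results, null_df


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def normality_report(values) -> pd.DataFrame:
    """Shapiro-Wilk, D'Agostino-Pearson and Kolmogorov-Smirnov diagnostics.

    Advisory only: the empirical-p path never depends on these tests (they
    motivate it — log2 ratios are generally non-normal).
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    rows = []
    if x.size >= 3:
        sw = stats.shapiro(x)
        rows.append(("shapiro_wilk", sw.statistic, sw.pvalue))
    if x.size >= 20:
        dp = stats.normaltest(x)
        rows.append(("dagostino_pearson", dp.statistic, dp.pvalue))
    if x.size >= 3:
        ks = stats.kstest((x - x.mean()) / x.std(ddof=1), "norm")
        rows.append(("kolmogorov_smirnov", ks.statistic, ks.pvalue))
    return pd.DataFrame(rows, columns=["test", "statistic", "p"])


def results_to_frame(results: list[DepletionResult]) -> pd.DataFrame:
    """Rectangular cohort table of depletion results."""
    return pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "nobs": [r.nobs for r in results],
            "bobs": [r.bobs for r in results],
            "npred": [r.npred for r in results],
            "bpred": [r.bpred for r in results],
            "expected": [r.expected for r in results],
            "observed": [r.observed for r in results],
            "R": [r.r for r in results],
            "log2R": [r.log2r for r in results],
            "p_empirical": [r.p_empirical for r in results],
        }
    )
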