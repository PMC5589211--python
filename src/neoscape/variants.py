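"""Somatic mutation organisation for multi-lesion tumor cohorts.

Mutations are single-nucleotide somatic variants carrying their trinucleotide
context on the reference (+) strand.  With 64 possible contexts and 3 possible
alternate bases per context there are 192 substitution classes; no
pyrimidine-strand collapsing is applied (collapsing would halve the space to
96 and break the 64 x 3 arithmetic the depletion statistic relies on).

The class ordering is frozen: contexts lexicographic over {A,C,G,T}, and
within a context the three non-reference alternate bases in alphabetical
order.  Class 0 is AAA->C (context AAA, alt C); class 191 is TTT->G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
N_CLASSES = 192

MCLASSES = ("missense", "silent", "nonsense")

TRUNCAL = "truncal"
SHARED = "shared"
PRIVATE = "private"


class MutationError(ValueError):
    """Raised on malformed mutation input."""


# ---------------------------------------------------------------------------
# 192-class substitution encoding
# ---------------------------------------------------------------------------

def classify_substitution(context: str, alt_base: str) -> int:
    """Encode a (trinucleotide context, alternate base) pair as a class index.

    Parameters
    ----------
    context
        Three bases on the reference strand; the middle base is the
        reference base of the substitution.
    alt_base
        The alternate (mutant) base; must differ from the middle base.

    Returns
    -------
    int
        Class index in ``0..191``.  The map is a bijection onto the 192
        valid (context, alt) pairs.
    """
    context = context.upper()
    alt_base = alt_base.upper()
    if len(context) != 3 or any(b not in BASES for b in context):
        raise MutationError(f"invalid trinucleotide context {context!r}")
    if alt_base not in BASES:
        raise MutationError(f"invalid alternate base {alt_base!r}")
    ref = context[1]
    if alt_base == ref:
        raise MutationError(f"alternate base equals reference base in {context!r}")
    ctx_index = (
        BASES.index(context[0]) * 16
        + BASES.index(context[1]) * 4
        + BASES.index(context[2])
    )
    alts = sorted(b for b in BASES if b != ref)
    return 3 * ctx_index + alts.index(alt_base)


def decode_substitution(class_index: int) -> tuple[str, str]:
    """Inverse of :func:`classify_substitution`."""
    if not 0 <= class_index < N_CLASSES:
        raise MutationError(f"class index {class_index} outside 0..191")
    ctx_index, alt_rank = divmod(class_index, 3)
    i5, rem = divmod(ctx_index, 16)
    iref, i3 = divmod(rem, 4)
    context = BASES[i5] + BASES[iref] + BASES[i3]
    alts = sorted(b for b in BASES if b != context[1])
    return context, alts[alt_rank]


def class_label(class_index: int) -> str:
    """Human-readable label, e.g. ``AAA>ACA`` for context AAA, alt C."""
    context, alt = decode_substitution(class_index)
    return f"{context}>{context[0]}{alt}{context[2]}"


# ---------------------------------------------------------------------------
# Mutation records
# ---------------------------------------------------------------------------

@dataclass
class MutationRecord:
    """One somatic single-nucleotide variant shared across samples.

    ``present_in`` is the set of sample ids carrying the variant; clonality
    is derived from it relative to the full sample set.
    """

    id: str
    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    context: str
    gene: str
    protein_change: str
    mclass: str
    expressed: bool
    present_in: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.context = self.context.upper()
        self.ref_base = self.ref_base.upper()
        self.alt_base = self.alt_base.upper()
        if len(self.context) != 3:
            raise MutationError(f"{self.id}: context must have length 3")
        if self.context[1] != self.ref_base:
            raise MutationError(
                f"{self.id}: context middle base {self.context[1]} != ref {self.ref_base}"
            )
        if self.alt_base == self.ref_base:
            raise MutationError(f"{self.id}: alt equals ref")
        if self.mclass not in MCLASSES:
            raise MutationError(f"{self.id}: unknown mutation class {self.mclass!r}")
        if not self.present_in:
            raise MutationError(f"{self.id}: present_in is empty")
        self.present_in = frozenset(self.present_in)

    @property
    def class_index(self) -> int:
        return classify_substitution(self.context, self.alt_base)


def assign_clonality(mutation: MutationRecord, all_samples: Iterable[str]) -> str:
    """Label a mutation truncal / shared / private relative to the cohort.

    Truncal: present in every sample; private: present in exactly one;
    shared: a strict subset of two or more.
    """
    all_samples = frozenset(all_samples)
    if not mutation.present_in:
        raise MutationError(f"{mutation.id}: present_in is empty")
    if not mutation.present_in <= all_samples:
        raise MutationError(
            f"{mutation.id}: present_in contains samples outside the cohort"
        )
    if mutation.present_in == all_samples:
        return TRUNCAL
    if len(mutation.present_in) == 1:
        return PRIVATE
    return SHARED


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def build_spectrum(
    mutations: Sequence[MutationRecord],
    sample: str | None = None,
    mclass: str | None = None,
    expressed_only: bool = False,
    gene_blacklist: Iterable[str] | None = None,
) -> np.ndarray:
    """Tally mutations into a length-192 substitution-class count vector.

    Parameters
    ----------
    sample
        Restrict to mutations present in this sample; ``None`` pools the
        whole catalog (one count per mutation, not per occurrence).
    mclass
        Restrict to one mutation class (``missense``/``silent``/``nonsense``).
    expressed_only
        Keep only mutations with upstream expression evidence.
    gene_blacklist
        Genes to exclude (e.g. commonly-mutated genes); no default list.
    """
    blacklist = frozenset(gene_blacklist or ())
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    for m in mutations:
        if sample is not None and sample not in m.present_in:
            continue
        if mclass is not None and m.mclass != mclass:
            continue
        if expressed_only and not m.expressed:
            continue
        if m.gene in blacklist:
            continue
        counts[m.class_index] += 1
    return counts


# ---------------------------------------------------------------------------
# Binary presence/absence matrix
# ---------------------------------------------------------------------------

def build_binary_matrix(
    mutations: Sequence[MutationRecord],
    samples: Sequence[str] | None = None,
    include_silent: bool = False,
    outgroup: str | None = None,
) -> pd.DataFrame:
    """Binary presence/absence matrix (rows samples, columns mutations).

    Silent mutations are excluded by default (the tree is built on non-silent
    characters).  An optional all-zero outgroup row (e.g. ``"normal"``) is
    appended for rooting/display.
    """
    if samples is None:
        samples = sorted({s for m in mutations for s in m.present_in})
    if len(samples) < 2:
        raise MutationError("binary matrix needs at least 2 samples")
    kept = [m for m in mutations if include_silent or m.mclass != "silent"]
    if not kept:
        raise MutationError("no non-silent mutations to build a matrix from")
    data = {
        m.id: [1 if s in m.present_in else 0 for s in samples] for m in kept
    }
    matrix = pd.DataFrame(data, index=list(samples), dtype=np.int8)
    if outgroup is not None:
        matrix.loc[outgroup] = 0
    return matrix


# ---------------------------------------------------------------------------
# Copy-number event calling
# ---------------------------------------------------------------------------

def call_cna_events(segments: pd.DataFrame, value_col: str = "log_ratio") -> pd.DataFrame:
    """Call amplified/deleted/neutral segments by a +/- 2 MAD rule.

    Per sample, a segment is amplified when its log-ratio is at least
    ``median + 2*MAD`` and deleted when at most ``median - 2*MAD``; the MAD
    is the unscaled median absolute deviation of that sample's segment
    values.  Requires >= 3 finite segment values per sample and a nonzero
    MAD (a degenerate, constant distribution cannot be thresholded).
    """
    required = {"sample", "chrom", "start", "end", value_col}
    missing = required - set(segments.columns)
    if missing:
        raise MutationError(f"segment table missing columns: {sorted(missing)}")
    if (segments["start"] >= segments["end"]).any():
        raise MutationError("segment start must be < end")
    out = segments.copy()
    out["call"] = "neutral"
    for sample, grp in segments.groupby("sample"):
        values = grp[value_col].to_numpy(dtype=float)
        if np.sum(np.isfinite(values)) < 3:
            raise MutationError(f"sample {sample}: need >= 3 finite segment values")
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        if mad == 0:
            raise MutationError(
                f"sample {sample}: MAD is zero (degenerate copy-number distribution); "
                "cannot apply the +/-2 MAD rule"
            )
        amp = values >= med + 2 * mad
        dele = values <= med - 2 * mad
        out.loc[grp.index[amp], "call"] = "amplified"
        out.loc[grp.index[dele], "call"] = "deleted"
    return out


# ---------------------------------------------------------------------------
# I/O — MAF-like TSV
# ---------------------------------------------------------------------------

MAF_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "context",
    "gene", "protein_change", "class", "expressed",
]


def read_mutation_table(path) -> list[MutationRecord]:
    """Read a MAF-like TSV (one row per mutation x sample occurrence).

    Rows sharing (chrom, pos, ref, alt) are collapsed into a single
    :class:`MutationRecord` whose ``present_in`` is the union of their
    samples.  Context/ref consistency is validated on construction.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise MutationError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for (chrom, pos, ref, alt), grp in df.groupby(
        ["chrom", "pos", "ref", "alt"], sort=False
    ):
        first = grp.iloc[0]
        records.append(
            MutationRecord(
                id=f"{chrom}:{pos}:{ref}>{alt}",
                chrom=str(chrom),
                pos=int(pos),
                ref_base=str(ref),
                alt_base=str(alt),
                context=str(first["context"]),
                gene=str(first["gene"]),
                protein_change=str(first["protein_change"]),
                mclass=str(first["class"]),
                expressed=str(first["expressed"]).lower() in ("1", "true", "yes"),
                present_in=frozenset(grp["sample"]),
            )
        )
    return records


def mutations_to_table(
    mutations: Sequence[MutationRecord], all_samples: Iterable[str] | None = None
) -> pd.DataFrame:
    """Flatten records to one row per (mutation, sample) occurrence.

    The occurrence table is the exchange format consumed by the depletion
    machinery: columns ``sample``, ``mutation_id``, ``class_idx``,
    ``mclass``, ``expressed``, ``gene``, ``clonality``.
    """
    samples = frozenset(all_samples) if all_samples is not None else frozenset(
        s for m in mutations for s in m.present_in
    )
    rows = []
    for m in mutations:
        clon = assign_clonality(m, samples)
        for s in sorted(m.present_in):
            rows.append(
                (s, m.id, m.class_index, m.mclass, m.expressed, m.gene, clon)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "mutation_id", "class_idx", "mclass",
            "expressed", "gene", "clonality",
        ],
    )


def write_spectrum(counts: np.ndarray, path) -> None:
    """Write a 192-row spectrum TSV (class label, count)."""
    if len(counts) != N_CLASSES:
        raise MutationError("spectrum must have 192 entries")
    pd.DataFrame(
        {"class": [class_label(k) for k in range(N_CLASSES)], "count": counts}
    ).to_csv(path, sep="\t", index=False)
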