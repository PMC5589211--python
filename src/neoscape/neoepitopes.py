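"""Neoepitope candidate generation and HLA binder calling.

For every missense mutation a wild-type and mutant peptide window is cut
from the protein — 17-mers for HLA class I and 29-mers for HLA class II,
with the affected residue in the middle; windows near a terminus are
truncated, never padded.  Candidate epitopes are the 9-mers (HLA-I) or
15-mers (HLA-II) overlapping the mutated residue.

Binder calling follows the affinity-cutoff rules of the analysis this
package reproduces: HLA-I 9-mers are binders when the predicted IC50 is at
or below an allele-specific cutoff (HLA-C alleles, which lack published
cutoffs, fall back to 500 nM); HLA-II 15-mers are binders when the
NetMHCII-style IC50 is <= 500 nM OR the Sturniolo-style percentile rank is
<= 1%.  Affinity prediction itself is external: any callable satisfying
``AffinityPredictor`` can be plugged in (see ``neoscape.synthetic`` for the
deterministic mock used in tests).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Protocol, Sequence

HLA2_IC50_CUTOFF_NM = 500.0
HLA2_RANK_CUTOFF_PCT = 1.0
HLA_C_FALLBACK_NM = 500.0

#: Allele-specific HLA-I IC50 cutoffs (nM).  Values follow the published
#: allele-specific thresholds distributed with the IEDB class-I tools; the
#: table is configuration — callers may supply their own mapping.
DEFAULT_HLA1_CUTOFFS: dict[str, float] = {
    "HLA-A*01:01": 884.0,
    "HLA-A*02:01": 255.0,
    "HLA-A*03:01": 602.0,
    "HLA-A*11:01": 382.0,
    "HLA-A*24:02": 849.0,
    "HLA-B*07:02": 687.0,
    "HLA-B*08:01": 663.0,
    "HLA-B*27:05": 367.0,
    "HLA-B*35:01": 348.0,
    "HLA-B*44:02": 701.0,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class NeoepitopeError(ValueError):
    """Raised on malformed peptide/prediction input."""


def read_protein_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by record id, from a FASTA file."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(proteins: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class PeptideWindow:
    """Matched wild-type/mutant peptide windows around one missense residue."""

    mutation_id: str
    wt_seq: str
    mut_seq: str
    mut_offset: int  # 0-based index of the mutated residue in the window
    window_size_nominal: int

    def __post_init__(self) -> None:
        if len(self.wt_seq) != len(self.mut_seq):
            raise NeoepitopeError(f"{self.mutation_id}: wt/mut window length mismatch")
        diffs = [i for i, (a, b) in enumerate(zip(self.wt_seq, self.mut_seq)) if a != b]
        if diffs != [self.mut_offset]:
            raise NeoepitopeError(
                f"{self.mutation_id}: windows must differ exactly at mut_offset"
            )


@dataclass
class BindingPrediction:
    """One peptide-allele affinity prediction from an external predictor."""

    peptide: str
    allele: str
    ic50: float | None = None
    percentile_rank: float | None = None
    method: str = "netmhc_like"
    is_binder: bool | None = None

    def __post_init__(self) -> None:
        if self.ic50 is not None and self.ic50 <= 0:
            raise NeoepitopeError(f"{self.peptide}/{self.allele}: ic50 must be > 0")
        if self.percentile_rank is not None and not 0 <= self.percentile_rank <= 100:
            raise NeoepitopeError(
                f"{self.peptide}/{self.allele}: percentile rank outside [0, 100]"
            )


class AffinityPredictor(Protocol):
    """Deterministic map from (peptide, allele) to a prediction."""

    def __call__(self, peptide: str, allele: str) -> BindingPrediction: ...


@dataclass
class NeoepitopeRecord:
    """A mutant binder with its paired wild-type affinity and annotations."""

    mutation_id: str
    peptide: str
    allele: str
    mut_ic50: float
    wt_ic50: float | None = None
    clonality: str | None = None
    immunogenicity_score: float | None = None

    @property
    def wt_to_mut_ratio(self) -> float | None:
        """IC50 wild-type / mutant; > 1 means higher mutant affinity."""
        if self.wt_ic50 is None:
            return None
        return self.wt_ic50 / self.mut_ic50

    @property
    def higher_mutant_affinity(self) -> bool | None:
        r = self.wt_to_mut_ratio
        return None if r is None else r > 1


# ---------------------------------------------------------------------------
# Window generation and k-mer enumeration
# ---------------------------------------------------------------------------

def make_window(
    protein: str,
    position: int,
    mut_aa: str,
    size: int = 17,
    mutation_id: str = "",
    wt_aa: str | None = None,
) -> PeptideWindow | None:
    """Cut the wild-type/mutant peptide windows around a missense residue.

    Parameters
    ----------
    protein
        Wild-type protein sequence.
    position
        1-based residue index of the mutated amino acid.
    mut_aa
        Mutant residue; must differ from the wild-type residue.
    size
        Nominal window size (odd; 17 for HLA-I, 29 for HLA-II).  Near a
        terminus the window is truncated to the available sequence.
    wt_aa
        Optional stated wild-type residue; a mismatch with the protein is an
        annotation inconsistency and raises.

    Returns
    -------
    PeptideWindow, or ``None`` when the window contains a non-standard
    residue (U, X, ...), in which case a warning is emitted.
    """
    if size % 2 != 1 or size < 3:
        raise NeoepitopeError("window size must be odd and >= 3")
    if not 1 <= position <= len(protein):
        raise NeoepitopeError(
            f"{mutation_id}: position {position} outside protein of length {len(protein)}"
        )
    ref_aa = protein[position - 1]
    if wt_aa is not None and ref_aa != wt_aa:
        raise NeoepitopeError(
            f"{mutation_id}: protein has {ref_aa} at {position}, annotation says {wt_aa}"
        )
    if mut_aa == ref_aa:
        raise NeoepitopeError(f"{mutation_id}: mutant residue equals wild-type")
    half = (size - 1) // 2
    lo = max(1, position - half)
    hi = min(len(protein), position + half)
    wt_seq = protein[lo - 1 : hi]
    offset = position - lo
    mut_seq = wt_seq[:offset] + mut_aa + wt_seq[offset + 1 :]
    if any(aa not in AMINO_ACIDS for aa in mut_seq) or any(
        aa not in AMINO_ACIDS for aa in wt_seq
    ):
        warnings.warn(
            f"{mutation_id}: window contains a non-standard residue; dropped",
            stacklevel=2,
        )
        return None
    return PeptideWindow(
        mutation_id=mutation_id,
        wt_seq=wt_seq,
        mut_seq=mut_seq,
        mut_offset=offset,
        window_size_nominal=size,
    )


def enumerate_kmers(
    window: PeptideWindow, k: int, mutant: bool = True
) -> list[tuple[str, bool]]:
    """All k-length substrings of a window, flagged for mutation overlap.

    A full 17-mer window yields 9 distinct 9-mer start positions, all of
    which overlap the central mutated residue; truncated windows yield fewer.
    """
    seq = window.mut_seq if mutant else window.wt_seq
    if k > len(seq):
        warnings.warn(
            f"{window.mutation_id}: k={k} exceeds window length {len(seq)}",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(len(seq) - k + 1):
        contains = start <= window.mut_offset < start + k
        out.append((seq[start : start + k], contains))
    return out


def mutant_kmers_with_wt_pairs(
    window: PeptideWindow, k: int
) -> list[tuple[str, str]]:
    """(mutant k-mer, wild-type k-mer) pairs from identical window coordinates,
    restricted to k-mers overlapping the mutated residue."""
    pairs = []
    for start in range(max(0, len(window.mut_seq) - k + 1)):
        if start <= window.mut_offset < start + k:
            pairs.append(
                (window.mut_seq[start : start + k], window.wt_seq[start : start + k])
            )
    return pairs


# ---------------------------------------------------------------------------
# Binder calling
# ---------------------------------------------------------------------------

def _is_hla_c(allele: str) -> bool:
    return allele.upper().startswith(("HLA-C", "C*"))


def call_binders_hla1(
    predictions: Iterable[BindingPrediction],
    cutoffs: Mapping[str, float] | None = None,
) -> list[BindingPrediction]:
    """Set ``is_binder`` on HLA-I predictions by allele-specific IC50 cutoffs.

    A 9-mer is a binder when ``ic50 <= cutoff[allele]`` (inclusive).  HLA-C
    alleles missing from the cutoff table fall back to 500 nM; a missing
    cutoff for any other allele is an error.
    """
    table = DEFAULT_HLA1_CUTOFFS if cutoffs is None else cutoffs
    out = []
    for p in predictions:
        if p.ic50 is None:
            raise NeoepitopeError(f"{p.peptide}/{p.allele}: HLA-I call requires ic50")
        if p.allele in table:
            cutoff = table[p.allele]
        elif _is_hla_c(p.allele):
            cutoff = HLA_C_FALLBACK_NM
        else:
            raise NeoepitopeError(f"no HLA-I cutoff for allele {p.allele}")
        p.is_binder = p.ic50 <= cutoff
        out.append(p)
    return out


def call_binders_hla2(
    ic50: float | None, sturniolo_rank: float | None
) -> bool:
    """HLA-II disjunctive binder rule for one 15-mer/allele pair.

    Binder iff IC50 <= 500 nM OR Sturniolo percentile rank <= 1%.  At least
    one of the two scores must be present.
    """
    if ic50 is None and sturniolo_rank is None:
        raise NeoepitopeError("HLA-II call requires an IC50 or a Sturniolo rank")
    if ic50 is not None and ic50 <= HLA2_IC50_CUTOFF_NM:
        return True
    if sturniolo_rank is not None and sturniolo_rank <= HLA2_RANK_CUTOFF_PCT:
        return True
    return False


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class ImmunogenicityScorer(Protocol):
    def __call__(self, peptide: str, allele: str) -> float: ...


def score_neoepitopes(
    binders: Sequence[BindingPrediction],
    wt_predictions: Mapping[tuple[str, str], BindingPrediction],
    mutation_ids: Mapping[tuple[str, str], str],
    clonality: Mapping[str, str] | None = None,
    scorer: ImmunogenicityScorer | None = None,
) -> list[NeoepitopeRecord]:
    """Attach wild-type affinity ratios and immunogenicity scores to binders.

    ``wt_predictions`` maps (mutant peptide, allele) to the wild-type
    prediction from the same window coordinates; a missing pair yields a
    record with no ratio and a warning.  Duplicate (peptide, allele) pairs
    from repetitive sequence are deduplicated.
    """
    clonality = clonality or {}
    seen: set[tuple[str, str]] = set()
    records = []
    for p in binders:
        key = (p.peptide, p.allele)
        if key in seen:
            continue
        seen.add(key)
        mut_id = mutation_ids.get(key, "")
        wt = wt_predictions.get(key)
        if wt is None:
            warnings.warn(
                f"{p.peptide}/{p.allele}: no paired wild-type prediction",
                stacklevel=2,
            )
        records.append(
            NeoepitopeRecord(
                mutation_id=mut_id,
                peptide=p.peptide,
                allele=p.allele,
                mut_ic50=p.ic50,
                wt_ic50=None if wt is None else wt.ic50,
                clonality=clonality.get(mut_id),
                immunogenicity_score=(
                    None if scorer is None else scorer(p.peptide, p.allele)
                ),
            )
        )
    return records


class MockImmunogenicityScorer:
    """Deterministic position-weighted amino-acid immunogenicity score.

    A stand-in scoring contract for tests: each (residue, position-bucket)
    pair contributes a fixed weight derived from a seeded hash, centred so
    scores straddle zero.  Same (peptide, allele) always yields the same
    score.  This is a synthetic scorer, not a reproduction of any published
    weight table.
    """

    def __init__(self, seed: int = 0) -> None:
        import hashlib

        self._weights: dict[tuple[str, int], float] = {}
        for aa in AMINO_ACIDS:
            for bucket in range(3):  # N-terminal / core / C-terminal
                h = hashlib.blake2b(
                    f"{seed}:{aa}:{bucket}".encode(), digest_size=8
                ).digest()
                u = int.from_bytes(h, "big") / 2**64
                self._weights[(aa, bucket)] = u - 0.5

    def __call__(self, peptide: str, allele: str = "") -> float:
        n = len(peptide)
        total = 0.0
        for i, aa in enumerate(peptide):
            bucket = 0 if i < n // 3 else (2 if i >= n - n // 3 else 1)
            total += self._weights.get((aa, bucket), 0.0)
        return total
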