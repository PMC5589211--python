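"""Synthetic multi-lesion cohorts, expression matrices and TCR repertoires.

Everything the analysis stages consume can be generated here, so the whole
pipeline is testable without any external download:

* mutation catalogs for a cohort of tumor samples, with contexts drawn
  from a configurable 192-class substitution spectrum, silent/missense/
  nonsense labels, truncal/shared/private clonal structure realised by a
  shared trunk, a per-missense neoepitope flag with controllable baseline
  rate, and an injectable immune-depletion strength ``depletion_delta``
  (each neoepitope-yielding missense mutation is removed with that
  probability AFTER labelling, so silent mutations — the expectation's
  anchor — are untouched);
* protein sequences consistent with the catalog's annotated residue
  changes, plus a deterministic hash-based mock affinity predictor whose
  fraction of sub-cutoff peptides is controllable;
* log-scale expression matrices with gene sets and designated
  (set, sample) signal pairs for enrichment-outlier recovery;
* clonotype tables with one designated expanded clone over a power-law
  background.

Depletion is implemented by removal — the mutation is never observed —
matching the immunoediting interpretation, not by affinity re-assignment.
All generators are fully determined by their seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neoepitopes import (
    DEFAULT_HLA1_CUTOFFS,
    HLA_C_FALLBACK_NM,
    AMINO_ACIDS,
    BindingPrediction,
)
from .variants import N_CLASSES, MutationRecord, decode_substitution

IC50_MIN_NM = 1.0
IC50_MAX_NM = 50_000.0


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for a simulated multi-lesion cohort.

    Defaults emulate a modest-burden serous ovarian-like cohort: ~300
    mutations per sample, roughly 30% silent / 65% missense / 5% nonsense,
    a mixed clonal structure with a substantial trunk, and a baseline 15%
    chance that a missense mutation yields at least one predicted binder.
    """

    seed: int
    n_samples: int = 5
    mutations_per_sample: float = 300.0
    truncal_prop: float = 0.3
    shared_prop: float = 0.2
    private_prop: float = 0.5
    spectrum: np.ndarray | None = None  # None -> uniform over 192 classes
    silent_fraction: float = 0.30
    nonsense_fraction: float = 0.05
    binder_rate: float = 0.15
    depletion_delta: float = 0.0
    expressed_fraction: float = 1.0
    protein_length: int = 301

    def __post_init__(self) -> None:
        props = (self.truncal_prop, self.shared_prop, self.private_prop)
        if any(p < 0 for p in props) or not np.isclose(sum(props), 1.0):
            raise SimulationError("clonality proportions must be >= 0 and sum to 1")
        if self.n_samples == 1 and (self.truncal_prop + self.private_prop) < 1:
            raise SimulationError("shared mutations need >= 3 samples")
        for name in ("silent_fraction", "nonsense_fraction", "binder_rate",
                     "depletion_delta", "expressed_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if self.silent_fraction + self.nonsense_fraction >= 1:
            raise SimulationError("silent + nonsense fractions must leave room "
                                  "for missense mutations")
        if self.spectrum is not None:
            s = np.asarray(self.spectrum, dtype=float)
            if s.shape != (N_CLASSES,) or (s < 0).any() or not np.isclose(s.sum(), 1):
                raise SimulationError("spectrum must be a length-192 probability vector")
            self.spectrum = s

    @classmethod
    def reference_cohort(cls, seed: int, n_samples: int = 150,
                         **overrides) -> "SimulationConfig":
        """Conditions for a reference cohort of unrelated tumors.

        Emulates the large independent-patient cohort the null rates are
        anchored to: samples share no mutations (all private), unlike the
        multi-lesion configuration where a truncal/shared structure ties
        the samples together.
        """
        overrides.setdefault("truncal_prop", 0.0)
        overrides.setdefault("shared_prop", 0.0)
        overrides.setdefault("private_prop", 1.0)
        return cls(seed=seed, n_samples=n_samples, **overrides)


@dataclass
class SimulatedCohort:
    """Catalog after depletion plus the pre-depletion reference.

    ``occurrences`` / ``reference_occurrences`` are in the depletion
    exchange format (one row per mutation x sample).  The reference is the
    cohort as it would look with no immune selection; fitting null rates on
    it emulates the large selection-neutral reference cohort the statistic
    is anchored to.
    """

    config: SimulationConfig
    samples: list[str]
    mutations: pd.DataFrame
    occurrences: pd.DataFrame
    reference_occurrences: pd.DataFrame

    def mutation_records(self, reference: bool = False) -> list[MutationRecord]:
        """Catalog as validated MutationRecord objects."""
        df = self.mutations if reference else self.mutations[~self.mutations["depleted"]]
        records = []
        for row in df.itertuples():
            records.append(
                MutationRecord(
                    id=row.mutation_id,
                    chrom=row.chrom,
                    pos=row.pos,
                    ref_base=row.ref,
                    alt_base=row.alt,
                    context=row.context,
                    gene=row.gene,
                    protein_change=row.protein_change,
                    mclass=row.mclass,
                    expressed=row.expressed,
                    present_in=frozenset(row.present_in.split(",")),
                )
            )
        return records


def _expand_occurrences(mut: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for row in mut.itertuples():
        for s in row.present_in.split(","):
            rows.append((s, row.mutation_id, row.class_idx, row.mclass,
                         row.expressed, row.gene, row.clonality,
                         row.is_neoepitope))
    return pd.DataFrame(
        rows,
        columns=["sample", "mutation_id", "class_idx", "mclass", "expressed",
                 "gene", "clonality", "is_neoepitope"],
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a multi-sample somatic mutation catalog under the configured
    spectrum, clonal structure, binder rate and depletion strength."""
    rng = np.random.default_rng(config.seed)
    n_samp = config.n_samples
    samples = [f"S{i:02d}" for i in range(n_samp)]
    spectrum = (
        np.full(N_CLASSES, 1.0 / N_CLASSES)
        if config.spectrum is None
        else config.spectrum
    )

    # expected occurrences contributed per mutation, by clonality
    mean_shared = (2 + max(2, n_samp - 1)) / 2 if n_samp > 3 else 2.0
    exp_occ = (
        config.truncal_prop * n_samp
        + config.shared_prop * (mean_shared if n_samp > 2 else n_samp)
        + config.private_prop * 1.0
    )
    n_mut = max(1, round(n_samp * config.mutations_per_sample / exp_occ))

    cls = rng.choice(N_CLASSES, size=n_mut, p=spectrum)
    mclass = rng.choice(
        ["silent", "nonsense", "missense"],
        size=n_mut,
        p=[
            config.silent_fraction,
            config.nonsense_fraction,
            1 - config.silent_fraction - config.nonsense_fraction,
        ],
    )
    clonality = rng.choice(
        ["truncal", "shared", "private"],
        size=n_mut,
        p=[config.truncal_prop, config.shared_prop, config.private_prop],
    )
    if n_samp == 2:
        clonality[clonality == "shared"] = "truncal"
    expressed = rng.random(n_mut) < config.expressed_fraction
    is_neo = (mclass == "missense") & (rng.random(n_mut) < config.binder_rate)
    depleted = is_neo & (rng.random(n_mut) < config.depletion_delta)

    aa = np.array(list(AMINO_ACIDS))
    rows = []
    for i in range(n_mut):
        context, alt = decode_substitution(int(cls[i]))
        if clonality[i] == "truncal":
            present = samples
        elif clonality[i] == "private":
            present = [samples[rng.integers(n_samp)]]
        else:
            k = int(rng.integers(2, n_samp))  # strict subset of >= 2
            present = sorted(
                np.array(samples)[rng.choice(n_samp, size=k, replace=False)]
            )
        pos_aa = int(rng.integers(1, config.protein_length + 1))
        wt, mut_aa = rng.choice(len(aa), size=2, replace=False)
        rows.append(
            (
                f"M{i:05d}", f"chr{1 + i % 22}", 1000 + i * 100,
                context[1], alt, context, f"G{i:05d}",
                f"{aa[wt]}{pos_aa}{aa[mut_aa]}",
                mclass[i], bool(expressed[i]), ",".join(present),
                clonality[i], int(cls[i]), bool(is_neo[i]), bool(depleted[i]),
            )
        )
    mutations = pd.DataFrame(
        rows,
        columns=["mutation_id", "chrom", "pos", "ref", "alt", "context",
                 "gene", "protein_change", "mclass", "expressed",
                 "present_in", "clonality", "class_idx", "is_neoepitope",
                 "depleted"],
    )
    reference_occ = _expand_occurrences(mutations)
    occ = _expand_occurrences(mutations[~mutations["depleted"]])
    return SimulatedCohort(
        config=config,
        samples=samples,
        mutations=mutations,
        occurrences=occ,
        reference_occurrences=reference_occ,
    )


def simulate_proteins(
    mutations: pd.DataFrame, seed: int, protein_length: int = 301
) -> dict[str, str]:
    """Protein sequences consistent with the catalog's missense annotations.

    One random protein per missense-mutated gene, with the annotated
    wild-type residue placed at the annotated position.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    proteins = {}
    sub = mutations[mutations["mclass"] == "missense"]
    for row in sub.itertuples():
        pc = row.protein_change
        wt, pos = pc[0], int(pc[1:-1])
        length = max(protein_length, pos)
        seq = aa[rng.integers(0, len(aa), size=length)]
        seq[pos - 1] = wt
        proteins[row.gene] = "".join(seq)
    return proteins


# ---------------------------------------------------------------------------
# Mock affinity predictor
# ---------------------------------------------------------------------------

class MockAffinityPredictor:
    """Deterministic hash-based peptide-HLA affinity model.

    Maps (peptide, allele) through a seeded cryptographic hash to a
    log-uniform IC50 on [1, 50000] nM, forcing a ``binder_rate`` fraction
    of peptides under the allele's binder cutoff.  Dependency-free and
    byte-stable: the same (peptide, allele) always yields the same
    prediction.  A synthetic stand-in for an external neural-net or matrix
    predictor — it models no peptide biochemistry.
    """

    def __init__(
        self,
        seed: int = 0,
        binder_rate: float = 0.15,
        cutoffs: dict[str, float] | None = None,
    ) -> None:
        if not 0 <= binder_rate <= 1:
            raise SimulationError("binder_rate must lie in [0, 1]")
        self.seed = seed
        self.binder_rate = binder_rate
        self.cutoffs = DEFAULT_HLA1_CUTOFFS if cutoffs is None else cutoffs

    def _uniform(self, tag: str, peptide: str, allele: str) -> float:
        digest = hashlib.blake2b(
            f"{self.seed}:{tag}:{peptide}:{allele}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(digest, "big") / 2.0**64

    def _cutoff(self, allele: str) -> float:
        return self.cutoffs.get(allele, HLA_C_FALLBACK_NM)

    def __call__(self, peptide: str, allele: str) -> BindingPrediction:
        u = self._uniform("binder", peptide, allele)
        v = self._uniform("ic50", peptide, allele)
        cutoff = self._cutoff(allele)
        if u < self.binder_rate:
            lo, hi = np.log(IC50_MIN_NM), np.log(cutoff)
        else:
            lo, hi = np.log(cutoff), np.log(IC50_MAX_NM)
        ic50 = float(np.exp(lo + v * (hi - lo)))
        return BindingPrediction(
            peptide=peptide,
            allele=allele,
            ic50=ic50,
            percentile_rank=float(u * 100),
            method="netmhc_like",
        )


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Log-scale microarray-like expression with embedded gene-set signal.

    Gene baselines ~ N(baseline_mean, baseline_sd) are shared across
    samples; per-sample noise is N(0, noise_sd); each designated
    (set index, sample index) pair shifts that set's genes by
    ``signal_effect`` log2 units in that sample only.
    """

    seed: int
    n_genes: int = 2000
    n_samples: int = 5
    n_sets: int = 20
    set_size: int = 50
    signal_effect: float = 2.0
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    signal_pairs: list[tuple[int, int]] = field(default_factory=lambda: [(0, 0)])

    def __post_init__(self) -> None:
        if self.n_genes < 10 * self.set_size:
            raise SimulationError("n_genes must be >= 10 x set size")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, dict[str, list[str]], list[tuple[str, str]]]:
    """Expression matrix, gene-set collection and the ground-truth
    (set name, sample id) signal pairs."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    samples = [f"S{i:02d}" for i in range(config.n_samples)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_samples)
    )
    gene_sets = {
        f"SET_{k:02d}": sorted(
            np.array(genes)[
                rng.choice(config.n_genes, size=config.set_size, replace=False)
            ]
        )
        for k in range(config.n_sets)
    }
    gene_pos = {g: i for i, g in enumerate(genes)}
    truth = []
    for set_idx, sample_idx in config.signal_pairs:
        name = f"SET_{set_idx:02d}"
        idx = [gene_pos[g] for g in gene_sets[name]]
        values[idx, sample_idx] += config.signal_effect
        truth.append((name, samples[sample_idx]))
    expr = pd.DataFrame(values, index=genes, columns=samples)
    return expr, gene_sets, truth


# ---------------------------------------------------------------------------
# Clonotype simulation
# ---------------------------------------------------------------------------

def simulate_clonotypes(
    seed: int,
    totals: dict[str, int],
    n_clones: int = 200,
    expanded_clone_freq: float = 0.13,
    expanded_sample: str | None = None,
    background_freq: float = 0.001,
    zipf_exponent: float = 1.5,
) -> tuple[pd.DataFrame, str]:
    """Clonotype count table with one designated expanded clone.

    The designated clone sits at ``expanded_clone_freq`` of the expanded
    sample's repertoire and at ``background_freq`` elsewhere; the remaining
    repertoire follows a power-law (Zipf) clone-size distribution.

    Returns the (clonotype, sample, count) table and the expanded clone's
    CDR3-like identifier.
    """
    if not 0 < expanded_clone_freq < 1:
        raise SimulationError("expanded_clone_freq must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    samples = list(totals)
    if expanded_sample is None:
        expanded_sample = samples[0]
    if expanded_sample not in totals:
        raise SimulationError(f"{expanded_sample!r} not among the sample totals")
    if round(expanded_clone_freq * totals[expanded_sample]) < 1:
        raise SimulationError("total too small to realise the expanded frequency")

    aa = np.array(list(AMINO_ACIDS))
    def cdr3() -> str:
        return "CASS" + "".join(aa[rng.integers(0, len(aa), size=8)]) + "EQYF"

    clones = [cdr3() for _ in range(n_clones)]
    expanded = clones[0]
    zipf = 1.0 / np.arange(1, n_clones) ** zipf_exponent
    zipf /= zipf.sum()
    rows = []
    for s in samples:
        total = totals[s]
        freq = expanded_clone_freq if s == expanded_sample else background_freq
        n_exp = int(round(freq * total))
        background_counts = rng.multinomial(total - n_exp, zipf)
        if n_exp > 0:
            rows.append((expanded, s, n_exp))
        for clone, cnt in zip(clones[1:], background_counts):
            if cnt > 0:
                rows.append((clone, s, int(cnt)))
    return (
        pd.DataFrame(rows, columns=["clonotype", "sample", "count"]),
        expanded,
    )
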