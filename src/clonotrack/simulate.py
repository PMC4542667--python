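"""Synthetic TCR-beta repertoire generator with ground truth.

Builds a latent clone population for one subject and samples it into
bulk-NGS read tables and single-cell tables, so every downstream stage can
be tested against known truth. The latent structure:

* clone sizes follow a discrete power law (Zipf-like) with configurable
  exponent — the accepted stylization of heavy-tailed repertoires;
* a few *designated persistent* clones are pinned at fixed high
  frequencies in every memory-side compartment at every timepoint,
  emulating the persistently dominant memory expansions the pipeline is
  built to detect;
* each remaining clone has a home subset; a compartment contains the
  clones its sorting gate covers (plus a small gate-straddling fraction),
  with mild log-normal compartment-to-compartment jitter;
* synovium holds a random subset of clones (persistent clones always),
  so peripheral-blood/synovium intersection has a known answer.

Bulk sampling applies a per-clone log-normal PCR amplification factor,
draws reads multinomially, then mutates each read's CDR3 with i.i.d.
per-base substitutions (no indels) and re-aggregates into observed
clonotypes. Single-cell sampling is an error-free multinomial draw of
cells — the gold-standard arm. Every sample carries a hidden provenance
channel mapping observed clone keys to true-clone read counts, for
oracle use only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import CompartmentError
from .models import (
    AGGREGATE_SUBSETS,
    CloneKey,
    Clonotype,
    MEMORY_LEAF_SUBSETS,
    PLATFORM_BULK,
    PLATFORM_SINGLE_CELL,
    RepertoireSample,
    is_functional,
    strip_allele,
    subset_covers,
    translate_junction,
)

_BASES = np.array(list("ACGT"))
# Codons that can fill CDR3 interiors without creating a stop in frame.
_SAFE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]
_PHE_CODONS = ("TTT", "TTC")

_V_GENES = [
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-2", "TRBV6-5", "TRBV7-2",
    "TRBV7-9", "TRBV9", "TRBV11-2", "TRBV12-3", "TRBV15", "TRBV19",
    "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28", "TRBV29-1",
    "TRBV30",
]

#: Default true frequencies pinned for designated persistent clones, in rank
#: order (halving ladder from 10%).
DEFAULT_DOMINANT_FREQS = (0.10, 0.05, 0.025, 0.0125, 0.00625)


@dataclass(frozen=True)
class Compartment:
    """One sampled cell population: tissue x sorting gate x timepoint."""

    tissue: str
    subset: str
    timepoint: str

    def sample_id(self, subject_id: str, platform: str) -> str:
        tag = "sc" if platform == PLATFORM_SINGLE_CELL else "ngs"
        return f"{subject_id}_{self.tissue}_{self.subset}_{self.timepoint}_{tag}"


@dataclass
class NoiseModel:
    """Bulk-NGS noise: per-base substitution errors and PCR bias.

    ``substitution_rate`` is errors per base per read (typical NGS-era
    values 1e-3..5e-3); ``pcr_bias_sd`` is the standard deviation of the
    log-normal per-clone amplification factor (0 = unbiased). Both at 0
    reproduce exact multinomial sampling of the truth.
    """

    substitution_rate: float = 0.0
    pcr_bias_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 0.05:
            raise ValueError("substitution_rate outside [0, 0.05]")
        if self.pcr_bias_sd < 0.0:
            raise ValueError("pcr_bias_sd must be >= 0")


@dataclass(frozen=True)
class TrueClone:
    clone_key: CloneKey
    cdr3_nt: str
    v_call: str
    base_frequency: float
    home_subset: str
    in_synovium: bool


@dataclass
class GroundTruth:
    """Latent clone population with per-compartment frequency vectors."""

    subject_id: str
    clones: list[TrueClone]
    compartment_weights: dict[Compartment, np.ndarray]
    designated_persistent: set[CloneKey] = field(default_factory=set)

    def frequencies(self, compartment: Compartment) -> dict[CloneKey, float]:
        """True clone frequencies in one compartment (zeros dropped)."""
        w = self._weights(compartment)
        return {
            c.clone_key: float(w[i]) for i, c in enumerate(self.clones) if w[i] > 0
        }

    def _weights(self, compartment: Compartment) -> np.ndarray:
        if compartment not in self.compartment_weights:
            raise CompartmentError(f"unknown compartment {compartment}")
        return self.compartment_weights[compartment]


def _random_cdr3(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame CDR3: Cys codon ... Phe codon, stop-free."""
    middle = rng.choice(len(_SAFE_CODONS), size=n_codons - 2)
    return (
        "TGT"
        + "".join(_SAFE_CODONS[i] for i in middle)
        + _PHE_CODONS[rng.integers(2)]
    )


def build_ground_truth(
    n_clones: int,
    n_dominant: int,
    tail_exponent: float,
    compartments: Sequence[Compartment],
    seed: int,
    subject_id: str = "RA1",
    dominant_freqs: Optional[Sequence[float]] = None,
    jitter_sd: float = 0.3,
    synovium_share: float = 0.1,
    cross_subset_share: float = 0.05,
) -> GroundTruth:
    """Construct a latent clone population.

    Base clone frequencies follow rank^(-tail_exponent), renormalized.
    The top ``n_dominant`` clones are designated persistent: pinned at
    ``dominant_freqs`` (default a halving ladder from 10%) in every
    compartment whose gate covers their memory-side home, at every
    timepoint, and present in the synovium. Other clones get a home
    subset (a helper leaf, naive, or the memory pool at large), appear
    in compartments whose gate covers it, and carry log-normal jitter of
    scale ``jitter_sd`` across compartments. A fraction
    ``cross_subset_share`` of non-dominant clones straddles phenotype
    gates (making e.g. naive/memory clone sharing small but nonzero);
    ``synovium_share`` of clones also seed the synovium. CDR3s are
    distinct, 30-60 nt, in-frame, C...F anchored.
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    if n_dominant < 0 or n_dominant > n_clones:
        raise ValueError("need 0 <= n_dominant <= n_clones")
    if tail_exponent <= 0:
        raise ValueError("tail_exponent must be positive")
    if not compartments:
        raise ValueError("need at least one compartment")
    compartments = list(compartments)

    rng = np.random.default_rng(seed)

    # Distinct random CDR3s, 10-20 codons (30-60 nt).
    cdr3s: list[str] = []
    seen: set[str] = set()
    while len(cdr3s) < n_clones:
        s = _random_cdr3(rng, int(rng.integers(10, 21)))
        if s not in seen:
            seen.add(s)
            cdr3s.append(s)
    v_calls = [
        f"{_V_GENES[i]}*01"
        for i in rng.integers(0, len(_V_GENES), size=n_clones)
    ]

    base = np.arange(1, n_clones + 1, dtype=float) ** (-tail_exponent)
    base /= base.sum()

    # Home subsets: leaves actually present among the compartments; the
    # memory pool itself is a home option when memory-side gates are
    # sampled only in aggregate.
    leaf_subsets = sorted(
        {c.subset for c in compartments} - set(AGGREGATE_SUBSETS)
    )
    memory_leaves = [s for s in leaf_subsets if s in MEMORY_LEAF_SUBSETS]
    home_options = list(leaf_subsets)
    if not memory_leaves and any(
        c.subset in ("memory", "memory_all", "cd4_all") for c in compartments
    ):
        home_options.append("memory")
    if not home_options:
        home_options = ["memory"]
    dominant_home = (
        "nonTh1Th17Tfh"
        if "nonTh1Th17Tfh" in memory_leaves
        else (memory_leaves[0] if memory_leaves else "memory")
    )

    homes: list[str] = []
    for i in range(n_clones):
        if i < n_dominant:
            homes.append(dominant_home)
        else:
            homes.append(home_options[int(rng.integers(len(home_options)))])
    in_syn = rng.random(n_clones) < synovium_share
    in_syn[:n_dominant] = True
    cross_subset = rng.random(n_clones) < cross_subset_share
    cross_subset[:n_dominant] = False

    clones = [
        TrueClone(
            clone_key=(strip_allele(v_calls[i]), cdr3s[i]),
            cdr3_nt=cdr3s[i],
            v_call=v_calls[i],
            base_frequency=float(base[i]),
            home_subset=homes[i],
            in_synovium=bool(in_syn[i]),
        )
        for i in range(n_clones)
    ]

    if dominant_freqs is None:
        dom = list(DEFAULT_DOMINANT_FREQS[:n_dominant])
        while len(dom) < n_dominant:
            dom.append(dom[-1] / 2)
    else:
        dom = list(dominant_freqs)
        if len(dom) != n_dominant:
            raise ValueError("dominant_freqs length must equal n_dominant")
    if sum(dom) >= 1.0:
        raise ValueError("dominant frequencies must sum to < 1")

    weights: dict[Compartment, np.ndarray] = {}
    for comp in compartments:
        covered = np.array(
            [subset_covers(comp.subset, homes[i]) for i in range(n_clones)]
        )
        in_tissue = np.array(
            [comp.tissue != "synovium" or in_syn[i] for i in range(n_clones)]
        )
        # A small fraction of non-dominant clones straddles phenotype
        # gates (cross_subset flag); dominant clones are strictly
        # memory-phenotype. Tissue gating is hard.
        mult = np.where(covered | cross_subset, 1.0, 0.0)
        mult[~in_tissue] = 0.0
        jitter = (
            np.exp(rng.normal(0.0, jitter_sd, size=n_clones))
            if jitter_sd > 0
            else np.ones(n_clones)
        )
        w = base * jitter * mult
        support = w > 0
        pinned = covered & in_tissue
        pinned[n_dominant:] = False
        if pinned.any():
            rest = support & ~pinned
            rest_mass = 1.0 - sum(
                dom[i] for i in range(n_dominant) if pinned[i]
            )
            if w[rest].sum() > 0:
                w[rest] *= rest_mass / w[rest].sum()
            w[pinned] = [dom[i] for i in range(n_dominant) if pinned[i]]
        if w.sum() <= 0:
            raise CompartmentError(
                f"compartment {comp} covers no clone; check subsets"
            )
        weights[comp] = w / w.sum()

    return GroundTruth(
        subject_id=subject_id,
        clones=clones,
        compartment_weights=weights,
        designated_persistent={clones[i].clone_key for i in range(n_dominant)},
    )


def _mutate_reads(
    rng: np.random.Generator, cdr3: str, n_reads: int, rate: float
) -> dict[str, int]:
    """Apply i.i.d. per-base substitutions to ``n_reads`` copies of a CDR3.

    Equivalent to mutating every base of every read independently: the
    number of error-bearing reads is Binomial(n, 1-(1-rate)^L); each such
    read gets a per-base error mask conditioned on being non-empty.
    """
    L = len(cdr3)
    p_err = 1.0 - (1.0 - rate) ** L
    n_err = int(rng.binomial(n_reads, p_err)) if rate > 0 else 0
    out = {cdr3: n_reads - n_err}
    arr = np.frombuffer(cdr3.encode(), dtype="S1")
    for _ in range(n_err):
        while True:
            mask = rng.random(L) < rate
            if mask.any():
                break
        read = arr.copy()
        for pos in np.nonzero(mask)[0]:
            current = read[pos].decode()
            choices = [b for b in "ACGT" if b != current]
            read[pos] = choices[int(rng.integers(3))].encode()
        mutated = read.tobytes().decode()
        out[mutated] = out.get(mutated, 0) + 1
    if out[cdr3] == 0:
        del out[cdr3]
    return out


def _assemble_sample(
    truth: GroundTruth,
    compartment: Compartment,
    platform: str,
    obs: dict[CloneKey, tuple[str, str, int]],
    provenance: dict[CloneKey, dict[CloneKey, int]],
) -> RepertoireSample:
    clonotypes = [
        Clonotype(
            v_call=v_call,
            cdr3_nt=cdr3,
            count=count,
            productive=is_functional(cdr3),
        )
        for (v_call, cdr3, count) in obs.values()
    ]
    return RepertoireSample(
        sample_id=compartment.sample_id(truth.subject_id, platform),
        subject_id=truth.subject_id,
        tissue=compartment.tissue,
        subset=compartment.subset,
        timepoint=compartment.timepoint,
        platform=platform,
        clonotypes=clonotypes,
        provenance=provenance,
    )


def sample_bulk(
    truth: GroundTruth,
    compartment: Compartment,
    depth: int,
    noise: NoiseModel,
) -> RepertoireSample:
    """Draw a bulk-NGS sample of ``depth`` reads from one compartment.

    Per-clone expected read shares are true frequency x log-normal PCR
    factor (renormalized); counts are multinomial; each read's CDR3 is
    then mutated per-base at the substitution rate and reads are
    re-aggregated into observed clonotypes (a mutated CDR3 founds or
    joins a clonotype under the parent's V call). The observed table
    always sums to ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    w = truth._weights(compartment)
    rng = np.random.default_rng(noise.seed)

    p = w.copy()
    if noise.pcr_bias_sd > 0:
        amp = np.exp(rng.normal(0.0, noise.pcr_bias_sd, size=len(p)))
        p = p * amp
    p = p / p.sum()
    counts = rng.multinomial(depth, p)

    obs: dict[CloneKey, tuple[str, str, int]] = {}
    provenance: dict[CloneKey, dict[CloneKey, int]] = {}
    for i, n_reads in enumerate(counts):
        if n_reads == 0:
            continue
        clone = truth.clones[i]
        reads = _mutate_reads(rng, clone.cdr3_nt, int(n_reads), noise.substitution_rate)
        for cdr3, n in reads.items():
            key = (strip_allele(clone.v_call), cdr3)
            if key in obs:
                v, c, prev = obs[key]
                obs[key] = (v, c, prev + n)
            else:
                obs[key] = (clone.v_call, cdr3, n)
            prov = provenance.setdefault(key, {})
            prov[clone.clone_key] = prov.get(clone.clone_key, 0) + n

    return _assemble_sample(truth, compartment, PLATFORM_BULK, obs, provenance)


def sample_cells(
    truth: GroundTruth,
    compartment: Compartment,
    n_cells: int,
    seed: int,
) -> RepertoireSample:
    """Draw an error-free single-cell sample (multinomial over true clones).

    Emulates the single-cell Sanger gold standard: negligible PCR bias and
    error rate; counts are cell counts, one clone per cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    w = truth._weights(compartment)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, w / w.sum())

    obs: dict[CloneKey, tuple[str, str, int]] = {}
    provenance: dict[CloneKey, dict[CloneKey, int]] = {}
    for i, n in enumerate(counts):
        if n == 0:
            continue
        clone = truth.clones[i]
        obs[clone.clone_key] = (clone.v_call, clone.cdr3_nt, int(n))
        provenance[clone.clone_key] = {clone.clone_key: int(n)}

    return _assemble_sample(
        truth, compartment, PLATFORM_SINGLE_CELL, obs, provenance
    )


def write_truth(truth: GroundTruth, path) -> None:
    """Sidecar truth TSV: (clone_key, compartment, true_frequency)."""
    import pandas as pd

    rows = []
    for comp, w in truth.compartment_weights.items():
        for i, clone in enumerate(truth.clones):
            if w[i] > 0:
                rows.append(
                    {
                        "clone_key": f"{clone.clone_key[0]}/{clone.clone_key[1]}",
                        "compartment": f"{comp.tissue}:{comp.subset}:{comp.timepoint}",
                        "true_frequency": float(w[i]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
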