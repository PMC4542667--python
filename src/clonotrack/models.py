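"""Core domain types: clonotypes, repertoire samples, FACS fraction tables.

A *clonotype* is one distinct TCR-beta rearrangement — a V-gene call plus a
CDR3 (junction) nucleotide sequence — with an associated read count (bulk
NGS) or cell count (single-cell). Clone identity throughout the pipeline is
the pair (V gene with the allele suffix stripped, CDR3 nucleotide sequence):
nucleotide-level identity is what lets single-cell and bulk observations of
the same physical clone be matched, and what makes clones comparable across
tissues and timepoints. An amino-acid-level key is available for analyses
that want to pool synonymous rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Seq import Seq

from .errors import (
    DuplicateCloneKeyError,
    EmptySampleError,
    InvalidSequenceError,
    NegativeCountError,
    SubsetFractionError,
)

# Sample-sheet vocabulary. Subsets follow a CD4+ chemokine-receptor gating
# scheme: memory/naive split by CD45RO, memory further split into Tfh
# (CXCR5+), Th1 (CXCR3+CCR6-), Th17 (CXCR3-CCR6+) and the remainder
# ("nonTh1Th17Tfh", CXCR5-CXCR3-CCR6-). "memory"/"memory_all" and "cd4_all"
# are aggregate gates, not leaves.
TISSUES = ("PB", "synovium")
SUBSETS = (
    "naive",
    "memory",
    "Th1",
    "Th17",
    "Tfh",
    "nonTh1Th17Tfh",
    "memory_all",
    "cd4_all",
)
MEMORY_LEAF_SUBSETS = ("Th1", "Th17", "Tfh", "nonTh1Th17Tfh")
AGGREGATE_SUBSETS = ("memory", "memory_all", "cd4_all")

PLATFORM_BULK = "bulk-NGS"
PLATFORM_SINGLE_CELL = "single-cell"

_DNA = frozenset("ACGT")

CloneKey = tuple[str, str]


def subset_covers(gate: str, leaf: str) -> bool:
    """True when a sorting gate contains cells of a (leaf or aggregate) subset.

    ``cd4_all`` covers everything; ``memory``/``memory_all`` cover the four
    memory helper leaves and themselves; a leaf covers only itself.
    """
    if gate == leaf:
        return True
    if gate == "cd4_all":
        return True
    if gate in ("memory", "memory_all"):
        return leaf in MEMORY_LEAF_SUBSETS or leaf in ("memory", "memory_all")
    return False


def strip_allele(v_call: str) -> str:
    """Drop the ``*NN`` allele suffix from a V call (TRBV12-3*01 → TRBV12-3)."""
    return v_call.split("*", 1)[0]


def translate_junction(cdr3_nt: str) -> str:
    """Translate a junction in reading frame 1; stop codons appear as '*'.

    Out-of-frame junctions are translated over their complete codons only.
    """
    if not cdr3_nt:
        raise InvalidSequenceError("empty junction")
    usable = len(cdr3_nt) - len(cdr3_nt) % 3
    if usable == 0:
        return ""
    return str(Seq(cdr3_nt[:usable]).translate())


def is_functional(cdr3_nt: str, require_anchors: bool = True) -> bool:
    """Productivity rule for a CDR3 junction.

    Functional means in-frame (length a multiple of 3) and stop-free; with
    ``require_anchors`` the translation must additionally begin with the
    conserved Cys and end with Phe or Trp (C...F/W), the conventional
    junction anchors.
    """
    if not cdr3_nt or set(cdr3_nt) - _DNA:
        return False
    if len(cdr3_nt) % 3 != 0:
        return False
    aa = translate_junction(cdr3_nt)
    if not aa or "*" in aa:
        return False
    if require_anchors and not (aa[0] == "C" and aa[-1] in "FW"):
        return False
    return True


@dataclass(frozen=True)
class Clonotype:
    """One distinct rearrangement with its read or cell count."""

    v_call: str
    cdr3_nt: str
    count: int
    cdr3_aa: str = ""
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.cdr3_nt:
            raise InvalidSequenceError("clonotype with empty CDR3")
        if set(self.cdr3_nt) - _DNA:
            raise InvalidSequenceError(
                f"non-DNA characters in junction {self.cdr3_nt!r}"
            )
        if self.count < 0:
            raise NegativeCountError(f"negative count {self.count}")
        if not self.cdr3_aa:
            object.__setattr__(self, "cdr3_aa", translate_junction(self.cdr3_nt))


def make_clone_key(c: Clonotype) -> CloneKey:
    """Deterministic clone identity: (allele-stripped V call, CDR3 nt).

    Equal keys mean "same clone" everywhere in the pipeline, across
    subsets, tissues, timepoints and platforms.
    """
    if not c.cdr3_nt:
        raise InvalidSequenceError("cannot key a clonotype with empty CDR3")
    return (strip_allele(c.v_call), c.cdr3_nt)


def make_clone_key_aa(c: Clonotype) -> CloneKey:
    """Amino-acid-level alternative identity (pools synonymous junctions)."""
    return (strip_allele(c.v_call), c.cdr3_aa)


@dataclass
class RepertoireSample:
    """A set of clonotypes plus the metadata identifying where they came from.

    ``provenance`` is the simulator's hidden channel: for each *observed*
    clone key, the number of reads contributed by each *true* clone. Real
    data never has it; oracle-style evaluations require it.
    """

    sample_id: str
    subject_id: str
    tissue: str
    subset: str
    timepoint: str
    platform: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    provenance: Optional[dict[CloneKey, dict[CloneKey, int]]] = None

    def __post_init__(self) -> None:
        keys = [make_clone_key(c) for c in self.clonotypes]
        if len(keys) != len(set(keys)):
            seen: set[CloneKey] = set()
            for k in keys:
                if k in seen:
                    raise DuplicateCloneKeyError(
                        f"duplicate clone key {k} in sample {self.sample_id}"
                    )
                seen.add(k)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    @property
    def total_functional(self) -> int:
        """Total reads/cells over productive clonotypes."""
        return sum(c.count for c in self.clonotypes if c.productive)

    def key_counts(self, functional_only: bool = False) -> dict[CloneKey, int]:
        return {
            make_clone_key(c): c.count
            for c in self.clonotypes
            if not functional_only or c.productive
        }

    def frequencies(self) -> dict[CloneKey, float]:
        """Per-clone frequency over functional reads/cells."""
        total = self.total_functional
        if total == 0:
            raise EmptySampleError(
                f"sample {self.sample_id} has no functional reads"
            )
        return {
            make_clone_key(c): c.count / total
            for c in self.clonotypes
            if c.productive
        }

    def clone_keys(self, functional_only: bool = True) -> set[CloneKey]:
        return set(self.key_counts(functional_only=functional_only))


@dataclass
class SubsetFractionTable:
    """FACS-measured fraction of each CD4+ subset within all CD4+ T cells.

    Rows are (subject_id, timepoint, subset, fraction_of_cd4). The four
    memory helper leaves need not partition the memory gate (a
    CXCR3+CCR6+ double-positive gate is not part of the scheme), but their
    sum may not exceed it.
    """

    rows: list[tuple[str, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for subject, timepoint, subset, frac in self.rows:
            if not (0.0 <= frac <= 1.0):
                raise SubsetFractionError(
                    f"fraction {frac} for {subject}/{timepoint}/{subset} "
                    "outside [0, 1]"
                )
        # Helper-leaf fractions may not exceed the memory gate they sit in.
        by_st: dict[tuple[str, str], dict[str, float]] = {}
        for subject, timepoint, subset, frac in self.rows:
            by_st.setdefault((subject, timepoint), {})[subset] = frac
        for (subject, timepoint), fracs in by_st.items():
            mem = fracs.get("memory", fracs.get("memory_all"))
            if mem is None:
                continue
            leaf_sum = sum(fracs.get(s, 0.0) for s in MEMORY_LEAF_SUBSETS)
            if leaf_sum > mem + 1e-9:
                raise SubsetFractionError(
                    f"helper-subset fractions sum to {leaf_sum:.4g} > memory "
                    f"fraction {mem:.4g} for {subject}/{timepoint}"
                )

    def fraction(self, subject_id: str, timepoint: str, subset: str) -> float:
        for s, t, sub, frac in self.rows:
            if (s, t, sub) == (subject_id, timepoint, subset):
                return frac
        raise SubsetFractionError(
            f"no FACS fraction for {subject_id}/{timepoint}/{subset}"
        )

    def has(self, subject_id: str, timepoint: str, subset: str) -> bool:
        return any(
            (s, t, sub) == (subject_id, timepoint, subset)
            for s, t, sub, _ in self.rows
        )


def require_same_subject(samples: Iterable[RepertoireSample]) -> str:
    from .errors import SubjectMismatchError

    subjects = {s.subject_id for s in samples}
    if len(subjects) != 1:
        raise SubjectMismatchError(f"expected one subject, got {sorted(subjects)}")
    return subjects.pop()
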