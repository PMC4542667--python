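"""Single-cell vs bulk-NGS agreement, and a simple error-correction stage.

The single-cell arm (negligible PCR bias, low error rate) serves as the
gold standard against which the bulk-NGS repertoire is checked: for every
clone seen in the single-cell sample, its single-cell frequency is paired
with its bulk frequency (0 when undetected) and agreement is summarized
by Spearman's rank correlation plus a detection sensitivity.

The error-correction stage absorbs likely sequencing-error artifacts:
a "child" clonotype with the same V call, a CDR3 of equal length at
Hamming distance 1 from a "parent", and a count at most
``ratio_threshold`` x the parent's, has its reads reassigned to the
parent. Parents are processed in descending count order and each child is
absorbed at most once, by its largest eligible parent (ties broken by
lexicographic CDR3), so the procedure is deterministic and conserves the
total read count. On simulator output the hidden provenance channel makes
the correction quantitatively evaluable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import stats

from .errors import EmptySampleError, PlatformError, ProvenanceError
from .models import (
    CloneKey,
    Clonotype,
    PLATFORM_BULK,
    PLATFORM_SINGLE_CELL,
    RepertoireSample,
    make_clone_key,
)


@dataclass
class ConcordanceReport:
    """Agreement between a single-cell (gold) and a bulk-NGS repertoire."""

    matched_keys: set[CloneKey]
    sc_frequencies: dict[CloneKey, float]
    ngs_frequencies: dict[CloneKey, float]  # 0 when absent from NGS
    rho: float
    p_value: float
    detection_sensitivity: float  # gold clones with >= 1 NGS read / gold clones
    n_gold: int
    n_detected: int


@dataclass
class CorrectionEvaluation:
    """Truth-based before/after evaluation of the error-correction stage."""

    spurious_before: int
    spurious_after: int
    spurious_reduction: float  # 1 - after/before (0 when nothing to fix)
    true_clone_recall_before: float
    true_clone_recall_after: float
    misassigned_rate_before: float
    misassigned_rate_after: float
    rho_truth_before: float
    rho_truth_after: float


def _safe_spearman(x, y) -> tuple[float, float]:
    """Spearman rho with average-rank ties; rho = 0 when a vector is constant
    (no rank information)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, 1.0
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def concordance(
    sc: RepertoireSample, ngs: RepertoireSample
) -> ConcordanceReport:
    """Compare a single-cell sample against a bulk-NGS sample of the same
    subject and compartment.

    Both samples must be functional-filtered. Pairing is over the clones
    detected in the single-cell sample.
    """
    if sc.platform != PLATFORM_SINGLE_CELL:
        raise PlatformError(f"gold sample must be single-cell, got {sc.platform}")
    if ngs.platform != PLATFORM_BULK:
        raise PlatformError(f"test sample must be bulk-NGS, got {ngs.platform}")
    if sc.subject_id != ngs.subject_id:
        from .errors import SubjectMismatchError

        raise SubjectMismatchError(
            f"subject mismatch: {sc.subject_id} vs {ngs.subject_id}"
        )
    sc_freq = sc.frequencies()  # raises EmptySampleError when empty
    ngs_freq = ngs.frequencies()
    keys = sorted(sc_freq)
    paired_sc = {k: sc_freq[k] for k in keys}
    paired_ngs = {k: ngs_freq.get(k, 0.0) for k in keys}
    rho, p = _safe_spearman(
        [paired_sc[k] for k in keys], [paired_ngs[k] for k in keys]
    )
    detected = sum(1 for k in keys if paired_ngs[k] > 0)
    return ConcordanceReport(
        matched_keys={k for k in keys if paired_ngs[k] > 0},
        sc_frequencies=paired_sc,
        ngs_frequencies=paired_ngs,
        rho=rho,
        p_value=p,
        detection_sensitivity=detected / len(keys),
        n_gold=len(keys),
        n_detected=detected,
    )


def _hamming1(a: str, b: str) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > 1:
                return False
    return d == 1


def correct_errors(
    sample: RepertoireSample, ratio_threshold: float
) -> RepertoireSample:
    """Absorb Hamming-distance-1 low-count children into their parents.

    Runs before functional filtering (an error can toggle productivity).
    Total read count is conserved exactly and no new clone keys appear.
    """
    if sample.platform == PLATFORM_SINGLE_CELL:
        raise PlatformError("error correction is meaningless at cell resolution")
    if not 0.0 <= ratio_threshold < 1.0:
        raise ValueError("ratio_threshold must be in [0, 1)")

    counts = {make_clone_key(c): c.count for c in sample.clonotypes}
    by_key = {make_clone_key(c): c for c in sample.clonotypes}
    # Candidate pairs live in the same (stripped V, CDR3 length) bucket.
    buckets: dict[tuple[str, int], list[CloneKey]] = defaultdict(list)
    for key in counts:
        buckets[(key[0], len(key[1]))].append(key)

    absorbed_into: dict[CloneKey, CloneKey] = {}
    order = sorted(counts, key=lambda k: (-counts[k], k[1]))
    for parent in order:
        if parent in absorbed_into:
            continue
        limit = ratio_threshold * counts[parent]
        for child in buckets[(parent[0], len(parent[1]))]:
            if child == parent or child in absorbed_into:
                continue
            if counts[child] <= limit and _hamming1(parent[1], child[1]):
                absorbed_into[child] = parent

    final_counts: dict[CloneKey, int] = {}
    for key, n in counts.items():
        target = absorbed_into.get(key, key)
        final_counts[target] = final_counts.get(target, 0) + n

    provenance: Optional[dict[CloneKey, dict[CloneKey, int]]] = None
    if sample.provenance is not None:
        provenance = {}
        for key, prov in sample.provenance.items():
            target = absorbed_into.get(key, key)
            merged = provenance.setdefault(target, {})
            for true_key, n in prov.items():
                merged[true_key] = merged.get(true_key, 0) + n

    clonotypes = [
        Clonotype(
            v_call=by_key[key].v_call,
            cdr3_nt=by_key[key].cdr3_nt,
            count=n,
            cdr3_aa=by_key[key].cdr3_aa,
            productive=by_key[key].productive,
        )
        for key, n in final_counts.items()
    ]
    return RepertoireSample(
        sample_id=sample.sample_id,
        subject_id=sample.subject_id,
        tissue=sample.tissue,
        subset=sample.subset,
        timepoint=sample.timepoint,
        platform=sample.platform,
        clonotypes=clonotypes,
        provenance=provenance,
    )


def _truth_stats(
    sample: RepertoireSample,
    true_frequencies: Optional[Mapping[CloneKey, float]],
) -> tuple[int, float, float, float]:
    """(spurious count, recall, misassigned rate, rho to truth) for one sample."""
    if sample.provenance is None:
        raise ProvenanceError(
            "evaluation needs the simulator's provenance channel"
        )
    total = sample.total_count
    if total == 0:
        raise EmptySampleError("cannot evaluate an empty sample")
    true_reads: dict[CloneKey, int] = {}
    for prov in sample.provenance.values():
        for true_key, n in prov.items():
            true_reads[true_key] = true_reads.get(true_key, 0) + n
    true_keys = set(true_reads)

    observed = {make_clone_key(c): c.count for c in sample.clonotypes}
    spurious = sum(1 for k in observed if k not in true_keys)
    recall = sum(1 for k in true_keys if observed.get(k, 0) > 0) / len(true_keys)
    # Reads filed under a *true* key that is not their own true clone.
    misassigned = sum(
        n
        for obs_key, prov in sample.provenance.items()
        if obs_key in true_keys
        for true_key, n in prov.items()
        if true_key != obs_key
    )
    if true_frequencies is None:
        truth_vec = {k: true_reads[k] / total for k in true_keys}
    else:
        truth_vec = {k: float(true_frequencies.get(k, 0.0)) for k in true_keys}
    keys = sorted(true_keys)
    rho, _ = _safe_spearman(
        [truth_vec[k] for k in keys],
        [observed.get(k, 0) / total for k in keys],
    )
    return spurious, recall, misassigned / total, rho


def evaluate_correction(
    observed_before: RepertoireSample,
    observed_after: RepertoireSample,
    true_frequencies: Optional[Mapping[CloneKey, float]] = None,
) -> CorrectionEvaluation:
    """Score an error-correction run against the simulator's ground truth.

    Uses the hidden provenance channel carried on both samples: spurious
    clonotypes are observed keys matching no true clone; misassigned
    reads are reads filed under a true clone other than their own; rho is
    Spearman's correlation between observed and true frequencies over the
    true clones (read-level truth from provenance unless explicit
    ``true_frequencies`` are supplied).
    """
    sb, recb, misb, rhob = _truth_stats(observed_before, true_frequencies)
    sa, reca, misa, rhoa = _truth_stats(observed_after, true_frequencies)
    return CorrectionEvaluation(
        spurious_before=sb,
        spurious_after=sa,
        spurious_reduction=(1.0 - sa / sb) if sb else 0.0,
        true_clone_recall_before=recb,
        true_clone_recall_after=reca,
        misassigned_rate_before=misb,
        misassigned_rate_after=misa,
        rho_truth_before=rhob,
        rho_truth_after=rhoa,
    )
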