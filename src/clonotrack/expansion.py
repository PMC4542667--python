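"""Clonality statistics for bulk repertoires.

An *expanded clone* (EC) in a bulk-NGS repertoire is a clone whose
frequency among functional CDR3 reads exceeds a threshold (0.2% and 0.1%
are the conventional operating points). The *EC rate* of a sample is the
cumulative read count of its ECs divided by the total functional read
count; the *shared-clone rate* between two subsets is the cumulative read
count of clones present in both, again over each subset's own functional
total (so the rate is per-sample and not symmetric). Cohort comparisons
use the unpaired Student's t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import EmptySampleError
from .models import CloneKey, RepertoireSample, require_same_subject


@dataclass(frozen=True)
class ECCallResult:
    """Expanded-clone call at one frequency threshold."""

    threshold: float
    ec_keys: frozenset[CloneKey]
    ec_rate: float

    @property
    def n_ec(self) -> int:
        return len(self.ec_keys)


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    significant: bool  # at the conventional 0.05 level


def clone_frequency(sample: RepertoireSample, key: CloneKey) -> float:
    """Frequency of one clone: its reads / total functional reads.

    The sample is expected to be functional-filtered; an absent clone has
    frequency 0. Raises :class:`EmptySampleError` when the functional
    total is zero.
    """
    total = sample.total_functional
    if total == 0:
        raise EmptySampleError(f"sample {sample.sample_id} has no functional reads")
    return sample.key_counts(functional_only=True).get(key, 0) / total


def call_ecs(sample: RepertoireSample, threshold: float) -> ECCallResult:
    """Call expanded clones: frequency strictly greater than ``threshold``.

    "More than" is read as a strict inequality; a clone sitting exactly at
    the threshold is not expanded. The EC rate is the cumulative EC read
    count over the functional total.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    total = sample.total_functional
    if total == 0:
        raise EmptySampleError(f"sample {sample.sample_id} has no functional reads")
    counts = sample.key_counts(functional_only=True)
    ec_keys = frozenset(k for k, n in counts.items() if n / total > threshold)
    ec_reads = sum(counts[k] for k in ec_keys)
    return ECCallResult(
        threshold=threshold, ec_keys=ec_keys, ec_rate=ec_reads / total
    )


def shared_clone_rate(
    sample_a: RepertoireSample, sample_b: RepertoireSample
) -> tuple[float, float]:
    """Cumulative read fraction, per sample, of clones present in both.

    Returns ``(rate_in_a, rate_in_b)``: the shared clones' reads in each
    sample over that sample's own functional total. Both samples must come
    from the same subject.
    """
    require_same_subject([sample_a, sample_b])
    counts_a = sample_a.key_counts(functional_only=True)
    counts_b = sample_b.key_counts(functional_only=True)
    total_a = sample_a.total_functional
    total_b = sample_b.total_functional
    if total_a == 0 or total_b == 0:
        raise EmptySampleError("shared_clone_rate needs functional reads in both samples")
    shared = counts_a.keys() & counts_b.keys()
    rate_a = sum(counts_a[k] for k in shared) / total_a
    rate_b = sum(counts_b[k] for k in shared) / total_b
    return rate_a, rate_b


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided unpaired t-test between two groups of per-sample values.

    The classical (pooled-variance) Student form is the default; set
    ``equal_var=False`` for Welch. Degenerate zero-variance inputs are
    resolved explicitly: equal means give (0, 1), unequal means give an
    infinite statistic and p = 0.
    """
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs at least 2 values")
    result = stats.ttest_ind(values_a, values_b, equal_var=equal_var)
    statistic, p_value = float(result.statistic), float(result.pvalue)
    if math.isnan(statistic):
        mean_a = sum(values_a) / len(values_a)
        mean_b = sum(values_b) / len(values_b)
        if math.isclose(mean_a, mean_b, rel_tol=0.0, abs_tol=0.0):
            statistic, p_value = 0.0, 1.0
        else:
            statistic = math.copysign(math.inf, mean_a - mean_b)
            p_value = 0.0
    return GroupComparison(
        statistic=statistic, p_value=p_value, significant=p_value < 0.05
    )
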