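"""FACS-size-corrected distribution of clones across CD4+ subsets.

A clone's frequency *within* a sorted subset says nothing about how the
clone is spread over subsets of very different sizes. The correction is
the product

    contribution(subset) = in-subset frequency x subset fraction of CD4+,

i.e. the clone's share of *all* CD4+ T cells carried by each subset, with
the subset fraction taken from flow cytometry. Raw contributions and
normalized shares (contributions over their sum) are both reported; the
shares are what a stacked proportion plot shows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import EmptyCloneSetError, SubjectMismatchError, SubsetFractionError
from .expansion import clone_frequency
from .models import (
    CloneKey,
    RepertoireSample,
    SubsetFractionTable,
    require_same_subject,
)


@dataclass
class SubsetDistribution:
    """Corrected per-subset contributions of a clone (or clone set).

    ``contributions`` are fractions of all CD4+ T cells; ``shares`` are the
    contributions normalized to sum to 1 (``None`` when the clone was
    detected in no subset). ``provenance`` records the raw in-subset
    frequency and FACS fraction behind every entry.
    """

    label: str
    contributions: dict[str, float]
    shares: dict[str, float] | None
    provenance: dict[str, tuple[float, float]] = field(default_factory=dict)


def _check_inputs(
    subset_samples: Sequence[RepertoireSample], fractions: SubsetFractionTable
) -> tuple[str, str]:
    if not subset_samples:
        raise ValueError("need at least one subset sample")
    subject = require_same_subject(subset_samples)
    timepoints = {s.timepoint for s in subset_samples}
    if len(timepoints) != 1:
        raise SubjectMismatchError(
            f"subset samples span several timepoints: {sorted(timepoints)}"
        )
    timepoint = timepoints.pop()
    for s in subset_samples:
        if not fractions.has(subject, timepoint, s.subset):
            raise SubsetFractionError(
                f"no FACS fraction for {subject}/{timepoint}/{s.subset}"
            )
    return subject, timepoint


def distribute_clone(
    key: CloneKey,
    subset_samples: Sequence[RepertoireSample],
    fractions: SubsetFractionTable,
) -> SubsetDistribution:
    """Distribution of a single clone across sorted subsets.

    All samples must be functional-filtered, from one subject and one
    timepoint, with every sampled subset present in the FACS table. A
    clone detected in no subset yields an all-zero distribution with a
    warning (sampling dropout is expected at low depth), not an error.
    """
    return distribute_clone_set(
        [key], subset_samples, fractions, label=f"{key[0]}/{key[1]}"
    )


def distribute_clone_set(
    keys: Iterable[CloneKey],
    subset_samples: Sequence[RepertoireSample],
    fractions: SubsetFractionTable,
    label: str = "clone_set",
) -> SubsetDistribution:
    """Summed distribution of a set of clones (e.g. all ECs) across subsets.

    The per-subset contribution is additive over clones:
    sum over keys of (in-subset frequency x FACS fraction).
    """
    keys = list(keys)
    if not keys:
        raise EmptyCloneSetError("distribute_clone_set needs at least one clone key")
    subject, timepoint = _check_inputs(subset_samples, fractions)

    contributions: dict[str, float] = {}
    provenance: dict[str, tuple[float, float]] = {}
    for sample in subset_samples:
        frac = fractions.fraction(subject, timepoint, sample.subset)
        raw = sum(clone_frequency(sample, k) for k in keys)
        contributions[sample.subset] = raw * frac
        provenance[sample.subset] = (raw, frac)

    total = sum(contributions.values())
    if total > 0.0:
        shares = {s: v / total for s, v in contributions.items()}
    else:
        warnings.warn(
            f"{label}: detected in no subset sample; all-zero distribution",
            stacklevel=2,
        )
        shares = None
    return SubsetDistribution(
        label=label,
        contributions=contributions,
        shares=shares,
        provenance=provenance,
    )
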