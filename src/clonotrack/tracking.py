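"""Linking identical clones across samples and calling persistent expansion.

Clone identity (stripped V call + CDR3 nucleotide sequence) lets the same
physical clone be followed across timepoints, tissues, sorted subsets and
platforms. Two expansion definitions coexist and are never mixed
implicitly:

* single-cell samples (~10^2 cells): an *expanded clone* (EC) is a clone
  observed more than once; the *most expanded clone* (mEC) is the EC with
  the highest cell count (a tie means no mEC is designated); clones seen
  exactly once are non-expanded (NEC);
* bulk-NGS samples: an EC is a clone above a frequency threshold of
  functional reads (0.2% by default).

A clone is *persistent* when it meets the platform-appropriate EC
criterion at two or more timepoints of the same compartment
(tissue + subset). Persistent clones get stable IDs ``Ci.j``: ``i`` tags
the subject, ``j`` ranks persistent clones by mean frequency across
samples (j = 1 is the major clone).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import (
    EmptySampleError,
    PlatformError,
    SubjectMismatchError,
    TissueMismatchError,
)
from .models import (
    CloneKey,
    PLATFORM_BULK,
    PLATFORM_SINGLE_CELL,
    RepertoireSample,
    require_same_subject,
)

#: Default bulk-NGS expansion threshold (fraction of functional reads).
DEFAULT_BULK_EC_THRESHOLD = 0.002

MEC = "mEC"
EC = "EC"
NEC = "NEC"


@dataclass
class SingleCellCallResult:
    """mEC/EC/NEC classification of one single-cell sample."""

    sample_id: str
    labels: dict[CloneKey, str]
    counts: dict[CloneKey, int]
    mec_key: Optional[CloneKey]
    mec_tied: bool = False

    @property
    def ec_keys(self) -> set[CloneKey]:
        return {k for k, v in self.labels.items() if v in (EC, MEC)}

    @property
    def nec_keys(self) -> set[CloneKey]:
        return {k for k, v in self.labels.items() if v == NEC}


@dataclass
class TrackingMatrix:
    """Clone x sample frequency matrix with persistence annotations.

    ``frequencies`` has one row per clone key and one column per
    sample_id; absent clones are 0. ``clone_ids`` maps persistent clones
    to their ``Ci.j`` labels.
    """

    subject_id: str
    frequencies: pd.DataFrame
    persistent: dict[CloneKey, bool]
    clone_ids: dict[CloneKey, str] = field(default_factory=dict)

    @property
    def persistent_keys(self) -> list[CloneKey]:
        return [k for k, flag in self.persistent.items() if flag]


def classify_single_cell(sample: RepertoireSample) -> SingleCellCallResult:
    """Classify every clone of a single-cell sample as mEC, EC or NEC.

    NEC = observed exactly once; EC = observed more than once; mEC = the
    EC with the maximal cell count. A tie for the maximum leaves the mEC
    undesignated (reported via ``mec_tied``) rather than broken
    arbitrarily.
    """
    if sample.platform != PLATFORM_SINGLE_CELL:
        raise PlatformError(
            f"classify_single_cell needs a single-cell sample, got {sample.platform}"
        )
    counts = sample.key_counts(functional_only=True)
    counts = {k: n for k, n in counts.items() if n > 0}
    if not counts:
        raise EmptySampleError(f"sample {sample.sample_id} has no cells")
    labels = {k: (EC if n >= 2 else NEC) for k, n in counts.items()}
    mec_key: Optional[CloneKey] = None
    mec_tied = False
    ec_counts = {k: n for k, n in counts.items() if n >= 2}
    if ec_counts:
        top = max(ec_counts.values())
        top_keys = [k for k, n in ec_counts.items() if n == top]
        if len(top_keys) == 1:
            mec_key = top_keys[0]
            labels[mec_key] = MEC
        else:
            mec_tied = True
    return SingleCellCallResult(
        sample_id=sample.sample_id,
        labels=labels,
        counts=counts,
        mec_key=mec_key,
        mec_tied=mec_tied,
    )


def _is_expanded(
    sample: RepertoireSample, key: CloneKey, bulk_threshold: float
) -> bool:
    counts = sample.key_counts(functional_only=True)
    n = counts.get(key, 0)
    if sample.platform == PLATFORM_SINGLE_CELL:
        return n >= 2
    total = sample.total_functional
    return total > 0 and n / total > bulk_threshold


def _subject_index(subject_id: str) -> int:
    m = re.search(r"(\d+)\s*$", subject_id)
    return int(m.group(1)) if m else 1


def track_clones(
    samples: Sequence[RepertoireSample],
    bulk_threshold: float = DEFAULT_BULK_EC_THRESHOLD,
    subject_index: Optional[int] = None,
) -> TrackingMatrix:
    """Build the clone x sample frequency matrix and flag persistent clones.

    Persistence = platform-appropriate EC criterion satisfied at >= 2
    distinct timepoints within one compartment (tissue + subset).
    Persistent clones are labelled ``Ci.j`` in descending order of mean
    frequency across all samples; ties broken lexicographically by clone
    key, so the labels are stable under sample reordering.
    """
    if len(samples) < 2:
        raise ValueError("track_clones needs at least 2 samples")
    subject = require_same_subject(samples)
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")

    freq_by_sample = {s.sample_id: s.frequencies() for s in samples}
    all_keys = sorted({k for f in freq_by_sample.values() for k in f})
    matrix = pd.DataFrame(
        [[freq_by_sample[sid].get(k, 0.0) for sid in ids] for k in all_keys],
        index=pd.Index(all_keys, name="clone_key", tupleize_cols=False),
        columns=ids,
    )

    # EC timepoints per compartment; >= 2 distinct timepoints → persistent.
    persistent: dict[CloneKey, bool] = {}
    for key in all_keys:
        tp_by_compartment: dict[tuple[str, str], set[str]] = {}
        for s in samples:
            if _is_expanded(s, key, bulk_threshold):
                tp_by_compartment.setdefault(
                    (s.tissue, s.subset), set()
                ).add(s.timepoint)
        persistent[key] = any(len(tps) >= 2 for tps in tp_by_compartment.values())

    idx = subject_index if subject_index is not None else _subject_index(subject)
    ranked = sorted(
        (k for k in all_keys if persistent[k]),
        key=lambda k: (-matrix.loc[[k]].to_numpy().mean(), k),
    )
    clone_ids = {k: f"C{idx}.{j}" for j, k in enumerate(ranked, start=1)}

    return TrackingMatrix(
        subject_id=subject,
        frequencies=matrix,
        persistent=persistent,
        clone_ids=clone_ids,
    )


def tracking_long_table(matrix: TrackingMatrix) -> pd.DataFrame:
    """Long-format view: one row per (clone_key, sample_id) with labels."""
    rows = []
    for key in matrix.frequencies.index:
        for sid in matrix.frequencies.columns:
            rows.append(
                {
                    "clone_key": f"{key[0]}/{key[1]}",
                    "sample_id": sid,
                    "frequency": matrix.frequencies.at[key, sid],
                    "persistent": matrix.persistent[key],
                    "clone_id": matrix.clone_ids.get(key, ""),
                }
            )
    return pd.DataFrame(rows)


def intersect_tissues(
    pb_samples: Sequence[RepertoireSample],
    tissue_sample: RepertoireSample,
) -> set[CloneKey]:
    """Clones detected both in the synovium and in >= 1 PB sample.

    "Detected" = at least one functional read/cell (the most permissive
    reading); the result feeds the subset-distribution correction for
    synovium-infiltrating clones.
    """
    if tissue_sample.tissue != "synovium":
        raise TissueMismatchError(
            f"tissue sample must be synovium, got {tissue_sample.tissue}"
        )
    if not pb_samples:
        raise ValueError("need at least one PB sample")
    require_same_subject(list(pb_samples) + [tissue_sample])
    for s in pb_samples:
        if s.tissue != "PB":
            raise TissueMismatchError(f"PB sample {s.sample_id} has tissue {s.tissue}")
    synovium_keys = {
        k for k, n in tissue_sample.key_counts(functional_only=True).items() if n >= 1
    }
    pb_keys: set[CloneKey] = set()
    for s in pb_samples:
        pb_keys |= {k for k, n in s.key_counts(functional_only=True).items() if n >= 1}
    return synovium_keys & pb_keys
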