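"""Shared builders for clonotype tables and samples."""

from __future__ import annotations

import itertools

import pytest

from clonotrack.models import (
    Clonotype,
    PLATFORM_BULK,
    PLATFORM_SINGLE_CELL,
    RepertoireSample,
)

# Four stop-free codons give 4^8 distinct in-frame interiors.
_CODONS = ("GCA", "GAC", "GGA", "CTG")


def nth_cdr3(i: int, n_mid: int = 8) -> str:
    """Deterministic distinct in-frame CDR3 (C ... F anchored), index i."""
    digits = []
    for _ in range(n_mid):
        digits.append(i % 4)
        i //= 4
    return "TGT" + "".join(_CODONS[d] for d in digits) + "TTT"


def make_sample(
    counts,
    platform: str = PLATFORM_BULK,
    sample_id: str = "s1",
    subject_id: str = "RA1",
    tissue: str = "PB",
    subset: str = "memory",
    timepoint: str = "t0",
    v_call: str = "TRBV12-3*01",
) -> RepertoireSample:
    """Build a sample from clone counts.

    ``counts`` is either a dict {name: count} (each name gets a distinct
    CDR3, stable in sorted-name order) or a list of counts.
    """
    if isinstance(counts, dict):
        items = sorted(counts.items())
    else:
        items = [(str(i), n) for i, n in enumerate(counts)]
    clonotypes = [
        Clonotype(v_call=v_call, cdr3_nt=nth_cdr3(i), count=n)
        for i, (_, n) in enumerate(items)
    ]
    return RepertoireSample(
        sample_id=sample_id,
        subject_id=subject_id,
        tissue=tissue,
        subset=subset,
        timepoint=timepoint,
        platform=platform,
        clonotypes=clonotypes,
    )


def make_sc_sample(counts, **kw) -> RepertoireSample:
    return make_sample(counts, platform=PLATFORM_SINGLE_CELL, **kw)


@pytest.fixture
def named_keys():
    """Map logical clone names to the keys make_sample assigns them."""

    def _keys(counts: dict):
        names = sorted(counts)
        return {name: ("TRBV12-3", nth_cdr3(i)) for i, name in enumerate(names)}

    return _keys
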