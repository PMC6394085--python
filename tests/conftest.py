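"""Shared fixtures: toy catalogues and VCF-writing helpers."""

from __future__ import annotations

import pytest

from multicall.core import MutationCall, MutationCatalog, classify_variant


def make_call(subject: str, caller: str, chrom: str = "1", pos: int = 100,
              ref: str = "A", alt: str = "T", t_ref: int = 20, t_alt: int = 10,
              **kw) -> MutationCall:
    return MutationCall(
        subject_id=subject, caller_id=caller, chrom=chrom, pos=pos,
        ref=ref, alt=alt, vtype=classify_variant(ref, alt),
        tumor_ref_depth=t_ref, tumor_alt_depth=t_alt, **kw)


def catalog_from_sets(caller_sites: dict[str, dict[str, set[int]]]
                      ) -> MutationCatalog:
    """Build a catalogue from caller -> subject -> set of positions.

    All sites are A>T SNVs on chromosome 1, so positions act as site ids.
    """
    cat = MutationCatalog()
    for caller, per_subject in caller_sites.items():
        for subject, positions in per_subject.items():
            if subject not in cat.subjects:
                cat.subjects.append(subject)
            if caller not in cat.callers:
                cat.callers.append(caller)
            for pos in positions:
                cat.add(make_call(subject, caller, pos=pos + 1))
    return cat


@pytest.fixture
def two_caller_catalog() -> MutationCatalog:
    """Callers A={1,2,3}, B={2,3,4} for one subject."""
    return catalog_from_sets({
        "mutect2": {"S1": {1, 2, 3}},
        "varscan2": {"S1": {2, 3, 4}},
    })


@pytest.fixture
def toy_six_site_catalog() -> MutationCatalog:
    """Six sites for one subject; sites 10 and 20 have two-caller support."""
    return catalog_from_sets({
        "mutect2": {"S1": {10, 20, 30, 40}},
        "varscan2": {"S1": {10, 20, 50, 60}},
    })
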