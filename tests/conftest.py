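"""Shared fixtures and fragment-building helpers."""

from __future__ import annotations

import pytest

from methpat.io_model import CallState, FragmentCall, GenomicRegion

STATE = {"1": CallState.METH, "0": CallState.UNMETH, "A": CallState.AMBIG}


def make_fragment(
    sample_id: str,
    chrom: str,
    positions: list[int],
    states: str,
    start: int | None = None,
    end: int | None = None,
) -> FragmentCall:
    """Build a fragment from CpG positions and a compact state string.

    ``states`` uses '1' = methylated, '0' = unmethylated, 'A' = ambiguous.
    """
    assert len(positions) == len(states)
    calls = {pos: STATE[s] for pos, s in zip(positions, states)}
    if start is None:
        start = min(positions) if positions else 0
    if end is None:
        end = (max(positions) + 2) if positions else start + 1
    return FragmentCall(
        sample_id=sample_id, chrom=chrom, start=start, end=end, calls=calls
    )


@pytest.fixture
def four_cpg_region() -> GenomicRegion:
    """A small window with four CpGs at positions 100, 110, 120, 130."""
    return GenomicRegion(
        region_id="r4",
        chrom="chr1",
        start=100,
        end=132,
        cpg_offsets=(0, 10, 20, 30),
    )


def bruteforce_pattern_counts(fragments, region):
    """Independent string-scan oracle for pattern counting.

    Re-derives each fragment's covered CpG stretch directly from its
    call map, collects observed patterns, and recounts supporting and
    covering fragments by literal comparison.  Kept deliberately
    separate from the library implementation.
    """
    positions = list(region.cpg_positions)
    eligible = []
    for frag in fragments:
        if frag.chrom != region.chrom:
            continue
        idx = [
            i
            for i, p in enumerate(positions)
            if frag.start <= p < frag.end and p in frag.calls
        ]
        if not idx:
            continue
        if idx != list(range(idx[0], idx[-1] + 1)):
            continue
        if any(frag.calls[positions[i]] is STATE["A"] for i in idx):
            continue
        states = "".join(
            "1" if frag.calls[positions[i]] is STATE["1"] else "0" for i in idx
        )
        eligible.append((idx[0], states))
    result = {}
    for start, states in sorted(set(eligible)):
        sup = cov = 0
        for fs, fst in eligible:
            if fs <= start and fs + len(fst) >= start + len(states):
                cov += 1
                if fst[start - fs : start - fs + len(states)] == states:
                    sup += 1
        result[(start, states)] = (sup, cov)
    return result
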