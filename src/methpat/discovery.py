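"""Tissue-phase discovery of tumor-specific per-molecule methylation patterns.

The pipeline mirrors the discovery cascade used for RRBS tissue data:

1. :func:`detect_read_bundles` — find genomic intervals supported by at
   least ten aligned fragments (connected components of fragment
   overlap).
2. :func:`window_regions` — carve each bundle into candidate windows of
   at least four CpGs within at most 150 bp.
3. :func:`count_patterns` — per sample, count supporting/covering
   fragments for every observed per-molecule pattern.
4. :func:`pool_group` — pool reads across samples of a group
   (tumor vs. white-blood-cell background).
5. :func:`specificity_score` — score tumor over-representation (Sp).
6. :func:`filter_candidates` — apply the filter cascade (Sp >= 10,
   zero occurrences in every WBC sample, window geometry, minimum
   pooled tumor frequency, recurrence across tumor samples) and rank
   survivors.

A pattern is any binary string over a contiguous stretch of a region's
CpGs; the machinery is deliberately symmetric in '0' and '1' so that
hypomethylated and heterogeneous tumor patterns are discoverable, not
only fully methylated ones.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from methpat.io_model import CallState, FragmentCall, GenomicRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MethylationPattern:
    """A binary per-molecule pattern over a contiguous CpG stretch.

    ``start_index`` indexes the first covered CpG within the region's
    CpG list; ``states`` is a string over {'0','1'}, '1' = methylated.
    """

    region_id: str
    start_index: int
    states: str

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("pattern states must be non-empty")
        if set(self.states) - {"0", "1"}:
            raise ValueError("pattern states must be over {'0','1'}")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def end_index(self) -> int:
        return self.start_index + len(self.states)

    def contains(self, other: "MethylationPattern") -> bool:
        """True if *other* is a contiguous sub-pattern of this pattern."""
        if other.region_id != self.region_id:
            return False
        off = other.start_index - self.start_index
        if off < 0 or other.end_index > self.end_index:
            return False
        return self.states[off : off + len(other.states)] == other.states


@dataclass
class PatternCount:
    """Supporting/covering fragment counts for one pattern in one sample."""

    sample_id: str
    region_id: str
    pattern: MethylationPattern
    supporting: int
    covering: int

    def __post_init__(self) -> None:
        if not 0 <= self.supporting <= self.covering:
            raise ValueError("require 0 <= supporting <= covering")

    @property
    def frequency(self) -> Optional[float]:
        return self.supporting / self.covering if self.covering else None


@dataclass
class DiscoveryCandidate:
    """A scored (region, pattern) candidate with pooled counts and filters."""

    region: GenomicRegion
    pattern: MethylationPattern
    tumor_count: int
    tumor_total: int
    background_count: int
    background_total: int
    wbc_sample_counts: dict[str, int] = field(default_factory=dict)
    tumor_sample_counts: dict[str, int] = field(default_factory=dict)
    sp: float = 0.0
    filter_flags: dict[str, bool] = field(default_factory=dict)
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tumor_count > self.tumor_total:
            raise ValueError("tumor count exceeds total")
        if self.background_count > self.background_total:
            raise ValueError("background count exceeds total")

    @property
    def tumor_frequency(self) -> float:
        return self.tumor_count / self.tumor_total if self.tumor_total else 0.0

    @property
    def passed(self) -> bool:
        return bool(self.filter_flags) and all(self.filter_flags.values())


@dataclass
class FilterConfig:
    """Thresholds of the discovery filter cascade.

    Defaults implement: Sp >= 10; the pattern never observed in any WBC
    sample (100% background specificity); >= 4 CpGs within a <= 150 bp
    window; pooled tumor pattern frequency >= 0.05; observed in >= 2
    tumor samples.  ``suppress_nested`` drops a survivor whose pattern
    is a proper sub-pattern of a longer surviving pattern in the same
    region (truncations carry near-identical information).
    """

    sp_min: float = 10.0
    wbc_max_occurrences: int = 0
    min_cpgs: int = 4
    max_span: int = 150
    min_tumor_freq: float = 0.05
    min_tumor_samples: int = 2
    suppress_nested: bool = True


# ---------------------------------------------------------------------------
# Bundles and windows
# ---------------------------------------------------------------------------

def detect_read_bundles(
    fragments: Sequence[FragmentCall], min_fragments: int = 10
) -> list[tuple[str, int, int]]:
    """Find genomic intervals supported by at least ``min_fragments`` fragments.

    An interval is the union extent of a connected component of the
    fragment-overlap graph; only components with at least
    ``min_fragments`` members are returned as (chrom, start, end).
    Fragments must be sorted by (chrom, start).
    """
    keys = [(f.chrom, f.start) for f in fragments]
    if keys != sorted(keys):
        raise ValueError("fragments must be sorted by (chrom, start); sort them first")
    bundles: list[tuple[str, int, int]] = []
    cur_chrom: Optional[str] = None
    cur_start = cur_end = 0
    cur_n = 0

    def flush() -> None:
        if cur_chrom is not None and cur_n >= min_fragments:
            bundles.append((cur_chrom, cur_start, cur_end))

    for f in fragments:
        if f.chrom == cur_chrom and f.start < cur_end:
            cur_end = max(cur_end, f.end)
            cur_n += 1
        else:
            flush()
            cur_chrom, cur_start, cur_end, cur_n = f.chrom, f.start, f.end, 1
    flush()
    return bundles


def window_regions(
    bundle: tuple[str, int, int],
    cpg_positions: Sequence[int],
    min_cpgs: int = 4,
    max_span: int = 150,
) -> list[GenomicRegion]:
    """Carve a read bundle into candidate CpG windows.

    For each CpG i the maximal run [i..j] whose window — measured
    inclusive of the final CpG dinucleotide, ``positions[j] + 2 -
    positions[i]`` — fits in ``max_span`` bp is formed left to right;
    runs with at least ``min_cpgs`` CpGs are emitted and runs nested
    inside an already-emitted run are suppressed.  A window's extent is
    [first C, last C + 2), so its genomic span never exceeds
    ``max_span``.
    """
    chrom, bstart, bend = bundle
    pos = [p for p in cpg_positions if bstart <= p < bend]
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("cpg_positions must be sorted strictly increasing")
    regions: list[GenomicRegion] = []
    prev_j = -1
    j = 0
    for i in range(len(pos)):
        j = max(j, i)
        while j + 1 < len(pos) and pos[j + 1] + 2 - pos[i] <= max_span:
            j += 1
        if j - i + 1 < min_cpgs:
            continue
        if j <= prev_j:  # nested inside the previously emitted run
            continue
        start, end = pos[i], pos[j] + 2
        regions.append(
            GenomicRegion(
                region_id=f"{chrom}:{start}-{end}",
                chrom=chrom,
                start=start,
                end=end,
                cpg_offsets=tuple(p - start for p in pos[i : j + 1]),
            )
        )
        prev_j = j
    return regions


# ---------------------------------------------------------------------------
# Pattern counting
# ---------------------------------------------------------------------------

def _fragment_stretch(
    frag: FragmentCall, region: GenomicRegion
) -> Optional[tuple[int, str]]:
    """The (start_index, states) stretch a fragment contributes, or None.

    A fragment contributes only if it covers >= 1 region CpG, all covered
    region CpGs are called unambiguously, and the covered CpG subset is
    contiguous within the region's CpG list (deletions producing gapped
    coverage disqualify the fragment: pattern strings are defined on
    contiguous stretches).
    """
    positions = region.cpg_positions
    lo = bisect_left(positions, frag.start)
    hi = bisect_right(positions, frag.end - 1)
    covered = [i for i in range(lo, hi) if positions[i] in frag.calls]
    if not covered:
        return None
    if covered != list(range(covered[0], covered[-1] + 1)):
        return None
    states = []
    for i in covered:
        state = frag.calls[positions[i]]
        if state is CallState.AMBIG:
            return None
        states.append("1" if state is CallState.METH else "0")
    return covered[0], "".join(states)


def _stretches(
    fragments: Sequence[FragmentCall], region: GenomicRegion
) -> list[tuple[int, str]]:
    """The (start_index, states) stretches of all eligible fragments."""
    out: list[tuple[int, str]] = []
    for frag in fragments:
        if frag.chrom != region.chrom:
            continue
        s = _fragment_stretch(frag, region)
        if s is not None:
            out.append(s)
    return out


def _count_key(
    stretches: Sequence[tuple[int, str]], start: int, states: str
) -> tuple[int, int]:
    """(supporting, covering) of one pattern against raw fragment stretches."""
    end = start + len(states)
    covering = supporting = 0
    for fs, fstates in stretches:
        if fs <= start and fs + len(fstates) >= end:
            covering += 1
            if fstates[start - fs : end - fs] == states:
                supporting += 1
    return supporting, covering


def count_patterns(
    fragments: Sequence[FragmentCall], region: GenomicRegion
) -> dict[tuple[int, str], PatternCount]:
    """Count per-molecule patterns of one sample over one region.

    Each eligible fragment contributes exactly one *observed* pattern:
    its full call vector over the contiguous stretch of region CpGs it
    covers.  For every observed pattern the returned count holds

    * ``supporting`` — fragments whose calls match the pattern at all of
      its CpGs (a fragment supports every truncation of its own
      pattern), and
    * ``covering`` — fragments contributing a stretch that spans all of
      the pattern's CpGs.

    Fragments with any ambiguous call over their covered region CpGs, or
    covering a non-contiguous CpG subset, contribute nothing.
    """
    if region.n_cpgs == 0:
        raise ValueError("region has no CpGs")
    sample_id = fragments[0].sample_id if fragments else ""
    stretches = _stretches(fragments, region)
    observed = sorted(set(stretches))
    out: dict[tuple[int, str], PatternCount] = {}
    for start, states in observed:
        supporting, covering = _count_key(stretches, start, states)
        out[(start, states)] = PatternCount(
            sample_id=sample_id,
            region_id=region.region_id,
            pattern=MethylationPattern(region.region_id, start, states),
            supporting=supporting,
            covering=covering,
        )
    return out


def pool_group(
    per_sample_counts: Mapping[str, Mapping[tuple[int, str], PatternCount]],
    sample_groups: Mapping[str, str],
    group_label: str,
) -> dict[tuple[int, str], tuple[int, int]]:
    """Pool supporting/covering counts across all samples of a group.

    Pooling is read-weighted: pooled count = sum of supporting, pooled
    total = sum of covering, so the pooled frequency is the
    coverage-weighted mean of per-sample frequencies.
    """
    members = [s for s, g in sample_groups.items() if g == group_label]
    if not members:
        logger.warning("group %r has no samples; pooled counts are zero", group_label)
    pooled: dict[tuple[int, str], tuple[int, int]] = {}
    for sample in members:
        for key, pc in per_sample_counts.get(sample, {}).items():
            c, n = pooled.get(key, (0, 0))
            pooled[key] = (c + pc.supporting, n + pc.covering)
    return pooled


def specificity_score(c_t: int, n_t: int, c_b: int, n_b: int) -> float:
    """Cancer-specificity score Sp of a pattern.

    Sp is the smoothed ratio of the pooled tumor pattern frequency to
    the pooled background frequency::

        Sp = (c_T / N_T) / ((c_B + 1) / (N_B + 1))

    The +1 pseudocount keeps Sp finite in the regime of interest
    (patterns never seen in background reads) and makes the discovery
    cut-off Sp >= 10 read as at-least-tenfold tumor enrichment.
    Sp = 0 whenever c_T = 0.
    """
    if n_t <= 0:
        raise ValueError("tumor total N_T must be positive")
    if c_t == 0:
        return 0.0
    return (c_t / n_t) / ((c_b + 1) / (n_b + 1))


# ---------------------------------------------------------------------------
# Candidate assembly and filtering
# ---------------------------------------------------------------------------

def build_candidates(
    regions: Sequence[GenomicRegion],
    per_sample_fragments: Mapping[str, Sequence[FragmentCall]],
    sample_groups: Mapping[str, str],
    tumor_group: str = "case",
    wbc_group: str = "control",
) -> list[DiscoveryCandidate]:
    """Count, pool and score every observed pattern over the given regions."""
    tumor_samples = [s for s, g in sample_groups.items() if g == tumor_group]
    wbc_samples = [s for s, g in sample_groups.items() if g == wbc_group]
    candidates: list[DiscoveryCandidate] = []
    for region in regions:
        stretch_map = {
            s: _stretches(list(per_sample_fragments.get(s, [])), region)
            for s in list(tumor_samples) + list(wbc_samples)
        }
        # candidate keys: every pattern observed as a fragment stretch
        # in any sample; counts are then taken against every sample's
        # fragments so pooled totals reflect true group coverage.
        keys = sorted({k for st in stretch_map.values() for k in st})
        for key in keys:
            start, states = key
            tumor_counts: dict[str, int] = {}
            wbc_counts: dict[str, int] = {}
            c_t = n_t = c_b = n_b = 0
            for s in tumor_samples:
                sup, cov = _count_key(stretch_map[s], start, states)
                tumor_counts[s] = sup
                c_t += sup
                n_t += cov
            for s in wbc_samples:
                sup, cov = _count_key(stretch_map[s], start, states)
                wbc_counts[s] = sup
                c_b += sup
                n_b += cov
            if n_t == 0:
                continue
            pattern = MethylationPattern(region.region_id, start, states)
            candidates.append(
                DiscoveryCandidate(
                    region=region,
                    pattern=pattern,
                    tumor_count=c_t,
                    tumor_total=n_t,
                    background_count=c_b,
                    background_total=n_b,
                    wbc_sample_counts=wbc_counts,
                    tumor_sample_counts=tumor_counts,
                    sp=specificity_score(c_t, n_t, c_b, n_b),
                )
            )
    return candidates


def _pattern_span(candidate: DiscoveryCandidate) -> int:
    # window span inclusive of the final CpG dinucleotide
    positions = candidate.region.cpg_positions
    p = candidate.pattern
    return positions[p.end_index - 1] + 2 - positions[p.start_index]


def filter_candidates(
    candidates: Iterable[DiscoveryCandidate],
    config: Optional[FilterConfig] = None,
) -> list[DiscoveryCandidate]:
    """Apply the discovery filter cascade and rank the survivors.

    Every input candidate gets a named pass/fail flag per filter.
    Survivors (all flags pass) are returned ranked by Sp descending,
    ties broken by pooled tumor frequency descending, then region_id,
    then pattern.  With ``suppress_nested`` (default) a survivor whose
    pattern is a proper contiguous sub-pattern of a longer surviving
    pattern in the same region is dropped in favour of the longer one.
    """
    config = config or FilterConfig()
    cands = list(candidates)
    for c in cands:
        c.filter_flags = {
            "sp": c.sp >= config.sp_min,
            "wbc": all(
                n <= config.wbc_max_occurrences for n in c.wbc_sample_counts.values()
            ),
            "min_cpgs": len(c.pattern) >= config.min_cpgs,
            "max_span": _pattern_span(c) <= config.max_span,
            "tumor_freq": c.tumor_frequency >= config.min_tumor_freq,
            "tumor_samples": sum(
                1 for n in c.tumor_sample_counts.values() if n > 0
            )
            >= config.min_tumor_samples,
        }
        c.rank = None
    survivors = [c for c in cands if c.passed]
    if config.suppress_nested:
        kept: list[DiscoveryCandidate] = []
        for c in survivors:
            nested = any(
                o is not c
                and o.region.region_id == c.region.region_id
                and len(o.pattern) > len(c.pattern)
                and o.pattern.contains(c.pattern)
                for o in survivors
            )
            if not nested:
                kept.append(c)
        survivors = kept
    survivors.sort(
        key=lambda c: (
            -c.sp,
            -c.tumor_frequency,
            c.region.region_id,
            c.pattern.start_index,
            c.pattern.states,
        )
    )
    for i, c in enumerate(survivors, start=1):
        c.rank = i
    return survivors


def enumerate_subpatterns(
    region: GenomicRegion,
    fragments: Sequence[FragmentCall],
    target: MethylationPattern,
) -> dict[tuple[int, str], PatternCount]:
    """Supporting/covering counts for every truncation of a target pattern.

    Truncations are all contiguous sub-stretches (length >= 2) of the
    target's CpGs with the matching restricted to that stretch.  In
    informative marker regions truncation frequencies track the full
    pattern closely, which is why the full pattern can be quantified
    from fragments that do not span the whole region.
    """
    raw: list[tuple[int, str]] = []
    for frag in fragments:
        if frag.chrom != region.chrom:
            continue
        s = _fragment_stretch(frag, region)
        if s is not None:
            raw.append(s)
    out: dict[tuple[int, str], PatternCount] = {}
    sample_id = fragments[0].sample_id if fragments else ""
    for length in range(2, len(target.states) + 1):
        for off in range(len(target.states) - length + 1):
            start = target.start_index + off
            states = target.states[off : off + length]
            covering = supporting = 0
            for fs, fstates in raw:
                if fs <= start and fs + len(fstates) >= start + length:
                    covering += 1
                    if fstates[start - fs : start - fs + length] == states:
                        supporting += 1
            out[(start, states)] = PatternCount(
                sample_id=sample_id,
                region_id=region.region_id,
                pattern=MethylationPattern(region.region_id, start, states),
                supporting=supporting,
                covering=covering,
            )
    return out
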