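"""Serum-phase marker quantification and the three-marker threshold panel.

In serum, each marker region is sequenced ultra-deep (coverage of order
10^5-10^6 molecules) and the *pattern frequency* is the number of reads
containing the tumor pattern divided by the total reads covering the
pattern's CpGs.  A sample is panel-positive if at least one valid
marker's frequency lies strictly above its named cut-off.

Three named threshold sets are shipped:

* ``sets12``  — the cut-offs chosen on serum development sets
  (#141: 8e-4, #204: 1e-4, #228: 1e-4),
* ``refined`` — the refined final cut-offs
  (#141: 8e-4, #204: 3e-5, #228: 1e-5),
* ``ukctocs`` — the refined set divided by three, compensating for
  white-blood-cell DNA leakage in long-transit screening-trial sera
  (#141: 2.7e-4, #204: 1e-5, #228: 3.3e-6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from methpat.discovery import MethylationPattern, _fragment_stretch
from methpat.io_model import CallState, FragmentCall, GenomicRegion

MARKER_141 = "#141"
MARKER_204 = "#204"
MARKER_228 = "#228"


@dataclass(frozen=True)
class ThresholdSet:
    """Named per-marker pattern-frequency cut-offs."""

    name: str
    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        for marker, t in self.thresholds.items():
            if not 0 < t < 1:
                raise ValueError(
                    f"threshold for {marker} must be in (0, 1); got {t}"
                )
        object.__setattr__(self, "thresholds", dict(self.thresholds))

    def __getitem__(self, marker: str) -> float:
        return self.thresholds[marker]


@dataclass
class MarkerQuantification:
    """Pattern frequency of one marker in one sample.

    ``frequency`` is absent (None) when no fragment covers the pattern;
    such a marker is *invalid* and contributes nothing to the panel
    call.  ``low_coverage_flag`` marks coverage below 100,000 molecules;
    it is a QC annotation only and never an exclusion.
    """

    sample_id: str
    region_id: str
    supporting: int
    covering: int
    low_coverage_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.supporting <= self.covering:
            raise ValueError("require 0 <= supporting <= covering")

    @property
    def frequency(self) -> Optional[float]:
        return self.supporting / self.covering if self.covering else None

    @property
    def valid(self) -> bool:
        return self.covering > 0


@dataclass
class PanelCall:
    """Per-marker and overall panel decision for one sample."""

    sample_id: str
    marker_status: dict[str, str]  # region_id -> positive|negative|invalid
    overall: str  # positive|negative|not_evaluable
    threshold_set: str

    def __post_init__(self) -> None:
        valid = {m: s for m, s in self.marker_status.items() if s != "invalid"}
        if not valid:
            expect = "not_evaluable"
        elif any(s == "positive" for s in valid.values()):
            expect = "positive"
        else:
            expect = "negative"
        if self.overall != expect:
            raise ValueError(
                f"overall {self.overall!r} inconsistent with marker statuses"
            )


LOW_COVERAGE_CUTOFF = 100_000


def quantify_marker(
    fragments: Sequence[FragmentCall],
    region: GenomicRegion,
    target_pattern: MethylationPattern,
) -> MarkerQuantification:
    """Quantify a target pattern's frequency from ultra-deep serum reads.

    ``covering`` counts fragments with unambiguous calls at *all* of the
    target pattern's CpGs; ``supporting`` counts the covering fragments
    whose calls match the pattern exactly at those CpGs.  Fragments with
    an ambiguous call at any target CpG enter neither numerator nor
    denominator.  Zero covering fragments makes the marker invalid.
    """
    positions = region.cpg_positions
    lo, hi = target_pattern.start_index, target_pattern.end_index
    if hi > len(positions):
        raise ValueError("target pattern exceeds region CpG count")
    target_positions = positions[lo:hi]
    supporting = covering = 0
    sample_id = fragments[0].sample_id if fragments else ""
    for frag in fragments:
        if frag.chrom != region.chrom:
            continue
        states = []
        ok = True
        for pos in target_positions:
            state = frag.calls.get(pos)
            if state is None or state is CallState.AMBIG:
                ok = False
                break
            states.append("1" if state is CallState.METH else "0")
        if not ok:
            continue
        covering += 1
        if "".join(states) == target_pattern.states:
            supporting += 1
    return MarkerQuantification(
        sample_id=sample_id,
        region_id=region.region_id,
        supporting=supporting,
        covering=covering,
        low_coverage_flag=covering < LOW_COVERAGE_CUTOFF,
    )


def call_panel(
    quantifications: Sequence[MarkerQuantification], threshold_set: ThresholdSet
) -> PanelCall:
    """Make the any-marker-above panel decision for one sample.

    A marker is positive iff its frequency is strictly above its
    cut-off ("above" is read strictly; at 10^5-read denominators exact
    boundary ties are vanishingly rare).  Invalid markers (no covering
    reads) are ignored; a sample with no valid marker is not evaluable.
    """
    if not quantifications:
        raise ValueError("at least one marker quantification required")
    status: dict[str, str] = {}
    for q in quantifications:
        if q.region_id not in threshold_set.thresholds:
            raise ValueError(
                f"no threshold for marker {q.region_id!r} in set "
                f"{threshold_set.name!r}"
            )
        if not q.valid:
            status[q.region_id] = "invalid"
        elif q.frequency > threshold_set[q.region_id]:
            status[q.region_id] = "positive"
        else:
            status[q.region_id] = "negative"
    valid = [s for s in status.values() if s != "invalid"]
    if not valid:
        overall = "not_evaluable"
    elif "positive" in valid:
        overall = "positive"
    else:
        overall = "negative"
    return PanelCall(
        sample_id=quantifications[0].sample_id,
        marker_status=status,
        overall=overall,
        threshold_set=threshold_set.name,
    )


def named_threshold_sets() -> dict[str, ThresholdSet]:
    """The three shipped threshold presets (see module docstring)."""
    return {
        "sets12": ThresholdSet(
            "sets12",
            {MARKER_141: 0.0008, MARKER_204: 0.0001, MARKER_228: 0.0001},
        ),
        "refined": ThresholdSet(
            "refined",
            {MARKER_141: 0.0008, MARKER_204: 0.00003, MARKER_228: 0.00001},
        ),
        "ukctocs": ThresholdSet(
            "ukctocs",
            {MARKER_141: 0.00027, MARKER_204: 0.00001, MARKER_228: 0.0000033},
        ),
    }


def _round_2_sig(x: float) -> float:
    return round(x, -int(math.floor(math.log10(abs(x)))) + 1)


def scale_threshold_set(threshold_set: ThresholdSet, factor: float) -> ThresholdSet:
    """Divide every cut-off by ``factor`` and round to 2 significant digits.

    Dividing the refined set by 3 reproduces the screening-trial
    (``ukctocs``) preset; the rescaling compensates for dilution of the
    tumor signal by leaked white-blood-cell DNA.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    name = threshold_set.name if factor == 1 else f"{threshold_set.name}/{factor:g}"
    return ThresholdSet(
        name,
        {m: _round_2_sig(t / factor) for m, t in threshold_set.thresholds.items()},
    )
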