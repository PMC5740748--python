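"""Domain types and readers/writers for read-level methylation calls.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open internally (BED-style); SAM's
1-based positions are converted on parse.  A CpG site is identified by
the position of its forward-strand cytosine; calls made on the G of a
reverse-strand alignment are collapsed to C-1 so that every CpG unit has
exactly one coordinate, as binary pattern strings require.

The canonical on-disk carrier for per-molecule calls is a plain TSV
(``sample_id  chrom  start  end  pos:state;pos:state;...``), which keeps
fixtures desk-scale and language-agnostic; SAM with a Bismark-style
methylation call tag is supported as an importer.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

logger = logging.getLogger(__name__)

GROUPS = frozenset(
    {
        "healthy",
        "benign_mass",
        "borderline",
        "non_epithelial",
        "other_cancer",
        "oc_non_hgs",
        "oc_hgs",
        "control",
        "case",
    }
)
COHORTS = frozenset({"set1", "set2", "set3", "nact", "ukctocs", "synthetic"})
TIMEPOINTS = frozenset({"pre", "post_cycle1", "post_cycle2"})
RESPONSES = frozenset({"responder", "non_responder", "unknown"})
RESIDUAL = frozenset({"R0_1", "macroscopic", "unknown"})


class CallState(str, Enum):
    """Methylation state of a single CpG on a single molecule."""

    METH = "M"
    UNMETH = "U"
    AMBIG = "A"


@dataclass(frozen=True)
class GenomicRegion:
    """A candidate genomic window with the CpG sites it contains.

    ``cpg_offsets`` are offsets from ``start`` of the forward-strand C of
    each CpG, strictly increasing.  A typical marker region is on the
    order of 136 bp and carries 4-16 linked CpGs.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    cpg_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.region_id}: end must exceed start")
        offs = tuple(self.cpg_offsets)
        object.__setattr__(self, "cpg_offsets", offs)
        if not offs:
            raise ValueError(f"region {self.region_id}: at least one CpG required")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError(
                f"region {self.region_id}: cpg_offsets must be strictly increasing"
            )
        if offs[0] < 0 or offs[-1] >= self.end - self.start:
            raise ValueError(
                f"region {self.region_id}: cpg_offsets must lie in [0, end-start)"
            )

    @property
    def cpg_positions(self) -> tuple[int, ...]:
        """Absolute forward-strand C positions of the region's CpGs."""
        return tuple(self.start + o for o in self.cpg_offsets)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentCall:
    """Per-CpG methylation calls of one sequenced DNA molecule.

    ``calls`` maps the genomic CpG position (forward-strand C) to its
    state.  Ambiguous calls (e.g. mate disagreement) are kept as
    :attr:`CallState.AMBIG`; downstream counting excludes them, never
    imputes.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    calls: dict[int, CallState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")
        for pos in self.calls:
            if not (self.start <= pos < self.end):
                raise ValueError(
                    f"call position {pos} outside fragment extent "
                    f"[{self.start}, {self.end})"
                )


@dataclass
class SampleRecord:
    """Clinical metadata for one serum (or tissue) sample."""

    sample_id: str
    cohort: str
    group: str
    stage: Optional[str] = None
    ca125: Optional[float] = None
    timepoint: Optional[str] = None
    dna_conc: Optional[float] = None
    small_frag_fraction: Optional[float] = None
    clinical_response: Optional[str] = None
    residual_disease: Optional[str] = None
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; allowed: {sorted(GROUPS)}"
            )
        if self.ca125 is not None and self.ca125 < 0:
            raise ValueError("ca125 must be >= 0")
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r}; allowed: {sorted(TIMEPOINTS)}"
            )
        if (
            self.small_frag_fraction is not None
            and not 0 <= self.small_frag_fraction <= 1
        ):
            raise ValueError("small_frag_fraction must be in [0, 1]")
        if (
            self.clinical_response is not None
            and self.clinical_response not in RESPONSES
        ):
            raise ValueError(f"unknown clinical_response {self.clinical_response!r}")
        if self.residual_disease is not None and self.residual_disease not in RESIDUAL:
            raise ValueError(f"unknown residual_disease {self.residual_disease!r}")


# ---------------------------------------------------------------------------
# SAM import (Bismark methylation-call dialect)
# ---------------------------------------------------------------------------

def _fragment_from_aligned_segment(aln, sample_id: str) -> Optional[FragmentCall]:
    """Decode one aligned segment's methylation call tag into a FragmentCall.

    Only CpG-context characters are interpreted: 'Z' = methylated,
    'z' = unmethylated.  On reverse-strand alignments the call sits on
    the G of the CpG and is collapsed to the forward-strand C (pos - 1).
    Returns None for records that must be skipped.
    """
    if aln.is_unmapped:
        return None
    try:
        tag = aln.get_tag("XM")
    except KeyError:
        logger.warning("read %s has no XM methylation tag; skipped", aln.query_name)
        return None
    seq_len = aln.query_length or (len(aln.query_sequence or ""))
    if seq_len and len(tag) != seq_len:
        logger.warning(
            "read %s: XM tag length %d != read length %d; record rejected",
            aln.query_name,
            len(tag),
            seq_len,
        )
        return None
    calls: dict[int, CallState] = {}
    # The bisulfite strand decides whether a CpG call sits on the C
    # (top strand, XG:Z:CT) or on the G (bottom strand, XG:Z:GA, shift
    # to C-1).  Fall back to the SAM reverse flag when XG is absent.
    try:
        strand = aln.get_tag("XG")
        shift = -1 if strand == "GA" else 0
    except KeyError:
        shift = -1 if aln.is_reverse else 0
    for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
        ch = tag[qpos]
        if ch == "Z":
            calls[rpos + shift] = CallState.METH
        elif ch == "z":
            calls[rpos + shift] = CallState.UNMETH
    start = min(aln.reference_start, *calls.keys()) if calls else aln.reference_start
    end = max(aln.reference_end, *(p + 1 for p in calls)) if calls else aln.reference_end
    return FragmentCall(
        sample_id=sample_id,
        chrom=aln.reference_name,
        start=start,
        end=end,
        calls=calls,
    )


def parse_bisulfite_alignments(
    path: Union[str, Path], sample_id: Optional[str] = None
) -> list[FragmentCall]:
    """Import aligned bisulfite reads from SAM into per-template fragments.

    Records must carry a Bismark-style methylation call string in the XM
    tag (uppercase = methylated, lowercase = unmethylated; only the
    CpG-context characters 'Z'/'z' are interpreted, everything else is
    ignored).  Mate pairs are merged into a single fragment via
    :func:`merge_mates`; the fragment, not the read, is the counting
    unit downstream.

    Malformed records (tag length inconsistent with the alignment) are
    rejected with a logged warning; unmapped reads are skipped.
    """
    import pysam

    path = str(path)
    if sample_id is None:
        sample_id = Path(path).stem
    by_name: dict[str, FragmentCall] = {}
    out: list[FragmentCall] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for aln in fh:
            frag = _fragment_from_aligned_segment(aln, sample_id)
            if frag is None:
                continue
            name = aln.query_name
            if aln.is_paired and name in by_name:
                out.append(merge_mates(by_name.pop(name), frag))
            elif aln.is_paired:
                by_name[name] = frag
            else:
                out.append(frag)
    # unpaired leftovers (mate unmapped or absent) count as fragments
    out.extend(by_name.values())
    return out


def merge_mates(mate1: FragmentCall, mate2: FragmentCall) -> FragmentCall:
    """Merge the two mates of a paired-end template into one fragment.

    The extent is the union of the mates' extents and the call map the
    union of their calls; a position where the mates disagree
    (METH vs UNMETH) becomes AMBIG.  Merging is commutative.
    """
    if mate1.chrom != mate2.chrom:
        raise ValueError(
            f"mates on different chromosomes ({mate1.chrom} vs {mate2.chrom}): "
            "corrupt pairing"
        )
    if mate1.sample_id != mate2.sample_id:
        raise ValueError("mates from different samples: corrupt pairing")
    calls = dict(mate1.calls)
    for pos, state in mate2.calls.items():
        if pos in calls and calls[pos] != state:
            calls[pos] = CallState.AMBIG
        else:
            calls.setdefault(pos, state)
    return FragmentCall(
        sample_id=mate1.sample_id,
        chrom=mate1.chrom,
        start=min(mate1.start, mate2.start),
        end=max(mate1.end, mate2.end),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Region table (BED-derived TSV)
# ---------------------------------------------------------------------------

_REGION_COLUMNS = ("chrom", "start", "end", "region_id", "pattern", "cpg_offsets")


def read_region_table(path: Union[str, Path]) -> list[tuple[GenomicRegion, str]]:
    """Read a marker region table: (region, target pattern string) rows.

    Tab-separated columns: chrom, start, end, region_id, pattern,
    comma-joined cpg_offsets.  A header row matching the column names is
    permitted and skipped.
    """
    rows: list[tuple[GenomicRegion, str]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[: len(_REGION_COLUMNS)] == list(_REGION_COLUMNS):
                continue
            if len(parts) < 6:
                raise ValueError(f"region table row {lineno}: expected 6 columns")
            chrom, start_s, end_s, region_id, pattern, offs_s = parts[:6]
            try:
                offsets = tuple(int(x) for x in offs_s.split(",") if x != "")
                region = GenomicRegion(
                    region_id=region_id,
                    chrom=chrom,
                    start=int(start_s),
                    end=int(end_s),
                    cpg_offsets=offsets,
                )
            except ValueError as exc:
                raise ValueError(f"region table row {lineno} ({region_id}): {exc}")
            if pattern and (
                len(pattern) > region.n_cpgs or set(pattern) - {"0", "1"}
            ):
                raise ValueError(
                    f"region table row {lineno} ({region_id}): pattern {pattern!r} "
                    f"invalid for {region.n_cpgs} CpGs"
                )
            rows.append((region, pattern))
    return rows


def write_region_table(
    path: Union[str, Path], rows: Iterable[tuple[GenomicRegion, str]]
) -> None:
    """Write a marker region table; inverse of :func:`read_region_table`."""
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(_REGION_COLUMNS) + "\n")
        for region, pattern in rows:
            fh.write(
                "\t".join(
                    [
                        region.chrom,
                        str(region.start),
                        str(region.end),
                        region.region_id,
                        pattern,
                        ",".join(str(o) for o in region.cpg_offsets),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Canonical per-molecule call TSV
# ---------------------------------------------------------------------------

def read_fragment_tsv(path: Union[str, Path]) -> list[FragmentCall]:
    """Read the canonical read-call TSV.

    Columns: sample_id, chrom, start, end, semicolon-joined ``pos:state``
    entries with state one of M/U/A.  An empty fifth column means a
    fragment with no CpG evidence.
    """
    frags: list[FragmentCall] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":
                continue
            if len(parts) < 4:
                raise ValueError(f"read-call TSV row {lineno}: expected >= 4 columns")
            sample_id, chrom, start_s, end_s = parts[:4]
            calls: dict[int, CallState] = {}
            if len(parts) > 4 and parts[4]:
                for item in parts[4].split(";"):
                    pos_s, state_s = item.split(":")
                    calls[int(pos_s)] = CallState(state_s)
            frags.append(
                FragmentCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(start_s),
                    end=int(end_s),
                    calls=calls,
                )
            )
    return frags


def write_fragment_tsv(path: Union[str, Path], frags: Iterable[FragmentCall]) -> None:
    """Write fragments as the canonical read-call TSV (sorted call order)."""
    with open(path, "w", newline="") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcalls\n")
        for f in frags:
            call_s = ";".join(
                f"{pos}:{f.calls[pos].value}" for pos in sorted(f.calls)
            )
            fh.write(f"{f.sample_id}\t{f.chrom}\t{f.start}\t{f.end}\t{call_s}\n")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_FLOAT_FIELDS = {"ca125", "dna_conc", "small_frag_fraction"}
_OPTIONAL_STR_FIELDS = {
    "stage",
    "timepoint",
    "clinical_response",
    "residual_disease",
    "patient_id",
}


def read_sample_sheet(path: Union[str, Path]) -> list[SampleRecord]:
    """Read a sample sheet CSV into vocabulary-checked records.

    Required columns: sample_id, cohort, group.  Optional columns (empty
    cells become absent, never zero): stage, ca125, timepoint, dna_conc,
    small_frag_fraction, clinical_response, residual_disease,
    patient_id.  Unknown columns are preserved in the file but ignored.
    """
    records: list[SampleRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            kwargs: dict = {
                "sample_id": row["sample_id"],
                "cohort": row.get("cohort", "synthetic") or "synthetic",
                "group": row["group"],
            }
            for name in _FLOAT_FIELDS:
                raw = (row.get(name) or "").strip()
                if raw:
                    kwargs[name] = float(raw)
            for name in _OPTIONAL_STR_FIELDS:
                raw = (row.get(name) or "").strip()
                if raw:
                    kwargs[name] = raw
            records.append(SampleRecord(**kwargs))
    return records


def write_sample_sheet(path: Union[str, Path], records: Iterable[SampleRecord]) -> None:
    """Write sample records as CSV; inverse of :func:`read_sample_sheet`."""
    cols = [
        "sample_id",
        "cohort",
        "group",
        "stage",
        "ca125",
        "timepoint",
        "dna_conc",
        "small_frag_fraction",
        "clinical_response",
        "residual_disease",
        "patient_id",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            writer.writerow(
                ["" if getattr(r, c) is None else getattr(r, c) for c in cols]
            )
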