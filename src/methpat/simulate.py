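"""Synthetic cohorts with the statistical structure of a serum methylation study.

The generator emulates, at desk scale, the data a per-molecule
methylation-pattern liquid-biopsy study produces:

* tissue-phase bisulfite fragments over planted tumor-specific regions
  and null regions, for validating the discovery cascade;
* serum-phase ultra-deep per-marker counts, where the expected target
  pattern frequency of a sample with tumor fraction ``phi`` is

      q = (phi / lambda) * m + (1 - phi / lambda) * eps**K

  with ``m`` the fraction of tumor molecules carrying the full pattern,
  ``eps`` the independent per-CpG background methylation noise, ``K``
  the number of pattern CpGs, and ``lambda >= 1`` the dilution of the
  tumor signal by white-blood-cell DNA leaking into serum during
  delayed processing (leakage also inflates total DNA concentration);
* CA125 values calibrated so that the clinical 35 IU/mL cut-off
  reaches roughly 83% sensitivity for high-grade serous cases and 87%
  specificity for controls;
* three-timepoint NACT series in which the tumor fraction of
  responders decays geometrically with treatment cycle.

All draws are deterministic given (seed, config); per-sample streams
are derived by stable hashing of (seed, sample_id) so cohorts are
reproducible under reordering.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from methpat.discovery import MethylationPattern
from methpat.io_model import (
    CallState,
    FragmentCall,
    GenomicRegion,
    SampleRecord,
    write_fragment_tsv,
    write_region_table,
    write_sample_sheet,
)
from methpat.panel import MarkerQuantification, LOW_COVERAGE_CUTOFF

LN35 = math.log(35.0)


@dataclass(frozen=True)
class RegionSpec:
    """Shape of one marker region: CpG count and window span in bp."""

    region_id: str
    n_cpgs: int
    span: int

    def __post_init__(self) -> None:
        if self.n_cpgs < 4:
            raise ValueError("marker regions carry at least 4 CpGs")
        if self.span < 2 * self.n_cpgs:
            raise ValueError("span too small for CpG count")


# Default marker geometry: #141 is a 136-bp window with seven linked
# CpGs; the other two markers are given plausible shapes of the same
# class (the pipeline only uses CpG count and span).
DEFAULT_REGIONS = (
    RegionSpec("#141", 7, 136),
    RegionSpec("#204", 5, 118),
    RegionSpec("#228", 6, 131),
)

# Per-group log-normal parameters (mu, sigma) of the tumor fraction phi.
# Groups not listed shed no tumor DNA (phi = 0).  Medians are set so
# that phi*m for high-grade serous cases sits around 1e-4, the serum
# operating regime of the assay.
DEFAULT_PHI = {
    "oc_hgs": (math.log(1.25e-4), 1.5),
    "case": (math.log(1.25e-4), 1.5),
    "oc_non_hgs": (math.log(3e-5), 1.5),
    "other_cancer": (math.log(1.5e-5), 1.5),
    "borderline": (math.log(8e-6), 1.5),
    "non_epithelial": (math.log(8e-6), 1.5),
}

# Per-group log-normal parameters of CA125 (IU/mL).  Calibrated so that
# P(value > 35) is ~0.83 for high-grade serous cases and ~0.13 for
# healthy controls: mu = ln(35) - z_group * sigma with
# z = Phi^-1(1 - target sensitivity/1 - specificity).
DEFAULT_CA125 = {
    "oc_hgs": (LN35 + 0.9541653 * 1.2, 1.2),
    "case": (LN35 + 0.9541653 * 1.2, 1.2),
    "healthy": (LN35 - 1.1263911 * 0.9, 0.9),
    "control": (LN35 - 1.1263911 * 0.9, 0.9),
    "benign_mass": (LN35 - 0.8416212 * 1.0, 1.0),
    "non_epithelial": (LN35 - 0.8416212 * 1.0, 1.0),
    "other_cancer": (LN35 - 0.5244005 * 1.1, 1.1),
    "borderline": (LN35 - 0.3853205 * 1.1, 1.1),
    "oc_non_hgs": (LN35 + 0.2533471 * 1.2, 1.2),
}

PRESET_GROUPS = {
    "set3_like": {"healthy": 20, "benign_mass": 20, "oc_hgs": 20},
    "ukctocs_like": {"control": 30, "case": 15},
    "nact_like": {},  # patients are generated by simulate_nact_series
}


@dataclass
class SimConfig:
    """Generative parameters of the synthetic study.

    Defaults are the study conditions the rest of the package is
    validated against; the docstrings of the individual simulators say
    which aspect of the real data each parameter emulates.
    """

    seed: int = 0
    regions: tuple[RegionSpec, ...] = DEFAULT_REGIONS
    phi_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHI)
    )
    methylated_tumor_fraction: float = 0.8  # m: tumor molecules carrying the pattern
    background_noise: float = 0.003  # eps: per-CpG background methylation
    cpg_correlation: float = 0.0  # neighbour-state copy probability in background
    coverage_mean: float = 100_000.0  # C: mean molecules per marker (Poisson)
    leakage: float = 1.0  # lambda >= 1: WBC-DNA dilution factor
    invalid_rate: float = 0.01  # per-marker probability of assay failure
    small_frag_fraction_mean: float = 0.55  # apoptotic (50-250 bp) DNA fraction
    dna_conc_median: float = 20.0  # ng DNA per mL serum, before leakage
    ca125_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CA125)
    )
    nact_phi0_lognormal: tuple[float, float] = (math.log(1e-3), 0.8)
    nact_decay: float = 0.05  # d: per-cycle phi multiplier in responders
    ca125_decay: float = 0.5  # weaker per-cycle decay of CA125 in responders
    n_nact_patients: int = 20
    responder_prob: float = 0.55
    # tissue mode
    fragments_per_region: float = 200.0
    partial_coverage_rate: float = 0.2
    n_tumor_samples: int = 6
    n_wbc_samples: int = 6
    n_null_regions: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.methylated_tumor_fraction <= 1:
            raise ValueError("methylated_tumor_fraction must be in (0, 1]")
        if not 0 <= self.background_noise <= 0.05:
            raise ValueError("background_noise must be in [0, 0.05]")
        if self.leakage < 1:
            raise ValueError("leakage must be >= 1")
        if not 0 < self.nact_decay <= 1:
            raise ValueError("nact_decay must be in (0, 1]")
        if not 0 <= self.invalid_rate < 1:
            raise ValueError("invalid_rate must be in [0, 1)")
        for spec in self.regions:
            if spec.n_cpgs < 4:
                raise ValueError("regions need >= 4 CpGs")


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-(seed, keys) random stream via stable hashing."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def region_from_spec(spec: RegionSpec, chrom: str = "chrS", start: int = 0) -> GenomicRegion:
    """Lay out a region with evenly spaced CpGs over its span."""
    k, span = spec.n_cpgs, spec.span
    offsets = tuple(round(i * (span - 2) / (k - 1)) for i in range(k))
    return GenomicRegion(
        region_id=spec.region_id,
        chrom=chrom,
        start=start,
        end=start + span,
        cpg_offsets=offsets,
    )


def target_pattern(spec: RegionSpec) -> MethylationPattern:
    """The fully methylated target pattern over all of a region's CpGs."""
    return MethylationPattern(spec.region_id, 0, "1" * spec.n_cpgs)


# ---------------------------------------------------------------------------
# Tissue phase
# ---------------------------------------------------------------------------

def _background_states(k: int, eps: float, corr: float, rng: np.random.Generator) -> str:
    if corr <= 0:
        return "".join("1" if b else "0" for b in rng.random(k) < eps)
    states = []
    for i in range(k):
        if i > 0 and rng.random() < corr:
            states.append(states[-1])
        else:
            states.append("1" if rng.random() < eps else "0")
    return "".join(states)


def _simulate_region_fragments(
    sample_id: str,
    region: GenomicRegion,
    is_tumor_marker: bool,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[FragmentCall]:
    positions = region.cpg_positions
    k = len(positions)
    n = rng.poisson(config.fragments_per_region)
    frags: list[FragmentCall] = []
    for _ in range(n):
        if rng.random() < config.partial_coverage_rate and k > 2:
            length = int(rng.integers(2, k + 1))
            a = int(rng.integers(0, k - length + 1))
            idx = range(a, a + length)
        else:
            idx = range(k)
        covered = [positions[i] for i in idx]
        if is_tumor_marker and rng.random() < config.methylated_tumor_fraction:
            states = "1" * len(covered)
        else:
            states = _background_states(
                len(covered), config.background_noise, config.cpg_correlation, rng
            )
        calls = {
            pos: CallState.METH if s == "1" else CallState.UNMETH
            for pos, s in zip(covered, states)
        }
        frags.append(
            FragmentCall(
                sample_id=sample_id,
                chrom=region.chrom,
                start=covered[0],
                end=covered[-1] + 2,
                calls=calls,
            )
        )
    return frags


def simulate_tissue_cohort(
    config: SimConfig,
) -> tuple[
    list[GenomicRegion],
    dict[str, MethylationPattern],
    dict[str, list[FragmentCall]],
    dict[str, str],
]:
    """Simulate the tissue discovery setting: tumor vs. WBC fragment sets.

    ``config.regions`` are the planted tumor-specific regions: in tumor
    samples a fraction ``m`` of molecules over them carries the fully
    methylated pattern, the rest (and all molecules in WBC samples and
    over the ``n_null_regions`` null regions) follow the independent
    per-CpG noise model at rate ``eps``.  Fragment extents cover either
    the full region or a random contiguous CpG sub-stretch
    (``partial_coverage_rate``).

    Returns (regions, target patterns per planted region, fragments per
    sample, group per sample) with groups "case" (tumor) and
    "control" (WBC).
    """
    layout_rng = _rng(config.seed, "tissue-layout")
    regions: list[GenomicRegion] = []
    cursor = 1000
    planted_ids = set()
    for spec in config.regions:
        regions.append(region_from_spec(spec, start=cursor))
        planted_ids.add(spec.region_id)
        cursor += 1000
    for i in range(config.n_null_regions):
        spec = RegionSpec(
            f"null{i:03d}",
            int(layout_rng.integers(4, 9)),
            int(layout_rng.integers(100, 151)),
        )
        regions.append(region_from_spec(spec, start=cursor))
        cursor += 1000
    targets = {spec.region_id: target_pattern(spec) for spec in config.regions}
    samples = [(f"tumor{i:02d}", "case") for i in range(config.n_tumor_samples)] + [
        (f"wbc{i:02d}", "control") for i in range(config.n_wbc_samples)
    ]
    frags: dict[str, list[FragmentCall]] = {}
    groups: dict[str, str] = {}
    for sample_id, group in samples:
        groups[sample_id] = group
        out: list[FragmentCall] = []
        for region in regions:
            rng = _rng(config.seed, "tissue", sample_id, region.region_id)
            out.extend(
                _simulate_region_fragments(
                    sample_id,
                    region,
                    group == "case" and region.region_id in planted_ids,
                    config,
                    rng,
                )
            )
        out.sort(key=lambda f: (f.chrom, f.start))
        frags[sample_id] = out
    return regions, targets, frags, groups


# ---------------------------------------------------------------------------
# Serum phase
# ---------------------------------------------------------------------------

def draw_tumor_fraction(group: str, config: SimConfig, rng: np.random.Generator) -> float:
    """Draw a sample's tumor fraction phi (0 for non-shedding groups)."""
    params = config.phi_lognormal.get(group)
    if params is None:
        return 0.0
    mu, sigma = params
    return float(min(rng.lognormal(mu, sigma), 1.0))


def pattern_rate(phi: float, config: SimConfig, n_cpgs: int) -> float:
    """Expected target-pattern frequency q for a given tumor fraction."""
    eff = min(phi / config.leakage, 1.0)
    eps_k = config.background_noise**n_cpgs
    return eff * config.methylated_tumor_fraction + (1.0 - eff) * eps_k


def simulate_serum_counts(
    sample_group: str,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    phi: Optional[float] = None,
) -> tuple[float, dict[str, tuple[int, int]]]:
    """Simulate per-marker (supporting, covering) counts for one sample.

    Coverage is Poisson with mean ``coverage_mean`` (zero with
    probability ``invalid_rate``, emulating assay failure); supporting
    reads are binomial with the closed-form pattern rate ``q``.
    Returns (phi, counts per marker).
    """
    rng = rng if rng is not None else _rng(config.seed, "serum", sample_group)
    if phi is None:
        phi = draw_tumor_fraction(sample_group, config, rng)
    counts: dict[str, tuple[int, int]] = {}
    for spec in config.regions:
        if rng.random() < config.invalid_rate:
            counts[spec.region_id] = (0, 0)
            continue
        covering = int(rng.poisson(config.coverage_mean))
        q = pattern_rate(phi, config, spec.n_cpgs)
        supporting = int(rng.binomial(covering, q)) if covering else 0
        counts[spec.region_id] = (supporting, covering)
    return phi, counts


def simulate_ca125(
    group: str, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> float:
    """Draw a CA125 value (IU/mL) from the group's log-normal model."""
    rng = rng if rng is not None else _rng(config.seed, "ca125", group)
    mu, sigma = config.ca125_lognormal.get(group, config.ca125_lognormal["healthy"])
    return float(rng.lognormal(mu, sigma))


def estimate_tumor_fraction(
    frequency: float, m: float, epsilon: float, n_cpgs: int
) -> float:
    """Invert the pattern-rate model: recover phi/lambda from a frequency."""
    eps_k = epsilon**n_cpgs
    if m <= eps_k:
        raise ValueError("m must exceed the background full-pattern rate")
    return (frequency - eps_k) / (m - eps_k)


# ---------------------------------------------------------------------------
# NACT series
# ---------------------------------------------------------------------------

@dataclass
class NACTPatientSim:
    """Simulated three-timepoint serum series of one NACT patient."""

    patient_id: str
    clinical_response: str
    residual_disease: str
    phi0: float
    # timepoint -> (ca125, {region_id: (supporting, covering)})
    timepoints: dict[str, tuple[float, dict[str, tuple[int, int]]]]


NACT_TIMEPOINTS = ("pre", "post_cycle1", "post_cycle2")


def simulate_nact_series(config: SimConfig) -> list[NACTPatientSim]:
    """Simulate pre / post-cycle-1 / post-cycle-2 samples per patient.

    Responders' tumor fraction decays geometrically,
    ``phi_t = phi0 * d**t`` with ``d = nact_decay``; non-responders keep
    d = 1.  CA125 decays with the weaker ``ca125_decay`` in responders,
    reflecting its longer serum half-life and non-tumor sources.
    """
    patients: list[NACTPatientSim] = []
    for i in range(config.n_nact_patients):
        pid = f"nact{i:02d}"
        rng = _rng(config.seed, "nact", pid)
        responder = rng.random() < config.responder_prob
        residual = "R0_1" if rng.random() < (0.8 if responder else 0.6) else "macroscopic"
        mu, sigma = config.nact_phi0_lognormal
        phi0 = float(min(rng.lognormal(mu, sigma), 1.0))
        ca0 = float(rng.lognormal(*config.ca125_lognormal["oc_hgs"]))
        d = config.nact_decay if responder else 1.0
        d_ca = config.ca125_decay if responder else 1.0
        tps: dict[str, tuple[float, dict[str, tuple[int, int]]]] = {}
        for t, tp in enumerate(NACT_TIMEPOINTS):
            phi_t = phi0 * d**t
            _, counts = simulate_serum_counts(
                "oc_hgs", config, rng=_rng(config.seed, "nact", pid, tp), phi=phi_t
            )
            tps[tp] = (ca0 * d_ca**t, counts)
        patients.append(
            NACTPatientSim(
                patient_id=pid,
                clinical_response="responder" if responder else "non_responder",
                residual_disease=residual,
                phi0=phi0,
                timepoints=tps,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

def simulate_cohort(
    preset: str,
    config: SimConfig,
    out_dir: Optional[Union[str, Path]] = None,
) -> tuple[list[SampleRecord], list[MarkerQuantification]]:
    """Generate a full serum cohort under a named preset.

    Presets:

    * ``set3_like`` — prospective diagnostic setting: healthy and
      benign-mass controls vs. high-grade serous cases, no leakage;
    * ``ukctocs_like`` — screening-trial setting: delayed serum
      separation modelled as leakage lambda = 3 (tumor signal diluted
      threefold, DNA concentration inflated threefold, small-fragment
      fraction down to a mean of 0.199);
    * ``nact_like`` — three-timepoint chemotherapy series.

    Returns (sample records, marker quantifications); when ``out_dir``
    is given, writes ``sample_sheet.csv``, ``quantifications.tsv`` and
    ``regions.tsv``.
    """
    if preset not in PRESET_GROUPS:
        raise ValueError(
            f"unknown preset {preset!r}; allowed: {sorted(PRESET_GROUPS)}"
        )
    if preset == "ukctocs_like":
        config = replace(
            config,
            leakage=max(config.leakage, 3.0),
            small_frag_fraction_mean=0.199,
        )
    records: list[SampleRecord] = []
    quants: list[MarkerQuantification] = []

    def add_sample(
        sample_id: str,
        cohort: str,
        group: str,
        counts: dict[str, tuple[int, int]],
        ca125: float,
        rng: np.random.Generator,
        **extra,
    ) -> None:
        dna = float(
            rng.lognormal(math.log(config.dna_conc_median * config.leakage), 0.5)
        )
        frac = float(
            np.clip(rng.beta(*_beta_ab(config.small_frag_fraction_mean, 30.0)), 0, 1)
        )
        records.append(
            SampleRecord(
                sample_id=sample_id,
                cohort="synthetic",
                group=group,
                ca125=round(ca125, 1),
                dna_conc=round(dna, 2),
                small_frag_fraction=round(frac, 3),
                **extra,
            )
        )
        for region_id, (s, c) in counts.items():
            quants.append(
                MarkerQuantification(
                    sample_id=sample_id,
                    region_id=region_id,
                    supporting=s,
                    covering=c,
                    low_coverage_flag=c < LOW_COVERAGE_CUTOFF,
                )
            )

    if preset == "nact_like":
        for patient in simulate_nact_series(config):
            for tp in NACT_TIMEPOINTS:
                ca, counts = patient.timepoints[tp]
                sid = f"{patient.patient_id}_{tp}"
                add_sample(
                    sid,
                    "synthetic",
                    "oc_hgs",
                    counts,
                    ca,
                    _rng(config.seed, "meta", sid),
                    timepoint=tp,
                    clinical_response=patient.clinical_response,
                    residual_disease=patient.residual_disease,
                    patient_id=patient.patient_id,
                )
    else:
        for group, size in PRESET_GROUPS[preset].items():
            for i in range(size):
                sid = f"{preset}_{group}_{i:03d}"
                rng = _rng(config.seed, "serum-sample", sid)
                phi, counts = simulate_serum_counts(group, config, rng=rng)
                ca = simulate_ca125(group, config, rng=rng)
                add_sample(sid, "synthetic", group, counts, ca, rng)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sample_sheet(out / "sample_sheet.csv", records)
        _write_quant_tsv(out / "quantifications.tsv", quants)
        rows = [
            (region_from_spec(spec, start=1000 * (i + 1)), "1" * spec.n_cpgs)
            for i, spec in enumerate(config.regions)
        ]
        write_region_table(out / "regions.tsv", rows)
    return records, quants


def _beta_ab(mean: float, concentration: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    return mean * concentration, (1 - mean) * concentration


def _write_quant_tsv(path: Union[str, Path], quants: Sequence[MarkerQuantification]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tregion_id\tsupporting\tcovering\tfrequency\tlow_coverage\n")
        for q in quants:
            freq = "" if q.frequency is None else f"{q.frequency:.10g}"
            fh.write(
                f"{q.sample_id}\t{q.region_id}\t{q.supporting}\t{q.covering}\t"
                f"{freq}\t{int(q.low_coverage_flag)}\n"
            )


def read_quant_tsv(path: Union[str, Path]) -> list[MarkerQuantification]:
    """Read the quantification TSV written by :func:`simulate_cohort`."""
    out: list[MarkerQuantification] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append(
                MarkerQuantification(
                    sample_id=parts[0],
                    region_id=parts[1],
                    supporting=int(parts[2]),
                    covering=int(parts[3]),
                    low_coverage_flag=bool(int(parts[5])),
                )
            )
    return out
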