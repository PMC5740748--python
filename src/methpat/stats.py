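"""Evaluation statistics for the serum methylation panel.

Implements the statistics used to report diagnostic performance:

* binomial proportions with the continuity-corrected score
  ("efficient-score") 95% confidence interval,
* Fisher's exact test (two-sided, probability-mass convention),
* the Mann-Whitney U test for group comparisons,
* CA125 benchmarking at the clinical 35 IU/mL cut-off and the
  CA125 x methylation-panel overlap tables,
* neoadjuvant-chemotherapy (NACT) response prediction from the panel
  call dynamics between the pre-treatment and post-cycle-2 samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats as sps

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # standard-normal 97.5% quantile, as conventionally tabulated


@dataclass(frozen=True)
class Confusion2x2:
    """A 2x2 confusion/contingency table of non-negative counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def table(self) -> list[list[int]]:
        return [[self.tp, self.fn], [self.fp, self.tn]]


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion k/n with a confidence interval."""

    k: int
    n: int
    estimate: float
    lower: float
    upper: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.estimate <= self.upper <= 1:
            raise ValueError("require 0 <= lower <= estimate <= upper <= 1")


@dataclass
class OverlapTable:
    """Counts of samples by (truth, CA125 call, methylation-panel call).

    Keys are (truth in {case, control}, ca125 in {neg, pos},
    dname in {neg, pos}); margins reproduce group sizes.
    """

    counts: dict[tuple[str, str, str], int]

    def total(self, truth: str) -> int:
        return sum(v for (t, _, _), v in self.counts.items() if t == truth)

    def cell(self, truth: str, ca125: str, dname: str) -> int:
        return self.counts.get((truth, ca125, dname), 0)


@dataclass
class NACTRecord:
    """Panel dynamics and clinical outcome of one NACT patient."""

    patient_id: str
    pre_call: str
    post2_call: str
    predicted: str
    clinical_response: str = "unknown"
    residual_disease: str = "unknown"

    def __post_init__(self) -> None:
        expect = predict_nact_response(self.pre_call, self.post2_call)
        if self.predicted != expect:
            raise ValueError(
                f"predicted {self.predicted!r} inconsistent with calls "
                f"({self.pre_call!r} -> {self.post2_call!r})"
            )


# ---------------------------------------------------------------------------
# Proportion confidence intervals
# ---------------------------------------------------------------------------

def wilson_cc_ci(k: int, n: int, confidence: float = 0.95) -> ProportionCI:
    """Continuity-corrected score confidence interval for k/n.

    This is the "efficient-score" interval: the score (Wilson) interval
    with a continuity correction, in the closed form

        lower = (2k + z^2 - 1 - z*sqrt(z^2 - 2 - 1/n + 4p(n(1-p)+1))) / (2(n+z^2))
        upper = (2k + z^2 + 1 + z*sqrt(z^2 + 2 - 1/n + 4p(n(1-p)-1))) / (2(n+z^2))

    with p = k/n.  The lower bound is forced to 0 when k = 0 and the
    upper to 1 when k = n; both are clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if confidence == 0.95:
        z = Z_95
    else:
        z = sps.norm.ppf(0.5 + confidence / 2)
    p = k / n
    z2 = z * z
    lower = (
        2 * k + z2 - 1 - z * math.sqrt(z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
    ) / (2 * (n + z2))
    upper = (
        2 * k + z2 + 1 + z * math.sqrt(z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
    ) / (2 * (n + z2))
    if k == 0:
        lower = 0.0
    if k == n:
        upper = 1.0
    lower = min(max(lower, 0.0), p)
    upper = max(min(upper, 1.0), p)
    return ProportionCI(
        k=k, n=n, estimate=p, lower=lower, upper=upper, confidence=confidence
    )


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Uses the probability-mass convention: the p-value is the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (with a
    relative tolerance of 1e-7 on the comparison).  Degenerate tables
    (a zero margin) return p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    import numpy as np

    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(probs[support == a][0])
    total = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return min(total, 1.0)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of x, p).

    The p-value is exact (full enumeration over labelings) when both
    samples have at most 8 observations and there are no ties, and a
    normal approximation with tie and continuity correction otherwise.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(set(list(x) + list(y))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Diagnostic performance
# ---------------------------------------------------------------------------

def sens_spec(
    calls: Mapping[str, str], truth_labels: Mapping[str, str]
) -> tuple[Optional[ProportionCI], Optional[ProportionCI]]:
    """Sensitivity and specificity with score confidence intervals.

    ``calls`` maps sample -> positive|negative (samples that are not
    evaluable must be excluded upstream); ``truth_labels`` maps
    sample -> case|control.  A metric is absent (None) when its group
    is empty.
    """
    cases = [s for s, t in truth_labels.items() if t == "case" and s in calls]
    controls = [s for s, t in truth_labels.items() if t == "control" and s in calls]
    for s in list(cases) + list(controls):
        if calls[s] not in ("positive", "negative"):
            raise ValueError(f"sample {s!r} has non-binary call {calls[s]!r}")
    sens = (
        wilson_cc_ci(sum(calls[s] == "positive" for s in cases), len(cases))
        if cases
        else None
    )
    spec = (
        wilson_cc_ci(sum(calls[s] == "negative" for s in controls), len(controls))
        if controls
        else None
    )
    return sens, spec


CA125_CUTOFF = 35.0  # IU/mL, clinical convention


def ca125_call(value_iu_ml: Optional[float], cutoff: float = CA125_CUTOFF) -> Optional[str]:
    """CA125 positivity at the clinical cut-off (strictly above 35 IU/mL)."""
    if value_iu_ml is None:
        return None
    if value_iu_ml < 0:
        raise ValueError("CA125 must be >= 0")
    return "positive" if value_iu_ml > cutoff else "negative"


def overlap_table(
    panel_calls: Mapping[str, str],
    ca125_calls: Mapping[str, str],
    truth: Mapping[str, str],
) -> OverlapTable:
    """Cross-tabulate CA125 and panel calls within cases and controls.

    Samples missing either call are excluded with a log message; margins
    over the eight cells reproduce the included group sizes.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for sample, t in truth.items():
        pc = panel_calls.get(sample)
        cc = ca125_calls.get(sample)
        if pc not in ("positive", "negative") or cc not in ("positive", "negative"):
            logger.info("sample %s missing a call; excluded from overlap table", sample)
            continue
        key = (t, "pos" if cc == "positive" else "neg", "pos" if pc == "positive" else "neg")
        counts[key] = counts.get(key, 0) + 1
    return OverlapTable(counts=counts)


# ---------------------------------------------------------------------------
# NACT response prediction
# ---------------------------------------------------------------------------

def predict_nact_response(pre_call: str, post2_call: str) -> str:
    """Predict chemotherapy response from panel dynamics.

    Positive -> negative predicts a responder; positive-or-negative ->
    positive predicts a non-responder.  A patient in whom neither the
    pre-treatment nor the post-cycle-2 sample is positive cannot be
    assessed, as can none whose calls are themselves not evaluable.
    """
    for call in (pre_call, post2_call):
        if call not in ("positive", "negative", "not_evaluable"):
            raise ValueError(f"unknown panel call {call!r}")
    if pre_call == "not_evaluable" or post2_call == "not_evaluable":
        return "not_evaluable"
    if pre_call != "positive" and post2_call != "positive":
        return "not_evaluable"
    return "non_responder" if post2_call == "positive" else "responder"


def evaluate_nact(
    records: Iterable[NACTRecord], subset: str = "all"
) -> tuple[float, float, float]:
    """Accuracy of NACT response prediction and Fisher's exact p.

    Returns (responder accuracy, non-responder accuracy, two-sided
    Fisher p on the prediction-by-truth 2x2) over evaluable records with
    known clinical response.  ``subset="R0_1"`` restricts to patients
    left without macroscopic residual disease after interval debulking.
    """
    if subset not in ("all", "R0_1"):
        raise ValueError("subset must be 'all' or 'R0_1'")
    rows = [
        r
        for r in records
        if r.predicted != "not_evaluable"
        and r.clinical_response in ("responder", "non_responder")
        and (subset == "all" or r.residual_disease == "R0_1")
    ]
    if not rows:
        raise ValueError("no evaluable NACT records")
    resp = [r for r in rows if r.clinical_response == "responder"]
    nonresp = [r for r in rows if r.clinical_response == "non_responder"]
    a = sum(r.predicted == "responder" for r in resp)
    b = len(resp) - a
    d = sum(r.predicted == "non_responder" for r in nonresp)
    c = len(nonresp) - d
    resp_acc = a / len(resp) if resp else float("nan")
    nonresp_acc = d / len(nonresp) if nonresp else float("nan")
    p = fisher_exact_two_sided([[a, b], [c, d]])
    return resp_acc, nonresp_acc, p


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero, the convention used for printed p-values."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
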