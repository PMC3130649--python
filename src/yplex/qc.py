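"""Panel quality metrics: call rates, pass rate, concordance.

Call rate is the percentage of attempted genotypes that yielded an allele
call; pass rate is the percentage of designed assays that worked at all.
Samples with zero calls (loading failures) are excluded from denominators
by default. All reported percentages are rounded half-up to one decimal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

from .errors import QCError
from .panel import Panel
from .profile import NO_CALL, GenotypeProfile


def round1(value: float) -> float:
    """Half-up rounding to one decimal (bankers' rounding would drift)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class Mismatch:
    sample_id: str
    marker: str
    observed: str
    reference: str


@dataclass
class QCReport:
    marker_call_rates: dict[str, float]
    sample_call_rates: dict[str, float]
    pass_rate: float
    mean_call_rate: float
    min_call_rate: tuple[str, float]
    concordance: Optional[float] = None
    mismatches: list[Mismatch] = field(default_factory=list)
    excluded_empty_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pass_rate": self.pass_rate,
            "mean_call_rate": self.mean_call_rate,
            "min_call_rate": {"marker": self.min_call_rate[0], "rate": self.min_call_rate[1]},
            "concordance": self.concordance,
            "n_mismatches": len(self.mismatches),
            "excluded_empty_samples": self.excluded_empty_samples,
            "marker_call_rates": self.marker_call_rates,
            "sample_call_rates": self.sample_call_rates,
        }


def _non_empty(profiles: Iterable[GenotypeProfile], exclude_empty: bool):
    profiles = list(profiles)
    if exclude_empty:
        kept = [p for p in profiles if not p.is_empty]
        excluded = sorted(p.sample_id for p in profiles if p.is_empty)
    else:
        kept, excluded = profiles, []
    return kept, excluded


def marker_call_rates(
    profiles: Iterable[GenotypeProfile], panel: Panel, exclude_empty: bool = True
) -> dict[str, float]:
    """Per-marker call rate (%) over the cohort, one-decimal precision."""
    kept, _ = _non_empty(profiles, exclude_empty)
    if not kept:
        raise QCError("call-rate denominator is zero: no usable samples")
    return {
        m: round1(100.0 * sum(1 for p in kept if p[m] != NO_CALL) / len(kept))
        for m in panel.active_marker_names
    }


def sample_call_rates(
    profiles: Iterable[GenotypeProfile], panel: Panel
) -> dict[str, float]:
    n = len(panel.active_markers)
    if n == 0:
        raise QCError("panel has no active markers")
    return {p.sample_id: round1(100.0 * p.n_called / n) for p in profiles}


@dataclass
class CallRateSummary:
    mean: float
    min_marker: str
    min_rate: float
    pass_rate: Optional[float] = None


def summarize(call_rates: Mapping[str, float], panel: Optional[Panel] = None) -> CallRateSummary:
    """Mean and minimum of a call-rate map (lexicographic tie-break on the
    minimum's marker); panel pass rate when a panel is supplied."""
    if not call_rates:
        raise QCError("cannot summarize an empty call-rate map")
    mean = round1(sum(call_rates.values()) / len(call_rates))
    min_rate = min(call_rates.values())
    min_marker = min(m for m, r in call_rates.items() if r == min_rate)
    pass_rate = round1(panel.pass_rate) if panel is not None else None
    return CallRateSummary(mean=mean, min_marker=min_marker, min_rate=round1(min_rate), pass_rate=pass_rate)


def concordance(
    profiles: Mapping[str, GenotypeProfile] | Iterable[GenotypeProfile],
    reference: Mapping[str, GenotypeProfile] | Iterable[GenotypeProfile],
) -> tuple[float, list[Mismatch]]:
    """Percent agreement on (sample, marker) pairs called in both sets.

    Mirrors a re-typing control: reference genotypes from independent
    single-plex runs compared against the multiplex calls.
    """
    profiles = _as_map(profiles)
    reference = _as_map(reference)
    compared = 0
    mismatches: list[Mismatch] = []
    for sample_id, ref in reference.items():
        obs = profiles.get(sample_id)
        if obs is None:
            continue
        for marker, ref_state in ref.calls.items():
            obs_state = obs[marker]
            if NO_CALL in (ref_state, obs_state):
                continue
            compared += 1
            if obs_state != ref_state:
                mismatches.append(Mismatch(sample_id, marker, obs_state, ref_state))
    if compared == 0:
        raise QCError("no (sample, marker) pairs called in both profile sets")
    rate = round1(100.0 * (compared - len(mismatches)) / compared)
    return rate, mismatches


def _as_map(profiles) -> dict[str, GenotypeProfile]:
    if isinstance(profiles, Mapping):
        return dict(profiles)
    return {p.sample_id: p for p in profiles}


def build_report(
    profiles: Iterable[GenotypeProfile],
    panel: Panel,
    reference: Optional[Mapping[str, GenotypeProfile]] = None,
    exclude_empty: bool = True,
) -> QCReport:
    profiles = list(profiles)
    kept, excluded = _non_empty(profiles, exclude_empty)
    rates = marker_call_rates(kept, panel, exclude_empty=False)
    summary = summarize(rates, panel)
    conc, mism = (None, [])
    if reference is not None:
        conc, mism = concordance(kept, reference)
    return QCReport(
        marker_call_rates=rates,
        sample_call_rates=sample_call_rates(profiles, panel),
        pass_rate=summary.pass_rate,
        mean_call_rate=summary.mean,
        min_call_rate=(summary.min_marker, summary.min_rate),
        concordance=conc,
        mismatches=mism,
        excluded_empty_samples=excluded,
    )
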