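"""Per-sample genotype profiles over a hemizygous marker panel.

Every male sample carries a single Y chromosome, so each marker has exactly
one observed allele: the state space per marker is {ancestral, derived,
no-call}, never a heterozygote.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

ANCESTRAL = "A"
DERIVED = "D"
NO_CALL = "N"
STATES = frozenset({ANCESTRAL, DERIVED, NO_CALL})


@dataclass
class GenotypeProfile:
    """Marker -> {A, D, N} state vector for one sample."""

    sample_id: str
    calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.calls.values() if s not in STATES}
        if bad:
            raise ValueError(f"invalid genotype states {sorted(bad)} for sample {self.sample_id}")

    def __getitem__(self, marker: str) -> str:
        return self.calls.get(marker, NO_CALL)

    def __iter__(self) -> Iterator[str]:
        return iter(self.calls)

    @property
    def derived_markers(self) -> set[str]:
        return {m for m, s in self.calls.items() if s == DERIVED}

    @property
    def ancestral_markers(self) -> set[str]:
        return {m for m, s in self.calls.items() if s == ANCESTRAL}

    @property
    def called_markers(self) -> set[str]:
        return {m for m, s in self.calls.items() if s != NO_CALL}

    @property
    def n_called(self) -> int:
        return sum(1 for s in self.calls.values() if s != NO_CALL)

    @property
    def is_empty(self) -> bool:
        """True when no marker yielded a call (e.g. an unloaded well)."""
        return self.n_called == 0

    def with_calls(self, updates: Mapping[str, str]) -> "GenotypeProfile":
        merged = dict(self.calls)
        merged.update(updates)
        return GenotypeProfile(self.sample_id, merged)
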