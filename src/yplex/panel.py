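"""Marker panel model and panel-table parsing.

A panel describes one multiplex genotyping array: for every assay the
haplogroup it defines, its ancestral/derived allele states, which dye
reports which allele, whether the assay worked at all, and its published
per-marker call rate. Assays that share a redundancy group interrogate the
same branch (or the same variant with swapped dyes) and act as internal
controls.
"""
from __future__ import annotations

import enum
import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import EncodingError, PanelError
from .profile import ANCESTRAL, DERIVED, NO_CALL, GenotypeProfile

MISSING_TOKEN = "."

PANEL_COLUMNS = [
    "marker",
    "haplogroup",
    "ancestral",
    "derived",
    "variant_class",
    "dye_ancestral",
    "dye_derived",
    "call_rate_or_failed",
    "redundancy_group",
]


class VariantClass(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


class MarkerStatus(str, enum.Enum):
    ACTIVE = "active"
    FAILED = "failed"


@dataclass(frozen=True)
class DyeMap:
    """Which fluorophore reports which allele state."""

    ancestral: str
    derived: str

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise PanelError(f"dye map must use two distinct dyes, got {self.ancestral!r} twice")

    def allele_for_dye(self, dye: str) -> str:
        if dye == self.ancestral:
            return ANCESTRAL
        if dye == self.derived:
            return DERIVED
        raise PanelError(f"dye {dye!r} not in dye map ({self.ancestral}/{self.derived})")

    def swapped(self) -> "DyeMap":
        return DyeMap(ancestral=self.derived, derived=self.ancestral)


@dataclass(frozen=True)
class Marker:
    """One assay: a biallelic Y-SNP (or small indel) anchored to a haplogroup."""

    name: str
    haplogroup: str
    ancestral_allele: str
    derived_allele: str
    variant_class: VariantClass = VariantClass.SUBSTITUTION
    dye_map: DyeMap = DyeMap("VIC", "FAM")
    status: MarkerStatus = MarkerStatus.ACTIVE
    published_call_rate: Optional[float] = None
    redundancy_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ancestral_allele == self.derived_allele:
            raise PanelError(
                f"marker {self.name}: ancestral and derived alleles are identical "
                f"({self.ancestral_allele!r})"
            )
        if (self.status is MarkerStatus.FAILED) != (self.published_call_rate is None):
            raise PanelError(
                f"marker {self.name}: a call rate is present iff the assay is active"
            )
        if self.published_call_rate is not None and not 0.0 <= self.published_call_rate <= 100.0:
            raise PanelError(f"marker {self.name}: call rate outside [0, 100]")

    @property
    def is_active(self) -> bool:
        return self.status is MarkerStatus.ACTIVE

    def state_of(self, allele: str) -> str:
        """Map an observed allele token to its A/D/N state."""
        if allele == MISSING_TOKEN or allele == NO_CALL or allele == "":
            return NO_CALL
        if allele == self.ancestral_allele:
            return ANCESTRAL
        if allele == self.derived_allele:
            return DERIVED
        raise EncodingError(
            f"marker {self.name}: allele {allele!r} matches neither ancestral "
            f"{self.ancestral_allele!r} nor derived {self.derived_allele!r}"
        )

    def allele_of(self, state: str) -> str:
        if state == ANCESTRAL:
            return self.ancestral_allele
        if state == DERIVED:
            return self.derived_allele
        return MISSING_TOKEN


@dataclass
class Panel:
    """An ordered marker collection plus the number of assays designed."""

    markers: list[Marker]
    designed_count: int = 0

    def __post_init__(self) -> None:
        if self.designed_count == 0:
            self.designed_count = len(self.markers)
        names = [m.name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate marker names in panel: {sorted(dupes)}")
        if len(self.markers) != self.designed_count:
            raise PanelError(
                f"active + failed markers ({len(self.markers)}) must equal "
                f"designed_count ({self.designed_count})"
            )
        self._by_name = {m.name: m for m in self.markers}
        for gid, members in self.redundancy_groups.items():
            if len(members) < 2:
                raise PanelError(f"redundancy group {gid!r} has fewer than two members")
            haps = {m.haplogroup for m in members}
            variants = {(m.ancestral_allele, m.derived_allele) for m in members}
            if len(haps) > 1 and len(variants) > 1:
                raise PanelError(
                    f"redundancy group {gid!r} mixes haplogroups {sorted(haps)} "
                    "without interrogating one variant"
                )

    def __len__(self) -> int:
        return len(self.markers)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Marker:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"marker {name!r} not in panel") from None

    @property
    def active_markers(self) -> list[Marker]:
        return [m for m in self.markers if m.is_active]

    @property
    def failed_markers(self) -> list[Marker]:
        return [m for m in self.markers if not m.is_active]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def active_marker_names(self) -> list[str]:
        return [m.name for m in self.active_markers]

    @property
    def redundancy_groups(self) -> dict[str, list[Marker]]:
        groups: dict[str, list[Marker]] = {}
        for m in self.markers:
            if m.redundancy_group:
                groups.setdefault(m.redundancy_group, []).append(m)
        return groups

    def published_call_rates(self) -> dict[str, float]:
        """Per-marker published call rates (%), active assays only."""
        return {m.name: m.published_call_rate for m in self.active_markers}

    @property
    def pass_rate(self) -> float:
        """Percentage of designed assays that genotyped successfully."""
        return 100.0 * len(self.active_markers) / self.designed_count


def _parse_call_rate(token: str, row_label: str) -> tuple[MarkerStatus, Optional[float]]:
    token = str(token).strip()
    if token.lower() == "failed":
        return MarkerStatus.FAILED, None
    try:
        return MarkerStatus.ACTIVE, float(token)
    except ValueError:
        raise PanelError(f"{row_label}: call rate {token!r} is neither a number nor 'Failed'")


def load_panel(path) -> Panel:
    """Parse a tab-separated panel table into a :class:`Panel`.

    Failed assays are retained and flagged; indel allele tokens are kept
    verbatim. Duplicate marker names and identical allele pairs are fatal.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise PanelError(f"panel table {path}: missing columns {missing}")
    if table.empty:
        raise PanelError(f"panel table {path}: no markers parsed")

    dupes = table["marker"][table["marker"].duplicated()].tolist()
    if dupes:
        raise PanelError(f"panel table {path}: duplicate marker names {sorted(set(dupes))}")

    markers = []
    for idx, row in table.iterrows():
        label = f"panel row {idx + 2} ({row['marker']})"
        if row["ancestral"] == row["derived"]:
            raise PanelError(f"{label}: ancestral and derived allele states are identical")
        status, rate = _parse_call_rate(row["call_rate_or_failed"], label)
        group = row["redundancy_group"].strip()
        markers.append(
            Marker(
                name=row["marker"],
                haplogroup=row["haplogroup"],
                ancestral_allele=row["ancestral"],
                derived_allele=row["derived"],
                variant_class=VariantClass(row["variant_class"]),
                dye_map=DyeMap(row["dye_ancestral"], row["dye_derived"]),
                status=status,
                published_call_rate=rate,
                redundancy_group=group if group not in ("", MISSING_TOKEN) else None,
            )
        )
    return Panel(markers=markers, designed_count=len(markers))


def packaged_panel_path():
    """Path of the packaged 128-assay OpenArray panel table."""
    return importlib.resources.files("yplex") / "data" / "panel_openarray121.tsv"


def packaged_skeleton_path():
    """Path of the packaged phylogeny join table (Karafet-2008-style joins)."""
    return importlib.resources.files("yplex") / "data" / "skeleton_karafet2008.tsv"


def load_packaged_panel() -> Panel:
    return load_panel(packaged_panel_path())


def encode_genotypes(
    raw: pd.DataFrame, panel: Panel, missing_token: str = MISSING_TOKEN
) -> dict[str, GenotypeProfile]:
    """Encode a samples x markers matrix of allele bases into A/D/N profiles.

    ``raw`` is indexed by sample id with one column per marker, holding the
    observed allele token (or ``missing_token``). Columns for failed assays
    are dropped with a warning; an allele matching neither state raises
    :class:`EncodingError` naming sample, marker and allele.
    """
    unknown = [c for c in raw.columns if c not in panel]
    if unknown:
        raise PanelError(f"genotype matrix has columns absent from panel: {sorted(unknown)}")
    failed = [c for c in raw.columns if not panel[c].is_active]
    if failed:
        warnings.warn(f"dropping failed assays from genotype matrix: {sorted(failed)}")
    keep = [c for c in raw.columns if panel[c].is_active]

    profiles: dict[str, GenotypeProfile] = {}
    for sample_id, row in raw[keep].iterrows():
        calls = {}
        for marker_name, allele in row.items():
            token = MISSING_TOKEN if str(allele).strip() in (missing_token, "") else str(allele).strip()
            try:
                calls[marker_name] = panel[marker_name].state_of(token)
            except EncodingError as exc:
                raise EncodingError(f"sample {sample_id}: {exc}") from None
        profiles[str(sample_id)] = GenotypeProfile(str(sample_id), calls)
    return profiles


def decode_genotypes(
    profiles: Mapping[str, GenotypeProfile] | Iterable[GenotypeProfile], panel: Panel
) -> pd.DataFrame:
    """Inverse of :func:`encode_genotypes` on called states (N -> missing token)."""
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    else:
        profiles = list(profiles)
    markers = sorted({m for p in profiles for m in p.calls}, key=panel.marker_names.index)
    data = {
        p.sample_id: [panel[m].allele_of(p[m]) for m in markers] for p in profiles
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=markers)
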