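"""Synthetic cohorts and fluorescence plates with known truth.

The generator emulates the study design end-to-end: truth haplogroups
drawn over the tree's marker-defined nodes, truth genotypes derived on
every lineage marker and ancestral elsewhere, per-marker dropout,
independent allele-flip errors (false positives A->D, false negatives
D->A), whole-sample loading failures, and two-dye endpoint fluorescence
plates of 24 wells (22 samples + 2 no-template controls) per assay with
three Gaussian clusters per assay in normalised intensity units.

Everything is driven by one integer seed through numpy Generators, so a
fixed configuration reproduces byte-identical cohorts and plates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import SimulationError
from .haplogroups import Assignment, AssignmentStatus
from .calling import NTC_ID, PLATE_COLUMNS, PlateRun
from .panel import Panel
from .phylogeny import PhyloTree
from .profile import ANCESTRAL, DERIVED, NO_CALL, GenotypeProfile

SAMPLES_PER_PLATE = 22
NTCS_PER_PLATE = 2


@dataclass(frozen=True)
class ClusterGeometry:
    """Per-class (high-dye, low-dye) intensity means and SDs, normalised units.

    Defaults mimic a clean endpoint read: allele clusters high on their
    reporting dye and well off the background, background tight at the
    origin. Separation between class means is ~11-14 background SDs.
    """

    background_mean: tuple[float, float] = (0.1, 0.1)
    background_sd: float = 0.05
    signal_high: float = 1.0
    signal_low: float = 0.2
    signal_sd: float = 0.08

    def __post_init__(self) -> None:
        gap = np.hypot(self.signal_high - self.background_mean[0], self.signal_low - self.background_mean[1])
        if gap <= 0:
            raise SimulationError("allele cluster means must be separated from background")

    @property
    def min_separation_sd(self) -> float:
        """Smallest pairwise class-mean separation in units of the larger SD."""
        classes = [
            np.array(self.background_mean),
            np.array([self.signal_high, self.signal_low]),
            np.array([self.signal_low, self.signal_high]),
        ]
        sds = [self.background_sd, self.signal_sd, self.signal_sd]
        sep = min(
            float(np.linalg.norm(a - b)) / max(sa, sb)
            for i, (a, sa) in enumerate(zip(classes, sds))
            for b, sb in list(zip(classes, sds))[i + 1 :]
        )
        return sep


@dataclass
class SimConfig:
    n_samples: int = 100
    haplogroup_weights: Optional[dict[str, float]] = None  # None -> uniform over typed nodes
    truth_labels: Optional[Sequence[str]] = None  # explicit per-sample truth, overrides weights
    per_marker_dropout: Union[float, Mapping[str, float]] = 0.0
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    n_empty_samples: int = 0
    cluster_geometry: ClusterGeometry = field(default_factory=ClusterGeometry)
    assay_scale_range: tuple[float, float] = (8000.0, 32000.0)  # arbitrary fluorescence units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise SimulationError("n_samples must be positive")
        if not 0 <= self.n_empty_samples <= self.n_samples:
            raise SimulationError("n_empty_samples must lie in [0, n_samples]")
        for name, p in (
            ("false_positive_rate", self.false_positive_rate),
            ("false_negative_rate", self.false_negative_rate),
        ):
            if not 0.0 <= p < 1.0:
                raise SimulationError(f"{name} must be in [0, 1)")
        if self.haplogroup_weights is not None:
            total = sum(self.haplogroup_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(f"haplogroup weights sum to {total}, expected 1")

    def dropout_for(self, marker: str) -> float:
        p = (
            self.per_marker_dropout.get(marker, 0.0)
            if isinstance(self.per_marker_dropout, Mapping)
            else float(self.per_marker_dropout)
        )
        if not 0.0 <= p < 1.0:
            raise SimulationError(f"dropout for {marker} must be in [0, 1)")
        return p


@dataclass
class TruthRecord:
    sample_id: str
    true_haplogroup: str
    injected_errors: list[tuple[str, str]] = field(default_factory=list)  # (marker, flip type)
    dropped_markers: set[str] = field(default_factory=set)
    is_empty: bool = False


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, *stream]))


def truth_profile(label: str, tree: PhyloTree, panel: Panel, sample_id: str) -> GenotypeProfile:
    """Error-free genotype of a sample on branch ``label``: derived on every
    lineage marker, ancestral on the rest of the active panel."""
    if label not in tree:
        raise SimulationError(f"unknown haplogroup label {label!r}")
    on_path = tree.path_markers(label)
    calls = {
        m.name: DERIVED if m.name in on_path else ANCESTRAL for m in panel.active_markers
    }
    return GenotypeProfile(sample_id, calls)


def simulate_profiles(
    config: SimConfig, tree: PhyloTree, panel: Panel
) -> tuple[list[GenotypeProfile], list[TruthRecord]]:
    """Draw a cohort of genotype profiles plus per-sample truth records."""
    rng = _rng(config, 0)
    if config.truth_labels is not None:
        if len(config.truth_labels) != config.n_samples:
            raise SimulationError("truth_labels length must equal n_samples")
        labels = list(config.truth_labels)
    elif config.haplogroup_weights is not None:
        pool = sorted(config.haplogroup_weights)
        probs = np.array([config.haplogroup_weights[l] for l in pool])
        labels = list(rng.choice(pool, size=config.n_samples, p=probs))
    else:
        pool = tree.marker_defined_labels()
        labels = list(rng.choice(pool, size=config.n_samples))
    unknown = sorted({l for l in labels if l not in tree})
    if unknown:
        raise SimulationError(f"unknown haplogroup labels {unknown}")

    empty_ids = set(range(config.n_empty_samples))  # first wells fail loading
    profiles: list[GenotypeProfile] = []
    records: list[TruthRecord] = []
    for i, label in enumerate(labels):
        sample_id = f"S{i + 1:04d}"
        truth = truth_profile(label, tree, panel, sample_id)
        record = TruthRecord(sample_id, label, is_empty=i in empty_ids)
        if record.is_empty:
            profiles.append(GenotypeProfile(sample_id, {m: NO_CALL for m in truth.calls}))
            records.append(record)
            continue
        calls = {}
        for marker, state in truth.calls.items():
            if rng.random() < config.dropout_for(marker):
                calls[marker] = NO_CALL
                record.dropped_markers.add(marker)
                continue
            if state == ANCESTRAL and rng.random() < config.false_positive_rate:
                calls[marker] = DERIVED
                record.injected_errors.append((marker, "false_positive"))
            elif state == DERIVED and rng.random() < config.false_negative_rate:
                calls[marker] = ANCESTRAL
                record.injected_errors.append((marker, "false_negative"))
            else:
                calls[marker] = state
        profiles.append(GenotypeProfile(sample_id, calls))
        records.append(record)
    return profiles, records


def simulate_plate(
    config: SimConfig,
    profiles: Sequence[GenotypeProfile],
    panel: Panel,
    plate_id: str = "P1",
    plate_index: int = 0,
) -> PlateRun:
    """Render <=22 profiles as one plate of two-dye endpoint intensities.

    Each (assay, well) intensity pair is drawn from the Gaussian class of
    the sample's genotype at that marker — background for N and for the
    two NTC wells — oriented by the assay's dye map (so dye-swapped
    assays light the other axis), then scaled into arbitrary per-assay
    fluorescence units and clipped at zero.
    """
    if len(profiles) > SAMPLES_PER_PLATE:
        raise SimulationError(
            f"{len(profiles)} samples exceed plate capacity {SAMPLES_PER_PLATE}; paginate upstream"
        )
    rng = _rng(config, 1, plate_index)
    geom = config.cluster_geometry
    lo, hi = config.assay_scale_range

    wells = [(f"W{j + 1:02d}", p.sample_id) for j, p in enumerate(profiles)]
    wells += [(f"W{j + 1:02d}", NTC_ID) for j in range(SAMPLES_PER_PLATE, SAMPLES_PER_PLATE + NTCS_PER_PLATE)]
    by_id = {p.sample_id: p for p in profiles}

    rows = []
    for marker in panel.active_markers:
        scale = rng.uniform(lo, hi)
        for well_id, sample_id in wells:
            state = NO_CALL if sample_id == NTC_ID else by_id[sample_id][marker.name]
            if state == NO_CALL:
                mean = np.array(geom.background_mean)
                sd = geom.background_sd
            else:
                dye = marker.dye_map.ancestral if state == ANCESTRAL else marker.dye_map.derived
                high_on_vic = dye == "VIC"
                mean = np.array(
                    [geom.signal_high, geom.signal_low]
                    if high_on_vic
                    else [geom.signal_low, geom.signal_high]
                )
                sd = geom.signal_sd
            vic, fam = np.clip(rng.normal(mean, sd) * scale, 0.0, None)
            rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": well_id,
                    "sample_id": sample_id,
                    "assay": marker.name,
                    "vic": float(vic),
                    "fam": float(fam),
                }
            )
    return PlateRun(pd.DataFrame(rows, columns=PLATE_COLUMNS))


def simulate_plates(
    config: SimConfig, profiles: Sequence[GenotypeProfile], panel: Panel
) -> list[PlateRun]:
    """Paginate a cohort into consecutive 22-sample plates."""
    plates = []
    for k in range(0, len(profiles), SAMPLES_PER_PLATE):
        chunk = profiles[k : k + SAMPLES_PER_PLATE]
        plates.append(
            simulate_plate(config, chunk, panel, plate_id=f"P{k // SAMPLES_PER_PLATE + 1}", plate_index=k // SAMPLES_PER_PLATE)
        )
    return plates


@dataclass
class RecoveryMetrics:
    n: int
    n_empty: int
    accuracy: float  # fraction of non-empty samples assigned to their true node
    fraction_clean: float
    fraction_resolved: float
    fraction_unresolved: float
    confusion: list[tuple[str, str]] = field(default_factory=list)  # (truth, assigned) mismatches


def evaluate_recovery(
    assignments: Iterable[Assignment], records: Iterable[TruthRecord]
) -> RecoveryMetrics:
    """Score assignments against simulation truth (matching sample ids)."""
    by_id = {a.sample_id: a for a in assignments}
    records = list(records)
    truth_ids = {r.sample_id for r in records}
    if set(by_id) != truth_ids:
        raise SimulationError(
            f"sample id mismatch: {sorted(set(by_id) ^ truth_ids)[:5]} ..."
        )
    non_empty = [r for r in records if not by_id[r.sample_id].status is AssignmentStatus.EMPTY]
    n_empty = len(records) - len(non_empty)
    if not non_empty:
        return RecoveryMetrics(len(records), n_empty, 0.0, 0.0, 0.0, 0.0)
    hits, confusion = 0, []
    tallies = {s: 0 for s in AssignmentStatus}
    for r in non_empty:
        a = by_id[r.sample_id]
        tallies[a.status] += 1
        if a.node == r.true_haplogroup:
            hits += 1
        else:
            confusion.append((r.true_haplogroup, a.node or ""))
    n = len(non_empty)
    return RecoveryMetrics(
        n=len(records),
        n_empty=n_empty,
        accuracy=hits / n,
        fraction_clean=tallies[AssignmentStatus.CLEAN] / n,
        fraction_resolved=tallies[AssignmentStatus.RESOLVED] / n,
        fraction_unresolved=tallies[AssignmentStatus.UNRESOLVED] / n,
        confusion=sorted(confusion),
    )
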