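"""Endpoint two-dye fluorescence -> hemizygous allele calls.

Each assay's wells form at most three clusters in (VIC, FAM) intensity
space: one allele cluster per dye axis and a background cluster near the
origin holding the no-template controls (NTCs) and failed wells. Because
male Y-chromosome samples are hemizygous there is no heterozygote
(dual-high) cluster; dual-high outliers are abstained on rather than
called.

The partition is centroid-based on per-assay max-normalised, log1p
intensities: the background centroid is anchored by the NTC wells, the
allele centroids are seeded from the most dye-extreme signal wells, and a
short k-means refinement follows. Wells without a clear nearest centroid
(distance ratio above the no-call margin) are abstained on.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import CallingError
from .panel import Marker, Panel
from .profile import ANCESTRAL, DERIVED, NO_CALL, GenotypeProfile

NTC_ID = "NTC"

#: wells closer than this (normalised log space) to the background centroid
#: carry no signal
DEFAULT_SIGNAL_THRESHOLD = 0.25
#: abstain when nearest/second-nearest centroid distance ratio exceeds this
DEFAULT_NO_CALL_MARGIN = 0.7
#: dual-high outliers beyond this many cluster SDs of both allele centroids
DEFAULT_DUAL_HIGH_SD = 3.0
#: two allele seeds closer than this collapse to a single allele cluster
_MERGE_DISTANCE = 0.2
_SD_FLOOR = 0.03


class CallLabel(str, enum.Enum):
    ANCESTRAL = "ancestral"
    DERIVED = "derived"
    NO_CALL = "no_call"
    NTC = "ntc"


@dataclass(frozen=True)
class FluorescencePoint:
    """One well of one assay: raw VIC/FAM endpoint intensities."""

    well_id: str
    sample_id: Optional[str]  # None for no-template controls
    assay: str
    vic: float
    fam: float

    def __post_init__(self) -> None:
        for dye, v in (("vic", self.vic), ("fam", self.fam)):
            if not np.isfinite(v) or v < 0:
                raise CallingError(f"well {self.well_id} assay {self.assay}: {dye} intensity {v!r}")

    @property
    def is_ntc(self) -> bool:
        return self.sample_id is None


@dataclass(frozen=True)
class ClusterCall:
    well_id: str
    sample_id: Optional[str]
    genotype: CallLabel
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise CallingError("margin must be non-negative")


PLATE_COLUMNS = ["plate_id", "well_id", "sample_id", "assay", "vic", "fam"]


@dataclass
class PlateRun:
    """All fluorescence points of one plate: assays x 24 wells (22 samples + 2 NTCs)."""

    points: pd.DataFrame  # columns PLATE_COLUMNS; sample_id == "NTC" flags controls

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.points.columns]
        if missing:
            raise CallingError(f"plate table missing columns {missing}")
        if self.points.duplicated(["assay", "well_id"]).any():
            raise CallingError("duplicate (assay, well) pairs in plate")
        ntc_by_assay = {
            assay: frozenset(g.loc[g["sample_id"] == NTC_ID, "well_id"])
            for assay, g in self.points.groupby("assay")
        }
        if len(set(ntc_by_assay.values())) > 1:
            raise CallingError("NTC wells differ between assays of one plate")

    @property
    def assays(self) -> list[str]:
        return sorted(self.points["assay"].unique())

    @property
    def sample_ids(self) -> list[str]:
        ids = self.points.loc[self.points["sample_id"] != NTC_ID, "sample_id"]
        return sorted(ids.unique())

    def assay_points(self, assay: str) -> list[FluorescencePoint]:
        rows = self.points[self.points["assay"] == assay]
        return [
            FluorescencePoint(
                well_id=r.well_id,
                sample_id=None if r.sample_id == NTC_ID else r.sample_id,
                assay=assay,
                vic=float(r.vic),
                fam=float(r.fam),
            )
            for r in rows.itertuples()
        ]


def _no_calls(points: list[FluorescencePoint]) -> list[ClusterCall]:
    return [
        ClusterCall(p.well_id, p.sample_id, CallLabel.NTC if p.is_ntc else CallLabel.NO_CALL)
        for p in points
    ]


def call_assay(
    points: list[FluorescencePoint],
    marker: Marker,
    no_call_margin: float = DEFAULT_NO_CALL_MARGIN,
    signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    dual_high_sd: float = DEFAULT_DUAL_HIGH_SD,
) -> list[ClusterCall]:
    """Call one assay's wells from their two-dye endpoint intensities.

    Requires at least one NTC well to anchor the background cluster. An
    assay whose wells all sit at background yields no_call for every
    sample well (per-plate assay failure), not an error.
    """
    if not points:
        return []
    ntc_idx = [i for i, p in enumerate(points) if p.is_ntc]
    if not ntc_idx:
        raise CallingError(f"assay {marker.name}: no NTC wells, background unanchored")

    raw = np.array([[p.vic, p.fam] for p in points], dtype=float)
    scale = raw.max()
    if scale <= 0:
        return _no_calls(points)
    x = np.log1p(raw / scale)  # invariant under common positive rescaling

    bg = x[ntc_idx].mean(axis=0)
    d_bg = np.linalg.norm(x - bg, axis=1)
    signal = d_bg > signal_threshold
    if not signal.any():
        return _no_calls(points)

    # seed allele centroids at the most dye-extreme signal wells
    delta = x[:, 1] - x[:, 0]  # fam - vic
    sig_idx = np.flatnonzero(signal)
    hi_fam = sig_idx[np.argmax(delta[sig_idx])]
    hi_vic = sig_idx[np.argmin(delta[sig_idx])]
    # two allele clusters only when the seeds dominate opposite dye axes;
    # same-side seeds are one allele cloud spread along its minor axis
    two_alleles = (
        delta[hi_fam] > 0 > delta[hi_vic]
        and np.linalg.norm(x[hi_fam] - x[hi_vic]) >= _MERGE_DISTANCE
    )
    seeds = [x[hi_vic], x[hi_fam]] if two_alleles else [x[sig_idx[np.argmax(d_bg[sig_idx])]]]
    centers = np.vstack([bg] + seeds)

    km = KMeans(n_clusters=len(centers), init=centers, n_init=1, random_state=0).fit(x)
    centroids = km.cluster_centers_
    assigned = km.labels_

    bg_cluster = int(np.argmin(np.linalg.norm(centroids - bg, axis=1)))
    allele_clusters = [c for c in range(len(centroids)) if c != bg_cluster]

    def _rms(c: int) -> float:
        members = x[assigned == c]
        if len(members) == 0:
            return _SD_FLOOR
        return max(float(np.sqrt(((members - centroids[c]) ** 2).sum(axis=1).mean())), _SD_FLOOR)

    sds = {c: _rms(c) for c in range(len(centroids))}
    # an allele cluster is real only when separated from background by more
    # than its own scatter would explain; otherwise the assay is pure noise
    allele_clusters = [
        c
        for c in allele_clusters
        if np.linalg.norm(centroids[c] - centroids[bg_cluster])
        > dual_high_sd * max(sds[c], sds[bg_cluster])
    ]
    if not allele_clusters:
        return _no_calls(points)

    # a dye axis labels each allele cluster; dye_map then names the allele
    cluster_state: dict[int, str] = {}
    if len(allele_clusters) == 2:
        a, b = allele_clusters
        vic_first = centroids[a][0] - centroids[a][1] >= centroids[b][0] - centroids[b][1]
        vic_cluster, fam_cluster = (a, b) if vic_first else (b, a)
        cluster_state[vic_cluster] = marker.dye_map.allele_for_dye("VIC")
        cluster_state[fam_cluster] = marker.dye_map.allele_for_dye("FAM")
    else:
        (c,) = allele_clusters
        dye = "VIC" if centroids[c][0] >= centroids[c][1] else "FAM"
        cluster_state[c] = marker.dye_map.allele_for_dye(dye)

    live = [bg_cluster] + allele_clusters
    dists = np.linalg.norm(x[:, None, :] - centroids[None, live, :], axis=2)
    calls: list[ClusterCall] = []
    for i, p in enumerate(points):
        if p.is_ntc:
            calls.append(ClusterCall(p.well_id, None, CallLabel.NTC))
            continue
        order = np.argsort(dists[i])
        nearest = live[int(order[0])]
        d1 = dists[i, order[0]]
        d2 = dists[i, order[1]] if len(order) > 1 else np.inf
        dual_high = signal[i] and all(
            np.linalg.norm(x[i] - centroids[c]) > dual_high_sd * sds[c] for c in allele_clusters
        )
        if nearest == bg_cluster or dual_high or (d2 > 0 and d1 / d2 > no_call_margin):
            calls.append(ClusterCall(p.well_id, p.sample_id, CallLabel.NO_CALL))
        else:
            state = cluster_state[nearest]
            label = CallLabel.ANCESTRAL if state == ANCESTRAL else CallLabel.DERIVED
            calls.append(ClusterCall(p.well_id, p.sample_id, label, margin=float(d2 - d1)))
    return calls


_STATE = {CallLabel.ANCESTRAL: ANCESTRAL, CallLabel.DERIVED: DERIVED, CallLabel.NO_CALL: NO_CALL}


def call_plate(plate: PlateRun, panel: Panel, **kwargs) -> dict[str, GenotypeProfile]:
    """Call every assay of a plate; returns one profile per sample.

    Failed panel assays are skipped; an assay name absent from the panel is
    an error. A per-plate assay failure (all wells at background) records N
    for every sample at that marker.
    """
    unknown = [a for a in plate.assays if a not in panel]
    if unknown:
        raise CallingError(f"plate contains assays absent from panel: {unknown}")
    calls: dict[str, dict[str, str]] = {s: {} for s in plate.sample_ids}
    for assay in plate.assays:
        marker = panel[assay]
        if not marker.is_active:
            continue
        for call in call_assay(plate.assay_points(assay), marker, **kwargs):
            if call.genotype is CallLabel.NTC:
                continue
            calls[call.sample_id][assay] = _STATE[call.genotype]
    return {s: GenotypeProfile(s, c) for s, c in calls.items()}


def detect_empty_samples(profiles: dict[str, GenotypeProfile]) -> list[str]:
    """Samples with zero called markers (e.g. empty wells after a loading failure).

    These are excluded from call-rate denominators and haplogroup
    assignment downstream.
    """
    return sorted(s for s, p in profiles.items() if p.is_empty)
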