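"""Flat-file formats: genotype matrices, fluorescence exports, reports.

Genotype matrices are TSV, rows = samples, columns = markers, tokens
A/D and "." for no-call. Fluorescence exports are long-format CSV with
one row per (assay, well). Output files carry a header comment with the
tool version and a digest of the content so runs are traceable and
byte-reproducible for identical inputs.
"""
from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from . import __version__
from .calling import PLATE_COLUMNS, PlateRun
from .errors import YplexError
from .panel import MISSING_TOKEN, Panel
from .profile import NO_CALL, GenotypeProfile
from .qc import QCReport
from .simulate import TruthRecord


def _header_comment(kind: str, body: str, seed: Optional[int] = None) -> str:
    digest = hashlib.sha256(body.encode()).hexdigest()[:12]
    seed_part = f" seed={seed}" if seed is not None else ""
    return f"# yplex v{__version__} {kind}{seed_part} sha256:{digest}\n"


def _write(path, kind: str, body: str, seed: Optional[int] = None) -> None:
    Path(path).write_text(_header_comment(kind, body, seed) + body)


def write_genotypes(
    profiles: Iterable[GenotypeProfile], panel: Panel, path, seed: Optional[int] = None
) -> None:
    profiles = sorted(profiles, key=lambda p: p.sample_id)
    markers = [m for m in panel.active_marker_names]
    frame = pd.DataFrame(
        [[MISSING_TOKEN if p[m] == NO_CALL else p[m] for m in markers] for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=markers,
    )
    frame.index.name = "sample_id"
    _write(path, "genotypes", frame.to_csv(sep="\t"), seed)


def read_genotypes(path, panel: Optional[Panel] = None) -> dict[str, GenotypeProfile]:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", index_col="sample_id", keep_default_na=False)
    if panel is not None:
        unknown = [c for c in frame.columns if c not in panel]
        if unknown:
            raise YplexError(f"genotype file {path}: unknown marker columns {sorted(unknown)}")
    profiles = {}
    for sample_id, row in frame.iterrows():
        calls = {m: (NO_CALL if v in (MISSING_TOKEN, "") else v) for m, v in row.items()}
        profiles[str(sample_id)] = GenotypeProfile(str(sample_id), calls)
    return profiles


def write_plates(plates: Iterable[PlateRun], path, seed: Optional[int] = None) -> None:
    frame = pd.concat([p.points for p in plates], ignore_index=True)
    _write(path, "fluorescence", frame.to_csv(index=False), seed)


def read_plates(path) -> list[PlateRun]:
    frame = pd.read_csv(path, comment="#", dtype={"vic": float, "fam": float}, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise YplexError(f"fluorescence file {path}: missing columns {missing}")
    return [
        PlateRun(g.reset_index(drop=True)) for _, g in frame.groupby("plate_id", sort=True)
    ]


def write_truth(records: Iterable[TruthRecord], path, seed: Optional[int] = None) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "true_haplogroup": r.true_haplogroup,
            "is_empty": int(r.is_empty),
            "dropped_markers": ",".join(sorted(r.dropped_markers)),
            "injected_errors": ",".join(f"{m}:{kind}" for m, kind in r.injected_errors),
        }
        for r in records
    ]
    frame = pd.DataFrame(rows)
    _write(path, "truth", frame.to_csv(sep="\t", index=False), seed)


def read_truth(path) -> list[TruthRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    records = []
    for r in frame.itertuples():
        errors = [tuple(e.split(":", 1)) for e in r.injected_errors.split(",") if e]
        dropped = {m for m in r.dropped_markers.split(",") if m}
        records.append(
            TruthRecord(
                sample_id=r.sample_id,
                true_haplogroup=r.true_haplogroup,
                injected_errors=errors,
                dropped_markers=dropped,
                is_empty=bool(int(r.is_empty)),
            )
        )
    return records


def write_assignments(table: pd.DataFrame, path, seed: Optional[int] = None) -> None:
    _write(path, "assignments", table.to_csv(sep="\t", index=False), seed)


def write_counts(counts: pd.DataFrame, tally: Mapping[str, int], path_tsv, path_json) -> None:
    buf = _io.StringIO()
    counts.to_csv(buf, sep="\t")
    _write(path_tsv, "haplogroup_counts", buf.getvalue())
    payload = {
        "status_tally": dict(tally),
        "haplogroup_counts": {
            label: {pop: int(n) for pop, n in row.items()} for label, row in counts.iterrows()
        },
    }
    Path(path_json).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_qc(report: QCReport, path_json, path_tsv) -> None:
    Path(path_json).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    lines = ["metric\tname\tvalue"]
    lines.append(f"pass_rate\t.\t{report.pass_rate:.1f}")
    lines.append(f"mean_call_rate\t.\t{report.mean_call_rate:.1f}")
    lines.append(f"min_call_rate\t{report.min_call_rate[0]}\t{report.min_call_rate[1]:.1f}")
    if report.concordance is not None:
        lines.append(f"concordance\t.\t{report.concordance:.1f}")
    for marker, rate in sorted(report.marker_call_rates.items()):
        lines.append(f"marker_call_rate\t{marker}\t{rate:.1f}")
    for sample, rate in sorted(report.sample_call_rates.items()):
        lines.append(f"sample_call_rate\t{sample}\t{rate:.1f}")
    _write(path_tsv, "qc", "\n".join(lines) + "\n")
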