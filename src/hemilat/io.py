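"""Core data model and delimited-text I/O.

Interchange is plain delimited text (TSV/CSV auto-detected from the file
extension).  ROI indexing is 1-based in every file and report; internal
arrays are 0-based and the offset never leaks outside this module's
accessors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("RLS", "NRLS", "CTRL")

#: Column order of the aggregate metrics table.
METRIC_NAMES = ("ACC", "PRE", "SPE", "SEN", "F1", "ROC")

_LH_TOKEN = re.compile(r"(?:^|_)LH(?:_|$)")
_RH_TOKEN = re.compile(r"(?:^|_)RH(?:_|$)")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# parcel table


@dataclass(frozen=True)
class ParcelTable:
    """Parcellation lookup: ROI ids, names, hemisphere and network labels.

    ROIs are ordered left hemisphere first (ids ``1..n/2``), right hemisphere
    second (ids ``n/2+1..n``), matching the summation ranges of the laterality
    index definitions.  ``pair_id`` optionally maps each ROI to its homotopic
    partner in the opposite hemisphere (needed only by the legacy pairwise
    index).
    """

    roi_id: np.ndarray
    roi_name: tuple[str, ...]
    hemisphere: tuple[str, ...]
    network: tuple[str, ...]
    pair_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.roi_name)
        if n < 2 or n % 2:
            raise FormatError(f"parcel table needs an even ROI count >= 2, got {n}")
        ids = np.asarray(self.roi_id)
        if ids.shape != (n,) or not np.array_equal(np.sort(ids), np.arange(1, n + 1)):
            raise FormatError("roi_id must cover 1..n exactly once")
        if not np.array_equal(ids, np.arange(1, n + 1)):
            raise FormatError("parcel rows must be sorted by roi_id")
        half = n // 2
        for row, h in enumerate(self.hemisphere):
            want = "L" if row < half else "R"
            if h != want:
                raise FormatError(
                    f"row {row + 1}: hemisphere {h!r} but rows 1..{half} must be L "
                    f"and rows {half + 1}..{n} must be R"
                )
        if self.pair_id is not None:
            pid = np.asarray(self.pair_id)
            if pid.shape != (n,):
                raise FormatError("pair_id length mismatch")
            for row, p in enumerate(pid):
                if not 1 <= p <= n:
                    raise FormatError(f"row {row + 1}: pair_id {p} out of range")
                if pid[p - 1] != row + 1:
                    raise FormatError(f"pair_id is not an involution at roi {row + 1}")
                if (row < half) == (p - 1 < half):
                    raise FormatError(f"pair_id at roi {row + 1} stays in one hemisphere")

    @property
    def n_rois(self) -> int:
        return len(self.roi_name)

    @property
    def half(self) -> int:
        return self.n_rois // 2

    @property
    def left_slice(self) -> slice:
        return slice(0, self.half)

    @property
    def right_slice(self) -> slice:
        return slice(self.half, self.n_rois)

    def name_of(self, roi_id: int) -> str:
        return self.roi_name[roi_id - 1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "roi_id": np.asarray(self.roi_id),
                "roi_name": list(self.roi_name),
                "hemisphere": list(self.hemisphere),
                "network": list(self.network),
            }
        )
        if self.pair_id is not None:
            df["pair_id"] = np.asarray(self.pair_id)
        return df


def _infer_hemisphere(name: str) -> str | None:
    lh = bool(_LH_TOKEN.search(name))
    rh = bool(_RH_TOKEN.search(name))
    if lh == rh:
        return None
    return "L" if lh else "R"


def _infer_network(name: str) -> str:
    # Schaefer-style names: <scheme>_<hemi>_<network>_<area>...
    parts = name.split("_")
    for i, tok in enumerate(parts):
        if tok in ("LH", "RH") and i + 1 < len(parts):
            return parts[i + 1]
    return ""


def make_parcel_table(
    roi_names: Sequence[str],
    hemisphere: Sequence[str] | None = None,
    network: Sequence[str] | None = None,
    pair_id: Sequence[int] | None = None,
) -> ParcelTable:
    """Build a validated :class:`ParcelTable` from ROI names.

    Hemisphere is inferred from ``_LH_`` / ``_RH_`` tokens when not given.
    """
    n = len(roi_names)
    if hemisphere is None:
        hemisphere = []
        for row, name in enumerate(roi_names):
            h = _infer_hemisphere(name)
            if h is None:
                raise FormatError(f"row {row + 1} ({name!r}): cannot infer hemisphere")
            hemisphere.append(h)
    if network is None:
        network = [_infer_network(nm) for nm in roi_names]
    return ParcelTable(
        roi_id=np.arange(1, n + 1),
        roi_name=tuple(str(nm) for nm in roi_names),
        hemisphere=tuple(hemisphere),
        network=tuple(network),
        pair_id=None if pair_id is None else np.asarray(pair_id, dtype=int),
    )


def read_parcel_table(path: str | Path, expect_rois: int = 400) -> ParcelTable:
    """Read a Schaefer-style lookup table (TSV/CSV with roi_id, roi_name, ...).

    Hemisphere may be given as a column or inferred from the ``_LH_``/``_RH_``
    token of the ROI name.  The row count must equal ``expect_rois``
    (pass ``None`` to accept any even count).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    if "roi_id" not in df.columns or "roi_name" not in df.columns:
        raise FormatError(f"{path}: need columns roi_id, roi_name; got {list(df.columns)}")
    if expect_rois is not None and len(df) != expect_rois:
        raise FormatError(f"{path}: expected {expect_rois} rows, found {len(df)}")
    if df["roi_id"].duplicated().any():
        dup = int(df.loc[df["roi_id"].duplicated(), "roi_id"].iloc[0])
        raise FormatError(f"{path}: duplicate roi_id {dup}")
    df = df.sort_values("roi_id").reset_index(drop=True)
    hemi = None
    if "hemisphere" in df.columns:
        hemi = [str(h).strip().upper()[:1] for h in df["hemisphere"]]
    net = [str(x) for x in df["network"]] if "network" in df.columns else None
    pair = df["pair_id"].to_numpy(dtype=int) if "pair_id" in df.columns else None
    return make_parcel_table(list(df["roi_name"]), hemi, net, pair)


def write_parcel_table(parcels: ParcelTable, path: str | Path) -> None:
    path = Path(path)
    parcels.to_frame().to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# ROI time series


@dataclass
class RoiTimeSeries:
    """One subject's parcellated signal: timepoints x ROIs, with group label."""

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (timepoints x ROIs)")
        if not np.isfinite(self.data).all():
            raise ValueError(f"{self.subject_id}: non-finite values in time series")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def validate(self, parcels: ParcelTable, min_timepoints: int = 30) -> "RoiTimeSeries":
        t, p = self.data.shape
        if p != parcels.n_rois:
            raise FormatError(
                f"{self.subject_id}: {p} columns but parcel table has {parcels.n_rois} ROIs"
            )
        if t < min_timepoints:
            raise FormatError(f"{self.subject_id}: only {t} timepoints (need >= {min_timepoints})")
        sd = self.data.std(axis=0)
        flat = np.nonzero(sd == 0)[0]
        if flat.size:
            raise FormatError(
                f"{self.subject_id}: constant signal in ROI {flat[0] + 1} "
                f"({parcels.name_of(int(flat[0]) + 1)})"
            )
        return self


def read_timeseries(
    path: str | Path,
    parcels: ParcelTable,
    subject_id: str | None = None,
    group: str = "CTRL",
    tr_seconds: float = 2.0,
    min_timepoints: int = 30,
) -> RoiTimeSeries:
    """Read a delimited T x ROI matrix (no header), one column per parcel row."""
    path = Path(path)
    try:
        data = pd.read_csv(path, sep=_sep_for(path), header=None).to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    ts = RoiTimeSeries(
        subject_id=subject_id or path.stem,
        group=group,
        data=data,
        tr_seconds=tr_seconds,
    )
    return ts.validate(parcels, min_timepoints=min_timepoints)


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, ts.data, delimiter=_sep_for(path), fmt="%.12g")


# ---------------------------------------------------------------------------
# clinical covariates


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-subject clinical covariates.

    ``embolic_count`` (contrast-TCD embolic signals) exists only for the
    right-to-left-shunt group, where it grades shunt severity.
    """

    subject_id: str
    group: str
    duration_years: float
    attacks_per_month: float
    vas: float
    embolic_count: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if not 0 <= self.vas <= 10:
            raise ValueError(f"{self.subject_id}: VAS {self.vas} outside [0, 10]")
        if self.duration_years < 0 or self.attacks_per_month < 0:
            raise ValueError(f"{self.subject_id}: negative duration/frequency")
        if self.embolic_count is not None:
            if self.group != "RLS":
                raise ValueError(
                    f"{self.subject_id}: embolic_count set for group {self.group} "
                    "(only the RLS group undergoes shunt grading)"
                )
            if self.embolic_count < 0:
                raise ValueError("embolic_count must be non-negative")


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    records = []
    for _, row in df.iterrows():
        emb = row.get("embolic_count")
        emb = None if emb is None or pd.isna(emb) else int(emb)
        records.append(
            ClinicalRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                duration_years=float(row["duration_years"]),
                attacks_per_month=float(row["attacks_per_month"]),
                vas=float(row["vas"]),
                embolic_count=emb,
            )
        )
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "duration_years": r.duration_years,
                "attacks_per_month": r.attacks_per_month,
                "vas": r.vas,
                "embolic_count": r.embolic_count,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# run reports


def write_report(report, out_dir: str | Path, config=None) -> dict[str, Path]:
    """Write a classification run to disk.

    Emits ``per_repetition.csv`` (one row per repetition, all six metrics),
    ``aggregate.csv`` (mean and 95% CI per metric), ``feature_scores.csv``
    when importances are present, and ``manifest.json`` capturing the
    configuration and seed so the run can be replayed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_rep = report.per_repetition_frame()
    if per_rep.empty:
        raise ValueError("report has no completed repetitions")
    paths = {}
    p = out_dir / "per_repetition.csv"
    per_rep.to_csv(p, index=False)
    paths["per_repetition"] = p
    p = out_dir / "aggregate.csv"
    report.aggregate_frame().to_csv(p, index=False)
    paths["aggregate"] = p
    manifest = {
        "seed": report.seed,
        "n_repetitions": len(report.records),
        "n_skipped": report.n_skipped,
        "metric_averaging": "macro one-vs-rest",
        "config": dict(config.as_dict()) if config is not None else None,
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = p
    return paths
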