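"""Feature scoring, key-ROI extraction, shunt grading, clinical correlation.

Each feature's per-repetition score is its random-forest importance times
the mean of two accuracies — the internal test accuracy of that repetition
and the matching external-validation accuracy — with unselected features
scoring exactly zero; cumulative scores sum over all repetitions.  The top
40 features by cumulative score name the candidate brain regions; an ROI
appearing in at least two of the four index families is flagged a key
region.  Right-to-left shunt severity is graded from embolic-signal
counts, and regional laterality is correlated (Pearson, p < 0.05
uncorrected) with clinical covariates per patient group.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hemilat.classify import RunReport
from hemilat.io import ClinicalRecord, ParcelTable
from hemilat.laterality import FAMILIES, LateralityProfile

#: ordinal encoding of shunt grades used in correlations
GRADE_ORDINAL = {"none": 0, "minimal": 1, "moderate": 2, "large": 3}


@dataclass(frozen=True)
class RlsGrade:
    embolic_count: int
    grade: str


def grade_rls(embolic_count: int) -> RlsGrade:
    """Grade a right-to-left shunt from its embolic-signal count.

    0 signals: none; 1-10: minimal; 11-25: moderate; >25: large.
    """
    if embolic_count < 0:
        raise ValueError("embolic count must be non-negative")
    if embolic_count == 0:
        grade = "none"
    elif embolic_count <= 10:
        grade = "minimal"
    elif embolic_count <= 25:
        grade = "moderate"
    else:
        grade = "large"
    return RlsGrade(embolic_count=int(embolic_count), grade=grade)


@dataclass
class FeatureScoreTable:
    """Cumulative and per-repetition feature scores."""

    provenance: tuple[tuple[str, int], ...]
    per_repetition: np.ndarray  # (n_repetitions, n_features)
    cumulative: np.ndarray  # (n_features,)

    def to_frame(self, parcels: ParcelTable | None = None) -> pd.DataFrame:
        fam = [f for f, _ in self.provenance]
        roi = [r for _, r in self.provenance]
        df = pd.DataFrame({"family": fam, "roi_id": roi, "score": self.cumulative})
        if parcels is not None:
            df["roi_name"] = [parcels.name_of(r) for r in roi]
            df = df[["family", "roi_id", "roi_name", "score"]]
        return df


def accumulate_scores(report: RunReport, validation: RunReport) -> FeatureScoreTable:
    """Per-repetition feature scores: importance x mean(test, validation) accuracy.

    Features a repetition did not select keep importance zero, hence score
    zero; cumulative scores are the sums across repetitions.
    """
    n_rep = report.importances.shape[0]
    if len(validation.records) != n_rep:
        raise ValueError(
            f"report has {n_rep} repetitions but validation has {len(validation.records)}"
        )
    acc1 = report.accuracies()
    acc2 = validation.accuracies()
    per_rep = report.importances * ((acc1 + acc2) / 2.0)[:, None]
    return FeatureScoreTable(
        provenance=report.provenance,
        per_repetition=per_rep,
        cumulative=per_rep.sum(axis=0),
    )


def top_features(
    table: FeatureScoreTable,
    k: int = 40,
    parcels: ParcelTable | None = None,
    per_family: bool = False,
) -> pd.DataFrame:
    """Top-``k`` features by cumulative score.

    The cut is global across all families (``per_family=True`` takes ``k``
    within each family instead); ties break deterministically by family
    order then roi_id.  Rows are reported grouped by family.
    """
    df = table.to_frame(parcels)
    if k > len(df):
        raise ValueError(f"k={k} exceeds the {len(df)} scored features")
    fam_rank = {f: i for i, f in enumerate(FAMILIES)}
    df["_fam_rank"] = df["family"].map(fam_rank)
    df = df.sort_values(
        ["score", "_fam_rank", "roi_id"], ascending=[False, True, True], kind="mergesort"
    )
    top = df.groupby("family", sort=False).head(k) if per_family else df.head(k)
    top = top.sort_values(["_fam_rank", "score"], ascending=[True, False], kind="mergesort")
    return top.drop(columns="_fam_rank").reset_index(drop=True)


def key_rois(top: pd.DataFrame, min_families: int = 2) -> pd.DataFrame:
    """Count, per ROI, the distinct index families containing it in the top list.

    ROIs appearing in at least ``min_families`` families are flagged key
    regions.
    """
    counts = (
        top.groupby("roi_id")["family"].nunique().rename("n_families").reset_index()
    )
    counts["key"] = counts["n_families"] >= min_families
    return counts.sort_values(["n_families", "roi_id"], ascending=[False, True]).reset_index(
        drop=True
    )


def load_reference_top40() -> pd.DataFrame:
    """The published top-40 feature table (family, roi_id, roi_name, score).

    Bundled so the key-ROI occurrence logic can be exercised against the
    published ranking without any external data.
    """
    with importlib.resources.files("hemilat").joinpath("data/top40_features.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def clinical_correlations(
    profiles: Sequence[LateralityProfile],
    records: Sequence[ClinicalRecord],
    group: str,
    rois: Sequence[int],
    families: Sequence[str] = FAMILIES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between key-ROI laterality and clinical covariates.

    For one patient group, every (ROI, family) pair is correlated with
    disease duration, attack frequency, and VAS — plus the ordinal shunt
    grade for the RLS group.  ``significant`` flags two-sided p < alpha,
    uncorrected; the caller sees the number of tests and can correct.
    Zero-variance variables are skipped with a warning row omitted.
    """
    members = [p for p in profiles if p.group == group]
    if len(members) < 4:
        raise ValueError(f"group {group}: need >= 4 subjects for correlation")
    by_id: Mapping[str, ClinicalRecord] = {r.subject_id: r for r in records}
    missing = [p.subject_id for p in members if p.subject_id not in by_id]
    if missing:
        raise ValueError(f"no clinical record for subjects {missing[:3]}")
    recs = [by_id[p.subject_id] for p in members]
    variables = {
        "duration": np.array([r.duration_years for r in recs]),
        "frequency": np.array([r.attacks_per_month for r in recs]),
        "vas": np.array([r.vas for r in recs]),
    }
    if group == "RLS":
        variables["rls_grade"] = np.array(
            [GRADE_ORDINAL[grade_rls(r.embolic_count or 0).grade] for r in recs], dtype=float
        )
    rows = []
    for roi in rois:
        for fam in families:
            lat = np.array([p.vectors[fam].values[roi - 1] for p in members])
            for var, vals in variables.items():
                if np.std(vals) == 0 or np.std(lat) == 0:
                    continue
                r, p_val = stats.pearsonr(lat, vals)
                rows.append(
                    {
                        "group": group,
                        "roi_id": roi,
                        "family": fam,
                        "variable": var,
                        "r": float(r),
                        "p": float(p_val),
                        "significant": bool(p_val < alpha),
                    }
                )
    return pd.DataFrame(rows)
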