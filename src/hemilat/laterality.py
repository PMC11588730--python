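"""Weighted laterality indices of connectivity and nodal network topology.

For every seed ROI ``i`` the connectivity index compares its mean retained
correlation toward the left hemisphere (``MeanRL_i``, targets ``1..200``)
against the right (``MeanRR_i``, targets ``201..400``), with weighting
coefficients that up-weight strongly connected seeds:

    ``W_RL_i = MeanRL_i / mean(MeanRL)``   (likewise ``W_RR_i``)
    ``index_i = (MeanRL_i W_RL_i - MeanRR_i W_RR_i)
              / (MeanRL_i W_RL_i + MeanRR_i W_RR_i)``

The topology indices apply the same ratio to threshold-integrated nodal
metrics (betweenness centrality, degree, strength): for a left node the
"own-side" term is its AUC inside the within-left network and the
"other-side" term its AUC inside the inter-hemispheric network, and
mirrored for right nodes.  All indices lie in [-1, 1]; positive means a
leftward bias.  Degenerate (both-zero) denominators yield index 0 with a
degeneracy flag, keeping feature matrices dense.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from hemilat.config import PipelineConfig
from hemilat.connectome import (
    Connectome,
    METRICS,
    compute_rfc,
    node_metric_aucs,
    partition_hemispheres,
)
from hemilat.io import ParcelTable, RoiTimeSeries

#: fixed family order of the feature layout
FAMILIES = ("LFunctionCorrR", "LBetweennessCentralityR", "LDegreeR", "LStrengthR")

_METRIC_FAMILY = {
    "betweenness": "LBetweennessCentralityR",
    "degree": "LDegreeR",
    "strength": "LStrengthR",
}


@dataclass(frozen=True)
class SeedHemiMeans:
    """Per-seed mean retained correlation toward each hemisphere's targets."""

    mean_rl: np.ndarray
    mean_rr: np.ndarray
    half: int
    n_left_targets: np.ndarray
    n_right_targets: np.ndarray


@dataclass(frozen=True)
class LateralityVector:
    family: str
    values: np.ndarray
    degenerate: np.ndarray


@dataclass
class LateralityProfile:
    """One subject's four laterality-index families (4 x n_rois features)."""

    subject_id: str
    group: str
    vectors: dict[str, LateralityVector]

    @property
    def n_rois(self) -> int:
        return self.vectors[FAMILIES[0]].values.size

    def feature_vector(self) -> np.ndarray:
        """Concatenated features in fixed family order (length 4 x n_rois)."""
        return np.concatenate([self.vectors[f].values for f in FAMILIES])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in FAMILIES:
            v = self.vectors[fam]
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": self.subject_id,
                        "group": self.group,
                        "family": fam,
                        "roi_id": np.arange(1, v.values.size + 1),
                        "value": v.values,
                        "degenerate": v.degenerate.astype(int),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def seed_hemi_means(
    c: Connectome, parcels: ParcelTable, include_self: bool = False
) -> SeedHemiMeans:
    """Mean retained correlation from every seed to each hemisphere's targets.

    The seed's own (unit) self-correlation is excluded by default, so left
    seeds average over the other ``half - 1`` left targets and all ``half``
    right targets (and symmetrically for right seeds);
    ``include_self=True`` reproduces the literal summation with ``j = i``
    included.
    """
    half = parcels.half
    m = c.matrix
    sum_l = m[:, :half].sum(axis=1)
    sum_r = m[:, half:].sum(axis=1)
    n_l = np.full(m.shape[0], float(half))
    n_r = np.full(m.shape[0], float(half))
    if not include_self:
        sum_l[:half] -= np.diag(m)[:half]
        sum_r[half:] -= np.diag(m)[half:]
        n_l[:half] -= 1
        n_r[half:] -= 1
    return SeedHemiMeans(
        mean_rl=sum_l / n_l,
        mean_rr=sum_r / n_r,
        half=half,
        n_left_targets=n_l,
        n_right_targets=n_r,
    )


def _scoped_mean(x: np.ndarray, half: int, scope: str) -> np.ndarray:
    """Normalizer mean broadcast per seed: over all seeds or per hemisphere."""
    if scope == "all_rois":
        return np.full_like(x, x.mean())
    out = np.empty_like(x)
    out[:half] = x[:half].mean()
    out[half:] = x[half:].mean()
    return out


def _weights(x: np.ndarray, norm: np.ndarray) -> np.ndarray:
    """x / norm with an all-zero scope collapsing to unit weights."""
    w = np.ones_like(x)
    nz = norm > 0
    w[nz] = x[nz] / norm[nz]
    return w


def _ratio_index(num_l: np.ndarray, num_r: np.ndarray) -> LateralityVector:
    den = num_l + num_r
    degenerate = den == 0
    values = np.zeros_like(den)
    ok = ~degenerate
    values[ok] = (num_l[ok] - num_r[ok]) / den[ok]
    return LateralityVector(family="", values=values, degenerate=degenerate)


def lfunctioncorr(
    means: SeedHemiMeans, weighting: bool = True, scope: str = "all_rois"
) -> LateralityVector:
    """Weighted connectivity-laterality index per seed ROI.

    ``scope`` picks the normalizer of the weighting coefficients: the mean
    of ``MeanRL`` (resp. ``MeanRR``) over all seeds (``all_rois``) or over
    the seed's own hemisphere (``per_hemisphere``).  With ``weighting``
    off all weights are 1 and the index reduces to the plain normalized
    difference of the two hemisphere means.
    """
    if scope not in ("all_rois", "per_hemisphere"):
        raise ValueError("scope must be all_rois|per_hemisphere")
    if weighting:
        w_rl = _weights(means.mean_rl, _scoped_mean(means.mean_rl, means.half, scope))
        w_rr = _weights(means.mean_rr, _scoped_mean(means.mean_rr, means.half, scope))
    else:
        w_rl = np.ones_like(means.mean_rl)
        w_rr = np.ones_like(means.mean_rr)
    vec = _ratio_index(means.mean_rl * w_rl, means.mean_rr * w_rr)
    return LateralityVector(
        family="LFunctionCorrR", values=vec.values, degenerate=vec.degenerate
    )


def lnetwork(
    auc_within: np.ndarray,
    auc_inter: np.ndarray,
    parcels: ParcelTable,
    weighting: bool = True,
    scope: str = "per_hemisphere",
    family: str = "",
) -> LateralityVector:
    """Topology-laterality index per node from threshold-integrated metrics.

    For a left node the own-side term ``XRL`` is its within-left-network
    AUC and the other-side term ``XRR`` its inter-hemispheric AUC; for a
    right node the roles mirror (``XRL`` inter, ``XRR`` within-right).
    Weight normalizers are computed separately over the left-node and
    right-node sets for each role (default ``per_hemisphere``), because the
    two roles mix within- and inter-network scales; ``all_rois`` pools the
    assembled role vectors over all nodes instead.
    """
    if scope not in ("all_rois", "per_hemisphere"):
        raise ValueError("scope must be all_rois|per_hemisphere")
    auc_within = np.asarray(auc_within, dtype=float)
    auc_inter = np.asarray(auc_inter, dtype=float)
    n = parcels.n_rois
    if auc_within.shape != (n,) or auc_inter.shape != (n,):
        raise ValueError("AUC vectors misaligned with the parcel table")
    half = parcels.half
    x_rl = np.where(np.arange(n) < half, auc_within, auc_inter)
    x_rr = np.where(np.arange(n) < half, auc_inter, auc_within)
    if weighting:
        w_rl = _weights(x_rl, _scoped_mean(x_rl, half, scope))
        w_rr = _weights(x_rr, _scoped_mean(x_rr, half, scope))
    else:
        w_rl = np.ones_like(x_rl)
        w_rr = np.ones_like(x_rr)
    vec = _ratio_index(x_rl * w_rl, x_rr * w_rr)
    return LateralityVector(family=family, values=vec.values, degenerate=vec.degenerate)


def compute_profile(
    ts: RoiTimeSeries | Connectome,
    parcels: ParcelTable,
    config: PipelineConfig | None = None,
) -> LateralityProfile:
    """All four laterality families for one subject.

    Accepts a raw time series (the connectome is computed first) or an
    already-built connectome.  The connectivity index uses the configured
    normalizer scope; the topology indices use per-hemisphere (per-role)
    normalizers as described in :func:`lnetwork`.
    """
    config = config or PipelineConfig()
    c = ts if isinstance(ts, Connectome) else compute_rfc(ts)
    means = seed_hemi_means(c, parcels, include_self=config.include_self)
    vectors = {
        "LFunctionCorrR": lfunctioncorr(
            means, weighting=config.weighting_enabled, scope=config.weight_normalizer_scope
        )
    }
    hemi = partition_hemispheres(c, parcels, inter_network=config.inter_network)
    aucs = node_metric_aucs(
        hemi, parcels, config.threshold_grid, betweenness_mode=config.betweenness_mode
    )
    for metric in METRICS:
        fam = _METRIC_FAMILY[metric]
        vectors[fam] = lnetwork(
            aucs[metric]["within"],
            aucs[metric]["inter"],
            parcels,
            weighting=config.weighting_enabled,
            family=fam,
        )
    return LateralityProfile(subject_id=c.subject_id, group=c.group, vectors=vectors)


def legacy_indices(
    means: SeedHemiMeans,
    parcels: ParcelTable,
    feature: np.ndarray | None = None,
) -> pd.DataFrame:
    """Homotopic-pair baseline indices from earlier lateralization work.

    Per homotopic pair (left ROI ``i`` paired with right ROI ``j``):

    * ``pair_index``  — ``(X_i - X_j) / (X_i + X_j)`` on a per-ROI feature
      ``X`` (default: the seed's overall mean connectivity);
    * ``segregation`` — ``(XLL - XLR) - (XRR - XRL)``, within- minus
      cross-hemisphere connectivity contrast of the two members;
    * ``integration`` — ``(XLL + XLR) - (XRR + XRL)``, total-connectivity
      contrast.

    Requires ``pair_id`` in the parcel table.
    """
    if parcels.pair_id is None:
        raise ValueError("legacy indices need a homotopic pairing (pair_id) in the parcel table")
    half = parcels.half
    if feature is None:
        feature = (means.mean_rl + means.mean_rr) / 2.0
    feature = np.asarray(feature, dtype=float)
    left_ids = np.arange(1, half + 1)
    right_ids = np.asarray(parcels.pair_id)[:half]
    li = left_ids - 1
    ri = right_ids - 1
    x_l, x_r = feature[li], feature[ri]
    den = x_l + x_r
    pair_index = np.where(den != 0, (x_l - x_r) / np.where(den == 0, 1, den), 0.0)
    xll, xlr = means.mean_rl[li], means.mean_rr[li]
    xrr, xrl = means.mean_rr[ri], means.mean_rl[ri]
    return pd.DataFrame(
        {
            "left_roi": left_ids,
            "right_roi": right_ids,
            "pair_index": pair_index,
            "segregation": (xll - xlr) - (xrr - xrl),
            "integration": (xll + xlr) - (xrr + xrl),
        }
    )


def legacy_feature_matrix(
    connectomes: Sequence[Connectome],
    parcels: ParcelTable,
    include_self: bool = False,
):
    """Baseline features for comparison runs: the homotopic-pair index,
    segregation, and integration per pair, stacked into a feature matrix
    the classification pipeline accepts directly.

    Column provenance uses the pair's left ROI id under the families
    ``LateralityIndex``, ``Segregation``, ``Integration``.
    """
    from hemilat.classify import FeatureMatrix

    rows = []
    for c in connectomes:
        means = seed_hemi_means(c, parcels, include_self=include_self)
        df = legacy_indices(means, parcels)
        rows.append(np.concatenate([df["pair_index"], df["segregation"], df["integration"]]))
    half = parcels.half
    prov = tuple(
        (fam, rid)
        for fam in ("LateralityIndex", "Segregation", "Integration")
        for rid in range(1, half + 1)
    )
    sids = np.array([c.subject_id for c in connectomes])
    return FeatureMatrix(
        x=np.stack(rows),
        labels=np.array([c.group for c in connectomes]),
        subject_ids=sids,
        origin=np.array([s.split("__seg")[0] for s in sids]),
        provenance=prov,
    )


def group_summary(profiles: Sequence[LateralityProfile]) -> pd.DataFrame:
    """Per-ROI and whole-brain mean with SEM, per family per group.

    Rows with ``roi_id == "ALL"`` summarize the whole brain: the group mean
    of each subject's across-ROI average.
    """
    if not profiles:
        raise ValueError("no profiles given")
    rows = []
    groups = sorted({p.group for p in profiles})
    for g in groups:
        members = [p for p in profiles if p.group == g]
        if len(members) < 2:
            raise ValueError(f"group {g}: need >= 2 subjects for a summary")
        for fam in FAMILIES:
            mat = np.stack([p.vectors[fam].values for p in members])
            sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
            for roi in range(mat.shape[1]):
                rows.append(
                    {
                        "group": g,
                        "family": fam,
                        "roi_id": roi + 1,
                        "mean": mat[:, roi].mean(),
                        "sem": sem[roi],
                    }
                )
            wb = mat.mean(axis=1)
            rows.append(
                {
                    "group": g,
                    "family": fam,
                    "roi_id": "ALL",
                    "mean": wb.mean(),
                    "sem": wb.std(ddof=1) / np.sqrt(wb.size),
                }
            )
    return pd.DataFrame(rows)
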