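"""Synthetic three-group cohort generator with analytic ground truth.

Each group's ROI signals follow a two-factor Gaussian model: one latent
factor per hemisphere, correlated across hemispheres.  ROI ``i`` loads
``a_i`` on its own hemisphere's factor and ``b_i`` on the other's, with the
residual variance chosen so every marginal variance is one — the population
covariance is therefore an exact correlation matrix, positive semi-definite
by construction, and every population correlation has a closed form:

* within hemisphere:  ``a_i a_j + b_i b_j + (a_i b_j + b_i a_j) rho``
* across hemispheres: ``a_i b_j + b_i a_j + (a_i a_j + b_i b_j) rho``

Hemispheric asymmetry is injected by shifting ``delta`` of a signal ROI's
loading from the non-target to the target hemisphere's factor (``+delta``
on the target factor, ``-delta`` on the other).  This raises its mean
connectivity toward the target hemisphere while lowering it toward the
other, producing a population laterality index of the designated sign; a
pure boost of one loading would largely cancel in the ratio-form index,
because with a single transmission path a seed's left and right mean
connectivities scale together.  The cross-loading ``kappa`` must be
positive for the same reason: it gives each ROI its own connection to the
opposite hemisphere, so the two hemisphere means can move independently.  Clinical covariates are affine
in the (standardized) laterality of an anchor ROI, so the downstream
correlation stage has planted positives with tunable power.

Timepoints are i.i.d. by default (an optional AR(1) knob adds temporal
smoothness without changing the stationary correlations); Pearson
connectivity is invariant in expectation, and the analysis uses temporal
order only for segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from hemilat.io import ClinicalRecord, GROUPS, ParcelTable, RoiTimeSeries, make_parcel_table

#: embolic-signal count ranges for the shunt grades (minimal, moderate, large)
_GRADE_RANGES = {"minimal": (1, 10), "moderate": (11, 25), "large": (26, 60)}


def default_parcel_names(n_rois: int = 400) -> list[str]:
    """Schaefer-style ROI names, left hemisphere first."""
    half = n_rois // 2
    return [f"17Networks_LH_Synth_{i + 1}" for i in range(half)] + [
        f"17Networks_RH_Synth_{i + 1}" for i in range(half)
    ]


def default_signal_rois(n_rois: int = 400) -> dict[str, dict[int, str]]:
    """Default planted asymmetries: the RLS-like group gets a leftward boost
    on a block of left-hemisphere ROIs, the NRLS-like group a rightward boost
    on the mirrored right-hemisphere block, controls none."""
    half = n_rois // 2
    k = min(20, max(2, half // 10))
    left_block = {i: "L" for i in range(10, 10 + k)} if half >= 10 + k else {
        i: "L" for i in range(1, 1 + k)
    }
    right_block = {i + half: "R" for i in left_block}
    return {"RLS": left_block, "NRLS": right_block, "CTRL": {}}


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the reference study's design: groups of 11/16/16
    (shunt-positive migraineurs, shunt-negative migraineurs, controls) with
    150/150/118 timepoints, 400 ROIs split 200 left / 200 right, a
    positive-dominant correlation structure, and clinical covariates whose
    marginal means and spreads match the reported cohort statistics.
    """

    n_per_group: tuple[int, int, int] = (11, 16, 16)
    t_per_group: tuple[int, int, int] = (150, 150, 118)
    n_rois: int = 400
    #: loading of every ROI on its own hemisphere's factor
    base_loading: float = 0.7
    #: loading on the opposite hemisphere's factor (negative values inject
    #: negative cross-hemisphere correlations, exercising the zeroing rule)
    cross_loading: float = 0.3
    #: correlation between the two hemisphere factors
    hemisphere_factor_corr: float = 0.3
    #: group -> {roi_id: target hemisphere "L"|"R"} receiving the boost
    signal_rois: dict[str, dict[int, str]] = field(default_factory=default_signal_rois)
    #: loading shifted from the non-target to the target hemisphere's factor
    #: for each signal ROI
    asymmetry_delta: float = 0.2
    #: sd of additional white measurement noise (attenuates all correlations)
    noise_sd: float = 0.0
    #: AR(1) coefficient of the latent factors/residuals (0 = i.i.d. timepoints)
    ar1_phi: float = 0.0
    #: clinical coupling: covariate = mean + a * z(anchor laterality) + noise
    a_duration: float = 0.0
    a_vas: float = 0.0
    a_freq: float = 0.0
    a_embolic: float = 0.0
    clinical_noise_sd: tuple[float, float, float] = (10.67, 1.16, 2.94)
    clinical_means: tuple[float, float, float] = (16.65, 8.34, 2.66)
    #: marginal shunt-grade proportions (minimal, moderate, large)
    grade_proportions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    #: ROI whose laterality drives the clinical covariates; default: the
    #: group's first signal ROI (ROI 1 for groups without signal)
    anchor_roi: int | None = None
    tr_seconds: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 4 or self.n_rois % 2:
            raise ValueError("n_rois must be an even integer >= 4")
        if not 0 < self.base_loading < 1:
            raise ValueError("base_loading must lie in (0, 1)")
        if not 0 <= self.hemisphere_factor_corr < 1:
            raise ValueError("hemisphere_factor_corr must lie in [0, 1)")
        if abs(self.base_loading) + abs(self.asymmetry_delta) >= 1:
            raise ValueError("|base_loading| + |asymmetry_delta| must be < 1")
        for g, rois in self.signal_rois.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in signal_rois")
            for rid, hemi in rois.items():
                if not 1 <= rid <= self.n_rois:
                    raise ValueError(f"signal ROI {rid} outside 1..{self.n_rois}")
                if hemi not in ("L", "R"):
                    raise ValueError("signal target hemisphere must be 'L' or 'R'")
        if abs(np.sum(self.grade_proportions) - 1) > 1e-9 or min(self.grade_proportions) < 0:
            raise ValueError("grade_proportions must be nonnegative and sum to 1")

    def anchor_for(self, group: str) -> int:
        if self.anchor_roi is not None:
            return self.anchor_roi
        rois = self.signal_rois.get(group, {})
        return min(rois) if rois else 1

    def parcel_table(self) -> ParcelTable:
        return make_parcel_table(default_parcel_names(self.n_rois))


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: signal ROIs with their laterality sign per group,
    and the analytic population correlation matrix of each group."""

    signal_rois: dict[str, dict[int, int]]  # group -> {roi_id: +1 leftward / -1 rightward}
    population_corr: dict[str, np.ndarray]

    def correlation(self, group: str, roi_i: int, roi_j: int) -> float:
        """Population correlation between ROIs ``roi_i`` and ``roi_j`` (1-based)."""
        return float(self.population_corr[group][roi_i - 1, roi_j - 1])


def _loadings(spec: CohortSpec, group: str) -> np.ndarray:
    """Per-ROI loadings on (left factor, right factor), shape (n_rois, 2)."""
    half = spec.n_rois // 2
    load = np.zeros((spec.n_rois, 2))
    load[:half, 0] = spec.base_loading
    load[:half, 1] = spec.cross_loading
    load[half:, 1] = spec.base_loading
    load[half:, 0] = spec.cross_loading
    for rid, hemi in spec.signal_rois.get(group, {}).items():
        target = 0 if hemi == "L" else 1
        load[rid - 1, target] += spec.asymmetry_delta
        load[rid - 1, 1 - target] -= spec.asymmetry_delta
    return load


def build_population_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Analytic population correlation matrix of one group's ROI signals.

    Includes the attenuation from ``noise_sd`` so it matches what Pearson
    correlation of the sampled series estimates.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    load = _loadings(spec, group)
    rho = spec.hemisphere_factor_corr
    psi = np.array([[1.0, rho], [rho, 1.0]])
    common = load @ psi @ load.T
    resid = 1.0 - np.diag(common)
    if np.any(resid < -1e-12):
        raise ValueError("factor loadings produce a diagonal > 1; reduce loadings")
    sigma = common + np.diag(np.clip(resid, 0.0, None))
    atten = 1.0 + spec.noise_sd**2
    corr = sigma / atten
    np.fill_diagonal(corr, 1.0)
    return corr


def _ar1_colored(white: np.ndarray, phi: float) -> np.ndarray:
    """AR(1)-filter columns of ``white``, rescaled to unit marginal variance."""
    if phi == 0.0:
        return white
    out = np.empty_like(white)
    out[0] = white[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, white.shape[0]):
        out[t] = phi * out[t - 1] + scale * white[t]
    return out


def _sample_subject(spec: CohortSpec, group: str, t: int, rng: np.random.Generator) -> np.ndarray:
    load = _loadings(spec, group)
    rho = spec.hemisphere_factor_corr
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    factors = _ar1_colored(rng.standard_normal((t, 2)), spec.ar1_phi) @ chol.T
    resid_var = np.clip(1.0 - np.einsum("ij,jk,ik->i", load, np.array([[1, rho], [rho, 1]]), load), 0, None)
    resid = _ar1_colored(rng.standard_normal((t, spec.n_rois)), spec.ar1_phi)
    data = factors @ load.T + resid * np.sqrt(resid_var)
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal((t, spec.n_rois))
    return data


def sample_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[RoiTimeSeries], GroundTruth]:
    """Draw the three groups' ROI time series.

    Deterministic given ``seed`` (falls back to ``spec.seed``); each subject
    gets an independent child stream, so groups with identical parameters are
    exchangeable by construction.
    """
    root = np.random.default_rng(spec.seed if seed is None else seed)
    subjects: list[RoiTimeSeries] = []
    for group, n, t in zip(GROUPS, spec.n_per_group, spec.t_per_group):
        for k in range(n):
            rng = np.random.default_rng(root.integers(2**63))
            data = _sample_subject(spec, group, t, rng)
            subjects.append(
                RoiTimeSeries(
                    subject_id=f"{group}_{k + 1:03d}",
                    group=group,
                    data=data,
                    tr_seconds=spec.tr_seconds,
                )
            )
    signal = {
        g: {rid: (1 if hemi == "L" else -1) for rid, hemi in spec.signal_rois.get(g, {}).items()}
        for g in GROUPS
    }
    pop = {g: build_population_covariance(spec, g) for g in GROUPS}
    return subjects, GroundTruth(signal_rois=signal, population_corr=pop)


def _anchor_laterality(subjects: Sequence[RoiTimeSeries], spec: CohortSpec) -> dict[str, float]:
    """Connectivity-laterality of each subject's group anchor ROI."""
    from hemilat.connectome import compute_rfc
    from hemilat.laterality import lfunctioncorr, seed_hemi_means

    parcels = spec.parcel_table()
    out = {}
    for ts in subjects:
        means = seed_hemi_means(compute_rfc(ts), parcels)
        idx = lfunctioncorr(means, weighting=True, scope="all_rois")
        out[ts.subject_id] = float(idx.values[spec.anchor_for(ts.group) - 1])
    return out


def sample_clinical(
    subjects: Sequence[RoiTimeSeries],
    spec: CohortSpec,
    seed: int | None = None,
    anchor_laterality: Mapping[str, float] | None = None,
) -> list[ClinicalRecord]:
    """Draw clinical covariates coupled to the anchor ROI's laterality.

    Each covariate is ``mean + a * z + noise`` where ``z`` is the anchor
    laterality standardized within group (so the coupling coefficient ``a``
    is in clinical units per laterality SD and the implied correlation is
    ``a / sqrt(a^2 + noise_sd^2)``).  Embolic counts exist only for the RLS
    group: a latent ``a_embolic * z + N(0,1)`` variable is cut at its own
    quantiles to honour the configured grade proportions, then a count is
    drawn uniformly inside the grade's range.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    if anchor_laterality is None:
        anchor_laterality = _anchor_laterality(subjects, spec)
    lat = np.array([anchor_laterality[ts.subject_id] for ts in subjects])
    groups = np.array([ts.group for ts in subjects])
    z = np.zeros(len(subjects))
    for g in GROUPS:
        m = groups == g
        if m.any():
            sd = lat[m].std()
            z[m] = (lat[m] - lat[m].mean()) / sd if sd > 0 else 0.0

    mu_dur, mu_vas, mu_freq = spec.clinical_means
    sd_dur, sd_vas, sd_freq = spec.clinical_noise_sd
    records = []
    props = np.asarray(spec.grade_proportions, dtype=float)
    # latent quantile cuts reproducing the marginal grade proportions
    latent_sd = float(np.hypot(spec.a_embolic, 1.0))
    from scipy.stats import norm

    cut1, cut2 = norm.ppf(np.cumsum(props)[:2], scale=latent_sd)
    for ts, zi in zip(subjects, z):
        dur = mu_dur + spec.a_duration * zi + rng.normal(0, sd_dur)
        vas = mu_vas + spec.a_vas * zi + rng.normal(0, sd_vas)
        freq = mu_freq + spec.a_freq * zi + rng.normal(0, sd_freq)
        emb = None
        if ts.group == "RLS":
            latent = spec.a_embolic * zi + rng.normal(0, 1.0)
            grade = "minimal" if latent <= cut1 else ("moderate" if latent <= cut2 else "large")
            lo, hi = _GRADE_RANGES[grade]
            emb = int(rng.integers(lo, hi + 1))
        records.append(
            ClinicalRecord(
                subject_id=ts.subject_id,
                group=ts.group,
                duration_years=max(0.0, dur),
                attacks_per_month=max(0.0, freq),
                vas=float(np.clip(vas, 0.0, 10.0)),
                embolic_count=emb,
            )
        )
    return records
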