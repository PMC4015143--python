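"""Gold-standard normalization and imputation for test beta matrices.

Array methylation data shift between batches and platforms, so before
prediction each test sample is mapped onto the training cohort's beta
distribution.  The "gold standard" records, from the training data, the
per-probe mean beta and the pooled sorted quantiles over the probe set of
interest (typically the clock CpGs).  Normalization is per-sample empirical
quantile mapping onto those reference quantiles; imputation replaces missing
entries by the gold-standard probe mean.  The normalization order is:
normalize first, impute second, so imputed values are already on the
reference scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix

__all__ = [
    "GoldStandard",
    "build_gold_standard",
    "normalize_to_gold_standard",
    "impute_missing",
]

MIN_SHARED_PROBES = 30


@dataclass
class GoldStandard:
    """Training-cohort reference: per-probe mean betas + pooled quantiles."""

    probe_means: pd.Series           # probe_id -> mean beta over training samples
    reference_quantiles: np.ndarray  # sorted pooled betas of the probe set
    dropped_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.probe_means.to_numpy(float)
        if np.any((m < 0) | (m > 1)):
            raise ValueError("gold-standard means must lie in [0,1]")
        q = np.asarray(self.reference_quantiles, float)
        if np.any(np.diff(q) < 0):
            raise ValueError("reference quantiles must be non-decreasing")
        self.reference_quantiles = q


def build_gold_standard(betas: BetaMatrix) -> GoldStandard:
    """Summarize a training beta matrix into a :class:`GoldStandard`.

    Probes with no observed values are dropped (recorded in
    ``dropped_probes``).  Requires at least two samples.
    """
    if betas.n_samples < 2:
        raise ValueError("gold standard requires >= 2 training samples")
    means = betas.values.mean(axis=1, skipna=True)
    dropped = list(means.index[means.isna()])
    means = means.dropna()
    if means.empty:
        raise ValueError("no probe has any observed value")
    pooled = betas.values.loc[means.index].to_numpy(float).ravel()
    pooled = np.sort(pooled[~np.isnan(pooled)])
    return GoldStandard(probe_means=means, reference_quantiles=pooled,
                        dropped_probes=dropped)


def normalize_to_gold_standard(
    betas: BetaMatrix, std: GoldStandard
) -> tuple[BetaMatrix, list[str]]:
    """Quantile-map each sample's betas onto the gold-standard distribution.

    For each sample the non-missing values over probes shared with the
    standard are ranked and replaced by linear interpolation into the
    reference quantile vector at matching plotting positions.  Rank order
    within a sample is preserved exactly; missing entries stay missing;
    probes outside the standard pass through unchanged.

    Returns the normalized matrix and the ids of samples skipped because
    they share fewer than 30 probes with the standard.
    """
    shared = betas.values.index.intersection(std.probe_means.index)
    out = betas.values.copy()
    ref = std.reference_quantiles
    ref_pos = np.linspace(0.0, 1.0, len(ref))
    failed: list[str] = []
    for sid in out.columns:
        col = out.loc[shared, sid].to_numpy(float)
        obs = ~np.isnan(col)
        n = int(obs.sum())
        if n < MIN_SHARED_PROBES:
            failed.append(sid)
            continue
        vals = col[obs]
        # average ranks so tied values map to a common reference value
        ranks = pd.Series(vals).rank(method="average").to_numpy() - 1.0
        pos = ranks / (n - 1) if n > 1 else np.full(n, 0.5)
        mapped = np.interp(pos, ref_pos, ref)
        col[obs] = np.clip(mapped, 0.0, 1.0)
        out.loc[shared, sid] = col
    return BetaMatrix(out), failed


def impute_missing(
    betas: BetaMatrix, std: GoldStandard
) -> tuple[BetaMatrix, pd.Series, list[str]]:
    """Replace missing betas with the gold-standard probe mean.

    Observed values are never altered.  Returns the imputed matrix, a
    per-sample count of imputed cells, and the probes that stayed missing
    because the standard does not cover them.
    """
    out = betas.values.copy()
    counts = pd.Series(0, index=out.columns, dtype=int)
    uncovered: list[str] = []
    isna = out.isna()
    for probe in out.index[isna.any(axis=1)]:
        if probe not in std.probe_means.index:
            uncovered.append(probe)
            continue
        mask = isna.loc[probe]
        out.loc[probe, mask] = float(std.probe_means.loc[probe])
        counts[mask.index[mask]] += 1
    return BetaMatrix(out), counts, uncovered
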