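"""Evaluation and downstream statistics for the methylation clock.

Covers the three accuracy measures (age correlation, median absolute error,
average age acceleration), leave-one-dataset-out cross-validation, Falconer
twin heritability of age acceleration, the biweight midcorrelation, a
Stouffer meta-analysis of within-dataset age correlations, per-probe tissue
F statistics, Fisher-exact category enrichment, and the coefficient of
variation.  Sample standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clock_model import (
    ClockModel,
    compute_age_acceleration,
    fit_clock,
    predict_dnam_age,
)
from .io_formats import BetaMatrix, SampleTable

__all__ = [
    "AccuracyReport",
    "HeritabilityEstimate",
    "MetaResult",
    "EnrichmentResult",
    "accuracy_report",
    "loocv_by_dataset",
    "falconer_heritability",
    "marginal_probe_summary",
    "biweight_midcorrelation",
    "meta_analysis_age_correlation",
    "tissue_f_statistics",
    "category_enrichment",
    "coefficient_of_variation",
]


@dataclass
class AccuracyReport:
    """The three headline accuracy measures for an age predictor.

    age_correlation: Pearson r between DNAm age and chronological age
    (NaN when undefined, e.g. constant ages).  median_error: median of
    |dnam_age - age| in years.  average_age_acceleration: mean of
    (dnam_age - age) in years.
    """

    age_correlation: float
    median_error: float
    average_age_acceleration: float
    n: int


@dataclass
class HeritabilityEstimate:
    """Falconer broad-sense heritability from twin correlations.

    h2 = 2 * (cor(MZ) - cor(DZ)), clamped to [0, 1].
    """

    cor_mz: float
    cor_dz: float
    h2: float
    n_mz: int
    n_dz: int
    n_excluded: int = 0


@dataclass
class MetaResult:
    """Per-probe meta-analysis of age correlations, conditioned on dataset.

    ``table`` is indexed by probe with columns ``combined_z``,
    ``signed_log10_p`` (positive = hypermethylates with age) and one
    ``r_<dataset>`` column per dataset.
    """

    table: pd.DataFrame
    dataset_sizes: dict[str, int] = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    """2x2 Fisher-exact enrichment of a probe set in one annotation category."""

    category: str
    a: int  # selected & in category
    b: int  # selected & not in category
    c: int  # not selected & in category
    d: int  # not selected & not in category
    odds_ratio: float
    p_value: float


# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def accuracy_report(dnam_ages, ages) -> AccuracyReport:
    """Compute age correlation, median absolute error and mean acceleration.

    Pairs with a missing value on either side are dropped.  Correlation is
    reported as NaN (not 0) when fewer than two pairs remain or either
    vector is constant.
    """
    d = np.asarray(dnam_ages, dtype=float)
    a = np.asarray(ages, dtype=float)
    if d.shape != a.shape:
        raise ValueError("dnam_ages and ages must have equal length")
    ok = ~(np.isnan(d) | np.isnan(a))
    d, a = d[ok], a[ok]
    if len(d) < 1:
        raise ValueError("no complete (dnam_age, age) pair")
    diff = d - a
    return AccuracyReport(
        age_correlation=_pearson(d, a),
        median_error=float(np.median(np.abs(diff))),
        average_age_acceleration=float(np.mean(diff)),
        n=int(len(d)),
    )


def loocv_by_dataset(
    betas: BetaMatrix,
    samples: SampleTable,
    **fit_kwargs,
) -> tuple[dict[str, AccuracyReport], pd.DataFrame, dict[str, ClockModel]]:
    """Leave-one-dataset-out cross-validation of the clock.

    For every dataset D the clock is trained on all samples *not* in D and
    evaluated on D, so each dataset's accuracy is unbiased by its own
    samples.  Returns per-dataset reports, a summary table (n, age SD,
    LOOCV r, LOOCV error, average acceleration), and the per-fold models.
    """
    meta = samples.data
    if "dataset_id" not in meta.columns:
        raise ValueError("loocv_by_dataset requires a dataset_id column")
    ds_ids = sorted(meta["dataset_id"].dropna().astype(str).unique())
    if len(ds_ids) < 2:
        raise ValueError("need >= 2 distinct dataset_ids")
    reports: dict[str, AccuracyReport] = {}
    models: dict[str, ClockModel] = {}
    rows = []
    for ds in ds_ids:
        held = meta.index[meta["dataset_id"].astype(str) == ds]
        train_ids = meta.index.difference(held)
        train_samples = SampleTable(meta.loc[train_ids])
        train_betas = BetaMatrix(betas.values[ [s for s in betas.sample_ids if s in set(train_ids)] ])
        model = fit_clock(train_betas, train_samples, **fit_kwargs)
        test_betas = BetaMatrix(betas.values[[s for s in betas.sample_ids if s in set(held)]])
        pred = predict_dnam_age(model, test_betas)
        ages = meta.loc[pred.table.index, "age"]
        rep = accuracy_report(pred.table["dnam_age"].to_numpy(), ages.to_numpy(float))
        reports[ds] = rep
        models[ds] = model
        rows.append(
            {
                "dataset_id": ds,
                "n": rep.n,
                "age_sd": float(ages.std(ddof=1)) if rep.n > 1 else float("nan"),
                "loocv_r": rep.age_correlation,
                "loocv_error": rep.median_error,
                "avg_acceleration": rep.average_age_acceleration,
            }
        )
    summary = pd.DataFrame(rows).set_index("dataset_id")
    return reports, summary, models


def falconer_heritability(
    pairs: pd.DataFrame,
    seed: int = 0,
    average_orderings: bool = True,
) -> HeritabilityEstimate:
    """Broad-sense heritability of a per-twin trait via Falconer's formula.

    ``pairs`` needs columns ``pair_id``, ``zygosity`` ("MZ"/"DZ") and
    ``acceleration`` (one row per twin, two rows per pair).  Within each
    zygosity group the trait of twin 1 is correlated against twin 2 and
    h2 = 2 * (rMZ - rDZ), clamped to [0, 1].

    Which twin of a pair is "first" is arbitrary; by default each pair is
    entered in both orderings (a symmetrized, deterministic correlation).
    With ``average_orderings=False`` a single random ordering drawn with
    ``seed`` is used, mimicking a scatter plot of randomly chosen first
    twins.
    """
    required = {"pair_id", "zygosity", "acceleration"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    usable = pairs.dropna(subset=["pair_id", "zygosity", "acceleration"])
    n_excluded = len(pairs) - len(usable)
    rng = np.random.default_rng(seed)

    def zyg_corr(zyg: str) -> tuple[float, int]:
        grp = usable[usable["zygosity"] == zyg]
        t1, t2 = [], []
        for _, twins in grp.groupby("pair_id", sort=True):
            if len(twins) != 2:
                continue
            vals = twins["acceleration"].to_numpy(float)
            if not average_orderings and rng.random() < 0.5:
                vals = vals[::-1]
            t1.append(vals[0])
            t2.append(vals[1])
        n = len(t1)
        if n < 3:
            raise ValueError(f"need >= 3 complete {zyg} pairs, got {n}")
        x, y = np.asarray(t1), np.asarray(t2)
        if average_orderings:
            r = _pearson(np.concatenate([x, y]), np.concatenate([y, x]))
        else:
            r = _pearson(x, y)
        return r, n

    cor_mz, n_mz = zyg_corr("MZ")
    cor_dz, n_dz = zyg_corr("DZ")
    h2 = float(np.clip(2.0 * (cor_mz - cor_dz), 0.0, 1.0))
    return HeritabilityEstimate(
        cor_mz=cor_mz, cor_dz=cor_dz, h2=h2,
        n_mz=n_mz, n_dz=n_dz, n_excluded=n_excluded,
    )


def biweight_midcorrelation(x, y) -> float:
    """Robust correlation that down-weights points beyond 9 MADs.

    u_i = (x_i - med(x)) / (9 * MAD(x)); weight w_i = (1 - u_i^2)^2 for
    |u_i| < 1, else 0 (analogously for y); the statistic is the normalized
    weighted cross-product of the deviations from the medians.  If a vector
    has zero MAD its weights are degenerate and that side falls back to
    plain mean/SD standardization (Pearson-style) — the statistic is then a
    hybrid.  Returns NaN if all weights vanish.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("biweight midcorrelation needs >= 3 complete pairs")

    def deviations(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            # degenerate spread: fall back to mean-centered, unit weights
            return v - np.mean(v)
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u * u) ** 2 * (np.abs(u) < 1.0)
        return (v - med) * w

    dx = deviations(x)
    dy = deviations(y)
    nx = np.sqrt(np.sum(dx * dx))
    ny = np.sqrt(np.sum(dy * dy))
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.sum(dx * dy) / (nx * ny))


def meta_analysis_age_correlation(
    betas: BetaMatrix,
    samples: SampleTable,
    min_per_dataset: int = 5,
) -> MetaResult:
    """Stouffer meta-analysis of per-probe age correlations across datasets.

    Confounding by dataset and tissue is removed by computing each probe's
    Pearson correlation with age strictly within dataset, Fisher-z
    transforming, and Stouffer-combining.  Each dataset's standard-normal
    statistic is sqrt(n_k - 3) * z_k, weighted by sqrt(n_k - 3), giving

        Z = sum_k (n_k - 3) * z_k / sqrt(sum_k (n_k - 3))

    which is standard normal under the null.

    The two-sided normal p-value is reported as a signed log10: positive
    when the probe hypermethylates with age (Z > 0).  A dataset is used for
    a probe only where the probe is observed in >= ``min_per_dataset``
    samples with age.
    """
    meta = samples.data
    if "dataset_id" not in meta.columns:
        raise ValueError("meta-analysis requires a dataset_id column")
    shared = [s for s in betas.sample_ids if s in meta.index]
    aged = meta.loc[shared][meta.loc[shared, "age"].notna()]
    groups = {
        str(ds): list(idx)
        for ds, idx in aged.groupby(aged["dataset_id"].astype(str)).groups.items()
    }
    groups = {ds: ids for ds, ids in groups.items() if len(ids) >= min_per_dataset}
    if len(groups) < 1:
        raise ValueError("no dataset with enough aged samples")

    probes = betas.values.index
    num = np.zeros(len(probes))
    den = np.zeros(len(probes))
    cols = {}
    for ds, ids in sorted(groups.items()):
        sub = betas.values[ids].to_numpy(float)
        age = aged.loc[ids, "age"].to_numpy(float)
        r = np.full(len(probes), np.nan)
        for i in range(len(probes)):
            row = sub[i]
            ok = ~np.isnan(row)
            n_k = int(ok.sum())
            if n_k < min_per_dataset or np.ptp(row[ok]) == 0 or np.ptp(age[ok]) == 0:
                continue
            r_i = np.corrcoef(row[ok], age[ok])[0, 1]
            r[i] = r_i
            z = np.arctanh(np.clip(r_i, -1 + 1e-15, 1 - 1e-15))
            w = n_k - 3
            if w > 0:
                num[i] += w * z
                den[i] += w
        cols[f"r_{ds}"] = r

    with np.errstate(invalid="ignore", divide="ignore"):
        combined_z = np.where(den > 0, num / np.sqrt(np.maximum(den, 1e-300)), np.nan)
    log10_p = _two_sided_log10_p(combined_z)
    signed = np.sign(combined_z) * np.abs(log10_p)
    table = pd.DataFrame(
        {"combined_z": combined_z, "signed_log10_p": signed, **cols},
        index=probes,
    )
    return MetaResult(table=table, dataset_sizes={ds: len(ids) for ds, ids in groups.items()})


def _two_sided_log10_p(z: np.ndarray) -> np.ndarray:
    """-log10 of the two-sided normal p-value, stable far in the tail."""
    with np.errstate(invalid="ignore"):
        logp = sps.norm.logsf(np.abs(z)) + np.log(2.0)
    return -logp / np.log(10.0)


def tissue_f_statistics(betas: BetaMatrix, samples: SampleTable) -> pd.Series:
    """Per-probe ANOVA F statistic for tissue after adjusting for age.

    Each probe's betas are regressed on age plus tissue indicators; the F
    statistic compares that model against the age-only model
    (extra-sum-of-squares test).  No p-value is attached — across a large
    methylome most probes carry some tissue effect, so the raw F is the
    informative quantity.  Probes with a rank-deficient or undersized
    design get NaN.
    """
    meta = samples.data
    if "tissue" not in meta.columns:
        raise ValueError("tissue_f_statistics requires a tissue column")
    shared = [s for s in betas.sample_ids if s in meta.index]
    sub = meta.loc[shared]
    sub = sub[sub["age"].notna() & sub["tissue"].notna()]
    tissues = sorted(sub["tissue"].astype(str).unique())
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissue labels")
    age = sub["age"].to_numpy(float)
    tiss = pd.get_dummies(sub["tissue"].astype(str), drop_first=True).to_numpy(float)
    n = len(sub)
    X_full = np.column_stack([np.ones(n), age, tiss])
    X_red = np.column_stack([np.ones(n), age])
    p_full, p_red = X_full.shape[1], X_red.shape[1]
    if n - p_full < 2:
        raise ValueError("need at least 2 more samples than model parameters")
    mat = betas.values[list(sub.index)].to_numpy(float)

    Q_full, _ = np.linalg.qr(X_full)
    Q_red, _ = np.linalg.qr(X_red)
    rank_full = np.linalg.matrix_rank(X_full)
    out = np.full(betas.n_probes, np.nan)
    df1 = p_full - p_red
    df2 = n - p_full
    for i in range(betas.n_probes):
        y = mat[i]
        ok = ~np.isnan(y)
        if ok.all():
            rss_full = float(np.sum((y - Q_full @ (Q_full.T @ y)) ** 2))
            rss_red = float(np.sum((y - Q_red @ (Q_red.T @ y)) ** 2))
            d1, d2 = df1, df2
            rank_ok = rank_full == p_full
        else:
            Xf, Xr, yy = X_full[ok], X_red[ok], y[ok]
            if len(yy) - p_full < 2:
                continue
            rank_ok = np.linalg.matrix_rank(Xf) == p_full
            if rank_ok:
                bf, rss_f, *_ = np.linalg.lstsq(Xf, yy, rcond=None)
                br, rss_r, *_ = np.linalg.lstsq(Xr, yy, rcond=None)
                rss_full = float(np.sum((yy - Xf @ bf) ** 2))
                rss_red = float(np.sum((yy - Xr @ br) ** 2))
                d1, d2 = df1, len(yy) - p_full
        if not rank_ok:
            continue
        if rss_full <= 0:
            out[i] = np.inf if rss_red > rss_full else 0.0
            continue
        out[i] = ((rss_red - rss_full) / d1) / (rss_full / d2)
    return pd.Series(out, index=betas.values.index, name="F_tissue")


def category_enrichment(
    selected: set[str],
    categories: pd.Series | dict,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Fisher-exact enrichment of a probe set in annotation categories.

    ``categories`` maps probe id -> category label (probes outside the map
    count as unannotated for every category).  For each label a 2x2 table
    (selected / not x in-category / not, within ``universe``) is tested with
    the two-sided Fisher exact test.  To test hyper- and hypomethylating
    clock CpGs separately, call once per direction subset.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected probes must be a subset of the universe")
    cat = pd.Series(categories)
    cat = cat[cat.index.isin(universe)]
    results = []
    for label in sorted(cat.dropna().unique()):
        in_cat = set(cat.index[cat == label])
        a = len(selected & in_cat)
        b = len(selected) - a
        c = len(in_cat) - a
        d = len(universe) - a - b - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(
            EnrichmentResult(
                category=str(label), a=a, b=b, c=c, d=d,
                odds_ratio=float(odds), p_value=float(p),
            )
        )
    return results


def marginal_probe_summary(
    betas: BetaMatrix,
    samples: SampleTable,
    young_max: float = 35.0,
    old_min: float = 55.0,
) -> pd.DataFrame:
    """Per-probe marginal age-effect summary.

    For each probe: median beta among subjects younger than ``young_max``,
    median beta among subjects older than ``old_min``, their absolute
    difference (the marginal effect size of aging on that CpG), plus
    variance, min and max across all aged samples.  Matches the per-CpG
    columns a published clock coefficient table carries.
    """
    meta = samples.data
    shared = [s for s in betas.sample_ids if s in meta.index]
    ages = meta.loc[shared, "age"]
    young = [s for s in shared if ages[s] < young_max]
    old = [s for s in shared if ages[s] > old_min]
    if not young or not old:
        raise ValueError("need samples on both sides of the young/old cut")
    v = betas.values
    out = pd.DataFrame(
        {
            "medianByCpGYoung": v[young].median(axis=1),
            "medianByCpGOld": v[old].median(axis=1),
            "varByCpG": v[shared].var(axis=1, ddof=1),
            "minByCpG": v[shared].min(axis=1),
            "maxByCpG": v[shared].max(axis=1),
        }
    )
    out["absAgeEffect"] = (out["medianByCpGOld"] - out["medianByCpGYoung"]).abs()
    return out


def coefficient_of_variation(values) -> float:
    """Sample SD divided by the mean; requires >= 2 values and mean > 0."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("coefficient of variation needs >= 2 values")
    m = float(np.mean(v))
    if m <= 0:
        raise ValueError(f"coefficient of variation undefined for mean {m}")
    return float(np.std(v, ddof=1) / m)
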