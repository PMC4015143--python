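"""Synthetic methylome cohorts with clock-like age structure, plus ground truth.

The generator emulates Illumina 27K/450K-style beta matrices in which a
subset of "causal" CpGs drift with age.  The true age signal is linear on
the calibrated age scale (fast change during development, steady in
adulthood), so a clock trained on these data must implicitly recover the
calibration transform.  Effect sizes are parameterized the way marginal
age effects are usually summarized for clock CpGs: the expected absolute
difference between median betas in old (>55 y) versus young (<35 y)
subjects, 0.032 by default.  Datasets and tissues add Gaussian offsets;
measurement noise is Gaussian on the beta scale; betas are clamped to
[0, 1] after noise.

A separate generator produces twin cohorts with a prescribed broad-sense
heritability of age acceleration (MZ co-twins share the full genetic part,
DZ co-twins share it with correlation 0.5), for exercising Falconer's
formula.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationSpec, transform_age
from .io_formats import BetaMatrix, SampleTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_methylome",
    "simulate_twin_cohort",
    "twin_pairs_with_exact_correlations",
]

#: direction split of clock CpGs: fraction that hypermethylate with age
DEFAULT_FRAC_POSITIVE = 193 / 353
#: target mean |median beta old - median beta young| across causal CpGs
DEFAULT_EFFECT_SIZE = 0.032
YOUNG_MAX = 35.0
OLD_MIN = 55.0


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for :func:`simulate_methylome`.

    The default scenario — 400 samples, 2,000 probes, 150 causal CpGs,
    ages uniform on [0, 101] years, beta noise SD 0.02, effect size 0.032 —
    is deliberately small enough to train on in seconds while keeping the
    age signal per CpG weak, as it is on real arrays.
    """

    n_samples: int = 400
    n_probes: int = 2000
    n_causal: int = 150
    frac_positive: float = DEFAULT_FRAC_POSITIVE
    age_min: float = 0.0
    age_max: float = 101.0
    effect_size: float = DEFAULT_EFFECT_SIZE
    noise_sd: float = 0.02
    n_datasets: int = 1
    dataset_offset_sd: float = 0.0
    tissues: tuple[str, ...] = ("blood",)
    tissue_offset_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    #: seed for probe-level biology (causal set, signs, amplitudes,
    #: baselines).  Defaults to ``seed``.  Give two cohorts the same
    #: probe_seed and different seeds to get independent samples measured
    #: on the same underlying CpGs — e.g. a train/test split.
    probe_seed: int | None = None
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_probes:
            raise ValueError("n_causal cannot exceed n_probes")
        if not 0.0 <= self.frac_positive <= 1.0:
            raise ValueError("frac_positive must be in [0, 1]")
        for name in ("noise_sd", "dataset_offset_sd", "tissue_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.age_min < 0 or self.age_max <= self.age_min:
            raise ValueError("need 0 <= age_min < age_max")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort."""

    ages: pd.Series                      # sample_id -> true age (years)
    causal_probes: pd.Series             # probe_id -> sign (+1 / -1)
    baselines: pd.Series                 # probe_id -> baseline beta
    amplitudes: pd.Series                # causal probe_id -> full-range beta change
    dataset_offsets: dict[str, float] = field(default_factory=dict)
    tissue_offsets: dict[str, float] = field(default_factory=dict)


def _mean_transformed_age(lo: float, hi: float, spec: CalibrationSpec, n_grid: int = 4001) -> float:
    """E[F(age)] for age uniform on [lo, hi], by dense trapezoid quadrature."""
    grid = np.linspace(lo, hi, n_grid)
    return float(np.trapezoid(transform_age(grid, spec), grid) / (hi - lo))


def _effect_scale(cfg: SimConfig, spec: CalibrationSpec) -> float:
    """Convert the old-vs-young effect size into a full-range amplitude.

    The causal signal for probe i is s_i * a_i * (F(age) - F_min) / range(F);
    the expected old-young median beta gap is then a_i * dF where dF is the
    normalized gap between mean transformed ages of the old (>55) and young
    (<35) strata.  Scaling amplitudes by 1/dF makes the configured
    ``effect_size`` land on the old-young gap rather than the full range.
    """
    f_lo = transform_age(cfg.age_min, spec)
    f_hi = transform_age(cfg.age_max, spec)
    f_range = f_hi - f_lo
    young_hi = min(YOUNG_MAX, cfg.age_max)
    old_lo = max(OLD_MIN, cfg.age_min)
    if young_hi <= cfg.age_min or old_lo >= cfg.age_max or old_lo <= young_hi:
        return 1.0  # degenerate age range: use amplitudes as given
    f_young = _mean_transformed_age(cfg.age_min, young_hi, spec)
    f_old = _mean_transformed_age(old_lo, cfg.age_max, spec)
    d_f = (f_old - f_young) / f_range
    return 1.0 / d_f


def simulate_methylome(cfg: SimConfig) -> tuple[BetaMatrix, SampleTable, SimTruth]:
    """Generate one cohort: beta matrix, sample annotation, ground truth.

    Causal probe i, sample j:

        beta_ij = clamp(b_i + s_i * a_i * (F(age_j) - F_min)/range(F)
                        + dataset_offset + tissue_offset + noise, 0, 1)

    with sign s_i in {+1, -1}, baseline b_i placed so the trajectory stays
    inside [0, 1], and F the calibration transform.  Non-causal probes are
    baseline + offsets + noise.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rng_probes = np.random.default_rng(
        cfg.seed if cfg.probe_seed is None else cfg.probe_seed
    )
    spec = CalibrationSpec(adult_age=cfg.adult_age)

    sample_ids = [f"S{j:04d}" for j in range(cfg.n_samples)]
    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    ages = rng.uniform(cfg.age_min, cfg.age_max, cfg.n_samples)

    f = transform_age(ages, spec)
    f_lo = transform_age(cfg.age_min, spec)
    f_hi = transform_age(cfg.age_max, spec)
    f_norm = (f - f_lo) / (f_hi - f_lo)  # in [0, 1]

    causal_idx = rng_probes.choice(cfg.n_probes, size=cfg.n_causal, replace=False)
    n_pos = int(round(cfg.frac_positive * cfg.n_causal))
    signs = np.full(cfg.n_causal, -1.0)
    signs[:n_pos] = 1.0
    rng_probes.shuffle(signs)

    # per-probe amplitude: spread around the configured effect size, then
    # rescaled so the old-vs-young gap (not the full range) hits the target
    raw = cfg.effect_size * rng_probes.uniform(0.5, 1.5, cfg.n_causal)
    amplitudes = raw * _effect_scale(cfg, spec)

    baselines = rng_probes.uniform(0.15, 0.85, cfg.n_probes)
    # keep causal trajectories inside [0,1] before noise
    for k, i in enumerate(causal_idx):
        a = amplitudes[k]
        if signs[k] > 0:
            baselines[i] = min(baselines[i], 1.0 - a - 0.02)
        else:
            baselines[i] = max(baselines[i], a + 0.02)

    values = np.tile(baselines[:, None], (1, cfg.n_samples))
    values[causal_idx] += (signs * amplitudes)[:, None] * f_norm[None, :]

    ds_labels = [f"D{k:02d}" for k in range(cfg.n_datasets)]
    sample_ds = np.array(ds_labels)[rng.integers(0, cfg.n_datasets, cfg.n_samples)]
    ds_offsets = {d: float(rng.normal(0.0, cfg.dataset_offset_sd)) for d in ds_labels}
    sample_tissue = np.array(cfg.tissues)[rng.integers(0, len(cfg.tissues), cfg.n_samples)]
    tis_offsets = {t: float(rng.normal(0.0, cfg.tissue_offset_sd)) for t in cfg.tissues}

    values += np.array([ds_offsets[d] for d in sample_ds])[None, :]
    values += np.array([tis_offsets[t] for t in sample_tissue])[None, :]
    values += rng.normal(0.0, cfg.noise_sd, values.shape)
    values = np.clip(values, 0.0, 1.0)

    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan

    betas = BetaMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=pd.Index(sample_ids, name="sample_id"))
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "age": ages,
                "tissue": sample_tissue,
                "dataset_id": sample_ds,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SimTruth(
        ages=pd.Series(ages, index=sample_ids, name="age"),
        causal_probes=pd.Series(signs, index=[probe_ids[i] for i in causal_idx],
                                name="sign"),
        baselines=pd.Series(baselines, index=probe_ids, name="baseline"),
        amplitudes=pd.Series(amplitudes, index=[probe_ids[i] for i in causal_idx],
                             name="amplitude"),
        dataset_offsets=ds_offsets,
        tissue_offsets=tis_offsets,
    )
    return betas, samples, truth


def simulate_train_test(
    cfg: SimConfig, n_test: int = 100
) -> tuple[
    tuple[BetaMatrix, SampleTable, SimTruth],
    tuple[BetaMatrix, SampleTable, SimTruth],
]:
    """A train/test cohort pair sharing the same probe-level biology.

    The test cohort draws fresh samples (ages, offsets, noise) from a seed
    offset from the training seed, while reusing the training cohort's
    probe seed, so a clock fitted on the first cohort is meaningfully
    evaluable on the second.  Test sample ids are prefixed ``T``.
    """
    probe_seed = cfg.seed if cfg.probe_seed is None else cfg.probe_seed
    train = simulate_methylome(dataclasses.replace(cfg, probe_seed=probe_seed))
    test_cfg = dataclasses.replace(
        cfg, n_samples=n_test, seed=cfg.seed + 100_003, probe_seed=probe_seed
    )
    tb, ts, tt = simulate_methylome(test_cfg)
    rename = {s: "T" + s for s in tb.sample_ids}
    tb = BetaMatrix(tb.values.rename(columns=rename))
    ts = SampleTable(ts.data.rename(index=rename))
    tt.ages = tt.ages.rename(index=rename)
    return train, (tb, ts, tt)


def simulate_twin_cohort(
    n_mz: int,
    n_dz: int,
    h2: float,
    total_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Twin pairs with age-acceleration values of prescribed heritability.

    Each twin's acceleration is g + e with var(g) = h2 * total_sd^2 and
    var(e) = (1 - h2) * total_sd^2.  MZ co-twins share g entirely; DZ
    co-twins' g values correlate 0.5 (additive-genetic expectation), so
    E[2 * (rMZ - rDZ)] = h2.  Returns one row per twin with columns
    ``pair_id``, ``zygosity``, ``acceleration``.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    if n_mz < 1 or n_dz < 1:
        raise ValueError("need at least one pair of each zygosity")
    rng = np.random.default_rng(seed)
    sd_g = total_sd * np.sqrt(h2)
    sd_e = total_sd * np.sqrt(1.0 - h2)
    rows = []
    for p in range(n_mz):
        g = rng.normal(0, sd_g)
        for t in range(2):
            rows.append(("MZ%04d" % p, "MZ", g + rng.normal(0, sd_e)))
    for p in range(n_dz):
        shared = rng.normal(0, sd_g * np.sqrt(0.5))
        for t in range(2):
            g = shared + rng.normal(0, sd_g * np.sqrt(0.5))
            rows.append(("DZ%04d" % p, "DZ", g + rng.normal(0, sd_e)))
    return pd.DataFrame(rows, columns=["pair_id", "zygosity", "acceleration"])


def twin_pairs_with_exact_correlations(
    r_mz: float,
    r_dz: float,
    n_pairs: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Construct twin-pair values whose within-zygosity correlations are exact.

    For each zygosity a pair-value matrix (x, y) is built with x, y each
    standardized to mean 0 and identical sum of squares and with
    corr(x, y) equal to the requested value to machine precision, so a
    worked example (e.g. published newborn correlations) can be reproduced
    without Monte-Carlo error.  Useful as a fixture for Falconer's formula.
    """
    rng = np.random.default_rng(seed)

    def standardize(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / np.sqrt(np.sum(v * v))

    def block(r: float, zyg: str, offset: int) -> list[tuple[str, str, float]]:
        x = standardize(rng.normal(size=n_pairs))
        z = rng.normal(size=n_pairs)
        z = z - z.mean()
        z = standardize(z - x * np.sum(x * z))  # orthogonal to x
        y = r * x + np.sqrt(1.0 - r * r) * z
        out = []
        for i in range(n_pairs):
            pid = f"{zyg}{offset + i:04d}"
            out.append((pid, zyg, float(x[i])))
            out.append((pid, zyg, float(y[i])))
        return out

    rows = block(r_mz, "MZ", 0) + block(r_dz, "DZ", 0)
    return pd.DataFrame(rows, columns=["pair_id", "zygosity", "acceleration"])
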