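"""Broad-sense heritability of treatment response via one-way ANOVA.

The phenotype (per-mouse RTC, rank-based inverse-normal transformed) is
partitioned into between-strain and within-strain mean squares and
heritability is computed as

    H^2 = MS_strain / (MS_strain + (n_bar - 1) * MS_resid)

with ``n_bar`` the mean per-strain sample size.  Inference is fully
resampling-based: a permutation test shuffles strain labels to build the null
distribution of H^2, and a bootstrap resamples mice (within strain by
default) for percentile confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "HeritabilityEstimate",
    "rankz_normalize",
    "anova_h2",
    "permutation_pvalue",
    "bootstrap_ci",
    "estimate_heritability",
]


@dataclass
class HeritabilityEstimate:
    h2: float
    mse_strain: float
    mse_resid: float
    n_bar: float
    p_perm: float | None = None
    p_is_bound: bool = False  # True: p_perm is the upper bound 1/n_perm
    ci_low: float | None = None
    ci_high: float | None = None
    n_perm: int | None = None
    n_boot: int | None = None
    seed: int | None = None

    @property
    def p_report(self) -> str:
        if self.p_perm is None:
            return "NA"
        return f"< {self.p_perm:g}" if self.p_is_bound else f"{self.p_perm:g}"


def rankz_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((r - 0.5)/n).

    Ties receive averaged ranks and hence equal transformed values; any
    strictly monotone transform of the input yields identical output.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateDataError("rankz_normalize needs at least 2 values")
    if not np.all(np.isfinite(values)):
        raise DegenerateDataError("rankz_normalize requires finite values")
    if np.ptp(values) == 0:
        raise DegenerateDataError("rankz_normalize: all values identical")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def _encode(strain_labels) -> tuple[np.ndarray, np.ndarray]:
    codes, counts = None, None
    _, codes = np.unique(np.asarray(strain_labels), return_inverse=True)
    counts = np.bincount(codes).astype(float)
    return codes, counts


def anova_h2(values: np.ndarray, strain_labels) -> HeritabilityEstimate:
    """Point estimate of broad-sense heritability from one-way ANOVA.

    Requires >= 2 strains and at least one strain with >= 2 observations.
    ``MS_resid = 0`` with distinct strain means yields H^2 = 1 exactly.
    """
    values = np.asarray(values, dtype=float)
    codes, counts = _encode(strain_labels)
    k = counts.size
    n = values.size
    if k < 2:
        raise DegenerateDataError("anova_h2 needs >= 2 strains")
    if n - k < 1:
        raise DegenerateDataError("anova_h2 needs a strain with >= 2 mice")
    ss_total = float(((values - values.mean()) ** 2).sum())
    if ss_total == 0:
        raise DegenerateDataError("anova_h2: zero total variance")
    group_sums = np.bincount(codes, weights=values, minlength=k)
    ss_between = float((group_sums**2 / counts).sum() - n * values.mean() ** 2)
    ss_within = ss_total - ss_between
    mse_strain = ss_between / (k - 1)
    mse_resid = max(ss_within, 0.0) / (n - k)
    n_bar = n / k
    denom = mse_strain + (n_bar - 1.0) * mse_resid
    h2 = mse_strain / denom if denom > 0 else math.nan
    return HeritabilityEstimate(
        h2=float(h2), mse_strain=mse_strain, mse_resid=mse_resid, n_bar=n_bar
    )


def _h2_many(values_matrix: np.ndarray, codes: np.ndarray, counts: np.ndarray
             ) -> np.ndarray:
    """Vectorized H^2 for each row of ``values_matrix`` (same labels)."""
    k = counts.size
    n = codes.size
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    group_sums = values_matrix @ onehot  # (m, k)
    means = values_matrix.mean(axis=1)
    ss_total = (values_matrix**2).sum(axis=1) - n * means**2
    ss_between = (group_sums**2 / counts).sum(axis=1) - n * means**2
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    mse_strain = ss_between / (k - 1)
    mse_resid = ss_within / (n - k)
    n_bar = n / k
    denom = mse_strain + (n_bar - 1.0) * mse_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, mse_strain / denom, np.nan)


def permutation_pvalue(
    values: np.ndarray,
    strain_labels,
    n_perm: int,
    seed: int | np.random.Generator = 0,
) -> tuple[float, bool]:
    """One-sided permutation p for H^2 > chance, shuffling strain labels.

    Returns ``(p, is_bound)``: ``p = #{h2_perm >= h2_obs} / n_perm``; at zero
    exceedances the reported value is the bound ``1/n_perm`` with
    ``is_bound=True`` (printed as e.g. "< 1e-4" at 10000 permutations).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    observed = anova_h2(values, strain_labels).h2
    codes, counts = _encode(strain_labels)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perms = np.array([rng.permutation(values) for _ in range(n_perm)])
    h2_null = _h2_many(perms, codes, counts)
    count = int(np.sum(h2_null >= observed - 1e-12))
    if count == 0:
        return 1.0 / n_perm, True
    return count / n_perm, False


def _one_bootstrap_sample(
    values: np.ndarray,
    blocks: list[np.ndarray],
    rng: np.random.Generator,
    scheme: str,
) -> tuple[np.ndarray, np.ndarray]:
    k = len(blocks)
    n = values.size
    if scheme == "rows":
        codes_all = np.concatenate(
            [np.full(b.size, s) for s, b in enumerate(blocks)]
        )
        order = np.concatenate(blocks)
        take = rng.integers(0, n, size=n)
        return values[order[take]], codes_all[take]
    if scheme == "within_strain":
        vals = [values[b[rng.integers(0, b.size, size=b.size)]] for b in blocks]
        labs = [np.full(b.size, s) for s, b in enumerate(blocks)]
        return np.concatenate(vals), np.concatenate(labs)
    # two_stage: resample strains, then mice within each drawn strain, with
    # within-strain deviations inflated by 1/sqrt(1 - 1/c) to undo the known
    # E[resampled SS] = (1 - 1/c) * SS shrinkage of the inner resample.
    chosen = rng.integers(0, k, size=k)
    vals, labs = [], []
    for newlab, s in enumerate(chosen):
        b = blocks[s]
        x = values[b[rng.integers(0, b.size, size=b.size)]]
        c = b.size
        if c > 1:
            x = x.mean() + (x - x.mean()) / math.sqrt(1.0 - 1.0 / c)
        vals.append(x)
        labs.append(np.full(c, newlab))
    return np.concatenate(vals), np.concatenate(labs)


def bootstrap_ci(
    values: np.ndarray,
    strain_labels,
    n_boot: int,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    scheme: str = "two_stage",
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI for H^2.

    The default ``two_stage`` scheme resamples strains with replacement and
    then mice within each drawn strain, inflating within-strain deviations
    by ``1/sqrt(1 - 1/c)`` (the exact correction for the inner resample's
    variance shrinkage).  This captures both between-strain and
    within-strain sampling variability, which a variance-ratio statistic
    needs for calibrated intervals.  Alternatives: ``within_strain``
    (resample mice within each strain, panel fixed) and ``rows``
    (unstratified row resampling).  Degenerate replicates (zero total
    variance, or fewer than 2 strains after resampling) are redrawn up to
    ``max_retries`` times each.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    if scheme not in ("two_stage", "within_strain", "rows"):
        raise ParameterError(f"unknown bootstrap scheme {scheme!r}")
    values = np.asarray(values, dtype=float)
    codes, counts = _encode(strain_labels)
    order = np.argsort(codes, kind="stable")
    offsets = np.concatenate(([0], np.cumsum(counts.astype(int))))
    blocks = [
        order[offsets[s]: offsets[s + 1]] for s in range(counts.size)
    ]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    reps = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_retries + 1):
            vals, labs = _one_bootstrap_sample(values, blocks, rng, scheme)
            try:
                reps[b] = anova_h2(vals, labs).h2
                break
            except DegenerateDataError:
                continue
        else:
            raise DegenerateDataError(
                "bootstrap retries exhausted on degenerate resamples"
            )
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def estimate_heritability(
    values: np.ndarray,
    strain_labels,
    n_perm: int = 10000,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    rankz: bool = True,
    bootstrap_scheme: str = "two_stage",
) -> HeritabilityEstimate:
    """Full pipeline: rankZ transform, point estimate, permutation p, bootstrap CI."""
    values = np.asarray(values, dtype=float)
    if rankz:
        values = rankz_normalize(values)
    est = anova_h2(values, strain_labels)
    rng = np.random.default_rng(seed)
    est.p_perm, est.p_is_bound = permutation_pvalue(
        values, strain_labels, n_perm, seed=rng
    )
    est.ci_low, est.ci_high = bootstrap_ci(
        values, strain_labels, n_boot, alpha=alpha, seed=rng,
        scheme=bootstrap_scheme,
    )
    est.n_perm, est.n_boot, est.seed = n_perm, n_boot, seed
    return est
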