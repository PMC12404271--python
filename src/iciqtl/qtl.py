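"""Genome scans over founder haplotypes, permutation thresholds, and epistasis.

Two mapping designs are supported:

* **CCF1** — each line's genome is a mosaic of eight founder haplotypes; the
  per-line phenotype (mean log RTC, or the combined response trait) is
  regressed at each marker on the eight founder-dosage columns
  (Haley–Knott-style single-marker regression).  Because the dosage columns
  sum to one, the intercept lies in the model's column space and
  ``LOD = (N/2) * log10(RSS0 / RSS1)`` with RSS0 from the intercept-only
  model is guaranteed nonnegative.

* **CCF1N1** — each mouse carries one of two possible ancestries at every
  locus on the CC-derived side.  Quantitative traits (raw slope, ordinal
  response class) use the same Gaussian LOD with a single binary predictor;
  the binary complete-responder indicator uses a logistic model whose
  single-binary-covariate MLE is available in closed form (the two
  genotype-group response fractions), giving
  ``LOD = LRT / (2 ln 10)`` exactly and finite log-likelihoods even under
  complete separation.

Genome-wide significance is the empirical ``1 - alpha`` quantile of the
maximum LOD across markers under phenotype permutation.  Epistasis between
mapped loci is tested by logistic-regression likelihood-ratio tests of
additive vs interactive models.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateDataError,
    ParameterError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "FounderDosageMatrix",
    "N1GenotypeMatrix",
    "ScanResult",
    "EpistasisResult",
    "ScanModel",
    "scan_founder_additive",
    "scan_binary_marker",
    "permutation_threshold",
    "epistasis_lrt",
    "haplotype_group_compare",
    "rank_sum_test",
]

FOUNDERS = tuple("ABCDEFGH")
LN10 = math.log(10.0)


class ScanModel(str, Enum):
    gaussian_founder = "gaussian_founder"
    gaussian_binary_marker = "gaussian_binary_marker"
    logistic_binary_marker = "logistic_binary_marker"


# ---------------------------------------------------------------------------
# Genotype containers

@dataclass
class MarkerMap:
    """Ordered marker map: ids, chromosome labels and positions in cM."""

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray

    def __post_init__(self):
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        for c in np.unique(self.chrom):
            p = self.pos_cm[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValidationError(
                    f"marker positions on chromosome {c} are not nondecreasing"
                )

    @property
    def n_markers(self) -> int:
        return self.marker_id.size

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_id, "chrom": self.chrom,
             "pos_cM": self.pos_cm}
        )


@dataclass
class FounderDosageMatrix:
    """Lines x markers x 8 founder dosages (each dosage vector sums to 1)."""

    markers: MarkerMap
    line_ids: list[str]
    dosages: np.ndarray  # (n_lines, n_markers, 8)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        expected = (len(self.line_ids), self.markers.n_markers, len(FOUNDERS))
        if self.dosages.shape != expected:
            raise ValidationError(
                f"dosage array shape {self.dosages.shape} != {expected}"
            )
        sums = self.dosages.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValidationError("founder dosage vectors must sum to 1")
        if np.any(self.dosages < 0):
            raise ValidationError("founder dosages must be nonnegative")

    def to_long_frame(self) -> pd.DataFrame:
        n_l, n_m, n_f = self.dosages.shape
        idx = pd.MultiIndex.from_product(
            [range(n_m), range(n_l), range(n_f)],
            names=["m", "l", "f"],
        ).to_frame(index=False)
        return pd.DataFrame(
            {
                "marker_id": self.markers.marker_id[idx["m"]],
                "chrom": self.markers.chrom[idx["m"]],
                "pos_cM": self.markers.pos_cm[idx["m"]],
                "line_id": np.asarray(self.line_ids, dtype=object)[idx["l"]],
                "founder": np.asarray(FOUNDERS, dtype=object)[idx["f"]],
                "dosage": self.dosages[idx["l"], idx["m"], idx["f"]],
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "FounderDosageMatrix":
        required = {"marker_id", "chrom", "pos_cM", "line_id", "founder",
                    "dosage"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(
                f"dosage table missing column(s): {sorted(missing)}"
            )
        mk = df[["marker_id", "chrom", "pos_cM"]].drop_duplicates("marker_id")
        markers = MarkerMap(
            mk["marker_id"].to_numpy(), mk["chrom"].to_numpy(),
            mk["pos_cM"].to_numpy(),
        )
        lines = sorted(df["line_id"].unique())
        m_index = {m: i for i, m in enumerate(markers.marker_id)}
        l_index = {l: i for i, l in enumerate(lines)}
        f_index = {f: i for i, f in enumerate(FOUNDERS)}
        dos = np.zeros((len(lines), markers.n_markers, len(FOUNDERS)))
        dos[
            df["line_id"].map(l_index).to_numpy(),
            df["marker_id"].map(m_index).to_numpy(),
            df["founder"].map(f_index).to_numpy(),
        ] = df["dosage"].to_numpy(dtype=float)
        return cls(markers, [str(l) for l in lines], dos)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FounderDosageMatrix":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


@dataclass
class N1GenotypeMatrix:
    """Mice x markers binary ancestry (which intercross parent transmitted).

    Missing genotypes are NaN and dropped marker-wise during scans.
    """

    markers: MarkerMap
    mouse_ids: list[str]
    genotype: np.ndarray  # (n_mice, n_markers) of {0.0, 1.0, nan}

    def __post_init__(self):
        self.genotype = np.asarray(self.genotype, dtype=float)
        expected = (len(self.mouse_ids), self.markers.n_markers)
        if self.genotype.shape != expected:
            raise ValidationError(
                f"genotype array shape {self.genotype.shape} != {expected}"
            )
        ok = np.isnan(self.genotype) | np.isin(self.genotype, (0.0, 1.0))
        if not ok.all():
            raise ValidationError("N1 genotypes must be 0, 1 or NA")

    def to_long_frame(self) -> pd.DataFrame:
        n_mice, n_m = self.genotype.shape
        idx = pd.MultiIndex.from_product(
            [range(n_m), range(n_mice)], names=["m", "i"]
        ).to_frame(index=False)
        geno = self.genotype[idx["i"], idx["m"]]
        return pd.DataFrame(
            {
                "marker_id": self.markers.marker_id[idx["m"]],
                "chrom": self.markers.chrom[idx["m"]],
                "pos_cM": self.markers.pos_cm[idx["m"]],
                "mouse_id": np.asarray(self.mouse_ids, dtype=object)[idx["i"]],
                "genotype": ["NA" if np.isnan(g) else str(int(g)) for g in geno],
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "N1GenotypeMatrix":
        required = {"marker_id", "chrom", "pos_cM", "mouse_id", "genotype"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(
                f"N1 genotype table missing column(s): {sorted(missing)}"
            )
        mk = df[["marker_id", "chrom", "pos_cM"]].drop_duplicates("marker_id")
        markers = MarkerMap(
            mk["marker_id"].to_numpy(), mk["chrom"].to_numpy(),
            mk["pos_cM"].to_numpy(),
        )
        mice = sorted(df["mouse_id"].unique())
        m_index = {m: i for i, m in enumerate(markers.marker_id)}
        i_index = {m: i for i, m in enumerate(mice)}
        geno = np.full((len(mice), markers.n_markers), np.nan)
        raw = df["genotype"].astype(str).str.strip()
        vals = raw.replace({"NA": "nan", "": "nan"}).astype(float)
        geno[
            df["mouse_id"].map(i_index).to_numpy(),
            df["marker_id"].map(m_index).to_numpy(),
        ] = vals.to_numpy()
        return cls(markers, [str(m) for m in mice], geno)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "N1GenotypeMatrix":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Scan results

@dataclass
class ScanResult:
    trait: str
    model: ScanModel
    markers: MarkerMap
    lod: np.ndarray
    threshold: float | None = None
    n_perm: int | None = None
    alpha: float | None = None
    seed: int | None = None
    separated_markers: list[str] = field(default_factory=list)

    @property
    def peak_index(self) -> int:
        return int(np.nanargmax(self.lod))

    def frame(self) -> pd.DataFrame:
        out = self.markers.frame()
        out["lod"] = self.lod
        return out


@dataclass
class EpistasisResult:
    qtl_ids: tuple
    order: int
    lrt_stat: float
    df: int
    p: float
    converged: bool = True


# ---------------------------------------------------------------------------
# Gaussian scans

def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of x (rank-deficiency-safe, via SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    return u[:, s > tol]


def _gaussian_lod(y: np.ndarray, bases: list[np.ndarray]) -> np.ndarray:
    """LOD = (N/2) log10(RSS0/RSS1) per marker, intercept-only null."""
    n = y.size
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    lod = np.empty(len(bases))
    for m, u in enumerate(bases):
        proj = u.T @ y
        rss1 = max(float(y @ y - proj @ proj), 0.0)
        if rss1 <= rss0 * 1e-15:
            # numerically perfect fit: cap via machine floor
            rss1 = max(rss1, rss0 * 1e-15)
        lod[m] = 0.5 * n * math.log10(rss0 / rss1)
    return np.maximum(lod, 0.0)


def scan_founder_additive(
    phenotype: np.ndarray,
    dosages: FounderDosageMatrix,
    trait: str = "mean_log_rtc",
) -> ScanResult:
    """Single-marker regression of a per-line phenotype on founder dosages.

    No separate intercept is added: the eight dosage columns sum to one, so
    the intercept-only null model is nested in every marker model and LOD is
    nonnegative by construction.  Rank-deficient dosage submatrices (e.g.
    monomorphic markers) are handled through an SVD basis, equivalent to the
    pseudoinverse fit.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.size != len(dosages.line_ids):
        raise ValidationError("phenotype length != number of lines")
    if not np.all(np.isfinite(y)):
        raise ValidationError("phenotype must be finite")
    if np.unique(y).size < 2:
        raise DegenerateDataError("phenotype has < 2 distinct values")
    bases = [
        _orthonormal_basis(dosages.dosages[:, m, :])
        for m in range(dosages.markers.n_markers)
    ]
    lod = _gaussian_lod(y, bases)
    return ScanResult(trait, ScanModel.gaussian_founder, dosages.markers, lod)


# ---------------------------------------------------------------------------
# Binary-marker scans (CCF1N1)

def _binom_ll(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood at the MLE p = k/n, with 0*log(0) = 0."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / n), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(1.0 - k / n), 0.0)
    return t1 + t2


def scan_binary_marker(
    trait: np.ndarray,
    genotypes: N1GenotypeMatrix,
    model: ScanModel = ScanModel.logistic_binary_marker,
    trait_name: str = "cr",
) -> ScanResult:
    """Single-marker scan of a per-mouse trait over binary ancestry.

    ``logistic_binary_marker``: LOD = LRT / (2 ln 10) comparing the
    two-group Bernoulli fit against the pooled intercept-only fit; with one
    binary covariate the group response fractions are the exact logistic MLE,
    so the likelihoods are closed-form and finite even under complete
    separation (separated markers are recorded in the result).
    ``gaussian_binary_marker``: Gaussian LOD with predictor [1, g].
    Missing genotypes are dropped marker-wise.
    """
    y = np.asarray(trait, dtype=float)
    if y.size != len(genotypes.mouse_ids):
        raise ValidationError("trait length != number of mice")
    if np.unique(y[np.isfinite(y)]).size < 2:
        raise DegenerateDataError("trait has < 2 distinct values")
    if model is ScanModel.logistic_binary_marker and not np.all(
        np.isin(y[np.isfinite(y)], (0.0, 1.0))
    ):
        raise ValidationError("logistic model requires a binary 0/1 trait")

    g_all = genotypes.genotype
    n_markers = genotypes.markers.n_markers
    lod = np.zeros(n_markers)
    separated: list[str] = []
    for m in range(n_markers):
        g = g_all[:, m]
        mask = np.isfinite(g) & np.isfinite(y)
        gm, ym = g[mask], y[mask]
        if np.unique(gm).size < 2 or np.unique(ym).size < 2:
            lod[m] = 0.0
            continue
        if model is ScanModel.logistic_binary_marker:
            n1 = float(gm.sum())
            n0 = float(gm.size - n1)
            k1 = float(ym[gm == 1].sum())
            k0 = float(ym[gm == 0].sum())
            ll_full = float(_binom_ll(np.array([k0, k1]),
                                      np.array([n0, n1])).sum())
            ll_null = float(_binom_ll(np.array([k0 + k1]),
                                      np.array([n0 + n1]))[0])
            lrt = max(2.0 * (ll_full - ll_null), 0.0)
            lod[m] = lrt / (2.0 * LN10)
            if k0 in (0.0, n0) or k1 in (0.0, n1):
                separated.append(str(genotypes.markers.marker_id[m]))
        else:
            x = np.column_stack([np.ones(gm.size), gm])
            lod[m] = _gaussian_lod(ym, [_orthonormal_basis(x)])[0]
    return ScanResult(trait_name, model, genotypes.markers, lod,
                      separated_markers=separated)


# ---------------------------------------------------------------------------
# Permutation thresholds

def permutation_threshold(
    scan_fn,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold from phenotype permutations.

    ``scan_fn`` maps a phenotype vector to a LOD array (genotypes closed
    over); the threshold is the empirical ``1 - alpha`` quantile of the
    genome-wide maximum LOD over ``n_perm`` permutations.  Returns the
    threshold and the max-LOD null sample.
    """
    if alpha < 1.0 / n_perm:
        raise ParameterError(
            f"alpha={alpha} is not resolvable with n_perm={n_perm}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y = np.asarray(phenotype, dtype=float)
    max_lod = np.empty(n_perm)
    for b in range(n_perm):
        max_lod[b] = float(np.nanmax(scan_fn(rng.permutation(y))))
    return float(np.quantile(max_lod, 1.0 - alpha)), max_lod


def founder_scan_fn(dosages: FounderDosageMatrix):
    """Fast closure for permutation scans: precomputes per-marker bases."""
    bases = [
        _orthonormal_basis(dosages.dosages[:, m, :])
        for m in range(dosages.markers.n_markers)
    ]
    return lambda y: _gaussian_lod(np.asarray(y, dtype=float), bases)


def binary_scan_fn(
    genotypes: N1GenotypeMatrix,
    model: ScanModel = ScanModel.logistic_binary_marker,
):
    """Closure over the genotype matrix for permutation scans."""
    def fn(y):
        return scan_binary_marker(y, genotypes, model=model).lod

    return fn


# ---------------------------------------------------------------------------
# Epistasis

def _interaction_columns(g: np.ndarray, combos) -> np.ndarray:
    cols = [np.prod(g[:, list(c)], axis=1) for c in combos]
    return np.column_stack(cols) if cols else np.empty((g.shape[0], 0))

def _fit_logit(y: np.ndarray, x: np.ndarray) -> tuple[float, bool]:
    """Log-likelihood of a logistic fit; iteration-capped, flags nonconvergence."""
    model = sm.Logit(y, x)
    with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=200, method="newton",
                            warn_convergence=False)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(disp=0, maxiter=500, method="bfgs",
                            warn_convergence=False)
            converged = bool(res.mle_retvals.get("converged", True))
        llf = float(res.llf)  # lazy property; evaluate under suppression
    return llf, converged


def epistasis_lrt(
    genotypes: np.ndarray,
    response: np.ndarray,
    order: int = 2,
    qtl_ids: tuple | None = None,
    baseline: str = "pairwise",
) -> EpistasisResult:
    """Likelihood-ratio test for epistatic interaction among binary QTLs.

    ``genotypes`` is (n_mice, k) binary ancestry at the k loci under test and
    ``response`` a binary complete-responder indicator; rows with missing
    values are dropped.  For ``order=2`` the additive model (intercept plus
    k main effects) is compared against the model adding all pairwise
    products among the tested loci.  For ``order=3`` the default compares
    additive+pairwise against the same model plus the single 3-way product
    (df=1); ``baseline='additive'`` instead tests all interactions jointly
    against the purely additive model.

    Every genotype cell used by the tested interaction must be nonempty;
    otherwise an error naming the cell is raised.  Nonconvergence of either
    fit is flagged on the result rather than raised.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(response, dtype=float)
    if g.ndim != 2:
        raise ValidationError("genotypes must be 2-D (mice x loci)")
    k = g.shape[1]
    if order not in (2, 3):
        raise ParameterError("order must be 2 or 3")
    if order > k:
        raise ParameterError(f"order={order} exceeds number of loci {k}")
    mask = np.all(np.isfinite(g), axis=1) & np.isfinite(y)
    g, y = g[mask], y[mask]
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("response must be binary 0/1")

    # every full genotype cell used by the highest-order term must be occupied
    cells = {tuple(int(v) for v in row) for row in g}
    for cell in itertools.product((0, 1), repeat=k):
        if cell not in cells:
            raise DegenerateDataError(
                "empty genotype cell "
                + "(" + ", ".join(f"g{i+1}={v}" for i, v in enumerate(cell)) + ")"
            )

    main = [np.ones(g.shape[0]), *(g[:, j] for j in range(k))]
    x_add = np.column_stack(main)
    pairs = list(itertools.combinations(range(k), 2))
    if order == 2:
        x_null = x_add
        x_full = np.column_stack([x_add, _interaction_columns(g, pairs)])
        df = len(pairs)
    else:
        triples = list(itertools.combinations(range(k), 3))
        if baseline == "pairwise":
            x_null = np.column_stack([x_add, _interaction_columns(g, pairs)])
            x_full = np.column_stack([x_null, _interaction_columns(g, triples)])
            df = len(triples)
        elif baseline == "additive":
            x_null = x_add
            x_full = np.column_stack(
                [x_add, _interaction_columns(g, pairs + triples)]
            )
            df = len(pairs) + len(triples)
        else:
            raise ParameterError("baseline must be 'pairwise' or 'additive'")

    ll0, conv0 = _fit_logit(y, x_null)
    ll1, conv1 = _fit_logit(y, x_full)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(lrt, df))
    ids = qtl_ids if qtl_ids is not None else tuple(f"Q{i+1}" for i in range(k))
    return EpistasisResult(tuple(ids), order, lrt, df, p,
                           converged=conv0 and conv1)


# ---------------------------------------------------------------------------
# Group comparisons (rank-sum)

def rank_sum_test(
    x: np.ndarray, y: np.ndarray, exact_limit: int = 20_000
) -> float:
    """Two-sided rank-sum (Mann–Whitney) p-value, tie-safe.

    Small samples (at most ``exact_limit`` label assignments) use exhaustive
    enumeration of the rank-sum permutation distribution, which is exact in
    the presence of ties; larger samples use the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires two nonempty groups")
    n, nx = x.size + y.size, x.size
    if math.comb(n, nx) <= exact_limit:
        ranks = stats.rankdata(np.concatenate([x, y]))
        obs = abs(ranks[:nx].sum() - nx * (n + 1) / 2.0)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), nx):
            dev = abs(ranks[list(combo)].sum() - nx * (n + 1) / 2.0)
            count += dev >= obs - 1e-9
            total += 1
        return count / total
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic").pvalue
    )


def haplotype_group_compare(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of per-mouse CR indicators across
    genotype-defined groups (e.g. responder/non-responder haplotype
    configurations at mapped QTLs)."""
    names = list(groups)
    rows = []
    for a, b in itertools.combinations(names, 2):
        ga, gb = np.asarray(groups[a]), np.asarray(groups[b])
        rows.append(
            (a, b, float(np.mean(ga)), float(np.mean(gb)),
             rank_sum_test(ga, gb))
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "frac_cr_a", "frac_cr_b", "p"]
    )
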