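"""Tumor-microenvironment statistics.

Three analyses of the immune microenvironment of responder vs non-responder
tumors:

* **Spatial colocalization** — a spatial spot is called colocalized for two
  cell types when markers of both types are detected (nonzero counts) in
  that spot; only spots expressing the immune gate gene (*Ptprc*/CD45 by
  default) are considered.  Responder/non-responder differences in
  per-sample colocalization fractions are tested by shuffling the
  spot-to-sample assignment.

* **Cxcl9/Spp1 ratio** — a macrophage-polarity biomarker: the ratio of
  counts-per-million of *Cxcl9* to *Spp1* per bulk RNA-seq sample, compared
  between groups with rank-sum tests.

* **MHC heterozygosity score** — the fraction of MHC-interval SNVs at which
  the CC-derived founder allele differs from the inbred partner strain's
  allele; an F1's expected functional MHC diversity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    ParameterError,
    SchemaError,
    ValidationError,
)
from .qtl import rank_sum_test

__all__ = [
    "MarkerPanel",
    "SpotTable",
    "coloc_fraction",
    "coloc_permutation_test",
    "cxcl9_spp1_ratio",
    "mhc_heterozygosity_score",
]

GROUPS = ("responder", "non_responder")


@dataclass
class MarkerPanel:
    """Marker-gene sets defining cell types on spatial spots.

    ``cell_types`` maps a type name to ``(genes, policy)`` where policy is
    ``"any"`` (at least one marker detected) or ``"all"`` (every marker
    detected).  The ``gate`` set (default {Ptprc}) restricts the analysis to
    immune-infiltrated spots and must be disjoint from every cell-type set.
    """

    gate: tuple[str, ...] = ("Ptprc",)
    cell_types: dict[str, tuple[tuple[str, ...], str]] = field(
        default_factory=lambda: {
            "ctl": (("Thy1", "Cd8a"), "all"),
            "macrophage": (("Adgre1", "Cd68", "Itgam", "Cxcl9"), "any"),
            "dc": (("Batf3", "Zbtb46"), "any"),
        }
    )

    def __post_init__(self):
        if not self.gate:
            raise ParameterError("gate set must be nonempty")
        gate = set(self.gate)
        for name, (genes, policy) in self.cell_types.items():
            if not genes:
                raise ParameterError(f"cell type {name!r} has no markers")
            if policy not in ("any", "all"):
                raise ParameterError(
                    f"policy for {name!r} must be 'any' or 'all'"
                )
            if gate & set(genes):
                raise ParameterError(
                    f"cell type {name!r} markers overlap the gate set"
                )

    @property
    def all_genes(self) -> tuple[str, ...]:
        genes = list(self.gate)
        for gs, _ in self.cell_types.values():
            genes.extend(gs)
        return tuple(dict.fromkeys(genes))

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        import yaml

        data = yaml.safe_load(open(path))
        cell_types = {
            name: (tuple(entry["genes"]), entry.get("policy", "any"))
            for name, entry in data.get("cell_types", {}).items()
        }
        kwargs = {}
        if "gate" in data:
            kwargs["gate"] = tuple(data["gate"])
        if cell_types:
            kwargs["cell_types"] = cell_types
        return cls(**kwargs)


@dataclass
class SpotTable:
    """Spatial spots with sample/group labels and per-gene counts.

    Wraps a DataFrame with columns ``spot_id, sample_id, group`` plus one
    integer count column per panel gene.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"spot_id", "sample_id", "group"}
        missing = required - set(self.df.columns)
        if missing:
            raise SchemaError(f"spot table missing column(s): {sorted(missing)}")
        bad = set(self.df["group"].unique()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        counts = self.df.drop(columns=["spot_id", "sample_id", "group"])
        if (counts.to_numpy(dtype=float) < 0).any():
            raise ValidationError("spot gene counts must be nonnegative")

    @property
    def gene_columns(self) -> list[str]:
        return [
            c for c in self.df.columns
            if c not in ("spot_id", "sample_id", "group")
        ]

    @classmethod
    def read_tsv(cls, path) -> "SpotTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _presence(df: pd.DataFrame, genes, policy: str) -> np.ndarray:
    detected = df[list(genes)].to_numpy(dtype=float) > 0
    return detected.all(axis=1) if policy == "all" else detected.any(axis=1)


def _spot_indicators(
    spots: SpotTable, panel: MarkerPanel, type_a: str, type_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """(gate_positive, colocalized) boolean vectors over spots."""
    for t in (type_a, type_b):
        if t not in panel.cell_types:
            raise ParameterError(f"unknown cell type {t!r}")
    missing = [g for g in panel.all_genes if g not in spots.df.columns]
    if missing:
        raise SchemaError(f"spot table missing panel gene(s): {missing}")
    gate = _presence(spots.df, panel.gate, "all")
    a = _presence(spots.df, *panel.cell_types[type_a])
    b = _presence(spots.df, *panel.cell_types[type_b])
    return gate, gate & a & b


def coloc_fraction(
    spots: SpotTable, panel: MarkerPanel, type_a: str, type_b: str
) -> pd.Series:
    """Per-sample fraction of gate-positive spots where both types are present.

    Raises on samples with zero gate-positive spots (the fraction is
    undefined there), naming the sample.
    """
    gate, coloc = _spot_indicators(spots, panel, type_a, type_b)
    sample = spots.df["sample_id"].to_numpy()
    out = {}
    for s in pd.unique(sample):
        m = sample == s
        n_gate = int(gate[m].sum())
        if n_gate == 0:
            raise DegenerateDataError(
                f"sample {s!r} has no {'+'.join(panel.gate)}-positive spots"
            )
        out[s] = float(coloc[m].sum() / n_gate)
    return pd.Series(out, name=f"{type_a}-{type_b}")


def coloc_permutation_test(
    spots: SpotTable,
    panel: MarkerPanel,
    type_a: str,
    type_b: str,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    two_sided: bool = True,
    max_retries: int = 100,
) -> tuple[float, float, bool]:
    """Label-shuffling test of responder vs non-responder colocalization.

    The observed statistic is the mean per-sample colocalization fraction in
    responders minus non-responders.  Each permutation shuffles the
    spot-to-sample assignment globally (sample sizes and sample-to-group
    mapping preserved) and recomputes the statistic; a permutation that
    leaves some sample without gate-positive spots is redrawn (up to
    ``max_retries`` per draw).  ``p = #{|diff_perm| >= |diff_obs|} / n_perm``
    (signed comparison when ``two_sided=False``); zero exceedances report the
    bound ``1/n_perm`` with the flag set.

    Returns ``(observed_diff, p, p_is_bound)``.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    gate, coloc = _spot_indicators(spots, panel, type_a, type_b)
    sample_labels = spots.df["sample_id"].to_numpy()
    samples = pd.unique(sample_labels)
    group_of = {
        s: spots.df.loc[sample_labels == s, "group"].iloc[0] for s in samples
    }
    for g in GROUPS:
        if g not in set(group_of.values()):
            raise ValidationError(f"group {g!r} has no samples")
    sidx = {s: i for i, s in enumerate(samples)}
    scode = np.array([sidx[s] for s in sample_labels])
    is_resp = np.array([group_of[s] == "responder" for s in samples])
    n_samples = samples.size

    def statistic(gate_v, coloc_v):
        n_gate = np.bincount(scode, weights=gate_v, minlength=n_samples)
        if np.any(n_gate == 0):
            return None
        n_co = np.bincount(scode, weights=coloc_v, minlength=n_samples)
        frac = n_co / n_gate
        return float(frac[is_resp].mean() - frac[~is_resp].mean())

    observed = statistic(gate.astype(float), coloc.astype(float))
    if observed is None:
        raise DegenerateDataError("a sample has no gate-positive spots")

    gate_f = gate.astype(float)
    coloc_f = coloc.astype(float)
    n = gate_f.size
    exceed = 0
    for _ in range(n_perm):
        for attempt in range(max_retries + 1):
            perm = rng.permutation(n)
            stat = statistic(gate_f[perm], coloc_f[perm])
            if stat is not None:
                break
        else:
            raise DegenerateDataError(
                "could not draw a permutation with all samples gate-positive"
            )
        if two_sided:
            exceed += abs(stat) >= abs(observed) - 1e-12
        else:
            exceed += stat >= observed - 1e-12
    if exceed == 0:
        return observed, 1.0 / n_perm, True
    return observed, exceed / n_perm, False


# ---------------------------------------------------------------------------
# Expression ratio

def cxcl9_spp1_ratio(
    counts: pd.DataFrame,
    sample_groups: pd.Series,
    gene_a: str = "Cxcl9",
    gene_b: str = "Spp1",
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample CPM ratio of two genes plus pairwise group comparisons.

    ``counts`` is genes x samples (nonnegative integers); the ratio is
    ``(CPM_a + eps) / (CPM_b + eps)`` with the pseudocount applied on the
    CPM scale so zero-count samples stay finite.  Groups are compared
    pairwise with two-sided rank-sum tests.

    Returns ``(per_sample, comparisons)``; ``per_sample`` has columns
    sample_id, group, cpm_a, cpm_b, ratio; ``comparisons`` has the pairwise
    p-values and per-group medians.
    """
    for g in (gene_a, gene_b):
        if g not in counts.index:
            raise SchemaError(f"gene {g!r} absent from the expression table")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise DegenerateDataError(f"zero library size for sample(s) {bad}")
    cpm_a = counts.loc[gene_a].astype(float) / lib * 1e6
    cpm_b = counts.loc[gene_b].astype(float) / lib * 1e6
    ratio = (cpm_a + pseudocount) / (cpm_b + pseudocount)
    per_sample = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "group": sample_groups.reindex(counts.columns).to_numpy(),
            "cpm_a": cpm_a.to_numpy(),
            "cpm_b": cpm_b.to_numpy(),
            "ratio": ratio.to_numpy(),
        }
    )
    rows = []
    groups = list(pd.unique(per_sample["group"]))
    for ga, gb in itertools.combinations(groups, 2):
        ra = per_sample.loc[per_sample["group"] == ga, "ratio"].to_numpy()
        rb = per_sample.loc[per_sample["group"] == gb, "ratio"].to_numpy()
        rows.append(
            (ga, gb, float(np.median(ra)), float(np.median(rb)),
             rank_sum_test(ra, rb))
        )
    comparisons = pd.DataFrame(
        rows, columns=["group_a", "group_b", "median_a", "median_b", "p"]
    )
    return per_sample, comparisons


# ---------------------------------------------------------------------------
# MHC heterozygosity

def mhc_heterozygosity_score(
    founder_genotypes: pd.DataFrame,
    line_haplotype: str | pd.Series,
    partner: str,
) -> float:
    """Fraction of interval SNVs where the carried founder allele differs
    from the partner strain's allele.

    ``founder_genotypes`` has one row per SNV and one allele column per
    founder strain; ``line_haplotype`` names the founder whose haplotype the
    line carries across the interval (or a per-SNV Series of founder names
    for recombinant intervals); ``partner`` names the inbred partner strain's
    allele column.  Missing calls (NaN, empty, or 'N') on either side are
    excluded from the denominator; an empty denominator raises.
    """
    if isinstance(line_haplotype, str):
        carried = pd.Series(line_haplotype, index=founder_genotypes.index)
    else:
        carried = line_haplotype.reindex(founder_genotypes.index)
    for col in set(carried.dropna()) | {partner}:
        if col not in founder_genotypes.columns:
            raise SchemaError(f"founder column {col!r} absent")

    def clean(series: pd.Series) -> pd.Series:
        s = series.astype(object).where(series.notna(), None)
        return s.map(
            lambda a: None
            if a is None or str(a).strip() in ("", "N", "NA", "nan")
            else str(a).strip().upper()
        )

    cc_allele = clean(
        pd.Series(
            [
                founder_genotypes.at[i, f] if isinstance(f, str) else np.nan
                for i, f in carried.items()
            ],
            index=founder_genotypes.index,
        )
    )
    partner_allele = clean(founder_genotypes[partner])
    both = cc_allele.notna() & partner_allele.notna()
    n_called = int(both.sum())
    if n_called == 0:
        raise DegenerateDataError(
            "no SNVs with allele calls for both haplotypes in the interval"
        )
    n_diff = int((cc_allele[both] != partner_allele[both]).sum())
    return n_diff / n_called
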