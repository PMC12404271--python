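"""Synthetic study generator with planted ground truth.

Every pipeline stage can be exercised end-to-end on data this module
produces: Collaborative-Cross-like founder mosaics, N1 backcross genotypes,
exponential tumor-growth tables with planted strain and QTL effects,
negative-binomial expression counts, and Bernoulli spot tables.  Each
generator is deterministic under a fixed seed and records the planted truth
so recovery tests can compare estimates against it.

Modeling choices (see docs/methods.md for rationale):

* Founder mosaics use a marker-to-marker Markov switch process with Haldane
  map distances expanded by a mosaic-density factor (default 7, the
  approximate realized map expansion of an eight-way recombinant inbred
  panel), not a full funnel pedigree.
* N1 meioses place crossovers by the Haldane (no-interference) map function
  at single-meiosis density.
* Tumor growth is exponential on the log10 scale with lognormal measurement
  noise, a detection limit below which volumes are recorded as 0, and a
  treated-arm complete-response mechanism: a sufficiently negative treated
  slope triggers regress-to-zero or (with configured probability)
  never-detected CR* trajectories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import GROWTH_COLUMNS
from .qtl import FOUNDERS, FounderDosageMatrix, MarkerMap, N1GenotypeMatrix
from .tme import GROUPS, MarkerPanel, SpotTable

__all__ = [
    "GroundTruth",
    "simulate_cc_genomes",
    "simulate_ccf1n1",
    "simulate_growth_study",
    "simulate_n1_growth_study",
    "simulate_strain_phenotypes",
    "simulate_cr_outcomes",
    "simulate_expression",
    "simulate_spots",
    "run_scenario",
]


@dataclass
class GroundTruth:
    """Planted parameters of a simulated dataset, JSON-serializable."""

    stage: str
    seed: int
    params: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=_json_default)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed)
    )


# ---------------------------------------------------------------------------
# Genomes

def haldane_recomb_fraction(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function: r = (1 - exp(-2d)) / 2, d in Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def simulate_cc_genomes(
    n_lines: int,
    chromosomes: list[tuple[int, float]],
    seed=0,
    map_expansion: float = 7.0,
) -> tuple[FounderDosageMatrix, GroundTruth]:
    """CC-like panel: per-line founder mosaics as one-hot dosage matrices.

    ``chromosomes`` is a list of ``(n_markers, length_cM)``.  Along each
    chromosome the founder identity follows a Markov chain: uniform over the
    eight founders at the first marker, then between adjacent markers a
    mosaic event occurs with probability ``1 - exp(-map_expansion * d)``
    (d the interval in Morgans), after which the founder is redrawn
    uniformly (so 7/8 of events change the founder).  Marginal founder
    frequency is exactly 1/8 at every marker.
    """
    if n_lines < 2:
        raise ParameterError("n_lines must be >= 2")
    rng = _rng(seed)
    marker_ids, chroms, pos = [], [], []
    for c, (n_markers, length_cm) in enumerate(chromosomes, start=1):
        if n_markers < 2:
            raise ParameterError("each chromosome needs >= 2 markers")
        if length_cm <= 0:
            raise ParameterError("chromosome map length must be positive")
        p = np.linspace(0.0, length_cm, n_markers)
        marker_ids.extend(f"c{c}m{j+1}" for j in range(n_markers))
        chroms.extend([str(c)] * n_markers)
        pos.extend(p)
    markers = MarkerMap(np.array(marker_ids, dtype=object),
                        np.array(chroms, dtype=object),
                        np.array(pos))

    n_total = markers.n_markers
    mosaic = np.empty((n_lines, n_total), dtype=int)
    start = 0
    for c, (n_markers, length_cm) in enumerate(chromosomes, start=1):
        d = np.diff(np.linspace(0.0, length_cm, n_markers)) / 100.0
        p_event = 1.0 - np.exp(-map_expansion * d)
        for l in range(n_lines):
            f = rng.integers(0, 8)
            mosaic[l, start] = f
            for j, pe in enumerate(p_event, start=1):
                if rng.random() < pe:
                    f = rng.integers(0, 8)
                mosaic[l, start + j] = f
        start += n_markers

    dosages = np.zeros((n_lines, n_total, 8))
    li, mi = np.meshgrid(np.arange(n_lines), np.arange(n_total), indexing="ij")
    dosages[li, mi, mosaic] = 1.0
    line_ids = [f"CC{100 + i}" for i in range(n_lines)]
    fdm = FounderDosageMatrix(markers, line_ids, dosages)
    truth = GroundTruth(
        "cc_genomes",
        seed if isinstance(seed, int) else -1,
        params={
            "n_lines": n_lines,
            "chromosomes": [list(c) for c in chromosomes],
            "map_expansion": map_expansion,
        },
        derived={"mosaic": mosaic},
    )
    return fdm, truth


def simulate_ccf1n1(
    parents: FounderDosageMatrix,
    n_mice: int,
    seed=0,
    parent_lines: tuple[int, int] = (0, 1),
) -> tuple[N1GenotypeMatrix, GroundTruth]:
    """N1 backcross genotypes: which intercross parent transmitted each locus.

    Each mouse's CC-derived chromosome is a recombinant of the two parent
    haplotype identities with crossovers placed by the Haldane map function
    at single-meiosis density.  Genotype 0/1 records the transmitting
    parent; the parents must share a marker map (guaranteed here by drawing
    both from the same panel).
    """
    if n_mice < 1:
        raise ParameterError("n_mice must be >= 1")
    a, b = parent_lines
    if not (0 <= a < len(parents.line_ids) and 0 <= b < len(parents.line_ids)):
        raise ValidationError("parent_lines indices out of range")
    rng = _rng(seed)
    markers = parents.markers
    geno = np.empty((n_mice, markers.n_markers))
    for chrom in pd.unique(markers.chrom):
        idx = np.flatnonzero(markers.chrom == chrom)
        r = haldane_recomb_fraction(np.diff(markers.pos_cm[idx]))
        state = rng.integers(0, 2, size=n_mice)
        geno[:, idx[0]] = state
        for j, rj in enumerate(r, start=1):
            flip = rng.random(n_mice) < rj
            state = np.where(flip, 1 - state, state)
            geno[:, idx[j]] = state
    mouse_ids = [f"N1-{i+1:04d}" for i in range(n_mice)]
    n1 = N1GenotypeMatrix(markers, mouse_ids, geno)
    truth = GroundTruth(
        "ccf1n1",
        seed if isinstance(seed, int) else -1,
        params={"n_mice": n_mice,
                "parents": [parents.line_ids[a], parents.line_ids[b]]},
    )
    return n1, truth


# ---------------------------------------------------------------------------
# Growth studies

@dataclass
class GrowthParams:
    """Generative parameters of the tumor-growth simulator.

    Defaults emulate an MC38-like study: engraftment at day 0, dosing from
    day 7, calipering every 3 days through day 28, ~3-day volume doubling in
    untreated tumors (slope 0.1 log10 mm^3/day), and measurement noise of
    0.08 on the log10 scale (~20% CV).
    """

    baseline_slope: float = 0.10       # log10(mm^3)/day
    sigma_strain: float = 0.0          # SD of per-line slope deviations
    sigma_noise: float = 0.08          # measurement noise, log10 scale
    treatment_effect: float = -0.05    # mean treated-arm slope shift
    v0: float = 60.0                   # mm^3 at start_day
    days: tuple = (7, 10, 13, 16, 19, 22, 25, 28)
    detection_limit: float = 1.0
    cr_slope_threshold: float = -0.02  # treated slope below this may trigger CR
    p_cr_regress: float = 0.0          # P(grew-once-then-regressed | eligible)
    p_crstar: float = 0.0              # P(never detected | eligible)

    def __post_init__(self):
        if self.sigma_noise < 0 or self.sigma_strain < 0:
            raise ParameterError("noise SDs must be nonnegative")
        if self.v0 <= 0 or self.detection_limit <= 0:
            raise ParameterError("v0 and detection_limit must be positive")
        if not 0 <= self.p_cr_regress + self.p_crstar <= 1:
            raise ParameterError("CR trajectory probabilities must sum to <= 1")


def simulate_growth_study(
    line_ids: list[str],
    n_control: int,
    n_treated: int,
    params: GrowthParams,
    seed=0,
    line_treatment_effects: dict[str, float] | None = None,
    start_day: int = 7,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format growth table for a panel of lines with two arms.

    Per mouse: ``log10 V(t) = log10 v0 + b (t - start_day) + eps_t`` with
    ``b = baseline + u_line + arm * (treatment_effect + delta_line)`` where
    ``u_line ~ N(0, sigma_strain^2)`` and ``delta_line`` plants QTL-driven
    response differences.  Volumes below the detection limit are recorded
    as 0.  Treated tumors whose slope falls below ``cr_slope_threshold``
    become grew-once-then-regressed or never-detected (CR*) series with the
    configured probabilities.
    """
    if n_control < 0 or n_treated < 0 or n_control + n_treated == 0:
        raise ParameterError("need at least one mouse per line")
    rng = _rng(seed)
    delta = dict(line_treatment_effects or {})
    days = np.asarray(params.days, dtype=int)
    if days[0] < start_day:
        raise ParameterError("measurement days must start at/after start_day")

    u_line = {l: rng.normal(0.0, params.sigma_strain) for l in line_ids}
    rows = []
    slopes = {}
    counter = 0
    for line in line_ids:
        for arm, n_arm in (("control", n_control), ("treated", n_treated)):
            for _ in range(n_arm):
                counter += 1
                mouse = f"M{counter:05d}"
                b = params.baseline_slope + u_line[line]
                if arm == "treated":
                    b += params.treatment_effect + delta.get(line, 0.0)
                slopes[mouse] = b
                kind = "exponential"
                if arm == "treated" and b < params.cr_slope_threshold:
                    u = rng.random()
                    if u < params.p_crstar:
                        kind = "crstar"
                    elif u < params.p_crstar + params.p_cr_regress:
                        kind = "regress"
                log_v = (
                    np.log10(params.v0)
                    + b * (days - start_day)
                    + rng.normal(0.0, params.sigma_noise, size=days.size)
                )
                vol = 10.0 ** log_v
                if kind == "crstar":
                    vol[:] = 0.0
                elif kind == "regress":
                    vol[1:] = 0.0
                    vol[0] = max(vol[0], params.detection_limit)
                else:
                    vol[vol < params.detection_limit] = 0.0
                for d, v in zip(days, vol):
                    rows.append((mouse, line, arm, int(d), float(v)))
    table = pd.DataFrame(rows, columns=list(GROWTH_COLUMNS))
    truth = GroundTruth(
        "growth_study",
        seed if isinstance(seed, int) else -1,
        params=dataclasses.asdict(params)
        | {"n_control": n_control, "n_treated": n_treated,
           "start_day": start_day,
           "line_treatment_effects": delta},
        derived={"line_random_effects": u_line, "true_slopes": slopes},
    )
    return table, truth


def simulate_n1_growth_study(
    n1: N1GenotypeMatrix,
    params: GrowthParams,
    seed=0,
    qtl_effects: dict[int, float] | None = None,
    interaction_effects: dict[tuple[int, int], float] | None = None,
    start_day: int = 7,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Growth table for an N1 mapping population (treated arm only).

    CCF1N1 mice are genetically unique and have no isotype control group, so
    every mouse is treated and the mapped quantities are the raw slope and
    the discrete response class.  Per mouse:
    ``b = baseline + treatment_effect + sum_q effect_q * g_q
    + sum_{qr} gamma_qr * g_q * g_r`` with ``g_q`` the binary ancestry at
    marker index q; trajectories and the CR mechanism are as in
    :func:`simulate_growth_study`.
    """
    rng = _rng(seed)
    days = np.asarray(params.days, dtype=int)
    effects = dict(qtl_effects or {})
    inter = dict(interaction_effects or {})
    rows = []
    slopes = {}
    for i, mouse in enumerate(n1.mouse_ids):
        b = params.baseline_slope + params.treatment_effect
        for m, eff in effects.items():
            b += eff * n1.genotype[i, m]
        for (m1, m2), gamma in inter.items():
            b += gamma * n1.genotype[i, m1] * n1.genotype[i, m2]
        slopes[mouse] = b
        kind = "exponential"
        if b < params.cr_slope_threshold:
            u = rng.random()
            if u < params.p_crstar:
                kind = "crstar"
            elif u < params.p_crstar + params.p_cr_regress:
                kind = "regress"
        log_v = (
            np.log10(params.v0)
            + b * (days - start_day)
            + rng.normal(0.0, params.sigma_noise, size=days.size)
        )
        vol = 10.0 ** log_v
        if kind == "crstar":
            vol[:] = 0.0
        elif kind == "regress":
            vol[1:] = 0.0
            vol[0] = max(vol[0], params.detection_limit)
        else:
            vol[vol < params.detection_limit] = 0.0
        for d, v in zip(days, vol):
            rows.append((mouse, "N1", "treated", int(d), float(v)))
    table = pd.DataFrame(rows, columns=list(GROWTH_COLUMNS))
    truth = GroundTruth(
        "n1_growth_study",
        seed if isinstance(seed, int) else -1,
        params=dataclasses.asdict(params)
        | {"start_day": start_day,
           "qtl_effects": {str(k): v for k, v in effects.items()},
           "interaction_effects": {str(k): v for k, v in inter.items()}},
        derived={"true_slopes": slopes},
    )
    return table, truth


def simulate_strain_phenotypes(
    n_strains: int,
    n_per_strain: int,
    h2: float,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced strain panel phenotypes with planted broad-sense heritability.

    ``h2`` is the estimand of the ANOVA statistic
    ``MS_strain / (MS_strain + (n_bar - 1) MS_resid)``, whose value under a
    balanced design with intraclass correlation f is
    ``1/n_bar + f (1 - 1/n_bar)``; the requested ``h2`` is inverted to f and
    strain/residual variance components are planted accordingly.  ``h2``
    must therefore lie in ``[1/n_per_strain, 1]`` — the statistic cannot sit
    below its null floor.
    """
    if n_strains < 2 or n_per_strain < 2:
        raise ParameterError("need >= 2 strains and >= 2 mice per strain")
    floor = 1.0 / n_per_strain
    if not floor <= h2 <= 1.0:
        raise ParameterError(
            f"h2 must lie in [{floor:.3f}, 1] for n_per_strain={n_per_strain}"
        )
    f = (h2 - floor) / (1.0 - floor)
    rng = _rng(seed)
    strain_effects = rng.normal(0.0, np.sqrt(f), size=n_strains)
    values = (
        np.repeat(strain_effects, n_per_strain)
        + rng.normal(0.0, np.sqrt(1.0 - f), size=n_strains * n_per_strain)
    )
    labels = np.repeat([f"S{i+1:03d}" for i in range(n_strains)], n_per_strain)
    return values, labels


def simulate_cr_outcomes(
    genotypes: np.ndarray,
    intercept: float,
    main_effects,
    interactions: dict[tuple, float] | None = None,
    seed=0,
) -> np.ndarray:
    """Bernoulli complete-responder outcomes from a logistic model.

    ``logit P(CR) = intercept + sum_j beta_j g_j + sum_c gamma_c prod(g_c)``
    with ``interactions`` mapping index tuples to coefficients; an empty or
    None mapping gives an exactly additive generative model.
    """
    g = np.asarray(genotypes, dtype=float)
    eta = intercept + g @ np.asarray(main_effects, dtype=float)
    for combo, gamma in (interactions or {}).items():
        eta = eta + gamma * np.prod(g[:, list(combo)], axis=1)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (_rng(seed).random(g.shape[0]) < p).astype(float)


# ---------------------------------------------------------------------------
# Expression and spots

def simulate_expression(
    n_per_group: dict[str, int],
    fold_changes: dict[str, dict[str, float]] | None = None,
    n_noise_genes: int = 200,
    base_mean: float = 100.0,
    dispersion: float = 0.3,
    seed=0,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Negative-binomial counts with group-specific fold changes on markers.

    ``fold_changes[group][gene]`` scales that gene's mean in that group
    (genes default to Cxcl9 and Spp1; unlisted genes are exchangeable
    noise).  Counts are NB with variance ``mu + dispersion * mu^2``.
    Returns (genes x samples counts, sample->group Series, truth).
    """
    if dispersion <= 0:
        raise ParameterError("dispersion must be > 0")
    fc = fold_changes or {}
    for group, genes in fc.items():
        for gene, value in genes.items():
            if value <= 0:
                raise ParameterError(
                    f"fold change for {gene} in {group} must be positive"
                )
    rng = _rng(seed)
    genes = ["Cxcl9", "Spp1"] + [f"G{i+1:04d}" for i in range(n_noise_genes)]
    samples, groups = [], []
    for group, n in n_per_group.items():
        for i in range(n):
            samples.append(f"{group}_{i+1:02d}")
            groups.append(group)
    n_size = 1.0 / dispersion
    counts = np.empty((len(genes), len(samples)), dtype=int)
    for j, group in enumerate(groups):
        mu = np.full(len(genes), base_mean)
        for gi, gene in enumerate(genes):
            mu[gi] *= fc.get(group, {}).get(gene, 1.0)
        p = n_size / (n_size + mu)
        counts[:, j] = rng.negative_binomial(n_size, p)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = GroundTruth(
        "expression",
        seed if isinstance(seed, int) else -1,
        params={"n_per_group": dict(n_per_group), "fold_changes": fc,
                "n_noise_genes": n_noise_genes, "base_mean": base_mean,
                "dispersion": dispersion},
    )
    return df, pd.Series(groups, index=samples, name="group"), truth


def simulate_spots(
    samples_per_group: int,
    spots_per_sample: int,
    joint_tables: dict[str, dict[str, float]],
    panel: MarkerPanel | None = None,
    type_a: str = "ctl",
    type_b: str = "macrophage",
    gate_prob: float = 0.8,
    seed=0,
) -> tuple[SpotTable, GroundTruth]:
    """Spot tables with group-specific type-A/type-B co-occurrence.

    ``joint_tables[group]`` gives ``p11, p10, p01`` — the joint presence
    probabilities of (A, B) conditional on the spot being gate-positive
    (``p00`` is the remainder and must be nonnegative).  Gate-negative spots
    carry no gate gene and enter no fraction.  Present cell types have every
    marker of their set switched on, satisfying either presence policy.
    """
    if not 0.0 < gate_prob <= 1.0:
        raise ParameterError("gate_prob must lie in (0, 1]")
    panel = panel or MarkerPanel()
    for group in GROUPS:
        if group not in joint_tables:
            raise ParameterError(f"joint_tables missing group {group!r}")
        t = joint_tables[group]
        p = [t.get("p11", 0), t.get("p10", 0), t.get("p01", 0)]
        if min(p) < 0 or sum(p) > 1 + 1e-12:
            raise ParameterError(f"infeasible joint table for group {group!r}")
    rng = _rng(seed)
    genes = list(panel.all_genes)
    a_genes = list(panel.cell_types[type_a][0])
    b_genes = list(panel.cell_types[type_b][0])
    rows = []
    spot = 0
    for group in GROUPS:
        t = joint_tables[group]
        probs = np.array(
            [t.get("p11", 0), t.get("p10", 0), t.get("p01", 0)], dtype=float
        )
        probs = np.append(probs, 1.0 - probs.sum())
        for s in range(samples_per_group):
            sample_id = f"{group}_{s+1:02d}"
            for _ in range(spots_per_sample):
                spot += 1
                counts = dict.fromkeys(genes, 0)
                if rng.random() < gate_prob:
                    for g in panel.gate:
                        counts[g] = 1
                    cell = rng.choice(4, p=probs)
                    if cell in (0, 1):  # A present
                        for g in a_genes:
                            counts[g] = 1
                    if cell in (0, 2):  # B present
                        for g in b_genes:
                            counts[g] = 1
                rows.append(
                    {"spot_id": f"spot{spot:05d}", "sample_id": sample_id,
                     "group": group, **counts}
                )
    table = SpotTable(pd.DataFrame(rows))
    truth = GroundTruth(
        "spots",
        seed if isinstance(seed, int) else -1,
        params={"samples_per_group": samples_per_group,
                "spots_per_sample": spots_per_sample,
                "joint_tables": joint_tables, "gate_prob": gate_prob,
                "type_a": type_a, "type_b": type_b},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Scenario runner

def run_scenario(scenario: dict, outdir: str | Path, seed: int) -> dict:
    """Materialize a full synthetic study from a scenario mapping.

    Recognized sections: ``cc_panel`` (n_lines, chromosomes), ``n1``
    (n_mice, optional parent line indices), ``growth`` (design + GrowthParams
    fields + optional planted ``qtl`` list), ``expression``, ``spots``.
    Writes stage-ready TSVs plus ``truth.json`` into ``outdir`` and returns
    the emitted file map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emitted: dict[str, str] = {}
    truths: dict[str, dict] = {}
    rng_seed = int(seed)

    fdm = None
    n1 = None
    if "cc_panel" in scenario:
        sec = scenario["cc_panel"]
        fdm, truth = simulate_cc_genomes(
            int(sec["n_lines"]),
            [tuple(c) for c in sec["chromosomes"]],
            seed=rng_seed,
            map_expansion=float(sec.get("map_expansion", 7.0)),
        )
        path = outdir / "dosages.tsv"
        fdm.write_tsv(path)
        emitted["dosages"] = str(path)
        truths["cc_panel"] = dataclasses.asdict(truth)

    if "n1" in scenario:
        if fdm is None:
            raise ParameterError("n1 section requires a cc_panel section")
        sec = scenario["n1"]
        n1, truth = simulate_ccf1n1(
            fdm, int(sec["n_mice"]), seed=rng_seed + 1,
            parent_lines=tuple(sec.get("parent_lines", (0, 1))),
        )
        path = outdir / "n1_genotypes.tsv"
        n1.write_tsv(path)
        emitted["n1_genotypes"] = str(path)
        truths["n1"] = dataclasses.asdict(truth)

    if "growth" in scenario:
        sec = dict(scenario["growth"])
        if fdm is None:
            raise ParameterError("growth section requires a cc_panel section")
        qtl = sec.pop("qtl", [])
        n_control = int(sec.pop("n_control", 4))
        n_treated = int(sec.pop("n_treated", 4))
        start_day = int(sec.pop("start_day", 7))
        params = GrowthParams(**{
            k: (tuple(v) if k == "days" else v) for k, v in sec.items()
        })
        line_effects = dict.fromkeys(fdm.line_ids, 0.0)
        planted = []
        for q in qtl:
            m = int(q["marker_index"])
            f_idx = FOUNDERS.index(q.get("founder", "A"))
            eff = float(q["effect"])
            carriers = fdm.dosages[:, m, f_idx] > 0.5
            for line, carry in zip(fdm.line_ids, carriers):
                if carry:
                    line_effects[line] += eff
            planted.append(
                {"marker_id": str(fdm.markers.marker_id[m]),
                 "marker_index": m, "founder": q.get("founder", "A"),
                 "effect": eff,
                 "n_carriers": int(carriers.sum())}
            )
        table, truth = simulate_growth_study(
            fdm.line_ids, n_control, n_treated, params, seed=rng_seed + 2,
            line_treatment_effects=line_effects, start_day=start_day,
        )
        truth.derived["planted_qtl"] = planted
        path = outdir / "growth.tsv"
        table.to_csv(path, sep="\t", index=False)
        emitted["growth"] = str(path)
        truths["growth"] = dataclasses.asdict(truth)

    if "n1_growth" in scenario:
        if n1 is None:
            raise ParameterError("n1_growth section requires an n1 section")
        sec = dict(scenario["n1_growth"])
        qtl_effects = {
            int(q["marker_index"]): float(q["effect"])
            for q in sec.pop("qtl", [])
        }
        inter = {
            tuple(int(i) for i in q["marker_indices"]): float(q["effect"])
            for q in sec.pop("interactions", [])
        }
        start_day = int(sec.pop("start_day", 7))
        params = GrowthParams(**{
            k: (tuple(v) if k == "days" else v) for k, v in sec.items()
        })
        table, truth = simulate_n1_growth_study(
            n1, params, seed=rng_seed + 5, qtl_effects=qtl_effects,
            interaction_effects=inter, start_day=start_day,
        )
        path = outdir / "n1_growth.tsv"
        table.to_csv(path, sep="\t", index=False)
        emitted["n1_growth"] = str(path)
        truths["n1_growth"] = dataclasses.asdict(truth)

    if "expression" in scenario:
        sec = scenario["expression"]
        counts, groups, truth = simulate_expression(
            {k: int(v) for k, v in sec["n_per_group"].items()},
            fold_changes=sec.get("fold_changes"),
            n_noise_genes=int(sec.get("n_noise_genes", 200)),
            base_mean=float(sec.get("base_mean", 100.0)),
            dispersion=float(sec.get("dispersion", 0.3)),
            seed=rng_seed + 3,
        )
        path = outdir / "expression.tsv"
        counts.rename_axis("gene").to_csv(path, sep="\t")
        meta_path = outdir / "expression_samples.tsv"
        groups.rename_axis("sample_id").reset_index().to_csv(
            meta_path, sep="\t", index=False
        )
        emitted["expression"] = str(path)
        emitted["expression_samples"] = str(meta_path)
        truths["expression"] = dataclasses.asdict(truth)

    if "spots" in scenario:
        sec = scenario["spots"]
        spots, truth = simulate_spots(
            int(sec["samples_per_group"]),
            int(sec["spots_per_sample"]),
            sec["joint_tables"],
            gate_prob=float(sec.get("gate_prob", 0.8)),
            type_a=sec.get("type_a", "ctl"),
            type_b=sec.get("type_b", "macrophage"),
            seed=rng_seed + 4,
        )
        path = outdir / "spots.tsv"
        spots.write_tsv(path)
        emitted["spots"] = str(path)
        truths["spots"] = dataclasses.asdict(truth)

    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps({"seed": rng_seed, "scenario": scenario, "stages": truths},
                   indent=2, sort_keys=True, default=_json_default)
        + "\n"
    )
    emitted["truth"] = str(truth_path)
    return emitted
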