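"""Synthetic breeding populations, QTL architectures and augmented-design trials.

The generator stands in for a private two-season winter-wheat data set: ~400
F6 lines from six breeding programs, split into a calibration set evaluated
in both seasons and two season-specific validation sets, genotyped at a few
thousand post-QC SNPs (mean MAF around 0.23) and phenotyped in unreplicated
augmented designs (ten blocks, three repeated checks, five locations per
season).

Genotypes use independent loci with Balding-Nichols-style between-program
allele-frequency divergence (``structure_strength`` plays the role of F_ST);
marker columns whose realized frequency falls outside the requested MAF
bounds are redrawn, so the emitted matrix is minor-allele coded and passes
quality control unchanged.  F6 material is nearly fully inbred; residual
heterozygosity is overlaid at a configurable rate (default 1%).

Phenotypes follow the trial model used downstream:

    y = mu + loc + block(loc) + g + gxl + e

with the residual variance back-solved from a target entry-mean heritability
h2 = s2_g / (s2_g + s2_gl/L + s2_e/L), so the generator's parameters are the
study conditions the estimators are asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phsgp.genotypes import GenotypeMatrix
from phsgp.trial import TRAIT_SCALES, PhenotypeTable

#: Program sizes of the emulated cohort (six breeding programs, 400 lines).
DEFAULT_PROGRAMS = [
    ("P1", 80),
    ("P2", 80),
    ("P3", 80),
    ("P4", 94),
    ("P5", 20),
    ("P6", 46),
]

DEFAULT_SEASON_SPLIT = {"CS": 200, "VS15": 100, "VS16": 100}


@dataclass
class PopulationSpec:
    """Parameters of a multi-program breeding population."""

    n_lines: int = 400
    programs: list = field(default_factory=lambda: list(DEFAULT_PROGRAMS))
    season_split: dict = field(default_factory=lambda: dict(DEFAULT_SEASON_SPLIT))
    n_markers: int = 6244
    maf_distribution: tuple = (0.02, 0.45)
    structure_strength: float = 0.02
    residual_het: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(n for _, n in self.programs) != self.n_lines:
            raise ValueError("program sizes must sum to n_lines")
        if sum(self.season_split.values()) != self.n_lines:
            raise ValueError("season split must sum to n_lines")
        lo, hi = self.maf_distribution
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < min <= max <= 0.5")
        if self.structure_strength < 0:
            raise ValueError("structure_strength must be >= 0")
        if not (0.0 <= self.residual_het <= 1.0):
            raise ValueError("residual_het must be a probability")


@dataclass
class QtlArchitecture:
    """Additive causal architecture over a marker panel.

    ``effects`` holds the additive effect per marker in trait units (zero for
    non-causal markers).  ``major_indices`` is the two-marker block of the
    major locus (a *Phs-A1* analogue tagged by two adjacent markers);
    ``panel_indices`` flags the 17 tracked QTL markers, ``fn_indices`` the
    three FN-per-se loci (T1RS.1BL / Rht analogues, no effect on the PHS
    trait itself).  ``qtl_groups`` maps each panel marker id to its QTL
    group; markers tagging the same locus share a group.
    """

    effects: np.ndarray
    major_indices: tuple
    polygenic_indices: np.ndarray
    panel_indices: np.ndarray
    fn_indices: np.ndarray
    qtl_groups: dict
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        major = set(int(i) for i in self.major_indices)
        poly = set(int(i) for i in self.polygenic_indices)
        if major & poly:
            raise ValueError("major and polygenic marker sets must be disjoint")
        panel_ids = set(self.marker_ids[self.panel_indices])
        if panel_ids - set(self.qtl_groups):
            raise ValueError("every panel marker must map to exactly one QTL group")

    @property
    def panel_marker_ids(self) -> np.ndarray:
        return self.marker_ids[self.panel_indices]

    @property
    def major_marker_ids(self) -> np.ndarray:
        return self.marker_ids[list(self.major_indices)]

    @property
    def fn_marker_ids(self) -> np.ndarray:
        return self.marker_ids[self.fn_indices]

    def genetic_values(self, geno: GenotypeMatrix) -> pd.Series:
        """True breeding values g = (dosages - mean) @ effects, per line."""
        Z = geno.dosages - np.nanmean(geno.dosages, axis=0)
        g = np.where(np.isnan(Z), 0.0, Z) @ self.effects
        return pd.Series(g, index=geno.line_ids, name="true_g")

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "effect": self.effects,
                "is_major": np.isin(np.arange(len(self.effects)), list(self.major_indices)),
                "is_panel": np.isin(np.arange(len(self.effects)), self.panel_indices),
                "is_fn": np.isin(np.arange(len(self.effects)), self.fn_indices),
            }
        )


@dataclass
class TrialDesignSpec:
    """One season's augmented-design layout and variance components."""

    locations: list = field(default_factory=lambda: ["L1", "L2", "L3", "L4", "L5"])
    n_blocks: int = 10
    checks: list = field(default_factory=lambda: ["chk_high", "chk_med", "chk_low"])
    sigma2_loc: float = 1.0
    sigma2_block: float = 0.25
    sigma2_gl: float = 0.05
    sigma2_e: float | None = None  # back-solved from target_h2 when None
    target_h2: float = 0.85
    mu: float = 300.0  # trait mean; the default sits on the falling-number seconds scale

    def __post_init__(self) -> None:
        for v in (self.sigma2_loc, self.sigma2_block, self.sigma2_gl):
            if v < 0:
                raise ValueError("variance components must be >= 0")
        if self.sigma2_e is not None and self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")
        if self.sigma2_e is None and not (0.0 < self.target_h2 <= 1.0):
            raise ValueError("target_h2 must be in (0, 1]")
        if self.n_blocks < 1 or not self.locations:
            raise ValueError("need at least one block and one location")

    def residual_variance(self, sigma2_g: float) -> float:
        """Residual variance delivering target_h2 at the realized genetic variance."""
        if self.sigma2_e is not None:
            return self.sigma2_e
        L = len(self.locations)
        s2e = L * sigma2_g * (1.0 - self.target_h2) / self.target_h2 - self.sigma2_gl
        if s2e < -1e-12:
            raise ValueError(
                f"target_h2={self.target_h2} infeasible with sigma2_gl={self.sigma2_gl}"
            )
        return max(s2e, 0.0)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    exact = total * weights / weights.sum()
    alloc = np.floor(exact).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(exact - alloc), kind="stable")
    alloc[order[:rem]] += 1
    return alloc


def simulate_population(spec: PopulationSpec) -> GenotypeMatrix:
    """Draw a minor-allele-coded dosage matrix with program structure.

    Each marker's ancestral frequency is uniform on the MAF bounds; program
    frequencies diverge by a Balding-Nichols Beta draw with parameter
    ``structure_strength``.  Columns are redrawn until the realized counted-
    allele frequency lies inside the bounds, so the output is minor-allele
    oriented and compatible with downstream QC at MAF > 0.01.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.maf_distribution
    n, m = spec.n_lines, spec.n_markers
    prog_sizes = np.array([c for _, c in spec.programs])
    prog_of_line = np.repeat(np.arange(len(spec.programs)), prog_sizes)

    dosages = np.empty((n, m))
    todo = np.arange(m)
    for _ in range(500):
        k = len(todo)
        if k == 0:
            break
        p_anc = rng.uniform(lo, hi, size=k)
        if spec.structure_strength > 0:
            F = spec.structure_strength
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p_prog = np.clip(rng.beta(a, b, size=(len(spec.programs), k)), 1e-4, 1 - 1e-4)
        else:
            p_prog = np.broadcast_to(p_anc, (len(spec.programs), k)).copy()
        p_cell = p_prog[prog_of_line, :]  # n x k
        dos = 2.0 * rng.binomial(1, p_cell)
        if spec.residual_het > 0:
            het = rng.random((n, k)) < spec.residual_het
            dos = np.where(het, 1.0, dos)
        dosages[:, todo] = dos
        freq = dosages[:, todo].mean(axis=0) / 2.0
        bad = (freq < lo) | (freq > hi)
        todo = todo[bad]
    if len(todo):
        raise RuntimeError(
            "could not realize MAF bounds; widen maf_distribution or add lines"
        )

    line_ids, programs = [], []
    for name, c in spec.programs:
        line_ids += [f"{name}_{i:03d}" for i in range(1, c + 1)]
        programs += [name] * c

    # Cohort membership stratified across programs (largest-remainder splits).
    labels = np.empty(n, dtype=object)
    order = list(spec.season_split)
    counts = np.array([spec.season_split[k] for k in order])
    per_prog = np.zeros((len(spec.programs), len(order)), dtype=int)
    for j, _tot in enumerate(counts[:-1]):
        per_prog[:, j] = _largest_remainder(counts[j], prog_sizes.astype(float))
    per_prog[:, -1] = prog_sizes - per_prog[:, :-1].sum(axis=1)
    for gi, (name, c) in enumerate(spec.programs):
        idx = np.flatnonzero(prog_of_line == gi)
        idx = rng.permutation(idx)
        s = 0
        for j, lab in enumerate(order):
            labels[idx[s : s + per_prog[gi, j]]] = lab
            s += per_prog[gi, j]

    return GenotypeMatrix(
        dosages=dosages,
        marker_ids=np.array([f"M{j + 1:05d}" for j in range(m)]),
        line_ids=np.array(line_ids),
        chrom=np.array([f"chr{(j % 21) + 1}" for j in range(m)]),
        pos=np.arange(1, m + 1) * 1000,
        program=np.array(programs),
        set_label=labels.astype(str),
        minor_coded=True,
    )


def make_qtl_architecture(
    geno: GenotypeMatrix,
    major_var_share: float = 0.30,
    n_polygenic: int = 200,
    n_panel: int = 17,
    n_fn: int = 3,
    total_genetic_var: float = 1.0,
    seed: int = 0,
) -> QtlArchitecture:
    """Build a trait architecture with one major two-marker locus.

    The major locus is represented by two adjacent markers carrying equal
    effects (three observable homozygous haplotype classes), scaled so the
    locus contributes approximately ``major_var_share`` of the genetic
    variance; a polygenic background of ``n_polygenic`` markers carries the
    rest.  The 17-marker tracked panel consists of the two major markers, a
    third marker grouped with them (one QTL tagged by three markers), and 14
    polygenic markers each tagging its own QTL group.  ``n_fn`` additional
    markers are flagged as FN-per-se loci with no effect on this trait.
    """
    if not (0.0 <= major_var_share < 1.0):
        raise ValueError("major_var_share must be in [0, 1)")
    rng = np.random.default_rng(seed)
    m = geno.n_markers
    if m < n_polygenic + n_fn + 3:
        raise ValueError("not enough markers for the requested architecture")
    perm = rng.permutation(m)
    major = (int(perm[0]), int(perm[1]))
    third_major_tag = int(perm[2])
    polygenic = np.sort(perm[3 : 3 + n_polygenic])
    fn = np.sort(perm[3 + n_polygenic : 3 + n_polygenic + n_fn])

    effects = np.zeros(m)
    effects[polygenic] = rng.normal(0.0, 1.0, size=n_polygenic)
    Z = geno.dosages - np.nanmean(geno.dosages, axis=0)
    Z = np.where(np.isnan(Z), 0.0, Z)
    g_poly = Z[:, polygenic] @ effects[polygenic]
    var_poly = float(np.var(g_poly))
    z_major = Z[:, major[0]] + Z[:, major[1]]
    var_major_unit = float(np.var(z_major))
    if major_var_share > 0:
        target = major_var_share / (1.0 - major_var_share) * var_poly
        c = np.sqrt(target / var_major_unit)
    else:
        c = 0.0
    effects[list(major)] = c
    g = Z @ effects
    sd = float(np.std(g))
    if sd > 0:
        effects *= np.sqrt(total_genetic_var) / sd

    # 17-marker panel: 3 markers tag the major QTL, 14 tag polygenic QTL.
    n_poly_panel = n_panel - 3
    poly_panel = rng.choice(polygenic, size=n_poly_panel, replace=False)
    panel = np.concatenate([[major[0], major[1], third_major_tag], poly_panel])
    groups = {geno.marker_ids[i]: "Phs-A1" for i in (major[0], major[1], third_major_tag)}
    for j, i in enumerate(poly_panel):
        groups[geno.marker_ids[i]] = f"QTL_{j + 1}"
    return QtlArchitecture(
        effects=effects,
        major_indices=major,
        polygenic_indices=polygenic,
        panel_indices=panel.astype(int),
        fn_indices=fn.astype(int),
        qtl_groups=groups,
        marker_ids=geno.marker_ids.copy(),
    )


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: QtlArchitecture,
    design: TrialDesignSpec,
    seed: int,
    trait: str = "FNS",
    season: str = "S15",
    lines=None,
) -> tuple[PhenotypeTable, pd.Series]:
    """Simulate one season of augmented-design plot records.

    Every entry appears exactly once per location (in a random block); every
    check appears once per block per location.  Returns the plot table and
    the true breeding values (entries and checks).  Values for bounded-scale
    traits (LS, GI) are truncated to their scale; LS is rounded to the 1-9
    ordinal grid.
    """
    rng = np.random.default_rng(seed)
    entry_ids = np.asarray(lines) if lines is not None else geno.line_ids
    missing = set(entry_ids) - set(geno.line_ids)
    if missing:
        raise KeyError(f"design entries not in genotype matrix: {sorted(missing)[:5]}")
    g_all = arch.genetic_values(geno)
    g_entries = g_all.loc[entry_ids]
    sigma2_g = float(np.var(g_entries.to_numpy()))
    s2e = design.residual_variance(sigma2_g)

    sd_g = np.sqrt(sigma2_g)
    g_checks = pd.Series(
        rng.normal(0.0, sd_g, size=len(design.checks)), index=design.checks
    )
    true_g = pd.concat([g_entries, g_checks])

    L = design.locations
    loc_eff = rng.normal(0.0, np.sqrt(design.sigma2_loc), size=len(L))
    rows = []
    gl_eff = {}  # (line, loc) -> effect
    for li, loc in enumerate(L):
        block_eff = rng.normal(0.0, np.sqrt(design.sigma2_block), size=design.n_blocks)
        entry_perm = rng.permutation(entry_ids)
        block_of = np.array_split(entry_perm, design.n_blocks)
        for b in range(design.n_blocks):
            plot_lines = list(block_of[b]) + list(design.checks)
            for ln in plot_lines:
                key = (ln, loc)
                if key not in gl_eff:
                    gl_eff[key] = rng.normal(0.0, np.sqrt(design.sigma2_gl))
                e = rng.normal(0.0, np.sqrt(s2e))
                y = design.mu + loc_eff[li] + block_eff[b] + true_g[ln] + gl_eff[key] + e
                rows.append((ln, season, loc, f"B{b + 1:02d}", trait, y))
    df = pd.DataFrame(rows, columns=["line", "season", "location", "block", "trait", "value"])
    lo, hi = TRAIT_SCALES.get(trait, (None, None))
    if trait == "LS":
        df["value"] = np.clip(np.round(df["value"]), 1, 9)
    else:
        if lo is not None:
            df["value"] = df["value"].clip(lower=lo)
        if hi is not None:
            df["value"] = df["value"].clip(upper=hi)
    return PhenotypeTable(records=df), true_g


def simulate_study_cohort(
    seed: int,
    n_markers: int = 600,
    h2: float = 0.85,
    major_var_share: float = 0.30,
    n_polygenic: int = 150,
    n_drop: tuple = (1, 1, 1),
    genetic_correlation: float = 1.0,
):
    """Two-season cohort with the study's bookkeeping, at line-mean level.

    Simulates the full 400-line cohort (six programs; 200 calibration lines
    evaluated in both seasons, 100 season-specific validation lines each),
    removes ``n_drop`` lines per cohort to mimic quality-control losses
    (397 lines by default), and produces per-season adjusted-mean-level
    phenotypes y = g + e with residual variance set by the entry-mean
    heritability ``h2``.  Season genetic values are identical when
    ``genetic_correlation`` is 1 (exchangeable seasons); smaller values mix
    in an independent genetic deviate.

    Returns a dict with the genotype matrix (post-drop), the architecture,
    the kinship matrix, true genetic values and ``means_by_season``
    ({"S15": Series over CS+VS15 lines, "S16": ...}).
    """
    from phsgp.genotypes import vanraden_grm

    spec = PopulationSpec(seed=seed, n_markers=n_markers)
    geno = simulate_population(spec)
    rng = np.random.default_rng(seed + 1)
    labels = pd.Series(geno.set_label, index=geno.line_ids)
    keep = []
    for cohort, nd in zip(("CS", "VS15", "VS16"), n_drop):
        ids = labels.index[labels == cohort].to_numpy()
        drop = set(rng.choice(ids, size=nd, replace=False)) if nd else set()
        keep += [l for l in ids if l not in drop]
    keep = [l for l in geno.line_ids if l in set(keep)]  # original order
    geno = geno.subset(lines=keep)
    arch = make_qtl_architecture(
        geno, major_var_share=major_var_share, n_polygenic=n_polygenic, seed=seed + 2
    )
    A = vanraden_grm(geno)
    g = arch.genetic_values(geno)
    s2g = float(np.var(g.to_numpy()))
    s2e = s2g * (1.0 - h2) / h2
    labels = pd.Series(geno.set_label, index=geno.line_ids)
    means = {}
    for season, cohorts in (("S15", ("CS", "VS15")), ("S16", ("CS", "VS16"))):
        lines = labels.index[labels.isin(cohorts)].to_numpy()
        g_season = g.loc[lines].to_numpy()
        if genetic_correlation < 1.0:
            rho = genetic_correlation
            dev = rng.normal(0.0, np.sqrt(s2g), size=len(lines))
            g_season = rho * g_season + np.sqrt(1 - rho**2) * dev
        e = rng.normal(0.0, np.sqrt(s2e), size=len(lines))
        means[season] = pd.Series(g_season + e, index=lines, name=f"obv_{season}")
    return {"geno": geno, "arch": arch, "A": A, "true_g": g, "means_by_season": means}


def simulate_germination_counts(
    propensity: float, n_seeds: int, n_days: int, seed=None, rng=None
) -> np.ndarray:
    """Daily germination counts under a geometric per-day hazard.

    Each seed germinates on day ``d`` with probability
    ``propensity * (1 - propensity)**(d-1)``; seeds may fail to germinate
    within the observation window.  Higher propensity shifts germination
    earlier in expectation; propensity 1 puts every seed on day one and
    propensity 0 yields no germination.
    """
    if not (0.0 <= propensity <= 1.0):
        raise ValueError("propensity must be in [0, 1]")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    p_day = propensity * (1.0 - propensity) ** np.arange(n_days)
    probs = np.append(p_day, max(0.0, 1.0 - p_day.sum()))
    counts = rng.multinomial(n_seeds, probs / probs.sum())
    return counts[:-1]
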