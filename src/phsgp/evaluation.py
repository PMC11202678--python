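"""Cross-validation, model comparison and across-season prediction scenarios.

Within a season, predictive ability is assessed by stratified five-fold
cross-validation repeated ten times: the lines of every breeding program are
split into five near-equal folds, four fifths form the estimation set (ES)
and the held-out fold the test set (TS), giving 50 (ES, TS) pairs per
replicate scheme.  Predictive ability is the Pearson correlation
r(y_TS, g_hat_TS) between observed adjusted means and predicted values.
Model variants are compared by a paired t-test over the 50 runs, pairing by
(replicate, fold) on a shared fold plan.

Across seasons, one season's adjusted means train the model and the other
season's means are predicted, with estimation sets of either all lines of the
training season or only the calibration set (CS, evaluated in both seasons),
and test sets of either the CS or the season-specific validation set (VS).

The two-marker haplotype analysis groups lines by their homozygous dosage
classes at the major locus and compares class means by pairwise Welch tests
with Bonferroni correction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from phsgp.gblup import GblupFit, ModelSpec, build_fixed_design, predict_gebv, reml_fit
from phsgp.genotypes import GenotypeMatrix, RelationshipMatrix


@dataclass
class FoldPlan:
    """Program-stratified fold assignments for repeated k-fold CV."""

    assignments: np.ndarray  # (reps, n_lines) of fold indices in [0, k)
    line_ids: np.ndarray
    programs: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.ndim != 2 or self.assignments.shape[1] != len(self.line_ids):
            raise ValueError("assignments must be (reps, n_lines)")
        if self.assignments.min() < 0 or self.assignments.max() >= self.k:
            raise ValueError("fold indices out of range")

    @property
    def reps(self) -> int:
        return self.assignments.shape[0]

    def test_lines(self, rep: int, fold: int) -> np.ndarray:
        return self.line_ids[self.assignments[rep] == fold]

    def train_lines(self, rep: int, fold: int) -> np.ndarray:
        return self.line_ids[self.assignments[rep] != fold]

    def identity(self) -> str:
        h = hashlib.sha256()
        h.update(self.assignments.tobytes())
        h.update(",".join(map(str, self.line_ids)).encode())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (rep + 1, line, int(fold) + 1)
            for rep in range(self.reps)
            for line, fold in zip(self.line_ids, self.assignments[rep])
        ]
        return pd.DataFrame(recs, columns=["replicate", "line", "fold"])


def make_folds(line_ids, programs, k: int = 5, reps: int = 10, seed: int = 0) -> FoldPlan:
    """Assign every line to one of ``k`` folds, stratified by program.

    Within every program the fold sizes differ by at most one; which folds
    receive the remainder lines is randomized so small programs do not always
    load the same folds.  Deterministic for a given seed.
    """
    line_ids = np.asarray(line_ids)
    programs = np.asarray(programs)
    if len(line_ids) != len(programs):
        raise ValueError("every line needs a program label")
    if len(np.unique(line_ids)) != len(line_ids):
        raise ValueError("line ids must be unique")
    rng = np.random.default_rng(seed)
    assignments = np.empty((reps, len(line_ids)), dtype=int)
    for rep in range(reps):
        for prog in np.unique(programs):
            idx = np.flatnonzero(programs == prog)
            idx = rng.permutation(idx)
            fold_order = rng.permutation(k)
            folds = np.tile(fold_order, len(idx) // k + 1)[: len(idx)]
            assignments[rep, idx] = folds
    return FoldPlan(assignments=assignments, line_ids=line_ids, programs=programs,
                    k=k, seed=seed)


@dataclass
class CVResult:
    """Predictive abilities of one (trait, model variant) over all CV runs."""

    trait: str
    variant: str
    runs: pd.DataFrame  # columns: replicate, fold, r, n_test
    plan_identity: str

    @property
    def abilities(self) -> np.ndarray:
        return self.runs["r"].to_numpy(dtype=float)

    @property
    def mean_ability(self) -> float:
        return float(np.nanmean(self.abilities))

    def __post_init__(self) -> None:
        r = self.runs["r"].to_numpy(dtype=float)
        ok = r[~np.isnan(r)]
        if ((ok < -1 - 1e-9) | (ok > 1 + 1e-9)).any():
            raise ValueError("correlations outside [-1, 1]")


def _rank_keep(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * (diag[0] if diag.size else 1.0)).sum())
    return np.sort(piv[:rank])


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate(
    means: pd.Series,
    geno: GenotypeMatrix,
    A: RelationshipMatrix,
    spec: ModelSpec,
    plan: FoldPlan,
    trait: str = "trait",
) -> CVResult:
    """Run all (replicate, fold) fits for one model variant on a shared plan.

    Runs whose test-set correlation is undefined (constant predictions or
    constant observations) are recorded as missing and excluded from the
    mean.  Reusing the same plan across variants pairs the runs.
    """
    missing = set(plan.line_ids) - set(means.index)
    if missing:
        raise ValueError(f"adjusted means missing for lines: {sorted(missing)[:5]}")
    X_all, names, _ = build_fixed_design(spec, geno, plan.line_ids)
    pos = pd.Index(plan.line_ids)
    rows = []
    for rep in range(plan.reps):
        for fold in range(plan.k):
            test = plan.test_lines(rep, fold)
            train = plan.train_lines(rep, fold)
            Xtr = X_all[pos.get_indexer(train)]
            Xte = X_all[pos.get_indexer(test)]
            keep = _rank_keep(Xtr)
            fit = reml_fit(
                means.loc[train], Xtr[:, keep], A, lines=train,
                fixed_names=[names[j] for j in keep],
            )
            pred = predict_gebv(
                fit,
                A.submatrix(test, train),
                A.submatrix(train),
                Xte[:, keep],
                target_lines=test,
            )
            r = _safe_pearson(pred.total.to_numpy(), means.loc[test].to_numpy())
            rows.append((rep + 1, fold + 1, r, len(test)))
    runs = pd.DataFrame(rows, columns=["replicate", "fold", "r", "n_test"])
    return CVResult(trait=trait, variant=spec.variant, runs=runs,
                    plan_identity=plan.identity())


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_models(a: CVResult, b: CVResult) -> dict:
    """Paired t-test of per-run predictive abilities (b minus a).

    Requires both results to come from the identical fold plan.  Identical
    abilities yield t = 0, p = 1 by convention.
    """
    if a.plan_identity != b.plan_identity:
        raise ValueError("CV results use different fold plans; pairing invalid")
    merged = a.runs.merge(b.runs, on=["replicate", "fold"], suffixes=("_a", "_b"))
    d = (merged["r_b"] - merged["r_a"]).to_numpy(dtype=float)
    d = d[~np.isnan(d)]
    if len(d) < 2 or np.allclose(d, d[0]) and abs(d[0]) < 1e-15:
        t, p = 0.0, 1.0
    elif np.std(d, ddof=1) == 0:
        t, p = (np.inf if d[0] > 0 else -np.inf), 0.0
    else:
        t, p = stats.ttest_rel(merged["r_b"], merged["r_a"], nan_policy="omit")
    return {
        "t": float(t),
        "p": float(p),
        "stars": significance_stars(float(p)),
        "mean_diff": float(np.mean(d)) if len(d) else float("nan"),
        "n_pairs": int(len(d)),
    }


@dataclass
class ScenarioSpec:
    """Across-season prediction scenario (estimation season -> test season)."""

    es_season: str
    ts_season: str
    es_subset: str = "all"  # "all" (CS + that season's VS) or "cs"
    ts_subset: str = "cs"  # "cs" or "vs"
    trait: str = "FNS"
    variant: str = "model1"

    def __post_init__(self) -> None:
        if self.es_subset not in ("all", "cs") or self.ts_subset not in ("cs", "vs"):
            raise ValueError("es_subset in {all, cs}; ts_subset in {cs, vs}")
        if self.es_season == self.ts_season:
            raise ValueError("estimation and test seasons must differ")


def _season_vs_label(season: str) -> str:
    # season labels "S15"/"S16" map to cohorts VS15/VS16
    return "VS" + "".join(ch for ch in str(season) if ch.isdigit())


def cross_season_predict(
    spec: ScenarioSpec,
    means_by_season: dict,
    geno: GenotypeMatrix,
    A: RelationshipMatrix,
    model_spec: ModelSpec,
) -> dict:
    """Fit on one season's adjusted means, predict the other season's lines.

    The test correlation uses only the test season's means; calibration-set
    lines may legitimately appear in both seasons' phenotype tables.
    Returns the correlation r(GEBV, OBV_TS) and the realized set sizes.
    """
    y_es = means_by_season[spec.es_season]
    y_ts = means_by_season[spec.ts_season]
    labels = pd.Series(geno.set_label, index=geno.line_ids)

    es_lines = np.asarray([l for l in y_es.index if l in labels.index])
    if spec.es_subset == "cs":
        es_lines = np.asarray([l for l in es_lines if labels[l] == "CS"])
    if spec.ts_subset == "cs":
        ts_lines = np.asarray([l for l in y_ts.index if l in labels.index and labels[l] == "CS"])
    else:
        vs = _season_vs_label(spec.ts_season)
        ts_lines = np.asarray([l for l in y_ts.index if l in labels.index and labels[l] == vs])
    if len(es_lines) == 0 or len(ts_lines) == 0:
        raise ValueError("empty estimation or test set for the scenario")

    X_es, names, _ = build_fixed_design(model_spec, geno, es_lines)
    keep = _rank_keep(X_es)
    fit = reml_fit(y_es.loc[es_lines], X_es[:, keep], A, lines=es_lines,
                   fixed_names=[names[j] for j in keep])
    X_ts, _, _ = build_fixed_design(model_spec, geno, ts_lines)
    pred = predict_gebv(
        fit,
        A.submatrix(ts_lines, es_lines),
        A.submatrix(es_lines),
        X_ts[:, keep],
        target_lines=ts_lines,
    )
    r = _safe_pearson(pred.total.to_numpy(), y_ts.loc[ts_lines].to_numpy())
    return {
        "r": r,
        "n_es": int(len(es_lines)),
        "n_ts": int(len(ts_lines)),
        "trait": spec.trait,
        "variant": model_spec.variant,
        "es": f"{spec.es_season}:{spec.es_subset}",
        "ts": f"{spec.ts_season}:{spec.ts_subset}",
    }


def season_gebv(
    means: pd.Series,
    geno: GenotypeMatrix,
    A: RelationshipMatrix,
    model_spec: ModelSpec,
) -> pd.Series:
    """Full-data GEBVs (X beta + t_hat) for all lines phenotyped in a season."""
    lines = np.asarray([l for l in means.index if l in set(geno.line_ids)])
    X, names, _ = build_fixed_design(model_spec, geno, lines)
    keep = _rank_keep(X)
    fit = reml_fit(means.loc[lines], X[:, keep], A, lines=lines,
                   fixed_names=[names[j] for j in keep])
    return pd.Series(X[:, keep] @ fit.beta + fit.t_hat.to_numpy(), index=lines,
                     name="gebv")


def season_correlations(
    means_by_season: dict,
    geno: GenotypeMatrix,
    A: RelationshipMatrix,
    model_spec: ModelSpec,
    seasons: tuple,
) -> dict:
    """Between-season OBV-OBV and GEBV-GEBV correlations on calibration lines."""
    s_a, s_b = seasons
    labels = pd.Series(geno.set_label, index=geno.line_ids)
    cs = [
        l
        for l in means_by_season[s_a].index
        if l in means_by_season[s_b].index and l in labels.index and labels[l] == "CS"
    ]
    if len(cs) < 3:
        raise ValueError("fewer than 3 calibration lines shared between seasons")
    obv_a = means_by_season[s_a].loc[cs].to_numpy()
    obv_b = means_by_season[s_b].loc[cs].to_numpy()
    g_a = season_gebv(means_by_season[s_a], geno, A, model_spec).loc[cs].to_numpy()
    g_b = season_gebv(means_by_season[s_b], geno, A, model_spec).loc[cs].to_numpy()
    return {
        "r_obv": _safe_pearson(obv_a, obv_b),
        "r_gebv": _safe_pearson(g_a, g_b),
        "n_cs": len(cs),
    }


def haplotype_analysis(
    geno: GenotypeMatrix,
    marker_pair,
    values: pd.Series,
    alpha: float = 0.05,
    min_class_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-locus haplotype classes at the major locus and their trait means.

    Lines heterozygous or missing at either marker are excluded.  Classes are
    the observed homozygous dosage combinations ("0/0", "0/2", "2/2", ...).
    Classes with at least ``min_class_n`` lines are compared pairwise by
    Welch's t-test with Bonferroni correction at ``alpha``.
    """
    mp = list(np.atleast_1d(marker_pair))
    if len(mp) != 2:
        raise ValueError("exactly two markers define the haplotype")
    sub = geno.subset(markers=mp)
    dos = sub.dosages
    common = [l for l in sub.line_ids if l in values.index]
    li = sub.line_index(common)
    dos = dos[li]
    vals = values.loc[common].to_numpy(dtype=float)
    keep = np.isin(dos[:, 0], (0.0, 2.0)) & np.isin(dos[:, 1], (0.0, 2.0)) & ~np.isnan(vals)
    n_excluded = len(common) - int(keep.sum())
    dos, vals = dos[keep], vals[keep]
    classes = np.array([f"{int(a)}/{int(b)}" for a, b in dos])

    rows = []
    for cls in sorted(np.unique(classes)):
        v = vals[classes == cls]
        rows.append((cls, len(v), float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")))
    table = pd.DataFrame(rows, columns=["haplotype", "n", "mean", "sd"])
    table.attrs["n_excluded"] = n_excluded

    testable = table.loc[table["n"] >= min_class_n, "haplotype"].tolist()
    if len(testable) < 2:
        raise ValueError("fewer than two haplotype classes with enough lines to test")
    pairs = list(combinations(testable, 2))
    m = len(pairs)
    trows = []
    for c1, c2 in pairs:
        v1, v2 = vals[classes == c1], vals[classes == c2]
        t, p = stats.ttest_ind(v1, v2, equal_var=False)
        p_adj = min(1.0, float(p) * m)
        trows.append((c1, c2, float(t), float(p), p_adj, p_adj < alpha))
    tests = pd.DataFrame(
        trows, columns=["class_a", "class_b", "t", "p", "p_bonferroni", "significant"]
    )
    return table, tests
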