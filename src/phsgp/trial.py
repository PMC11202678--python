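"""Plot-level trial statistics for unreplicated augmented designs.

The field layout is the classic augmented design: unreplicated entries plus a
few check varieties repeated in every block, which is what makes the residual
variance estimable.  Three models are fit by REML (:mod:`phsgp.mixed`):

* per-environment repeatability:  y = mu + block + entry + e, both random;
  rep2 = s2_entry / (s2_entry + s2_e);
* across-location adjusted means (BLUEs): genotype and location fixed,
  block-within-location and genotype-by-location random;
* across-location heritability: the all-random variant (genotype random),
  on an entry-mean basis with one replicate per location:
  h2 = s2_g / (s2_g + s2_gxl / L + s2_e / L).

The germination index weights early germination highest:
GI = sum_d (D - d + 1) n_d / (D * n_total) for daily counts n_1..n_D,
so GI = 1 when every seed germinates on day one and 0 with no germination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phsgp.mixed import MixedModelFit, indicator, reml

#: Trait registry: value bounds used for validation (None = unbounded side).
TRAIT_SCALES = {
    "LS": (1.0, 9.0),
    "GI": (0.0, 1.0),
    "FN1": (0.0, None),
    "FN2": (0.0, None),
    "FNS": (0.0, None),
    "PH": (0.0, None),
    "HD": (0.0, None),
}

REQUIRED_COLUMNS = ["line", "season", "location", "block", "trait", "value"]


@dataclass
class PhenotypeTable:
    """Plot-level phenotype records keyed by (line, season, location, block, trait)."""

    records: pd.DataFrame
    trait_scales: dict = field(default_factory=lambda: dict(TRAIT_SCALES))

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        self.records = self.records.reset_index(drop=True)
        keys = self.records[["line", "season", "location", "block", "trait"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (line, season, location, block, trait) records")
        for trait, grp in self.records.groupby("trait"):
            lo, hi = self.trait_scales.get(trait, (None, None))
            v = grp["value"].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if lo is not None and (v < lo - 1e-9).any():
                raise ValueError(f"{trait} values below scale minimum {lo}")
            if hi is not None and (v > hi + 1e-9).any():
                raise ValueError(f"{trait} values above scale maximum {hi}")

    def traits(self) -> list:
        return sorted(self.records["trait"].unique())

    def seasons(self) -> list:
        return sorted(self.records["season"].unique())

    def env_subset(self, season, location, trait) -> pd.DataFrame:
        r = self.records
        sub = r[(r.season == season) & (r.location == location) & (r.trait == trait)]
        return sub.dropna(subset=["value"])

    def season_subset(self, season, trait) -> pd.DataFrame:
        r = self.records
        sub = r[(r.season == season) & (r.trait == trait)]
        return sub.dropna(subset=["value"])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(records=pd.read_csv(path))


@dataclass
class VarianceDecomposition:
    """Variance-component estimates and the derived ratio (rep2 or h2)."""

    components: dict
    sigma2_e: float
    ratio: float
    ratio_name: str
    n_locations: int
    converged: bool
    loglik: float
    clamped: bool = False
    fit: MixedModelFit | None = None


def germination_index(counts, n_total: int, n_days: int | None = None) -> float:
    """Weighted germination index on daily removal counts.

    ``counts[d-1]`` seeds germinated on day ``d``; weights decline linearly
    from D (day 1) to 1 (day D); the maximum GI of 1 requires all ``n_total``
    seeds to germinate on day one.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a non-empty 1-d sequence")
    if (counts < 0).any():
        raise ValueError("negative germination counts")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if counts.sum() > n_total + 1e-9:
        raise ValueError("more germinated seeds than seeds tested")
    D = int(n_days) if n_days is not None else counts.size
    if D < counts.size:
        raise ValueError("n_days smaller than the number of daily counts")
    days = np.arange(1, counts.size + 1)
    return float(np.sum((D - days + 1) * counts) / (D * n_total))


def _require_rows(sub: pd.DataFrame, what: str) -> None:
    if sub.empty:
        raise ValueError(f"no phenotype records for {what}")


def repeatability(pheno: PhenotypeTable, trait, season, location) -> VarianceDecomposition:
    """Per-environment repeatability from the entries+blocks random model."""
    sub = pheno.env_subset(season, location, trait)
    _require_rows(sub, f"{trait} in {season}/{location}")
    if sub.groupby("line").size().max() < 2 and sub.groupby("block").size().max() < 2:
        raise ValueError("no replication in environment: repeatability not estimable")
    y = sub["value"].to_numpy(dtype=float)
    Zb, bl = indicator(sub["block"])
    Zg, gl = indicator(sub["line"])
    fit = reml(y, np.ones((len(y), 1)), {"block": (Zb, bl), "entry": (Zg, gl)},
               fixed_names=["mu"])
    s2g, s2e = fit.sigma2["entry"], fit.sigma2_e
    denom = s2g + s2e
    ratio = s2g / denom if denom > 0 else 0.0
    clamped = not (0.0 <= ratio <= 1.0)
    return VarianceDecomposition(
        components={"entry": s2g, "block": fit.sigma2["block"]},
        sigma2_e=s2e,
        ratio=float(np.clip(ratio, 0.0, 1.0)),
        ratio_name="rep2",
        n_locations=1,
        converged=fit.converged,
        loglik=fit.loglik,
        clamped=clamped,
        fit=fit,
    )


def _season_design(sub: pd.DataFrame):
    loc_block = sub["location"].astype(str) + ":" + sub["block"].astype(str)
    gxl = sub["line"].astype(str) + ":" + sub["location"].astype(str)
    Zb, bl = indicator(loc_block)
    Zgl, gll = indicator(gxl)
    return (Zb, bl), (Zgl, gll)


def adjusted_means(pheno: PhenotypeTable, trait, season) -> pd.Series:
    """Across-location adjusted means (BLUEs) per line.

    Genotype and location enter as fixed effects; block-within-location and
    genotype-by-location are random.  The reported mean for a line is its
    genotype BLUE plus the average fixed location effect, i.e. an
    lsmeans-style mean over the trial's locations.
    """
    sub = pheno.season_subset(season, trait)
    _require_rows(sub, f"{trait} in season {season}")
    locs = sub["location"].unique()
    if len(locs) < 2:
        raise ValueError("adjusted means require at least two locations")
    y = sub["value"].to_numpy(dtype=float)
    Xg, lines = indicator(sub["line"])
    Xl, loc_levels = indicator(sub["location"])
    X = np.hstack([Xg, Xl[:, 1:]])  # first location is the reference
    names = [f"g:{l}" for l in lines] + [f"loc:{l}" for l in loc_levels[1:]]
    (Zb, bl), (Zgl, gll) = _season_design(sub)
    fit = reml(y, X, {"block(loc)": (Zb, bl), "gxl": (Zgl, gll)}, fixed_names=names)
    g_hat = fit.beta[: len(lines)]
    loc_eff = np.concatenate([[0.0], fit.beta[len(lines):]])
    return pd.Series(g_hat + loc_eff.mean(), index=lines, name=f"{trait}_{season}")


def heritability(pheno: PhenotypeTable, trait, season) -> VarianceDecomposition:
    """Across-location entry-mean heritability for one season.

    All-random variant of the adjusted-means model; with L locations and one
    replicate per location, h2 = s2_g / (s2_g + s2_gxl/L + s2_e/L).
    """
    sub = pheno.season_subset(season, trait)
    _require_rows(sub, f"{trait} in season {season}")
    locs = sub["location"].unique()
    L = len(locs)
    if L < 2:
        raise ValueError(
            "heritability requires >=2 locations; use repeatability for one environment"
        )
    y = sub["value"].to_numpy(dtype=float)
    Xl, _ = indicator(sub["location"])
    X = np.hstack([np.ones((len(y), 1)), Xl[:, 1:]])
    names = ["mu"] + [f"loc:{l}" for l in np.unique(sub["location"])[1:]]
    Zg, gl = indicator(sub["line"])
    (Zb, bl), (Zgl, gll) = _season_design(sub)
    fit = reml(
        y, X,
        {"entry": (Zg, gl), "block(loc)": (Zb, bl), "gxl": (Zgl, gll)},
        fixed_names=names,
    )
    s2g = fit.sigma2["entry"]
    s2gl = fit.sigma2["gxl"]
    s2e = fit.sigma2_e
    denom = s2g + s2gl / L + s2e / L
    ratio = s2g / denom if denom > 0 else 0.0
    clamped = not (0.0 <= ratio <= 1.0)
    return VarianceDecomposition(
        components={"entry": s2g, "block(loc)": fit.sigma2["block(loc)"], "gxl": s2gl},
        sigma2_e=s2e,
        ratio=float(np.clip(ratio, 0.0, 1.0)),
        ratio_name="h2",
        n_locations=L,
        converged=fit.converged,
        loglik=fit.loglik,
        clamped=clamped,
        fit=fit,
    )


def repeatability_table(pheno: PhenotypeTable) -> pd.DataFrame:
    """rep2 for every (season, location, trait) combination with data."""
    rows = []
    r = pheno.records.dropna(subset=["value"])
    for (season, location, trait), _ in r.groupby(["season", "location", "trait"]):
        try:
            vd = repeatability(pheno, trait, season, location)
            rows.append((season, location, trait, vd.ratio, vd.converged))
        except ValueError:
            rows.append((season, location, trait, np.nan, False))
    return pd.DataFrame(rows, columns=["season", "location", "trait", "rep2", "converged"])


def heritability_table(pheno: PhenotypeTable) -> pd.DataFrame:
    """h2 per (season, trait)."""
    rows = []
    r = pheno.records.dropna(subset=["value"])
    for (season, trait), _ in r.groupby(["season", "trait"]):
        vd = heritability(pheno, trait, season)
        rows.append((season, trait, vd.ratio, vd.n_locations, vd.converged))
    return pd.DataFrame(rows, columns=["season", "trait", "h2", "n_locations", "converged"])
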