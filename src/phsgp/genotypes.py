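"""SNP genotype handling: recoding, quality control, kinship and PCA.

Dosages are stored as a dense float array with ``nan`` marking missing calls;
observed values are the minor-allele counts 0/1/2.  The genomic relationship
matrix follows VanRaden's first method,

    A = Z Z' / (2 * sum_j p_j (1 - p_j)),

with ``Z`` the dosage matrix column-centered by twice the allele frequency.
Because every column of ``Z`` sums to zero, ``A`` has zero row sums and is
positive semidefinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class EmptyPanelError(ValueError):
    """Raised when quality control removes every marker or every line."""


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with marker map and line metadata.

    Attributes
    ----------
    dosages : float array, shape (n_lines, n_markers)
        Values in {0, 1, 2} or nan for missing.
    marker_ids, chrom, pos : marker map (position is annotation only).
    line_ids : unique line identifiers.
    program : breeding-program label per line.
    set_label : cohort membership per line (CS / VS15 / VS16 / "").
    minor_coded : True once dosages count copies of the minor allele.
    """

    dosages: np.ndarray
    marker_ids: np.ndarray
    line_ids: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    program: np.ndarray | None = None
    set_label: np.ndarray | None = None
    minor_coded: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.marker_ids = np.asarray(self.marker_ids)
        self.line_ids = np.asarray(self.line_ids)
        n, m = self.dosages.shape
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("dosage shape does not match ids")
        if len(np.unique(self.marker_ids)) != m:
            raise ValueError("marker ids are not unique")
        if len(np.unique(self.line_ids)) != n:
            raise ValueError("line ids are not unique")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0/1/2 or missing")
        if self.chrom is None:
            self.chrom = np.asarray(["un"] * m)
        if self.pos is None:
            self.pos = np.arange(1, m + 1)
        if self.program is None:
            self.program = np.asarray([""] * n)
        if self.set_label is None:
            self.set_label = np.asarray([""] * n)

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per marker, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self, axis: int = 0) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=axis)

    def marker_index(self, marker_ids) -> np.ndarray:
        idx = pd.Index(self.marker_ids)
        pos = idx.get_indexer(np.atleast_1d(marker_ids))
        if (pos < 0).any():
            missing = np.atleast_1d(marker_ids)[pos < 0]
            raise KeyError(f"markers not in panel: {list(missing)}")
        return pos

    def line_index(self, line_ids) -> np.ndarray:
        idx = pd.Index(self.line_ids)
        pos = idx.get_indexer(np.atleast_1d(line_ids))
        if (pos < 0).any():
            missing = np.atleast_1d(line_ids)[pos < 0]
            raise KeyError(f"lines not in panel: {list(missing)}")
        return pos

    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given line/marker ids."""
        li = slice(None) if lines is None else self.line_index(lines)
        mi = slice(None) if markers is None else self.marker_index(markers)
        return GenotypeMatrix(
            dosages=self.dosages[li][:, mi].copy(),
            marker_ids=self.marker_ids[mi].copy(),
            line_ids=self.line_ids[li].copy(),
            chrom=self.chrom[mi].copy(),
            pos=self.pos[mi].copy(),
            program=self.program[li].copy(),
            set_label=self.set_label[li].copy(),
            minor_coded=self.minor_coded,
        )


@dataclass
class QCReport:
    """Bookkeeping of quality-control removals."""

    n_markers_in: int
    n_lines_in: int
    removed_maf: int = 0
    removed_missing: int = 0
    duplicates: int = 0
    lines_removed_missing: int = 0
    lines_removed_het: int = 0
    dropped_line_ids: list = field(default_factory=list)
    realized_mean_maf: float = float("nan")

    @property
    def n_markers_retained(self) -> int:
        return (
            self.n_markers_in
            - self.removed_maf
            - self.removed_missing
            - self.duplicates
        )

    @property
    def n_lines_retained(self) -> int:
        return self.n_lines_in - self.lines_removed_missing - self.lines_removed_het

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "markers_in",
                    "removed_maf",
                    "removed_missing",
                    "removed_duplicates",
                    "markers_retained",
                    "lines_in",
                    "lines_removed_missing",
                    "lines_removed_het",
                    "lines_retained",
                    "realized_mean_maf",
                ],
                "count": [
                    self.n_markers_in,
                    self.removed_maf,
                    self.removed_missing,
                    self.duplicates,
                    self.n_markers_retained,
                    self.n_lines_in,
                    self.lines_removed_missing,
                    self.lines_removed_het,
                    self.n_lines_retained,
                    self.realized_mean_maf,
                ],
            }
        )


@dataclass
class RelationshipMatrix:
    """VanRaden genomic relationship matrix with its construction metadata."""

    values: np.ndarray
    line_ids: np.ndarray
    p: np.ndarray
    denominator: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = np.asarray(self.line_ids)

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def submatrix(self, rows, cols=None) -> np.ndarray:
        """Kinship block A[rows, cols] addressed by line ids."""
        idx = pd.Index(self.line_ids)
        ri = idx.get_indexer(np.atleast_1d(rows))
        ci = ri if cols is None else idx.get_indexer(np.atleast_1d(cols))
        if (ri < 0).any() or (np.atleast_1d(ci) < 0).any():
            raise KeyError("line ids not present in relationship matrix")
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


def recode_minor_allele(g: GenotypeMatrix) -> GenotypeMatrix:
    """Orient every marker so dosage counts copies of the minor allele.

    A marker whose counted-allele frequency exceeds 0.5 is flipped
    (dosage -> 2 - dosage).  Markers at exactly 0.5 are left unchanged,
    which makes the operation idempotent.
    """
    p = g.allele_freq()
    flip = p > 0.5
    dos = g.dosages.copy()
    dos[:, flip] = 2.0 - dos[:, flip]
    return replace(g, dosages=dos, minor_coded=True)


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing: float = 0.05,
    line_max_missing: float = 0.20,
    line_max_het: float = 0.125,
) -> tuple[GenotypeMatrix, QCReport]:
    """Quality control for a recoded dosage matrix.

    Lines are dropped first (missing fraction > ``line_max_missing`` or
    heterozygosity > ``line_max_het``, the proxy for residual heterogeneity
    in inbred material).  Markers are then retained when MAF > ``maf_min``
    (strict), missing fraction < ``max_missing`` (strict), and exactly
    duplicated dosage columns are collapsed to the lexicographically first
    marker id, so the retained set does not depend on column order.
    """
    report = QCReport(n_markers_in=g.n_markers, n_lines_in=g.n_lines)

    line_miss = g.missing_fraction(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.nanmean(g.dosages == 1.0, axis=1)
    bad_miss = line_miss > line_max_missing
    bad_het = (~bad_miss) & (het > line_max_het)
    report.lines_removed_missing = int(bad_miss.sum())
    report.lines_removed_het = int(bad_het.sum())
    report.dropped_line_ids = list(g.line_ids[bad_miss | bad_het])
    keep_lines = ~(bad_miss | bad_het)
    if not keep_lines.any():
        raise EmptyPanelError("all lines removed by quality control")
    sub = g.subset(lines=g.line_ids[keep_lines])

    maf = sub.maf()
    miss = sub.missing_fraction(axis=0)
    ok = (maf > maf_min) & (miss < max_missing)
    report.removed_maf = int((~(maf > maf_min)).sum())
    report.removed_missing = int(((maf > maf_min) & ~(miss < max_missing)).sum())

    # Duplicate columns: exact equality including the missingness pattern.
    # Representative = smallest marker id, so the outcome is order-independent.
    keep = np.zeros(sub.n_markers, dtype=bool)
    cols = {}
    order = np.argsort(sub.marker_ids.astype(str), kind="stable")
    for j in order:
        if not ok[j]:
            continue
        key = sub.dosages[:, j].tobytes()
        if key in cols:
            report.duplicates += 1
        else:
            cols[key] = j
            keep[j] = True
    if not keep.any():
        raise EmptyPanelError("all markers removed by quality control")

    out = sub.subset(markers=sub.marker_ids[keep])
    report.realized_mean_maf = float(np.mean(out.maf()))
    return out, report


def impute_missing(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls with draws from Binomial(2, p_hat) per marker.

    ``p_hat`` is the counted-allele frequency among observed calls.  The fill
    is deterministic for a given seed; a marker with no observed calls is an
    error.  A matrix without missing values is returned unchanged.
    """
    miss = np.isnan(g.dosages)
    if not miss.any():
        return g
    if miss.all(axis=0).any():
        bad = g.marker_ids[miss.all(axis=0)]
        raise ValueError(f"markers with all calls missing: {list(bad)}")
    rng = np.random.default_rng(seed)
    p = g.allele_freq()
    dos = g.dosages.copy()
    rows, cols = np.nonzero(miss)
    dos[rows, cols] = rng.binomial(2, p[cols]).astype(float)
    return replace(g, dosages=dos)


def vanraden_grm(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix A = ZZ' / (2 * sum p(1-p)).

    Requires a complete (no-missing) matrix with at least two polymorphic
    markers.  Column ``j`` of ``Z`` is the dosage column centered by ``2 p_j``
    with ``p_j`` the counted-allele frequency estimated from the input.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("relationship matrix requires a complete matrix; impute first")
    p = g.allele_freq()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers")
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("zero VanRaden denominator: all markers monomorphic")
    Z = g.dosages - 2.0 * p
    A = (Z @ Z.T) / denom
    A = 0.5 * (A + A.T)
    return RelationshipMatrix(values=A, line_ids=g.line_ids.copy(), p=p, denominator=denom)


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_fraction: np.ndarray
    line_ids: np.ndarray


def pca(g: GenotypeMatrix, k: int = 2) -> PCAResult:
    """PCA of the column-centered dosage matrix.

    Returns line scores for the first ``k`` components and the fraction of
    total (genetic) variance each explains.  ``k`` beyond the matrix rank is
    an error rather than a silent truncation.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("PCA requires a complete matrix; impute first")
    if g.n_lines < k + 1:
        raise ValueError("need at least k+1 lines")
    Z = g.dosages - g.dosages.mean(axis=0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    tol = s[0] * max(Z.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    var = s**2
    frac = var[:k] / var.sum()
    return PCAResult(
        scores=U[:, :k] * s[:k],
        explained_fraction=frac,
        line_ids=g.line_ids.copy(),
    )
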