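"""Differential-expression engines and DEG selection rules.

Three engines share one result schema (a per-gene table with ``log2fc``,
``p_value``, ``q_value``, ``cd_score``, ``cd_sign``):

* :func:`two_sample_test` — per-gene Welch t-test on log-scale values, the
  generic stand-in for package-based bulk DE.
* :func:`characteristic_direction` — a multivariate DE score: the unit normal
  of a shrinkage-regularized linear-discriminant hyperplane separating the two
  groups.  A gene's score is its squared component of that unit vector, so
  scores sum to one and the uniform model assigns 1/n to each of n genes.
* :func:`two_part_zero_inflated_test` — single-cell DE combining a Fisher
  exact test on the zero/non-zero pattern with a Wilcoxon rank-sum test on the
  non-zero values (Fisher's method, chi-square with 4 df).

Selection follows the screen's rules: fold change > 2 and p < 0.01 for the
per-gene engines, and characteristic score above the uniform model 1/n (with
positive orientation for induced genes) for the multivariate engine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signatures import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ContrastSpec",
    "normalize_counts",
    "two_sample_test",
    "characteristic_direction",
    "two_part_zero_inflated_test",
    "select_degs",
]

DEG_COLUMNS = ["log2fc", "p_value", "q_value", "cd_score", "cd_sign"]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
        Raw counts when ``scale='count'``, log2 values otherwise.
    sample_meta
        DataFrame indexed by sample id; must contain a ``population`` column
        (``tissue``/``condition``/``replicate`` optional).
    scale
        ``'count'`` or ``'log-intensity'``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "count"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if "population" not in self.sample_meta.columns:
            raise ValueError("sample_meta must have a 'population' column")
        if not self.values.columns.equals(self.sample_meta.index):
            if set(self.values.columns) != set(self.sample_meta.index):
                raise ValueError("sample ids in values and sample_meta disagree")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.scale not in ("count", "log-intensity"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "count":
            vals = self.values.to_numpy()
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_of(self, populations: str | list[str]) -> list[str]:
        if isinstance(populations, str):
            populations = [populations]
        mask = self.sample_meta["population"].isin(populations)
        return list(self.sample_meta.index[mask])


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison: test population(s) vs reference population(s)."""

    test_group: str | tuple[str, ...]
    reference_group: str | tuple[str, ...]
    engine: str = "two-sample"
    direction: str = "up"

    def __post_init__(self) -> None:
        t = {self.test_group} if isinstance(self.test_group, str) else set(self.test_group)
        r = (
            {self.reference_group}
            if isinstance(self.reference_group, str)
            else set(self.reference_group)
        )
        if not t or not r or t & r:
            raise ValueError("test and reference groups must be disjoint and non-empty")
        if self.engine not in ("two-sample", "characteristic-direction", "two-part-zero-inflated"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def label(self) -> str:
        def j(x):  # noqa: ANN001
            return x if isinstance(x, str) else "+".join(x)

        return f"{j(self.test_group)}_vs_{j(self.reference_group)}[{self.engine}]"


def _split(mat: ExpressionMatrix, contrast: ContrastSpec) -> tuple[np.ndarray, np.ndarray]:
    test_cols = mat.samples_of(list(np.atleast_1d(contrast.test_group)))
    ref_cols = mat.samples_of(list(np.atleast_1d(contrast.reference_group)))
    if not test_cols or not ref_cols:
        raise ValueError(f"contrast {contrast.label}: empty test or reference group")
    return mat.values[test_cols].to_numpy(float), mat.values[ref_cols].to_numpy(float)


def _result(index: pd.Index, engine: str, **cols: np.ndarray) -> pd.DataFrame:
    out = pd.DataFrame(index=index, columns=DEG_COLUMNS, dtype=float)
    for k, v in cols.items():
        out[k] = v
    out.attrs["engine"] = engine
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; total-count fallback when undefined.

    The reference profile is the per-gene geometric mean over samples of genes
    with all-positive counts; each sample's factor is the median ratio to that
    reference.  When no gene is positive in every sample the factor is the
    sample's total count divided by the geometric mean of totals.  Factors are
    returned on the geometric-mean-one scale; only ratios matter downstream.
    """
    vals = counts.to_numpy(float)
    totals = vals.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[totals == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    all_pos = (vals > 0).all(axis=1)
    if all_pos.any():
        logref = np.log(vals[all_pos]).mean(axis=1)
        sf = np.exp(np.median(np.log(vals[all_pos]) - logref[:, None], axis=0))
    else:
        logger.info("size_factors: median-of-ratios undefined; total-count fallback")
        sf = totals
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Depth-normalize counts and move to log2 scale.

    Each sample is divided by its size factor (:func:`size_factors`), then
    ``log2(x + pseudocount)`` is applied.  Metadata is preserved and the
    result's scale is ``'log-intensity'``.
    """
    if mat.scale != "count":
        raise ValueError("normalize_counts expects a count-scale matrix")
    sf = size_factors(mat.values)
    norm = np.log2(mat.values / sf + pseudocount)
    return ExpressionMatrix(norm, mat.sample_meta.copy(), scale="log-intensity")


def two_sample_test(mat: ExpressionMatrix, contrast: ContrastSpec) -> pd.DataFrame:
    """Per-gene Welch t-test on log-scale values.

    ``log2fc`` is mean(test) - mean(reference); p-values are two-sided with
    Welch–Satterthwaite degrees of freedom; ``q_value`` is Benjamini–Hochberg
    within the contrast.  Degenerate genes (zero variance in both groups) get
    p = 1 when the means agree and the machine-minimum p when they differ.
    """
    if mat.scale != "log-intensity":
        raise ValueError("two_sample_test expects log-scale values; run normalize_counts first")
    x, y = _split(mat, contrast)
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(p, float)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    p[(degenerate | ~np.isfinite(p)) & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = np.finfo(float).tiny
    q = multipletests(p, method="fdr_bh")[1]
    return _result(mat.gene_ids, "two-sample", log2fc=log2fc, p_value=p, q_value=q)


def characteristic_direction(
    mat: ExpressionMatrix, contrast: ContrastSpec, shrinkage: float = 0.5
) -> pd.DataFrame:
    """Multivariate differential-expression direction (regularized LDA normal).

    The direction is ``b ∝ (γI + (1-γ)Σ̂)⁻¹ (μ_test − μ_ref)`` with Σ̂ the
    pooled within-group sample covariance and γ the shrinkage weight toward
    the identity.  Because genes vastly outnumber samples, the solve is done
    in the orthonormal subspace spanned by the grand-mean-centered samples
    (which contains both the mean difference and all within-group deviations);
    shrinking toward the identity is rotation-invariant, so the result equals
    the full-space solution.  ``b`` is normalized to unit length and oriented
    so its inner product with the mean difference is positive: ``cd_sign > 0``
    means induced in the test group.  ``cd_score = b_i²`` sums to 1.
    """
    if mat.scale != "log-intensity":
        raise ValueError("characteristic_direction expects log-scale values")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    x, y = _split(mat, contrast)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    data = np.hstack([x, y])
    delta = x.mean(axis=1) - y.mean(axis=1)

    centered = data - data.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    keep = s > s.max() * 1e-10 if s.size and s.max() > 0 else np.zeros(s.shape, bool)
    basis = u[:, keep]  # genes x r, orthonormal

    z = basis.T @ data  # r x n
    z1, z2 = z[:, :n1], z[:, n1:]
    dev = np.hstack([z1 - z1.mean(axis=1, keepdims=True), z2 - z2.mean(axis=1, keepdims=True)])
    sigma = dev @ dev.T / (n1 + n2 - 2)
    gamma = shrinkage
    reg = gamma * np.eye(sigma.shape[0]) + (1.0 - gamma) * sigma
    delta_z = basis.T @ delta
    try:
        b_z = np.linalg.solve(reg, delta_z)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance with shrinkage=0; use a positive shrinkage"
        ) from exc
    b = basis @ b_z
    norm = np.linalg.norm(b)
    if norm == 0:
        b = np.zeros_like(delta)
        score = np.zeros_like(delta)
        sign = np.zeros_like(delta)
    else:
        b = b / norm
        if float(b @ delta) < 0:
            b = -b
        score = b**2
        sign = np.sign(b)
    out = _result(
        mat.gene_ids, "characteristic-direction", log2fc=delta, cd_score=score, cd_sign=sign
    )
    return out


def two_part_zero_inflated_test(mat: ExpressionMatrix, contrast: ContrastSpec) -> pd.DataFrame:
    """Two-part single-cell DE test (zero pattern + non-zero magnitudes).

    Part 1 is a two-sided Fisher exact test on the 2x2 zero/non-zero table;
    part 2 a two-sided Wilcoxon rank-sum on depth-normalized non-zero values.
    The parts are combined by Fisher's method (chi-square, 4 df); if one part
    is undefined (a group with no non-zero cells) the other part's p stands
    alone.  ``log2fc`` compares normalized group means with a pseudocount.
    """
    if mat.scale != "count":
        raise ValueError("two_part_zero_inflated_test expects raw counts")
    test_cols = mat.samples_of(list(np.atleast_1d(contrast.test_group)))
    ref_cols = mat.samples_of(list(np.atleast_1d(contrast.reference_group)))
    if not test_cols or not ref_cols:
        raise ValueError("a contrast group has zero cells")
    x = mat.values[test_cols].to_numpy(float)
    y = mat.values[ref_cols].to_numpy(float)

    # library-size normalization to the median depth; zero pattern unaffected
    totals = np.concatenate([x.sum(axis=0), y.sum(axis=0)])
    ref_depth = np.median(totals[totals > 0])
    xn = x / np.where(x.sum(axis=0) > 0, x.sum(axis=0), 1.0) * ref_depth
    yn = y / np.where(y.sum(axis=0) > 0, y.sum(axis=0), 1.0) * ref_depth

    n_genes = x.shape[0]
    p_comb = np.ones(n_genes)
    log2fc = np.log2((xn.mean(axis=1) + 1.0) / (yn.mean(axis=1) + 1.0))
    for i in range(n_genes):
        nz1 = int((x[i] > 0).sum())
        nz2 = int((y[i] > 0).sum())
        table = [[nz1, x.shape[1] - nz1], [nz2, y.shape[1] - nz2]]
        p1 = float(stats.fisher_exact(table, alternative="two-sided")[1])
        vals1 = xn[i][x[i] > 0]
        vals2 = yn[i][y[i] > 0]
        if vals1.size and vals2.size:
            p2 = float(stats.ranksums(vals1, vals2).pvalue)
            chi = -2.0 * (np.log(max(p1, 1e-300)) + np.log(max(p2, 1e-300)))
            p_comb[i] = float(stats.chi2.sf(chi, df=4))
        else:
            p_comb[i] = p1
    q = multipletests(p_comb, method="fdr_bh")[1]
    return _result(mat.gene_ids, "two-part-zero-inflated", log2fc=log2fc, p_value=p_comb, q_value=q)


def select_degs(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    cd_rule: str = "uniform",
    direction: str = "both",
    name: str | None = None,
) -> GeneSet:
    """Apply the screen's DEG selection rules to one contrast's results.

    For the per-gene engines a gene is kept when its fold change exceeds
    ``fc_threshold`` on the requested side (``|log2fc| > log2(fc_threshold)``
    for ``direction='both'``) and ``p_value < p_threshold``.  For the
    characteristic-direction engine a gene is kept when its squared component
    exceeds the uniform model 1/n (n = genes tested); with ``direction='up'``
    only positively oriented (induced) genes are kept.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    engine = records.attrs.get("engine", "two-sample")
    if records.empty:
        warnings.warn("select_degs: empty record table", stacklevel=2)
        return GeneSet(name or "degs", frozenset(), ("select", engine, direction))
    if engine == "characteristic-direction":
        cutoff = 1.0 / len(records)
        keep = records["cd_score"] > cutoff
        if direction == "up":
            keep &= records["cd_sign"] > 0
        elif direction == "down":
            keep &= records["cd_sign"] < 0
    else:
        lfc = records["log2fc"]
        log_thresh = np.log2(fc_threshold)
        if direction == "up":
            keep = lfc > log_thresh
        elif direction == "down":
            keep = lfc < -log_thresh
        else:
            keep = lfc.abs() > log_thresh
        keep &= records["p_value"] < p_threshold
    ids = frozenset(records.index[keep.fillna(False)])
    prov = ("select", engine, f"fc>{fc_threshold}", f"p<{p_threshold}", direction)
    return GeneSet(name or "degs", ids, prov)
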