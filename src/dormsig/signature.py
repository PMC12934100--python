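"""Composite dormancy scoring and data-driven signature derivation.

The dormancy score contrasts, per sample, the summed z-scores of the
up-regulated signature genes (``U``) against the down-regulated ones
(``D``)::

    S = (U - D) / (|U| + |D|)        (S = 0 when U = D = 0)

so S always lies in [-1, +1]: +1 marks a fully dormant-like profile, -1 a
fully proliferative one, and zero is the decision boundary (S > 0 is
classified dormant).  z-scores are computed per gene across the cohort
being scored, on log2(TPM + 1), with the sample standard deviation (n-1).

Signature re-derivation mirrors the discovery procedure: a nonparametric
(Wilcoxon rank-sum) differential-expression filter with Bonferroni
correction, followed by a PCA over the passing genes in which the
component most correlated with the phenotype labels ranks genes by
absolute loading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .simulate import DORMANT, PROLIFERATIVE

__all__ = [
    "GeneSignature",
    "AUCResult",
    "default_signature",
    "log_transform",
    "zscore_genes",
    "dormancy_score",
    "roc_auc",
    "rank_de_genes",
    "select_discriminative_genes",
    "summarize_single_cell",
]


@dataclass(frozen=True)
class GeneSignature:
    """Ordered up- and down-regulated gene sets defining the composite score."""

    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.up or not self.down:
            raise ValueError("both up and down gene sets must be non-empty")
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets must be disjoint")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.up) + tuple(self.down)

    def swapped(self) -> "GeneSignature":
        return GeneSignature(up=tuple(self.down), down=tuple(self.up))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"up": list(self.up), "down": list(self.down)}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneSignature":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(up=tuple(d["up"]), down=tuple(d["down"]))


def default_signature() -> GeneSignature:
    """The packaged eight-gene melanoma dormancy signature."""
    text = resources.files("dormsig.data").joinpath("signature.json").read_text()
    d = json.loads(text)
    return GeneSignature(up=tuple(d["up"]), down=tuple(d["down"]))


@dataclass(frozen=True)
class AUCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def _validate_expression(m: pd.DataFrame) -> None:
    if m.index.has_duplicates:
        raise ValueError("duplicate gene identifiers")
    if m.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    values = m.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1), elementwise."""
    _validate_expression(m)
    return np.log2(m.astype(float) + 1.0)


def zscore_genes(m: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores across samples (sample sd, divisor n-1).

    Constant genes are mapped to all-zero rows rather than NaN; their ids
    are returned as the second element so callers can warn about them.
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = m.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd[degenerate] = 1.0
    z = (values - mean) / sd
    z[degenerate, :] = 0.0
    zdf = pd.DataFrame(z, index=m.index, columns=m.columns)
    return zdf, list(m.index[degenerate])


def dormancy_score(
    z: pd.DataFrame, sig: GeneSignature, allow_missing: bool = False
) -> pd.DataFrame:
    """Per-sample ScoreTable with columns U, D, score and label.

    Raises if a signature gene is absent unless ``allow_missing``, in which
    case missing genes are dropped and listed in ``result.attrs["missing"]``.
    """
    missing = [g for g in sig.genes if g not in z.index]
    if missing and not allow_missing:
        raise ValueError(f"signature genes missing from matrix: {missing}")
    up = [g for g in sig.up if g in z.index]
    down = [g for g in sig.down if g in z.index]
    u = z.loc[up].sum(axis=0) if up else pd.Series(0.0, index=z.columns)
    d = z.loc[down].sum(axis=0) if down else pd.Series(0.0, index=z.columns)
    denom = u.abs() + d.abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (u - d) / denom
    s = s.where(denom > 0, 0.0)
    table = pd.DataFrame(
        {
            "U": u,
            "D": d,
            "score": s,
            "label": np.where(s > 0, DORMANT, PROLIFERATIVE),
        }
    )
    table.index.name = "sample_id"
    table.attrs["missing"] = missing
    return table


def roc_auc(scores, truth) -> AUCResult:
    """ROC by threshold sweep over the score; AUC by the trapezoid rule.

    Ties receive half credit, so the AUC equals the Mann-Whitney U
    statistic divided by n1*n2.  ``scores`` may be a ScoreTable (its
    ``score`` column is used) or any per-sample numeric sequence; ``truth``
    holds the reference labels with "dormant" as the positive class.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["score"]
    s = np.asarray(pd.Series(scores), dtype=float)
    y = np.asarray(pd.Series(truth).astype(str) == DORMANT, dtype=int)
    if y.min() == y.max():
        raise ValueError("both classes must be present in the truth labels")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return AUCResult(auc=float(_trapezoid_auc(fpr, tpr)), fpr=fpr, tpr=tpr)


def _split_by_label(m: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(labels).astype(str)
    labels = labels.reindex(m.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every sample in the matrix")
    groups = set(labels)
    if groups != {DORMANT, PROLIFERATIVE}:
        raise ValueError(f"labels must be exactly {{dormant, proliferative}}, got {sorted(groups)}")
    x = m.loc[:, labels == DORMANT].to_numpy(dtype=float)
    y = m.loc[:, labels == PROLIFERATIVE].to_numpy(dtype=float)
    return x, y


def rank_de_genes(m: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene on log2(TPM+1), Bonferroni adjusted.

    Exact null distribution whenever the gene has no ties and both groups
    are small (min size <= 25); the normal approximation with continuity
    correction otherwise.  Exactness matters here: small-cohort Bonferroni
    thresholds sit close to the smallest p the normal approximation can
    produce.  ``direction`` is the sign of (dormant median - proliferative
    median).  Returned sorted by raw p, ties by gene id.
    """
    logm = log_transform(m)
    x, y = _split_by_label(logm, labels)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 samples")

    n_genes = m.shape[0]
    stat = np.empty(n_genes)
    pval = np.empty(n_genes)
    exact_ok = min(n1, n2) <= 25
    for i in range(n_genes):
        xi, yi = x[i], y[i]
        combined = np.concatenate([xi, yi])
        if np.all(combined == combined[0]):
            stat[i], pval[i] = n1 * n2 / 2.0, 1.0
            continue
        has_ties = np.unique(combined).size < combined.size
        method = "exact" if exact_ok and not has_ties else "asymptotic"
        res = stats.mannwhitneyu(xi, yi, alternative="two-sided", method=method)
        stat[i], pval[i] = float(res.statistic), float(min(res.pvalue, 1.0))
    diff = np.median(x, axis=1) - np.median(y, axis=1)
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "statistic": stat,
            "p_value": pval,
            "p_bonferroni": np.minimum(pval * n_genes, 1.0),
            "direction": direction,
        },
        index=m.index,
    )
    return table.sort_index().sort_values("p_value", kind="mergesort")


def select_discriminative_genes(
    m: pd.DataFrame, labels: pd.Series, k: int = 8, alpha: float = 0.05
) -> GeneSignature:
    """Re-derive a k-gene signature from a labeled cohort.

    Genes passing the Bonferroni-adjusted Wilcoxon filter are z-scored and
    fed to a PCA over samples; the component whose scores correlate most
    (in absolute value) with the dormant/proliferative labels ranks genes
    by absolute loading.  The top-k genes are split into up/down by their
    differential-expression direction.  Ties: larger absolute loading
    first, then lexicographic gene id.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    de = rank_de_genes(m, labels)
    passing = de.index[de["p_bonferroni"] < alpha]
    if len(passing) < k:
        raise ValueError(
            f"only {len(passing)} genes pass the DE filter at adjusted p < {alpha}; need {k}"
        )
    z, _ = zscore_genes(log_transform(m.loc[passing]))
    X = z.to_numpy(dtype=float).T  # samples x genes
    labels = pd.Series(labels).astype(str).reindex(z.columns)
    y = (labels.to_numpy() == DORMANT).astype(float)
    y = y - y.mean()
    pca = PCA(n_components=min(X.shape[0], X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    with np.errstate(invalid="ignore"):
        corrs = np.array(
            [
                0.0 if np.std(scores[:, j]) == 0
                else abs(np.corrcoef(scores[:, j], y)[0, 1])
                for j in range(scores.shape[1])
            ]
        )
    best = int(np.nanargmax(corrs))
    loadings = pd.Series(np.abs(pca.components_[best]), index=passing)
    order = sorted(loadings.index, key=lambda g: (-loadings[g], g))
    chosen = order[:k]
    up = tuple(g for g in chosen if de.loc[g, "direction"] == "up")
    down = tuple(g for g in chosen if de.loc[g, "direction"] != "up")
    if not up or not down:
        raise ValueError("selected genes are all one direction; cannot form a two-sided signature")
    return GeneSignature(up=up, down=down)


def summarize_single_cell(
    cells: pd.DataFrame, cell_to_sample: pd.Series, genes=None
) -> pd.DataFrame:
    """Per (sample, gene): fraction of cells expressing and mean expression.

    The fraction counts cells with value > 0 among all cells of the sample;
    the mean includes non-expressing zeros, matching how dot-plot summaries
    of single-cell cohorts are drawn.
    """
    cell_to_sample = pd.Series(cell_to_sample)
    unmapped = cells.index.difference(cell_to_sample.index)
    if len(unmapped) > 0:
        raise ValueError(f"cells without a sample mapping: {list(unmapped[:5])}")
    if genes is not None:
        missing = [g for g in genes if g not in cells.columns]
        if missing:
            raise ValueError(f"genes absent from the cell matrix: {missing}")
        cells = cells[list(genes)]
    grouped = cells.groupby(cell_to_sample.reindex(cells.index).to_numpy())
    frac = grouped.apply(lambda df: (df > 0).mean())
    mean = grouped.mean()
    out = (
        pd.concat({"frac_expressing": frac, "mean_expression": mean}, axis=1)
        .stack(future_stack=True)
        .reset_index()
    )
    out.columns = ["sample_id", "gene_id", "frac_expressing", "mean_expression"]
    return out.sort_values(["sample_id", "gene_id"]).reset_index(drop=True)
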