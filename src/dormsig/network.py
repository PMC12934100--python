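"""Weighted co-expression network analysis from first principles.

Implements the unsigned weighted-network pipeline: soft-thresholded
adjacency a_ij = |cor(g_i, g_j)|^beta, topological overlap (TOM), module
detection by average-linkage clustering of 1 - TOM with a static cut,
module eigengenes, module-trait correlation and hub identification by
intramodular connectivity (the "central degree" of the module graph).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkParams",
    "NetworkModule",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "intramodular_connectivity",
    "hub_gene",
    "network_analysis",
]


@dataclass(frozen=True)
class NetworkParams:
    """Tunables of the weighted network stage.

    ``beta`` is the soft-threshold power (unsigned WGCNA convention,
    default 6).  ``cut_height`` is the static cut on the 1 - TOM
    dendrogram scale; small planted modules in small cohorts carry TOM
    values well below what large real networks show, so the default cut
    sits high (see the methods note).  Clusters smaller than
    ``min_module_size`` are discarded as unassigned ("grey") genes.
    """

    beta: float = 6.0
    min_module_size: int = 5
    cut_height: float = 0.985

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height must be in (0, 1]")


@dataclass
class NetworkModule:
    genes: list[str]
    connectivity: pd.Series  # intramodular k_i per gene
    eigengene: pd.Series     # one value per sample, unit norm
    hub: str
    trait_r: float | None = None
    trait_p: float | None = None


def _check_square(a: pd.DataFrame, name: str) -> None:
    if a.shape[0] != a.shape[1] or not a.index.equals(a.columns):
        raise ValueError(f"{name} must be square with matching gene labels")
    v = a.to_numpy(dtype=float)
    if not np.allclose(v, v.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if (v < -1e-12).any() or (v > 1 + 1e-12).any():
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(np.diag(v), 1.0):
        raise ValueError(f"{name} diagonal must be 1")


def adjacency(z: pd.DataFrame, params: NetworkParams | None = None) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |pearson|^beta on gene rows.

    Degenerate (constant) genes get zero off-diagonal adjacency.
    """
    params = params or NetworkParams()
    if z.shape[1] < 3:
        raise ValueError("adjacency needs at least 3 samples")
    if z.shape[0] < 2:
        raise ValueError("adjacency needs at least 2 genes")
    values = z.to_numpy(dtype=float)
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[~np.isfinite(corr)] = 0.0
    a = np.abs(np.clip(corr, -1.0, 1.0)) ** params.beta
    a[sd == 0, :] = 0.0
    a[:, sd == 0] = 0.0
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    return pd.DataFrame(a, index=z.index, columns=z.index)


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity sum_{u != i} a_iu; TOM_ii = 1.
    """
    _check_square(a, "adjacency")
    v = a.to_numpy(dtype=float)
    k = v.sum(axis=1) - 1.0
    # sum over u != i,j of a_iu a_uj: (A^2)_ij minus the u=i and u=j terms
    numerator = v @ v - 2.0 * v + v  # = A^2 - a_ij, using unit diagonal
    denominator = np.minimum.outer(k, k) + 1.0 - v
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numerator / denominator
    tom[~np.isfinite(tom)] = 0.0
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


def detect_modules(tom: pd.DataFrame, params: NetworkParams | None = None) -> list[list[str]]:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Returns gene-id lists, largest module first (ties by first gene id);
    genes in clusters smaller than ``min_module_size`` stay unassigned.
    """
    params = params or NetworkParams()
    _check_square(tom, "TOM")
    genes = list(tom.index)
    if len(genes) < params.min_module_size:
        return []
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    tree = linkage(condensed, method="average")
    assignment = fcluster(tree, t=params.cut_height, criterion="distance")
    modules: list[list[str]] = []
    for cluster_id in np.unique(assignment):
        members = sorted(g for g, c in zip(genes, assignment) if c == cluster_id)
        if len(members) >= params.min_module_size:
            modules.append(members)
    modules.sort(key=lambda mod: (-len(mod), mod[0]))
    return modules


def module_eigengene(z: pd.DataFrame, module) -> tuple[pd.Series, float]:
    """First right-singular profile of the module's z-score submatrix.

    Returns the unit-norm eigengene over samples (sign oriented so its
    correlation with the module's per-sample mean z is non-negative) and
    the share of variance it explains.
    """
    module = list(module)
    if not module:
        raise ValueError("module is empty")
    missing = [g for g in module if g not in z.index]
    if missing:
        raise ValueError(f"module genes absent from the matrix: {missing}")
    if z.shape[1] < 2:
        raise ValueError("eigengene needs at least 2 samples")
    sub = z.loc[module].to_numpy(dtype=float)
    _, s, vt = np.linalg.svd(sub, full_matrices=False)
    eig = vt[0]
    total = float((s**2).sum())
    explained = float(s[0] ** 2 / total) if total > 0 else 0.0
    mean_profile = sub.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=z.columns, name="eigengene"), explained


def module_trait_correlation(eigengene: pd.Series, trait: pd.Series) -> tuple[float, float]:
    """Pearson r between eigengene and trait, p from the t-transform."""
    eig = pd.Series(eigengene)
    trait = pd.Series(trait).reindex(eig.index)
    if trait.isna().any():
        raise ValueError("trait must cover every eigengene sample")
    n = len(eig)
    if n < 3:
        raise ValueError("correlation needs at least 3 samples")
    if np.std(trait.to_numpy(dtype=float)) == 0 or np.std(eig.to_numpy()) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(eig.to_numpy(dtype=float), trait.to_numpy(dtype=float))
    return float(r), float(p)


def intramodular_connectivity(a: pd.DataFrame, module) -> pd.Series:
    """k_i = sum of adjacency to the other module members."""
    module = list(module)
    if not module:
        raise ValueError("module is empty")
    missing = [g for g in module if g not in a.index]
    if missing:
        raise ValueError(f"module genes absent from adjacency: {missing}")
    sub = a.loc[module, module].to_numpy(dtype=float)
    k = sub.sum(axis=1) - np.diag(sub)
    return pd.Series(k, index=module, name="connectivity")


def hub_gene(a: pd.DataFrame, module) -> str:
    """Module member with maximal intramodular connectivity (ties: lexicographic)."""
    k = intramodular_connectivity(a, module)
    best = k.max()
    return min(g for g in k.index if k[g] >= best - 1e-12)


def network_analysis(
    z: pd.DataFrame,
    params: NetworkParams | None = None,
    trait: pd.Series | None = None,
) -> list[NetworkModule]:
    """Full pipeline: adjacency -> TOM -> modules -> eigengene/hub/trait stats."""
    params = params or NetworkParams()
    a = adjacency(z, params)
    tom = topological_overlap(a)
    out = []
    for genes in detect_modules(tom, params):
        eig, _ = module_eigengene(z, genes)
        k = intramodular_connectivity(a, genes)
        mod = NetworkModule(genes=genes, connectivity=k, eigengene=eig, hub=hub_gene(a, genes))
        if trait is not None:
            mod.trait_r, mod.trait_p = module_trait_correlation(eig, trait)
        out.append(mod)
    return out
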