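"""Population structure: allele-frequency PCA, IBS distances, NJ tree.

PCA standardizes each variant by its estimated allele frequency
(mean 2p̂, sd sqrt(2p̂(1-p̂)) — the Patterson/EIGENSTRAT convention) so that
drift at rare and common variants contributes comparably; missing dosages
are mean-imputed for this step only. Identity-by-state distances instead use
pairwise-complete variants: for a sample pair the similarity is the fraction
of shared alleles over jointly-called variants. The neighbor-joining tree is
the Saitou–Nei agglomeration with the Studier–Keppler Q criterion, with
deterministic tie-breaking and non-negative branch lengths.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genotype_io import MISSING, GenotypeMatrix

log = logging.getLogger("selsig")


@dataclass(frozen=True)
class PCAResult:
    """Sample coordinates and the variance fraction per component."""

    coordinates: np.ndarray  # (n_samples, n_components)
    variance_explained: np.ndarray  # fraction per returned component
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.coordinates[:, k]
                for k in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def pca(
    g: GenotypeMatrix,
    n_components: int = 10,
    scaling: str = "patterson",
) -> PCAResult:
    """Principal components of the dosage matrix.

    ``scaling`` is one of ``patterson`` (divide by sqrt(2p̂(1-p̂))),
    ``unit`` (divide by the empirical sd) or ``none`` (centering only).
    Monomorphic variants (zero sd) are dropped with a logged count.
    ``variance_explained`` covers the returned components, as eigenvalue
    fractions of the total variance across all components.
    """
    if g.n_samples < 2 or g.n_variants < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variants")
    X = g.calls.astype(float)
    X[g.calls == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)

    if scaling == "patterson":
        p = mean / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
    elif scaling == "unit":
        sd = X.std(axis=0, ddof=0)
    elif scaling == "none":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")

    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("pca: dropped %d monomorphic variants", n_dropped)
    X = (X[:, keep] - mean[keep]) / sd[keep]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic variants after filtering")

    # SVD of the centered-scaled matrix; eigenvalues of the sample covariance
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    lam = s**2
    # deterministic sign: make the largest-|loading| coordinate positive
    for k in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, k]))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
    n_components = min(n_components, len(s))
    coords = U[:, :n_components] * s[:n_components]
    var_exp = lam[:n_components] / lam.sum()
    return PCAResult(
        coordinates=coords,
        variance_explained=var_exp,
        sample_ids=list(g.samples["sample_id"]),
    )


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix in [0, 1] with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValueError("IBS distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - (shared alleles) / (2 x jointly-called variants) per sample pair.

    Shared alleles at one variant = 2 - |dosage_i - dosage_j|. A pair with no
    jointly-called variant is an error (distance undefined).
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = g.calls.astype(np.int16)
    called = calls != MISSING
    n = g.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        L = both.sum(axis=1)
        diff = np.abs(calls[i] - calls[i + 1:])
        shared = np.where(both, 2 - diff, 0).sum(axis=1)
        if (L == 0).any():
            j = int(np.flatnonzero(L == 0)[0]) + i + 1
            raise ValueError(
                "no jointly-called variants for pair "
                f"({g.samples['sample_id'].iloc[i]}, {g.samples['sample_id'].iloc[j]})"
            )
        d[i, i + 1:] = 1.0 - shared / (2.0 * L)
    d = d + d.T
    return DistanceMatrix(labels=list(g.samples["sample_id"]), d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted skbio TreeNode.

    Q(i,j) = (n-2) d(i,j) - r(i) - r(j); the minimal pair is joined, ties
    broken by the lowest (row, col) index pair. Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch. The final
    three nodes attach to one internal trifurcation (unrooted convention).
    Children are ordered by first-seen label so the Newick output is
    deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.any(dm.d < 0):
        raise ValueError("distances must be non-negative")

    D = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    order = {id(node): i for i, node in enumerate(nodes)}  # first-seen rank

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) among minima: argmin on C-ordered flat index
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        order[id(parent)] = min(order[id(nodes[i])], order[id(nodes[j])])

        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        dnew = np.delete(dnew, j)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        nodes[i] = parent
        del nodes[j]

    # final trifurcation: three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    a.length, b.length = clamp(la, lb)
    c.length = max(lc, 0.0)
    children = sorted(nodes, key=lambda nd: order[id(nd)])
    root = TreeNode(children=children)

    def sort_children(node: TreeNode) -> None:
        if node.children:
            node.children.sort(key=lambda nd: order[id(nd)])
            for ch in node.children:
                sort_children(ch)

    sort_children(root)
    return root


def write_newick(tree: TreeNode, path: str | Path) -> None:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())
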