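"""Phylogenetic covariance structure for comparative regression.

Under Brownian-motion trait evolution on a phylogeny, the expected
covariance between two species' residuals is proportional to the branch
length they share from the root to their most recent common ancestor.
Pagel's lambda scales the off-diagonal (shared) part of this matrix:
lambda = 1 is pure Brownian structure, lambda = 0 a star phylogeny
(independent species).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .io_core import normalize_species_id


def tree_covariance(tree: dendropy.Tree, taxa: list[str] | None = None) -> pd.DataFrame:
    """Brownian covariance matrix C with C_ij = shared root-to-MRCA length.

    ``taxa`` fixes the row/column order (normalized species ids);
    defaults to sorted tip labels.
    """
    pdm = tree.phylogenetic_distance_matrix()
    label_of = {t: normalize_species_id(t.label) for t in tree.taxon_namespace if t.label}
    tips = {}
    tree.calc_node_root_distances()
    for leaf in tree.leaf_node_iter():
        tips[label_of[leaf.taxon]] = (leaf.taxon, leaf.root_distance)
    order = taxa if taxa is not None else sorted(tips)
    missing = [t for t in order if t not in tips]
    if missing:
        raise ValueError(f"taxa not on tree: {missing}")
    n = len(order)
    C = np.zeros((n, n))
    for i, a in enumerate(order):
        ta, da = tips[a]
        C[i, i] = da
        for j in range(i + 1, n):
            tb, db = tips[order[j]]
            shared = 0.5 * (da + db - pdm.patristic_distance(ta, tb))
            C[i, j] = C[j, i] = max(shared, 0.0)
    return pd.DataFrame(C, index=order, columns=order)


def scale_lambda(C: pd.DataFrame | np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal covariances by Pagel's lambda in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    A = np.asarray(C, dtype=float)
    out = lam * A
    np.fill_diagonal(out, np.diag(A))
    return out


def phylo_covariance(
    tree: dendropy.Tree, lam: float = 1.0, taxa: list[str] | None = None
) -> pd.DataFrame:
    """Lambda-scaled phylogenetic covariance, validated positive-definite."""
    C = tree_covariance(tree, taxa)
    V = scale_lambda(C, lam)
    try:
        np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    except np.linalg.LinAlgError:
        raise ValueError("phylogenetic covariance is not positive-definite") from None
    return pd.DataFrame(V, index=C.index, columns=C.columns)
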