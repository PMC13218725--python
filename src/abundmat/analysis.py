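"""Downstream analyses of substitution matrices.

Hierarchical clustering of matrix rows/columns, PCA of concatenated
to/from substitution profiles, correlation of the helix matrix with helix
propensity scales, and the analysis of loop residues adopting left-handed
helix-like backbone conformations.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from ._aa import AA_ORDER
from .matrices import SubstitutionMatrix, _matrix_from_records

#: Ramachandran window associated with left-handed helix formation (degrees,
#: open intervals).
LEFTHANDED_PHI = (0.0, 180.0)
LEFTHANDED_PSI = (-90.0, 90.0)


def _filled(m: SubstitutionMatrix) -> np.ndarray:
    """Matrix with synonymous cells set to 1.0 and missing cells imputed.

    Missing off-diagonal cells are imputed with the row mean of defined
    cells; counts on the original matrix let users judge the imputation.
    """
    x = m.mean.copy()
    np.fill_diagonal(x, 1.0)
    for i in range(20):
        row = x[i]
        missing = np.isnan(row)
        if missing.all():
            raise ValueError(f"row {m.aa_order[i]} is entirely missing")
        row[missing] = np.nanmean(row)
    return x


def cluster_matrix(m: SubstitutionMatrix) -> dict:
    """Average-linkage (Euclidean) clustering along both matrix axes.

    Rows are the mutation-from profiles and columns the mutation-to
    profiles.  Returns both linkage matrices, the deterministic leaf
    orders, and newick strings of the two dendrograms.
    """
    x = _filled(m)
    out = {}
    for axis, data in (("rows", x), ("columns", x.T)):
        link = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
        order = hierarchy.leaves_list(link)
        tree = hierarchy.to_tree(link)
        out[axis] = {
            "linkage": link,
            "order": [m.aa_order[i] for i in order],
            "newick": _to_newick(tree, m.aa_order),
        }
    return out


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    return f"({left},{right}):{node.dist:.6g}"


def profile_vectors(m: SubstitutionMatrix) -> pd.DataFrame:
    """20x40 table: per amino acid the 20 from-profile then 20 to-profile
    means, with synonymous slots set exactly to 1.0 and missing cells
    imputed row-/column-wise."""
    x = _filled(m)
    data = np.hstack([x, x.T])
    return pd.DataFrame(data, index=list(m.aa_order))


def pca_profiles(m: SubstitutionMatrix, n_components: int | None = None) -> dict:
    """Centred (unscaled) PCA of the 20x40 concatenated profiles.

    Returns per-amino-acid component scores and explained-variance ratios.
    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive (PCA signs are otherwise arbitrary).
    """
    vec = profile_vectors(m)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(vec.to_numpy())
    flip = np.sign(
        pca.components_[np.arange(pca.components_.shape[0]),
                        np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    components = pca.components_ * flip[:, None]
    return {
        "scores": pd.DataFrame(
            scores, index=list(m.aa_order),
            columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "components": components,
        "mean": pca.mean_,
    }


def load_propensity_scales(path=None) -> pd.DataFrame:
    """Helix propensity scales (kcal/mol relative to alanine), one column
    per scale, indexed by amino acid."""
    if path is None:
        ref = importlib.resources.files("abundmat") / "data" / "helix_propensity.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    return table.set_index("aa")


def propensity_matrix(scale: pd.Series) -> np.ndarray:
    """P_ij = ddg_i - ddg_j: helix-propensity substitution matrix.

    A substitution from a poor helix former (high ddG) to a good one gives
    a positive entry; antisymmetric by construction.
    """
    vals = np.array([float(scale[a]) for a in AA_ORDER])
    return vals[:, None] - vals[None, :]


def helix_propensity_correlation(
    m_helix_alpha_only: SubstitutionMatrix, scale: pd.Series
) -> dict:
    """Pearson r between an alpha-helix-only abundance matrix and a
    propensity-difference matrix, over defined off-diagonal cells."""
    p = propensity_matrix(scale)
    a = m_helix_alpha_only.mean
    off = ~np.eye(20, dtype=bool)
    ok = off & np.isfinite(a)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 defined paired cells")
    pa, aa = p[ok], a[ok]
    if np.std(pa) == 0 or np.std(aa) == 0:
        return {"r": np.nan, "n_cells": int(ok.sum()), "degenerate": True}
    r = float(np.corrcoef(pa, aa)[0, 1])
    return {"r": r, "n_cells": int(ok.sum()), "degenerate": False}


def select_lefthanded_loops(features: pd.DataFrame) -> pd.DataFrame:
    """Loop residues in the left-handed-helix Ramachandran window.

    Requires ss3 == loop, 0 < phi < 180, -90 < psi < 90 (open intervals)
    and crystal_resolved (predicted-only conformations are excluded).
    """
    f = features
    mask = (
        (f["ss3"] == "loop")
        & (f["phi"] > LEFTHANDED_PHI[0]) & (f["phi"] < LEFTHANDED_PHI[1])
        & (f["psi"] > LEFTHANDED_PSI[0]) & (f["psi"] < LEFTHANDED_PSI[1])
        & f["crystal_resolved"].astype(bool)
    )
    return f[mask]


def lefthanded_loop_analysis(pool: pd.DataFrame, features: pd.DataFrame) -> dict:
    """Substitution statistics of left-handed-helix-like loop residues.

    Builds the mean-score matrix restricted to the selected residues and
    summarises, per variant amino acid, the mean score across all wild-type
    types (with standard deviations), plus per-wild-type residue counts.
    """
    sel = select_lefthanded_loops(features)
    if sel.empty:
        raise ValueError("no left-handed-helix-like loop residues selected")
    keys = ["protein", "chain", "position"]
    sub = pool.merge(sel[keys], on=keys, how="inner")
    if sub.empty:
        raise ValueError("selected residues have no pooled scores")
    matrix = _matrix_from_records(sub, env="loop-lefthanded", scheme="custom-subset")
    col_means = sub.groupby("var")["score"].agg(["mean", "std", "count"])
    col_means = col_means.reindex(list(AA_ORDER))
    residue_counts = (
        sel.groupby("wt")["position"].count().reindex(list(AA_ORDER)).fillna(0).astype(int)
    )
    return {
        "matrix": matrix,
        "per_variant_aa": col_means,
        "per_wt_residue_counts": residue_counts,
        "n_residues": len(sel),
    }
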