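"""Environment-conditional 20x20 substitution matrices of mean abundance.

Each matrix cell holds the arithmetic mean of all abundance scores observed
for one wild-type -> variant amino-acid pair among residues belonging to one
structural environment (Eq.-style group mean); a parallel count matrix
records how many scores contributed to each cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._aa import AA_ORDER, AA_INDEX
from .structure import RASA_CUTOFF

SCHEMES = ("global", "exposure", "secondary", "combined")

_SCHEME_LABELS = {
    "global": ["all"],
    "exposure": ["buried", "exposed"],
    "secondary": ["helix", "strand", "loop"],
    "combined": [
        "buried-helix", "buried-strand", "buried-loop",
        "exposed-helix", "exposed-strand", "exposed-loop",
    ],
}


def classify_residue(
    rasa: float | np.ndarray,
    wcn: float | np.ndarray = 0.0,
    c_rasa: float = RASA_CUTOFF,
    c_wcn: float = 0.0,
):
    """Two-class burial call: buried iff rasa <= c_rasa AND wcn >= c_wcn.

    With the default ``c_wcn = 0`` the call reduces to the pure-rASA rule
    (every WCN is >= 0), which is the classification used throughout except
    in the cutoff grid search.  Vectorised; returns 'buried'/'exposed'.
    """
    rasa = np.asarray(rasa, dtype=float)
    wcn = np.broadcast_to(np.asarray(wcn, dtype=float), rasa.shape)
    buried = (rasa <= c_rasa) & (wcn >= c_wcn)
    out = np.where(buried, "buried", "exposed")
    return out if out.ndim else str(out)


def environment_labels(
    features: pd.DataFrame,
    scheme: str,
    c_rasa: float = RASA_CUTOFF,
    c_wcn: float = 0.0,
) -> pd.Series:
    """Per-residue environment label under a scheme.

    The labels of a scheme partition the residues: every residue gets
    exactly one label.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "global":
        lab = pd.Series("all", index=features.index)
    elif scheme == "exposure":
        lab = pd.Series(
            classify_residue(features["rasa"].to_numpy(),
                             features["wcn"].to_numpy(), c_rasa, c_wcn),
            index=features.index,
        )
    elif scheme == "secondary":
        lab = features["ss3"].astype(str)
    else:  # combined
        exp = classify_residue(features["rasa"].to_numpy(),
                               features["wcn"].to_numpy(), c_rasa, c_wcn)
        lab = pd.Series(exp, index=features.index) + "-" + features["ss3"].astype(str)
    return lab.rename("env")


@dataclass
class SubstitutionMatrix:
    """20x20 mean-abundance matrix with parallel counts.

    Rows index the wild-type residue, columns the variant residue, both in
    the fixed alphabetical order ``aa_order``.  Diagonal (synonymous) cells
    are structurally missing (NaN mean, zero count); missing off-diagonal
    cells (no observations) are NaN with zero count.
    """

    env: str
    mean: np.ndarray
    count: np.ndarray
    scheme: str = "global"
    aa_order: tuple[str, ...] = field(default=AA_ORDER)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.count = np.asarray(self.count, dtype=np.int64)
        if self.mean.shape != (20, 20) or self.count.shape != (20, 20):
            raise ValueError("substitution matrices must be 20x20")
        empty = self.count == 0
        if not np.isnan(self.mean[empty]).all():
            raise ValueError("cells with zero count must have NaN mean")

    def cell(self, wt: str, var: str) -> float:
        return float(self.mean[AA_INDEX[wt], AA_INDEX[var]])

    @property
    def n_scores(self) -> int:
        return int(self.count.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean, index=list(self.aa_order),
                            columns=list(self.aa_order))

    def count_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.count, index=list(self.aa_order),
                            columns=list(self.aa_order))


def _pool_with_env(
    pool: pd.DataFrame,
    features: pd.DataFrame,
    scheme: str,
    c_rasa: float,
    c_wcn: float,
) -> pd.DataFrame:
    feats = features.copy()
    feats["env"] = environment_labels(feats, scheme, c_rasa, c_wcn)
    keys = ["protein", "chain", "position"]
    merged = pool.merge(feats[keys + ["env"]], on=keys, how="inner")
    return merged


def build_matrix(
    pool: pd.DataFrame,
    features: pd.DataFrame,
    env: str,
    scheme: str = "global",
    exclude_proteins: set[str] | frozenset[str] = frozenset(),
    c_rasa: float = RASA_CUTOFF,
    c_wcn: float = 0.0,
) -> SubstitutionMatrix:
    """Mean-score matrix for one environment label.

    Averages all scores whose wild-type residue carries the environment
    label ``env`` under ``scheme`` and whose protein is not excluded.
    """
    if env not in _SCHEME_LABELS[scheme]:
        raise ValueError(f"label {env!r} not in scheme {scheme!r}")
    merged = _pool_with_env(pool, features, scheme, c_rasa, c_wcn)
    sub = merged[(merged["env"] == env)
                 & ~merged["protein"].isin(list(exclude_proteins))]
    return _matrix_from_records(sub, env, scheme)


def _matrix_from_records(records: pd.DataFrame, env: str, scheme: str) -> SubstitutionMatrix:
    wt_idx = records["wt"].map(AA_INDEX).to_numpy(dtype=np.intp)
    var_idx = records["var"].map(AA_INDEX).to_numpy(dtype=np.intp)
    flat = wt_idx * 20 + var_idx
    count = np.bincount(flat, minlength=400).reshape(20, 20)
    total = np.bincount(flat, weights=records["score"].to_numpy(float),
                        minlength=400).reshape(20, 20)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return SubstitutionMatrix(env=env, mean=mean, count=count, scheme=scheme)


def build_matrix_set(
    pool: pd.DataFrame,
    features: pd.DataFrame,
    scheme: str,
    exclude_proteins: set[str] | frozenset[str] = frozenset(),
    c_rasa: float = RASA_CUTOFF,
    c_wcn: float = 0.0,
) -> dict[str, SubstitutionMatrix]:
    """All matrices of a scheme (1, 2, 3 or 6 matrices).

    The scheme's environment labels partition the residues, so summed
    counts over the returned matrices equal the number of pooled records
    whose residues have features.
    """
    merged = _pool_with_env(pool, features, scheme, c_rasa, c_wcn)
    merged = merged[~merged["protein"].isin(list(exclude_proteins))]
    return {
        env: _matrix_from_records(merged[merged["env"] == env], env, scheme)
        for env in _SCHEME_LABELS[scheme]
    }


def scheme_labels(scheme: str) -> list[str]:
    return list(_SCHEME_LABELS[scheme])


def asymmetry(m: SubstitutionMatrix) -> np.ndarray:
    """Antisymmetric part mean - mean^T; NaN where either cell is missing."""
    return m.mean - m.mean.T


def matrix_difference(a: SubstitutionMatrix, b: SubstitutionMatrix) -> np.ndarray:
    """Elementwise a.mean - b.mean; NaN where either cell is missing."""
    if a.aa_order != b.aa_order:
        raise ValueError("amino-acid orders differ between matrices")
    return a.mean - b.mean


def save_matrix(m: SubstitutionMatrix, prefix) -> None:
    """Write mean and count CSVs (``<prefix>_mean.csv``, ``<prefix>_count.csv``)."""
    m.to_frame().to_csv(f"{prefix}_mean.csv")
    m.count_frame().to_csv(f"{prefix}_count.csv")


def load_matrix(prefix, env: str = "all", scheme: str = "global") -> SubstitutionMatrix:
    mean = pd.read_csv(f"{prefix}_mean.csv", index_col=0).to_numpy(float)
    count = pd.read_csv(f"{prefix}_count.csv", index_col=0).to_numpy(int)
    return SubstitutionMatrix(env=env, mean=mean, count=count, scheme=scheme)
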