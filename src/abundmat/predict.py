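"""Abundance prediction from substitution matrices, with LOPO evaluation.

A variant's predicted abundance is the mean-score matrix cell for its
wild-type residue's structural environment and its wt -> var substitution
type.  Matrices are always rebuilt leaving out the entire dataset of the
protein being predicted (leave-one-protein-out cross-validation), so no
prediction for a protein derives from that protein's own scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._aa import AA_INDEX, AA_ORDER
from .structure import RASA_CUTOFF

_SS3_CODE = {"helix": 0, "strand": 1, "loop": 2}

#: Default cutoff grids of the burial grid search.
DEFAULT_C_RASA_GRID = tuple(np.round(np.arange(0.0, 0.5001, 0.05), 2))
DEFAULT_C_WCN_GRID = tuple(range(0, 21))


@dataclass(frozen=True)
class EvaluationResult:
    """Per-protein agreement between predictions and experiment."""

    protein_id: str
    r: float
    r_s: float
    mae: float
    n_evaluated: int
    n_missing_predictions: int


class _IndexedPool:
    """Pool joined with features, encoded as flat integer arrays.

    Precomputing the codes once makes the cutoff grid search and the
    dataset-combination analysis (hundreds of matrix rebuilds) cheap.
    """

    def __init__(self, pool: pd.DataFrame, features: pd.DataFrame):
        keys = ["protein", "chain", "position"]
        cols = keys + ["rasa", "wcn", "ss3"]
        merged = pool.merge(features[cols], on=keys, how="inner")
        self.frame = merged.reset_index(drop=True)
        self.protein = self.frame["protein"].to_numpy()
        self.proteins = sorted(self.frame["protein"].unique())
        self.wt = self.frame["wt"].map(AA_INDEX).to_numpy(dtype=np.intp)
        self.var = self.frame["var"].map(AA_INDEX).to_numpy(dtype=np.intp)
        self.score = self.frame["score"].to_numpy(float)
        self.rasa = self.frame["rasa"].to_numpy(float)
        self.wcn = self.frame["wcn"].to_numpy(float)
        self.ss3 = self.frame["ss3"].map(_SS3_CODE).to_numpy(dtype=np.intp)
        self.pair = self.wt * 20 + self.var

    def env_codes(self, scheme: str, c_rasa: float, c_wcn: float):
        buried = (self.rasa <= c_rasa) & (self.wcn >= c_wcn)
        if scheme == "global":
            return np.zeros(len(self.score), dtype=np.intp), ["all"]
        if scheme == "exposure":
            return np.where(buried, 0, 1).astype(np.intp), ["buried", "exposed"]
        if scheme == "secondary":
            return self.ss3, ["helix", "strand", "loop"]
        if scheme == "combined":
            labels = [f"{e}-{s}" for e in ("buried", "exposed")
                      for s in ("helix", "strand", "loop")]
            return (np.where(buried, 0, 1) * 3 + self.ss3).astype(np.intp), labels
        raise ValueError(f"unknown scheme {scheme!r}")


def _mean_tables(pair: np.ndarray, env: np.ndarray, score: np.ndarray, n_env: int):
    """(n_env, 400) mean table plus the environment-agnostic 400 table."""
    flat = env * 400 + pair
    count = np.bincount(flat, minlength=n_env * 400).astype(float)
    total = np.bincount(flat, weights=score, minlength=n_env * 400)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    g_count = np.bincount(pair, minlength=400).astype(float)
    g_total = np.bincount(pair, weights=score, minlength=400)
    with np.errstate(invalid="ignore"):
        g_mean = np.where(g_count > 0, g_total / np.maximum(g_count, 1), np.nan)
    return mean.reshape(n_env, 400), g_mean


def _lopo_predictions(
    idx: _IndexedPool,
    scheme: str,
    c_rasa: float,
    c_wcn: float,
    train_subsets: dict[str, set[str]] | None = None,
    provenance: bool = False,
):
    """Predictions for every record; training always excludes its protein.

    ``train_subsets`` optionally restricts the training proteins per target
    (used by the dataset-combination analysis); the target protein is
    removed from the subset regardless.
    """
    env, labels = idx.env_codes(scheme, c_rasa, c_wcn)
    n_env = len(labels)
    pred = np.full(len(idx.score), np.nan)
    prov = np.full(len(idx.score), "missing", dtype=object) if provenance else None
    targets = idx.proteins if train_subsets is None else list(train_subsets)
    for prot in targets:
        target = idx.protein == prot
        if train_subsets is None:
            train = ~target
        else:
            allowed = train_subsets.get(prot, set(idx.proteins)) - {prot}
            train = np.isin(idx.protein, sorted(allowed))
        mean, g_mean = _mean_tables(
            idx.pair[train], env[train], idx.score[train], n_env
        )
        cell = mean[env[target], idx.pair[target]]
        fallback = g_mean[idx.pair[target]]
        use_fb = np.isnan(cell)
        pred[target] = np.where(use_fb, fallback, cell)
        if provenance:
            wt_names = np.array(list(AA_ORDER))[idx.wt[target]]
            var_names = np.array(list(AA_ORDER))[idx.var[target]]
            env_names = np.array(labels, dtype=object)[env[target]]
            p = np.array(
                [f"{scheme}:{e}[{w}->{v}]"
                 for e, w, v in zip(env_names, wt_names, var_names)],
                dtype=object,
            )
            p[use_fb] = np.array(
                [f"fallback-global[{w}->{v}]"
                 for w, v in zip(wt_names[use_fb], var_names[use_fb])],
                dtype=object,
            )
            p[np.isnan(pred[target])] = "missing"
            prov[target] = p
    return pred, prov


def predict_lopo(
    pool: pd.DataFrame,
    features: pd.DataFrame,
    scheme: str = "exposure",
    c_rasa: float = RASA_CUTOFF,
    c_wcn: float = 0.0,
) -> pd.DataFrame:
    """Leave-one-protein-out matrix predictions for every pooled variant.

    Returns the joined pool with ``prediction`` and ``provenance`` columns;
    provenance names the matrix cell (or global-matrix fallback) behind
    each prediction.  Missing cells that also have no global fallback stay
    NaN and are excluded from evaluation.
    """
    idx = _IndexedPool(pool, features)
    if len(idx.proteins) < 2:
        raise ValueError("LOPO prediction requires at least two proteins")
    pred, prov = _lopo_predictions(idx, scheme, c_rasa, c_wcn, provenance=True)
    out = idx.frame.copy()
    out["prediction"] = pred
    out["provenance"] = prov
    return out


def evaluate(pred: pd.DataFrame, by_protein: bool = True) -> pd.DataFrame:
    """Pearson r, Spearman r_s (average-rank ties) and MAE per protein.

    Pairs with a missing prediction are excluded and counted.  Requires at
    least three evaluable pairs per protein.
    """
    rows = []
    groups = pred.groupby("protein") if by_protein else [("all", pred)]
    for prot, g in groups:
        ok = g["prediction"].notna() & g["score"].notna()
        n_missing = int((~ok).sum())
        x = g.loc[ok, "score"].to_numpy(float)
        y = g.loc[ok, "prediction"].to_numpy(float)
        if len(x) < 3:
            raise ValueError(f"{prot}: fewer than 3 evaluable prediction pairs")
        r = float(stats.pearsonr(x, y).statistic)
        r_s = float(stats.spearmanr(x, y).statistic)
        mae = float(np.mean(np.abs(x - y)))
        rows.append(EvaluationResult(prot, r, r_s, mae, len(x), n_missing))
    return pd.DataFrame([r.__dict__ for r in rows])


def grid_search_cutoffs(
    pool: pd.DataFrame,
    features: pd.DataFrame,
    c_rasa_grid=DEFAULT_C_RASA_GRID,
    c_wcn_grid=DEFAULT_C_WCN_GRID,
) -> pd.DataFrame:
    """Scan burial cutoff combinations, scoring each by LOPO prediction.

    For every (c_rasa, c_wcn) pair, buried/exposed matrices are rebuilt and
    evaluated by leave-one-protein-out prediction; the returned surface has
    per-pair mean Pearson r and mean MAE across proteins, with the argmax-r
    row stored in ``DataFrame.attrs['best_r']`` and the argmin-MAE row in
    ``attrs['best_mae']``.  Rows with c_wcn = 0 constitute a pure-rASA scan.
    """
    if len(c_rasa_grid) == 0 or len(c_wcn_grid) == 0:
        raise ValueError("cutoff grids must be non-empty")
    idx = _IndexedPool(pool, features)
    rows = []
    for c_rasa in c_rasa_grid:
        for c_wcn in c_wcn_grid:
            pred, _ = _lopo_predictions(idx, "exposure", float(c_rasa), float(c_wcn))
            rs, maes = [], []
            for prot in idx.proteins:
                mask = (idx.protein == prot) & np.isfinite(pred)
                x, y = idx.score[mask], pred[mask]
                rs.append(np.corrcoef(x, y)[0, 1])
                maes.append(np.mean(np.abs(x - y)))
            rows.append({
                "c_rasa": float(c_rasa), "c_wcn": float(c_wcn),
                "mean_r": float(np.mean(rs)), "mean_mae": float(np.mean(maes)),
            })
    surface = pd.DataFrame(rows)
    surface.attrs["best_r"] = surface.loc[surface["mean_r"].idxmax()].to_dict()
    surface.attrs["best_mae"] = surface.loc[surface["mean_mae"].idxmin()].to_dict()
    return surface


def dataset_combination_analysis(
    pool: pd.DataFrame,
    features: pd.DataFrame,
    scheme: str = "exposure",
    c_rasa: float = RASA_CUTOFF,
    c_wcn: float = 0.0,
) -> pd.DataFrame:
    """Predict each protein from every non-empty subset of the others.

    Returns one row per (target, subset) with the subset size and Pearson
    r, quantifying how prediction quality grows with the number of
    datasets behind the matrices.
    """
    idx = _IndexedPool(pool, features)
    if len(idx.proteins) < 2:
        raise ValueError("requires at least two proteins")
    rows = []
    for target in idx.proteins:
        others = [p for p in idx.proteins if p != target]
        for size in range(1, len(others) + 1):
            for subset in itertools.combinations(others, size):
                pred, _ = _lopo_predictions(
                    idx, scheme, c_rasa, c_wcn,
                    train_subsets={target: set(subset)},
                )
                mask = (idx.protein == target) & np.isfinite(pred)
                r = float(np.corrcoef(idx.score[mask], pred[mask])[0, 1])
                rows.append({
                    "target": target, "subset": ",".join(subset),
                    "n_datasets": size, "r": r,
                })
    return pd.DataFrame(rows)


def baseline_matrix_predict(
    pool: pd.DataFrame, external_matrix: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Predictions from an external 20x20 scoring matrix (e.g. BLOSUM62).

    The prediction for a wt -> var variant is simply the matrix entry; a
    symmetric alignment-style matrix is acceptable.  Use :func:`evaluate`
    (typically via Spearman r_s) on the result.
    """
    if isinstance(external_matrix, pd.DataFrame):
        mat = external_matrix.loc[list(AA_ORDER), list(AA_ORDER)].to_numpy(float)
    else:
        mat = np.asarray(external_matrix, dtype=float)
    if mat.shape != (20, 20):
        raise ValueError("external matrix must cover all 20x20 ordered pairs")
    if np.isnan(mat[~np.eye(20, dtype=bool)]).any():
        raise ValueError("external matrix has missing off-diagonal entries")
    out = pool.copy()
    wt = out["wt"].map(AA_INDEX).to_numpy(dtype=np.intp)
    var = out["var"].map(AA_INDEX).to_numpy(dtype=np.intp)
    out["prediction"] = mat[wt, var]
    out["provenance"] = "external-matrix"
    return out


def ddg_prepare(
    raw: pd.DataFrame,
    unit: str = "kcal",
    assembly: str = "monomer",
    value_col: str = "ddg",
) -> pd.DataFrame:
    """Normalise an external per-variant stability-change table.

    Rosetta energy units are converted to kcal/mol with the factor
    2.9 REU/(kcal/mol); values computed by substituting both monomers of a
    homodimer are halved to obtain the per-residue stability change.
    """
    if unit not in {"kcal", "REU", "reu"}:
        raise ValueError(f"unknown unit {unit!r}; expected 'kcal' or 'REU'")
    if assembly not in {"monomer", "dimer"}:
        raise ValueError(f"unknown assembly {assembly!r}")
    out = raw.copy()
    vals = out[value_col].astype(float)
    if unit.lower() == "reu":
        vals = vals / 2.9
    if assembly == "dimer":
        vals = vals / 2.0
    out["ddg_kcal"] = vals
    return out


def descriptor_correlations(pool: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Per-protein Spearman r_s of abundance scores against rASA and WCN.

    WCN is negated for reporting symmetry (high packing predicts low
    abundance, so -WCN correlates positively like rASA does).
    """
    keys = ["protein", "chain", "position"]
    merged = pool.merge(features[keys + ["rasa", "wcn"]], on=keys, how="inner")
    rows = []
    for prot, g in merged.groupby("protein"):
        s = g["score"].to_numpy(float)
        if np.std(s) == 0:
            rows.append({"protein": prot, "r_s_rasa": np.nan, "r_s_wcn": np.nan,
                         "n": len(g), "degenerate": True})
            continue
        rows.append({
            "protein": prot,
            "r_s_rasa": float(stats.spearmanr(s, g["rasa"]).statistic),
            "r_s_wcn": float(stats.spearmanr(s, -g["wcn"]).statistic),
            "n": len(g),
            "degenerate": False,
        })
    return pd.DataFrame(rows)


def bootstrap_mean_ci(
    values, n_draws: int = 10_000, level: float = 0.95, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean of per-protein statistics.

    Mirrors the reported confidence intervals on mean r: the per-protein
    values are resampled with replacement ``n_draws`` times.
    """
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.choice(values, size=(n_draws, len(values)), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(values.mean()), float(lo), float(hi)
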