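"""Reading, filtering and combining variant-abundance score tables.

Variant abundance scores come from VAMP-seq experiments: each variant's
steady-state cellular abundance is normalised so that 0 corresponds to
nonsense-variant-like and 1 to wild-type-like abundance.  One dataset holds
the scores (and their standard deviations) for all assayed single-residue
substitutions of one protein.  Datasets are combined by plain concatenation
without any cross-dataset rescaling.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._aa import AA_ORDER

logger = logging.getLogger(__name__)

#: Canonical column order of the tidy score table used throughout the package.
POOL_COLUMNS = ["protein", "chain", "position", "wt", "var", "score", "sd"]

_AA_SET = set(AA_ORDER)
_STOP = {"*", "X", "Ter", "TER", "ter", "Stop", "STOP", "stop"}

_VARIANT_RE = re.compile(
    r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z*]{1,4}|\*)$"
)

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    "TER": "*",
}


class ScoreTableError(ValueError):
    """Malformed or inconsistent score table."""


@dataclass
class Dataset:
    """Variant abundance scores for one protein.

    Attributes
    ----------
    protein_id : str
        Identifier shared by all records.
    records : pandas.DataFrame
        Tidy table with columns ``protein, chain, position, wt, var, score, sd``.
    n_residues_total : int or None
        Protein length considered (needed for completeness statistics).
    metadata : dict
        Structure file paths, excluded ranges, and other per-protein config.
    """

    protein_id: str
    records: pd.DataFrame
    n_residues_total: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        if not (df["protein"] == self.protein_id).all():
            raise ScoreTableError(
                f"records with protein_id != {self.protein_id!r}"
            )
        dup = df.duplicated(subset=["position", "wt", "var"])
        if dup.any():
            keys = df.loc[dup, ["position", "wt", "var"]].head(5)
            raise ScoreTableError(
                f"duplicate variant keys in {self.protein_id}: "
                f"{keys.to_dict('records')}"
            )

    def __len__(self) -> int:
        return len(self.records)


def _aa1(token: str) -> str:
    token = token.strip()
    if token in _STOP:
        return "*"
    if len(token) == 1:
        return token.upper()
    return _THREE_TO_ONE.get(token.upper(), token)


def parse_variant(token: str) -> tuple[str, int, str] | None:
    """Parse a variant string like ``A123V``, ``p.Ala123Val`` or ``A123*``.

    Returns ``(wt, position, var)`` or None if the token is unparseable.
    """
    m = _VARIANT_RE.match(str(token).strip())
    if m is None:
        return None
    wt, var = _aa1(m.group(1)), _aa1(m.group(3))
    if wt not in _AA_SET:
        return None
    if var not in _AA_SET and var != "*":
        return None
    return wt, int(m.group(2)), var


def read_score_table(
    path,
    protein_id: str,
    dialect: dict | None = None,
    chain: str = "A",
    n_residues_total: int | None = None,
) -> Dataset:
    """Read a per-protein variant score table (CSV/TSV) into a Dataset.

    Parameters
    ----------
    dialect
        Column-mapping config.  Keys (all optional):
        ``variant`` — name of a single combined-notation column ("A123V");
        ``wt, position, var`` — names of three explicit columns (default
        ``wt, position, var``); ``score`` (default ``score``); ``sd``
        (default ``sd``; set to None if absent); ``sep`` (default: sniffed).

    Rows whose variant notation cannot be parsed or whose wild-type residue
    is not one of the 20 canonical amino acids are dropped with a logged
    count.  Duplicate (position, wt, var) keys are an error.  Nonsense
    variants ('*') are retained here and removed by
    :func:`filter_substitutions`.
    """
    dialect = dict(dialect or {})
    sep = dialect.pop("sep", None)
    raw = pd.read_csv(path, sep=sep, engine="python")

    score_col = dialect.get("score", "score")
    sd_col = dialect.get("sd", "sd")
    if score_col not in raw.columns:
        raise ScoreTableError(f"missing score column {score_col!r} in {path}")

    if "variant" in dialect:
        vcol = dialect["variant"]
        if vcol not in raw.columns:
            raise ScoreTableError(f"missing variant column {vcol!r} in {path}")
        parsed = [parse_variant(v) for v in raw[vcol]]
        bad = [i for i, p in enumerate(parsed) if p is None]
        if bad:
            logger.warning(
                "%s: dropped %d rows with unparseable variants", protein_id, len(bad)
            )
        keep = [i for i, p in enumerate(parsed) if p is not None]
        raw = raw.iloc[keep].reset_index(drop=True)
        trip = [parsed[i] for i in keep]
        wt = [t[0] for t in trip]
        pos = [t[1] for t in trip]
        var = [t[2] for t in trip]
    else:
        wt_col = dialect.get("wt", "wt")
        pos_col = dialect.get("position", "position")
        var_col = dialect.get("var", "var")
        for col in (wt_col, pos_col, var_col):
            if col not in raw.columns:
                raise ScoreTableError(f"missing column {col!r} in {path}")
        wt = [_aa1(str(x)) for x in raw[wt_col]]
        var = [_aa1(str(x)) for x in raw[var_col]]
        pos = pd.to_numeric(raw[pos_col]).astype(int).tolist()

    df = pd.DataFrame(
        {
            "protein": protein_id,
            "chain": chain,
            "position": pd.array(pos, dtype=int),
            "wt": wt,
            "var": var,
            "score": pd.to_numeric(raw[score_col]).astype(float).to_numpy(),
            "sd": (
                pd.to_numeric(raw[sd_col]).astype(float).to_numpy()
                if sd_col is not None and sd_col in raw.columns
                else np.nan
            ),
        }
    )

    ok_wt = df["wt"].isin(list(_AA_SET))
    if not ok_wt.all():
        n = int((~ok_wt).sum())
        logger.warning("%s: dropped %d rows with non-canonical wt", protein_id, n)
        df = df[ok_wt]
    ok_var = df["var"].isin(list(_AA_SET | {"*"}))
    if not ok_var.all():
        n = int((~ok_var).sum())
        logger.warning("%s: dropped %d rows with non-canonical var", protein_id, n)
        df = df[ok_var]
    if not np.isfinite(df["score"]).all():
        n = int((~np.isfinite(df["score"])).sum())
        logger.warning("%s: dropped %d rows with non-finite scores", protein_id, n)
        df = df[np.isfinite(df["score"])]
    if (df["position"] < 1).any():
        raise ScoreTableError(f"{protein_id}: positions must be >= 1")
    if ((df["sd"].notna()) & (df["sd"] < 0)).any():
        raise ScoreTableError(f"{protein_id}: negative score standard deviations")

    return Dataset(
        protein_id=protein_id,
        records=df.reset_index(drop=True),
        n_residues_total=n_residues_total,
    )


def filter_substitutions(
    ds: Dataset, excluded_ranges: list[tuple[int, int]] | None = None
) -> Dataset:
    """Keep only single missense substitutions.

    Removes synonymous records (wt == var), nonsense/stop records, and
    records within closed position intervals ``excluded_ranges`` (for
    example the CYP2C9 N-terminal transmembrane helix, residues 1-28).
    Idempotent.  Counts removed per category are logged.
    """
    df = ds.records
    if df.empty:
        logger.warning("%s: empty dataset passed to filter", ds.protein_id)
        return Dataset(ds.protein_id, df.copy(), ds.n_residues_total, dict(ds.metadata))
    syn = df["wt"] == df["var"]
    stop = df["var"] == "*"
    excl = pd.Series(False, index=df.index)
    ranges = list(excluded_ranges or ds.metadata.get("excluded_ranges", []) or [])
    for lo, hi in ranges:
        excl |= (df["position"] >= lo) & (df["position"] <= hi)
    removed = syn | stop | excl
    logger.info(
        "%s: removed %d synonymous, %d nonsense, %d in excluded ranges",
        ds.protein_id, int(syn.sum()), int(stop.sum()), int((excl & ~syn & ~stop).sum()),
    )
    out = df[~removed].reset_index(drop=True)
    if out.empty:
        logger.warning("%s: no records survive filtering", ds.protein_id)
    meta = dict(ds.metadata)
    meta["excluded_ranges"] = ranges
    return Dataset(ds.protein_id, out, ds.n_residues_total, meta)


def normalise_from_bin_weights(w_var: float, w_nonsense: float, w_wt: float) -> float:
    """Min-max normalise a weighted bin average to the abundance-score scale.

    score = (W_var - W_nonsense) / (W_wt - W_nonsense), anchoring the
    nonsense-variant average at 0 and the wild-type(-synonymous) average at 1.
    Published tables are already normalised and bypass this.
    """
    denom = w_wt - w_nonsense
    if denom == 0:
        raise ZeroDivisionError(
            "degenerate normalisation: wild-type and nonsense anchors coincide"
        )
    return (w_var - w_nonsense) / denom


def combine(datasets: list[Dataset]) -> pd.DataFrame:
    """Concatenate per-protein datasets into one indexed pool.

    No rescaling or harmonisation is applied; the pool is the plain union of
    records.  Total record count equals the sum of the parts.
    """
    if not datasets:
        raise ValueError("combine() requires at least one dataset")
    ids = [ds.protein_id for ds in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate protein_id in combine(): {ids}")
    pool = pd.concat([ds.records for ds in datasets], ignore_index=True)
    return pool[POOL_COLUMNS]


def dataset_summary(ds: Dataset) -> dict:
    """Mutational depth, completeness and size of one dataset.

    depth: mean number of scores per position having at least one score.
    completeness: 100 * n_records / (19 * n_residues_total), in percent.
    """
    if ds.n_residues_total is None or ds.n_residues_total <= 0:
        raise ValueError(f"{ds.protein_id}: n_residues_total must be positive")
    df = ds.records
    n = len(df)
    if n == 0:
        return {
            "protein": ds.protein_id, "n_records": 0,
            "depth": float("nan"), "completeness_pct": 0.0,
        }
    per_pos = df.groupby("position").size()
    return {
        "protein": ds.protein_id,
        "n_records": n,
        "depth": float(per_pos.mean()),
        "completeness_pct": 100.0 * n / (19.0 * ds.n_residues_total),
    }


@dataclass(frozen=True)
class NoiseSummary:
    """Resampling-based noise ceiling of one dataset.

    r_mean / r_s_mean are the average Pearson and Spearman correlations
    between the reported scores and Gaussian-resampled copies; they bound
    how well any perfect predictor could correlate with the data.
    """

    protein_id: str
    r_mean: float
    r_s_mean: float
    n_resamples: int


def noise_resample(ds: Dataset, n_resamples: int = 100, seed: int = 0) -> NoiseSummary:
    """Quantify dataset noise by resampling every score from its Gaussian.

    Each resample draws every score independently from
    Normal(score, score_sd) (draws are not clipped to [0, 1]); Pearson r and
    Spearman r_s between the original and resampled score vectors are
    averaged over ``n_resamples`` resamples.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    df = ds.records
    missing = df["sd"].isna()
    if missing.any():
        offenders = df.loc[missing, ["position", "wt", "var"]].head(10)
        raise ValueError(
            f"{ds.protein_id}: {int(missing.sum())} records without score_sd, "
            f"e.g. {offenders.to_dict('records')}"
        )
    scores = df["score"].to_numpy(float)
    sds = df["sd"].to_numpy(float)
    rng = np.random.default_rng(seed)
    rs_p = np.empty(n_resamples)
    rs_s = np.empty(n_resamples)
    ranks0 = stats.rankdata(scores)
    for k in range(n_resamples):
        draw = rng.normal(scores, sds)
        if np.std(draw) == 0 or np.std(scores) == 0:
            rs_p[k] = 1.0 if np.array_equal(draw, scores) else np.nan
            rs_s[k] = rs_p[k]
            continue
        rs_p[k] = np.corrcoef(scores, draw)[0, 1]
        rs_s[k] = np.corrcoef(ranks0, stats.rankdata(draw))[0, 1]
    return NoiseSummary(
        protein_id=ds.protein_id,
        r_mean=float(np.nanmean(rs_p)),
        r_s_mean=float(np.nanmean(rs_s)),
        n_resamples=n_resamples,
    )
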