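"""Resampling-based classification of residue substitution profiles.

A residue's substitution profile is the vector of abundance scores for its
observed variants.  Two classifiers are provided, both driven by 10,000
Gaussian resamples of the profile (draws use each variant's reported score
standard deviation, independently across variants):

* buried-like vs exposed-like — compares the profile's RMSD to the buried
  and exposed average profiles of the residue's amino-acid type; a call is
  made only when one RMSD is smaller for more than 95% of resamples.
* ddg-favoured vs matrix-favoured — compares how well an external stability
  change (ddG) ranks the profile against how well the substitution-matrix
  prediction does, with the same 95% resampling criterion.

Residues with fewer than five reported scores are never classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._aa import AA_INDEX
from .matrices import SubstitutionMatrix, build_matrix_set

MIN_PROFILE_SIZE = 5
N_RESAMPLES = 10_000
CRITERION = 0.95


@dataclass
class SubstitutionProfile:
    """Observed variant scores (and uncertainties) at one residue position."""

    protein_id: str
    position: int
    wt_aa: str
    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("profile must contain at least one entry")
        if self.wt_aa in self.entries:
            raise ValueError("profile may not contain a synonymous entry")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def variants(self) -> list[str]:
        return sorted(self.entries)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        var = self.variants
        scores = np.array([self.entries[v][0] for v in var], float)
        sds = np.array([self.entries[v][1] for v in var], float)
        return scores, sds, var


def profiles_from_pool(pool: pd.DataFrame):
    """Yield a SubstitutionProfile per (protein, position) in the pool."""
    for (prot, pos, wt), g in pool.groupby(["protein", "position", "wt"]):
        entries = {
            row["var"]: (float(row["score"]), float(row["sd"]))
            for _, row in g.iterrows()
        }
        yield SubstitutionProfile(prot, int(pos), wt, entries)


def profile_rmsd(profile: SubstitutionProfile, ref_matrix: SubstitutionMatrix):
    """RMSD between observed profile and the matrix row of its wt type.

    Only variants present both in the profile and (non-missing) in the
    matrix row contribute; their count is returned alongside.
    """
    scores, _, variants = profile.arrays()
    row = ref_matrix.mean[AA_INDEX[profile.wt_aa]]
    ref = np.array([row[AA_INDEX[v]] for v in variants])
    ok = np.isfinite(ref)
    if not ok.any():
        raise ValueError(
            f"{profile.protein_id} pos {profile.position}: no overlap with "
            f"matrix row {profile.wt_aa}"
        )
    rmsd = float(np.sqrt(np.mean((scores[ok] - ref[ok]) ** 2)))
    return rmsd, int(ok.sum())


@dataclass(frozen=True)
class RmsdComparison:
    """Burial-similarity call for one residue's profile."""

    protein_id: str
    position: int
    wt_aa: str
    n_scores: int
    rmsd_buried: float
    rmsd_exposed: float
    frac_buried_smaller: float
    sem_rmsd_buried: float
    call: str  # buried-like | exposed-like | inconclusive | not-evaluated


def classify_burial_like(
    profile: SubstitutionProfile,
    m_buried: SubstitutionMatrix,
    m_exposed: SubstitutionMatrix,
    n_resamples: int = N_RESAMPLES,
    criterion: float = CRITERION,
    seed: int | np.random.SeedSequence = 0,
) -> RmsdComparison:
    """Call a profile buried-like or exposed-like by resampled RMSDs.

    Per resample the profile is redrawn from Normal(score, sd) and both
    RMSDs recomputed; the residue is buried-like when RMSD_buried is
    strictly smaller in more than ``criterion`` of resamples, exposed-like
    when that fraction is below 1 - criterion, else inconclusive.  Exact
    RMSD ties count as "not buried-smaller" (only relevant at sd = 0).
    """
    scores, sds, variants = profile.arrays()
    if len(scores) < MIN_PROFILE_SIZE:
        return RmsdComparison(profile.protein_id, profile.position, profile.wt_aa,
                              len(scores), np.nan, np.nan, np.nan, np.nan,
                              "not-evaluated")
    if np.isnan(sds).any():
        raise ValueError(
            f"{profile.protein_id} pos {profile.position}: missing score_sd"
        )
    wt_i = AA_INDEX[profile.wt_aa]
    var_i = np.array([AA_INDEX[v] for v in variants], dtype=np.intp)
    ref_b = m_buried.mean[wt_i, var_i]
    ref_e = m_exposed.mean[wt_i, var_i]
    ok = np.isfinite(ref_b) & np.isfinite(ref_e)  # joint non-missing overlap
    if ok.sum() < MIN_PROFILE_SIZE:
        return RmsdComparison(profile.protein_id, profile.position, profile.wt_aa,
                              int(ok.sum()), np.nan, np.nan, np.nan, np.nan,
                              "not-evaluated")
    s, sd, rb, re_ = scores[ok], sds[ok], ref_b[ok], ref_e[ok]

    rmsd_b = float(np.sqrt(np.mean((s - rb) ** 2)))
    rmsd_e = float(np.sqrt(np.mean((s - re_) ** 2)))

    rng = np.random.default_rng(seed)
    draws = rng.normal(s, sd, size=(n_resamples, len(s)))
    res_b = np.sqrt(np.mean((draws - rb) ** 2, axis=1))
    res_e = np.sqrt(np.mean((draws - re_) ** 2, axis=1))
    frac = float(np.mean(res_b < res_e))

    if frac > criterion:
        call = "buried-like"
    elif frac < 1.0 - criterion:
        call = "exposed-like"
    else:
        call = "inconclusive"
    sem = float(np.std(res_b, ddof=1) / np.sqrt(n_resamples))
    return RmsdComparison(profile.protein_id, profile.position, profile.wt_aa,
                          int(ok.sum()), rmsd_b, rmsd_e, frac, sem, call)


@dataclass(frozen=True)
class FavouredCall:
    """Matrix-vs-ddG ranking call for one residue's profile."""

    protein_id: str
    position: int
    wt_aa: str
    n_scores: int
    r_s_matrix: float
    r_s_ddg: float
    frac_ddg_better: float
    call: str  # ddg-favoured | matrix-favoured | similar | not-evaluated


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with vector ``b``."""
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum(axis=-1) * (bc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ac @ bc) / denom


def classify_favoured(
    profile: SubstitutionProfile,
    matrix_pred: dict[str, float],
    ddg: dict[str, float],
    n_resamples: int = N_RESAMPLES,
    criterion: float = CRITERION,
    seed: int | np.random.SeedSequence = 0,
) -> FavouredCall:
    """Decide whether ddG or the matrix ranks a profile consistently better.

    On the observed profile, r_s,matrix (scores vs matrix predictions) and
    r_s,ddG (scores vs ddG) are computed; residues qualify only when
    -r_s,ddG and r_s,matrix are both positive.  Profiles are then resampled
    and the residue is ddg-favoured when -r_s,ddG > r_s,matrix in at least
    ``criterion`` of resamples, matrix-favoured when that holds in at most
    1 - criterion, and similar otherwise.
    """
    scores, sds, variants = profile.arrays()
    shared = [v for v in variants if v in matrix_pred and v in ddg
              and np.isfinite(matrix_pred[v]) and np.isfinite(ddg[v])]
    nshared = len(shared)
    if nshared < MIN_PROFILE_SIZE:
        return FavouredCall(profile.protein_id, profile.position, profile.wt_aa,
                            nshared, np.nan, np.nan, np.nan, "not-evaluated")
    sel = np.array([variants.index(v) for v in shared], dtype=np.intp)
    s, sd = scores[sel], sds[sel]
    if np.isnan(sd).any():
        raise ValueError(
            f"{profile.protein_id} pos {profile.position}: missing score_sd"
        )
    preds = np.array([matrix_pred[v] for v in shared], float)
    ddgs = np.array([ddg[v] for v in shared], float)

    r_s_matrix = float(stats.spearmanr(s, preds).statistic)
    r_s_ddg = float(stats.spearmanr(s, ddgs).statistic)
    if not (-r_s_ddg > 0 and r_s_matrix > 0):
        return FavouredCall(profile.protein_id, profile.position, profile.wt_aa,
                            nshared, r_s_matrix, r_s_ddg, np.nan, "not-evaluated")

    rng = np.random.default_rng(seed)
    draws = rng.normal(s, sd, size=(n_resamples, len(s)))
    ranks = _rank_rows(draws)
    rs_mat = _row_pearson(ranks, stats.rankdata(preds))
    rs_ddg = _row_pearson(ranks, stats.rankdata(ddgs))
    frac = float(np.mean(-rs_ddg > rs_mat))
    frac_matrix = float(np.mean(-rs_ddg < rs_mat))

    # exact ties (identical rankings) count for neither method, so a call
    # requires the strict inequality to hold in >= criterion of resamples
    if frac >= criterion:
        call = "ddg-favoured"
    elif frac_matrix >= criterion:
        call = "matrix-favoured"
    else:
        call = "similar"
    return FavouredCall(profile.protein_id, profile.position, profile.wt_aa,
                        nshared, r_s_matrix, r_s_ddg, frac, call)


def burial_like_scan(
    pool: pd.DataFrame,
    features_monomer: pd.DataFrame,
    n_resamples: int = N_RESAMPLES,
    criterion: float = CRITERION,
    seed: int = 0,
    positions: dict[str, set[int]] | None = None,
) -> pd.DataFrame:
    """Classify every (or selected) residue profile as buried-/exposed-like.

    For each protein the buried and exposed reference matrices are rebuilt
    leaving that protein's data out and classifying residues with the
    *monomer* feature set, matching how dimer interfaces are assessed.
    ``positions`` optionally restricts the scan per protein.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    proteins = sorted(pool["protein"].unique())
    lopo = {
        prot: build_matrix_set(pool, features_monomer, "exposure",
                               exclude_proteins={prot})
        for prot in proteins
    }
    children = iter(ss.spawn(pool.groupby(["protein", "position", "wt"]).ngroups))
    for profile in profiles_from_pool(pool):
        child = next(children)
        if positions is not None:
            wanted = positions.get(profile.protein_id, set())
            if profile.position not in wanted:
                continue
        mats = lopo[profile.protein_id]
        res = classify_burial_like(
            profile, mats["buried"], mats["exposed"],
            n_resamples=n_resamples, criterion=criterion, seed=child,
        )
        rows.append(res.__dict__ | {
            "mean_score": float(np.mean(profile.arrays()[0])),
        })
    return pd.DataFrame(rows)


def enrichment(
    calls: pd.DataFrame,
    group_a,
    group_b,
    aa_col: str = "wt_aa",
) -> pd.DataFrame:
    """Per-amino-acid frequencies within two residue groups.

    ``group_a``/``group_b`` are boolean masks or predicates over ``calls``.
    Counts are normalised to each group's size, so each frequency column
    sums to 1; the difference column highlights enrichment in group A.
    """
    mask_a = group_a(calls) if callable(group_a) else np.asarray(group_a, bool)
    mask_b = group_b(calls) if callable(group_b) else np.asarray(group_b, bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    aas = sorted(AA_INDEX)
    freq_a = calls.loc[mask_a, aa_col].value_counts(normalize=True)
    freq_b = calls.loc[mask_b, aa_col].value_counts(normalize=True)
    out = pd.DataFrame({
        "aa": aas,
        "freq_a": [float(freq_a.get(a, 0.0)) for a in aas],
        "freq_b": [float(freq_b.get(a, 0.0)) for a in aas],
    })
    out["diff"] = out["freq_a"] - out["freq_b"]
    return out


def interface_assessment(
    calls: pd.DataFrame, interface_positions: set[int]
) -> dict:
    """Summarise burial-like calls over a dimer-interface residue set.

    Residues with fewer than five scores are excluded from the evaluated
    denominator.  Returns counts plus the per-residue table.
    """
    sub = calls[calls["position"].isin(sorted(interface_positions))].copy()
    evaluated = sub[sub["call"] != "not-evaluated"]
    return {
        "n_interface": len(interface_positions),
        "n_evaluated": len(evaluated),
        "n_buried_like": int((evaluated["call"] == "buried-like").sum()),
        "n_exposed_like": int((evaluated["call"] == "exposed-like").sum()),
        "n_inconclusive": int((evaluated["call"] == "inconclusive").sum()),
        "table": sub.reset_index(drop=True),
    }
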