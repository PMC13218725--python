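"""Per-residue structural descriptors from protein structures.

Computes relative solvent accessibility (rASA), weighted contact number
(WCN), three-class secondary structure from DSSP files, and backbone
dihedrals, and identifies homodimer-interface residues from the change in
burial between monomer and dimer assemblies.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import biotite.structure.io.pdbx as pdbxio
from scipy.spatial.distance import cdist

from ._aa import THREE_TO_ONE

logger = logging.getLogger(__name__)

#: Default half-saturation distance of the WCN contact function, in Angstrom.
WCN_R0 = 7.0

#: rASA threshold separating buried from exposed residues.
RASA_CUTOFF = 0.1

#: Minimum monomer-to-dimer rASA drop for a residue to count as interface.
INTERFACE_DELTA_MIN = 0.01

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_SS8_TO_SS3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "loop", "S": "loop", "P": "loop", "C": "loop", " ": "loop",
    "-": "loop", "~": "loop", "": "loop",
}


def load_max_asa(path=None) -> dict[str, float]:
    """Load the per-residue-type theoretical maximum ASA table (A^2)."""
    if path is None:
        ref = importlib.resources.files("abundmat") / "data" / "max_asa.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    return dict(zip(table["aa"], table["max_asa"].astype(float)))


def load_structure(path, chains: list[str] | None = None) -> struc.AtomArray:
    """Read a PDB or mmCIF file into a cleaned heavy-atom AtomArray.

    Hetero atoms (waters, ligands, ions) and hydrogens are removed; alternate
    locations resolve to highest occupancy (biotite default).  If ``chains``
    is given, only those chains are kept.
    """
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif", ".pdbx"}:
        f = pdbxio.CIFFile.read(str(path))
        arr = pdbxio.get_structure(f, model=1)
    else:
        f = pdbio.PDBFile.read(str(path))
        arr = pdbio.get_structure(f, model=1)
    arr = arr[~arr.hetero]
    arr = arr[arr.element != "H"]
    if chains is not None:
        arr = arr[np.isin(arr.chain_id, chains)]
    if arr.array_length() == 0:
        raise ValueError(f"no protein atoms found in {path} for chains={chains}")
    return arr


def _residue_table(arr: struc.AtomArray, chain: str) -> pd.DataFrame:
    mask = arr.chain_id == chain
    if not mask.any():
        raise ValueError(f"chain {chain!r} not present in structure")
    sub = arr[mask]
    starts = struc.get_residue_starts(sub)
    res_ids = sub.res_id[starts]
    res_names = sub.res_name[starts]
    wt = [THREE_TO_ONE.get(rn, "X") for rn in res_names]
    return pd.DataFrame({"position": res_ids.astype(int), "wt": wt})


def compute_rasa(
    arr: struc.AtomArray,
    chain: str,
    max_asa_table: dict[str, float] | None = None,
    probe_radius: float = 1.4,
    point_number: int = 500,
) -> pd.DataFrame:
    """Relative solvent accessibility per residue of one chain.

    Absolute per-residue SASA (rolling-probe, heavy atoms, probe 1.4 A) is
    computed in the context of *all* chains present in ``arr`` — pass a
    dimer to obtain dimer-context burial — then divided by the residue
    type's theoretical maximum accessibility.
    """
    if max_asa_table is None:
        max_asa_table = load_max_asa()
    try:
        atom_sasa = struc.sasa(
            arr, probe_radius=probe_radius, point_number=point_number,
            vdw_radii="ProtOr",
        )
    except Exception:  # non-standard atoms (e.g. coarse models): single-atom radii
        atom_sasa = struc.sasa(
            arr, probe_radius=probe_radius, point_number=point_number,
            vdw_radii="Single",
        )
    atom_sasa = np.nan_to_num(atom_sasa)
    out = _residue_table(arr, chain)
    mask = arr.chain_id == chain
    sub = arr[mask]
    sub_sasa = atom_sasa[mask]
    starts = struc.get_residue_starts(sub, add_exclusive_stop=True)
    rasa = np.empty(len(out))
    for i, (lo, hi) in enumerate(zip(starts[:-1], starts[1:])):
        aa = out["wt"].iloc[i]
        if aa not in max_asa_table:
            raise KeyError(f"residue type {aa!r} missing from max-ASA table")
        rasa[i] = sub_sasa[lo:hi].sum() / max_asa_table[aa]
    out["rasa"] = rasa
    return out


def wcn_contact(r: np.ndarray | float, r0: float = WCN_R0):
    """Smooth contact weight s(r) = 1 / (1 + (r/r0)^6).

    Algebraically identical to (1-(r/r0)^6)/(1-(r/r0)^12) away from the
    removable singularity at r = r0, where the limit value 0.5 is taken.
    """
    x = np.asarray(r, dtype=float) / r0
    return 1.0 / (1.0 + x**6)


def compute_wcn(arr: struc.AtomArray, chain: str, r0: float = WCN_R0) -> pd.DataFrame:
    """Weighted contact number per residue of one chain.

    WCN_i = sum over j != i of s(r_ij), where r_ij is the shortest
    heavy-atom distance between the *side chains* of residues i and j —
    except when either residue is glycine (or has no side-chain atoms),
    where the shortest distance over all atom pairs of the two residues is
    used.  All chains present in ``arr`` contribute as neighbours.
    """
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    n_res = len(starts) - 1
    if n_res < 2:
        raise ValueError("WCN requires at least two residues")
    side_coords: list[np.ndarray] = []
    all_coords: list[np.ndarray] = []
    res_chain: list[str] = []
    res_id: list[int] = []
    for lo, hi in zip(starts[:-1], starts[1:]):
        coords = arr.coord[lo:hi]
        names = arr.atom_name[lo:hi]
        side = coords[~np.isin(names, list(_BACKBONE))]
        all_coords.append(coords)
        side_coords.append(side if len(side) else coords)
        res_chain.append(arr.chain_id[lo])
        res_id.append(int(arr.res_id[lo]))
    has_side = np.array([len(c[~np.isin(arr.atom_name[lo:hi], list(_BACKBONE))]) > 0
                         for c, (lo, hi) in zip(all_coords, zip(starts[:-1], starts[1:]))])

    wcn = np.zeros(n_res)
    min_d = np.full((n_res, n_res), np.inf)
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if has_side[i] and has_side[j]:
                d = cdist(side_coords[i], side_coords[j]).min()
            else:  # glycine rule: any interresidue atom pair
                d = cdist(all_coords[i], all_coords[j]).min()
            min_d[i, j] = min_d[j, i] = d
    for i in range(n_res):
        others = np.delete(min_d[i], i)
        wcn[i] = wcn_contact(others, r0).sum()

    out = pd.DataFrame({
        "chain": res_chain,
        "position": res_id,
        "wcn": wcn,
    })
    out = out[out["chain"] == chain].drop(columns="chain").reset_index(drop=True)
    if out.empty:
        raise ValueError(f"chain {chain!r} not present in structure")
    return out


def read_dssp(path, chain: str, alpha_only: bool = False) -> pd.DataFrame:
    """Parse a DSSP-format secondary-structure file for one chain.

    Returns a frame with ``position, ss8, ss3``.  Eight-class codes map
    H/G/I -> helix, E/B -> strand, and turn/bend/irregular -> loop; with
    ``alpha_only`` the helix class is restricted to code H (used by the
    helix-propensity analysis).
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise ValueError(f"{path}: not a DSSP file (no residue header)") from None
    rows = []
    for ln in lines[start + 1:]:
        if len(ln) < 17:
            continue
        resnum = ln[5:10].strip()
        ch = ln[11].strip()
        if not resnum or ln[13] == "!":  # chain break marker
            continue
        if ch != chain:
            continue
        code = ln[16]
        if code not in _SS8_TO_SS3:
            raise ValueError(f"{path}: unknown secondary-structure code {code!r}")
        rows.append((int(resnum), code if code != " " else "-"))
    if not rows:
        raise ValueError(f"{path}: no residues found for chain {chain!r}")
    df = pd.DataFrame(rows, columns=["position", "ss8"])
    if alpha_only:
        df["ss3"] = np.where(
            df["ss8"] == "H", "helix",
            np.where(df["ss8"].isin(["E", "B"]), "strand", "loop"),
        )
    else:
        df["ss3"] = df["ss8"].map(lambda c: _SS8_TO_SS3[c if c != "-" else " "])
    return df


def assign_ss3_from_dihedrals(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Coarse phi/psi-based 3-class assignment.

    Synthetic-fixture fallback only: real assignments should come from a
    DSSP file (hydrogen-bond based).  Helix: phi in (-100, -30) and psi in
    (-80, -5); strand: phi in (-180, -90) and psi in (90, 180); else loop.
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    ss = np.full(phi.shape, "loop", dtype=object)
    helix = (phi > -100) & (phi < -30) & (psi > -80) & (psi < -5)
    strand = (phi > -180) & (phi < -90) & (psi > 90) & (psi <= 180)
    ss[helix] = "helix"
    ss[strand & ~helix] = "strand"
    ss[~np.isfinite(phi) | ~np.isfinite(psi)] = "loop"
    return ss


def compute_dihedrals(arr: struc.AtomArray, chain: str) -> pd.DataFrame:
    """Backbone phi/psi angles in degrees per residue of one chain.

    Chain termini and residues with missing backbone atoms get NaN.
    """
    sub = arr[arr.chain_id == chain]
    if sub.array_length() == 0:
        raise ValueError(f"chain {chain!r} not present in structure")
    try:
        phi, psi, _omega = struc.dihedral_backbone(sub)
    except Exception as err:
        logger.warning("dihedral computation failed (%s); returning NaN", err)
        tab = _residue_table(arr, chain)
        tab["phi"] = np.nan
        tab["psi"] = np.nan
        return tab
    out = _residue_table(arr, chain)
    out["phi"] = np.degrees(phi)
    out["psi"] = np.degrees(psi)
    return out


def compute_features(
    arr: struc.AtomArray,
    chain: str,
    protein_id: str,
    dssp_path=None,
    crystal_resolved: set[int] | None = None,
    max_asa_table: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Full per-residue feature table for one chain of one assembly.

    Columns: protein, chain, position, wt, rasa, wcn, ss3, ss8, phi, psi,
    crystal_resolved.  rASA and WCN are evaluated in the context of all
    chains in ``arr``; secondary structure comes from ``dssp_path`` when
    given, else from the coarse dihedral-based fallback.
    """
    rasa = compute_rasa(arr, chain, max_asa_table)
    wcn = compute_wcn(arr, chain)
    dih = compute_dihedrals(arr, chain)
    feat = rasa.merge(wcn, on="position").merge(
        dih[["position", "phi", "psi"]], on="position"
    )
    if dssp_path is not None:
        ss = read_dssp(dssp_path, chain)
        feat = feat.merge(ss, on="position", how="left")
        feat["ss3"] = feat["ss3"].fillna("loop")
        feat["ss8"] = feat["ss8"].fillna("-")
    else:
        feat["ss3"] = assign_ss3_from_dihedrals(feat["phi"], feat["psi"])
        feat["ss8"] = np.where(feat["ss3"] == "helix", "H",
                               np.where(feat["ss3"] == "strand", "E", "-"))
    feat["crystal_resolved"] = (
        feat["position"].isin(sorted(crystal_resolved)).to_numpy()
        if crystal_resolved is not None
        else True
    )
    feat.insert(0, "protein", protein_id)
    feat.insert(1, "chain", chain)
    return feat


def find_interface(
    features_monomer: pd.DataFrame,
    features_dimer: pd.DataFrame,
    delta_min: float = INTERFACE_DELTA_MIN,
    rasa_cutoff: float = RASA_CUTOFF,
) -> pd.DataFrame:
    """Flag homodimer-interface residues from monomer-vs-dimer burial.

    A residue is interface when it is exposed in the monomer
    (rasa > cutoff), buried in the dimer (rasa <= cutoff), and loses more
    than ``delta_min`` rASA upon dimerisation — the last condition filters
    out residues that change class through a minor rASA change only.
    """
    m = features_monomer[["position", "rasa"]].rename(columns={"rasa": "rasa_monomer"})
    d = features_dimer[["position", "rasa"]].rename(columns={"rasa": "rasa_dimer"})
    merged = m.merge(d, on="position", how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both", "position"].tolist()
        raise ValueError(f"position mismatch between monomer and dimer features: {missing}")
    merged = merged.drop(columns="_merge")
    merged["is_interface"] = (
        (merged["rasa_monomer"] > rasa_cutoff)
        & (merged["rasa_dimer"] <= rasa_cutoff)
        & (merged["rasa_monomer"] - merged["rasa_dimer"] > delta_min)
    )
    return merged
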