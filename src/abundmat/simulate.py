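"""Synthetic benchmark generator with known ground truth.

Generates coarse-grained protein structures (Calpha + pseudo-side-chain
globules), per-residue features, and VAMP-seq-like variant score tables in
which every quantity the pipeline estimates is planted and therefore
checkable:

* environment-dependent mean effects — scores are drawn around the cells of
  two generating 20x20 matrices (buried means harsh, exposed means mild,
  substitutions to proline penalised everywhere), with the burial truth of
  a residue defined by its computed rASA in the generating assembly context
  (dimer for designated homodimer proteins) against the 0.1 threshold;
* per-variant Gaussian noise of reported standard deviation and incomplete
  mutational coverage;
* special residues whose profiles mismatch their monomer exposure:
  emergent homodimer-interface patches, designated degron-like surface
  sites (drawn from the buried matrix), and left-handed-helix-like loop
  residues with a variant-type-specific tolerance profile (glycine most
  tolerated; proline, isoleucine, valine and tryptophan least).

All randomness flows from a single mandatory seed; identical configuration
yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from ._aa import AA_ORDER, AA_INDEX, KD_HYDROPATHY, RESIDUE_VOLUME, ONE_TO_THREE
from .io import Dataset, combine
from .structure import compute_rasa, compute_wcn, find_interface, RASA_CUTOFF

_CA_SPACING = 3.8  # Angstrom, target spacing along the pseudo-backbone
_SHELL_GAP = 4.0
_CB_LENGTH = 1.8
_CG_LENGTH = 3.3
_SMALL_AA = frozenset("GAS")  # no CG pseudo-atom
_FACE_CUT = 3.0    # x beyond which residues are removed to flatten the
                   # dimer-contact face
_DIMER_GAP = 1.0   # face-to-mirror-image spacing in the dimer; snug enough
                   # that the probe cannot enter the contact

#: Mean-score profile of left-handed-helix-like loop residues, by variant
#: amino acid: tolerant of glycine, intolerant of beta-branched residues,
#: tryptophan and proline.
LEFTHANDED_PROFILE = {
    **{aa: 0.6 for aa in AA_ORDER},
    "G": 0.9, "P": 0.1, "I": 0.1, "V": 0.1, "W": 0.1, "T": 0.3,
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic benchmark.

    Defaults define the ``benchmark6`` preset: six proteins of 150 residues
    (two of them homodimers), per-variant Gaussian noise of sd 0.05, 80%
    mutational completeness, ten degron-like surface sites and forty
    left-handed-loop sites spread over the six proteins.
    """

    n_proteins: int = 6
    residues_per_protein: int = 150
    aa_composition: dict[str, float] | None = None  # uniform when None
    noise_sd: float = 0.05
    completeness: float = 0.8
    dimer_proteins: tuple[int, ...] = (3, 4)  # zero-based protein indices
    n_degron_sites: int = 10
    n_lefthanded_sites: int = 40
    true_matrices: dict[str, np.ndarray] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("GeneratorConfig.seed is mandatory")
        if not (0.0 < self.completeness <= 1.0):
            raise ValueError("completeness must be in (0, 1]")

    @property
    def protein_ids(self) -> list[str]:
        return [f"SYN{i+1}" for i in range(self.n_proteins)]


def default_true_matrices() -> dict[str, np.ndarray]:
    """Generating mean matrices for buried and exposed environments.

    Buried means decrease with a hydropathy/volume dissimilarity between
    wild-type and variant residues (conservative substitutions tolerated,
    non-conservative harsh); exposed means sit near 1 except substitutions
    to proline.  All cells lie in [-0.2, 1.2]; diagonals are NaN.
    """
    h = np.array([KD_HYDROPATHY[a] for a in AA_ORDER])
    v = np.array([RESIDUE_VOLUME[a] for a in AA_ORDER])
    dh = np.abs(h[:, None] - h[None, :]) / np.ptp(h)
    dv = np.abs(v[:, None] - v[None, :]) / np.ptp(v)
    d = 0.6 * dh + 0.4 * dv

    buried = np.clip(0.85 - 0.80 * d, 0.05, 0.95)
    exposed = np.clip(0.95 - 0.15 * d, 0.75, 0.95)
    p = AA_INDEX["P"]
    buried[:, p] = np.minimum(buried[:, p], 0.15)
    exposed[:, p] = 0.35
    np.fill_diagonal(buried, np.nan)
    np.fill_diagonal(exposed, np.nan)
    return {"buried": buried, "exposed": exposed}


def _spherical_spiral(radius: float, step: float = _CA_SPACING) -> np.ndarray:
    """Points along a pole-to-pole spiral on a sphere, ~step apart."""
    c = np.pi * radius / step  # winding rate; rings ~step apart
    pts = []
    theta = step / (2 * radius)
    while theta < np.pi:
        phi = c * theta
        pts.append([
            radius * np.sin(theta) * np.cos(phi),
            radius * np.sin(theta) * np.sin(phi),
            radius * np.cos(theta),
        ])
        speed = radius * np.sqrt(1.0 + (c * np.sin(theta)) ** 2)
        theta += step / speed
    return np.asarray(pts)


def _globule_coords(
    n: int, rng: np.random.Generator, flat_face: bool = False
) -> np.ndarray:
    """Calpha coordinates of a compact jittered globule of n residues.

    Residues are laid out centre-outwards on concentric spherical shells,
    following a spiral with ~3.8 A spacing within each shell, and jittered
    so the burial of individual residues varies continuously instead of in
    discrete lattice classes.  With ``flat_face`` the globule is truncated
    at x = +7 A, producing the flat surface used as the homodimer contact.
    """
    coords = [np.zeros(3)]
    k = 1
    while len(coords) < 3 * n:
        shell = _spherical_spiral(k * _SHELL_GAP)
        coords.extend(shell)
        k += 1
    coords = np.asarray(coords)
    coords = coords + rng.uniform(-0.9, 0.9, size=coords.shape)
    if flat_face:
        coords = coords[coords[:, 0] <= _FACE_CUT]
    return coords[:n]


def _build_atom_array(
    sequence: list[str],
    ca: np.ndarray,
    rng: np.random.Generator,
    chain_id: str = "A",
) -> struc.AtomArray:
    atoms = []
    for i, (aa, pos) in enumerate(zip(sequence, ca)):
        atoms.append((chain_id, i + 1, ONE_TO_THREE[aa], "CA", "C", pos))
        if aa != "G":
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append((chain_id, i + 1, ONE_TO_THREE[aa], "CB", "C",
                          pos + _CB_LENGTH * direction))
            if aa not in _SMALL_AA:
                atoms.append((chain_id, i + 1, ONE_TO_THREE[aa], "CG", "C",
                              pos + _CG_LENGTH * direction))
    arr = struc.AtomArray(len(atoms))
    arr.chain_id = np.array([a[0] for a in atoms])
    arr.res_id = np.array([a[1] for a in atoms])
    arr.res_name = np.array([a[2] for a in atoms])
    arr.atom_name = np.array([a[3] for a in atoms])
    arr.element = np.array([a[4] for a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    arr.coord = np.array([a[5] for a in atoms], dtype=np.float32)
    return arr


def _mirror_dimer(monomer: struc.AtomArray, gap: float = _DIMER_GAP) -> struc.AtomArray:
    """Two-chain assembly: chain B is chain A mirrored through a plane just
    beyond the flat face, creating a face-to-face contact patch."""
    plane_x = _FACE_CUT + gap / 2.0
    partner = monomer.copy()
    partner.chain_id = np.full(partner.array_length(), "B")
    coord = partner.coord.copy()
    coord[:, 0] = 2 * plane_x - coord[:, 0]
    partner.coord = coord
    return monomer + partner


def make_structures(cfg: GeneratorConfig, out_dir=None) -> dict:
    """Generate monomer (and dimer) structures for every protein.

    Returns ``{protein_id: {"sequence", "monomer", "dimer"}}`` with biotite
    AtomArrays; when ``out_dir`` is given, PDB files are also written as
    ``<protein>_monomer.pdb`` / ``<protein>_dimer.pdb``.
    """
    root = np.random.SeedSequence(cfg.seed)
    struct_seed, _, _ = root.spawn(3)
    per_protein = struct_seed.spawn(cfg.n_proteins)

    comp = cfg.aa_composition or {aa: 1.0 / 20 for aa in AA_ORDER}
    aas = sorted(comp)
    probs = np.array([comp[a] for a in aas], float)
    probs /= probs.sum()

    out = {}
    for i, prot in enumerate(cfg.protein_ids):
        rng = np.random.default_rng(per_protein[i])
        seq = list(rng.choice(aas, size=cfg.residues_per_protein, p=probs))
        ca = _globule_coords(cfg.residues_per_protein, rng,
                             flat_face=i in cfg.dimer_proteins)
        monomer = _build_atom_array(seq, ca, rng)
        dimer = _mirror_dimer(monomer) if i in cfg.dimer_proteins else None
        out[prot] = {"sequence": seq, "monomer": monomer, "dimer": dimer}
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            _write_pdb(monomer, out_dir / f"{prot}_monomer.pdb")
            if dimer is not None:
                _write_pdb(dimer, out_dir / f"{prot}_dimer.pdb")
    return out


def _write_pdb(arr: struc.AtomArray, path) -> None:
    f = pdbio.PDBFile()
    pdbio.set_structure(f, arr)
    f.write(str(path))


def _context_features(arr: struc.AtomArray, prot: str) -> pd.DataFrame:
    rasa = compute_rasa(arr, "A")
    wcn = compute_wcn(arr, "A")
    feat = rasa.merge(wcn, on="position")
    feat.insert(0, "protein", prot)
    feat.insert(1, "chain", "A")
    return feat


def make_features(cfg: GeneratorConfig, structures: dict | None = None) -> dict:
    """Per-residue features plus ground truth for the whole benchmark.

    Computes rASA and WCN from the generated structures in two contexts —
    the generating assembly (dimer for homodimer proteins) and the bare
    monomer — and plants secondary structure, backbone dihedrals and
    crystal-resolved flags consistently in both.  Ground-truth burial is
    rASA <= 0.1 in the assembly context; special sites (emergent dimer
    interface, degron-like surface sites, left-handed-loop sites) are
    recorded in the truth table.
    """
    if structures is None:
        structures = make_structures(cfg)
    root = np.random.SeedSequence(cfg.seed)
    _, feat_seed, _ = root.spawn(3)
    per_protein = feat_seed.spawn(cfg.n_proteins)

    feats_assembly, feats_monomer, truths = [], [], []
    interface: dict[str, set[int]] = {}
    for i, prot in enumerate(cfg.protein_ids):
        rng = np.random.default_rng(per_protein[i])
        mono_arr = structures[prot]["monomer"]
        dim_arr = structures[prot]["dimer"]
        f_mono = _context_features(mono_arr, prot)
        f_asm = _context_features(dim_arr, prot) if dim_arr is not None else f_mono.copy()

        n = len(f_mono)
        ss3 = rng.choice(["helix", "strand", "loop"], size=n, p=[0.35, 0.25, 0.40])
        phi = np.where(
            ss3 == "helix", rng.normal(-57, 8, n),
            np.where(ss3 == "strand", rng.normal(-120, 15, n), rng.normal(-75, 20, n)),
        )
        psi = np.where(
            ss3 == "helix", rng.normal(-47, 8, n),
            np.where(ss3 == "strand", rng.normal(130, 15, n), rng.normal(150, 20, n)),
        )
        crystal = rng.random(n) > 0.05

        # emergent interface: exposed in monomer, buried in the dimer assembly
        iface: set[int] = set()
        if dim_arr is not None:
            calls = find_interface(f_mono, f_asm)
            iface = set(calls.loc[calls["is_interface"], "position"].astype(int))
        interface[prot] = iface

        truth = pd.DataFrame({
            "protein": prot,
            "position": f_asm["position"].to_numpy(),
            "wt": f_asm["wt"].to_numpy(),
            "env": np.where(f_asm["rasa"] <= RASA_CUTOFF, "buried", "exposed"),
            "special": "none",
        })
        truth.loc[truth["position"].isin(sorted(iface)), "special"] = "interface"

        for f in (f_mono, f_asm):
            f["ss3"] = ss3
            f["ss8"] = np.where(ss3 == "helix", "H", np.where(ss3 == "strand", "E", "-"))
            f["phi"] = phi
            f["psi"] = psi
            f["crystal_resolved"] = crystal
        feats_assembly.append(f_asm)
        feats_monomer.append(f_mono)
        truths.append(truth)

    features = pd.concat(feats_assembly, ignore_index=True)
    features_monomer = pd.concat(feats_monomer, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)

    site_rng = np.random.default_rng(feat_seed.spawn(cfg.n_proteins + 1)[-1])
    _plant_special_sites(cfg, features, features_monomer, truth, site_rng)
    return {
        "features": features,
        "features_monomer": features_monomer,
        "truth": truth,
        "interface": interface,
        "structures": structures,
    }


def _plant_special_sites(cfg, features, features_monomer, truth, rng) -> None:
    """Designate degron-like and left-handed-loop sites on ordinary
    exposed/loop residues (in place, on both feature frames and truth)."""
    ordinary = truth[(truth["special"] == "none") & (truth["env"] == "exposed")]
    n_deg = min(cfg.n_degron_sites, len(ordinary))
    degron_idx = rng.choice(ordinary.index.to_numpy(), size=n_deg, replace=False)
    truth.loc[degron_idx, "special"] = "degron"

    loop_mask = (
        (truth["special"] == "none")
        & (truth["env"] == "exposed")
        & (features["ss3"] == "loop").to_numpy()
    )
    candidates = truth[loop_mask]
    n_lh = min(cfg.n_lefthanded_sites, len(candidates))
    lh_idx = rng.choice(candidates.index.to_numpy(), size=n_lh, replace=False)
    truth.loc[lh_idx, "special"] = "lefthanded"
    # plant backbone dihedrals inside the left-handed window on both frames
    phi_lh = rng.uniform(20, 140, size=n_lh)
    psi_lh = rng.uniform(-60, 60, size=n_lh)
    for f in (features, features_monomer):
        f.loc[lh_idx, "phi"] = phi_lh
        f.loc[lh_idx, "psi"] = psi_lh
        f.loc[lh_idx, "ss3"] = "loop"
        f.loc[lh_idx, "ss8"] = "-"
        f.loc[lh_idx, "crystal_resolved"] = True


def make_scores(
    cfg: GeneratorConfig,
    generated: dict,
    inject_controls: bool = False,
) -> list[Dataset]:
    """Per-protein score tables drawn around the planted mean effects.

    For every residue and variant (a random ``1 - completeness`` fraction is
    dropped): mean = generating-matrix cell of the residue's true
    environment, overridden at degron sites (buried matrix despite surface
    exposure) and left-handed-loop sites (variant-type tolerance profile);
    score = mean + Normal(0, noise_sd); reported sd = noise_sd.  With
    ``inject_controls`` synonymous and nonsense rows are added for
    filter-path testing.
    """
    mats = cfg.true_matrices or default_true_matrices()
    truth = generated["truth"]
    root = np.random.SeedSequence(cfg.seed)
    _, _, score_seed = root.spawn(3)
    per_protein = score_seed.spawn(cfg.n_proteins)

    datasets = []
    for i, prot in enumerate(cfg.protein_ids):
        rng = np.random.default_rng(per_protein[i])
        tr = truth[truth["protein"] == prot]
        rows = []
        for _, res in tr.iterrows():
            wt = res["wt"]
            wt_i = AA_INDEX[wt]
            for var in AA_ORDER:
                if var == wt:
                    continue
                if rng.random() > cfg.completeness:
                    continue
                if res["special"] == "lefthanded":
                    mean = LEFTHANDED_PROFILE[var]
                elif res["special"] == "degron":
                    mean = mats["buried"][wt_i, AA_INDEX[var]]
                else:
                    mean = mats[res["env"]][wt_i, AA_INDEX[var]]
                score = mean + rng.normal(0.0, cfg.noise_sd)
                rows.append((prot, "A", int(res["position"]), wt, var,
                             score, cfg.noise_sd))
        df = pd.DataFrame(rows, columns=["protein", "chain", "position",
                                         "wt", "var", "score", "sd"])
        if inject_controls:
            extra = pd.DataFrame([
                (prot, "A", int(tr["position"].iloc[0]), tr["wt"].iloc[0],
                 tr["wt"].iloc[0], 1.0, cfg.noise_sd),
                (prot, "A", int(tr["position"].iloc[1]), tr["wt"].iloc[1],
                 "*", 0.0, cfg.noise_sd),
            ], columns=df.columns)
            df = pd.concat([df, extra], ignore_index=True)
        datasets.append(Dataset(
            protein_id=prot, records=df,
            n_residues_total=cfg.residues_per_protein,
        ))
    return datasets


@dataclass
class Benchmark:
    """Everything the pipeline needs, with ground truth attached."""

    config: GeneratorConfig
    pool: pd.DataFrame
    features: pd.DataFrame           # generating-assembly context
    features_monomer: pd.DataFrame   # monomer context for every protein
    truth: pd.DataFrame
    interface: dict[str, set[int]]
    true_matrices: dict[str, np.ndarray]
    datasets: list = field(default_factory=list)

    def special_positions(self, kind: str) -> dict[str, set[int]]:
        sub = self.truth[self.truth["special"] == kind]
        return {p: set(g["position"].astype(int)) for p, g in sub.groupby("protein")}

    def ordinary_exposed_positions(self) -> dict[str, set[int]]:
        sub = self.truth[(self.truth["special"] == "none")
                         & (self.truth["env"] == "exposed")]
        return {p: set(g["position"].astype(int)) for p, g in sub.groupby("protein")}


def make_benchmark(cfg: GeneratorConfig | None = None, seed: int | None = None,
                   inject_controls: bool = False) -> Benchmark:
    """Generate the full synthetic benchmark (``benchmark6`` preset by
    default): structures, features, truth and the combined score pool."""
    if cfg is None:
        cfg = GeneratorConfig(seed=seed if seed is not None else 1)
    generated = make_features(cfg)
    datasets = make_scores(cfg, generated, inject_controls=inject_controls)
    from .io import filter_substitutions
    datasets = [filter_substitutions(ds) for ds in datasets]
    pool = combine(datasets)
    return Benchmark(
        config=cfg,
        pool=pool,
        features=generated["features"],
        features_monomer=generated["features_monomer"],
        truth=generated["truth"],
        interface=generated["interface"],
        true_matrices=cfg.true_matrices or default_true_matrices(),
        datasets=datasets,
    )


def build_peptide(phi_psi: list[tuple[float, float]]) -> struc.AtomArray:
    """Synthetic all-backbone peptide built by forward kinematics.

    Places N, CA, C atoms of ``len(phi_psi)`` alanine residues with ideal
    bond geometry and the given (phi, psi) angles in degrees (omega fixed
    at 180 deg).  Fixture generator for dihedral-recovery tests.
    """
    b_n_ca, b_ca_c, b_c_n = 1.458, 1.525, 1.329
    a_n_ca_c, a_ca_c_n, a_c_n_ca = 111.2, 116.2, 121.7

    def place(a, b, c, bond, angle, torsion):
        angle, torsion = np.radians(angle), np.radians(torsion)
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        n = np.cross(ab, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d = np.array([
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ])
        return c + d[0] * bc + d[1] * m + d[2] * n

    coords = [
        np.array([0.0, 0.0, 0.0]),                 # N1
        np.array([b_n_ca, 0.0, 0.0]),              # CA1
    ]
    coords.append(place(np.array([0.0, 1.0, 0.0]), coords[0], coords[1],
                        b_ca_c, a_n_ca_c, 60.0))   # C1 (arbitrary phi1)
    for i, (phi, psi) in enumerate(phi_psi):
        n_prev, ca_prev, c_prev = coords[3 * i], coords[3 * i + 1], coords[3 * i + 2]
        # psi_i positions N_{i+1}; omega positions CA_{i+1}; phi_{i+1} positions C_{i+1}
        n_next = place(n_prev, ca_prev, c_prev, b_c_n, a_ca_c_n, psi)
        ca_next = place(ca_prev, c_prev, n_next, b_n_ca, a_c_n_ca, 180.0)
        coords.extend([n_next, ca_next])
        if i + 1 < len(phi_psi):
            c_next = place(c_prev, n_next, ca_next, b_ca_c, a_n_ca_c,
                           phi_psi[i + 1][0])
            coords.append(c_next)
    n_res = len(phi_psi) + 1
    names = (["N", "CA", "C"] * n_res)[: len(coords)]
    res_ids = np.repeat(np.arange(1, n_res + 1), 3)[: len(coords)]
    arr = struc.AtomArray(len(coords))
    arr.chain_id = np.full(len(coords), "A")
    arr.res_id = res_ids
    arr.res_name = np.full(len(coords), "ALA")
    arr.atom_name = np.array(names)
    arr.element = np.array([n[0] for n in names])
    arr.hetero = np.zeros(len(coords), dtype=bool)
    arr.coord = np.asarray(coords, dtype=np.float32)
    return arr
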