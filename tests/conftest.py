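import numpy as np
import pandas as pd
import pytest
import biotite.structure as struc

from abundmat import simulate
from abundmat._aa import AA_ORDER


@pytest.fixture(scope="session")
def benchmark6():
    """The default synthetic benchmark: 6 proteins x 150 residues, noise sd
    0.05, 80% completeness, seed 1."""
    return simulate.make_benchmark(seed=1)


@pytest.fixture(scope="session")
def mini_benchmark():
    """A small, fast benchmark for unit-level checks."""
    cfg = simulate.GeneratorConfig(
        n_proteins=3, residues_per_protein=40, dimer_proteins=(2,),
        n_degron_sites=3, n_lefthanded_sites=6, seed=7,
    )
    return simulate.make_benchmark(cfg)


@pytest.fixture()
def random_pool():
    """Random 5,000-record pool with matching features, for oracle tests."""
    rng = np.random.default_rng(123)
    n = 5000
    proteins = rng.choice(["P1", "P2", "P3"], size=n)
    positions = rng.integers(1, 120, size=n)
    wt = rng.choice(list(AA_ORDER), size=n)
    var = rng.choice(list(AA_ORDER), size=n)
    keep = wt != var
    pool = pd.DataFrame({
        "protein": proteins[keep], "chain": "A",
        "position": positions[keep],
        "wt": wt[keep], "var": var[keep],
        "score": rng.uniform(-0.2, 1.2, size=keep.sum()),
        "sd": rng.uniform(0.01, 0.3, size=keep.sum()),
    }).drop_duplicates(["protein", "position", "wt", "var"])
    residues = pool[["protein", "chain", "position", "wt"]].drop_duplicates(
        ["protein", "chain", "position"])
    rng2 = np.random.default_rng(456)
    features = residues.assign(
        rasa=rng2.uniform(0, 0.8, len(residues)),
        wcn=rng2.uniform(0, 20, len(residues)),
        ss3=rng2.choice(["helix", "strand", "loop"], len(residues)),
        ss8="-", phi=np.nan, psi=np.nan, crystal_resolved=True,
    ).reset_index(drop=True)
    return pool.reset_index(drop=True), features


def make_atom_array(records):
    """Build an AtomArray from (chain, res_id, res_name, atom_name, element,
    xyz) tuples."""
    arr = struc.AtomArray(len(records))
    arr.chain_id = np.array([r[0] for r in records])
    arr.res_id = np.array([r[1] for r in records])
    arr.res_name = np.array([r[2] for r in records])
    arr.atom_name = np.array([r[3] for r in records])
    arr.element = np.array([r[4] for r in records])
    arr.hetero = np.zeros(len(records), dtype=bool)
    arr.coord = np.array([r[5] for r in records], dtype=np.float32)
    return arr


@pytest.fixture()
def alanine():
    """Ideal heavy-atom alanine (N, CA, C, O, CB)."""
    coords = {
        "N": (1.458, 0.0, 0.0), "CA": (0.0, 0.0, 0.0),
        "C": (-0.55, 1.42, 0.0), "O": (0.10, 2.39, 0.35),
        "CB": (-0.54, -0.78, -1.21),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    return make_atom_array([
        ("A", 1, "ALA", name, elements[name], xyz) for name, xyz in coords.items()
    ])
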