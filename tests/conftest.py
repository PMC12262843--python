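import numpy as np
import pytest

import tmrkit as tk


@pytest.fixture(scope="session")
def submap():
    return tk.default_subdomain_map()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_model(coords, res_ids=None, atom_names=None, chain_ids=None,
               b=None, model_id="fixture", res_names=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    return tk.StructureModel(
        model_id=model_id,
        predictor="test",
        chain_id=np.asarray(chain_ids) if chain_ids is not None else np.full(n, "A"),
        res_id=np.asarray(res_ids, int) if res_ids is not None else np.arange(1, n + 1),
        res_name=np.asarray(res_names) if res_names is not None else np.full(n, "ALA"),
        atom_name=np.asarray(atom_names) if atom_names is not None else np.full(n, "CA"),
        coord=coords,
        confidence=None if b is None else np.asarray(b, float),
    )


@pytest.fixture
def four_residue_pdb(tmp_path):
    """Hand-written 4-residue PDB with known B-factors."""
    lines = []
    coords = [(0.0, 0.0, 0.0), (3.8, 0.0, 0.0), (7.6, 0.0, 0.0), (11.4, 0.0, 0.0)]
    bfac = [90.0, 80.5, 70.25, 60.0]
    for i, ((x, y, z), b) in enumerate(zip(coords, bfac), start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C  "
        )
    lines.append("END")
    path = tmp_path / "four.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path, coords, bfac
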