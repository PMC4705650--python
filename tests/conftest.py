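import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from helixgauge.fixtures import HelixSpec, make_ideal_helix


THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ATOM      3  C   ALA A   1      10.560   5.705  -4.123  1.00 14.00           C
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def multi_model_pdb(tmp_path):
    lines = []
    for m in range(3):
        lines.append(f"MODEL     {m + 1:>4d}")
        for i in range(3):
            x = 1.0 * i + 10.0 * m
            lines.append(
                f"ATOM  {i + 1:>5d}  CA  GLY A{i + 1:>4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "multi.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def canonical_helix():
    """Noiseless 9-anchor helix: radius 9.4 A, pitch 34 A, 36 deg/step."""
    return make_ideal_helix(HelixSpec(n_points=9, radius=9.4, pitch=34.0, sweep_per_step=36.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
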