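import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dhprof import (CoupledRegion, SyntheticStructureSpec, make_domain_bundle,
                    make_structure_pair)

TOY_PDB = """\
REMARK 465   M RES C SSSEQI
REMARK 465     ALA A   240
REMARK 465     GLY A   241
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  CA  GLY A   2       8.502   5.242  -4.439  1.00 12.00           C
ATOM      4  CA  HIS A   3       5.605   4.856  -2.100  1.00 14.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture(scope="session")
def two_loop_bundle():
    """Emulation of the two-variable-loop pattern: one high-entropy loop
    with missing density, one high-entropy loop with elevated B-factors."""
    spec = SyntheticStructureSpec(n_residues=290, seed=11)
    coupling = [CoupledRegion(120, 130, high_h=True, unmodeled=True),
                CoupledRegion(200, 212, high_h=True, high_b=True)]
    return make_domain_bundle(spec, coupling=coupling), coupling


@pytest.fixture(scope="session")
def noisy_pair():
    spec = SyntheticStructureSpec(n_residues=200, noise_sigma=0.3,
                                  displaced=list(range(10, 30)), seed=42)
    return make_structure_pair(spec)
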