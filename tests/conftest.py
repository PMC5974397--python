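import math

import numpy as np
import pytest

from oligoscope.structures import ChromophoreSet, MolecularStructure


def make_structure(positions, radii=None, chain_ids=None, residue_numbers=None,
                   residue_names=None, atom_names=None, elements=None,
                   frame_label="raw"):
    """Assemble a MolecularStructure from plain lists (test helper)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    radii = np.full(n, 0.17) if radii is None else np.asarray(radii, dtype=float)
    return MolecularStructure(
        positions=positions,
        radii=radii,
        elements=np.array(elements or ["C"] * n, dtype=object),
        chain_ids=np.array(chain_ids or ["A"] * n, dtype=object),
        residue_names=np.array(residue_names or ["GLY"] * n, dtype=object),
        residue_numbers=np.array(residue_numbers or range(1, n + 1), dtype=int),
        atom_names=np.array(atom_names or ["CA"] * n, dtype=object),
        frame_label=frame_label,
    )


def ring_chromophores(n, ring_radius, delta_deg, tilt_deg, z=1.75,
                      site_wavelength=524.0, dipole_strength=0.03, phase=0.3):
    """Cn ring of dipoles; delta is the azimuth off radial (90 = tangential)."""
    tilt, delta = math.radians(tilt_deg), math.radians(delta_deg)
    pos, dirs = [], []
    for i in range(n):
        a = 2 * math.pi * i / n + phase
        radial = np.array([math.cos(a), math.sin(a), 0.0])
        tangent = np.array([-math.sin(a), math.cos(a), 0.0])
        inplane = math.cos(delta) * radial + math.sin(delta) * tangent
        dirs.append(math.cos(tilt) * inplane + math.sin(tilt) * np.array([0, 0, 1.0]))
        pos.append(ring_radius * radial + [0.0, 0.0, z])
    return ChromophoreSet(
        positions=np.array(pos),
        directions=np.array(dirs),
        site_wavelengths=np.full(n, site_wavelength),
        dipole_strengths=np.full(n, dipole_strength),
    )


MINIMAL_PDB = """\
ATOM      1  CA  GLY A   1      10.000   0.000   0.000  1.00  0.00           C
END
"""

PDB_WITH_WATER_AND_H = """\
ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  HA  GLY A   1       1.500   2.000   3.000  1.00  0.00           H
ATOM      3  N   GLY A   2       4.000   5.000   6.000  1.00  0.00           N
HETATM    4  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    def write(text, name="test.pdb"):
        p = tmp_path / name
        p.write_text(text)
        return str(p)

    return write
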