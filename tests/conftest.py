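import numpy as np
import pytest

import cxdisim as cx


def write_toy_pdb(path, positions, elements, occupancies=None):
    """Write a minimal but column-correct PDB file for round-trip tests."""
    occupancies = occupancies if occupancies is not None else [1.0] * len(positions)
    lines = []
    for i, (pos, el, occ) in enumerate(zip(positions, elements, occupancies), start=1):
        name = el.upper().ljust(3)
        lines.append(
            f"ATOM  {i:5d}  {name:<3s}ALA A{i:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{occ:6.2f}  0.00"
            f"          {el.upper():>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_pdb(tmp_path):
    positions = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (0.0, 2.25, -1.125)]
    elements = ["C", "N", "O"]
    return write_toy_pdb(tmp_path / "toy.pdb", positions, elements), positions, elements


@pytest.fixture
def small_detector():
    geom = cx.DetectorGeometry.monolithic(64, 200e-6, 0.1)
    maps = cx.pixel_maps(geom, 3.0)
    return geom, maps


@pytest.fixture
def coil40():
    return cx.make_fixture("random_coil", n=40, seed=1)
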