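import numpy as np
import pytest

from lovhydra.frames import Frame


def make_water_frame(o_positions, h_offsets=None, extra_atoms=None):
    """Frame of waters from oxygen positions; hydrogens default to a rigid
    pair of fixed offsets unless per-water offsets are given.

    ``extra_atoms``: list of (xyz, resid, resname, element, name) appended
    after the waters (e.g. protein beads).
    """
    o_positions = np.asarray(o_positions, dtype=float)
    n = o_positions.shape[0]
    if h_offsets is None:
        h_offsets = [np.array([[0.9572, 0.0, 0.0],
                               [-0.24, 0.927, 0.0]])] * n
    coords, resid, resname, element, name = [], [], [], [], []
    for i, o in enumerate(o_positions):
        coords.extend([o, o + h_offsets[i][0], o + h_offsets[i][1]])
        resid.extend([i + 1] * 3)
        resname.extend(["HOH"] * 3)
        element.extend(["O", "H", "H"])
        name.extend(["OW", "HW1", "HW2"])
    for xyz, rid, rn, el, nm in (extra_atoms or []):
        coords.append(np.asarray(xyz, dtype=float))
        resid.append(rid)
        resname.append(rn)
        element.append(el)
        name.append(nm)
    return Frame(np.array(coords), np.array(resid),
                 np.array(resname, dtype=object),
                 np.array(element, dtype=object),
                 np.array(name, dtype=object))


def make_bead_frame(xyz, resid_start=403, time_ps=0.0):
    """Chain of carbon beads, one residue each."""
    xyz = np.asarray(xyz, dtype=float)
    n = xyz.shape[0]
    return Frame(xyz, np.arange(resid_start, resid_start + n),
                 np.array(["ALA"] * n, dtype=object),
                 np.array(["C"] * n, dtype=object),
                 np.array(["CA"] * n, dtype=object), time_ps)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
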