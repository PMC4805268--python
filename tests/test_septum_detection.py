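"""Septum peak detection, manual edits, and chain-to-cell splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import septachain as sc
from septachain.chain_detection import ChainObject
from septachain.config import SeptumParams

PX = 0.066
NOSMOOTH = SeptumParams(profile_smooth_um=0.0)


# independent exhaustive oracle shared with the acceptance suite
from peak_oracle import brute_force_detect  # noqa: E402


@pytest.mark.parametrize("seed", range(6))
def test_peak_selection_matches_brute_force(seed):
    """find_peaks-based detection equals the exhaustive prominence scan."""
    rng = np.random.default_rng(seed)
    y = rng.normal(100, 20, size=160)
    pos = (np.arange(160) + 0.5) * PX
    p = SeptumParams(profile_smooth_um=0.0, pole_margin_um=0.0,
                     min_cell_length_um=0.4)
    got = sc.detect_septa(pos, y, p, axis_length=160 * PX)
    expected = brute_force_detect(y, p, int(np.ceil(0.4 / PX)))
    assert len(got) == len(expected)
    for m, i in zip(got, expected):
        assert abs(m.axial_position - pos[i]) <= 0.51 * PX


def gaussian_bumps(length_um, centers, amp=150.0, sigma=0.1, base=100.0):
    n = int(round(length_um / PX))
    pos = (np.arange(n) + 0.5) * PX
    y = np.full(n, base)
    for c in centers:
        y += amp * np.exp(-((pos - c) ** 2) / (2 * sigma ** 2))
    return pos, y


def test_three_bumps_localized():
    """Bumps at 2/4/6 um on an 8 um chain found within 0.05 um."""
    pos, y = gaussian_bumps(8.0, [2.0, 4.0, 6.0])
    markers = sc.detect_septa(pos, y, axis_length=8.0)
    assert [m.origin for m in markers] == ["auto"] * 3
    np.testing.assert_allclose([m.axial_position for m in markers],
                               [2.0, 4.0, 6.0], atol=0.05)


def test_close_pair_keeps_taller():
    """Two bumps 0.3 um apart with 0.5 um minimum separation -> the taller wins."""
    n = int(round(8.0 / PX))
    pos = (np.arange(n) + 0.5) * PX
    y = np.full(n, 100.0)
    y += 150 * np.exp(-((pos - 4.0) ** 2) / (2 * 0.06 ** 2))
    y += 100 * np.exp(-((pos - 4.3) ** 2) / (2 * 0.06 ** 2))
    p = SeptumParams(min_cell_length_um=0.5, profile_smooth_um=0.0)
    markers = sc.detect_septa(pos, y, p, axis_length=8.0)
    assert len(markers) == 1
    assert markers[0].axial_position == pytest.approx(4.0, abs=0.1)


def test_flat_profile_no_septa():
    pos = (np.arange(100) + 0.5) * PX
    assert sc.detect_septa(pos, np.full(100, 5.0), axis_length=100 * PX) == []


def test_pole_caps_rejected():
    """Peaks inside the pole margin (membrane caps) are not septa."""
    pos, y = gaussian_bumps(8.0, [0.1, 4.0, 7.9])
    markers = sc.detect_septa(pos, y, axis_length=8.0)
    assert [round(m.axial_position, 1) for m in markers] == [4.0]


def test_affine_intensity_invariance():
    """Detection depends only on profile shape, not gain or offset."""
    pos, y = gaussian_bumps(10.0, [2.5, 5.0, 7.5])
    rng = np.random.default_rng(3)
    y = y + rng.normal(0, 5, size=y.size)
    a = sc.detect_septa(pos, y, axis_length=10.0)
    b = sc.detect_septa(pos, 7.3 * y + 1234.5, axis_length=10.0)
    assert len(a) == len(b)
    np.testing.assert_allclose([m.axial_position for m in a],
                               [m.axial_position for m in b], atol=1e-9)


# ----------------------------------------------------------------- editing

def markers_at(*positions):
    return [sc.SeptumMarker(chain_id=1, axial_position=p) for p in positions]


def test_edit_add_and_remove():
    m, rep = sc.edit_septa(markers_at(2.0, 6.0), add=[3.0], axis_length=8.0)
    assert rep == []
    assert [x.axial_position for x in m] == [2.0, 3.0, 6.0]
    assert [x.origin for x in m] == ["auto", "manual", "auto"]
    m2, _ = sc.edit_septa(m, remove=[2.0], axis_length=8.0)
    assert [x.axial_position for x in m2] == [3.0, 6.0]


def test_edit_rejects_close_addition_with_report():
    m, rep = sc.edit_septa(markers_at(2.0, 6.0), add=[2.05], axis_length=8.0,
                           params=SeptumParams(min_cell_length_um=0.5))
    assert [x.axial_position for x in m] == [2.0, 6.0]
    assert len(rep) == 1 and "rejected" in rep[0]


def test_edit_errors():
    with pytest.raises(ValueError):
        sc.edit_septa(markers_at(2.0), add=[9.0], axis_length=8.0)
    with pytest.raises(ValueError):
        sc.edit_septa(markers_at(2.0), remove=[5.0], axis_length=8.0)


# ---------------------------------------------------------------- splitting

def chain_of_length(L):
    ch = ChainObject(chain_id=1, mask=np.ones((1, 1), bool), offset=(0, 0),
                     pixel_size=PX)
    ch.axis = np.array([[0.0, 0.0], [L, 0.0]])
    ch.axis_length = L
    return ch


def test_split_no_markers_margin_zero():
    cells = sc.split_into_cells(chain_of_length(8.0), [],
                                params=SeptumParams(pole_margin_um=0.0))
    assert len(cells) == 1
    assert cells[0].length == pytest.approx(8.0)


def test_split_three_markers():
    cells = sc.split_into_cells(chain_of_length(8.0), markers_at(2.0, 4.0, 6.0),
                                params=SeptumParams(pole_margin_um=0.0))
    assert len(cells) == 4
    assert [c.length for c in cells] == pytest.approx([2.0] * 4)
    assert [c.cell_index for c in cells] == [1, 2, 3, 4]


def test_short_chain_disqualified():
    ch = chain_of_length(0.4)
    assert sc.split_into_cells(ch, [], pole_margin_um=0.25) == []
    assert not ch.qualified


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.5, 11.5), min_size=0, max_size=8, unique=True))
def test_cell_lengths_telescope(marker_positions):
    """Sum of cell lengths = axis length - 2 x pole margin, any marker set."""
    L, margin = 12.0, 0.25
    cells = sc.split_into_cells(chain_of_length(L),
                                markers_at(*sorted(marker_positions)),
                                pole_margin_um=margin)
    assert len(cells) == len(marker_positions) + 1
    total = sum(c.length for c in cells)
    assert total == pytest.approx(L - 2 * margin)
    # intervals partition without overlap
    for a, b in zip(cells[:-1], cells[1:]):
        assert a.axial_interval[1] == pytest.approx(b.axial_interval[0])
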