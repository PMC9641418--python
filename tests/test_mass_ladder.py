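"""Exact-mass ladder chemistry against an independent residue-mass oracle.

The oracle recomputes every residue mass from atomic monoisotopic masses
(CODATA/IUPAC values typed in here by hand), entirely independent of the
constants used by the implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycomsi import mass_ladder as ml
from glycomsi.mass_ladder import Adduct

# --- independent atomic-mass oracle ---------------------------------------
C = 12.0
H = 1.0078250319
O = 15.9949146221
N = 14.0030740052
P = 30.97376200
NA = 22.98976928
K = 38.96370649
ELECTRON = 0.00054858

ORACLE = {
    "hexose": 6 * C + 10 * H + 5 * O,          # C6H10O5 in-chain residue
    "hexnac": 8 * C + 13 * H + N + 5 * O,      # C8H13NO5
    "fucose": 6 * C + 10 * H + 4 * O,          # C6H10O4
    "neuac": 11 * C + 17 * H + N + 8 * O,      # C11H17NO8
    "water": 2 * H + O,
    "hpo3": H + P + 3 * O,
    "na+": NA - ELECTRON,
    "k+": K - ELECTRON,
    "h+": H - ELECTRON,
}
ORACLE_ADDUCT = {Adduct.sodium: ORACLE["na+"], Adduct.potassium: ORACLE["k+"],
                 Adduct.proton: ORACLE["h+"]}


def oracle_polymer_mz(dp, n_phosphate, adduct):
    return (dp * ORACLE["hexose"] + ORACLE["water"]
            + n_phosphate * ORACLE["hpo3"] + ORACLE_ADDUCT[adduct])


def oracle_glycan_mz(composition, adduct):
    res = {"Hex": ORACLE["hexose"], "HexNAc": ORACLE["hexnac"],
           "Fuc": ORACLE["fucose"], "NeuAc": ORACLE["neuac"]}
    return (sum(res[r] * n for r, n in composition.items())
            + ORACLE["water"] + ORACLE_ADDUCT[adduct])


# --- polymer masses --------------------------------------------------------

def test_cl7_sodiated_integer_label_is_1175():
    """The sodiated 7-mer labels as m/z 1,175 (round half-up)."""
    assert ml.round_half_up(ml.polymer_mz(7, 0, Adduct.sodium)) == 1175
    assert ml.polymer_mz(7, 0, Adduct.sodium) == pytest.approx(1175.37, abs=0.005)


def test_successive_polymer_spacing_is_one_hexose():
    """Consecutive chain lengths differ by one hexose residue, ~162 m/z."""
    diff = ml.polymer_mz(8) - ml.polymer_mz(7)
    assert diff == pytest.approx(162.05, abs=0.005)
    assert ml.round_half_up(diff) == 162


@pytest.mark.parametrize("adduct", list(Adduct))
@pytest.mark.parametrize("n_phosphate", [0, 1, 2])
def test_polymer_mz_matches_atomic_mass_oracle(adduct, n_phosphate):
    for dp in range(3, 26):
        assert ml.polymer_mz(dp, n_phosphate, adduct) == pytest.approx(
            oracle_polymer_mz(dp, n_phosphate, adduct), abs=1e-4)


def test_phospho_shift_is_hpo3():
    for dp in (3, 5, 12):
        shift = ml.polymer_mz(dp, 1) - ml.polymer_mz(dp, 0)
        assert shift == pytest.approx(ORACLE["hpo3"], abs=1e-4)


@pytest.mark.parametrize("dp,n_phos", [(1, 0), (0, 0), (5, -1), (3, 4)])
def test_polymer_mz_rejects_bad_arguments(dp, n_phos):
    with pytest.raises(ValueError):
        ml.polymer_mz(dp, n_phos)


# --- glycan masses ---------------------------------------------------------

@pytest.mark.parametrize("comp,expect", [
    ({"Hex": 5, "HexNAc": 4}, 1663.58),
    ({"Hex": 5, "HexNAc": 4, "Fuc": 1}, 1663.58 + 146.058),
])
def test_glycan_mz_examples(comp, expect):
    assert ml.glycan_mz(comp, Adduct.sodium) == pytest.approx(expect, abs=0.005)
    assert ml.glycan_mz(comp, Adduct.sodium) == pytest.approx(
        oracle_glycan_mz(comp, Adduct.sodium), abs=1e-4)


def test_glycan_mz_rejects_empty_and_unknown():
    with pytest.raises(ValueError):
        ml.glycan_mz({})
    with pytest.raises(ValueError):
        ml.glycan_mz({"Hex": 0})
    with pytest.raises(ValueError):
        ml.glycan_mz({"Pentose": 1})


# --- ladder construction ---------------------------------------------------

def test_build_ladder_window_filtering():
    ladder = ml.build_ladder(3, 25, 0, (Adduct.sodium,), (500.0, 3000.0))
    expected = [dp for dp in range(3, 26)
                if 500 <= oracle_polymer_mz(dp, 0, Adduct.sodium) <= 3000]
    assert [s.dp for s in ladder] == expected
    assert all(ladder[i].mz < ladder[i + 1].mz for i in range(len(ladder) - 1))


def test_build_ladder_empty_window():
    assert ml.build_ladder(3, 3, 0, (Adduct.sodium,), (0.0, 100.0)) == []


def test_build_ladder_gp4_to_gp8():
    ladder = ml.build_ladder(4, 8, 0, (Adduct.sodium,), (500.0, 3000.0))
    assert [s.dp for s in ladder] == [4, 5, 6, 7, 8]
    assert [s.label for s in ladder] == ["CL4", "CL5", "CL6", "CL7", "CL8"]


@given(st.integers(3, 20), st.integers(0, 1),
       st.sampled_from(list(Adduct)))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_ladder_spacing_property(dp, n_phos, adduct):
    """Successive polymers differ by exactly one hexose; integer gap 162."""
    gap = ml.polymer_mz(dp + 1, n_phos, adduct) - ml.polymer_mz(dp, n_phos, adduct)
    assert gap == pytest.approx(ml.CONSTANTS.hexose_residue, abs=1e-9)
    assert ml.round_half_up(gap) == 162


# --- peak matching ---------------------------------------------------------

def brute_force_match(peaks, ladder, tolerance):
    """Exhaustive nearest-species assignment (the independent oracle)."""
    best = {}
    for mz, inten in peaks:
        cands = [(abs(mz - s.mz), s.mz, s) for s in ladder
                 if abs(mz - s.mz) <= tolerance]
        if not cands:
            continue
        cands.sort(key=lambda t: (t[0], t[1]))  # tie -> lower-mass species
        sp = cands[0][2]
        if sp.mz not in best or inten > best[sp.mz][1]:
            best[sp.mz] = (mz, inten, sp)
    return {k: (v[0], v[1]) for k, v in best.items()}


def test_match_peaks_simple(default_ladder):
    out = ml.match_peaks([(1175.32, 10.0)], default_ladder, tolerance=0.2)
    assert len(out) == 1
    assert out[0].species.label == "CL7"
    assert out[0].delta_mz == pytest.approx(1175.32 - ml.polymer_mz(7), abs=1e-9)
    assert out[0].within_tolerance


def test_match_peaks_empty():
    assert ml.match_peaks([], [], tolerance=0.2) == []


def test_match_peaks_requires_positive_tolerance(default_ladder):
    with pytest.raises(ValueError):
        ml.match_peaks([(1175.3, 1.0)], default_ladder, tolerance=0.0)


def test_match_peaks_tie_breaks_to_lower_mass():
    a = ml.make_polymer(7)
    b = ml.make_polymer(8)
    mid = (a.mz + b.mz) / 2
    out = ml.match_peaks([(mid, 1.0)], [a, b], tolerance=100.0)
    assert out[0].species.dp == 7


def test_match_peaks_keeps_most_intense_per_species(default_ladder):
    cl7 = ml.polymer_mz(7)
    peaks = [(cl7 - 0.05, 3.0), (cl7 + 0.01, 9.0), (cl7 + 0.08, 1.0)]
    out = ml.match_peaks(peaks, default_ladder, tolerance=0.2)
    assert len(out) == 1
    assert out[0].intensity == 9.0


def test_match_peaks_equals_brute_force(default_ladder, rng):
    """Implementation agrees with exhaustive search on 100-peak instances."""
    for _ in range(5):
        peaks = [(float(rng.uniform(500, 3000)), float(rng.uniform(0, 100)))
                 for _ in range(100)]
        got = ml.match_peaks(peaks, default_ladder, tolerance=0.2)
        want = brute_force_match(peaks, default_ladder, tolerance=0.2)
        assert {a.species.mz: (a.observed_mz, a.intensity) for a in got} == want


def test_match_peaks_idempotent(default_ladder, rng):
    peaks = [(float(rng.normal(ml.polymer_mz(dp), 0.05)), float(rng.uniform(1, 5)))
             for dp in range(4, 12)]
    once = ml.match_peaks(peaks, default_ladder, tolerance=0.2)
    again = ml.match_peaks([(a.observed_mz, a.intensity) for a in once],
                           default_ladder, tolerance=0.2)
    assert [(a.observed_mz, a.species.label) for a in once] == \
        [(a.observed_mz, a.species.label) for a in again]


# --- table round trip ------------------------------------------------------

def test_ladder_table_round_trip(tmp_path, default_ladder):
    glycans = [ml.make_glycan({"Hex": 5, "HexNAc": 4}),
               ml.make_glycan({"Hex": 5, "HexNAc": 4, "Fuc": 1})]
    path = tmp_path / "ladder.tsv"
    ml.write_ladder_table(list(default_ladder) + glycans, path)
    back = ml.read_ladder_table(path)
    assert [(s.label, s.adduct) for s in back] == \
        [(s.label, s.adduct) for s in list(default_ladder) + glycans]
    assert np.allclose([s.mz for s in back],
                       [s.mz for s in list(default_ladder) + glycans])
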