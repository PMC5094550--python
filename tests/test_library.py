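"""Fragment filtering, consensus iRT, m/z arithmetic and library assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_fragment_rows
from irtnorm.calibration import CalibrationSet, precursor_id
from irtnorm.library import (
    LibraryBuildError,
    assemble_library,
    consensus_irt,
    filter_fragments,
    fragment_mz,
    precursor_mz,
)

# Independent oracle for m/z arithmetic: published monoisotopic residue
# masses, proton and water, summed by hand.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
PROTON = 1.00728
WATER = 18.01056


def frag_table(rows):
    return pd.DataFrame(rows, columns=["series", "ordinal", "fragment_charge",
                                       "mz", "intensity"])


class TestFilterFragments:
    def test_mz_range_bounds_inclusive(self):
        frags = frag_table([
            ("y", 5, 1, 299.9, 10.0),   # below range
            ("y", 5, 1, 300.0, 10.0),   # boundary kept
            ("y", 5, 1, 1800.0, 10.0),  # boundary kept
            ("y", 5, 1, 1800.5, 10.0),  # above range
        ])
        kept = filter_fragments(frags)
        assert sorted(kept.mz) == [300.0, 1800.0]

    def test_short_fragments_removed(self):
        frags = frag_table([("y", 2, 1, 500.0, 99.0), ("b", 3, 1, 500.0, 1.0)])
        kept = filter_fragments(frags)
        assert list(kept.ordinal) == [3]

    def test_top6_by_intensity_with_mz_tiebreak(self):
        rows = [("y", 3 + i, 1, 400.0 + 10 * i, 100.0 - 10 * i)
                for i in range(7)]
        rows += [("b", 10, 1, 350.0, 100.0), ("b", 11, 1, 340.0, 100.0)]
        kept = filter_fragments(frag_table(rows))
        assert len(kept) == 6
        assert list(kept.intensity) == sorted(kept.intensity, reverse=True)
        # three fragments tie at 100; lower m/z wins
        top3 = kept[kept.intensity == 100.0]
        assert list(top3.mz) == [340.0, 350.0, 400.0]

    def test_empty_input_gives_empty_output(self):
        assert len(filter_fragments(frag_table([]))) == 0


@pytest.mark.parametrize("values, expected", [
    ([10, 11, 30], 11.0),
    ([10, 20], 15.0),
    ([7], 7.0),
])
def test_consensus_irt_is_the_median(values, expected):
    assert consensus_irt(values) == expected


def test_consensus_irt_empty_rejected():
    with pytest.raises(ValueError):
        consensus_irt([])


class TestFragmentMz:
    def test_b2_against_residue_mass_oracle(self):
        expected = RESIDUE_MASS["A"] + RESIDUE_MASS["G"] + PROTON
        assert fragment_mz("AGK", "b", 2, 1) == pytest.approx(expected, abs=1e-3)
        assert fragment_mz("AGK", "b", 2, 1) == pytest.approx(129.0659, abs=1e-3)

    def test_y1_against_residue_mass_oracle(self):
        expected = RESIDUE_MASS["K"] + WATER + PROTON
        assert fragment_mz("AGK", "y", 1, 1) == pytest.approx(expected, abs=1e-3)
        assert fragment_mz("AGK", "y", 1, 1) == pytest.approx(147.1128, abs=1e-3)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            fragment_mz("ABK", "y", 1, 1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seq=st.text(alphabet=sorted(RESIDUE_MASS), min_size=2, max_size=15),
           data=st.data())
    def test_b_y_mass_conservation(self, seq, data):
        """b_k + y_(L-k) = precursor neutral mass + 2 protons (1+ ions)."""
        k = data.draw(st.integers(1, len(seq) - 1))
        b = fragment_mz(seq, "b", k, 1)
        y = fragment_mz(seq, "y", len(seq) - k, 1)
        neutral = sum(RESIDUE_MASS[c] for c in seq) + WATER
        assert b + y == pytest.approx(neutral + 2 * PROTON, abs=1e-3)

    def test_precursor_mz_matches_residue_sum(self):
        expected = (sum(RESIDUE_MASS[c] for c in "AGK") + WATER
                    + 2 * PROTON) / 2
        assert precursor_mz("AGK", 2) == pytest.approx(expected, abs=1e-3)


def _calibration_db(rng, n=300):
    rts = np.sort(rng.uniform(10.0, 110.0, n))
    return CalibrationSet(entries=pd.DataFrame({
        "precursor_id": [precursor_id(f"CAL{i}", 2) for i in range(n)],
        "irt": (rts - 10.0),
        "rt_mean": rts,
        "rt_sd": 0.01,
    }))


def _psm_rows(db, run_id, a, b, extra=()):
    rows = []
    for pid, rt in zip(db.entries.precursor_id, db.entries.rt_mean):
        rows.append({"run_id": run_id, "precursor_id": pid,
                     "modified_sequence": pid.rsplit("/", 1)[0],
                     "sequence": "ACDEFGHIK", "charge": 2,
                     "rt_apex": a * rt + b, "score": 0.01})
    for pid, rt, score in extra:
        rows.append({"run_id": run_id, "precursor_id": pid,
                     "modified_sequence": pid.rsplit("/", 1)[0],
                     "sequence": "LMNPQRSTVK", "charge": 2,
                     "rt_apex": a * rt + b, "score": score})
    return rows


class TestAssembleLibrary:
    def test_affine_shifted_runs_converge_to_tight_irt(self, rng):
        """Two runs related by RT2 = 1.1 RT1 + 3 must map to near-identical
        iRTs after per-run segmented regression."""
        db = _calibration_db(rng)
        psms, frags = [], []
        for run_id, (a, b) in [("r1", (1.0, 0.0)), ("r2", (1.1, 3.0))]:
            psms += _psm_rows(db, run_id, a, b)
            for pid in db.entries.precursor_id:
                frags += make_fragment_rows(run_id, pid)
        lib = assemble_library(pd.DataFrame(psms), pd.DataFrame(frags), db)
        assert len(lib) == len(db)
        # per-precursor iRT spread across runs is bounded by regression error
        irts = {e.precursor_id: e.irt for e in lib.entries}
        truth = db.irt_of()
        spread = max(abs(irts[p] - truth[p]) for p in irts)
        assert spread < 0.1

    def test_sparse_fragment_precursors_dropped(self, rng):
        db = _calibration_db(rng)
        extra = [("EXTRA1/2", 50.0, 0.5), ("EXTRA2/2", 60.0, 0.5)]
        psms = pd.DataFrame(_psm_rows(db, "r1", 1.0, 0.0, extra=extra))
        frags = []
        for pid in db.entries.precursor_id:
            frags += make_fragment_rows("r1", pid)
        frags += make_fragment_rows("r1", "EXTRA1/2", n_fragments=2)
        frags += make_fragment_rows("r1", "EXTRA2/2", n_fragments=3)
        lib = assemble_library(psms, pd.DataFrame(frags), db)
        ids = {e.precursor_id for e in lib.entries}
        assert "EXTRA1/2" not in ids  # only 2 surviving fragments
        assert "EXTRA2/2" in ids

    def test_consensus_irt_is_run_median(self, rng):
        db = _calibration_db(rng)
        psms, frags = [], []
        # three runs; one precursor's RT perturbed differently per run
        offsets = {"r1": 0.0, "r2": 0.4, "r3": 18.0}
        for run_id, off in offsets.items():
            rows = _psm_rows(db, run_id, 1.0, 0.0)
            for r in rows:
                if r["precursor_id"] == "CAL0/2":
                    r["rt_apex"] += off
            psms += rows
            for pid in db.entries.precursor_id:
                frags += make_fragment_rows(run_id, pid)
        lib = assemble_library(pd.DataFrame(psms), pd.DataFrame(frags), db)
        irts = {e.precursor_id: e.irt for e in lib.entries}
        base = db.irt_of()["CAL0/2"]
        # median of {~base, ~base+0.4, ~base+18} is the +0.4 variant
        assert irts["CAL0/2"] == pytest.approx(base + 0.4, abs=0.2)

    def test_run_order_permutation_invariance(self, rng):
        db = _calibration_db(rng, n=250)
        psms, frags = [], []
        for run_id, (a, b) in [("r1", (1.0, 0.0)), ("r2", (1.05, 1.0)),
                               ("r3", (0.97, -2.0))]:
            psms += _psm_rows(db, run_id, a, b)
            for pid in db.entries.precursor_id:
                frags += make_fragment_rows(run_id, pid)
        psms = pd.DataFrame(psms)
        frags = pd.DataFrame(frags)
        fwd = assemble_library(psms, frags, db)
        rev = assemble_library(psms.iloc[::-1].reset_index(drop=True),
                               frags.iloc[::-1].reset_index(drop=True), db)
        irts_fwd = {e.precursor_id: e.irt for e in fwd.entries}
        irts_rev = {e.precursor_id: e.irt for e in rev.entries}
        assert irts_fwd.keys() == irts_rev.keys()
        assert all(irts_fwd[p] == pytest.approx(irts_rev[p], abs=1e-9)
                   for p in irts_fwd)

    def test_no_overlap_raises(self, rng):
        db = _calibration_db(rng, n=50)
        psms = pd.DataFrame([{
            "run_id": "r1", "precursor_id": "XX/2", "modified_sequence": "XX",
            "sequence": "ACDEFGHIK", "charge": 2, "rt_apex": 30.0,
            "score": 0.1,
        }])
        frags = pd.DataFrame(make_fragment_rows("r1", "XX/2"))
        with pytest.raises(LibraryBuildError):
            assemble_library(psms, frags, db)

    def test_openswath_export_invariants(self, rng):
        db = _calibration_db(rng)
        psms = pd.DataFrame(_psm_rows(db, "r1", 1.0, 0.0))
        frags = []
        for pid in db.entries.precursor_id:
            frags += make_fragment_rows("r1", pid, n_fragments=9)
        lib = assemble_library(psms, pd.DataFrame(frags), db)
        for entry in lib.entries:
            assert 3 <= len(entry.fragments) <= 6
            assert (entry.fragments.mz.between(300.0, 1800.0)).all()
            assert (entry.fragments.ordinal >= 3).all()
            ints = entry.fragments.intensity.to_numpy()
            assert (np.diff(ints) <= 0).all()
        osw = lib.to_openswath()
        assert list(osw.columns) == [
            "PrecursorMz", "ProductMz", "LibraryIntensity",
            "NormalizedRetentionTime", "PeptideSequence",
            "ModifiedPeptideSequence", "PrecursorCharge", "FragmentType",
            "FragmentSeriesNumber", "FragmentCharge", "ProteinId"]
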