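"""Event calling on constructed genotype matrices: phase, merging, lengths,
pattern rendering."""

import numpy as np
import pytest

from conftest import octad_signatures, tetrad_signatures
from hdna.events import (
    CallerParams,
    PhaseError,
    call_chromosome,
    estimate_tract_length,
    infer_parental_phase,
)
from hdna.segregation import Tract, call_marker_segregation, segment_tracts


def _co_matrix(positions, junction_bp, left=(1, 1, 0, 0), right=(0, 1, 1, 0)):
    """Octad matrix with a clean reciprocal exchange at junction_bp."""
    arr = octad_signatures(len(positions), left)
    mask = np.asarray(positions) > junction_bp
    arr[mask] = np.repeat(np.asarray(right, dtype=np.int8), 2)
    return arr


class TestPhase:
    def test_no_phase_change_single_segment(self):
        arr = octad_signatures(10)
        calls = [call_marker_segregation(s) for s in arr]
        phase = infer_parental_phase(segment_tracts(calls))
        assert phase.junctions == []

    def test_one_reciprocal_swap_one_junction(self):
        pos = np.arange(1000, 11000, 1000)
        arr = _co_matrix(pos, 5500)
        events = call_chromosome(pos, arr)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "CO" and ev.pattern == "none"
        assert ev.exchange_pair == (0, 2)
        assert ev.junction_bp == pytest.approx(5500.0)

    def test_double_co_two_junctions(self):
        """Two successive swaps of different chromatid pairs, far apart."""
        pos = np.arange(0, 40, dtype=float) * 1000 + 1000
        arr = octad_signatures(len(pos))
        arr[pos > 12000] = np.repeat(np.asarray([0, 1, 1, 0], np.int8), 2)
        arr[pos > 30000] = np.repeat(np.asarray([0, 0, 1, 1], np.int8), 2)
        events = call_chromosome(pos, arr)
        assert [e.kind for e in events] == ["CO", "CO"]
        assert events[0].exchange_pair == (0, 2)
        assert events[1].exchange_pair == (1, 3)

    def test_no_mendelian_background_raises(self):
        arr = np.tile(np.asarray([1, 1, 1, 1, 1, 0, 0, 0], np.int8), (5, 1))
        with pytest.raises(PhaseError):
            call_chromosome(np.arange(1, 6) * 100.0, arr)


class TestLengths:
    def test_midpoint_rule_two_marker_tract(self):
        """Flanks at 900 and 2100, tract markers at 1000 and 2000: 950->2050."""
        pos = np.array([900.0, 1000.0, 2000.0, 2100.0])
        arr = octad_signatures(4)
        arr[1:3, 4] = 1  # chromatid 2 mother cell converted: 5:3 tract
        events = call_chromosome(pos, arr)
        assert len(events) == 1
        assert events[0].length_bp == pytest.approx(1100.0)

    def test_midpoint_rule_single_marker(self):
        pos = np.array([100.0, 200.0, 300.0])
        call = call_marker_segregation([1, 1, 1, 1, 1, 0, 0, 0])
        tract = Tract(chrom="c", first=1, last=1, markers=[1], call=call)
        assert estimate_tract_length(tract, pos, 0, 2) == pytest.approx(100.0)

    def test_chromosome_end_falls_back_to_terminal_marker(self):
        pos = np.array([100.0, 200.0])
        call = call_marker_segregation([1, 1, 1, 1, 1, 0, 0, 0])
        tract = Tract(chrom="c", first=0, last=0, markers=[0], call=call)
        assert estimate_tract_length(tract, pos, None, 1) == pytest.approx(50.0)


class TestCallingRules:
    def test_isolated_half_conversion_is_nco(self):
        pos = np.arange(1, 12, dtype=float) * 1000
        arr = octad_signatures(len(pos))
        arr[4:6, 4] = 1
        events = call_chromosome(pos, arr)
        assert len(events) == 1
        ev = events[0]
        assert (ev.kind, ev.pattern, ev.distribution) == ("NCO", "5:3", "single")
        assert ev.marker_support == 2

    def test_single_marker_nco_discarded(self):
        pos = np.arange(1, 12, dtype=float) * 1000
        arr = octad_signatures(len(pos))
        arr[5, 4] = 1  # one 6:2-free single-marker 5:3
        assert call_chromosome(pos, arr) == []

    def test_mitotic_8_0_markers_excluded(self):
        pos = np.arange(1, 12, dtype=float) * 1000
        arr = octad_signatures(len(pos))
        arr[4:6] = 1  # all eight strands parent 1: 4:0 chromatid segregation
        assert call_chromosome(pos, arr) == []

    def test_trans_hdna_pattern_rendering(self):
        pos = np.arange(1, 15, dtype=float) * 500
        arr = octad_signatures(len(pos))
        arr[4:7, 4] = 1   # chromatid 2, mother strand
        arr[7:10, 5] = 1  # chromatid 2, daughter strand: same ratio, new signature
        events = call_chromosome(pos, arr)
        assert len(events) == 1
        assert events[0].pattern == "5:3_5:3*"
        assert events[0].distribution == "single"

    def test_interior_restoration_patch_rendering(self):
        pos = np.arange(1, 16, dtype=float) * 400
        arr = octad_signatures(len(pos))
        arr[4:6, 4] = 1
        arr[8:10, 5] = 1  # same chromatid, other strand, Mendelian gap between
        events = call_chromosome(pos, arr)
        assert len(events) == 1
        assert events[0].pattern == "5:3_4:4_5:3*"

    def test_tetrad_conversion_patterns(self):
        pos = np.arange(1, 16, dtype=float) * 400
        arr = tetrad_signatures(len(pos))
        arr[4:6, 3] = 1   # spore 4 converted: 3:1
        arr[8:10, 3] = 1  # again after a 2:2 patch
        events = call_chromosome(pos, arr, mode="tetrad")
        assert len(events) == 1
        assert events[0].kind == "NCO"
        assert events[0].pattern == "3:1_2:2_3:1"

    def test_tetrad_starred_interior_patch(self):
        """An interior 2:2 segment matching neither flanking phase gains a star."""
        pos = np.arange(1, 16, dtype=float) * 400
        arr = tetrad_signatures(len(pos), phase=(1, 1, 0, 0))
        arr[4:6, 3] = 1                 # 3:1
        arr[6:8] = [1, 0, 0, 1]         # 2:2 but a different spore split
        arr[8:10, 3] = 1                # 3:1 again
        events = call_chromosome(pos, arr, mode="tetrad")
        assert len(events) == 1
        assert events[0].pattern == "3:1_2:2*_3:1"


class TestMerging:
    def _nco_at(self, arr, pos, lo, hi, cell=4):
        mask = (pos >= lo) & (pos <= hi)
        arr[mask, cell] = 1 - arr[mask, cell]

    def test_events_within_5kb_combine(self):
        pos = np.arange(1, 60, dtype=float) * 500
        arr = octad_signatures(len(pos))
        self._nco_at(arr, pos, 5000, 6000)
        self._nco_at(arr, pos, 9000, 10000)  # 3 kb away, same chromatid
        events = call_chromosome(pos, arr)
        assert len(events) == 1
        assert events[0].pattern == "5:3_4:4_5:3"

    def test_events_beyond_5kb_stay_separate(self):
        pos = np.arange(1, 60, dtype=float) * 500
        arr = octad_signatures(len(pos))
        self._nco_at(arr, pos, 5000, 6000)
        self._nco_at(arr, pos, 12500, 13500)
        events = call_chromosome(pos, arr)
        assert [e.pattern for e in events] == ["5:3", "5:3"]

    def test_conversion_on_uninvolved_chromatid_stays_separate(self):
        """A NCO 3 kb from a CO between two other chromatids is not absorbed."""
        pos = np.arange(1, 60, dtype=float) * 500
        arr = _co_matrix(pos, 20250, left=(1, 1, 0, 0), right=(0, 1, 1, 0))
        # conversion on chromatid 3 (cells 6, 7), not part of the 0<->2 exchange
        mask = (pos >= 16000) & (pos <= 17000)
        arr[mask, 6] = 1
        events = call_chromosome(pos, arr)
        kinds = sorted(e.kind for e in events)
        assert kinds == ["CO", "NCO"]
        nco = next(e for e in events if e.kind == "NCO")
        assert nco.chromatids == {3}

    def test_conversion_on_involved_chromatid_joins_the_co(self):
        pos = np.arange(1, 60, dtype=float) * 500
        arr = _co_matrix(pos, 20250, left=(1, 1, 0, 0), right=(0, 1, 1, 0))
        mask = (pos >= 16000) & (pos <= 17000)
        arr[mask, 1] = 0  # chromatid 0 daughter strand: 3:5 on exchanged chromatid
        events = call_chromosome(pos, arr)
        assert len(events) == 1
        assert events[0].kind == "CO"
        assert events[0].pattern == "3:5"
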