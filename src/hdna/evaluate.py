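"""Comparing caller output against the simulator's ground truth.

Used by the test-suite and the reproduction script to measure event
recovery: a truth event is *eligible* when its visible strand transfers span
at least two markers (COs are always eligible, since the phase change is
detectable from flanking Mendelian markers alone), and *recovered* when a
called event of the same kind overlaps its span within a slack distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import Event
from .io import MarkerMap
from .simulate import TruthEvent, TruthLog

__all__ = ["RecoveryResult", "match_events", "expected_tokens"]


@dataclass
class RecoveryResult:
    n_eligible: int
    n_recovered: int
    n_called: int
    n_spurious: int
    missed: list

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else 1.0


def _truth_kind(ev: TruthEvent) -> str:
    """Expected called kind: a CO whose junction is genetically silent (the
    exchanged arms are locally identical after earlier events) can only be
    seen through its transfers, i.e. as a NCO."""
    return "CO" if ev.outcome == "CO" and ev.junction_informative else "NCO"


def _eligible(ev: TruthEvent) -> bool:
    if ev.outcome == "CO" and ev.junction_informative:
        return True
    if ev.outcome in ("CO", "NCO"):
        return ev.n_visible_markers >= 2
    return False


def match_events(
    truth: TruthLog, called: list[Event], slack_bp: float = 1000.0
) -> RecoveryResult:
    """Match eligible truth events to called events by kind and overlap."""
    eligible = [e for e in truth.events if _eligible(e)]
    by_chrom: dict = {}
    for ev in called:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    recovered = 0
    missed = []
    matched_called = set()
    for te in eligible:
        lo, hi = te.span()
        hit = None
        for ce in by_chrom.get(te.chrom, []):
            if ce.kind != _truth_kind(te):
                continue
            if ce.start_bp - slack_bp <= hi and ce.end_bp + slack_bp >= lo:
                hit = ce
                break
        if hit is not None:
            recovered += 1
            matched_called.add(id(hit))
        else:
            missed.append(te)
    spurious = sum(1 for ce in called if id(ce) not in matched_called)
    return RecoveryResult(
        n_eligible=len(eligible),
        n_recovered=recovered,
        n_called=len(called),
        n_spurious=spurious,
        missed=missed,
    )


def expected_tokens(truth: TruthLog, marker_map: MarkerMap) -> dict:
    """Per-marker segregation tokens derived from truth tracts alone.

    Builds the expected strand ratio from the recorded tract intervals and
    donor/recipient alleles without touching the genotype matrix, so it is an
    independent oracle for the segregation caller.  Returns chrom ->
    list of tokens ("4:4", "5:3", "6:2", "4:4*", ...) per marker, assuming no
    overlapping events (complications off).
    """
    out = {}
    for chrom in marker_map.chromosomes:
        n = len(marker_map.positions(chrom))
        # parent-1 strand count per marker; background 4:4
        a = np.full(n, 4, dtype=int)
        het_delta = [dict() for _ in range(n)]  # chromatid -> minority allele
        for ev in truth.events:
            if ev.chrom != chrom:
                continue
            for t in ev.tracts:
                if t.transient:
                    continue
                if t.state == "hDNA":
                    restored = [
                        (p.i0, p.i1)
                        for p in ev.tracts
                        if p.state == "restoration-patch"
                        and p.chromatid == t.chromatid
                        and p.strand == t.strand
                    ]
                    for k in range(t.i0, t.i1):
                        if any(i0 <= k < i1 for i0, i1 in restored):
                            continue
                        dv = int(t.donor_vals[k - t.i0])
                        rv = int(t.recip_vals[k - t.i0])
                        if dv == rv:
                            continue
                        a[k] += 1 if dv == 1 else -1
                        het_delta[k][t.chromatid] = dv
                elif t.state == "full-conversion":
                    for k in range(t.i0, t.i1):
                        dv = int(t.donor_vals[k - t.i0])
                        rv = int(t.recip_vals[k - t.i0])
                        if dv == rv:
                            continue
                        a[k] += 2 if dv == 1 else -2
        tokens = []
        for k in range(n):
            b = 8 - a[k]
            tok = f"{a[k]}:{b}"
            if a[k] == b == 4 and het_delta[k]:
                tok = "4:4*"
            tokens.append(tok)
        out[chrom] = tokens
    return out
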