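"""Crossover / non-crossover event calling from segregation tracts.

The calling rules mirror the curation procedure the segregation patterns were
designed around:

* a crossover is a change of the parental *phase* — the chromatid-to-parent
  assignment read off Mendelian background markers — between two consecutive
  Mendelian regions;
* clusters of non-Mendelian tracts become events; clusters less than 5 kb
  apart are combined as products of a single DSB, except that a gene
  conversion on a chromatid not involved in a nearby CO stays separate;
* markers segregating 4:0 chromatid-wise (8:0 strand-wise) are of mitotic
  origin and removed before calling; non-crossovers supported by a single
  marker are discarded;
* tract and event lengths use midpoints of flanking inter-marker intervals.

After merging, an event's kind is decided by the *net* phase across it:
different flanking phases make a CO (whatever the interior alternation, e.g.
the tetrad pattern 3:1_2:2_3:1_2:2_3:1), identical phases a NCO (covering
interior Mendelian patches that match neither flank, rendered starred, e.g.
3:1_2:2*_3:1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Genotypes, MarkerMap
from .segregation import SegregationCall, Tract, call_marker_segregation, segment_tracts

__all__ = [
    "PhaseError",
    "CallerParams",
    "Event",
    "infer_parental_phase",
    "call_events",
    "merge_events",
    "estimate_tract_length",
    "pattern_string",
    "call_chromosome",
    "call_all_events",
]

logger = logging.getLogger(__name__)


class PhaseError(ValueError):
    """No Mendelian background available to anchor the parental phase."""


@dataclass
class CallerParams:
    merge_distance_bp: float = 5000.0
    min_marker_support: int = 2


# ---------------------------------------------------------------------------
# Phase inference
# ---------------------------------------------------------------------------

def _phase_vector(call: SegregationCall) -> tuple:
    """Chromatid -> parental allele map at a Mendelian marker."""
    sig = call.signature
    if len(sig) == 8:
        return tuple(sig[0::2])
    return tuple(sig)


@dataclass
class Phase:
    """Piecewise-constant chromatid-to-parent assignment along a chromosome.

    ``segments`` is a list of (background tract index range, phase vector);
    ``junctions`` lists indices into ``background`` where the vector changes
    between consecutive Mendelian background tracts.
    """

    background: list[Tract]
    vectors: list[tuple]

    @property
    def junctions(self) -> list[int]:
        return [
            i
            for i in range(len(self.vectors) - 1)
            if self.vectors[i] != self.vectors[i + 1]
        ]

    def vector_left_of(self, tract_first_marker: int) -> tuple | None:
        """Phase vector of the closest Mendelian background left of a marker."""
        best = None
        for bg, vec in zip(self.background, self.vectors):
            if bg.last < tract_first_marker:
                best = vec
            else:
                break
        return best

    def vector_right_of(self, tract_last_marker: int) -> tuple | None:
        for bg, vec in zip(self.background, self.vectors):
            if bg.first > tract_last_marker:
                return vec
        return None


def infer_parental_phase(background_tracts: list[Tract]) -> Phase:
    """Build the phase function from Mendelian background tracts.

    Raises :class:`PhaseError` when the chromosome carries no Mendelian
    background at all (fully converted chromosome).
    """
    if not background_tracts:
        raise PhaseError("no Mendelian background on chromosome; phase undefined")
    vectors = [_phase_vector(t.call) for t in background_tracts]
    return Phase(background=background_tracts, vectors=vectors)


# ---------------------------------------------------------------------------
# Length estimation
# ---------------------------------------------------------------------------

def estimate_tract_length(
    tract: Tract, positions: np.ndarray, prev_idx: int | None, next_idx: int | None
) -> float:
    """Midpoint tract length: from the midpoint of the interval between the
    previous marker and the tract's first marker to the midpoint of the
    interval between the last marker and the next marker.

    ``prev_idx``/``next_idx`` are indices of the adjacent callable markers, or
    None at a chromosome end, where the boundary falls back to the terminal
    tract marker itself (logged).
    """
    first_pos = positions[tract.markers[0]]
    last_pos = positions[tract.markers[-1]]
    if prev_idx is not None:
        left = (positions[prev_idx] + first_pos) / 2.0
    else:
        logger.info("tract at chromosome start: no left flanking marker")
        left = float(first_pos)
    if next_idx is not None:
        right = (last_pos + positions[next_idx]) / 2.0
    else:
        logger.info("tract at chromosome end: no right flanking marker")
        right = float(last_pos)
    return float(right - left)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass
class Event:
    kind: str                      # "CO" | "NCO"
    chrom: object
    tracts: list[Tract] = field(default_factory=list)   # ordered, incl. interior Mendelian
    chromatids: set[int] = field(default_factory=set)   # bearing non-Mendelian tracts
    exchange_pair: tuple[int, int] | None = None
    left_phase: tuple | None = None
    right_phase: tuple | None = None
    junction_bp: float | None = None
    start_bp: float = 0.0          # outermost affected marker position
    end_bp: float = 0.0
    length_bp: float = 0.0         # sum of constituent patch lengths
    pattern: str = "none"
    distribution: str = "none"     # none | single | two-non-sister | two-sister | multi

    @property
    def marker_support(self) -> int:
        return sum(t.n_markers for t in self.tracts if not t.is_mendelian)

    def chromatid_lengths(self) -> dict[int, float]:
        """Per-chromatid summed transfer length (bp) over non-Mendelian tracts."""
        out: dict[int, float] = {}
        for t in self.tracts:
            if t.is_mendelian or t.length_bp is None:
                continue
            for c in _tract_chromatids(t, self.left_phase, self.right_phase):
                out[c] = out.get(c, 0.0) + t.length_bp
        return out


def _tract_chromatids(tract: Tract, left_phase, right_phase) -> set[int]:
    """Chromatids carrying non-parental information in one tract.

    Heteroduplex chromatids come from the signature.  A homoduplex chromatid
    counts as converted only when its allele differs from the local phase on
    *both* sides — at a CO the flanking phases differ at the exchanged
    chromatids and matching either flank may simply reflect the arm exchange.
    """
    involved = set(tract.call.heteroduplex)
    sig = tract.call.signature
    n_chromatids = 4 if len(sig) == 8 else len(sig)
    for chromatid in range(n_chromatids):
        if len(sig) == 8:
            m, d = sig[2 * chromatid], sig[2 * chromatid + 1]
            if m != d:
                continue
            allele = m
        else:
            allele = sig[chromatid]
        mismatch_left = left_phase is not None and allele != left_phase[chromatid]
        mismatch_right = right_phase is not None and allele != right_phase[chromatid]
        if (left_phase is None or mismatch_left) and (right_phase is None or mismatch_right):
            if left_phase is not None or right_phase is not None:
                involved.add(chromatid)
    return involved


def _distribution_summary(chromatids: set[int], phase: tuple | None) -> str:
    if not chromatids:
        return "none"
    if len(chromatids) == 1:
        return "single"
    if len(chromatids) == 2:
        if phase is None:
            return "two-non-sister"
        a, b = sorted(chromatids)
        return "two-sister" if phase[a] == phase[b] else "two-non-sister"
    return "multi"


def pattern_string(event: Event) -> str:
    """Render the event's ordered tract classes as a ratio-token string.

    Within an event, the first distinct signature of each ratio class is
    unstarred and subsequent distinct signatures gain one star per new
    distribution.  Interior Mendelian patches are rendered plain when their
    chromatid assignment matches a flanking background phase and starred
    otherwise; the octad aberrant 4:4 is always "4:4*".
    """
    if not event.tracts:
        return "none"
    tokens: list[str] = []
    seen: dict[tuple[int, int], list[tuple]] = {}
    for t in event.tracts:
        a, b = t.call.ratio
        base = f"{a}:{b}"
        if t.call.is_aberrant:
            tokens.append(base + "*")
            continue
        if t.is_mendelian:
            vec = _phase_vector(t.call)
            if vec == event.left_phase or vec == event.right_phase:
                tokens.append(base)
            else:
                tokens.append(base + "*")
            continue
        sigs = seen.setdefault((a, b), [])
        if t.call.signature not in sigs:
            sigs.append(t.call.signature)
        tokens.append(base + "*" * sigs.index(t.call.signature))
    return "_".join(tokens) if tokens else "none"


def _finalize_event(event: Event, positions: np.ndarray, n_markers: int) -> Event:
    """Fill lengths, pattern, chromatid summary after tracts are final."""
    transfer = [t for t in event.tracts if not t.is_mendelian]
    if event.tracts:
        all_markers = [m for t in event.tracts for m in t.markers]
        first, last = min(all_markers), max(all_markers)
        event.start_bp = float(positions[first])
        event.end_bp = float(positions[last])
        # per-patch midpoint lengths: boundaries with the adjacent callable marker
        for t in event.tracts:
            prev_idx = t.markers[0] - 1 if t.markers[0] > 0 else None
            next_idx = t.markers[-1] + 1 if t.markers[-1] < n_markers - 1 else None
            t.length_bp = estimate_tract_length(t, positions, prev_idx, next_idx)
        event.length_bp = float(sum(t.length_bp for t in event.tracts))
    elif event.junction_bp is not None:
        event.start_bp = event.end_bp = event.junction_bp
        event.length_bp = 0.0
    event.chromatids = set()
    for t in transfer:
        event.chromatids |= _tract_chromatids(t, event.left_phase, event.right_phase)
    event.pattern = pattern_string(event) if transfer else "none"
    event.distribution = _distribution_summary(event.chromatids, event.left_phase)
    return event


def call_events(
    tracts: list[Tract],
    phase: Phase,
    positions: np.ndarray,
    params: CallerParams | None = None,
) -> list[Event]:
    """Initial (pre-merge) event list for one chromosome.

    Every cluster of consecutive non-Mendelian tracts becomes an event; every
    phase junction without an intervening cluster becomes a transfer-less CO
    candidate.  Kinds here are provisional — :func:`merge_events` re-derives
    each event's kind from its net flanking phase.
    """
    params = params or CallerParams()
    events: list[Event] = []
    n_markers = len(positions)

    # cluster consecutive non-Mendelian tracts (background tracts break runs)
    clusters: list[list[Tract]] = []
    current: list[Tract] = []
    for t in tracts:
        if t.is_mendelian:
            if current:
                clusters.append(current)
                current = []
        else:
            current.append(t)
    if current:
        clusters.append(current)

    for cluster in clusters:
        left = phase.vector_left_of(cluster[0].first)
        right = phase.vector_right_of(cluster[-1].last)
        kind = "CO" if (left is not None and right is not None and left != right) else "NCO"
        ev = Event(
            kind=kind,
            chrom=cluster[0].chrom,
            tracts=list(cluster),
            left_phase=left,
            right_phase=right,
            exchange_pair=_exchange_pair(left, right),
        )
        events.append(_finalize_event(ev, positions, n_markers))

    # transfer-less COs: junctions between *adjacent* Mendelian background
    # tracts (no non-Mendelian tract in between)
    bg = phase.background
    for j in phase.junctions:
        lt, rt = bg[j], bg[j + 1]
        if any(lt.last < t.first and t.last < rt.first for t in tracts if not t.is_mendelian):
            continue  # junction already owned by a cluster event
        junction = (positions[lt.last] + positions[rt.first]) / 2.0
        ev = Event(
            kind="CO",
            chrom=lt.chrom,
            tracts=[],
            left_phase=phase.vectors[j],
            right_phase=phase.vectors[j + 1],
            exchange_pair=_exchange_pair(phase.vectors[j], phase.vectors[j + 1]),
            junction_bp=junction,
        )
        events.append(_finalize_event(ev, positions, n_markers))

    events.sort(key=lambda e: (e.start_bp, e.end_bp))
    return events


def _exchange_pair(left: tuple | None, right: tuple | None) -> tuple[int, int] | None:
    if left is None or right is None or left == right:
        return None
    diff = [i for i in range(len(left)) if left[i] != right[i]]
    if len(diff) == 2:
        return (diff[0], diff[1])
    return None  # multi-chromatid / complex junction


def merge_events(
    events: list[Event],
    tracts: list[Tract],
    positions: np.ndarray,
    params: CallerParams | None = None,
) -> list[Event]:
    """Combine events closer than the merge distance and settle kinds.

    Boundary-to-boundary distance between outermost affected markers (the
    junction midpoint for transfer-less COs).  The exception: a conversion on
    a chromatid not involved in a nearby CO stays separate.  Intervening
    Mendelian tracts join the merged event as interior patches.  After
    merging, kind = CO iff the net flanking phase changes; single-marker NCOs
    are then discarded.
    """
    params = params or CallerParams()
    n_markers = len(positions)
    merged: list[Event] = []
    for ev in sorted(events, key=lambda e: (e.start_bp, e.end_bp)):
        if merged:
            prev = merged[-1]
            gap = ev.start_bp - prev.end_bp
            if gap < params.merge_distance_bp and not _co_exception(prev, ev):
                combined = _combine(prev, ev, tracts, positions, n_markers)
                merged[-1] = combined
                continue
        merged.append(ev)

    out: list[Event] = []
    for ev in merged:
        # settle kind from net phase across the merged event
        if ev.left_phase is not None and ev.right_phase is not None:
            ev.kind = "CO" if ev.left_phase != ev.right_phase else "NCO"
            ev.exchange_pair = _exchange_pair(ev.left_phase, ev.right_phase)
        if ev.kind == "NCO" and ev.marker_support < params.min_marker_support:
            logger.info(
                "discarding NCO at %s:%s supported by %d marker(s)",
                ev.chrom, ev.start_bp, ev.marker_support,
            )
            continue
        out.append(ev)
    return out


def _co_exception(a: Event, b: Event) -> bool:
    """True when the pair is a CO plus a conversion on an uninvolved chromatid."""
    co, nco = (a, b) if a.kind == "CO" else (b, a) if b.kind == "CO" else (None, None)
    if co is None or (a.kind == "CO" and b.kind == "CO"):
        return False
    co_chromatids = set(co.exchange_pair or ()) | co.chromatids
    return bool(nco.chromatids) and not (nco.chromatids & co_chromatids)


def _combine(
    a: Event, b: Event, tracts: list[Tract], positions: np.ndarray, n_markers: int
) -> Event:
    """Merge two adjacent events, pulling in intervening Mendelian tracts."""
    a_markers = [m for t in a.tracts for m in t.markers]
    b_markers = [m for t in b.tracts for m in t.markers]
    lo = max(a_markers) if a_markers else None
    hi = min(b_markers) if b_markers else None
    interior = [
        t
        for t in tracts
        if t.is_mendelian
        and lo is not None
        and hi is not None
        and t.first > lo
        and t.last < hi
    ]
    ev = Event(
        kind="CO" if "CO" in (a.kind, b.kind) else "NCO",
        chrom=a.chrom,
        tracts=sorted(a.tracts + interior + b.tracts, key=lambda t: t.first),
        left_phase=a.left_phase,
        right_phase=b.right_phase,
        junction_bp=a.junction_bp if a.junction_bp is not None else b.junction_bp,
    )
    return _finalize_event(ev, positions, n_markers)


# ---------------------------------------------------------------------------
# Whole-chromosome / whole-genome pipeline
# ---------------------------------------------------------------------------

def call_chromosome(
    positions: np.ndarray,
    signatures: np.ndarray,
    mode: str = "octad",
    params: CallerParams | None = None,
    chrom=None,
) -> list[Event]:
    """Run segregation calling, phase inference, event calling and merging on
    one chromosome.

    ``signatures`` is (n_markers, n_cells) with values in {0, 1, -1}.
    Mitotic 4:0 chromatid-segregating markers are removed before calling.
    """
    params = params or CallerParams()
    calls = [call_marker_segregation(sig, mode) for sig in signatures]
    keep = [i for i, c in enumerate(calls) if c.callable and not c.is_mitotic]
    n_mitotic = sum(1 for c in calls if c.callable and c.is_mitotic)
    if n_mitotic:
        logger.info("removed %d mitotic 4:0-segregating markers on %s", n_mitotic, chrom)
    kept_calls = [calls[i] for i in keep]
    kept_positions = np.asarray(positions, dtype=float)[keep]
    tracts = segment_tracts(kept_calls, chrom=chrom)
    background = [t for t in tracts if t.is_mendelian]
    phase = infer_parental_phase(background)
    events = call_events(tracts, phase, kept_positions, params)
    return merge_events(events, tracts, kept_positions, params)


def call_all_events(
    marker_map: MarkerMap,
    genotypes: Genotypes,
    params: CallerParams | None = None,
    skip_phaseless: bool = True,
) -> list[Event]:
    """Call events on every chromosome of a genotype table."""
    events: list[Event] = []
    for chrom in marker_map.chromosomes:
        rows = marker_map.rows_for(chrom)
        try:
            events.extend(
                call_chromosome(
                    marker_map.table.loc[rows, "S288C_pos"].to_numpy(),
                    genotypes.calls[rows],
                    mode=genotypes.mode,
                    params=params,
                    chrom=chrom,
                )
            )
        except PhaseError:
            if not skip_phaseless:
                raise
            logger.warning("chromosome %s has no Mendelian background; skipped", chrom)
    return events
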