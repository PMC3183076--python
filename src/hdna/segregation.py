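"""Per-marker segregation calls and tract segmentation.

In an octad the eight cell populations give the genotype of each DNA strand
of the four chromatids.  At each marker the strand ratio ``a:b`` (parent-1
strands first) classifies the marker: 4:4 Mendelian, 5:3/3:5 half conversion
(one heteroduplex chromatid), 6:2/2:6 full conversion, and the aberrant 4:4*
where two chromatids are heteroduplex with opposite minorities (symmetric
hDNA).  Tetrad (MMR-proficient) data only resolves chromatids: 2:2 Mendelian
and 3:1/1:3 conversions.

Tract segmentation collapses maximal runs of *signature-equivalent* markers —
identical ordered cell-allele vectors, not merely equal ratios — because the
strand distribution is what separates e.g. the two tracts of a 5:3_5:3* trans
hDNA.  Uncallable markers are transparent: runs extend across them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegregationCall", "Tract", "call_marker_segregation", "segment_tracts"]


@dataclass(frozen=True)
class SegregationCall:
    """Classification of one marker from its ordered cell-allele signature."""

    signature: tuple
    ratio: tuple[int, int]
    #: chromatid id -> (mother allele, daughter allele) where the two differ
    heteroduplex: dict
    token: str
    callable: bool = True

    @property
    def is_mendelian(self) -> bool:
        a, b = self.ratio
        return a == b and not self.heteroduplex and self.callable

    @property
    def is_aberrant(self) -> bool:
        return self.token.endswith("*")

    @property
    def is_mitotic(self) -> bool:
        """True for 4:0 chromatid-level segregation (8:0 strand-level)."""
        a, b = self.ratio
        return self.callable and (a == 0 or b == 0)


def call_marker_segregation(signature, mode: str = "octad") -> SegregationCall:
    """Classify one marker's ordered cell-allele vector.

    Octad signatures are eight values ordered spore-wise as (mother,
    daughter) pairs; chromatid ``i`` is positions ``2i`` and ``2i + 1``.
    Tetrad signatures are four spore values.  Values are 0/1 with -1 for
    missing; any missing value makes the marker uncallable (it is skipped by
    tract building, not an error).
    """
    sig = tuple(int(v) for v in signature)
    expected = 8 if mode == "octad" else 4
    if mode not in ("octad", "tetrad"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(sig) != expected:
        raise ValueError(f"signature length {len(sig)} != {expected} for {mode} mode")
    if any(v not in (0, 1) for v in sig):
        return SegregationCall(sig, (0, 0), {}, token="NA", callable=False)
    a = sum(sig)
    b = expected - a
    het: dict[int, tuple[int, int]] = {}
    if mode == "octad":
        for chromatid in range(4):
            m, d = sig[2 * chromatid], sig[2 * chromatid + 1]
            if m != d:
                het[chromatid] = (m, d)
    token = f"{a}:{b}"
    if mode == "octad" and a == b == 4 and het:
        token = "4:4*"
    return SegregationCall(sig, (a, b), het, token=token)


@dataclass
class Tract:
    """A maximal run of signature-equivalent markers on one chromosome."""

    chrom: object
    first: int                      # chromosome-local index of first callable marker
    last: int                       # ... and of the last (inclusive)
    markers: list[int]              # callable marker indices in the run
    call: SegregationCall
    distribution_id: int = 0        # per-chromosome id among equal-ratio tracts
    length_bp: float | None = None  # midpoint length, filled by the event caller

    @property
    def token(self) -> str:
        return self.call.token

    @property
    def is_mendelian(self) -> bool:
        return self.call.is_mendelian

    @property
    def is_mitotic(self) -> bool:
        return self.call.is_mitotic

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromatids(self, phase_vector=None) -> set[int]:
        """Chromatids carrying non-parental information at this tract.

        Heteroduplex chromatids come straight from the signature.  Fully
        converted chromatids need the local parental ``phase_vector`` (the
        chromatid -> allele map of the flanking Mendelian background): a
        homoduplex chromatid whose allele differs from its phase is converted.
        """
        involved = set(self.call.heteroduplex)
        if phase_vector is not None and len(self.call.signature) == 8:
            for chromatid in range(4):
                m = self.call.signature[2 * chromatid]
                d = self.call.signature[2 * chromatid + 1]
                if m == d and m != phase_vector[chromatid]:
                    involved.add(chromatid)
        elif phase_vector is not None:
            for chromatid in range(4):
                if self.call.signature[chromatid] != phase_vector[chromatid]:
                    involved.add(chromatid)
        return involved


def segment_tracts(calls: list[SegregationCall], chrom=None) -> list[Tract]:
    """Collapse ordered per-marker calls into maximal signature-equivalent runs.

    ``calls`` must be ordered by position along one chromosome.  Uncallable
    markers never break a run.  Mendelian background runs are emitted like any
    other tract; the event caller separates background from events.
    Distribution ids number equal-ratio tracts with distinct signatures in
    order of first appearance along the chromosome.
    """
    tracts: list[Tract] = []
    current: Tract | None = None
    for i, call in enumerate(calls):
        if not call.callable:
            continue
        if current is not None and call.signature == current.call.signature:
            current.last = i
            current.markers.append(i)
        else:
            current = Tract(chrom=chrom, first=i, last=i, markers=[i], call=call)
            tracts.append(current)
    # distribution ids: per ratio token (ignoring stars), number distinct signatures
    seen: dict[tuple[int, int], list[tuple]] = {}
    for tract in tracts:
        sigs = seen.setdefault(tract.call.ratio, [])
        if tract.call.signature not in sigs:
            sigs.append(tract.call.signature)
        tract.distribution_id = sigs.index(tract.call.signature)
    return tracts
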