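"""Recompute the headline pattern-inventory numbers from the bundled fixtures.

Each function takes fixture rows (see :mod:`hdna.io`) and recomputes a
summary with the pattern operations — nothing is hard-coded beyond the
printed inventories themselves.
"""

from __future__ import annotations

from .io import PatternRow, load_bundled_fixture
from .patterns import (
    Token,
    canonicalize_pattern,
    count_tracts,
    has_opposite_directions,
    parse_pattern,
)

__all__ = [
    "msh2_nco_rows",
    "multitract_percent",
    "count_single_half_conversion",
    "count_canonical_trans",
    "count_trans_with_restoration_patch",
    "count_opposite_direction_ncos",
    "reproduce_all",
]


def msh2_nco_rows() -> list[PatternRow]:
    rows: list[PatternRow] = []
    for name in ("nco_msh2_sdsa", "nco_msh2_trans", "nco_msh2_other"):
        rows.extend(load_bundled_fixture(name).rows)
    return rows


def _grammar_mode(row: PatternRow) -> str:
    return "octad" if row.mode == "msh2" else "tetrad"


def multitract_percent(rows, min_tracts: int = 3) -> int:
    """Occurrence-weighted percentage of events with at least ``min_tracts``
    successive segregation tracts, over all events (transfer-less included).

    Aggregate rows count entirely when their minimum tract number qualifies.
    Rounded half-up to the nearest integer percent, matching the printed
    presentation.
    """
    total = 0
    qualifying = 0
    for row in rows:
        total += row.occurrence
        if row.is_aggregate:
            if row.min_tracts >= min_tracts:
                qualifying += row.occurrence
        elif not row.is_none:
            if count_tracts(row.pattern, _grammar_mode(row)) >= min_tracts:
                qualifying += row.occurrence
    return int(qualifying / total * 100 + 0.5)


def count_single_half_conversion(rows) -> int:
    """Events whose canonicalized pattern is one continuous half-conversion
    tract confined to a single chromatid (the canonical SDSA signature)."""
    n = 0
    for row in rows:
        if row.is_aggregate or row.is_none or row.chromatid_assignment != "single":
            continue
        mode = _grammar_mode(row)
        tokens = parse_pattern(canonicalize_pattern(row.pattern, mode), mode)
        if len(tokens) == 1 and tokens[0].is_half_conversion:
            n += row.occurrence
    return n


def count_canonical_trans(rows) -> int:
    """Events with exactly two adjacent half-conversion tracts of the same
    asymmetry direction but different strand distributions, on one chromatid
    (the 5:3_5:3* trans-hDNA signature)."""
    n = 0
    for row in rows:
        if row.is_aggregate or row.is_none or row.chromatid_assignment != "single":
            continue
        mode = _grammar_mode(row)
        tokens = parse_pattern(canonicalize_pattern(row.pattern, mode), mode)
        if (
            len(tokens) == 2
            and all(t.is_half_conversion for t in tokens)
            and tokens[0].direction == tokens[1].direction
            and tokens[0].stars != tokens[1].stars
        ):
            n += row.occurrence
    return n


def count_trans_with_restoration_patch(rows) -> int:
    """Trans hDNAs interrupted by one Mendelian restoration patch: the
    three-tract half-conversion / 4:4 / starred half-conversion pattern on a
    single chromatid."""
    n = 0
    for row in rows:
        if row.is_aggregate or row.is_none or row.chromatid_assignment != "single":
            continue
        mode = _grammar_mode(row)
        tokens = parse_pattern(canonicalize_pattern(row.pattern, mode), mode)
        if (
            len(tokens) == 3
            and tokens[0].is_half_conversion
            and tokens[1].is_mendelian
            and tokens[2].is_half_conversion
            and tokens[0].direction == tokens[2].direction
            and tokens[0].stars != tokens[2].stars
        ):
            n += row.occurrence
    return n


def count_opposite_direction_ncos(rows) -> int:
    """Events whose pattern carries half-conversion tracts of both asymmetry
    directions (the 5:3_3:5 configuration)."""
    return sum(
        row.occurrence
        for row in rows
        if not row.is_aggregate
        and not row.is_none
        and has_opposite_directions(row.pattern, _grammar_mode(row))
    )


def reproduce_all() -> dict:
    """All fixture-derived quantities, keyed by a short descriptive name."""
    nco_rows = msh2_nco_rows()
    co_msh2 = load_bundled_fixture("co_msh2").rows
    co_wt = load_bundled_fixture("co_wt").rows
    return {
        "msh2_co_multitract_percent": multitract_percent(co_msh2),
        "wt_co_multitract_percent": multitract_percent(co_wt),
        "msh2_nco_single_half_conversion": count_single_half_conversion(nco_rows),
        "msh2_nco_canonical_trans": count_canonical_trans(nco_rows),
        "msh2_nco_trans_with_patch": count_trans_with_restoration_patch(nco_rows),
        "msh2_nco_opposite_directions": count_opposite_direction_ncos(nco_rows),
    }
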