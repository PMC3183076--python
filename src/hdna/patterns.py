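"""Strand-transfer pattern grammar and mechanistic classification.

A recombination event is summarised by a *pattern string*: segregation-ratio
tokens joined by underscores, ordered along the chromosome, e.g.
``"3:5_4:4_3:5*"``.  Each token ``a:b`` gives the number of DNA strands
carrying the parent-1 (S288C) allele versus the parent-2 (SK1) allele — eight
strands in octad data, four chromatids in tetrad data.  A trailing ``*``
distinguishes tracts that share a global ratio but differ in which cells carry
the minority allele ("different strand distributions").  The octad token
``4:4*`` is reserved for aberrant 4:4 tracts: overall Mendelian ratio but two
heteroduplex chromatids with opposite minorities (symmetric hDNA, the mark of
Holliday-junction branch migration).

Classification maps an event's pattern plus its chromatid footprint onto the
mechanistic classes expected from the repair pathways: simple SDSA leaves a
single half-conversion tract on one chromatid; double SDSA and double
Holliday-junction dissolution leave two adjacent half-conversion tracts with
the same asymmetry but different strand distributions on one chromatid (trans
hDNA); dHJ resolution leaves transfers on both recombining non-sister
chromatids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "PatternError",
    "Token",
    "NCOClass",
    "COClass",
    "parse_pattern",
    "format_pattern",
    "canonicalize_pattern",
    "count_tracts",
    "has_opposite_directions",
    "classify_nco",
    "classify_co",
]

NONE_PATTERN = "none"

_TOKEN_RE = re.compile(r"^(\d+):(\d+)(\**)$")


class PatternError(ValueError):
    """A pattern string does not parse under the ratio-token grammar."""


@dataclass(frozen=True)
class Token:
    """One segregation tract token: ratio ``a:b`` plus a star index.

    ``a`` counts parent-1 strands (octads) or chromatids (tetrads), ``b``
    parent 2.  ``stars`` is the number of trailing asterisks; for octad 4:4
    tokens any star marks the aberrant symmetric-hDNA tract.
    """

    a: int
    b: int
    stars: int = 0

    # -- derived properties ------------------------------------------------
    @property
    def total(self) -> int:
        return self.a + self.b

    @property
    def diff(self) -> int:
        return self.a - self.b

    @property
    def direction(self) -> int:
        """+1 when parent 1 is in excess, -1 when parent 2 is, 0 if balanced."""
        return 0 if self.a == self.b else (1 if self.a > self.b else -1)

    @property
    def is_mendelian(self) -> bool:
        """Balanced ratio without a star (4:4 in octads, 2:2 in tetrads)."""
        return self.a == self.b and self.stars == 0

    @property
    def is_aberrant(self) -> bool:
        """Octad aberrant 4:4* (balanced ratio, symmetric hDNA)."""
        return self.a == self.b == 4 and self.stars > 0

    @property
    def is_half_conversion(self) -> bool:
        """One heteroduplex chromatid: 5:3 or 3:5 (octads only)."""
        return self.total == 8 and abs(self.diff) == 2

    @property
    def is_full_conversion(self) -> bool:
        """One fully converted chromatid: 6:2/2:6 (octad), 3:1/1:3 (tetrad)."""
        if self.total == 8:
            return abs(self.diff) == 4
        return abs(self.diff) == 2

    def swapped(self) -> "Token":
        return Token(self.b, self.a, self.stars)

    def __str__(self) -> str:
        return f"{self.a}:{self.b}" + "*" * self.stars


class NCOClass(str, Enum):
    SDSA_CANONICAL = "SDSA_canonical"
    SDSA_COMPLEX = "SDSA_complex"
    TRANS_CANONICAL = "trans_canonical"
    TRANS_COMPLEX = "trans_complex"
    OTHER = "other"


class COClass(str, Enum):
    NO_TRANSFER = "no_transfer"
    SINGLE_CHROMATID = "single_chromatid"
    TWO_NON_SISTER_DSBR_COMPATIBLE = "two_non_sister_DSBR_compatible"
    TWO_NON_SISTER_DSBR_ASYMMETRIC = "two_non_sister_DSBR_asymmetric"
    TWO_NON_SISTER_OTHER = "two_non_sister_other"
    OTHER = "other"


def _strand_total(mode: str) -> int:
    if mode == "octad":
        return 8
    if mode == "tetrad":
        return 4
    raise ValueError(f"unknown mode {mode!r}; expected 'octad' or 'tetrad'")


def parse_pattern(pattern: str, mode: str = "octad") -> list[Token]:
    """Parse a pattern string into tokens, validating the per-mode strand sum.

    Accepts the typographic ratio character (``∶``) used in printed
    transcriptions as a synonym for ASCII ``:``.
    """
    total = _strand_total(mode)
    if pattern is None or pattern.strip() in ("", NONE_PATTERN):
        raise PatternError(f"pattern {pattern!r} has no tracts to parse")
    tokens = []
    for raw in pattern.replace("∶", ":").split("_"):
        m = _TOKEN_RE.match(raw.strip())
        if not m:
            raise PatternError(f"unparseable token {raw!r} in pattern {pattern!r}")
        tok = Token(int(m.group(1)), int(m.group(2)), len(m.group(3)))
        if tok.total != total:
            raise PatternError(
                f"token {raw!r} sums to {tok.total}, expected {total} in {mode} mode"
            )
        tokens.append(tok)
    return tokens


def format_pattern(tokens: list[Token]) -> str:
    return "_".join(str(t) for t in tokens)


def canonicalize_pattern(pattern: str, mode: str = "octad") -> str:
    """Return the canonical representative under a global parent swap.

    The printed inventories are orientation-normalised (no table lists both
    "3:5" and "5:3" as single-tract rows), so comparisons go through this
    canonical form: if the first unbalanced token has its larger count first,
    every token is swapped ``a:b -> b:a``.  Idempotent; ``"none"`` is fixed.
    """
    if pattern == NONE_PATTERN:
        return pattern
    tokens = parse_pattern(pattern, mode)
    for tok in tokens:
        if tok.direction != 0:
            if tok.direction > 0:
                tokens = [t.swapped() for t in tokens]
            break
    return format_pattern(tokens)


def count_tracts(pattern: str, mode: str = "octad") -> int:
    """Number of successive segregation tracts in the pattern (0 for "none")."""
    if pattern == NONE_PATTERN:
        return 0
    return len(parse_pattern(pattern, mode))


def has_opposite_directions(pattern: str, mode: str = "octad") -> bool:
    """True when the pattern carries half-conversion tracts of both asymmetry
    directions (the 5:3_3:5 configuration).

    Only heteroduplex (half-conversion) tracts count in octad mode; full
    conversions and aberrant 4:4* tracts are direction-neutral here.  In
    tetrad mode, where hDNA is invisible, conversion tracts (3:1/1:3) play the
    same role.  Invariant under :func:`canonicalize_pattern`.
    """
    if pattern == NONE_PATTERN:
        return False
    if mode == "octad":
        dirs = {t.direction for t in parse_pattern(pattern, mode) if t.is_half_conversion}
    else:
        dirs = {t.direction for t in parse_pattern(pattern, mode) if t.is_full_conversion}
    return dirs >= {1, -1}


# ---------------------------------------------------------------------------
# NCO classification
# ---------------------------------------------------------------------------

def _single_chromatid(chromatid_distribution: str) -> bool:
    return chromatid_distribution == "single"


def _half_distributions(tokens: list[Token]) -> list[int]:
    """Distinct star-ids of half-conversion tracts, in order of appearance."""
    seen: list[int] = []
    for t in tokens:
        if t.is_half_conversion and t.stars not in seen:
            seen.append(t.stars)
    return seen


def classify_nco(pattern: str, chromatid_distribution: str, mode: str = "octad") -> NCOClass:
    """Assign a non-crossover event to its mechanistic class.

    SDSA-like: all transfers on one chromatid, at least one half-conversion
    tract, a single strand distribution shared by every half-conversion tract,
    half-conversion tracts at both ends, one asymmetry direction throughout,
    and no aberrant 4:4*.  Canonical when the whole pattern is one tract.

    Trans: as above but with exactly two half-conversion distributions (the
    5:3_5:3* signature of dHJ dissolution / double SDSA).  Canonical when the
    pattern is exactly the two-tract "X_X*".

    Everything else — full-conversion-only patterns, terminal full
    conversions, multi-chromatid footprints, opposite directions, aberrant
    4:4* — is "other".  Trans is tested before SDSA-like so tie-breaking is
    explicit, although the two rule sets are disjoint by construction.
    """
    tokens = parse_pattern(pattern, mode)
    if not _single_chromatid(chromatid_distribution):
        return NCOClass.OTHER

    halves = [t for t in tokens if t.is_half_conversion]
    if not halves:
        return NCOClass.OTHER
    if any(t.is_aberrant for t in tokens):
        return NCOClass.OTHER
    # one asymmetry direction across every unbalanced tract, interior repair
    # patches (full conversions) included
    directions = {t.direction for t in tokens if t.direction != 0}
    if len(directions) != 1:
        return NCOClass.OTHER
    # terminal tracts must be half conversions
    if not (tokens[0].is_half_conversion and tokens[-1].is_half_conversion):
        return NCOClass.OTHER
    # interior tracts restricted to restoration patches and full conversions
    if any(
        not (t.is_half_conversion or t.is_full_conversion or t.is_mendelian)
        for t in tokens
    ):
        return NCOClass.OTHER

    dists = _half_distributions(tokens)
    if len(dists) == 2:
        if len(tokens) == 2 and tokens[0].stars != tokens[1].stars:
            return NCOClass.TRANS_CANONICAL
        return NCOClass.TRANS_COMPLEX
    if len(dists) == 1:
        if len(tokens) == 1:
            return NCOClass.SDSA_CANONICAL
        return NCOClass.SDSA_COMPLEX
    return NCOClass.OTHER


# ---------------------------------------------------------------------------
# CO classification
# ---------------------------------------------------------------------------

def classify_co(
    pattern: str,
    chromatid_distribution: str,
    tract_geometry: tuple[float, float] | None = None,
    asymmetry_threshold: float = 3.0,
    mode: str = "octad",
) -> COClass:
    """Assign a crossover event to its strand-transfer class.

    ``tract_geometry`` gives the per-chromatid transfer lengths (bp) for
    two-non-sister events; when absent (e.g. fixture rows transcribed from the
    printed tables) the overlap test falls back to the pattern alone — an
    aberrant 4:4* tract is the signature of overlapping transfers — and
    asymmetry cannot be assessed.
    """
    if pattern == NONE_PATTERN:
        return COClass.NO_TRANSFER
    tokens = parse_pattern(pattern, mode)
    if _single_chromatid(chromatid_distribution):
        return COClass.SINGLE_CHROMATID
    if chromatid_distribution == "two-non-sister":
        overlapping = any(t.is_aberrant for t in tokens)
        if overlapping:
            return COClass.TWO_NON_SISTER_OTHER
        if tract_geometry is not None:
            lo, hi = sorted(tract_geometry)
            if lo > 0 and hi / lo >= asymmetry_threshold:
                return COClass.TWO_NON_SISTER_DSBR_ASYMMETRIC
        return COClass.TWO_NON_SISTER_DSBR_COMPATIBLE
    return COClass.OTHER
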