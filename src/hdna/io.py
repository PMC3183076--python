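"""Reading and writing marker genotype tables and pattern-inventory fixtures.

The genotype table dialect is tab-separated with one row per polymorphic
marker: ``chrom``, ``index`` (marker index on its chromosome), ``Ali_pos``
(position in the whole-genome alignment of the two parents; carried but never
used in computation), ``S288C_pos`` (1-based position in the S288C genome),
``type`` (``S`` SNP, ``I`` insertion, ``D`` deletion), then one 0/1 genotype
call column per cell population.  A call of 1 is the S288C (parent 1) allele,
0 the SK1 (parent 2) allele.  Octad tables carry eight call columns — four
spores times mother/daughter cells from the first mitotic division — ordered
``<spore>_m, <spore>_d``; tetrad tables carry four.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .patterns import PatternError, parse_pattern

__all__ = [
    "FormatError",
    "MarkerMap",
    "Genotypes",
    "PatternRow",
    "PatternFixture",
    "MISSING",
    "read_genotype_table",
    "write_genotype_table",
    "load_pattern_fixture",
    "load_bundled_fixture",
    "BUNDLED_FIXTURES",
]

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

META_COLUMNS = ["chrom", "index", "Ali_pos", "S288C_pos", "type"]

#: fixture name -> (resource file, expected occurrence total)
BUNDLED_FIXTURES = {
    "nco_msh2_sdsa": ("nco_msh2_sdsa.tsv", 75),
    "nco_msh2_trans": ("nco_msh2_trans.tsv", 59),
    "nco_msh2_other": ("nco_msh2_other.tsv", 35),
    "co_msh2": ("co_msh2.tsv", 181),
    "co_wt": ("co_wt.tsv", 282),
    "nco_wt": ("nco_wt.tsv", 65),
}


class FormatError(ValueError):
    """A file violates the genotype-table or fixture contract."""


@dataclass
class MarkerMap:
    """Ordered polymorphic-marker coordinates for one or more chromosomes.

    ``table`` has the META_COLUMNS layout, sorted by (chrom, S288C_pos); all
    coordinates are 1-based inclusive.  Parent alleles are abstract: parent 1
    (S288C) is call value 1, parent 2 (SK1) is 0 at every marker.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in META_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"marker table lacks columns {missing}")
        t = t.sort_values(["chrom", "S288C_pos"], kind="stable").reset_index(drop=True)
        if t.duplicated(["chrom", "S288C_pos"]).any():
            dup = t[t.duplicated(["chrom", "S288C_pos"])].iloc[0]
            raise FormatError(
                f"duplicate marker at {dup['chrom']}:{dup['S288C_pos']}"
            )
        bad = ~t["type"].isin(["S", "I", "D"])
        if len(t) and bad.any():
            raise FormatError(f"unknown marker type {t.loc[bad, 'type'].iloc[0]!r}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def rows_for(self, chrom) -> np.ndarray:
        """Global row indices of a chromosome's markers, in position order."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def positions(self, chrom) -> np.ndarray:
        return self.table.loc[self.rows_for(chrom), "S288C_pos"].to_numpy()


@dataclass
class Genotypes:
    """A cells x markers 0/1 call matrix aligned to a :class:`MarkerMap`.

    ``calls`` is (n_markers, n_cells) int8 with -1 for missing.  Octad cell
    order is the file contract: spore 1 mother, spore 1 daughter, ..., spore 4
    daughter — chromatid ``i`` of the meiosis is cells ``2i`` and ``2i+1``.
    """

    cells: list[str]
    calls: np.ndarray
    mode: str = "octad"

    def __post_init__(self) -> None:
        expected = 8 if self.mode == "octad" else 4
        if self.mode not in ("octad", "tetrad"):
            raise FormatError(f"unknown mode {self.mode!r}")
        if len(self.cells) != expected:
            raise FormatError(
                f"{self.mode} mode requires {expected} cell columns, got {len(self.cells)}"
            )
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[1] != expected:
            raise FormatError(f"call matrix shape {self.calls.shape} does not match cells")
        ok = np.isin(self.calls, [-1, 0, 1])
        if not ok.all():
            bad = self.calls[~ok].flat[0]
            raise FormatError(f"genotype call {bad} outside {{0, 1, missing}}")

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]


def read_genotype_table(path, mode: str = "octad") -> tuple[MarkerMap, Genotypes]:
    """Read a tab-separated genotype table; see module docstring for layout."""
    path = Path(path)
    expected_cells = 8 if mode == "octad" else 4
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "type": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=META_COLUMNS)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    cell_cols = [c for c in df.columns if c not in META_COLUMNS]
    if len(cell_cols) != expected_cells:
        raise FormatError(
            f"{path}: {len(cell_cols)} call columns but {mode} mode expects {expected_cells}"
        )
    if len(df):
        raw = df[cell_cols].to_numpy(dtype=object)
        calls = np.full(raw.shape, MISSING, dtype=np.int8)
        for v, code in (("1", 1), ("0", 0), (1, 1), (0, 0), (1.0, 1), (0.0, 0)):
            calls[raw == v] = code
        unknown = (calls == MISSING) & ~pd.isna(raw.astype(object)) & ~np.isin(
            raw.astype(str), ["NA", "nan", ".", ""]
        )
        if unknown.any():
            raise FormatError(
                f"{path}: genotype call {raw[unknown].flat[0]!r} outside {{0, 1, missing}}"
            )
    else:
        calls = np.empty((0, expected_cells), dtype=np.int8)
    marker_map = MarkerMap(df[META_COLUMNS].copy())
    # align calls to the sorted marker order (chrom primary, position secondary)
    if len(df):
        order = np.lexsort(
            (df["S288C_pos"].to_numpy(), df["chrom"].astype(str).to_numpy())
        )
        calls = calls[order]
    return marker_map, Genotypes(cells=cell_cols, calls=calls, mode=mode)


def write_genotype_table(marker_map: MarkerMap, genotypes: Genotypes, path) -> None:
    """Write the tab-separated dialect read by :func:`read_genotype_table`."""
    if genotypes.n_markers != len(marker_map):
        raise FormatError(
            f"genotypes have {genotypes.n_markers} markers, map has {len(marker_map)}"
        )
    df = marker_map.table.copy()
    calls = genotypes.calls.astype(object)
    for cell_idx, cell in enumerate(genotypes.cells):
        col = calls[:, cell_idx]
        df[cell] = ["NA" if v == -1 else str(v) for v in col]
    path = Path(path)
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write genotype table to {path}: {exc}") from exc


def drop_high_missing_markers(
    marker_map: MarkerMap, genotypes: Genotypes, max_missing_fraction: float = 0.0
) -> tuple[MarkerMap, Genotypes]:
    """Drop markers whose missing-call fraction exceeds the tolerance.

    Synthetic data is complete, hence the default of 0; real tables may need
    slack.  Dropped markers are logged.
    """
    frac = (genotypes.calls == MISSING).mean(axis=1)
    keep = frac <= max_missing_fraction
    if not keep.all():
        logger.warning(
            "dropping %d markers with missing-call fraction > %g",
            int((~keep).sum()), max_missing_fraction,
        )
    mm = MarkerMap(marker_map.table[keep].reset_index(drop=True))
    return mm, Genotypes(genotypes.cells, genotypes.calls[keep], genotypes.mode)


# ---------------------------------------------------------------------------
# Pattern-inventory fixtures
# ---------------------------------------------------------------------------

CHROMATID_ASSIGNMENTS = {"none", "single", "two-non-sister", "two-sister", "unspecified"}


@dataclass(frozen=True)
class PatternRow:
    """One printed inventory row: a pattern, its occurrence count, and the
    printed chromatid-assignment / class annotations.

    Aggregate rows (the msh2 CO table's "more than 3 DNA tracts" line) carry
    ``pattern=None`` and ``min_tracts`` giving the smallest tract count in the
    aggregate.
    """

    kind: str
    mode: str
    pattern: str | None
    occurrence: int
    chromatid_assignment: str
    printed_class: str | None = None
    min_tracts: int | None = None

    @property
    def is_aggregate(self) -> bool:
        return self.pattern is None and self.min_tracts is not None

    @property
    def is_none(self) -> bool:
        return self.pattern == "none"


@dataclass
class PatternFixture:
    name: str
    rows: list[PatternRow] = field(default_factory=list)

    @property
    def total_occurrence(self) -> int:
        return sum(r.occurrence for r in self.rows)


def load_pattern_fixture(path, expected_total: int | None = None) -> PatternFixture:
    """Load a tab-separated pattern inventory transcribed from a printed table.

    The header comment ``# total_occurrence=N`` is a transcription checksum
    asserted at load time; ``expected_total`` adds an external check.  Ratio
    tokens are validated against the per-mode grammar (octad tokens sum to 8,
    tetrad tokens to 4) and the typographic ratio character is normalised to
    ASCII ``:``.
    """
    path = Path(path)
    checksum = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if "total_occurrence=" in line:
                checksum = int(line.split("total_occurrence=")[1].strip())
            continue
        if line.strip():
            body.append(line.split("\t"))
    if not body:
        raise FormatError(f"{path}: empty fixture")
    header = body[0]
    rows = []
    for lineno, fields in enumerate(body[1:], start=2):
        rec = dict(zip(header, fields))
        kind = rec["kind"]
        mode_label = rec["mode"]
        grammar_mode = "octad" if mode_label == "msh2" else "tetrad"
        raw_pattern = rec["pattern"].replace("∶", ":").strip()
        occurrence = int(rec["occurrence"])
        if occurrence <= 0:
            raise FormatError(f"{path}:{lineno}: occurrence must be positive")
        assignment = rec.get("chromatid_assignment", "unspecified") or "unspecified"
        if assignment not in CHROMATID_ASSIGNMENTS:
            raise FormatError(f"{path}:{lineno}: bad chromatid assignment {assignment!r}")
        printed = rec.get("printed_class") or None
        pattern: str | None = raw_pattern
        min_tracts = None
        if raw_pattern.startswith(">"):
            pattern = None
            min_tracts = int(raw_pattern[1:]) + 1
        elif raw_pattern != "none":
            try:
                parse_pattern(raw_pattern, grammar_mode)
            except PatternError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
        rows.append(
            PatternRow(
                kind=kind,
                mode=mode_label,
                pattern=pattern,
                occurrence=occurrence,
                chromatid_assignment=assignment,
                printed_class=printed,
                min_tracts=min_tracts,
            )
        )
    fixture = PatternFixture(name=path.stem, rows=rows)
    if checksum is not None and fixture.total_occurrence != checksum:
        raise FormatError(
            f"{path}: occurrence total {fixture.total_occurrence} != checksum {checksum}"
        )
    if expected_total is not None and fixture.total_occurrence != expected_total:
        raise FormatError(
            f"{path}: occurrence total {fixture.total_occurrence} != expected {expected_total}"
        )
    return fixture


def load_bundled_fixture(name: str) -> PatternFixture:
    """Load one of the inventories shipped with the package (see
    :data:`BUNDLED_FIXTURES` for names and occurrence totals)."""
    try:
        resource, total = BUNDLED_FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(BUNDLED_FIXTURES)}")
    ref = importlib.resources.files("hdna.data") / resource
    with importlib.resources.as_file(ref) as path:
        return load_pattern_fixture(path, expected_total=total)
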