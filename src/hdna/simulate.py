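"""Strand-resolution simulation of a single meiosis in a two-parent hybrid.

The simulator tracks all eight DNA strands of the four chromatids of one
meiosis.  Two chromatids start as replicated copies of the parent-1 (S288C,
allele 1) haplotype and two of the parent-2 (SK1, allele 0) haplotype.
Programmed DSBs land on random chromatids and are repaired off a non-sister
homolog by one of six pathways, each writing its characteristic strand
transfers:

* ``simple_SDSA`` — one hDNA tract on one strand of the broken chromatid
  (plus a *transient* invading-end hDNA that is undetectable without MMR);
* ``double_SDSA`` — two adjacent hDNA tracts on opposite strands of the
  broken chromatid, meeting at the DSB (trans hDNA);
* ``dHJ_dissolution`` — the same trans configuration; an unligated nick can
  prime nick translation, restoring a central patch to 4:4;
* ``dHJ_resolution_NCO`` — hDNA on both recombining non-sister chromatids,
  no arm exchange;
* ``dHJ_resolution_CO`` / ``nicked_HJ_CO`` — hDNA on the two non-sister
  chromatids plus reciprocal exchange of the distal arms at the junction.

Optional elaborations reproduce the complexity observed in real octads:
template switches to the sister insert interior restoration patches,
migration of the D-loop erases the first-end hDNA at COs (leaving it
transient), double-strand gap repair writes full-conversion tracts, HJ
branch migration writes short symmetric hDNA (aberrant 4:4*), and nick
translation can place a CO's second hDNA tract on the far side of the
junction, flipping its apparent asymmetry direction.

The first mitotic division separates the two strands of each chromatid into
the mother and daughter cell genotypes (octad output).  In MMR-proficient
(``wt``) mode, :func:`apply_mmr` converts or restores every hDNA tract —
including transient ones — before emitting four-spore tetrad genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io import Genotypes, MarkerMap

__all__ = [
    "SimConfig",
    "TruthTract",
    "TruthEvent",
    "TruthLog",
    "ConfigError",
    "DegenerateMapError",
    "YEAST_CHROMOSOME_SIZES",
    "make_marker_map",
    "simulate_meiosis",
    "apply_mmr",
]

logger = logging.getLogger(__name__)

#: S. cerevisiae chromosome sizes (bp), chromosomes I-XVI.
YEAST_CHROMOSOME_SIZES = [
    230218, 813184, 316620, 1531933, 576874, 270161, 1090940, 562643,
    439888, 745751, 666816, 1078177, 924431, 784333, 1091291, 948066,
]

PATHWAYS = (
    "simple_SDSA",
    "double_SDSA",
    "dHJ_dissolution",
    "dHJ_resolution_NCO",
    "dHJ_resolution_CO",
    "nicked_HJ_CO",
)

CO_PATHWAYS = {"dHJ_resolution_CO", "nicked_HJ_CO"}


class ConfigError(ValueError):
    pass


class DegenerateMapError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulation parameters; defaults reproduce the msh2-deficient octad
    study conditions (see docs/methods.md for provenance of each value)."""

    chromosome_sizes: list[int] = field(default_factory=lambda: list(YEAST_CHROMOSOME_SIZES))
    marker_spacing: float = 194.0          # mean inter-marker distance, bp
    dsb_mean: float = 160.0                # Poisson mean DSBs per meiosis
    pathway_probs: dict = field(
        default_factory=lambda: {
            "simple_SDSA": 0.21,
            "double_SDSA": 0.05,
            "dHJ_dissolution": 0.12,
            "dHJ_resolution_NCO": 0.10,
            "dHJ_resolution_CO": 0.42,
            "nicked_HJ_CO": 0.10,
        }
    )
    # per-event total strand-transfer length, log-normal by median and shape
    hdna_median_nco: float = 1000.0
    hdna_median_co: float = 1600.0
    hdna_sigma: float = 0.6
    transient_median: float = 800.0        # invading-end transient hDNA
    patch_median: float = 400.0            # interior restoration / gap patches
    p_conv: float = 0.5                    # MMR conversion (vs restoration)
    p_switch: float = 0.1                  # template switch per event
    p_nick: float = 0.45                   # nick translation within dissolved dHJ
    p_dloop_erase: float = 0.75            # D-loop migration erases first-end hDNA
    p_gap: float = 0.0                     # double-strand gap repair (6:2)
    p_branch_migration: float = 0.0        # symmetric hDNA (aberrant 4:4*)
    branch_migration_bp: float = 260.0     # inter-junction distance
    p_invert: float = 0.0                  # nick-translation 5:3 -> 3:5 flip at COs
    p_asymmetric: float = 0.7              # DSBR CO with clearly asymmetric tracts
    dsbr_asymmetry_ratio: float = 3.0      # long/short hDNA ratio when asymmetric
    p_sister: float = 0.0                  # intersister repair (invisible event)
    mitotic_rate: float = 0.0              # Poisson mean of injected 4:0 artifacts
    dsb_exclusion_bp: float = 10000.0      # redraw DSBs closer than this on a chromatid
    mmr_mode: str = "msh2"                 # "msh2" (octad) or "wt" (tetrad)
    seed: int | None = None

    def validate(self) -> None:
        probs = self.pathway_probs
        unknown = set(probs) - set(PATHWAYS)
        if unknown:
            raise ConfigError(f"unknown pathways {sorted(unknown)}")
        total = sum(probs.values())
        if any(p < 0 for p in probs.values()) or abs(total - 1.0) > 1e-9:
            raise ConfigError(f"pathway probabilities must be >= 0 and sum to 1, got {total}")
        for name in ("hdna_median_nco", "hdna_median_co", "transient_median",
                     "patch_median", "marker_spacing"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mmr_mode not in ("msh2", "wt"):
            raise ConfigError(f"mmr_mode must be 'msh2' or 'wt', got {self.mmr_mode!r}")

    @classmethod
    def wild_type(cls, **kwargs) -> "SimConfig":
        """MMR-proficient defaults: tetrad output, 1.8 kb transfer medians."""
        kwargs.setdefault("mmr_mode", "wt")
        kwargs.setdefault("hdna_median_nco", 1800.0)
        kwargs.setdefault("hdna_median_co", 1800.0)
        return cls(**kwargs)

    def no_complications(self) -> "SimConfig":
        """Copy with every optional elaboration switched off (pathway
        fingerprints only)."""
        return replace(
            self, p_switch=0.0, p_nick=0.0, p_gap=0.0, p_dloop_erase=0.0,
            p_branch_migration=0.0, p_invert=0.0, p_sister=0.0, mitotic_rate=0.0,
            p_asymmetric=0.0,
        )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class TruthTract:
    """One written (or transient) strand-transfer tract."""

    chrom: object
    chromatid: int
    strand: int | None          # None when both strands are affected
    x0: float                   # bp interval [x0, x1)
    x1: float
    state: str                  # hDNA | full-conversion | restoration-patch
    transient: bool = False
    i0: int = 0                 # covered marker index range [i0, i1)
    i1: int = 0
    donor_vals: np.ndarray | None = None   # per-marker donor alleles
    recip_vals: np.ndarray | None = None   # per-marker recipient alleles

    @property
    def n_markers(self) -> int:
        return self.i1 - self.i0

    @property
    def informative_markers(self) -> set[int]:
        """Markers where the transfer actually changes the allele.

        After earlier crossovers a "non-sister" donor can be locally
        identical in sequence to the broken chromatid, making the repair
        genetically silent.
        """
        if self.donor_vals is None or self.recip_vals is None:
            return set()
        diff = np.flatnonzero(self.donor_vals != self.recip_vals)
        return {int(k) + self.i0 for k in diff}


@dataclass
class TruthEvent:
    chrom: object
    pos: float
    chromatid: int              # broken
    donor: int
    pathway: str
    outcome: str                # CO | NCO | invisible | mitotic-artifact
    tracts: list[TruthTract] = field(default_factory=list)
    visible_markers: set[int] = field(default_factory=set)
    #: a CO junction is silent when the exchanged arms are locally identical
    junction_informative: bool = True

    @property
    def n_visible_markers(self) -> int:
        return len(self.visible_markers)

    def span(self) -> tuple[float, float]:
        xs = [self.pos] + [t.x0 for t in self.tracts if not t.transient]
        ys = [self.pos] + [t.x1 for t in self.tracts if not t.transient]
        return (min(xs), max(ys))


@dataclass
class TruthLog:
    events: list[TruthEvent] = field(default_factory=list)
    mmr_actions: list[tuple[TruthTract, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Marker map generation
# ---------------------------------------------------------------------------

def make_marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    """Draw marker positions with geometric inter-marker spacing.

    Mean gap = ``config.marker_spacing`` bp (the study hybrid averages one
    polymorphism per 194 bp).  Every chromosome receives at least one marker;
    a mean spacing at or above the smallest chromosome size is rejected as a
    degenerate map.
    """
    import pandas as pd

    if config.marker_spacing >= min(config.chromosome_sizes):
        raise DegenerateMapError(
            f"mean spacing {config.marker_spacing} >= smallest chromosome "
            f"({min(config.chromosome_sizes)} bp)"
        )
    frames = []
    p = 1.0 / config.marker_spacing
    for c, size in enumerate(config.chromosome_sizes):
        chrom = f"chr{c + 1:02d}"
        n_guess = int(size * p * 1.3) + 10
        gaps = rng.geometric(p, size=n_guess)
        pos = np.cumsum(gaps)
        while pos[-1] < size:
            gaps = rng.geometric(p, size=n_guess)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(gaps)])
        pos = pos[pos <= size]
        if len(pos) == 0:
            pos = np.array([int(rng.integers(1, size + 1))])
        types = rng.choice(["S", "I", "D"], size=len(pos), p=[0.90, 0.05, 0.05])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "index": np.arange(1, len(pos) + 1),
                    "Ali_pos": pos,
                    "S288C_pos": pos,
                    "type": types,
                }
            )
        )
    return MarkerMap(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Meiosis simulation
# ---------------------------------------------------------------------------

class _ChromState:
    """Eight-strand genotype state of one chromosome; row = 2*chromatid + strand."""

    def __init__(self, chrom, positions: np.ndarray):
        self.chrom = chrom
        self.positions = np.asarray(positions, dtype=float)
        n = len(positions)
        self.arr = np.zeros((8, n), dtype=np.int8)
        self.arr[0:4] = 1  # chromatids 0, 1 carry parent 1
        self.tracts: list[TruthTract] = []

    def marker_range(self, x0: float, x1: float) -> tuple[int, int]:
        i0 = int(np.searchsorted(self.positions, x0, side="left"))
        i1 = int(np.searchsorted(self.positions, x1, side="left"))
        return i0, i1

    def write_hdna(self, chromatid: int, donor: int, strand: int,
                   x0: float, x1: float, transient: bool = False) -> TruthTract:
        i0, i1 = self.marker_range(x0, x1)
        donor_vals = self.arr[2 * donor, i0:i1].copy()
        recip_vals = self.arr[2 * chromatid + strand, i0:i1].copy()
        if not transient:
            self.arr[2 * chromatid + strand, i0:i1] = donor_vals
        tract = TruthTract(self.chrom, chromatid, strand, x0, x1, "hDNA",
                           transient=transient, i0=i0, i1=i1,
                           donor_vals=donor_vals, recip_vals=recip_vals)
        self.tracts.append(tract)
        return tract

    def write_full_conversion(self, chromatid: int, donor: int,
                              x0: float, x1: float) -> TruthTract:
        i0, i1 = self.marker_range(x0, x1)
        donor_vals = self.arr[2 * donor, i0:i1].copy()
        recip_vals = self.arr[2 * chromatid, i0:i1].copy()
        self.arr[2 * chromatid, i0:i1] = donor_vals
        self.arr[2 * chromatid + 1, i0:i1] = donor_vals
        tract = TruthTract(self.chrom, chromatid, None, x0, x1, "full-conversion",
                           i0=i0, i1=i1, donor_vals=donor_vals, recip_vals=recip_vals)
        self.tracts.append(tract)
        return tract

    def restore_patch(self, source: TruthTract, x0: float, x1: float) -> TruthTract:
        """Undo part of an hDNA tract (nick translation / template switch)."""
        x0 = max(x0, source.x0)
        x1 = min(x1, source.x1)
        i0, i1 = self.marker_range(x0, x1)
        row = 2 * source.chromatid + source.strand
        off = source.i0
        self.arr[row, i0:i1] = source.recip_vals[i0 - off: i1 - off]
        tract = TruthTract(self.chrom, source.chromatid, source.strand, x0, x1,
                           "restoration-patch", i0=i0, i1=i1)
        self.tracts.append(tract)
        return tract

    def exchange_arms(self, c: int, d: int, x: float) -> None:
        """Reciprocal exchange of the arms distal (right) of ``x``."""
        i = int(np.searchsorted(self.positions, x, side="left"))
        rows_c = slice(2 * c, 2 * c + 2)
        rows_d = slice(2 * d, 2 * d + 2)
        tmp = self.arr[rows_c, i:].copy()
        self.arr[rows_c, i:] = self.arr[rows_d, i:]
        self.arr[rows_d, i:] = tmp
        # tract records distal of the junction move with the arms
        for t in self.tracts:
            if t.x0 >= x and t.chromatid in (c, d):
                t.chromatid = d if t.chromatid == c else c


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _split_lengths(rng, total: float, asymmetric: bool, ratio: float) -> tuple[float, float]:
    if asymmetric:
        u = ratio / (1.0 + ratio)
    else:
        u = float(rng.beta(4.0, 4.0))
    return total * u, total * (1.0 - u)


def simulate_meiosis(
    config: SimConfig,
    marker_map: MarkerMap | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[MarkerMap, Genotypes, TruthLog]:
    """Simulate one meiosis; returns (marker map, genotypes, ground truth).

    Octad (``msh2``) mode emits eight cell columns (four spores x
    mother/daughter); wild-type mode applies MMR and emits four spores.  The
    random generator fully determines the output.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if marker_map is None:
        marker_map = make_marker_map(config, rng)

    sizes = dict(zip([f"chr{c + 1:02d}" for c in range(len(config.chromosome_sizes))],
                     config.chromosome_sizes))
    states: dict = {}
    for chrom in marker_map.chromosomes:
        states[chrom] = _ChromState(chrom, marker_map.positions(chrom))

    truth = TruthLog()
    chrom_names = list(states)
    weights = np.array([sizes.get(c, 1.0) for c in chrom_names], dtype=float)
    weights /= weights.sum()

    n_dsb = int(rng.poisson(config.dsb_mean))
    pathways = list(config.pathway_probs)
    pathway_p = np.array([config.pathway_probs[k] for k in pathways])

    placed: dict = {name: [] for name in chrom_names}  # (pos, chromatid)
    for _ in range(n_dsb):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        size = sizes.get(chrom, states[chrom].positions[-1] if len(states[chrom].positions) else 1)
        chromatid = int(rng.integers(0, 4))
        for _attempt in range(100):
            x = float(rng.uniform(1, size))
            near = [p for p, c in placed[chrom]
                    if c == chromatid and abs(p - x) < config.dsb_exclusion_bp]
            if not near:
                break
            logger.debug("redrawing DSB at %s:%.0f (exclusion)", chrom, x)
        placed[chrom].append((x, chromatid))
        donor = int(rng.choice([2, 3] if chromatid < 2 else [0, 1]))
        pathway = pathways[int(rng.choice(len(pathways), p=pathway_p))]
        event = TruthEvent(chrom=chrom, pos=x, chromatid=chromatid, donor=donor,
                           pathway=pathway, outcome="NCO")
        if rng.uniform() < config.p_sister:
            event.outcome = "invisible"
            event.pathway = "intersister"
            truth.events.append(event)
            continue
        _repair(states[chrom], event, config, rng)
        truth.events.append(event)

    # optional mitotic 4:0 artifacts to exercise the downstream filter
    for _ in range(int(rng.poisson(config.mitotic_rate))):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        size = sizes.get(chrom, 1)
        x = float(rng.uniform(1, size))
        width = _lognormal(rng, 1000.0, 0.5)
        st = states[chrom]
        i0, i1 = st.marker_range(x, x + width)
        st.arr[:, i0:i1] = int(rng.integers(0, 2))
        truth.events.append(TruthEvent(chrom=chrom, pos=x, chromatid=-1, donor=-1,
                                       pathway="mitotic", outcome="mitotic-artifact"))

    if config.mmr_mode == "wt":
        genotypes = apply_mmr(states, truth, config.p_conv, rng, mmr_mode="wt")
    else:
        calls = np.concatenate([states[c].arr.T for c in chrom_names], axis=0) \
            if chrom_names else np.empty((0, 8), dtype=np.int8)
        cells = [f"spore{s + 1}_{md}" for s in range(4) for md in ("m", "d")]
        genotypes = Genotypes(cells=cells, calls=calls, mode="octad")
    return marker_map, genotypes, truth


def _repair(st: _ChromState, event: TruthEvent, config: SimConfig,
            rng: np.random.Generator) -> None:
    """Write the strand transfers of one DSB repair event."""
    x = event.pos
    c, d = event.chromatid, event.donor
    is_co = event.pathway in CO_PATHWAYS
    median = config.hdna_median_co if is_co else config.hdna_median_nco
    total = _lognormal(rng, median, config.hdna_sigma)
    strand = int(rng.integers(0, 2))
    visible: list[TruthTract] = []

    if event.pathway == "simple_SDSA":
        side = int(rng.integers(0, 2))
        x0, x1 = (x, x + total) if side else (x - total, x)
        tr = st.write_hdna(c, d, strand, x0, x1)
        visible.append(tr)
        # invading-end hDNA on the far side of the DSB: transient, MMR-visible only
        tt = _lognormal(rng, config.transient_median, config.hdna_sigma)
        t0, t1 = (x - tt, x) if side else (x, x + tt)
        st.write_hdna(c, d, strand, t0, t1, transient=True)
        event.tracts.append(st.tracts[-2])
        event.tracts.append(st.tracts[-1])
        if rng.uniform() < config.p_switch:
            _carve_patch(st, event, tr, rng, config)

    elif event.pathway in ("double_SDSA", "dHJ_dissolution"):
        left, right = _split_lengths(rng, total, False, 1.0)
        t_left = st.write_hdna(c, d, 0, x - left, x)
        t_right = st.write_hdna(c, d, 1, x, x + right)
        event.tracts += [t_left, t_right]
        visible += [t_left, t_right]
        if event.pathway == "dHJ_dissolution" and rng.uniform() < config.p_nick:
            # unrepaired nick at the junction primes nick translation: a
            # central patch of the trans hDNA reverts to 4:4
            patch = _lognormal(rng, config.patch_median, config.hdna_sigma)
            pt = st.restore_patch(t_right, x, x + patch)
            event.tracts.append(pt)
        elif rng.uniform() < config.p_switch:
            _carve_patch(st, event, t_right if rng.integers(0, 2) else t_left, rng, config)

    elif event.pathway == "dHJ_resolution_NCO":
        left, right = _split_lengths(rng, total, False, 1.0)
        t1 = st.write_hdna(d, c, strand, x - left, x)   # donor-side hDNA
        t2 = st.write_hdna(c, d, strand, x, x + right)  # second-end capture
        event.tracts += [t1, t2]
        visible += [t1, t2]

    else:  # dHJ_resolution_CO, nicked_HJ_CO
        event.outcome = "CO"
        i = int(np.searchsorted(st.positions, x, side="left"))
        event.junction_informative = bool(
            i < st.arr.shape[1] and st.arr[2 * c, i] != st.arr[2 * d, i]
        )
        st.exchange_arms(c, d, x)
        asym = rng.uniform() < config.p_asymmetric
        left, right = _split_lengths(rng, total, asym, config.dsbr_asymmetry_ratio)
        erase = rng.uniform() < config.p_dloop_erase
        # first-end hDNA, left of the junction on the broken chromatid;
        # D-loop migration can erase it, leaving it transient
        t1 = st.write_hdna(c, d, strand, x - left, x, transient=erase)
        event.tracts.append(t1)
        if not erase:
            visible.append(t1)
        if rng.uniform() < config.p_invert:
            # nick translation plus HJ migration rewrites the second-end
            # tract on the far side of the junction (opposite direction)
            t2 = st.write_hdna(c, d, strand, x, x + right)
        else:
            t2 = st.write_hdna(d, c, strand, x, x + right)
        event.tracts.append(t2)
        visible.append(t2)
        if rng.uniform() < config.p_gap:
            gap = _lognormal(rng, config.patch_median, config.hdna_sigma)
            tg = st.write_full_conversion(c, d, x - gap / 2.0, x + gap / 2.0)
            event.tracts.append(tg)
            visible.append(tg)
        if rng.uniform() < config.p_branch_migration:
            # dHJ migration beyond the exchange writes symmetric hDNA on both
            # chromatids (aberrant 4:4*); strand 1 on both so each donor read
            # (strand 0) stays clean of the other write
            bm = config.branch_migration_bp
            b1 = st.write_hdna(c, d, 1, x + right, x + right + bm)
            b2 = st.write_hdna(d, c, 1, x + right, x + right + bm)
            event.tracts += [b1, b2]
            visible += [b1, b2]

    for t in visible:
        if not t.transient:
            event.visible_markers.update(t.informative_markers)
    for t in event.tracts:
        if t.state == "restoration-patch":
            event.visible_markers -= set(range(t.i0, t.i1))


def _carve_patch(st: _ChromState, event: TruthEvent, tract: TruthTract,
                 rng: np.random.Generator, config: SimConfig) -> None:
    """Template switch to the sister: an interior patch of an hDNA tract is
    restored to parental information."""
    width = tract.x1 - tract.x0
    if width <= 0:
        return
    patch = min(_lognormal(rng, config.patch_median, config.hdna_sigma), width * 0.8)
    start = tract.x0 + rng.uniform(0.05, 0.95 - patch / width if patch < width else 0.05) * width
    pt = st.restore_patch(tract, start, start + patch)
    event.tracts.append(pt)
    event.visible_markers -= set(range(pt.i0, pt.i1))


def apply_mmr(states, truth: TruthLog, p_conv: float,
              rng: np.random.Generator, mmr_mode: str = "wt") -> Genotypes:
    """Mismatch-repair every hDNA tract and emit four-spore tetrad genotypes.

    Each hDNA tract — transient invading-end tracts included — is
    independently converted toward the donor with probability ``p_conv`` and
    otherwise restored to the recipient parent.  The result is homoduplex
    chromatids, so the spore genotype equals the chromatid genotype.
    """
    if mmr_mode != "wt":
        raise ConfigError("apply_mmr is only meaningful in wild-type (MMR+) mode")
    chrom_names = list(states)
    for chrom in chrom_names:
        st = states[chrom]
        for tract in st.tracts:
            if tract.state != "hDNA":
                continue
            convert = rng.uniform() < p_conv
            row = 2 * tract.chromatid + (tract.strand or 0)
            other = 2 * tract.chromatid + 1 - (tract.strand or 0)
            sl = slice(tract.i0, tract.i1)
            if tract.transient:
                if convert:
                    st.arr[row, sl] = tract.donor_vals
                    st.arr[other, sl] = tract.donor_vals
            else:
                if convert:
                    st.arr[other, sl] = st.arr[row, sl]
                else:
                    st.arr[row, sl] = st.arr[other, sl]
            truth.mmr_actions.append((tract, "convert" if convert else "restore"))
    calls = np.concatenate([states[c].arr[0::2].T for c in chrom_names], axis=0) \
        if chrom_names else np.empty((0, 4), dtype=np.int8)
    cells = [f"spore{s + 1}" for s in range(4)]
    return Genotypes(cells=cells, calls=calls, mode="tetrad")
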