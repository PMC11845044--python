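"""Synthetic meiosis: parents, markers, tetrads, and ground-truth events.

The generator emulates a tetrad-sequencing study design: two homozygous
parental haplotypes separated by fixed differences, with heterozygous
introgression blocks carrying elevated marker density; 48 four-spore meioses
per cross; crossovers as reciprocal exchanges between one chromatid of each
homolog; non-crossover gene conversions as short tracts (geometric length,
mean 550 bp) copied onto one chromatid.

Crossover positions follow a stationary gamma-renewal process on the
rate-weighted (genetic) axis; shape 1 reduces to a Poisson process (no
interference).  Because crossovers exchange whole chromatid suffixes, a
crossover between chromatids that locally carry the same parental origin
produces no 2:2 phase change — the classical invisibility of two- and
three-strand double crossovers in origin-coded tetrad data.  Each truth event
therefore carries geometry-derived observability annotations (computed here
from truth plus the marker layout, independent of any event caller).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import (
    A_ORIGIN,
    B_ORIGIN,
    MISSING,
    IntrogressionSet,
    MarkerMap,
    TetradOriginMatrix,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# chromosome lengths (bp) used as the default study genome: 16 chromosomes,
# ~12.07 Mb total, with a budding-yeast-like length profile
STUDY_CHROM_LENGTHS: dict[str, int] = {
    f"chr{i + 1:02d}": L * 1000
    for i, L in enumerate(
        [230, 813, 316, 1532, 576, 270, 1091, 562, 440, 745, 666, 1078, 924, 784, 1091, 948]
    )
}

# nine heterozygous introgression intervals (0-based half-open) of the
# fermentation-cross design, on chromosomes 4, 6, 7, 9, 10, 10, 13, 14, 15
STUDY_INTROGRESSIONS: list[tuple[str, int, int]] = [
    ("chr04", 866500, 983774),
    ("chr06", 0, 65500),
    ("chr07", 0, 53500),
    ("chr09", 158500, 298500),
    ("chr10", 234500, 288500),
    ("chr10", 301500, 428500),
    ("chr13", 26500, 103500),
    ("chr14", 18500, 586500),
    ("chr15", 367500, 434500),
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cross.

    Densities are markers per kb; ``co_per_meiosis`` is the expected number of
    crossover events generated per meiosis genome-wide (apportioned across
    chromosomes by length); ``nco_per_meiosis`` the expected number of
    conversion initiations.  ``interference_shape`` is the gamma-renewal shape
    for inter-crossover spacing (1 = Poisson, no interference).  Rate
    multipliers reshape where events fall inside introgressions without
    changing per-chromosome totals.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_CHROM_LENGTHS)
    )
    background_marker_density: float = 1.35
    introgressions: list[tuple[str, int, int]] = field(default_factory=list)
    introgression_marker_density: float = 3.225
    co_per_meiosis: float = 82.5
    nco_per_meiosis: float = 30.0
    nco_tract_mean: float = 550.0
    nco_tract_distribution: str = "geometric"  # or "gamma"
    nco_tract_shape: float = 2.0  # gamma shape, if selected
    interference_shape: float = 1.0
    introgression_co_multiplier: float = 1.0
    introgression_nco_multiplier: float = 1.0
    error_rate: float = 0.0
    missing_rate: float = 0.0
    polymorphic_density: float = 0.5  # parental het sites per kb, for similarity
    gc_content: float = 0.39
    n_tetrads: int = 48
    seed: int = 0

    def __post_init__(self):
        if any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for name in (
            "background_marker_density",
            "introgression_marker_density",
            "co_per_meiosis",
            "nco_per_meiosis",
            "polymorphic_density",
            "introgression_co_multiplier",
            "introgression_nco_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nco_tract_mean < 1:
            raise ValueError("nco_tract_mean must be >= 1 bp")
        if self.interference_shape <= 0:
            raise ValueError("interference_shape must be > 0")
        for name in ("error_rate", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if self.nco_tract_distribution not in ("geometric", "gamma"):
            raise ValueError("nco_tract_distribution must be 'geometric' or 'gamma'")
        self.introgressions = [tuple(iv) for iv in self.introgressions]
        # validates bounds and overlap
        if self.introgressions:
            iset = IntrogressionSet(
                pd.DataFrame(self.introgressions, columns=["chrom", "start", "end"])
            )
            for chrom, s, e in iset.intervals():
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"introgression on unknown chromosome {chrom!r}")
                if e > self.chrom_lengths[chrom]:
                    raise ValueError(
                        f"introgression {chrom}:{s}-{e} exceeds chromosome length"
                    )

    def expected_co(self, chrom: str) -> float:
        total = sum(self.chrom_lengths.values())
        return self.co_per_meiosis * self.chrom_lengths[chrom] / total

    def expected_nco(self, chrom: str) -> float:
        total = sum(self.chrom_lengths.values())
        return self.nco_per_meiosis * self.chrom_lengths[chrom] / total

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["introgressions"] = [list(iv) for iv in self.introgressions]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["introgressions"] = [tuple(iv) for iv in d.get("introgressions", [])]
        return cls(**d)


def study_config(cross: str = "fermentation", n_tetrads: int = 48, seed: int = 0) -> SimulationConfig:
    """Default configurations emulating the two study crosses.

    The fermentation cross carries the nine heterozygous introgressions with
    dense markers, fewer crossovers per meiosis, crossover suppression and
    conversion enrichment inside introgressions; the natural cross has
    background marker density everywhere.
    """
    if cross == "fermentation":
        return SimulationConfig(
            introgressions=list(STUDY_INTROGRESSIONS),
            co_per_meiosis=63.7,
            introgression_co_multiplier=0.4,
            introgression_nco_multiplier=2.0,
            n_tetrads=n_tetrads,
            seed=seed,
        )
    if cross == "natural":
        return SimulationConfig(co_per_meiosis=82.5, n_tetrads=n_tetrads, seed=seed)
    raise ValueError("cross must be 'fermentation' or 'natural'")


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------

@dataclass
class Parents:
    """Two homozygous parental haplotypes plus the marker scaffold."""

    sequences_a: dict[str, np.ndarray]  # uint8 byte arrays (ACGT)
    sequences_b: dict[str, np.ndarray]
    marker_map: MarkerMap
    introgressions: IntrogressionSet
    polymorphic: dict[str, np.ndarray]  # het-site positions per chromosome

    def sequence_str(self, chrom: str, parent: str = "a") -> str:
        seq = self.sequences_a if parent == "a" else self.sequences_b
        return seq[chrom].tobytes().decode()


def _density_segments(
    length: int, intervals: list[tuple[int, int]], bg: float, fg: float
) -> list[tuple[int, int, float]]:
    """Partition [0, length) into (start, end, density) segments."""
    segs = []
    cur = 0
    for s, e in sorted(intervals):
        if s > cur:
            segs.append((cur, s, bg))
        segs.append((s, e, fg))
        cur = e
    if cur < length:
        segs.append((cur, length, bg))
    return segs


def _poisson_positions(
    rng: np.random.Generator, segs: list[tuple[int, int, float]]
) -> np.ndarray:
    """Homogeneous Poisson point process within each density stratum
    (densities per kb); integer positions, deduplicated and sorted."""
    pos = []
    for s, e, d in segs:
        n = rng.poisson(d * (e - s) / 1000.0)
        if n:
            pos.append(rng.integers(s, e, size=n))
    if not pos:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(pos)).astype(np.int64)


def simulate_parents(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Parents:
    """Generate parental sequences, the fixed-difference marker map, and the
    introgression set.  Parents are homozygous and differ at every marker."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    iset = IntrogressionSet(
        pd.DataFrame(config.introgressions or [], columns=["chrom", "start", "end"])
        if config.introgressions
        else pd.DataFrame({"chrom": [], "start": [], "end": []})
    )

    seqs_a: dict[str, np.ndarray] = {}
    seqs_b: dict[str, np.ndarray] = {}
    poly: dict[str, np.ndarray] = {}
    marker_rows = []
    gc = config.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for chrom, L in config.chrom_lengths.items():
        seq = rng.choice(BASES, size=L, p=base_probs)
        intervals = [(s, e) for c, s, e in iset.intervals(chrom)]
        segs = _density_segments(
            L, intervals, config.background_marker_density, config.introgression_marker_density
        )
        mpos = _poisson_positions(rng, segs)
        seq_b = seq.copy()
        if len(mpos):
            ref = seq[mpos]
            # pick a different base for parent B at each marker
            shift = rng.integers(1, 4, size=len(mpos))
            base_index = np.empty(256, dtype=np.int64)
            for i, b in enumerate(BASES):
                base_index[b] = i
            alt = BASES[(base_index[ref] + shift) % 4]
            seq_b[mpos] = alt
            for p, r, a in zip(mpos, ref, alt):
                marker_rows.append((chrom, int(p), chr(r), chr(a)))
        # parental het sites (polymorphic), excluding marker positions
        ppos = _poisson_positions(
            rng, [(0, L, config.polymorphic_density)]
        )
        ppos = np.setdiff1d(ppos, mpos)
        poly[chrom] = ppos
        seqs_a[chrom] = seq
        seqs_b[chrom] = seq_b

    if marker_rows:
        mdf = pd.DataFrame(marker_rows, columns=["chrom", "pos", "allele_a", "allele_b"])
    else:
        mdf = pd.DataFrame({"chrom": [], "pos": [], "allele_a": [], "allele_b": []})
    # keep chromosome order of the config even for empty chromosomes
    marker_map = MarkerMap(mdf)
    return Parents(seqs_a, seqs_b, marker_map, iset, poly)


# ---------------------------------------------------------------------------
# one tetrad
# ---------------------------------------------------------------------------

def _rate_segments(
    config: SimulationConfig, chrom: str, multiplier: float
) -> list[tuple[int, int, float]]:
    L = config.chrom_lengths[chrom]
    intervals = [
        (s, e) for c, s, e in config.introgressions if c == chrom
    ] if config.introgressions else []
    return _density_segments(L, sorted(intervals), 1.0, multiplier)


def _genetic_axis(segs: list[tuple[int, int, float]]):
    """Cumulative rate-weighted coordinate: returns (phys_breaks, gen_breaks)."""
    phys = [segs[0][0]]
    gen = [0.0]
    for s, e, w in segs:
        phys.append(e)
        gen.append(gen[-1] + (e - s) * w)
    return np.array(phys, dtype=float), np.array(gen, dtype=float)


def _gen_to_phys(u: np.ndarray, phys: np.ndarray, gen: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(gen, u, side="right") - 1, 0, len(gen) - 2)
    w = (gen[idx + 1] - gen[idx]) / (phys[idx + 1] - phys[idx])
    return phys[idx] + (u - gen[idx]) / w


def _renewal_points(
    rng: np.random.Generator, total: float, expected: float, shape: float
) -> np.ndarray:
    """Stationary gamma-renewal points on [0, total) with expected count
    `expected`; shape 1 is exactly Poisson.  Stationarity via burn-in."""
    if expected <= 0 or total <= 0:
        return np.empty(0)
    mean_gap = total / expected
    if shape == 1.0:
        n = rng.poisson(expected)
        return np.sort(rng.uniform(0, total, size=n))
    t = -10.0 * mean_gap
    pts = []
    while t < total:
        t += rng.gamma(shape, mean_gap / shape)
        if 0 <= t < total:
            pts.append(t)
    return np.asarray(pts)


def _sample_tract_lengths(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> np.ndarray:
    if config.nco_tract_distribution == "geometric":
        return rng.geometric(1.0 / config.nco_tract_mean, size=n)
    k = config.nco_tract_shape
    return np.maximum(1, np.round(rng.gamma(k, config.nco_tract_mean / k, size=n))).astype(int)


def simulate_tetrad(
    parents: Parents,
    config: SimulationConfig,
    rng: np.random.Generator,
    tetrad_id: str = "t0",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one meiosis: four spores' true marker origins plus ground truth.

    Returns ``(true_origins, truth)`` where ``true_origins`` is the 4 x M int8
    matrix of parental origins at the markers (0 = parent A, 1 = parent B) and
    ``truth`` is a DataFrame of CO/NCO events with observability annotations.
    Spores 0-1 start as parent-A chromatids, 2-3 as parent-B chromatids; each
    CO exchanges the suffixes of one chromatid per homolog; each NCO flips the
    recipient chromatid's origin over its tract (guaranteeing 3:1 at converted
    markers).
    """
    mm = parents.marker_map
    true_origins = np.empty((4, len(mm)), dtype=np.int8)
    truth_rows: list[dict] = []

    for chrom, L in config.chrom_lengths.items():
        pos = mm.positions(chrom) if chrom in mm.chroms else np.empty(0, dtype=np.int64)
        sl = mm.chrom_slice(chrom) if chrom in mm.chroms else slice(0, 0)
        m = len(pos)

        # --- crossovers on the rate-weighted axis
        segs = _rate_segments(config, chrom, config.introgression_co_multiplier)
        phys, gen = _genetic_axis(segs)
        upts = _renewal_points(rng, gen[-1], config.expected_co(chrom), config.interference_shape)
        co_x = _gen_to_phys(upts, phys, gen)
        co_pairs = np.column_stack(
            [rng.integers(0, 2, size=len(co_x)), rng.integers(2, 4, size=len(co_x))]
        ) if len(co_x) else np.empty((0, 2), dtype=int)

        # apply COs left to right; record per-spore origin transitions
        cur = [0, 0, 1, 1]
        trans_pos: list[list[float]] = [[] for _ in range(4)]
        trans_val: list[list[int]] = [[] for _ in range(4)]
        for x, (i, j) in zip(co_x, co_pairs):
            visible = cur[i] != cur[j]
            if visible:
                cur[i], cur[j] = cur[j], cur[i]
                trans_pos[i].append(x)
                trans_val[i].append(cur[i])
                trans_pos[j].append(x)
                trans_val[j].append(cur[j])
            truth_rows.append(
                dict(
                    tetrad_id=tetrad_id, chrom=chrom, kind="CO", pos=float(x),
                    tract_start=-1, tract_end=-1,
                    spore_a=int(i), spore_b=int(j), visible=bool(visible),
                )
            )

        # marker-level origins from the transition lists
        chrom_orig = np.empty((4, m), dtype=np.int8)
        for s in range(4):
            base = 0 if s < 2 else 1
            if trans_pos[s]:
                tp = np.asarray(trans_pos[s])
                tv = np.asarray(trans_val[s], dtype=np.int8)
                idx = np.searchsorted(tp, pos, side="right")
                chrom_orig[s] = np.where(idx == 0, base, tv[np.maximum(idx - 1, 0)])
            else:
                chrom_orig[s] = base

        # --- non-crossover conversion tracts
        nsegs = _rate_segments(config, chrom, config.introgression_nco_multiplier)
        nphys, ngen = _genetic_axis(nsegs)
        n_nco = rng.poisson(config.expected_nco(chrom))
        if n_nco:
            mids = _gen_to_phys(rng.uniform(0, ngen[-1], size=n_nco), nphys, ngen)
            lens = _sample_tract_lengths(rng, n_nco, config)
            recips = rng.integers(0, 4, size=n_nco)
            for mid, tl, r in zip(mids, lens, recips):
                s0 = int(np.clip(round(mid - tl / 2), 0, max(L - 1, 0)))
                e0 = int(min(s0 + int(tl), L))
                lo, hi = np.searchsorted(pos, (s0, e0))
                chrom_orig[r, lo:hi] = 1 - chrom_orig[r, lo:hi]
                truth_rows.append(
                    dict(
                        tetrad_id=tetrad_id, chrom=chrom, kind="NCO",
                        pos=float((s0 + e0) / 2), tract_start=s0, tract_end=e0,
                        spore_a=int(r), spore_b=-1, visible=hi > lo,
                    )
                )
        true_origins[:, sl] = chrom_orig

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "tetrad_id", "chrom", "kind", "pos", "tract_start", "tract_end",
            "spore_a", "spore_b", "visible",
        ],
    )
    return true_origins, truth


def genotype_tetrad(
    true_origins: np.ndarray,
    marker_map: MarkerMap,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
    tetrad_id: str = "t0",
    spore_ids: Sequence[str] | None = None,
) -> TetradOriginMatrix:
    """Observation model: flip each origin code with probability `error_rate`,
    then mask with probability `missing_rate`."""
    for name, v in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    codes = np.asarray(true_origins, dtype=np.int8).copy()
    if codes.shape[1] != len(marker_map):
        raise ValueError("origin matrix does not match marker map length")
    if error_rate > 0:
        flip = rng.random(codes.shape) < error_rate
        codes[flip] = 1 - codes[flip]
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    if spore_ids is None:
        spore_ids = tuple(f"{tetrad_id}_s{i + 1}" for i in range(4))
    return TetradOriginMatrix(tetrad_id, tuple(spore_ids), codes)


# ---------------------------------------------------------------------------
# truth observability annotations (geometry only; independent of the caller)
# ---------------------------------------------------------------------------

def annotate_truth(truth: pd.DataFrame, marker_map: MarkerMap) -> pd.DataFrame:
    """Add marker-geometry observability flags to a truth table.

    CO: ``clean`` = visible in origin space, has >= 1 marker on each side, and
    is the only visible CO transition in its inter-marker gap.  NCO:
    ``n_conv_markers`` = markers inside the tract; ``clean`` = its marker span
    does not interfere with another NCO of the same tetrad/chromosome (span
    overlap, or same-spore span adjacency, which merges runs) and no visible
    CO falls within or immediately flanking the span.  ``first_conv`` /
    ``last_conv`` are the outermost converted marker positions (-1 if none).
    """
    truth = truth.copy()
    n = len(truth)
    clean = np.zeros(n, dtype=bool)
    n_conv = np.zeros(n, dtype=np.int64)
    first_conv = np.full(n, -1, dtype=np.int64)
    last_conv = np.full(n, -1, dtype=np.int64)

    for (tid, chrom), grp in truth.groupby(["tetrad_id", "chrom"], sort=False):
        pos = (
            marker_map.positions(chrom)
            if chrom in marker_map.chroms
            else np.empty(0, dtype=np.int64)
        )
        m = len(pos)
        cos = grp[grp["kind"] == "CO"]
        ncos = grp[grp["kind"] == "NCO"]
        vis = cos[cos["visible"]]
        gaps = np.searchsorted(pos, vis["pos"].to_numpy())
        gap_counts = pd.Series(gaps).value_counts().to_dict()

        for (idx, row), g in zip(vis.iterrows(), gaps):
            interior = 0 < g < m
            clean[truth.index.get_loc(idx)] = interior and gap_counts[g] == 1

        # NCO marker spans (marker index ranges)
        spans = {}
        for idx, row in ncos.iterrows():
            lo, hi = np.searchsorted(pos, (row["tract_start"], row["tract_end"]))
            n_conv[truth.index.get_loc(idx)] = hi - lo
            if hi > lo:
                first_conv[truth.index.get_loc(idx)] = pos[lo]
                last_conv[truth.index.get_loc(idx)] = pos[hi - 1]
            spans[idx] = (lo, hi, int(row["spore_a"]))
        vis_gaps = set(int(g) for g in gaps)
        for idx, (lo, hi, spore) in spans.items():
            if hi <= lo:
                continue
            ok = True
            for jdx, (lo2, hi2, spore2) in spans.items():
                if jdx == idx:
                    continue
                if lo < hi2 and lo2 < hi:  # overlap
                    ok = False
                elif spore == spore2 and (hi == lo2 or hi2 == lo):  # adjacency merges
                    ok = False
            # visible CO inside or immediately flanking the converted span
            if ok and any(lo <= g <= hi for g in vis_gaps):
                ok = False
            clean[truth.index.get_loc(idx)] = ok
    truth["clean"] = clean
    truth["n_conv_markers"] = n_conv
    truth["first_conv"] = first_conv
    truth["last_conv"] = last_conv
    return truth


# ---------------------------------------------------------------------------
# whole cross
# ---------------------------------------------------------------------------

@dataclass
class CrossSimulation:
    config: SimulationConfig
    parents: Parents
    tetrads: list[TetradOriginMatrix]  # observed (with error/missing applied)
    true_origins: list[np.ndarray]
    truth: pd.DataFrame  # annotated


def simulate_cross(config: SimulationConfig) -> CrossSimulation:
    """Simulate a full cross: parents, ``n_tetrads`` meioses, genotyped spores,
    and the annotated ground-truth event table.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    tetrads = []
    origins = []
    truths = []
    for t in range(config.n_tetrads):
        tid = f"t{t + 1:03d}"
        tor, truth = simulate_tetrad(parents, config, rng, tetrad_id=tid)
        om = genotype_tetrad(
            tor, parents.marker_map, config.error_rate, config.missing_rate, rng, tid
        )
        tetrads.append(om)
        origins.append(tor)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    if len(truth):
        truth = annotate_truth(truth, parents.marker_map)
    return CrossSimulation(config, parents, tetrads, origins, truth)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(parents: Parents, path: str | Path, parent: str = "a", width: int = 70) -> None:
    seqs = parents.sequences_a if parent == "a" else parents.sequences_b
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            s = seq.tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_vcf(
    sim: CrossSimulation,
    path: str | Path,
    parent_a: str = "parentA",
    parent_b: str = "parentB",
) -> None:
    """Joint VCF: two homozygous parents plus every spore (1-based positions)."""
    mm = sim.parents.marker_map
    poly = sim.parents.polymorphic
    samples = [parent_a, parent_b] + [s for om in sim.tetrads for s in om.spore_ids]
    code_to_gt = {A_ORIGIN: "0/0", B_ORIGIN: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, L in sim.config.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        records = []
        for chrom in sim.config.chrom_lengths:
            if chrom in mm.chroms:
                sl = mm.chrom_slice(chrom)
                pos = mm.positions(chrom)
                aa, ab = mm.alleles(chrom)
                for k in range(len(pos)):
                    gcol = sl.start + k
                    gts = ["0/0", "1/1"] + [
                        code_to_gt[int(om.codes[i, gcol])]
                        for om in sim.tetrads
                        for i in range(4)
                    ]
                    records.append((chrom, int(pos[k]), aa[k], ab[k], gts))
            # parental het sites: parent A heterozygous, everything else ref
            seq = sim.parents.sequences_a[chrom]
            for p in poly.get(chrom, ()):  # positions absent from markers
                ref = chr(seq[p])
                alt = "A" if ref != "A" else "G"
                gts = ["0/1", "0/0"] + ["0/0"] * (len(samples) - 2)
                records.append((chrom, int(p), ref, alt, gts))
        records.sort(key=lambda r: (list(sim.config.chrom_lengths).index(r[0]), r[1]))
        for chrom, p, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{p + 1}\t.\t{ref}\t{alt}\t100\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_sample_sheet(sim: CrossSimulation, path: str | Path) -> None:
    rows = [
        {"tetrad_id": om.tetrad_id, "spore_id": s}
        for om in sim.tetrads
        for s in om.spore_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Truth events as BED-like TSV (0-based half-open tracts; CO pos as point)."""
    truth.to_csv(path, sep="\t", index=False)
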