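"""Parental-origin ("seg") encoding of tetrad genotypes, and tabular I/O.

The analysis traces each spore's chromosomes back to one of the two parents of
the cross.  The informative sites are *fixed differences*: positions where the
two parental strains are homozygous for different alleles.  Every spore allele
at such a marker is coded ``A`` (0) or ``B`` (1) by parent of origin, or
missing (-1).  The resulting 4 x M matrix per tetrad is the input for event
calling.

Coordinate conventions: VCF positions are 1-based on disk and converted to
0-based internally; BED intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# origin codes
A_ORIGIN = 0
B_ORIGIN = 1
MISSING = -1

ORIGIN_TO_CHAR = {A_ORIGIN: "A", B_ORIGIN: "B", MISSING: "."}
CHAR_TO_ORIGIN = {v: k for k, v in ORIGIN_TO_CHAR.items()}

# per-sample genotype codes used in the genotype table
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1


class MarkerMap:
    """Ordered fixed-difference markers: the coordinate scaffold of the analysis.

    Wraps a DataFrame with columns ``chrom``, ``pos`` (0-based), ``allele_a``,
    ``allele_b``.  Positions are strictly increasing within each chromosome and
    the two parental alleles differ at every marker.  Chromosome order is the
    order of first appearance and fixes the global column order of every
    origin matrix.
    """

    REQUIRED = ("chrom", "pos", "allele_a", "allele_b")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"MarkerMap frame missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        chrom_order = list(dict.fromkeys(df["chrom"]))
        df["chrom"] = pd.Categorical(df["chrom"], categories=chrom_order, ordered=True)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
        if (df["allele_a"] == df["allele_b"]).any():
            raise ValueError("parental alleles must differ at every marker")
        self.df = df
        self._chroms = chrom_order
        # global slice per chromosome
        self._slices: dict[str, slice] = {}
        start = 0
        for chrom in chrom_order:
            n = int((df["chrom"] == chrom).sum())
            self._slices[chrom] = slice(start, start + n)
            start += n

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def positions(self, chrom: str) -> np.ndarray:
        return self.df["pos"].to_numpy()[self._slices[chrom]]

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of this chromosome's markers in the global column order."""
        return self._slices[chrom]

    def alleles(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sl = self._slices[chrom]
        return (
            self.df["allele_a"].to_numpy()[sl],
            self.df["allele_b"].to_numpy()[sl],
        )

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        """New MarkerMap from a boolean mask or integer index over global order."""
        return MarkerMap(self.df.iloc[np.asarray(keep)].reset_index(drop=True))

    def density_per_kb(self, chrom: str, start: int, end: int) -> float:
        pos = self.positions(chrom)
        n = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
        return n / ((end - start) / 1000.0)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, MarkerMap) and self.df.equals(other.df)


@dataclass
class TetradOriginMatrix:
    """4 x M parent-of-origin codes for one tetrad, aligned to a MarkerMap."""

    tetrad_id: str
    spore_ids: tuple[str, str, str, str]
    codes: np.ndarray  # int8, shape (4, M); values in {0, 1, -1}

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != 4:
            raise ValueError("origin matrix must have exactly 4 rows")
        if len(self.spore_ids) != 4:
            raise ValueError("a tetrad has exactly 4 spores")
        bad = ~np.isin(self.codes, (A_ORIGIN, B_ORIGIN, MISSING))
        if bad.any():
            raise ValueError("origin codes must be in {0, 1, -1}")

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def swapped_parents(self) -> "TetradOriginMatrix":
        """Relabel parents A<->B: flips every non-missing code."""
        codes = self.codes.copy()
        nonmiss = codes != MISSING
        codes[nonmiss] = 1 - codes[nonmiss]
        return TetradOriginMatrix(self.tetrad_id, self.spore_ids, codes)


class IntrogressionSet:
    """Non-overlapping genomic intervals (0-based half-open), e.g. introgressions
    or excluded regions."""

    def __init__(self, df: pd.DataFrame):
        for c in ("chrom", "start", "end"):
            if c not in df.columns:
                raise ValueError(f"interval frame missing column {c!r}")
        df = df.loc[:, ["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValueError("interval start must be < end")
        if (df["start"] < 0).any():
            raise ValueError("interval start must be >= 0")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self, chrom: str | None = None) -> list[tuple[str, int, int]]:
        df = self.df if chrom is None else self.df[self.df["chrom"] == chrom]
        return list(df.itertuples(index=False, name=None))

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside an interval of `chrom`."""
        pos = np.asarray(pos)
        mask = np.zeros(pos.shape, dtype=bool)
        for _, s, e in self.intervals(chrom):
            mask |= (pos >= s) & (pos < e)
        return mask

    def overlaps_window(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and e > start for _, s, e in self.intervals(chrom))

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntrogressionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
        )
        return cls(df)

    def to_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF reading and marker selection
# ---------------------------------------------------------------------------

def read_joint_vcf(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Read a joint-genotyped VCF into a genotype table.

    Keeps biallelic SNV records only; multiallelic and indel records are
    dropped and counted.  Returns ``(table, stats)`` where the table has
    columns ``chrom``, ``pos`` (0-based), ``ref``, ``alt`` plus one int8
    genotype-code column per sample (0 hom-ref, 1 het, 2 hom-alt, -1 missing).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_ids is not None:
        absent = [s for s in sample_ids if s not in samples]
        if absent:
            raise ValueError(f"sample(s) not present in VCF: {absent}")
        keep_idx = [samples.index(s) for s in sample_ids]
        out_samples = list(sample_ids)
    else:
        keep_idx = list(range(len(samples)))
        out_samples = samples

    rows = []
    gts = []
    n_excluded = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_excluded += 1
            continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        g = var.gt_types
        codes = np.full(len(keep_idx), GT_MISSING, dtype=np.int8)
        for out_i, i in enumerate(keep_idx):
            t = g[i]
            if t == 0:
                codes[out_i] = GT_HOM_REF
            elif t == 1:
                codes[out_i] = GT_HET
            elif t == 3:
                codes[out_i] = GT_HOM_ALT
        rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
        gts.append(codes)
    vcf.close()

    table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    if gts:
        gt_arr = np.vstack(gts)
    else:
        gt_arr = np.empty((0, len(out_samples)), dtype=np.int8)
    for j, s in enumerate(out_samples):
        table[s] = gt_arr[:, j]
    stats = {"n_kept": len(table), "n_excluded": n_excluded, "samples": out_samples}
    if n_excluded:
        logger.info("read_joint_vcf: dropped %d non-biallelic-SNV records", n_excluded)
    return table, stats


def select_fixed_differences(
    table: pd.DataFrame,
    parent_a: str,
    parent_b: str,
) -> MarkerMap:
    """Keep exactly the sites where both parents are homozygous for different
    alleles; these are the markers that trace parental origin."""
    for p in (parent_a, parent_b):
        if p not in table.columns:
            raise ValueError(f"parent {p!r} not in genotype table")
    ga = table[parent_a].to_numpy()
    gb = table[parent_b].to_numpy()
    hom = np.isin(ga, (GT_HOM_REF, GT_HOM_ALT)) & np.isin(gb, (GT_HOM_REF, GT_HOM_ALT))
    keep = hom & (ga != gb)
    sub = table.loc[keep]
    allele_a = np.where(sub[parent_a].to_numpy() == GT_HOM_REF, sub["ref"], sub["alt"])
    allele_b = np.where(sub[parent_b].to_numpy() == GT_HOM_REF, sub["ref"], sub["alt"])
    return MarkerMap(
        pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "pos": sub["pos"].to_numpy(),
                "allele_a": allele_a,
                "allele_b": allele_b,
            }
        )
    )


def encode_origin(
    table: pd.DataFrame,
    marker_map: MarkerMap,
    sample_sheet: pd.DataFrame,
    parent_a: str,
    parent_b: str,
) -> tuple[list[TetradOriginMatrix], dict]:
    """Encode each spore's genotype at every marker as parental origin.

    ``sample_sheet`` has columns ``tetrad_id`` and ``spore_id``; each tetrad
    must group exactly four spores.  Spore calls matching parent A's genotype
    code A-origin, matching parent B's code B-origin; heterozygous calls
    (impossible for a true haploid) and missing calls are coded missing and
    counted in the returned stats.
    """
    for c in ("tetrad_id", "spore_id"):
        if c not in sample_sheet.columns:
            raise ValueError(f"sample sheet missing column {c!r}")
    groups = sample_sheet.groupby("tetrad_id", sort=False)["spore_id"].apply(list)
    for tid, spores in groups.items():
        if len(spores) != 4:
            raise ValueError(f"tetrad {tid!r} has {len(spores)} spores, expected 4")

    # align table rows to marker order
    key = pd.MultiIndex.from_frame(table[["chrom", "pos"]])
    marker_key = pd.MultiIndex.from_frame(marker_map.df[["chrom", "pos"]])
    indexer = key.get_indexer(marker_key)
    if (indexer < 0).any():
        raise ValueError("marker positions absent from genotype table")
    aligned = table.iloc[indexer]
    ga = aligned[parent_a].to_numpy()
    gb = aligned[parent_b].to_numpy()

    n_het = 0
    n_missing = 0
    out = []
    for tid, spores in groups.items():
        codes = np.full((4, len(marker_map)), MISSING, dtype=np.int8)
        for i, spore in enumerate(spores):
            if spore not in aligned.columns:
                raise ValueError(f"spore {spore!r} not in genotype table")
            gs = aligned[spore].to_numpy()
            codes[i, gs == ga] = A_ORIGIN
            codes[i, gs == gb] = B_ORIGIN
            het = gs == GT_HET
            codes[i, het] = MISSING
            n_het += int(het.sum())
            n_missing += int((gs == GT_MISSING).sum())
        out.append(TetradOriginMatrix(str(tid), tuple(spores), codes))
    stats = {"n_het_masked": n_het, "n_missing": n_missing}
    return out, stats


def apply_exclusions(
    marker_map: MarkerMap, exclusions: IntrogressionSet
) -> tuple[MarkerMap, np.ndarray]:
    """Drop markers inside excluded intervals (e.g. poorly mapping regions).

    Returns the filtered map and the boolean keep-mask over the original
    global marker order, so origin matrices can be subset consistently.
    """
    keep = np.ones(len(marker_map), dtype=bool)
    for chrom in marker_map.chroms:
        sl = marker_map.chrom_slice(chrom)
        keep[sl] = ~exclusions.contains(chrom, marker_map.positions(chrom))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("apply_exclusions: dropped %d markers", n_dropped)
    return marker_map.subset(keep), keep


# ---------------------------------------------------------------------------
# seg-matrix and sample-sheet I/O
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tetrad_id", "spore_id"} <= set(df.columns):
        raise ValueError("sample sheet needs columns tetrad_id, spore_id")
    return df


def write_seg(om: TetradOriginMatrix, marker_map: MarkerMap, path: str | Path) -> None:
    """One seg file per tetrad: chrom, pos, and the four spores' origin codes."""
    df = marker_map.df[["chrom", "pos"]].copy()
    for i, spore in enumerate(om.spore_ids):
        df[spore] = [ORIGIN_TO_CHAR[c] for c in om.codes[i]]
    with open(path, "w") as fh:
        fh.write(f"#tetrad_id={om.tetrad_id}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_seg(path: str | Path) -> TetradOriginMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#tetrad_id="):
            raise ValueError(f"{path}: missing #tetrad_id header line")
        tetrad_id = header.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    spores = [c for c in df.columns if c not in ("chrom", "pos")]
    if len(spores) != 4:
        raise ValueError(f"{path}: expected 4 spore columns, found {len(spores)}")
    codes = np.array(
        [[CHAR_TO_ORIGIN[v] for v in df[s]] for s in spores], dtype=np.int8
    )
    return TetradOriginMatrix(tetrad_id, tuple(spores), codes)
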