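"""Allele shuffling: per-gamete parental proportions and r-bar.

For a region (a chromosome or an introgressed interval) and a gamete, ``p``
is the fraction of the region's bases inherited from parent A.  Loci between
same-origin markers are assumed to share that origin; a change of origin
between successive markers is placed at their midpoint; terminal spans take
the nearest informative marker's origin.  The intra-region shuffling
statistic is r̄ = 2p(1-p): the probability that a randomly chosen pair of
loci in the region carries alleles from different parents in this gamete.
r̄ ranges from 0 (no shuffling) to 0.5 and is symmetric in the parents.

Cross comparisons average r̄ across gametes per region and use Welch
two-sample t-tests with a Bonferroni-adjusted significance threshold
(family-wise α divided by the number of regions in the family; chromosome
and introgressed-region families are corrected separately).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats as st

from .genotype_io import A_ORIGIN, MISSING, MarkerMap, TetradOriginMatrix

logger = logging.getLogger(__name__)


def rbar(p: float) -> float:
    """Intra-region shuffling statistic r̄ = 2p(1-p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return 2.0 * p * (1.0 - p)


def gamete_proportion(
    positions: np.ndarray,
    codes: np.ndarray,
    region_start: int,
    region_end: int,
) -> float | None:
    """Fraction of region bases inherited from parent A for one gamete.

    ``positions``/``codes`` are the gamete's marker positions and origin codes
    on the region's chromosome; markers outside the region and missing codes
    are ignored.  Returns None when no informative marker lies in the region.
    Origin transitions sit at inter-marker midpoints; the spans from the
    region edges to the first/last informative marker take that marker's
    origin, so A-span + B-span equals the region length exactly.
    """
    positions = np.asarray(positions)
    codes = np.asarray(codes)
    sel = (positions >= region_start) & (positions < region_end) & (codes != MISSING)
    pos = positions[sel]
    orig = codes[sel]
    if len(pos) == 0:
        return None
    # collapse consecutive same-origin markers; boundaries at midpoints
    change = np.flatnonzero(orig[1:] != orig[:-1])
    bounds = [region_start]
    span_orig = []
    for k in change:
        bounds.append((int(pos[k]) + int(pos[k + 1])) // 2)
        span_orig.append(orig[k])
    bounds.append(region_end)
    span_orig.append(orig[-1])
    a_total = 0
    for (lo, hi), o in zip(zip(bounds[:-1], bounds[1:]), span_orig):
        if o == A_ORIGIN:
            a_total += hi - lo
    return a_total / (region_end - region_start)


def shuffling_records(
    tetrads: list[TetradOriginMatrix],
    marker_map: MarkerMap,
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gamete, per-region p and r̄.

    ``regions`` has columns ``region_id``, ``chrom``, ``start``, ``end``.
    Gametes without an informative marker in a region are recorded with NaN
    and flagged missing.
    """
    for c in ("region_id", "chrom", "start", "end"):
        if c not in regions.columns:
            raise ValueError(f"regions frame missing column {c!r}")
    rows = []
    for om in tetrads:
        for r in regions.itertuples():
            if r.chrom in marker_map.chroms:
                sl = marker_map.chrom_slice(r.chrom)
                pos = marker_map.positions(r.chrom)
            else:
                sl, pos = slice(0, 0), np.empty(0, dtype=np.int64)
            for i, spore in enumerate(om.spore_ids):
                p = gamete_proportion(pos, om.codes[i, sl], r.start, r.end)
                rows.append(
                    dict(
                        gamete_id=spore, tetrad_id=om.tetrad_id,
                        region_id=r.region_id,
                        p=np.nan if p is None else p,
                        rbar=np.nan if p is None else rbar(p),
                        missing=p is None,
                    )
                )
    return pd.DataFrame(rows)


def chromosome_regions(chrom_lengths: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"region_id": chrom, "chrom": chrom, "start": 0, "end": L}
            for chrom, L in chrom_lengths.items()
        ]
    )


def mean_rbar(records: pd.DataFrame, region_id: str | None = None) -> tuple[float, float, int]:
    """Arithmetic mean, standard error and n of r̄ across gametes."""
    df = records if region_id is None else records[records["region_id"] == region_id]
    vals = df["rbar"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise ValueError("need at least 2 non-missing gametes")
    return float(np.mean(vals)), float(st.sem(vals)), len(vals)


def compare_rbar(
    records_1: pd.DataFrame,
    records_2: pd.DataFrame,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test of mean r̄ between two crosses per region, with a
    Bonferroni-adjusted threshold over the family of regions compared.

    Regions with degenerate variance in both crosses are skipped with a
    reason.  The adjusted α is also reported rounded to 3 significant
    figures, the resolution at which such thresholds are conventionally
    quoted.
    """
    region_ids = [r for r in records_1["region_id"].unique()]
    m = len(region_ids)
    if m == 0:
        raise ValueError("no regions to compare")
    adj = family_alpha / m
    adj_3sf = float(f"{adj:.3g}")
    rows = []
    for rid in region_ids:
        a = records_1.loc[records_1["region_id"] == rid, "rbar"].to_numpy(dtype=float)
        b = records_2.loc[records_2["region_id"] == rid, "rbar"].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        row = dict(
            region_id=rid,
            mean_1=float(np.mean(a)) if len(a) else np.nan,
            se_1=float(st.sem(a)) if len(a) > 1 else np.nan,
            mean_2=float(np.mean(b)) if len(b) else np.nan,
            se_2=float(st.sem(b)) if len(b) > 1 else np.nan,
            n_1=len(a), n_2=len(b),
            t=np.nan, p=np.nan,
            adjusted_alpha=adj, adjusted_alpha_3sf=adj_3sf,
            significant=False, skipped="",
        )
        if len(a) < 2 or len(b) < 2:
            row["skipped"] = "fewer than 2 gametes in a cross"
        elif np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                row["t"], row["p"] = 0.0, 1.0
            else:
                row["skipped"] = "degenerate variance in both groups"
        else:
            t, p = st.ttest_ind(a, b, equal_var=False)
            row["t"], row["p"] = float(t), float(p)
            row["significant"] = bool(p < adj)
        rows.append(row)
    return pd.DataFrame(rows)
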