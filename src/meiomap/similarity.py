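"""Diploid sequence similarity and its relation to conversion events.

Each genomic position between the two parental strains is scored 1 (invariant
between strains), 0.5 (polymorphic in either or both strains), or 0 (fixed
difference); the window mean is the probability that one base sampled from
each strain matches.  Similarity is computed in 101 bp sliding windows with a
50 bp step, alongside an NCO-depth track (number of conversion tracts
intersecting each window) and CO counts, then related by Spearman correlation
and loess regression per introgressed region.  Flank comparisons contrast
mean similarity in the 100 bp up/downstream of CO breakpoints vs NCO tracts
with Welch two-sample t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .events import EventList
from .genotype_io import GT_HOM_ALT, GT_HOM_REF, IntrogressionSet

logger = logging.getLogger(__name__)

WINDOW = 101
STEP = 50
FLANK = 100
REPORT_CUTOFF = 0.001  # significance cutoff used in per-region reports

SCORE_INVARIANT = 1.0
SCORE_POLYMORPHIC = 0.5
SCORE_FIXED = 0.0


@dataclass
class SiteClasses:
    """Per-chromosome site classification between the two parent strains."""

    chrom_lengths: dict[str, int]
    fixed: dict[str, np.ndarray]  # positions of fixed differences
    polymorphic: dict[str, np.ndarray]

    def scores(self, chrom: str, start: int = 0, end: int | None = None) -> np.ndarray:
        """Per-base similarity scores over [start, end)."""
        if end is None:
            end = self.chrom_lengths[chrom]
        s = np.full(end - start, SCORE_INVARIANT)
        for pos_arr, val in (
            (self.polymorphic.get(chrom), SCORE_POLYMORPHIC),
            (self.fixed.get(chrom), SCORE_FIXED),
        ):
            if pos_arr is not None and len(pos_arr):
                sel = pos_arr[(pos_arr >= start) & (pos_arr < end)]
                s[sel - start] = val
        return s


def classify_sites(table: pd.DataFrame, parent_a: str, parent_b: str,
                   chrom_lengths: dict[str, int]) -> SiteClasses:
    """Site classes from a joint genotype table: sites absent from the table
    are invariant; both parents homozygous for different alleles is a fixed
    difference; anything else recorded (a heterozygous or missing parent, or
    both homozygous for the same allele is invariant) is polymorphic."""
    fixed: dict[str, np.ndarray] = {}
    poly: dict[str, np.ndarray] = {}
    ga = table[parent_a].to_numpy()
    gb = table[parent_b].to_numpy()
    hom = np.isin(ga, (GT_HOM_REF, GT_HOM_ALT)) & np.isin(gb, (GT_HOM_REF, GT_HOM_ALT))
    is_fixed = hom & (ga != gb)
    is_invariant = hom & (ga == gb)
    is_poly = ~is_fixed & ~is_invariant
    for chrom in table["chrom"].unique():
        m = (table["chrom"] == chrom).to_numpy()
        fixed[chrom] = table.loc[m & is_fixed, "pos"].to_numpy()
        poly[chrom] = table.loc[m & is_poly, "pos"].to_numpy()
    return SiteClasses(chrom_lengths, fixed, poly)


def sliding_windows(start: int, end: int, width: int = WINDOW, step: int = STEP) -> np.ndarray:
    """Window start positions: fixed width/step, last window fully inside."""
    if end - start < width:
        return np.empty(0, dtype=np.int64)
    return np.arange(start, end - width + 1, step, dtype=np.int64)


def diploid_similarity(
    scores: np.ndarray,
    region_start: int = 0,
    width: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Mean per-site similarity in sliding windows over a score vector.

    ``scores`` covers the region starting at ``region_start``; every site must
    be classified (non-NaN)."""
    if np.isnan(scores).any():
        raise ValueError("unclassified (NaN) site in scores")
    starts = sliding_windows(region_start, region_start + len(scores), width, step)
    c = np.concatenate([[0.0], np.cumsum(scores)])
    rel = starts - region_start
    vals = (c[rel + width] - c[rel]) / width
    return pd.DataFrame({"start": starts, "end": starts + width, "similarity": vals})


def nco_depth(events: EventList, windows: pd.DataFrame, chrom: str) -> np.ndarray:
    """Number of NCO tracts (minimal extent) intersecting each half-open window."""
    tracts = [
        (e.tract_start, e.tract_end)
        for e in events
        if e.kind == "NCO" and e.chrom == chrom
    ]
    starts = np.sort([t[0] for t in tracts])
    ends = np.sort([t[1] for t in tracts])
    out = np.empty(len(windows), dtype=np.int64)
    for k, (ws, we) in enumerate(zip(windows["start"], windows["end"])):
        out[k] = np.searchsorted(starts, we, side="left") - np.searchsorted(ends, ws, side="right")
    return out


def co_count_in_windows(events: EventList, windows: pd.DataFrame, chrom: str) -> np.ndarray:
    pos = np.sort([e.pos for e in events if e.kind == "CO" and e.chrom == chrom])
    out = np.empty(len(windows), dtype=np.int64)
    for k, (ws, we) in enumerate(zip(windows["start"], windows["end"])):
        out[k] = np.searchsorted(pos, we) - np.searchsorted(pos, ws)
    return out


def build_similarity_track(
    site_classes: SiteClasses,
    events: EventList,
    region: tuple[str, int, int],
    width: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """SimilarityTrack for one region: similarity, NCO depth, CO count."""
    chrom, start, end = region
    scores = site_classes.scores(chrom, start, end)
    track = diploid_similarity(scores, start, width, step)
    track.insert(0, "chrom", chrom)
    track["nco_depth"] = nco_depth(events, track, chrom)
    track["co_count"] = co_count_in_windows(events, track, chrom)
    return track


# ---------------------------------------------------------------------------
# loess (local polynomial regression with tricube weights and an SE band)
# ---------------------------------------------------------------------------

def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    x_out: np.ndarray | None = None,
) -> pd.DataFrame:
    """Local polynomial regression (tricube kernel) with a pointwise SE band.

    At each output point the nearest ``ceil(span * n)`` observations are fit
    with a weighted polynomial of the given degree; the standard error uses
    the equivalent-kernel row norm and a residual variance estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(x)
    if n < degree + 2:
        raise ValueError("too few points for loess")
    if x_out is None:
        x_out = np.sort(x)
    q = max(int(np.ceil(span * n)), degree + 1)

    fitted = np.empty(len(x_out))
    l2 = np.empty(len(x_out))  # squared norm of the equivalent kernel
    # residual variance from a fit evaluated at the data points
    resid_fit = np.empty(n)
    order = np.argsort(x)

    def _local(x0):
        d = np.abs(x - x0)
        h = np.partition(d, q - 1)[q - 1]
        h = max(h, 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sel = w > 0
        X = np.vander(x[sel] - x0, degree + 1, increasing=True)
        W = w[sel]
        XtW = X.T * W
        beta, *_ = np.linalg.lstsq(XtW @ X, XtW @ y[sel], rcond=None)
        # equivalent kernel row for the intercept coordinate
        A = np.linalg.pinv(XtW @ X) @ XtW
        return float(beta[0]), float(np.sum(A[0] ** 2))

    for i, x0 in enumerate(x):
        resid_fit[i], _ = _local(x0)
    dof = max(n - (degree + 1), 1)
    sigma2 = float(np.sum((y - resid_fit) ** 2) / dof)

    for i, x0 in enumerate(x_out):
        fitted[i], l2[i] = _local(x0)
    se = np.sqrt(sigma2 * l2)
    return pd.DataFrame({"x": x_out, "fitted": fitted, "se": se})


def similarity_nco_association(
    track: pd.DataFrame,
    span: float = 0.75,
    degree: int = 2,
) -> dict:
    """Spearman correlation (tie-corrected p) and loess fit of NCO depth on
    similarity across a region's windows.  Constant similarity or depth makes
    the correlation undefined and is reported as such."""
    if len(track) < 10:
        raise ValueError("need at least 10 windows in the region")
    x = track["similarity"].to_numpy(dtype=float)
    y = track["nco_depth"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": float("nan"), "p": float("nan"), "defined": False, "loess": None,
                "significant": False}
    rho, p = st.spearmanr(x, y)
    loess = loess_fit(x, y, span=span, degree=degree)
    return {
        "rho": float(rho), "p": float(p), "defined": True, "loess": loess,
        "significant": bool(p < REPORT_CUTOFF), "n": len(track),
    }


# ---------------------------------------------------------------------------
# CO- vs NCO-flank similarity
# ---------------------------------------------------------------------------

def _flank_mean(scores: np.ndarray, region_start: int, lo: int, hi: int) -> float:
    lo = max(lo, region_start)
    hi = min(hi, region_start + len(scores))
    if hi <= lo:
        return float("nan")
    return float(np.mean(scores[lo - region_start : hi - region_start]))


def event_flank_similarity(
    events: EventList,
    site_classes: SiteClasses,
    region: tuple[str, int, int],
    flank: int = FLANK,
) -> pd.DataFrame:
    """Per-event mean similarity over the flanks.

    CO flanks are centred on the breakpoint midpoint; NCO flanks abut the
    maximal tract interval.  Flanks are clipped at the region bounds.
    """
    chrom, start, end = region
    scores = site_classes.scores(chrom, start, end)
    rows = []
    for e in events:
        if e.chrom != chrom or not (start <= e.pos < end):
            continue
        if e.kind == "CO":
            lo_up, hi_up = e.pos - flank, e.pos
            lo_dn, hi_dn = e.pos, e.pos + flank
        else:
            lo_up, hi_up = e.max_start - flank, e.max_start
            lo_dn, hi_dn = e.max_end, e.max_end + flank
        vals = [
            _flank_mean(scores, start, lo_up, hi_up),
            _flank_mean(scores, start, lo_dn, hi_dn),
        ]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            rows.append(dict(event_id=e.event_id, kind=e.kind, similarity=float(np.mean(vals))))
    return pd.DataFrame(rows, columns=["event_id", "kind", "similarity"])


def flank_similarity_test(
    events: EventList,
    site_classes: SiteClasses,
    regions: IntrogressionSet,
    flank: int = FLANK,
) -> pd.DataFrame:
    """Welch t-test of CO-flank vs NCO-flank similarity per region.

    Regions with fewer than two events in either class, or with degenerate
    (zero-variance, equal-mean) values, are skipped with a reason.
    """
    rows = []
    for chrom, start, end in regions.intervals():
        per_event = event_flank_similarity(events, site_classes, (chrom, start, end), flank)
        co = per_event.loc[per_event["kind"] == "CO", "similarity"].to_numpy()
        nco = per_event.loc[per_event["kind"] == "NCO", "similarity"].to_numpy()
        row = dict(
            chrom=chrom, start=start, end=end,
            n_co=len(co), n_nco=len(nco),
            co_mean=float(np.mean(co)) if len(co) else float("nan"),
            co_se=float(st.sem(co)) if len(co) > 1 else float("nan"),
            nco_mean=float(np.mean(nco)) if len(nco) else float("nan"),
            nco_se=float(st.sem(nco)) if len(nco) > 1 else float("nan"),
            t=float("nan"), p=float("nan"), skipped="",
        )
        if len(co) < 2 or len(nco) < 2:
            row["skipped"] = "insufficient events"
        elif np.var(co) == 0 and np.var(nco) == 0:
            row["skipped"] = "degenerate (zero variance in both classes)"
        else:
            t, p = st.ttest_ind(co, nco, equal_var=False)
            row["t"], row["p"] = float(t), float(p)
        rows.append(row)
    return pd.DataFrame(rows)
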