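"""Windowed recombination landscapes and their statistics.

The genome is split into non-overlapping 20 kb windows (terminal remainder
truncated).  Per window the table carries raw and smoothed CO counts, raw and
detection-corrected NCO counts, marker count, GC fraction, and an
introgression flag.  Two corrections address marker-density artefacts:

* **CO smoothing** — crossovers falling in long marker deserts are localised
  to the middle of the empty stretch, so CO counts within each maximal run of
  consecutive marker-free windows are redistributed evenly across the run
  (chromosome totals conserved exactly).
* **NCO detection-probability correction** — for each window, a tract of the
  reference conversion length (550 bp) is placed uniformly at random 10,000
  times; the fraction of placements covering at least ``min_markers`` markers
  is the detection probability, and the observed NCO count is divided by it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .events import EventList
from .genotype_io import IntrogressionSet, MarkerMap, TetradOriginMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20_000
DEFAULT_TRACT = 550
DEFAULT_REPS = 10_000


def make_windows(chrom_lengths: dict[str, int], width: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Consecutive half-open windows per chromosome; last window truncated."""
    if width <= 0:
        raise ValueError("window width must be > 0")
    rows = []
    for chrom, L in chrom_lengths.items():
        if L <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        starts = np.arange(0, L, width)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + width, L))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _window_index(windows: pd.DataFrame, chrom: str, pos: int, width: int) -> int:
    sub = windows.index[windows["chrom"] == chrom]
    if len(sub) == 0:
        raise ValueError(f"event on chromosome {chrom!r} outside any window")
    idx = sub[0] + pos // width
    if idx > sub[-1] or pos < 0 or pos >= int(windows.loc[sub[-1], "end"]):
        raise ValueError(f"event at {chrom}:{pos} outside any window")
    return int(idx)


def count_in_windows(events: EventList, windows: pd.DataFrame) -> pd.DataFrame:
    """Raw per-window CO and NCO counts.  COs are assigned by breakpoint point
    estimate, NCOs by minimal-tract midpoint (the event's ``pos``)."""
    windows = windows.copy()
    width = int((windows["end"] - windows["start"]).max())
    co = np.zeros(len(windows), dtype=np.int64)
    nco = np.zeros(len(windows), dtype=np.int64)
    for e in events:
        idx = _window_index(windows, e.chrom, e.pos, width)
        if e.kind == "CO":
            co[idx] += 1
        else:
            nco[idx] += 1
    windows["co_raw"] = co
    windows["nco_raw"] = nco
    return windows


def count_markers(windows: pd.DataFrame, marker_map: MarkerMap) -> pd.DataFrame:
    windows = windows.copy()
    counts = np.zeros(len(windows), dtype=np.int64)
    for i, row in windows.iterrows():
        if row.chrom in marker_map.chroms:
            pos = marker_map.positions(row.chrom)
            counts[i] = np.searchsorted(pos, row.end) - np.searchsorted(pos, row.start)
    windows["marker_count"] = counts
    return windows


_SMOOTH_SCALE = 1 << 20  # dyadic quantum for exactly conserved redistribution


def smooth_co(windows: pd.DataFrame) -> pd.DataFrame:
    """Redistribute CO counts evenly across each maximal run of consecutive
    marker-free windows; all other windows are unchanged.

    Per-chromosome totals are conserved exactly in floating point: the even
    split is quantised to a dyadic grid (units of 2**-20, i.e. deviations
    below 1e-6 from the ideal split), so every window value and every partial
    sum is exactly representable and the totals match bit-for-bit in any
    summation order.
    """
    for col in ("co_raw", "marker_count"):
        if col not in windows.columns:
            raise ValueError(f"smooth_co needs column {col!r}")
    windows = windows.copy()
    smoothed = windows["co_raw"].to_numpy(dtype=float).copy()
    for chrom, grp in windows.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        free = grp["marker_count"].to_numpy() == 0
        k = 0
        while k < len(idx):
            if free[k]:
                j = k
                while j + 1 < len(idx) and free[j + 1]:
                    j += 1
                run = idx[k : j + 1]
                n = len(run)
                total_scaled = int(round(float(smoothed[run].sum()) * _SMOOTH_SCALE))
                q, r = divmod(total_scaled, n)
                vals = np.full(n, q, dtype=np.int64)
                vals[:r] += 1
                smoothed[run] = vals / _SMOOTH_SCALE
                k = j + 1
            else:
                k += 1
    windows["co_smoothed"] = smoothed
    return windows


def nco_detection_probability(
    window: tuple[int, int],
    marker_positions: np.ndarray,
    tract_length: int = DEFAULT_TRACT,
    n_reps: int = DEFAULT_REPS,
    min_markers: int = 3,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Monte-Carlo probability that a conversion tract of ``tract_length``
    placed uniformly inside the window covers >= ``min_markers`` markers.

    Placements keep the tract entirely inside the window; a window shorter
    than the tract has no feasible placement and the probability is NaN.
    """
    if tract_length < 1 or n_reps < 1:
        raise ValueError("tract_length and n_reps must be >= 1")
    start, end = window
    last_start = end - tract_length
    if last_start < start:
        return float("nan")
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = np.asarray(marker_positions)
    starts = rng.integers(start, last_start + 1, size=n_reps)
    n_in = np.searchsorted(pos, starts + tract_length) - np.searchsorted(pos, starts)
    return float(np.mean(n_in >= min_markers))


def detection_probabilities(
    windows: pd.DataFrame,
    marker_map: MarkerMap,
    tract_length: int = DEFAULT_TRACT,
    n_reps: int = DEFAULT_REPS,
    min_markers: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window detection probabilities against the full marker map."""
    windows = windows.copy()
    rng = np.random.default_rng(seed)
    probs = np.empty(len(windows))
    for i, row in windows.iterrows():
        pos = (
            marker_map.positions(row.chrom)
            if row.chrom in marker_map.chroms
            else np.empty(0, dtype=np.int64)
        )
        probs[i] = nco_detection_probability(
            (row.start, row.end), pos, tract_length, n_reps, min_markers, rng=rng
        )
    windows["detection_prob"] = probs
    return windows


def correct_nco(windows: pd.DataFrame) -> pd.DataFrame:
    """Corrected NCO count = raw / detection probability.  Windows with zero
    (or undefined) probability get NaN and are excluded downstream; the count
    of such windows is logged."""
    for col in ("nco_raw", "detection_prob"):
        if col not in windows.columns:
            raise ValueError(f"correct_nco needs column {col!r}")
    windows = windows.copy()
    p = windows["detection_prob"].to_numpy(dtype=float)
    raw = windows["nco_raw"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(p > 0, raw / p, np.nan)
    n_undef = int(np.sum(~(p > 0)))
    if n_undef:
        logger.info("correct_nco: %d windows with zero/undefined detection probability", n_undef)
    windows["nco_corrected"] = corrected
    return windows


def gc_content(sequence: str | np.ndarray, windows: pd.DataFrame, chrom: str) -> np.ndarray:
    """GC fraction per window over non-N bases; all-N windows are NaN."""
    if isinstance(sequence, np.ndarray):
        seq = sequence
    else:
        seq = np.frombuffer(str(sequence).upper().encode(), dtype=np.uint8)
    sub = windows[windows["chrom"] == chrom]
    if len(sub) and int(sub["end"].max()) > len(seq):
        raise ValueError(f"sequence for {chrom} shorter than windows")
    is_gc = (seq == ord("G")) | (seq == ord("C"))
    is_base = seq != ord("N")
    cgc = np.concatenate([[0], np.cumsum(is_gc)])
    cb = np.concatenate([[0], np.cumsum(is_base)])
    out = np.empty(len(sub))
    for k, (s, e) in enumerate(zip(sub["start"], sub["end"])):
        nb = cb[e] - cb[s]
        out[k] = (cgc[e] - cgc[s]) / nb if nb else np.nan
    return out


def add_gc(windows: pd.DataFrame, sequences: dict[str, np.ndarray | str]) -> pd.DataFrame:
    windows = windows.copy()
    gc = np.full(len(windows), np.nan)
    for chrom in windows["chrom"].unique():
        mask = windows["chrom"] == chrom
        gc[mask.to_numpy()] = gc_content(sequences[chrom], windows, chrom)
    windows["gc"] = gc
    return windows


def flag_introgression(windows: pd.DataFrame, introgressions: IntrogressionSet) -> pd.DataFrame:
    windows = windows.copy()
    windows["introgression"] = [
        int(introgressions.overlaps_window(r.chrom, r.start, r.end))
        for r in windows.itertuples()
    ]
    return windows


def assemble_window_table(
    events: EventList,
    marker_map: MarkerMap,
    chrom_lengths: dict[str, int],
    sequences: dict[str, np.ndarray | str] | None = None,
    introgressions: IntrogressionSet | None = None,
    cross: str = "",
    width: int = DEFAULT_WINDOW,
    tract_length: int = DEFAULT_TRACT,
    n_reps: int = DEFAULT_REPS,
    min_markers: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Full WindowTable: counts, smoothing, detection correction, GC, flags."""
    win = make_windows(chrom_lengths, width)
    win = count_in_windows(events, win)
    win = count_markers(win, marker_map)
    win = smooth_co(win)
    win = detection_probabilities(win, marker_map, tract_length, n_reps, min_markers, seed)
    win = correct_nco(win)
    if sequences is not None:
        win = add_gc(win, sequences)
    if introgressions is not None:
        win = flag_introgression(win, introgressions)
    win["cross"] = cross
    return win


# ---------------------------------------------------------------------------
# downsampling experiment
# ---------------------------------------------------------------------------

def downsample_experiment(
    tetrads: list[TetradOriginMatrix],
    marker_map: MarkerMap,
    region: tuple[str, int, int],
    target_densities: list[float],
    n_reps: int = 20,
    seed: int = 0,
    min_nco_markers: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-call events after subsampling region markers to target densities.

    For each target density (markers/kb) the region's markers are subsampled
    uniformly without replacement, events are re-called on the reduced map,
    and per-rep CO count, NCO count and mean NCO tract length are recorded.
    Returns the per-rep table and per-response linear regressions (response on
    density) over all reps.
    """
    from .events import call_all  # local import avoids cycle at module load

    chrom, start, end = region
    rng = np.random.default_rng(seed)
    sl = marker_map.chrom_slice(chrom)
    pos = marker_map.positions(chrom)
    in_region = (pos >= start) & (pos < end)
    region_global = np.flatnonzero(in_region) + sl.start
    n_avail = len(region_global)
    len_kb = (end - start) / 1000.0

    rows = []
    for dens in target_densities:
        n_target = int(round(dens * len_kb))
        if n_target > n_avail:
            raise ValueError(
                f"target density {dens}/kb needs {n_target} markers; only {n_avail} available"
            )
        for rep in range(n_reps):
            keep_region = np.sort(rng.choice(region_global, size=n_target, replace=False))
            sub_mm = marker_map.subset(keep_region)
            sub_tetrads = [
                TetradOriginMatrix(om.tetrad_id, om.spore_ids, om.codes[:, keep_region])
                for om in tetrads
            ]
            el = call_all(sub_tetrads, sub_mm, min_nco_markers=min_nco_markers)
            df = el.to_frame()
            df = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
            nco = df[df["kind"] == "NCO"]
            rows.append(
                dict(
                    density=dens, rep=rep,
                    co_count=int((df["kind"] == "CO").sum()),
                    nco_count=len(nco),
                    mean_tract_length=float(nco["length_mid"].mean()) if len(nco) else np.nan,
                )
            )
    table = pd.DataFrame(rows)

    reg_rows = []
    for response in ("co_count", "nco_count", "mean_tract_length"):
        sub = table.dropna(subset=[response])
        if sub["density"].nunique() < 2:
            continue
        X = sm.add_constant(sub["density"].to_numpy())
        fit = sm.OLS(sub[response].to_numpy(), X).fit()
        reg_rows.append(
            dict(
                response=response, slope=fit.params[1], slope_se=fit.bse[1],
                p_value=fit.pvalues[1], r_squared=fit.rsquared,
            )
        )
    return table, pd.DataFrame(reg_rows)


# ---------------------------------------------------------------------------
# landscape statistics
# ---------------------------------------------------------------------------

def landscape_stats(win_a: pd.DataFrame, win_b: pd.DataFrame) -> dict:
    """Between-cross Spearman correlations and introgressed-vs-background
    Wilcoxon rank-sum tests (tie-corrected normal approximation).

    The two tables must share window coordinates.  Returns a dict with
    ``spearman`` (per response) and ``wilcoxon`` (per cross and between
    crosses, for CO, corrected NCO, and CO+NCO totals).
    """
    if not (win_a[["chrom", "start", "end"]].reset_index(drop=True)
            .equals(win_b[["chrom", "start", "end"]].reset_index(drop=True))):
        raise ValueError("window tables must share coordinates")

    out: dict = {"spearman": {}, "wilcoxon": {}}
    for response in ("co_smoothed", "nco_corrected"):
        a = win_a[response].to_numpy(dtype=float)
        b = win_b[response].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            raise ValueError("fewer than 2 comparable windows")
        if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
            rho, p = float("nan"), float("nan")  # constant input: undefined
        else:
            rho, p = st.spearmanr(a[ok], b[ok])
        out["spearman"][response] = {"rho": float(rho), "p": float(p), "n": int(ok.sum())}

    def _wilcox(x, y):
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValueError("fewer than 2 windows per group")
        stat, p = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return {"u": float(stat), "p": float(p), "n1": len(x), "n2": len(y)}

    for label, win in (("a", win_a), ("b", win_b)):
        if "introgression" not in win.columns:
            continue
        flag = win["introgression"].to_numpy() == 1
        for response in ("co_smoothed", "nco_corrected"):
            vals = win[response].to_numpy(dtype=float)
            out["wilcoxon"][f"{label}:{response}:intro_vs_bg"] = _wilcox(vals[flag], vals[~flag])
        total = win["co_smoothed"].to_numpy(dtype=float) + win["nco_corrected"].to_numpy(dtype=float)
        out["wilcoxon"][f"{label}:total:intro_vs_bg"] = _wilcox(total[flag], total[~flag])
    if "introgression" in win_a.columns and "introgression" in win_b.columns:
        flag = win_a["introgression"].to_numpy() == 1
        for response in ("co_smoothed", "nco_corrected"):
            out["wilcoxon"][f"between:{response}:introgressed_windows"] = _wilcox(
                win_b.loc[flag, response].to_numpy(dtype=float),
                win_a.loc[flag, response].to_numpy(dtype=float),
            )
    return out


@dataclass
class GlmResult:
    """Gaussian identity-link fit of window counts on design terms."""

    table: pd.DataFrame  # term, estimate, se, t, p
    model: object
    dropped_terms: list[str]

    def estimate(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def conf_int(self, term: str, alpha: float = 0.05) -> tuple[float, float]:
        ci = self.model.conf_int(alpha)
        row = ci.loc[term]
        return float(row[0]), float(row[1])


def fit_window_glm(
    windows: pd.DataFrame,
    response: str,
    terms: list[str],
    drop_nonsig_interaction: bool = True,
    alpha: float = 0.05,
) -> GlmResult:
    """Gaussian GLM (identity link, equivalent to OLS) of a per-window count
    on design terms, with an interaction-dropping pass.

    ``terms`` use patsy formula syntax (e.g. ``["cross", "introgression",
    "gc", "introgression:cross"]``).  When ``drop_nonsig_interaction`` is set,
    interaction terms whose coefficients are all non-significant at ``alpha``
    are removed and the model refit.
    """
    import statsmodels.formula.api as smf
    from patsy import dmatrices

    data = windows.dropna(
        subset=[response] + [t for t in terms if t in windows.columns]
    )
    dropped: list[str] = []

    def _fit(term_list):
        formula = f"{response} ~ " + " + ".join(term_list)
        y, X = dmatrices(formula, data, return_type="dataframe")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # name the collinear columns
            _, r = np.linalg.qr(X.to_numpy())
            bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
            raise ValueError(f"rank-deficient design; collinear terms: {bad}")
        return smf.glm(formula, data, family=sm.families.Gaussian()).fit()

    fit = _fit(terms)
    if drop_nonsig_interaction:
        inter = [t for t in terms if ":" in t]
        for t in inter:
            cols = [c for c in fit.pvalues.index if ":" in c]
            if cols and all(fit.pvalues[c] >= alpha for c in cols):
                terms = [u for u in terms if u != t]
                dropped.append(t)
                fit = _fit(terms)
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    if not np.isfinite(table["estimate"]).all():
        raise ValueError("non-finite GLM estimates")
    return GlmResult(table, fit, dropped)


def cm_per_kb(mean_co_per_meiosis: float, genome_length_bp: float) -> float:
    """Genome-average map density summarised as 100 x (mean COs per meiosis)
    per genome kb."""
    return 100.0 * mean_co_per_meiosis / (genome_length_bp / 1000.0)
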