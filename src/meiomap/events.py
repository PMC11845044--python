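"""Crossover / non-crossover detection from parental-origin matrices.

At every informative marker the four spores of a tetrad segregate 2:2 in the
absence of recombination intermediates.  A persistent change of the 2:2 phase
in which two spores exchange origin is a crossover (CO); a maximal 3:1 run on
a single deviating spore that reverts to the surrounding phase is a
non-crossover gene-conversion tract (NCO).  A phase change accompanied by an
adjacent 3:1 run is decomposed into one CO plus one NCO (CO-associated
conversion).  Markers with any missing spore call are skipped as
uninformative; 4:0 / 0:4 markers (impossible under 2:2 segregation without
error) are flagged and skipped.

Terminal 3:1 runs (bounded by a 2:2 phase on one side and the chromosome end
on the other) are called NCO against that phase: crossovers are reciprocal
and cannot produce a 3:1 tally, so a 3:1 run is a conversion wherever it
sits.

Breakpoints are placed at the midpoint between flanking informative markers
(integer floor); a CO's uncertainty interval spans the flanking *balanced*
(2:2) markers, which always contains the true exchange point even when a
conversion tract abuts the crossover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, MarkerMap, TetradOriginMatrix

logger = logging.getLogger(__name__)


def breakpoint_midpoint(left: int, right: int) -> int:
    """Midpoint convention for origin transitions: floor((left + right) / 2)."""
    if left >= right:
        raise ValueError(f"left marker ({left}) must be < right marker ({right})")
    return (int(left) + int(right)) // 2


@dataclass
class RecombinationEvent:
    """One CO or NCO with uncertainty interval and supporting markers.

    ``pos`` is the breakpoint point estimate (CO) or the minimal-tract
    midpoint (NCO).  ``ci_left``/``ci_right`` are the flanking informative
    marker positions bounding the event.  For NCOs, ``tract_start``/
    ``tract_end`` is the minimal tract (first to last converted marker,
    half-open), ``max_start``/``max_end`` the maximal extent to the flanking
    unconverted markers, and ``length_mid`` the midpoint-to-midpoint span used
    for tract-length statistics.
    """

    event_id: str
    tetrad_id: str
    chrom: str
    kind: str  # "CO" | "NCO"
    pos: int
    ci_left: int
    ci_right: int
    spores: tuple[str, ...]
    n_markers: int = 1
    tract_start: int = -1
    tract_end: int = -1
    max_start: int = -1
    max_end: int = -1
    length_mid: int = -1

    def __post_init__(self):
        if self.kind not in ("CO", "NCO"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.n_markers < 1:
            raise ValueError("supporting marker count must be >= 1")
        if not self.ci_left <= self.pos <= self.ci_right:
            raise ValueError("uncertainty interval must contain the point estimate")
        if self.kind == "NCO" and self.tract_end <= self.tract_start:
            raise ValueError("NCO tract length must be > 0")


class EventList:
    """Sorted collection of recombination events with count summaries."""

    def __init__(self, events: list[RecombinationEvent], diagnostics: dict | None = None):
        self.events = sorted(events, key=lambda e: (e.tetrad_id, e.chrom, e.pos))
        self.diagnostics = diagnostics or {}

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "event_id", "tetrad_id", "chrom", "kind", "pos", "ci_left", "ci_right",
            "n_markers", "tract_start", "tract_end", "max_start", "max_end",
            "length_mid", "spores",
        ]
        rows = [
            {**{c: getattr(e, c) for c in cols[:-1]}, "spores": ",".join(e.spores)}
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=cols)

    def counts(self) -> pd.DataFrame:
        """Per-tetrad, per-chromosome CO/NCO counts."""
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame(columns=["tetrad_id", "chrom", "CO", "NCO"])
        out = (
            df.groupby(["tetrad_id", "chrom", "kind"]).size().unstack(fill_value=0)
            .reindex(columns=["CO", "NCO"], fill_value=0).reset_index()
        )
        out.columns.name = None
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EventList":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tetrad_id": str})
        events = [
            RecombinationEvent(
                event_id=r.event_id, tetrad_id=r.tetrad_id, chrom=r.chrom, kind=r.kind,
                pos=int(r.pos), ci_left=int(r.ci_left), ci_right=int(r.ci_right),
                spores=tuple(str(r.spores).split(",")), n_markers=int(r.n_markers),
                tract_start=int(r.tract_start), tract_end=int(r.tract_end),
                max_start=int(r.max_start), max_end=int(r.max_end),
                length_mid=int(r.length_mid),
            )
            for r in df.itertuples()
        ]
        return cls(events)

    def write_bed(self, path: str | Path) -> None:
        """BED: 0-based half-open; name = kind:tetrad:spores; score = markers."""
        with open(path, "w") as fh:
            for e in self.events:
                if e.kind == "CO":
                    start, end = e.pos, e.pos + 1
                else:
                    start, end = e.tract_start, e.tract_end
                name = f"{e.kind}:{e.tetrad_id}:{'|'.join(e.spores)}"
                fh.write(f"{e.chrom}\t{start}\t{end}\t{name}\t{e.n_markers}\n")


def _pattern_int(col: np.ndarray) -> int:
    return int(col[0]) | int(col[1]) << 1 | int(col[2]) << 2 | int(col[3]) << 3


def _diff_spores(p: int, q: int) -> list[int]:
    d = p ^ q
    return [i for i in range(4) if d >> i & 1]


class _ChromCaller:
    """Stateful per-(tetrad, chromosome) segmentation of origin patterns."""

    def __init__(self, om: TetradOriginMatrix, chrom: str, pos: np.ndarray,
                 codes: np.ndarray, chrom_len: int):
        self.om = om
        self.chrom = chrom
        self.chrom_len = chrom_len
        informative = (codes != MISSING).all(axis=0)
        sums = codes.sum(axis=0)
        bad = informative & ((sums == 0) | (sums == 4))
        self.n_bad = int(bad.sum())
        keep = informative & ~bad
        self.pos = pos[keep]
        c = codes[:, keep]
        self.pat = np.array([_pattern_int(c[:, k]) for k in range(c.shape[1])])
        self.sums = c.sum(axis=0)
        self.events: list[RecombinationEvent] = []
        self.n_complex = 0

    # -- helpers -----------------------------------------------------------
    def _flank(self, idx_first: int, idx_last: int) -> tuple[int, int]:
        """Positions of informative markers flanking [idx_first, idx_last]."""
        left = int(self.pos[idx_first - 1]) if idx_first > 0 else -1
        right = int(self.pos[idx_last + 1]) if idx_last + 1 < len(self.pos) else -1
        return left, right

    def _emit_nco(self, run: list[int], spore: int) -> None:
        first, last = run[0], run[-1]
        p_first, p_last = int(self.pos[first]), int(self.pos[last])
        left, right = self._flank(first, last)
        ci_left = left if left >= 0 else 0
        ci_right = right if right >= 0 else self.chrom_len - 1
        max_start = left + 1 if left >= 0 else 0
        max_end = right if right >= 0 else self.chrom_len
        mid_left = breakpoint_midpoint(left, p_first) if left >= 0 else 0
        mid_right = breakpoint_midpoint(p_last, right) if right >= 0 else self.chrom_len
        tract_start, tract_end = p_first, p_last + 1
        self.events.append(
            RecombinationEvent(
                event_id="", tetrad_id=self.om.tetrad_id, chrom=self.chrom,
                kind="NCO", pos=(tract_start + tract_end) // 2,
                ci_left=ci_left, ci_right=ci_right,
                spores=(self.om.spore_ids[spore],),
                n_markers=len(run), tract_start=tract_start, tract_end=tract_end,
                max_start=max_start, max_end=max_end,
                length_mid=mid_right - mid_left,
            )
        )

    def _emit_nco_runs(self, idxs: list[int], ref_phase: int) -> None:
        """Group consecutive unbalanced markers by deviating spore; each clean
        single-spore run is one NCO."""
        run: list[int] = []
        run_spore = -1
        for k in idxs:
            dev = _diff_spores(self.pat[k], ref_phase)
            if len(dev) != 1:
                self.n_complex += 1
                if run:
                    self._emit_nco(run, run_spore)
                run, run_spore = [], -1
                continue
            s = dev[0]
            if run and (s != run_spore or k != run[-1] + 1):
                self._emit_nco(run, run_spore)
                run = []
            run.append(k)
            run_spore = s
        if run:
            self._emit_nco(run, run_spore)

    def _emit_co(self, left_idx: int, right_idx: int, bal_left: int, bal_right: int,
                 spores: tuple[int, int]) -> None:
        left_pos, right_pos = int(self.pos[left_idx]), int(self.pos[right_idx])
        self.events.append(
            RecombinationEvent(
                event_id="", tetrad_id=self.om.tetrad_id, chrom=self.chrom,
                kind="CO", pos=breakpoint_midpoint(left_pos, right_pos),
                ci_left=int(self.pos[bal_left]), ci_right=int(self.pos[bal_right]),
                spores=(self.om.spore_ids[spores[0]], self.om.spore_ids[spores[1]]),
                n_markers=1,
            )
        )

    # -- main segmentation --------------------------------------------------
    def call(self) -> None:
        balanced = np.flatnonzero(self.sums == 2)
        if len(balanced) == 0:
            if len(self.pos):
                self.n_complex += len(self.pos)
            return
        # terminal head: unbalanced markers before the first balanced marker
        head = list(range(0, balanced[0]))
        if head:
            self._emit_nco_runs(head, int(self.pat[balanced[0]]))
        tail = list(range(balanced[-1] + 1, len(self.pos)))
        if tail:
            self._emit_nco_runs(tail, int(self.pat[balanced[-1]]))

        for b0, b1 in zip(balanced[:-1], balanced[1:]):
            p0, p1 = int(self.pat[b0]), int(self.pat[b1])
            between = list(range(b0 + 1, b1))
            if p0 == p1:
                if between:
                    self._emit_nco_runs(between, p0)
                continue
            # phase change: split the in-between markers by nearest phase
            split = len(between)
            for j, k in enumerate(between):
                kl = bin(self.pat[k] ^ p0).count("1")
                kr = bin(self.pat[k] ^ p1).count("1")
                if kr < kl:
                    split = j
                    break
            left_part, right_part = between[:split], between[split:]
            if left_part:
                self._emit_nco_runs(left_part, p0)
            if right_part:
                self._emit_nco_runs(right_part, p1)
            left_idx = left_part[-1] if left_part else int(b0)
            right_idx = right_part[0] if right_part else int(b1)
            diff = _diff_spores(p0, p1)
            if len(diff) == 2:
                self._emit_co(left_idx, right_idx, int(b0), int(b1), (diff[0], diff[1]))
            else:  # four-spore jump: two simultaneous crossovers
                gained = sorted(s for s in diff if not p0 >> s & 1)
                lost = sorted(s for s in diff if p0 >> s & 1)
                for a, b in zip(gained, lost):
                    self._emit_co(left_idx, right_idx, int(b0), int(b1), (a, b))


def call_events(
    om: TetradOriginMatrix,
    marker_map: MarkerMap,
    chrom_lengths: dict[str, int] | None = None,
) -> EventList:
    """Detect CO and NCO events in one tetrad's origin matrix.

    ``chrom_lengths`` bounds terminal uncertainty intervals; when omitted the
    last marker position + 1 is used.  Diagnostics carry the counts of 4:0/0:4
    markers and complex (multi-spore-deviation) patterns encountered.
    """
    if om.n_markers != len(marker_map):
        raise ValueError(
            f"origin matrix has {om.n_markers} columns but marker map has {len(marker_map)}"
        )
    events: list[RecombinationEvent] = []
    n_bad = n_complex = 0
    for chrom in marker_map.chroms:
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.positions(chrom)
        if chrom_lengths and chrom in chrom_lengths:
            L = chrom_lengths[chrom]
        else:
            L = int(pos[-1]) + 1 if len(pos) else 0
        cc = _ChromCaller(om, chrom, pos, om.codes[:, sl], L)
        cc.call()
        events.extend(cc.events)
        n_bad += cc.n_bad
        n_complex += cc.n_complex
    for i, e in enumerate(
        sorted(events, key=lambda e: (e.chrom, e.pos, e.kind))
    ):
        e.event_id = f"{om.tetrad_id}_e{i + 1:04d}"
    if n_bad:
        logger.info("%s: %d markers with 4:0/0:4 tally treated as missing", om.tetrad_id, n_bad)
    return EventList(events, {"n_bad_markers": n_bad, "n_complex": n_complex})


def filter_nco_support(events: EventList, min_markers: int = 3) -> EventList:
    """Remove NCOs supported by fewer than ``min_markers`` converted markers;
    COs are untouched.  Mirrors the standard tetrad-analysis support filter."""
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    kept = [e for e in events if e.kind == "CO" or e.n_markers >= min_markers]
    n_removed = len(events) - len(kept)
    if n_removed:
        logger.info("filter_nco_support: removed %d NCOs with < %d markers", n_removed, min_markers)
    diag = dict(events.diagnostics)
    diag["n_nco_removed"] = n_removed
    return EventList(kept, diag)


def call_all(
    tetrads: list[TetradOriginMatrix],
    marker_map: MarkerMap,
    chrom_lengths: dict[str, int] | None = None,
    min_nco_markers: int = 3,
) -> EventList:
    """Call and support-filter events across a whole cross."""
    events: list[RecombinationEvent] = []
    diag: dict[str, int] = {"n_bad_markers": 0, "n_complex": 0, "n_nco_removed": 0}
    for om in tetrads:
        el = filter_nco_support(call_events(om, marker_map, chrom_lengths), min_nco_markers)
        events.extend(el.events)
        for k in diag:
            diag[k] += el.diagnostics.get(k, 0)
    return EventList(events, diag)
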