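"""Read-depth scans: PAR detection and copy-number-expansion candidates.

The pseudoautosomal region (PAR) recombines between X and Y, so a male's
X-mapped coverage there matches the autosomes while the rest of the X
sits at half depth.  ``detect_par`` segments a male's autosome-normalized
X track into ~1.0 and ~0.5 plateaus and reports the terminal ~1.0 run
anchored at a chromosome end.  ``cnv_ratio_scan`` compares chromosome-
normalized tracks between a target and reference sample(s) and calls
runs of windows with an elevated coverage ratio, candidates for copy-
number expansions (and hence possible meiotic-drive elements).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("ygeneflow")

__all__ = [
    "CoverageTrack",
    "normalize_coverage",
    "detect_par",
    "cnv_ratio_scan",
    "read_coverage_tsv",
    "write_bed",
]

AUTOSOMAL_MEAN = "autosomal_mean"
CHROMOSOME_MEAN = "chromosome_mean"


@dataclass
class CoverageTrack:
    """Per-window mean depth for one sample on one chromosome.

    Windows are fixed-width, 0-based half-open.  ``divisor`` records the
    normalization applied (None for raw depth).
    """

    sample: str
    sex: str
    chrom: str
    start: np.ndarray
    end: np.ndarray
    depth: np.ndarray
    divisor: float | None = None
    norm_mode: str | None = None

    def __post_init__(self):
        if (self.depth < 0).any():
            raise ValueError("depths must be >= 0")
        if len(self.start) != len(self.depth) or len(self.end) != len(self.depth):
            raise ValueError("coordinate and depth arrays must align")

    @property
    def n_windows(self) -> int:
        return len(self.depth)


def normalize_coverage(
    track: CoverageTrack,
    mode: str,
    autosomal_mean: float | None = None,
) -> CoverageTrack:
    """Divide window depths by the chosen mean depth.

    ``autosomal_mean`` mode requires the sample's autosome-wide mean
    depth (used for PAR detection); ``chromosome_mean`` divides by the
    track's own mean (used for the CNV ratio scan).
    """
    if mode == AUTOSOMAL_MEAN:
        if autosomal_mean is None:
            raise ValueError("autosomal_mean value required")
        divisor = float(autosomal_mean)
    elif mode == CHROMOSOME_MEAN:
        divisor = float(track.depth.mean())
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if divisor <= 0:
        raise ValueError("normalization divisor must be > 0")
    return replace(
        track, depth=track.depth / divisor, divisor=divisor, norm_mode=mode
    )


def _run_length_segment(
    values: np.ndarray, boundary: float, min_run: int
) -> np.ndarray:
    """Two-state segmentation by threshold then min-run-length smoothing.

    Windows are first assigned to the ~1.0 / ~0.5 state by the decision
    boundary.  Runs shorter than ``min_run`` are then absorbed into their
    neighbours, cheapest first: the cost of flipping a run is its summed
    squared distance to the opposite plateau level minus that to its own,
    so a borderline noise spike flips before a well-supported short run.
    Iterated to a fixed point (no run shorter than ``min_run`` remains
    except a single-run track).
    """
    state = (values >= boundary).astype(int)
    hi = values[state == 1]
    lo = values[state == 0]
    level = {1: hi.mean() if hi.size else 1.0, 0: lo.mean() if lo.size else 0.5}
    while True:
        runs = []
        start = 0
        for i in range(1, len(state) + 1):
            if i == len(state) or state[i] != state[start]:
                runs.append((start, i))
                start = i
        if len(runs) <= 1:
            break
        costs = []
        for ri, (s, e) in enumerate(runs):
            if e - s >= min_run:
                continue
            own = level[state[s]]
            other = level[1 - state[s]]
            chunk = values[s:e]
            cost = float(((chunk - other) ** 2 - (chunk - own) ** 2).sum())
            costs.append((cost, ri))
        if not costs:
            break
        _, ri = min(costs)
        s, e = runs[ri]
        state[s:e] = 1 - state[s]
    return state


def detect_par(
    male_track: CoverageTrack,
    female_track: CoverageTrack | None = None,
    boundary: float = 0.75,
    min_run: int = 10,
) -> dict:
    """Locate the PAR as a terminal full-coverage plateau on the male X.

    The male autosome-normalized track is segmented into ~1.0 and ~0.5
    states (decision boundary ``boundary``, minimum run length
    ``min_run`` windows; at Poisson noise on depth ~20 a run of ten
    windows is needed to make chance state flips negligible).  The PAR
    call is the contiguous ~1.0 segment
    anchored at a chromosome end (both ends are searched; the longer
    anchored segment wins).  A female track, when supplied, must be ~1.0
    across the call, recorded as a consistency flag.
    """
    if male_track.norm_mode != AUTOSOMAL_MEAN:
        raise ValueError("male track must be normalized by the autosomal mean")
    n = male_track.n_windows
    if n < 50:
        raise ValueError("need at least 50 windows to call a PAR")
    state = _run_length_segment(male_track.depth, boundary, min_run)
    flags = []
    if not (state == 0).any():
        flags.append("no non-PAR detected")
        return {"par": None, "flags": flags, "state": state}
    if not (state == 1).any():
        return {"par": None, "flags": ["empty PAR"], "state": state}
    # terminal ~1.0 runs anchored at either end
    candidates = []
    if state[0] == 1:
        e = int(np.argmax(state == 0))
        candidates.append((0, e))
    if state[-1] == 1:
        s = n - int(np.argmax(state[::-1] == 0))
        candidates.append((s, n))
    if not candidates:
        return {"par": None, "flags": ["empty PAR"], "state": state}
    s, e = max(candidates, key=lambda c: c[1] - c[0])
    par = {
        "chrom": male_track.chrom,
        "start": int(male_track.start[s]),
        "end": int(male_track.end[e - 1]),
        "first_window": s,
        "last_window": e - 1,
        "n_windows": e - s,
    }
    if female_track is not None:
        female_ok = bool((female_track.depth[s:e] >= boundary).all())
        flags.append("female consistent" if female_ok else "female inconsistent")
    return {"par": par, "flags": flags, "state": state}


def cnv_ratio_scan(
    target: CoverageTrack,
    references,
    min_ratio: float = 2.0,
    min_span_windows: int = 5,
    max_gap_windows: int = 2,
) -> pd.DataFrame:
    """Call runs of windows with elevated target/reference coverage ratio.

    With several reference tracks a region must exceed ``min_ratio``
    against every reference (the all-pairwise-comparisons rule).
    Reference windows with zero depth are skipped (logged).  Runs
    separated by at most ``max_gap_windows`` sub-threshold windows are
    merged (depth noise dips single windows below the ratio cut); a
    region must still contain ``min_span_windows`` passing windows.
    Returns a BED-like table of merged regions with each region's mean
    ratio over its passing windows.
    """
    if isinstance(references, CoverageTrack):
        references = [references]
    n = target.n_windows
    ok = np.ones(n, dtype=bool)
    ratios = []
    for ref in references:
        if ref.n_windows != n or ref.chrom != target.chrom:
            raise ValueError("target and reference tracks must share windowing")
        zero = ref.depth == 0
        if zero.any():
            logger.info("cnv_ratio_scan: skipping %d zero-depth reference windows", zero.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(zero, np.nan, target.depth / ref.depth)
        ratios.append(r)
        ok &= ~zero & (r >= min_ratio)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        mean_ratio = np.nanmean(np.vstack(ratios), axis=0)
    hits = np.flatnonzero(ok)
    rows = []
    if hits.size:
        run_start = hits[0]
        prev = hits[0]
        spans = []
        for h in hits[1:]:
            if h - prev > max_gap_windows + 1:
                spans.append((run_start, prev))
                run_start = h
            prev = h
        spans.append((run_start, prev))
        for i, j in spans:
            passing = ok[i : j + 1]
            if int(passing.sum()) >= min_span_windows:
                sel = np.arange(i, j + 1)[passing]
                rows.append(
                    {
                        "chrom": target.chrom,
                        "start": int(target.start[i]),
                        "end": int(target.end[j]),
                        "n_windows": int(passing.sum()),
                        "mean_ratio": float(np.nanmean(mean_ratio[sel])),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows", "mean_ratio"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_coverage_tsv(path: str) -> list[CoverageTrack]:
    """Read per-window depth TSV (sample, sex, chrom, start, end, depth)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "sex", "chrom", "start", "end", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coverage TSV missing columns: {sorted(missing)}")
    tracks = []
    for (sample, sex, chrom), g in df.groupby(["sample", "sex", "chrom"], sort=False):
        g = g.sort_values("start")
        tracks.append(
            CoverageTrack(
                sample=sample,
                sex=sex,
                chrom=chrom,
                start=g["start"].to_numpy(),
                end=g["end"].to_numpy(),
                depth=g["depth"].to_numpy(dtype=float),
            )
        )
    return tracks


def write_bed(regions: pd.DataFrame, path: str) -> None:
    regions[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )
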