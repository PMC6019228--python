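"""Read-depth copy-number detection and cross-pairing CNVR intersection.

Case and control read counts on a fixed non-overlapping window grid are
turned into normalized log2 ratios (library-size corrected, with a 0.5
pseudocount so homozygous deletions remain finite).  Calls are maximal runs
of consecutive windows beyond a symmetric log2 threshold, scored with a
Geary–Hinkley normal approximation to the Poisson count ratio and combined
across the run by Stouffer's method.  Calls from several case-control
pairings intersect into copy-number regions (CNVRs) when every pairing
contributes a same-direction call with at least a minimum common overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import GenomicInterval


@dataclass
class DepthTrack:
    """Aligned per-window read counts for one chromosome."""

    chromosome: str
    window_start: np.ndarray  # 1-based start of each fixed-size window
    window_size: int
    case_count: np.ndarray
    control_count: np.ndarray
    # genome-wide totals for normalization; default to this track's sums
    total_case: float = 0.0
    total_control: float = 0.0

    def __post_init__(self) -> None:
        self.window_start = np.asarray(self.window_start, dtype=np.int64)
        self.case_count = np.asarray(self.case_count, dtype=np.int64)
        self.control_count = np.asarray(self.control_count, dtype=np.int64)
        if not (len(self.window_start) == len(self.case_count) == len(self.control_count)):
            raise ValueError("window grids for case and control must match")
        if (self.case_count < 0).any() or (self.control_count < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.total_case == 0.0:
            self.total_case = float(self.case_count.sum())
        if self.total_control == 0.0:
            self.total_control = float(self.control_count.sum())


@dataclass(frozen=True)
class CnvCall:
    interval: GenomicInterval
    direction: str  # "loss" or "gain"
    mean_log2: float
    n_windows: int
    p_value: float


@dataclass
class Cnvr:
    """A copy-number region supported by a same-direction call from every
    pairing, intersected to their common interval."""

    interval: GenomicInterval
    direction: str
    supporting: List[CnvCall]


def read_depth_tsv(path) -> Dict[str, DepthTrack]:
    """Load count tracks from TSV (chrom, window_start, window_size,
    case_count, control_count), normalizing by grand totals."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    total_case = float(df["case_count"].sum())
    total_control = float(df["control_count"].sum())
    tracks = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        tracks[str(chrom)] = DepthTrack(
            chromosome=str(chrom),
            window_start=sub["window_start"].to_numpy(),
            window_size=int(sub["window_size"].iloc[0]),
            case_count=sub["case_count"].to_numpy(),
            control_count=sub["control_count"].to_numpy(),
            total_case=total_case,
            total_control=total_control,
        )
    return tracks


def log2_ratios(track: DepthTrack, pseudocount: float = 0.5) -> np.ndarray:
    """Normalized per-window log2(case/control) ratios.

    r = (case / control) * (total_control / total_case), with the
    pseudocount added to both counts so zero-coverage windows (homozygous
    deletions) stay finite.
    """
    if track.total_case <= 0 or track.total_control <= 0:
        raise ValueError("track totals must be positive")
    norm = track.total_control / track.total_case
    r = (track.case_count + pseudocount) / (track.control_count + pseudocount) * norm
    return np.log2(r)


def _run_p_value(
    case: np.ndarray,
    control: np.ndarray,
    mu_case: float,
    mu_control: float,
) -> float:
    """Stouffer-combined Geary–Hinkley p-value for one run of windows.

    Per window the count ratio T = x/y of two Poisson variables is
    transformed to t = (mu_y*T - mu_x) / sqrt(mu_y*T^2 + mu_x), standard
    normal under the null of equal relative coverage; the per-window t are
    combined as Z = sum(t)/sqrt(k) and converted to a two-sided p.
    """
    y = np.maximum(control.astype(float), 0.5)
    t_ratio = case.astype(float) / y
    t = (mu_control * t_ratio - mu_case) / np.sqrt(mu_control * t_ratio**2 + mu_case)
    z = float(t.sum() / np.sqrt(len(t)))
    return float(2.0 * stats.norm.sf(abs(z)))


def call_cnvs(
    track: DepthTrack,
    threshold: float = 0.7,
    min_windows: int = 10,
    alpha: float = 0.001,
    pseudocount: float = 0.5,
) -> List[CnvCall]:
    """Call CNVs as maximal runs of >= ``min_windows`` consecutive windows
    all beyond the log2 threshold in the same direction.

    A call spans the first window start to the last window end; calls whose
    combined p-value is >= ``alpha`` are discarded.
    """
    values = log2_ratios(track, pseudocount)
    state = np.zeros(len(values), dtype=np.int8)
    state[values <= -threshold] = -1
    state[values >= threshold] = 1
    # expected per-window means under the null, for the ratio test
    mu_control = float(track.control_count.mean()) if len(values) else 0.0
    mu_case = mu_control * track.total_case / track.total_control
    calls: List[CnvCall] = []
    i, n = 0, len(values)
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == state[i]:
            j += 1
        n_win = j - i + 1
        if n_win >= min_windows:
            p = _run_p_value(
                track.case_count[i : j + 1],
                track.control_count[i : j + 1],
                mu_case,
                mu_control,
            )
            if p < alpha:
                calls.append(
                    CnvCall(
                        interval=GenomicInterval(
                            track.chromosome,
                            int(track.window_start[i]),
                            int(track.window_start[j]) + track.window_size - 1,
                        ),
                        direction="loss" if state[i] < 0 else "gain",
                        mean_log2=float(values[i : j + 1].mean()),
                        n_windows=n_win,
                        p_value=p,
                    )
                )
        i = j + 1
    return calls


def intersect_cnvrs(
    call_sets: Sequence[Sequence[CnvCall]], min_overlap_bp: int = 50
) -> List[Cnvr]:
    """Intersect per-pairing call lists into CNVRs.

    A CNVR is emitted for each maximal interval where every pairing
    contributes a call of the same direction and the common intersection is
    at least ``min_overlap_bp`` long.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets to intersect")
    out: List[Cnvr] = []
    for direction in ("loss", "gain"):
        # seed with singleton stacks from the first set, then fold
        stacks = [
            ([c], c.interval)
            for c in call_sets[0]
            if c.direction == direction
        ]
        for calls in call_sets[1:]:
            nxt = []
            for support, iv in stacks:
                for c in calls:
                    if c.direction != direction:
                        continue
                    lo = max(iv.start, c.interval.start)
                    hi = min(iv.end, c.interval.end)
                    if iv.chromosome == c.interval.chromosome and lo <= hi:
                        nxt.append(
                            (support + [c], GenomicInterval(iv.chromosome, lo, hi))
                        )
            stacks = nxt
        for support, iv in stacks:
            if iv.length_bp >= min_overlap_bp:
                out.append(Cnvr(interval=iv, direction=direction, supporting=support))
    return sorted(out, key=lambda r: (r.interval.chromosome, r.interval.start))


def classify_zygosity(call: CnvCall) -> str:
    """Coarse copy-state from the mean log2 ratio.

    A heterozygous deletion halves coverage (log2 ~ -1); a homozygous
    deletion leaves only the pseudocount (strongly negative).
    """
    m = call.mean_log2
    if m <= -2.5:
        return "homozygous_loss"
    if -1.5 <= m <= -0.7:
        return "heterozygous_loss"
    if m >= 0.7:
        return "gain"
    return "ambiguous"
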