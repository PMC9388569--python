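"""Read-depth copy-number tracks: log ratios, decimation, arm and focal calls.

The genome is tiled into fixed-width windows (1000 bp by default) and
aligned-read counts per window are compared between tumor and a matched
(or process-matched) normal.  Per window the statistic is

    log2( (tumor_w / T) / (normal_w / N) )

with T, N the genome-wide totals (library-size normalization), so scaling
all of a sample's counts leaves the track unchanged.  Tracks are then
median-decimated (200-fold by default) to suppress counting noise before
arm-level calling; focal deletions are detected on the undecimated track
where a 50 kb event would otherwise vanish into a 200 kb median.

Windows are BED-style 0-based half-open.  Masked (missing) windows are
represented as NaN: a window is masked when either the normal or the tumor
has zero reads there, keeping every reported ratio finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel


@dataclass
class CoverageTrack:
    """Per-chromosome fixed-width window read counts for one sample."""

    sample_id: str
    window_size: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        self.counts = {c: np.asarray(v) for c, v in self.counts.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def same_windowing(self, other: "CoverageTrack") -> bool:
        return (
            self.window_size == other.window_size
            and set(self.counts) == set(other.counts)
            and all(len(self.counts[c]) == len(other.counts[c]) for c in self.counts)
        )


@dataclass
class LogRatioTrack:
    """Per-window log2 tumor/normal coverage ratios (NaN = masked).

    ``window_size`` is the *effective* window width: decimation by a factor
    k multiplies it by k, so coordinates remain window_index * window_size.
    ``decimation`` records the cumulative factor applied.
    """

    sample_id: str
    window_size: int
    ratios: dict[str, np.ndarray] = field(default_factory=dict)
    decimation: int = 1


@dataclass
class ArmCall:
    """Gain/loss/neutral status of one chromosome arm."""

    arm: str
    median_log2: float
    call: str  # loss | neutral | gain | missing


@dataclass
class FocalDeletion:
    """A focal run of deleted windows overlapping a gene."""

    gene_id: str
    chrom: str
    start: int
    end: int
    n_windows: int
    tss_overlap: bool


def log_ratio(tumor: CoverageTrack, normal: CoverageTrack) -> LogRatioTrack:
    """Library-size-normalized per-window log2 tumor/normal ratio track."""
    if not tumor.same_windowing(normal):
        raise ValueError("tumor and normal tracks must share identical windowing")
    t_total, n_total = tumor.total(), normal.total()
    if t_total <= 0 or n_total <= 0:
        raise ValueError("both tracks need at least one read")
    ratios = {}
    for chrom in tumor.counts:
        t = tumor.counts[chrom].astype(float)
        n = normal.counts[chrom].astype(float)
        ok = (n > 0) & (t > 0)
        r = np.full(len(t), np.nan)
        r[ok] = np.log2((t[ok] / t_total) / (n[ok] / n_total))
        ratios[chrom] = r
    return LogRatioTrack(sample_id=tumor.sample_id, window_size=tumor.window_size, ratios=ratios)


def median_decimate(track: LogRatioTrack, factor: int = 200) -> LogRatioTrack:
    """Collapse consecutive blocks of ``factor`` windows to their median.

    Masked values are excluded from each block's median; a block whose
    inputs are all masked stays masked.  The terminal partial block uses
    the median of whatever it contains.  ``factor = 1`` is the identity.
    """
    if factor < 1:
        raise ValueError(f"decimation factor must be >= 1, got {factor}")
    if factor == 1:
        return LogRatioTrack(
            sample_id=track.sample_id,
            window_size=track.window_size,
            ratios={c: v.copy() for c, v in track.ratios.items()},
            decimation=track.decimation,
        )
    out = {}
    for chrom, vals in track.ratios.items():
        blocks = [vals[i : i + factor] for i in range(0, len(vals), factor)]
        med = np.array(
            [np.nan if np.all(np.isnan(b)) else np.nanmedian(b) for b in blocks]
        )
        out[chrom] = med
    return LogRatioTrack(
        sample_id=track.sample_id,
        window_size=track.window_size * factor,
        ratios=out,
        decimation=track.decimation * factor,
    )


def arm_summary(
    track: LogRatioTrack, arms: pd.DataFrame, loss_thr: float = -0.3, gain_thr: float = 0.3
) -> list[ArmCall]:
    """Median log ratio and gain/loss/neutral call per chromosome arm.

    A window belongs to the arm containing its midpoint.  Arms with zero
    unmasked windows are reported with call ``missing``.
    """
    if loss_thr >= gain_thr:
        raise ValueError("loss_thr must be below gain_thr")
    calls = []
    for row in arms.itertuples(index=False):
        vals = track.ratios.get(row.chrom)
        if vals is None:
            calls.append(ArmCall(row.arm, float("nan"), "missing"))
            continue
        mids = (np.arange(len(vals)) + 0.5) * track.window_size
        sel = vals[(mids >= row.start) & (mids < row.end)]
        sel = sel[~np.isnan(sel)]
        if len(sel) == 0:
            calls.append(ArmCall(row.arm, float("nan"), "missing"))
            continue
        med = float(np.median(sel))
        if med <= loss_thr:
            call = "loss"
        elif med >= gain_thr:
            call = "gain"
        else:
            call = "neutral"
        calls.append(ArmCall(row.arm, med, call))
    return calls


def detect_codeletion(arm_calls: list[ArmCall]) -> bool:
    """True iff both 1p and 19q are called loss (the oligodendroglioma hallmark)."""
    by_arm = {c.arm: c for c in arm_calls}
    for arm in ("1p", "19q"):
        if arm not in by_arm or by_arm[arm].call == "missing":
            raise ValueError(f"codeletion undefined: no usable call for arm {arm}")
    return by_arm["1p"].call == "loss" and by_arm["19q"].call == "loss"


def focal_deletions(
    track: LogRatioTrack,
    genes: list[GeneModel],
    del_thr: float = -1.0,
    max_span: int = 3_000_000,
    min_windows: int = 1,
) -> list[FocalDeletion]:
    """Maximal runs of windows at/below ``del_thr`` spanning <= ``max_span``.

    Masked windows break a run.  A run is reported once per overlapping
    gene span; ``tss_overlap`` is true when the run covers the gene's TSS.
    Runs wider than ``max_span`` are treated as arm-level, not focal;
    runs shorter than ``min_windows`` windows are treated as noise.

    On noisy tracks, call this on a lightly decimated track with
    ``del_thr`` placed *between* the deep-focal level (~-2 for a
    homozygous-looking event) and the single-copy arm-loss level (-1), so
    that windows of a hemizygously lost arm do not produce spurious runs.
    """
    events = []
    w = track.window_size
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, vals in track.ratios.items():
        below = np.zeros(len(vals), dtype=bool)
        ok = ~np.isnan(vals)
        below[ok] = vals[ok] <= del_thr
        if not below.any():
            continue
        idx = np.flatnonzero(below)
        run_breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.r_[idx[0], idx[run_breaks + 1]]
        ends = np.r_[idx[run_breaks], idx[-1]] + 1
        for i0, i1 in zip(starts, ends):
            if i1 - i0 < min_windows:
                continue
            start, end = int(i0) * w, int(i1) * w
            if end - start > max_span:
                continue
            for g in by_chrom.get(chrom, []):
                if start < g.end and g.start < end:
                    events.append(
                        FocalDeletion(
                            gene_id=g.gene_id,
                            chrom=chrom,
                            start=start,
                            end=end,
                            n_windows=int(i1 - i0),
                            tss_overlap=start <= g.tss < end,
                        )
                    )
    return events


def write_bedgraph(track: CoverageTrack | LogRatioTrack, path: str | Path, header: str | None = None) -> None:
    """Write a track as bedGraph (masked windows omitted)."""
    values = track.counts if isinstance(track, CoverageTrack) else track.ratios
    w = track.window_size
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f'track type=bedGraph name="{track.sample_id}"\n')
        for chrom, vals in values.items():
            for i, v in enumerate(vals):
                if isinstance(v, float) and np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{v:g}\n")


def read_coverage_bedgraph(path: str | Path, sample_id: str, window_size: int) -> CoverageTrack:
    df = pd.read_csv(
        path, sep="\t", comment="#", skiprows=lambda i: False, header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str}, engine="python",
        skip_blank_lines=True,
    )
    df = df[~df["chrom"].str.startswith("track")]
    df["start"] = df["start"].astype(int)
    counts = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        n = int(sub["start"].max()) // window_size + 1
        arr = np.zeros(n)
        arr[(sub["start"] // window_size).to_numpy()] = sub["value"].to_numpy()
        counts[chrom] = arr
    return CoverageTrack(sample_id=sample_id, window_size=window_size, counts=counts)


def arm_calls_frame(per_sample: dict[str, list[ArmCall]]) -> pd.DataFrame:
    """Long-format arm-call table (sample, arm, median_log2, call)."""
    rows = []
    for sid, calls in per_sample.items():
        for c in calls:
            rows.append({"sample_id": sid, "arm": c.arm, "median_log2": c.median_log2, "call": c.call})
    return pd.DataFrame(rows)
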