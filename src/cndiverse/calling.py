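"""Per-strain CNV calling from windowed read depth.

Stages: GC-binned median normalization of depth to copy-number ratios,
rounding to integer CN states, run-merging segmentation into candidate
regions, and a Wilcoxon rank-sum significance filter of candidate windows
against neutral (CN = 1) windows.  Defaults mirror a 250 bp window
read-depth protocol with a 7 kb telocentromeric mask.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .genome import GenomeModel
from .simulate import read_depth

logger = logging.getLogger(__name__)


def round_half_up(x):
    """Round half away from zero upward: 1.5 -> 2, 0.5 -> 1, 0.49 -> 0."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


@dataclasses.dataclass
class CallConfig:
    """Tunable parameters of the caller."""

    window: int = 250
    gc_bins: int = 25
    mask_telocentromeric: int = 7000
    min_windows: int = 2
    alpha: float = 0.05
    smooth: int = 3  # running-median width in windows; 1 disables

    def validate(self) -> None:
        if self.window <= 0 or self.gc_bins < 1 or self.min_windows < 1:
            raise ValueError("window, gc_bins and min_windows must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.smooth < 1 or self.smooth % 2 == 0:
            raise ValueError("smooth must be an odd positive window count")


@dataclasses.dataclass
class WindowTrack:
    """A strain's windowed track: depth, GC, and derived ratio/CN state."""

    strain_id: str
    window: int
    data: pd.DataFrame  # chrom, start, depth, gc [, ratio, cn_state]


@dataclasses.dataclass
class CNVR:
    """A copy-number variable region in one strain (0-based half-open)."""

    strain_id: str
    chromosome: str
    start: int
    end: int
    cn: int
    event_class: str  # "dup" | "del"
    p_value: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.cn == 1:
            raise ValueError("a CNVR cannot have baseline CN 1")
        expected = "dup" if self.cn > 1 else "del"
        if self.event_class != expected:
            raise ValueError(
                f"event_class {self.event_class} inconsistent with cn={self.cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _mask_telocentromeric(
    tab: pd.DataFrame, genome: GenomeModel, window: int, mask: int
) -> np.ndarray:
    """True for windows within ``mask`` bp of a chromosome end or centromere."""
    out = np.zeros(len(tab), dtype=bool)
    for name, idx in tab.groupby("chrom", sort=False).groups.items():
        c = genome.chromosome(str(name))
        starts = tab.loc[idx, "start"].to_numpy()
        ends = starts + window
        near_end = (starts < mask) | (ends > c.length - mask)
        near_cen = (starts < c.cen_end + mask) & (ends > c.cen_start - mask)
        out[tab.index.get_indexer(idx)] = near_end | near_cen
    return out


def normalize_track(
    raw: pd.DataFrame | WindowTrack,
    genome: GenomeModel,
    window: int = 250,
    gc_bins: int = 25,
    mask_telocentromeric: int = 7000,
    strain_id: str = "",
) -> WindowTrack:
    """Convert raw window depths to GC-corrected CN ratios and states.

    Each window's depth is divided by the median depth of windows in the
    same GC bin; bin medians are computed excluding windows within
    ``mask_telocentromeric`` bp of chromosome ends or centromeres (those
    regions are still normalized and called).  Ratios are then rescaled so
    the genome-wide median ratio is 1, and ``cn_state`` is the
    round-half-up integer state.
    """
    if isinstance(raw, WindowTrack):
        strain_id = strain_id or raw.strain_id
        raw = raw.data
    tab = raw.copy().reset_index(drop=True)

    # tiling check: fixed steps of `window` from 0 on each chromosome
    for name, sub in tab.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        expect = genome.window_starts(str(name), window)
        if len(starts) != len(expect) or not np.array_equal(starts, expect):
            raise ValueError(
                f"{strain_id or 'track'}: windows on {name} do not tile the "
                f"chromosome in steps of {window} bp"
            )

    depth = tab["depth"].to_numpy(dtype=float)
    if (depth == 0).mean() > 0.5:
        raise ValueError(
            f"{strain_id or 'track'}: more than half of all windows have zero "
            "depth; input looks corrupt"
        )
    gc = tab["gc"].to_numpy(dtype=float)
    if gc.min() < 0 or gc.max() > 1:
        raise ValueError("gc values must lie in [0, 1]")

    masked = _mask_telocentromeric(tab, genome, window, mask_telocentromeric)
    usable = ~masked
    if not usable.any():
        logger.warning("telocentromeric mask covers every window; ignoring mask")
        usable = np.ones(len(tab), dtype=bool)
    global_median = float(np.median(depth[usable]))
    if global_median <= 0:
        raise ValueError("median depth of unmasked windows is zero")

    span = gc.max() - gc.min()
    if span < 1e-9:
        bin_idx = np.zeros(len(tab), dtype=int)
        n_bins = 1
    else:
        edges = np.linspace(gc.min(), gc.max(), gc_bins + 1)
        bin_idx = np.clip(np.digitize(gc, edges[1:-1]), 0, gc_bins - 1)
        n_bins = gc_bins

    bin_median = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = usable & (bin_idx == b)
        if sel.any():
            m = float(np.median(depth[sel]))
            bin_median[b] = m if m > 0 else np.nan
    empty = np.isnan(bin_median)
    if empty.any():
        logger.warning(
            "%d of %d GC bins empty after masking; falling back to global median",
            int(empty.sum()),
            n_bins,
        )
        bin_median[empty] = global_median

    ratio = depth / bin_median[bin_idx]
    scale = float(np.median(ratio))
    if scale > 0:
        ratio = ratio / scale
    tab["ratio"] = ratio
    tab["cn_state"] = round_half_up(ratio)
    return WindowTrack(strain_id=strain_id, window=window, data=tab)


def smooth_states(track: WindowTrack, width: int = 3) -> WindowTrack:
    """Re-derive CN states from a per-chromosome running median of ratios.

    Damps isolated single-window rounding flips that would otherwise
    fragment runs; ``width`` = 1 is a no-op.
    """
    if width <= 1:
        return track
    tab = track.data.copy()
    smoothed = np.empty(len(tab))
    for _, idx in tab.groupby("chrom", sort=False).groups.items():
        loc = tab.index.get_indexer(idx)
        smoothed[loc] = ndimage.median_filter(
            tab["ratio"].to_numpy()[loc], size=width, mode="nearest"
        )
    tab["ratio_smooth"] = smoothed
    tab["cn_state"] = round_half_up(smoothed)
    return WindowTrack(track.strain_id, track.window, tab)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment(track: WindowTrack, min_windows: int = 2) -> list[CNVR]:
    """Merge consecutive non-neutral windows of the same class into CNVRs.

    Maximal runs of adjacent windows that are all duplicated (state > 1) or
    all deleted (state < 1) on one chromosome become candidates; the region
    CN is the round-half-up of the median ratio over the run's windows
    (which is guaranteed non-baseline because every window in a dup run has
    ratio ≥ 1.5 and every window in a del run ratio < 0.5).  Runs shorter
    than ``min_windows`` are discarded.  Candidates carry p_value = NaN
    until tested.
    """
    out: list[CNVR] = []
    w = track.window
    for chrom, sub in track.data.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        states = sub["cn_state"].to_numpy()
        ratios = sub["ratio"].to_numpy(dtype=float)
        cls = np.where(states > 1, 1, np.where(states < 1, -1, 0))
        n = len(states)
        i = 0
        while i < n:
            if cls[i] == 0:
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and cls[j + 1] == cls[i]
                and starts[j + 1] == starts[j] + w
            ):
                j += 1
            if j - i + 1 >= min_windows:
                cn = int(round_half_up(np.median(ratios[i : j + 1])))
                out.append(
                    CNVR(
                        strain_id=track.strain_id,
                        chromosome=str(chrom),
                        start=int(starts[i]),
                        end=int(starts[j]) + w,
                        cn=cn,
                        event_class="dup" if cn > 1 else "del",
                        p_value=float("nan"),
                        n_windows=j - i + 1,
                    )
                )
            i = j + 1
    out.sort(key=lambda r: (r.chromosome, r.start))
    return out


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration for small tie-free samples (both sides ≤ 20),
    otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def neutral_ratios(track: WindowTrack, chromosome: str | None = None) -> np.ndarray:
    """Raw ratios of neutral (state = 1) windows, optionally per chromosome."""
    tab = track.data
    sel = tab["cn_state"] == 1
    if chromosome is not None:
        sel = sel & (tab["chrom"] == chromosome)
    return tab.loc[sel, "ratio"].to_numpy(dtype=float)


def test_significance(
    candidate: CNVR, track: WindowTrack, alpha: float = 0.05
) -> CNVR | None:
    """Rank-sum test of candidate-window ratios against neutral windows.

    Neutral windows are taken from the candidate's chromosome; when a
    chromosome has none (e.g. fully aneuploid), the genome-wide neutral set
    is used and the fallback is logged.  Returns the candidate with its
    p-value if p < alpha, else ``None``.
    """
    tab = track.data
    in_cand = (
        (tab["chrom"] == candidate.chromosome)
        & (tab["start"] >= candidate.start)
        & (tab["start"] < candidate.end)
    )
    cand = tab.loc[in_cand, "ratio"].to_numpy(dtype=float)
    neut = neutral_ratios(track, candidate.chromosome)
    if len(neut) == 0:
        logger.warning(
            "%s: no neutral windows on %s; using genome-wide neutral windows",
            track.strain_id,
            candidate.chromosome,
        )
        neut = neutral_ratios(track)
    if len(cand) == 0 or len(neut) == 0:
        return None
    p = rank_sum_test(cand, neut)
    if p < alpha:
        return dataclasses.replace(candidate, p_value=p)
    return None


# ---------------------------------------------------------------------------
# Composition and I/O
# ---------------------------------------------------------------------------

def call_strain(
    depth: str | Path | pd.DataFrame,
    genome: GenomeModel,
    config: CallConfig | None = None,
    strain_id: str = "",
) -> tuple[WindowTrack, list[CNVR]]:
    """normalize → (smooth) → segment → test, for one strain's depth track."""
    config = config or CallConfig()
    config.validate()
    if isinstance(depth, (str, Path)):
        strain_id = strain_id or Path(depth).name.split(".")[0]
        depth = read_depth(depth)
    track = normalize_track(
        depth,
        genome,
        window=config.window,
        gc_bins=config.gc_bins,
        mask_telocentromeric=config.mask_telocentromeric,
        strain_id=strain_id,
    )
    track = smooth_states(track, config.smooth)
    candidates = segment(track, min_windows=config.min_windows)
    kept = []
    for cand in candidates:
        res = test_significance(cand, track, alpha=config.alpha)
        if res is not None:
            kept.append(res)
    return track, kept


def write_cnvr_bed(cnvrs: list[CNVR], path: str | Path) -> Path:
    """BED-like CNVR table: chrom, start, end, name, cn, class, p_value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, r in enumerate(cnvrs):
            name = f"{r.strain_id}_cnvr_{i + 1:04d}"
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t{name}\t{r.cn}\t"
                f"{r.event_class}\t{r.p_value:.6g}\n"
            )
    return path


def read_cnvr_bed(path: str | Path, strain_id: str = "") -> list[CNVR]:
    strain_id = strain_id or Path(path).name.split(".")[0]
    cols = ["chrom", "start", "end", "name", "cn", "class", "p_value"]
    tab = pd.read_csv(path, sep="\t", names=cols, comment="#")
    out = []
    for _, r in tab.iterrows():
        out.append(
            CNVR(
                strain_id=strain_id,
                chromosome=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                cn=int(r["cn"]),
                event_class=str(r["class"]),
                p_value=float(r["p_value"]),
                n_windows=0,
            )
        )
    return out
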