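"""Synthetic multi-strain depth data with embedded, ground-truth CN variants.

The generator emulates the statistical structure of read-depth data from a
cohort of haploid-reference yeast strains: duplication sizes skewed below
1 kb, deletions with a 5–7 kb mode, a tunable concentration of events in
subtelomeric zones, per-locus carrier frequencies drawn from a Beta
distribution (so both rare and common CN alleles occur), GC-dependent depth
modulation, and overdispersed (negative-binomial) window counts.

Baseline copy number is 1 — one copy relative to the reference genome; a
deletion carrier has CN 0 and a duplication carrier CN ≥ 2.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel

logger = logging.getLogger(__name__)

SUBTEL_SPAN = 25_000  # bp from each chromosome end counted as subtelomeric


@dataclasses.dataclass
class SimConfig:
    """Parameters of the population simulator.

    dup_size_dist is (log-mean, log-sd) of a lognormal in bp; del_size_dist
    is the mixture weight pair (short: uniform 250–1000 bp, long: uniform
    5–7 kb).  base_depth is the mean read count per window at CN 1;
    dispersion is the negative-binomial size parameter r (variance
    m + m²/r).  gc_amplitude is the relative depth modulation applied by the
    unimodal GC response centered at GC 0.45.
    """

    n_strains: int = 132
    n_loci: int = 100
    p_duplication: float = 0.4
    p_subtelomeric: float = 0.5
    dup_size_dist: tuple[float, float] = (np.log(600.0), 0.7)
    del_size_dist: tuple[float, float] = (0.3, 0.7)
    allele_freq_dist: tuple[float, float] = (0.8, 0.8)
    max_extra_copies: int = 6
    base_depth: float = 30.0
    dispersion: float = 100.0
    gc_amplitude: float = 0.3
    window: int = 250
    seed: int = 0
    snap_to_window: bool = True
    min_event_gap: int = 2  # windows of clearance between events
    min_event_size: int = 250  # bp floor applied to drawn sizes

    def validate(self) -> None:
        for name in ("p_duplication", "p_subtelomeric"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.base_depth <= 0:
            raise ValueError("base_depth must be > 0")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_strains < 1 or self.n_loci < 0:
            raise ValueError("n_strains must be >= 1 and n_loci >= 0")
        w_short, w_long = self.del_size_dist
        if w_short < 0 or w_long < 0 or w_short + w_long <= 0:
            raise ValueError("del_size_dist weights must be non-negative, not both 0")


@dataclasses.dataclass
class TruthEvent:
    """A simulated CN variant locus with its per-strain copy numbers."""

    locus_id: str
    chromosome: str
    start: int
    end: int
    event_class: str  # "dup" | "del"
    cn: np.ndarray  # per-strain integer CN, baseline 1
    carrier_freq: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: end must exceed start")
        if self.event_class not in ("dup", "del"):
            raise ValueError(f"{self.locus_id}: bad event_class {self.event_class}")
        cn = np.asarray(self.cn, dtype=np.int64)
        if (cn < 0).any():
            raise ValueError(f"{self.locus_id}: negative CN")
        if self.event_class == "del" and (cn > 1).any():
            raise ValueError(f"{self.locus_id}: deletion with CN > 1")
        if self.event_class == "dup" and (cn < 1).any():
            raise ValueError(f"{self.locus_id}: duplication with CN < 1")
        self.cn = cn


def strain_ids(n: int) -> list[str]:
    return [f"strain_{i + 1:03d}" for i in range(n)]


# ---------------------------------------------------------------------------
# GC field and GC response
# ---------------------------------------------------------------------------

def gc_field(n_windows: int, rng: np.random.Generator, scale: int = 10) -> np.ndarray:
    """Smooth per-window GC fractions in [0.30, 0.60].

    White noise is smoothed with a moving-average kernel of ``scale``
    windows, standardized, and squashed around 0.45.
    """
    if n_windows == 0:
        return np.empty(0)
    noise = rng.standard_normal(n_windows + 2 * scale)
    kernel = np.ones(scale) / scale
    smooth = np.convolve(noise, kernel, mode="same")[scale:-scale]
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.clip(0.45 + 0.05 * smooth, 0.30, 0.60)


def gc_response(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Unimodal depth modulation factor, peaked at GC 0.45, mean exactly 1.

    The factor multiplies the expected depth of a window; centering on the
    realized GC field keeps genome-wide mean depth at base_depth so the
    caller's GC correction is exercised without shifting overall coverage.
    """
    bump = np.exp(-0.5 * ((gc - 0.45) / 0.07) ** 2)
    return 1.0 + amplitude * (bump - bump.mean())


# ---------------------------------------------------------------------------
# Event placement
# ---------------------------------------------------------------------------

def _draw_size(cfg: SimConfig, is_dup: bool, rng: np.random.Generator) -> int:
    if is_dup:
        mu, sigma = cfg.dup_size_dist
        size = float(rng.lognormal(mu, sigma))
    else:
        w_short, w_long = cfg.del_size_dist
        if rng.random() < w_short / (w_short + w_long):
            size = float(rng.uniform(250, 1000))
        else:
            size = float(rng.uniform(5000, 7000))
    size = max(size, cfg.window, cfg.min_event_size)
    if cfg.snap_to_window:
        size = max(cfg.window, round(size / cfg.window) * cfg.window)
    return int(size)


def _place_event(
    genome: GenomeModel,
    cfg: SimConfig,
    size: int,
    subtelomeric: bool,
    occupied: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> tuple[str, int, int]:
    """Place one event of ``size`` bp in the requested stratum, no overlap.

    Subtelomeric events lie entirely inside the 25 kb end zones; others lie
    entirely outside them.  Events never span a centromere and keep
    ``min_event_gap`` windows of clearance from already-placed events.
    """
    lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    gap = cfg.min_event_gap * cfg.window
    for _ in range(max_tries):
        ci = rng.choice(len(genome.chromosomes), p=probs)
        chrom = genome.chromosomes[ci]
        if subtelomeric:
            if size > SUBTEL_SPAN:
                continue
            if rng.random() < 0.5:
                lo, hi = 0, SUBTEL_SPAN - size
            else:
                lo, hi = chrom.length - SUBTEL_SPAN, chrom.length - size
        else:
            lo, hi = SUBTEL_SPAN, chrom.length - SUBTEL_SPAN - size
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        if cfg.snap_to_window:
            start = (start // cfg.window) * cfg.window
            if subtelomeric and start < lo:
                start += cfg.window
        end = start + size
        if end > chrom.length:
            continue
        if start < chrom.cen_end and chrom.cen_start < end:
            continue  # never span the centromere
        clash = any(
            start - gap < e and s < end + gap for s, e in occupied.get(chrom.name, [])
        )
        if clash:
            continue
        occupied.setdefault(chrom.name, []).append((start, end))
        return chrom.name, start, end
    raise RuntimeError(
        f"could not place a {size} bp "
        f"{'subtelomeric' if subtelomeric else 'interstitial'} event after "
        f"{max_tries} tries; reduce n_loci or event sizes, or enlarge the genome"
    )


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

def simulate_population(
    genome: GenomeModel, cfg: SimConfig
) -> tuple[list[TruthEvent], dict[str, pd.DataFrame]]:
    """Simulate truth events and per-strain windowed depth tracks.

    Returns ``(events, tracks)`` where ``tracks`` maps strain id to a
    DataFrame with columns ``chrom, start, depth, gc``.  Window depth is
    negative-binomial with mean ``base_depth × CN × gc_response`` and size
    parameter ``dispersion``.  Deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sids = strain_ids(cfg.n_strains)

    # per-chromosome GC fields (shared by all strains: same reference genome)
    gc: dict[str, np.ndarray] = {
        c.name: gc_field(genome.n_windows(c.name, cfg.window), rng)
        for c in genome.chromosomes
    }
    all_gc = np.concatenate([gc[c.name] for c in genome.chromosomes])
    bump_mean = np.exp(-0.5 * ((all_gc - 0.45) / 0.07) ** 2).mean()

    def response(g: np.ndarray) -> np.ndarray:
        bump = np.exp(-0.5 * ((g - 0.45) / 0.07) ** 2)
        return 1.0 + cfg.gc_amplitude * (bump - bump_mean)

    # --- events -----------------------------------------------------------
    subtel_flags = rng.random(cfg.n_loci) < cfg.p_subtelomeric
    occupied: dict[str, list[tuple[int, int]]] = {}
    events: list[TruthEvent] = []
    for i in range(cfg.n_loci):
        is_dup = rng.random() < cfg.p_duplication
        size = _draw_size(cfg, is_dup, rng)
        chrom, start, end = _place_event(
            genome, cfg, size, bool(subtel_flags[i]), occupied, rng
        )
        if is_dup:
            event_cn = 1 + int(rng.integers(1, cfg.max_extra_copies + 1))
        else:
            event_cn = 0
        q = float(rng.beta(*cfg.allele_freq_dist))
        carriers = rng.random(cfg.n_strains) < q
        cn = np.where(carriers, event_cn, 1).astype(np.int64)
        events.append(
            TruthEvent(
                locus_id=f"locus_{i + 1:04d}",
                chromosome=chrom,
                start=start,
                end=end,
                event_class="dup" if is_dup else "del",
                cn=cn,
                carrier_freq=q,
            )
        )
    events.sort(key=lambda e: (genome.names().index(e.chromosome), e.start))

    # --- depth tracks -----------------------------------------------------
    tracks: dict[str, pd.DataFrame] = {}
    for si, sid in enumerate(sids):
        frames = []
        for c in genome.chromosomes:
            starts = genome.window_starts(c.name, cfg.window)
            cn_w = np.ones(len(starts))
            for ev in events:
                if ev.chromosome != c.name or ev.cn[si] == 1:
                    continue
                # fractional dose for windows partially under the event
                ov = np.minimum(starts + cfg.window, ev.end) - np.maximum(
                    starts, ev.start
                )
                frac = np.clip(ov, 0, cfg.window) / cfg.window
                cn_w = cn_w + (ev.cn[si] - 1) * frac
            mean = cfg.base_depth * cn_w * response(gc[c.name])
            depth = np.zeros(len(starts), dtype=np.int64)
            pos = mean > 0
            r = cfg.dispersion
            p = r / (r + mean[pos])
            depth[pos] = rng.negative_binomial(r, p)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c.name,
                        "start": starts,
                        "depth": depth,
                        "gc": np.round(gc[c.name], 4),
                    }
                )
            )
        tracks[sid] = pd.concat(frames, ignore_index=True)
    return events, tracks


# ---------------------------------------------------------------------------
# Synthetic gene annotations
# ---------------------------------------------------------------------------

def simulate_genes(
    genome: GenomeModel,
    mean_length: int = 1400,
    mean_gap: int = 600,
    seed: int = 0,
) -> pd.DataFrame:
    """Tile chromosomes with non-overlapping synthetic genes.

    Gene lengths are normal around ``mean_length`` (min 300 bp), intergenic
    gaps exponential around ``mean_gap`` — a caricature of the compact yeast
    genome.  Returns columns ``gene_id, chrom, start, end, strand``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for c in genome.chromosomes:
        pos = int(rng.exponential(mean_gap))
        while True:
            length = max(300, int(rng.normal(mean_length, 300)))
            if pos + length >= c.length:
                break
            k += 1
            rows.append(
                (
                    f"gene_{k:05d}",
                    c.name,
                    pos,
                    pos + length,
                    "+" if rng.random() < 0.5 else "-",
                )
            )
            pos += length + int(rng.exponential(mean_gap))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# Truth and depth I/O
# ---------------------------------------------------------------------------

def write_truth(events: list[TruthEvent], outdir: str | Path) -> tuple[Path, Path]:
    """Write truth as BED4 (0-based half-open) plus a per-strain CN TSV.

    The TSV carries one row per locus: ``locus_id, class, carrier_freq`` then
    one integer CN column per strain.  Round-trips losslessly through
    :func:`read_truth`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed = outdir / "truth.bed"
    tsv = outdir / "truth_cn.tsv"
    n_strains = len(events[0].cn) if events else 0
    sids = strain_ids(n_strains)
    with open(bed, "w") as fh:
        for ev in events:
            fh.write(f"{ev.chromosome}\t{ev.start}\t{ev.end}\t{ev.locus_id}\n")
    header = ["locus_id", "class", "carrier_freq", *sids]
    with open(tsv, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for ev in events:
            cells = [ev.locus_id, ev.event_class, f"{ev.carrier_freq:.6f}"]
            cells += [str(int(v)) for v in ev.cn]
            fh.write("\t".join(cells) + "\n")
    return bed, tsv


def read_truth(bed: str | Path, tsv: str | Path) -> list[TruthEvent]:
    coords = pd.read_csv(
        bed, sep="\t", names=["chrom", "start", "end", "locus_id"], comment="#"
    )
    cn_tab = pd.read_csv(tsv, sep="\t")
    strain_cols = [c for c in cn_tab.columns if c.startswith("strain_")]
    cn_tab = cn_tab.set_index("locus_id")
    events = []
    for r in coords.itertuples():
        row = cn_tab.loc[r.locus_id]
        events.append(
            TruthEvent(
                locus_id=str(r.locus_id),
                chromosome=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                event_class=str(row["class"]),
                cn=row[strain_cols].to_numpy(dtype=np.int64),
                carrier_freq=float(row["carrier_freq"]),
            )
        )
    return events


def write_depth(track: pd.DataFrame, path: str | Path) -> Path:
    """Write a 4-column depth TSV (gzip-transparent by suffix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    track.to_csv(path, sep="\t", index=False, columns=["chrom", "start", "depth", "gc"])
    return path


def read_depth(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    expected = {"chrom", "start", "depth", "gc"}
    if not expected.issubset(tab.columns):
        raise ValueError(f"{path}: depth file must have columns {sorted(expected)}")
    return tab


def truth_intervals_by_strain(
    events: list[TruthEvent],
) -> dict[str, pd.DataFrame]:
    """Per-strain table of intervals where that strain's CN differs from 1."""
    n = len(events[0].cn) if events else 0
    out = {}
    for si, sid in enumerate(strain_ids(n)):
        rows = [
            (ev.chromosome, ev.start, ev.end, ev.locus_id, int(ev.cn[si]), ev.event_class)
            for ev in events
            if ev.cn[si] != 1
        ]
        out[sid] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "locus_id", "cn", "class"]
        )
    return out
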