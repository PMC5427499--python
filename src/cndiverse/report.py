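"""Cohort descriptive statistics, gene-family views, and the full pipeline.

Covers per-strain CNVR counts and genome fraction affected, CNVR size
distributions split by duplication/deletion, per-gene proportions of
duplicated/deleted strains, intragenic fine-window CN profiles, and a
reproducible simulate → call → score → summarize pipeline that writes a
checksum manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, context, diversity, genic, simulate
from .genome import GenomeModel, build_genome

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = [0, 1000, 2000, 3000, 4000, 5000, 7000, 10_000, float("inf")]


@dataclasses.dataclass
class StrainSummary:
    strain_id: str
    n_cnvrs: int
    n_dup: int
    n_del: int
    genome_affected_bp: int
    genome_affected_fraction: float


@dataclasses.dataclass
class GeneFamilyView:
    """Ordered gene × strain CN matrix plus per-gene strain proportions."""

    matrix: pd.DataFrame  # integer CN, genes in requested order
    proportions: pd.DataFrame  # prop_duplicated, prop_deleted, prop_unchanged


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def strain_summary(
    strain_id: str, cnvrs: list[calling.CNVR], genome: GenomeModel
) -> StrainSummary:
    bp = sum(r.length for r in cnvrs)
    return StrainSummary(
        strain_id=strain_id,
        n_cnvrs=len(cnvrs),
        n_dup=sum(1 for r in cnvrs if r.event_class == "dup"),
        n_del=sum(1 for r in cnvrs if r.event_class == "del"),
        genome_affected_bp=bp,
        genome_affected_fraction=bp / genome.total_length,
    )


def cohort_summary(
    cnvrs_by_strain: dict[str, list[calling.CNVR]],
    genome: GenomeModel,
    genes: list[genic.GeneAnnotation] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-strain summary table plus cohort aggregates.

    Aggregates include mean, SD, SE and median of per-strain CNVR counts,
    the mean/median genome fraction affected, and cohort-level union
    statistics: number of distinct (merged) CNVR loci, their total span,
    and how many genes they overlap.
    """
    rows = [
        dataclasses.asdict(strain_summary(sid, cnvrs, genome))
        for sid, cnvrs in cnvrs_by_strain.items()
    ]
    tab = pd.DataFrame(rows).set_index("strain_id")
    counts = tab["n_cnvrs"].to_numpy(dtype=float)
    fracs = tab["genome_affected_fraction"].to_numpy(dtype=float)
    n = len(tab)
    sd = float(np.std(counts, ddof=1)) if n > 1 else 0.0
    agg = {
        "n_strains": n,
        "mean_n_cnvrs": float(np.mean(counts)),
        "sd_n_cnvrs": sd,
        "se_n_cnvrs": sd / np.sqrt(n) if n > 1 else 0.0,
        "median_n_cnvrs": float(np.median(counts)),
        "mean_fraction_affected": float(np.mean(fracs)),
        "median_fraction_affected": float(np.median(fracs)),
    }
    all_ivs = [
        (r.chromosome, r.start, r.end)
        for cnvrs in cnvrs_by_strain.values()
        for r in cnvrs
    ]
    if all_ivs:
        merged = diversity.merge_intervals(all_ivs)
        agg["n_union_loci"] = len(merged)
        agg["union_span_bp"] = int(sum(e - s for _, s, e in merged))
        if genes is not None:
            hit = set()
            for chrom, s, e in merged:
                for g in genes:
                    if g.chromosome == chrom and s < g.end and g.start < e:
                        hit.add(g.gene_id)
            agg["n_genes_overlapped"] = len(hit)
    else:
        agg["n_union_loci"] = 0
        agg["union_span_bp"] = 0
    return tab, agg


def size_distribution(
    cnvrs: list[calling.CNVR],
    bin_edges: list[float] | None = None,
    split_by_class: bool = True,
) -> pd.DataFrame:
    """Fraction of CNVRs per size bin, overall and per dup/del series.

    Bins are half-open (lo, hi]; each non-empty series sums to 1.
    """
    edges = list(bin_edges or DEFAULT_BIN_EDGES)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly ascending")
    labels = [
        f"({int(lo)},{int(hi)}]" if np.isfinite(hi) else f">{int(lo)}"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    if not cnvrs:
        logger.warning("no CNVRs; size distribution is empty")
        return pd.DataFrame(index=labels)

    def frac(series: list[calling.CNVR]) -> np.ndarray:
        if not series:
            return np.full(len(labels), np.nan)
        lengths = np.array([r.length for r in series], dtype=float)
        counts = np.array(
            [
                np.sum((lengths > lo) & (lengths <= hi))
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        return counts / len(lengths)

    out = pd.DataFrame(index=labels)
    out["all"] = frac(cnvrs)
    if split_by_class:
        out["dup"] = frac([r for r in cnvrs if r.event_class == "dup"])
        out["del"] = frac([r for r in cnvrs if r.event_class == "del"])
    out.index.name = "size_bin"
    return out


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------

def gene_family_view(cn_int: pd.DataFrame, family_genes: list[str]) -> GeneFamilyView:
    """Per-gene proportions of duplicated / deleted / unchanged strains.

    ``cn_int`` is a gene × strain matrix of integer-binned genic CN; a
    strain counts as duplicated for a gene when CN > 1 and deleted when
    CN < 1.  Proportions sum to 1 for every gene.
    """
    missing = [g for g in family_genes if g not in cn_int.index]
    if missing:
        raise KeyError(f"family genes absent from matrix: {missing}")
    sub = cn_int.loc[family_genes].astype(np.int64)
    vals = sub.to_numpy()
    n = vals.shape[1]
    props = pd.DataFrame(
        {
            "prop_duplicated": (vals > 1).sum(axis=1) / n,
            "prop_deleted": (vals < 1).sum(axis=1) / n,
            "prop_unchanged": (vals == 1).sum(axis=1) / n,
        },
        index=sub.index,
    )
    return GeneFamilyView(matrix=sub, proportions=props)


# ---------------------------------------------------------------------------
# Intragenic fine-window profile
# ---------------------------------------------------------------------------

def intragenic_profile(
    depth: pd.DataFrame,
    genome: GenomeModel,
    gene: genic.GeneAnnotation,
    fine_window: int = 25,
    config: calling.CallConfig | None = None,
    span_threshold: float = 0.8,
) -> tuple[pd.DataFrame, str]:
    """Fine-window CN states across a gene body, with a summary label.

    The depth track (tiled at ``fine_window``) is renormalized genome-wide,
    then restricted to windows overlapping the gene.  Labels: ``intact``
    (all windows at CN 1), ``duplicated``/``deleted`` when at least
    ``span_threshold`` of the gene's windows share that class,
    ``partial_duplication``/``partial_deletion`` for smaller affected
    fractions, and ``mixed`` when both classes occur.
    """
    config = config or calling.CallConfig(window=fine_window, min_windows=1)
    track = calling.normalize_track(
        depth,
        genome,
        window=fine_window,
        gc_bins=config.gc_bins,
        mask_telocentromeric=config.mask_telocentromeric,
        strain_id="fine",
    )
    track = calling.smooth_states(track, config.smooth)
    tab = track.data
    sel = (
        (tab["chrom"] == gene.chromosome)
        & (tab["start"] < gene.end)
        & (tab["start"] + fine_window > gene.start)
    )
    body = tab.loc[sel, ["chrom", "start", "ratio", "cn_state"]].reset_index(drop=True)
    if len(body) == 0:
        raise ValueError(f"no fine windows overlap gene {gene.gene_id}")
    states = body["cn_state"].to_numpy()
    f_dup = float((states > 1).mean())
    f_del = float((states < 1).mean())
    if f_dup == 0 and f_del == 0:
        label = "intact"
    elif f_dup > 0 and f_del > 0:
        label = "mixed"
    elif f_dup > 0:
        label = "duplicated" if f_dup >= span_threshold else "partial_duplication"
    else:
        label = "deleted" if f_del >= span_threshold else "partial_deletion"
    return body, label


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """simulate → call all strains → matrices → diversity → context → report.

    Writes every artifact under ``outdir`` and returns the manifest (also
    written as ``manifest.json``) mapping relative paths to SHA-256
    checksums; a fixed seed reproduces the manifest byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)

    gcfg = dict(config.get("genome", {}))
    genome = build_genome(
        n_chrom=int(gcfg.get("n_chromosomes", 2)),
        chrom_length=int(gcfg.get("chromosome_length", 300_000)),
        centromere_fraction=float(gcfg.get("centromere_fraction", 0.45)),
        seed=seed,
        essential_gene_spacing=gcfg.get("essential_gene_spacing"),
    )
    genome.to_tsv(outdir / "genome.tsv")

    scfg = dict(config.get("simulate", {}))
    scfg["seed"] = seed + 1
    sim = simulate.SimConfig(**scfg)
    events, tracks_raw = simulate.simulate_population(genome, sim)
    simulate.write_truth(events, outdir / "truth")
    for sid, tab in tracks_raw.items():
        simulate.write_depth(tab, outdir / "depth" / f"{sid}.tsv")

    genes_cfg = dict(config.get("genes", {}))
    genes_tab = simulate.simulate_genes(
        genome,
        mean_length=int(genes_cfg.get("mean_length", 1400)),
        mean_gap=int(genes_cfg.get("mean_gap", 600)),
        seed=seed + 2,
    )
    genes = genic.genes_from_frame(genes_tab)
    genic.write_genes_bed(genes, outdir / "genes.bed")

    ccfg = calling.CallConfig(**config.get("calling", {}))
    tracks: dict[str, calling.WindowTrack] = {}
    cnvrs_by_strain: dict[str, list[calling.CNVR]] = {}
    for sid in sorted(tracks_raw):
        track, cnvrs = calling.call_strain(
            tracks_raw[sid], genome, ccfg, strain_id=sid
        )
        tracks[sid] = track
        cnvrs_by_strain[sid] = cnvrs
        calling.write_cnvr_bed(cnvrs, outdir / "cnvr" / f"{sid}.bed")

    matrix = diversity.build_matrix(cnvrs_by_strain, sorted(cnvrs_by_strain))
    (outdir / "matrix").mkdir(exist_ok=True)
    matrix.values.to_csv(outdir / "matrix" / "loci_cn.tsv", sep="\t")
    _, cn_int = genic.genic_cn_matrix(tracks, genes)
    cn_int.to_csv(outdir / "matrix" / "genic_cn.tsv", sep="\t")

    if len(matrix.values):
        div_tab = diversity.diversity_table(matrix)
        div_tab, div_summary = diversity.select_diverse(div_tab)
    else:
        div_tab = pd.DataFrame()
        div_summary = {"both": 0, "s2_only": 0, "pic_only": 0, "union": 0}
    (outdir / "diversity").mkdir(exist_ok=True)
    div_tab.to_csv(outdir / "diversity" / "loci_diversity.tsv", sep="\t")
    _dump_json(div_summary, outdir / "diversity" / "summary.json")

    xcfg = dict(config.get("context", {}))
    zones = context.build_zones(
        genome,
        subtel_span=int(xcfg.get("subtel_span", 25_000)),
        peri_flank=int(xcfg.get("peri_flank", 7_000)),
    )
    context.write_zones_bed(zones, outdir / "context" / "zones_A.bed", "A")
    diverse_loci = (
        div_tab[div_tab["cn_diverse"]][["chrom", "start", "end"]]
        if len(div_tab)
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    ctx_summary = context.context_summary(diverse_loci, None, zones)
    _dump_json(ctx_summary, outdir / "context" / "summary.json")

    # per-chromosome diversity map at window resolution
    map_rows = []
    for c in genome.chromosomes:
        starts = genome.window_starts(c.name, ccfg.window)
        score = np.zeros(len(starts))
        if len(div_tab):
            for r in div_tab.itertuples():
                if r.chrom == c.name:
                    sel = (starts < r.end) & (starts + ccfg.window > r.start)
                    score[sel] = np.maximum(score[sel], r.pic)
        labels = [
            context.classify_locus(c.name, int(s), int(s) + ccfg.window, zones, "A")
            for s in starts
        ]
        map_rows.append(
            pd.DataFrame(
                {"chrom": c.name, "start": starts, "pic": np.round(score, 6),
                 "context": labels}
            )
        )
    pd.concat(map_rows, ignore_index=True).to_csv(
        outdir / "context" / "chromosome_map.tsv", sep="\t", index=False
    )

    summary_tab, agg = cohort_summary(cnvrs_by_strain, genome, genes)
    (outdir / "report").mkdir(exist_ok=True)
    summary_tab.to_csv(outdir / "report" / "strain_summary.tsv", sep="\t")
    _dump_json(agg, outdir / "report" / "cohort_summary.json")
    all_cnvrs = [r for cnvrs in cnvrs_by_strain.values() for r in cnvrs]
    size_distribution(all_cnvrs).to_csv(outdir / "report" / "size_distribution.tsv", sep="\t")

    manifest = {
        "seed": seed,
        "artifacts": {},
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            rel = str(path.relative_to(outdir))
            manifest["artifacts"][rel] = {
                "sha256": _sha256(path),
                "bytes": path.stat().st_size,
            }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
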