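"""Gene-level views of CN variation: overlap classification and genic CN.

A CNVR is genic when it overlaps any annotated gene by at least one
nucleotide (half-open intersection); the copy number of a gene is the
unweighted mean of the integer CN states of every fixed-size window that
overlaps the gene by at least one nucleotide.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .calling import CNVR, WindowTrack, round_half_up

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")


@dataclasses.dataclass(frozen=True)
class GenicCN:
    gene_id: str
    strain_id: str
    cn: float
    cn_int: int


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def genes_from_frame(tab: pd.DataFrame) -> list[GeneAnnotation]:
    return [
        GeneAnnotation(
            str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand)
        )
        for r in tab.itertuples()
    ]


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """BED4/BED6 gene annotations (0-based half-open)."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#")
    if tab.shape[1] < 4:
        raise ValueError(f"{path}: need at least 4 BED columns")
    out = []
    for row in tab.itertuples(index=False):
        strand = str(row[5]) if len(row) >= 6 else "."
        out.append(
            GeneAnnotation(str(row[3]), str(row[0]), int(row[1]), int(row[2]), strand)
        )
    return out


def read_genes_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """GFF3 gene annotations; 1-based inclusive coordinates are converted
    to the 0-based half-open convention used internally."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        out.append(
            GeneAnnotation(str(gid), str(feat.seqid), feat.start - 1, feat.end, feat.strand or ".")
        )
    return out


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_genes_gff3(path)
    return read_genes_bed(path)


def write_genes_bed(genes: list[GeneAnnotation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    return path


# ---------------------------------------------------------------------------
# Overlap classification
# ---------------------------------------------------------------------------

def _gene_trees(genes: list[GeneAnnotation]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end, g.gene_id)
    return trees


def classify_cnvrs(
    cnvrs: list[CNVR], genes: list[GeneAnnotation]
) -> list[str]:
    """Label each CNVR ``genic`` or ``nongenic`` (≥ 1 bp half-open overlap)."""
    trees = _gene_trees(genes)
    labels = []
    for r in cnvrs:
        tree = trees.get(r.chromosome)
        hit = bool(tree is not None and tree.overlap(r.start, r.end))
        labels.append("genic" if hit else "nongenic")
    return labels


# ---------------------------------------------------------------------------
# Genic CN
# ---------------------------------------------------------------------------

def genic_cn(track: WindowTrack, gene: GeneAnnotation) -> GenicCN:
    """Mean integer CN state over windows overlapping the gene by ≥ 1 bp.

    Partially overlapping windows contribute with full (unit) weight.
    """
    tab = track.data
    sub = tab[tab["chrom"] == gene.chromosome]
    if len(sub) == 0:
        raise ValueError(
            f"gene {gene.gene_id}: chromosome {gene.chromosome} absent from track"
        )
    starts = sub["start"].to_numpy()
    hit = (starts < gene.end) & (starts + track.window > gene.start)
    if not hit.any():
        raise ValueError(
            f"gene {gene.gene_id}: no windows overlap [{gene.start},{gene.end}) "
            f"on {gene.chromosome} (gene beyond the tiled span?)"
        )
    cn = float(sub.loc[hit, "cn_state"].mean())
    return GenicCN(gene.gene_id, track.strain_id, cn, int(round_half_up(cn)))


def genic_cn_matrix(
    tracks: dict[str, WindowTrack], genes: list[GeneAnnotation]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene × strain matrices of fractional and integer-binned genic CN."""
    sids = list(tracks)
    frac = pd.DataFrame(index=[g.gene_id for g in genes], columns=sids, dtype=float)
    for sid, track in tracks.items():
        for g in genes:
            frac.loc[g.gene_id, sid] = genic_cn(track, g).cn
    ints = pd.DataFrame(
        round_half_up(frac.to_numpy(dtype=float)), index=frac.index, columns=frac.columns
    )
    frac.index.name = ints.index.name = "gene_id"
    return frac, ints


# ---------------------------------------------------------------------------
# Duplication vs deletion comparison
# ---------------------------------------------------------------------------

def count_by_class(
    cnvrs_by_strain: dict[str, list[CNVR]], genes: list[GeneAnnotation]
) -> pd.DataFrame:
    """Per-strain counts of genic/nongenic × dup/del CNVRs."""
    rows = []
    for sid, cnvrs in cnvrs_by_strain.items():
        labels = classify_cnvrs(cnvrs, genes)
        counts = {"genic_dup": 0, "genic_del": 0, "nongenic_dup": 0, "nongenic_del": 0}
        for r, lab in zip(cnvrs, labels):
            counts[f"{lab}_{r.event_class}"] += 1
        rows.append({"strain_id": sid, **counts})
    return pd.DataFrame(rows).set_index("strain_id")


def dup_del_comparison(counts: pd.DataFrame) -> dict[str, dict[str, float | str]]:
    """Mann-Whitney U (two-sided, continuity-corrected) of dup vs del counts.

    Run separately on genic and nongenic per-strain count vectors; reports
    U, p, the two medians and the direction of the difference.
    """
    if len(counts) < 2:
        raise ValueError("need counts for at least two strains")
    report: dict[str, dict[str, float | str]] = {}
    for kind in ("genic", "nongenic"):
        dup = counts[f"{kind}_dup"].to_numpy(dtype=float)
        dele = counts[f"{kind}_del"].to_numpy(dtype=float)
        res = stats.mannwhitneyu(
            dup, dele, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        med_dup, med_del = float(np.median(dup)), float(np.median(dele))
        if med_del > med_dup:
            direction = "del > dup"
        elif med_dup > med_del:
            direction = "dup > del"
        else:
            direction = "dup == del"
        report[kind] = {
            "U": float(res.statistic),
            "p_value": float(res.pvalue),
            "median_dup": med_dup,
            "median_del": med_del,
            "direction": direction,
        }
    return report


def inframe_fraction(genic_duplications: list[CNVR]) -> float:
    """Fraction of genic duplications whose length is a multiple of three."""
    if not genic_duplications:
        logger.warning("no genic duplications; in-frame fraction undefined")
        return float("nan")
    lengths = np.array([r.length for r in genic_duplications])
    return float((lengths % 3 == 0).mean())
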