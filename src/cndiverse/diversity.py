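"""Per-locus CN diversity across strains: log10 sample variance and PIC.

PIC (polymorphic information content) at a locus is 1 − Σ f_i² over the
frequencies f_i of the distinct CN alleles observed across strains; it is 0
for a monomorphic locus and approaches 1 − 1/n when every strain carries a
different CN.  The second measure is the log10 of the across-strain sample
variance s² (n − 1 denominator); zero-variance loci have no defined
log10(s²) and are excluded from that measure's percentile pool.

A locus is "CN diverse" when it sits at or above the median of either
measure (the inclusive top-50% rule).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .calling import CNVR

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CNMatrix:
    """Loci × strains integer CN table plus locus coordinates.

    ``values``: DataFrame indexed by locus_id with one integer column per
    strain (baseline 1 where a strain has no call).  ``loci``: DataFrame
    with columns locus_id, chrom, start, end.
    """

    values: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("CN matrix must be complete")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("CN values must be non-negative")
        if len(set(self.values.columns)) != len(self.values.columns):
            raise ValueError("duplicate strain IDs")


def merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Union of intervals: connected components under ≥1 bp half-open
    overlap (abutting intervals stay separate)."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e:  # strict overlap
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def build_matrix(
    cnvrs_by_strain: dict[str, list[CNVR]],
    strain_ids: list[str] | None = None,
) -> CNMatrix:
    """Union loci across strains and fill the loci × strains CN matrix.

    Loci are the connected components of overlapping CNVR intervals pooled
    over strains.  A strain's CN at a locus is the CN of its
    largest-overlap CNVR there (baseline 1 when it has no overlapping
    call); when one strain has several CNVRs in a union locus, the largest
    overlap wins so a short high-CN fragment cannot be diluted away.
    """
    if strain_ids is None:
        strain_ids = list(cnvrs_by_strain)
    if len(set(strain_ids)) != len(strain_ids):
        raise ValueError("duplicate strain IDs")
    all_ivs = [
        (r.chromosome, r.start, r.end)
        for sid in strain_ids
        for r in cnvrs_by_strain.get(sid, [])
    ]
    if not all_ivs:
        empty = pd.DataFrame(columns=strain_ids, dtype=np.int64)
        empty.index.name = "locus_id"
        return CNMatrix(
            empty, pd.DataFrame(columns=["locus_id", "chrom", "start", "end"])
        )
    merged = merge_intervals(all_ivs)
    loci = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    loci.insert(0, "locus_id", [f"locus_{i + 1:05d}" for i in range(len(loci))])

    values = np.ones((len(loci), len(strain_ids)), dtype=np.int64)
    locus_lookup: dict[str, list[tuple[int, int, int]]] = {}
    for li, row in loci.iterrows():
        locus_lookup.setdefault(row.chrom, []).append((row.start, row.end, li))
    for sj, sid in enumerate(strain_ids):
        best_overlap = np.zeros(len(loci), dtype=np.int64)
        for r in cnvrs_by_strain.get(sid, []):
            for s, e, li in locus_lookup.get(r.chromosome, []):
                ov = min(e, r.end) - max(s, r.start)
                if ov > 0 and ov > best_overlap[li]:
                    best_overlap[li] = ov
                    values[li, sj] = r.cn
    tab = pd.DataFrame(values, index=loci["locus_id"], columns=strain_ids)
    return CNMatrix(tab, loci)


# ---------------------------------------------------------------------------
# Diversity measures
# ---------------------------------------------------------------------------

def pic(values: np.ndarray | list) -> float:
    """Polymorphic information content: 1 − Σ (count_i / n)²."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("need at least one value")
    _, counts = np.unique(values, return_counts=True)
    freqs = counts / values.size
    return float(1.0 - np.sum(freqs**2))


def log_variance(values: np.ndarray | list) -> tuple[float, float]:
    """Sample variance (n−1 denominator) and its log10.

    Returns ``(s2, log10_s2)``; log10_s2 is NaN for zero variance (the
    locus then drops out of the log10(s²) percentile pool).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values for a sample variance")
    s2 = float(np.var(values, ddof=1))
    return s2, (float(np.log10(s2)) if s2 > 0 else float("nan"))


def diversity_table(matrix: CNMatrix) -> pd.DataFrame:
    """Per-locus s², log10(s²), PIC and allele count."""
    rows = []
    for locus_id, row in matrix.values.iterrows():
        vec = row.to_numpy()
        s2, log_s2 = log_variance(vec)
        rows.append(
            {
                "locus_id": locus_id,
                "s2": s2,
                "log10_s2": log_s2,
                "pic": pic(vec),
                "n_alleles": int(len(np.unique(vec))),
            }
        )
    tab = pd.DataFrame(rows).set_index("locus_id")
    return matrix.loci.set_index("locus_id").join(tab, how="right")


def select_diverse(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag loci at or above the median of either diversity measure.

    Medians use midpoint interpolation; the log10(s²) median is taken over
    loci where it is defined.  Returns the flagged table and the summary
    counts (both measures / s²-only / PIC-only / union).
    """
    if len(table) == 0:
        raise ValueError("diversity table is empty")
    tab = table.copy()
    defined = tab["log10_s2"].dropna()
    if len(defined):
        med_s2 = float(np.median(defined.to_numpy()))
        tab["top50_s2"] = tab["log10_s2"] >= med_s2
    else:
        logger.warning("no locus has positive variance; top50_s2 all False")
        tab["top50_s2"] = False
    med_pic = float(np.median(tab["pic"].to_numpy()))
    tab["top50_pic"] = tab["pic"] >= med_pic
    tab["cn_diverse"] = tab["top50_s2"] | tab["top50_pic"]
    both = int((tab["top50_s2"] & tab["top50_pic"]).sum())
    s2_only = int((tab["top50_s2"] & ~tab["top50_pic"]).sum())
    pic_only = int((~tab["top50_s2"] & tab["top50_pic"]).sum())
    summary = {
        "both": both,
        "s2_only": s2_only,
        "pic_only": pic_only,
        "union": both + s2_only + pic_only,
    }
    return tab, summary
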