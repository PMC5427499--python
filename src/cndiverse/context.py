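"""Genomic-context classification: subtelomeres and pericentromeres.

Two subtelomere definitions are supported: a fixed span from each
chromosome end (definition A, default 25 kb) and the span from each end to
the first essential gene (definition B).  The pericentromere is the
centromere plus a flank on each side (default 7 kb).  A locus overlapping a
subtelomeric zone by at least 1 bp is subtelomeric; otherwise a locus
overlapping the pericentromeric zone is pericentromeric; everything else is
interstitial (subtelomere takes precedence when zones overlap on short
chromosomes).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from .genome import GenomeModel

logger = logging.getLogger(__name__)

SUBTELOMERIC = "subtelomeric"
PERICENTROMERIC = "pericentromeric"
INTERSTITIAL = "interstitial"


@dataclasses.dataclass
class ContextZones:
    """Per-chromosome context intervals (0-based half-open)."""

    subtel_a: dict[str, list[tuple[int, int]]]
    pericentromeric: dict[str, list[tuple[int, int]]]
    subtel_b: dict[str, list[tuple[int, int]]] | None = None

    def zones_for(self, definition: str) -> dict[str, list[tuple[int, int]]]:
        if definition == "A":
            return self.subtel_a
        if definition == "B":
            if self.subtel_b is None:
                raise ValueError(
                    "definition B requires zones built with an essential-gene list"
                )
            return self.subtel_b
        raise ValueError(f"unknown subtelomere definition {definition!r}")


def build_zones(
    genome: GenomeModel,
    subtel_span: int = 25_000,
    peri_flank: int = 7_000,
    essential_genes: dict[str, list[tuple[str, int, int]]] | None = None,
) -> ContextZones:
    """Materialize context zones, clipped to chromosome bounds.

    Definition B is built when an essential-gene list is available (either
    passed explicitly or carried by the genome model): each chromosome-end
    zone runs to the nearest boundary of the first/last essential gene; a
    chromosome with no essential gene is entirely subtelomeric under B.
    """
    if subtel_span <= 0 or peri_flank < 0:
        raise ValueError("subtel_span must be positive and peri_flank non-negative")
    essential_genes = essential_genes or genome.essential_genes

    subtel_a: dict[str, list[tuple[int, int]]] = {}
    peri: dict[str, list[tuple[int, int]]] = {}
    for c in genome.chromosomes:
        if 2 * subtel_span >= c.length:
            logger.warning(
                "%s: subtelomeric span %d covers the whole chromosome", c.name, subtel_span
            )
            subtel_a[c.name] = [(0, c.length)]
        else:
            subtel_a[c.name] = [(0, subtel_span), (c.length - subtel_span, c.length)]
        peri[c.name] = [
            (max(0, c.cen_start - peri_flank), min(c.length, c.cen_end + peri_flank))
        ]

    subtel_b = None
    if essential_genes is not None:
        subtel_b = {}
        for c in genome.chromosomes:
            genes = sorted(essential_genes.get(c.name, []), key=lambda g: g[1])
            if not genes:
                logger.warning("%s: no essential gene; whole chromosome is "
                               "subtelomeric under definition B", c.name)
                subtel_b[c.name] = [(0, c.length)]
                continue
            left_end = genes[0][1]
            right_start = genes[-1][2]
            zones = []
            if left_end > 0:
                zones.append((0, left_end))
            if right_start < c.length:
                zones.append((right_start, c.length))
            subtel_b[c.name] = zones
    return ContextZones(subtel_a=subtel_a, pericentromeric=peri, subtel_b=subtel_b)


def _overlaps(start: int, end: int, zones: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in zones)


def classify_locus(
    chromosome: str,
    start: int,
    end: int,
    zones: ContextZones,
    definition: str = "A",
) -> str:
    """Context label for one locus (≥ 1 bp overlap; subtelomere wins)."""
    if _overlaps(start, end, zones.zones_for(definition).get(chromosome, [])):
        return SUBTELOMERIC
    if _overlaps(start, end, zones.pericentromeric.get(chromosome, [])):
        return PERICENTROMERIC
    return INTERSTITIAL


def classify_table(
    table: pd.DataFrame, zones: ContextZones, definition: str = "A"
) -> pd.Series:
    """Vector of context labels for a table with chrom/start/end columns."""
    labels = [
        classify_locus(r.chrom, r.start, r.end, zones, definition)
        for r in table.itertuples()
    ]
    return pd.Series(labels, index=table.index, name=f"context_{definition}")


def _summarize(table: pd.DataFrame, zones: ContextZones, definition: str) -> dict:
    n = len(table)
    if n == 0:
        logger.warning("no loci to summarize; fractions undefined")
        return {"n_total": 0}
    labels = classify_table(table, zones, definition)
    n_sub = int((labels == SUBTELOMERIC).sum())
    n_peri = int((labels == PERICENTROMERIC).sum())
    return {
        "n_total": n,
        "n_subtelomeric": n_sub,
        "n_pericentromeric": n_peri,
        "n_interstitial": n - n_sub - n_peri,
        "fraction_subtelomeric": n_sub / n,
        "pct_subtelomeric": round(100.0 * n_sub / n, 1),
        "fraction_pericentromeric": n_peri / n,
        "pct_pericentromeric": round(100.0 * n_peri / n, 1),
    }


def context_summary(
    diverse_loci: pd.DataFrame,
    diverse_genes: pd.DataFrame | None,
    zones: ContextZones,
) -> dict:
    """Counts and fractions of diverse loci/genes per context, per definition.

    Input tables need chrom/start/end columns (loci already filtered to the
    CN-diverse set).  Fractions are also given as percentages rounded to
    0.1%.
    """
    definitions = ["A"] + (["B"] if zones.subtel_b is not None else [])
    out: dict = {}
    for d in definitions:
        entry = {"loci": _summarize(diverse_loci, zones, d)}
        if diverse_genes is not None:
            entry["genes"] = _summarize(diverse_genes, zones, d)
        out[f"definition_{d}"] = entry
    return out


def write_zones_bed(zones: ContextZones, path: str | Path, definition: str = "A") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom, ivs in sorted(zones.zones_for(definition).items()):
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\tsubtelomere_{definition}\n")
        for chrom, ivs in sorted(zones.pericentromeric.items()):
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\tpericentromere\n")
    return path
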