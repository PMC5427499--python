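"""Genome model: chromosome layout, centromeres, essential-gene anchors.

A :class:`GenomeModel` fixes the coordinate system every other stage works in.
Coordinates are 0-based half-open throughout, window grids are fixed-step
tilings starting at 0 (a partial tail window shorter than the step is dropped).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Minimum chromosome length able to host a subtelomeric zone at each end.
MIN_CHROM_LENGTH = 2 * 25_000


@dataclasses.dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, length (bp) and centromere interval."""

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise ValueError(
                f"{self.name}: centromere [{self.cen_start},{self.cen_end}) "
                f"must lie strictly inside the chromosome (length {self.length})"
            )


@dataclasses.dataclass
class GenomeModel:
    """Ordered chromosomes plus optional essential-gene anchors.

    ``essential_genes`` maps chromosome name to a list of
    ``(gene_id, start, end)`` tuples sorted by start; they anchor the
    "end to first essential gene" subtelomere definition.
    """

    chromosomes: list[Chromosome]
    essential_genes: dict[str, list[tuple[str, int, int]]] | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if self.essential_genes is not None:
            lengths = dict(zip(names, (c.length for c in self.chromosomes)))
            for chrom, genes in self.essential_genes.items():
                if chrom not in lengths:
                    raise ValueError(f"essential genes on unknown chromosome {chrom}")
                for gid, s, e in genes:
                    if not (0 <= s < e <= lengths[chrom]):
                        raise ValueError(
                            f"essential gene {gid} [{s},{e}) outside {chrom}"
                        )

    # -- lookups -----------------------------------------------------------
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    # -- window grid -------------------------------------------------------
    def n_windows(self, name: str, window: int) -> int:
        return self.chromosome(name).length // window

    def window_starts(self, name: str, window: int) -> np.ndarray:
        """0-based start coordinates of the fixed-step window tiling."""
        return np.arange(self.n_windows(name, window), dtype=np.int64) * window

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the chromosome table (and essential genes alongside)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = [
            (c.name, c.length, c.cen_start, c.cen_end) for c in self.chromosomes
        ]
        pd.DataFrame(
            rows, columns=["chrom", "length", "cen_start", "cen_end"]
        ).to_csv(path, sep="\t", index=False)
        if self.essential_genes is not None:
            erows = [
                (chrom, s, e, gid)
                for chrom, genes in self.essential_genes.items()
                for gid, s, e in genes
            ]
            pd.DataFrame(
                erows, columns=["chrom", "start", "end", "gene_id"]
            ).to_csv(path.with_suffix(".essential.tsv"), sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeModel":
        path = Path(path)
        tab = pd.read_csv(path, sep="\t")
        chroms = [
            Chromosome(str(r.chrom), int(r.length), int(r.cen_start), int(r.cen_end))
            for r in tab.itertuples()
        ]
        essential = None
        epath = path.with_suffix(".essential.tsv")
        if epath.exists():
            etab = pd.read_csv(epath, sep="\t")
            essential = {}
            for r in etab.itertuples():
                essential.setdefault(str(r.chrom), []).append(
                    (str(r.gene_id), int(r.start), int(r.end))
                )
            for genes in essential.values():
                genes.sort(key=lambda g: g[1])
        return cls(chroms, essential)


def build_genome(
    n_chrom: int,
    chrom_length: int,
    centromere_fraction: float = 0.4,
    seed: int = 0,
    centromere_width: int = 500,
    jitter_fraction: float = 0.02,
    essential_gene_spacing: int | None = None,
) -> GenomeModel:
    """Construct a synthetic genome with one centromere per chromosome.

    The centromere midpoint is placed at ``centromere_fraction`` of each
    chromosome's length, jittered uniformly by ``±jitter_fraction`` of the
    length.  When ``essential_gene_spacing`` is given, 1.5 kb essential-gene
    anchors are dropped at roughly that spacing along each chromosome (the
    first one at about one spacing from the left end), enabling the
    end-to-first-essential-gene subtelomere definition.

    Deterministic for a fixed seed.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < MIN_CHROM_LENGTH:
        raise ValueError(
            f"chrom_length {chrom_length} too small to host a 25 kb "
            f"subtelomeric zone at each end (need >= {MIN_CHROM_LENGTH})"
        )
    if not (0.0 < centromere_fraction < 1.0):
        raise ValueError("centromere_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    chroms: list[Chromosome] = []
    essential: dict[str, list[tuple[str, int, int]]] = {}
    for i in range(n_chrom):
        name = f"chr{i + 1}"
        jitter = rng.uniform(-jitter_fraction, jitter_fraction) * chrom_length
        mid = int(centromere_fraction * chrom_length + jitter)
        half = centromere_width // 2
        cen_start = max(1, mid - half)
        cen_end = min(chrom_length - 1, cen_start + centromere_width)
        chroms.append(Chromosome(name, chrom_length, cen_start, cen_end))

        if essential_gene_spacing is not None:
            genes: list[tuple[str, int, int]] = []
            pos = int(rng.uniform(0.6, 1.4) * essential_gene_spacing)
            k = 0
            while pos + 1500 < chrom_length:
                iv = (pos, pos + 1500)
                # keep anchors off the centromere so zones stay unambiguous
                if not (iv[0] < cen_end and cen_start < iv[1]):
                    genes.append((f"{name}_ess{k}", iv[0], iv[1]))
                    k += 1
                pos += int(rng.uniform(0.6, 1.4) * essential_gene_spacing)
            essential[name] = genes

    return GenomeModel(chroms, essential or None)
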