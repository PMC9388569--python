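"""Deterministic toy reference genome, chromosome arms and gene models.

Real analyses of diffuse glioma genomes run against GRCh38.  For simulation
and testing this package carries a small synthetic genome (~5 Mb over five
chromosomes) whose geography mirrors the loci that matter in
oligodendroglioma biology: the 1p/19q arms whose codeletion defines the
entity, chromosome 7 (gained in IDH-wildtype glioblastoma; carries
*CNTNAP2* on 7q), chromosome 9 (carries *PTPRD* on 9p) and chromosome 10
(lost in IDH-wildtype glioblastoma).  The sequence is generated from a
fixed internal seed, so trinucleotide contexts, window counts and gene
overlaps are byte-stable across runs and machines without any download.

Coordinates follow BED convention (0-based, half-open) for genes, exons and
arms; variant positions elsewhere in the package are 1-based (VCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

_GENOME_SEED = 94177  # fixed: the reference is a constant, not a simulation draw

#: chromosome name -> (length, centromere midpoint); all multiples of 1 kb
_CHROMS: dict[str, tuple[int, int]] = {
    "chr1": (1_200_000, 600_000),
    "chr7": (1_400_000, 600_000),
    "chr9": (1_000_000, 500_000),
    "chr10": (800_000, 400_000),
    "chr19": (800_000, 400_000),
}


@dataclass(frozen=True)
class GeneModel:
    """A gene span with ordered exons and a transcription start site.

    ``exons`` are (start, end) in genomic order, 0-based half-open;
    ``coding_lengths`` gives the coding nucleotides contributed by each exon
    (same genomic order).  Transcript order is genomic order for ``+`` genes
    and reversed for ``-`` genes.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    coding_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ValueError(f"{self.gene_id}: exons must be ordered, non-overlapping and within the span")
            prev = e

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def transcript_exon_index(self, genomic_index: int) -> int:
        """1-based exon number in transcript (5'->3') order."""
        if self.strand == "+":
            return genomic_index + 1
        return len(self.exons) - genomic_index

    def intron(self, transcript_index: int) -> tuple[int, int]:
        """Genomic interval of the intron following the given transcript exon."""
        order = range(len(self.exons)) if self.strand == "+" else range(len(self.exons) - 1, -1, -1)
        order = list(order)
        i = order[transcript_index - 1]
        j = order[transcript_index]
        lo, hi = sorted([i, j])
        return self.exons[lo][1], self.exons[hi][0]


@dataclass
class ToyGenome:
    """Sequences, arm definitions and gene models for the toy genome."""

    chroms: dict[str, str]
    arms: pd.DataFrame  # columns: chrom, start, end, arm
    genes: list[GeneModel] = field(default_factory=list)

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene {gene_id!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def chrom_length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def arm_interval(self, arm: str) -> tuple[str, int, int]:
        row = self.arms.loc[self.arms["arm"] == arm]
        if row.empty:
            raise KeyError(f"unknown chromosome arm {arm!r}")
        r = row.iloc[0]
        return r["chrom"], int(r["start"]), int(r["end"])

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_arms_bed(self, path: str | Path) -> None:
        self.arms.to_csv(path, sep="\t", header=False, index=False)

    def write_genes_bed12(self, path: str | Path) -> None:
        """Gene models as BED12 (block starts relative to gene start)."""
        rows = []
        for g in self.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            rows.append(
                [g.chrom, g.start, g.end, g.gene_id, 0, g.strand, g.start, g.end, "0", len(g.exons), sizes, starts]
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _make_gene(gene_id, chrom, strand, first_start, offsets, lengths, coding) -> GeneModel:
    exons = tuple((first_start + o, first_start + o + l) for o, l in zip(offsets, lengths))
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=exons[0][0],
        end=exons[-1][1],
        exons=exons,
        coding_lengths=tuple(coding),
    )


def _toy_genes() -> list[GeneModel]:
    # CNTNAP2 analog: large 7q gene, 14 exons; coding lengths chosen so that
    # exons 2-8 (774 nt) and 9-12 (459 nt) are each divisible by 3, mirroring
    # in-frame intragenic deletions seen in relapsed tumors.
    cntnap2 = _make_gene(
        "CNTNAP2", "chr7", "+", 900_000,
        offsets=[0, 15_000, 30_000, 42_000, 55_000, 68_000, 80_000, 95_000,
                 110_000, 125_000, 140_000, 155_000, 170_000, 195_000],
        lengths=[100, 120, 90, 150, 99, 120, 87, 108, 93, 120, 150, 96, 84, 204],
        coding=[100, 120, 90, 150, 99, 120, 87, 108, 93, 120, 150, 96, 84, 204],
    )
    # PTPRD analog: 9p gene on the minus strand, TSS at the genomic end.
    ptprd = _make_gene(
        "PTPRD", "chr9", "-", 200_000,
        offsets=[0, 22_000, 45_000, 70_000, 95_000, 120_000, 145_000, 165_000, 180_000, 198_000],
        lengths=[141, 120, 90, 120, 150, 99, 120, 90, 120, 150],
        coding=[141, 120, 90, 120, 150, 99, 120, 90, 120, 150],
    )
    # Small companions on the codeleted arms (FUBP1 on 1p, CIC on 19q).
    fubp1 = _make_gene(
        "FUBP1", "chr1", "+", 100_000,
        offsets=[0, 5_000, 11_000, 18_000, 26_000, 33_000],
        lengths=[120, 150, 90, 120, 150, 120],
        coding=[120, 150, 90, 120, 150, 120],
    )
    cic = _make_gene(
        "CIC", "chr19", "-", 600_000,
        offsets=[0, 6_000, 13_000, 21_000, 30_000],
        lengths=[150, 120, 90, 150, 120],
        coding=[150, 120, 90, 150, 120],
    )
    return [cntnap2, ptprd, fubp1, cic]


@lru_cache(maxsize=1)
def build_toy_genome() -> ToyGenome:
    """Build (once) the deterministic toy genome shared by all simulations."""
    rng = np.random.default_rng(_GENOME_SEED)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    chroms = {}
    for name, (length, _cen) in _CHROMS.items():
        chroms[name] = rng.choice(bases, size=length).tobytes().decode("ascii")
    arm_rows = []
    for name, (length, cen) in _CHROMS.items():
        num = name[3:]
        arm_rows.append([name, 0, cen, f"{num}p"])
        arm_rows.append([name, cen, length, f"{num}q"])
    arms = pd.DataFrame(arm_rows, columns=["chrom", "start", "end", "arm"])
    return ToyGenome(chroms=chroms, arms=arms, genes=_toy_genes())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader returning uppercase sequences keyed by contig."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence line before any header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def read_arms_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "arm"], comment="#")
    return df
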