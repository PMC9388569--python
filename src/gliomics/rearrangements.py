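"""Structural-variant filtering and intragenic rearrangement annotation.

SV records are BEDPE-shaped: two breakpoints, each (chrom, 0-based pos,
orientation), plus read-support evidence.  Three filters are provided:

* read support (``unique_reads >= 5`` by default),
* cohort recurrence: an SV seen (within a matching window, with the same
  orientations) in strictly more than 30% of a reference cohort's samples
  is treated as a recurrent artifact and removed,
* an evidence filter for Delly-style cohort calls: keep records whose
  junction-spanning read fraction is >= 0.2 *or* whose variant read-pair
  count is >= 4 (inclusive OR).

All filters are pure row predicates and commute with one another.

An SV is *intragenic* for a gene when both breakpoints fall on the gene's
chromosome inside its span.  With breakpoints ordered so pos1 < pos2, the
orientation pair classifies the event: (+,-) deletion, (-,+) duplication,
(+,+) or (-,-) inversion (the BEDPE strand-pair reading of paired-end
evidence).  Classification uses breakpoint orientations only and is
independent of the gene's strand.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel

SV_COLUMNS = [
    "sample_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
    "unique_reads", "junction_fraction", "variant_read_pairs",
]


def canonical(svs: pd.DataFrame) -> pd.DataFrame:
    """Order each record's breakpoints by (chrom, pos).

    Breakpoints are swapped as (chrom, pos, strand) units, so orientation
    semantics are preserved.
    """
    out = svs.copy()
    swap = (out["chrom1"] > out["chrom2"]) | (
        (out["chrom1"] == out["chrom2"]) & (out["pos1"] > out["pos2"])
    )
    for a, b in [("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")]:
        av, bv = out.loc[swap, a].copy(), out.loc[swap, b].copy()
        out.loc[swap, a], out.loc[swap, b] = bv, av
    return out


def filter_support(svs: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Keep records supported by at least ``min_reads`` unique reads (inclusive)."""
    if svs.empty:
        return svs.copy()
    return svs.loc[svs["unique_reads"] >= min_reads].copy()


def filter_recurrent(
    svs: pd.DataFrame,
    cohort: pd.DataFrame,
    max_fraction: float = 0.30,
    match_window: int = 100,
) -> pd.DataFrame:
    """Remove SVs recurring in strictly more than ``max_fraction`` of cohort samples.

    Two records match when both breakpoints lie within ``match_window`` bp
    and orientations agree (after canonical breakpoint ordering).  Presence
    in exactly ``max_fraction`` of samples is *not* "over" the threshold
    and is retained.  An empty cohort leaves the input unchanged.
    """
    if svs.empty or cohort.empty:
        return svs.copy()
    n_cohort = cohort["sample_id"].nunique()
    svs_c = canonical(svs)
    coh = canonical(cohort)
    c1 = coh["chrom1"].to_numpy()
    c2 = coh["chrom2"].to_numpy()
    p1 = coh["pos1"].to_numpy()
    p2 = coh["pos2"].to_numpy()
    s1 = coh["strand1"].to_numpy()
    s2 = coh["strand2"].to_numpy()
    sample = coh["sample_id"].to_numpy()
    keep = []
    for row in svs_c.itertuples(index=False):
        m = (
            (c1 == row.chrom1) & (c2 == row.chrom2)
            & (np.abs(p1 - row.pos1) <= match_window) & (np.abs(p2 - row.pos2) <= match_window)
            & (s1 == row.strand1) & (s2 == row.strand2)
        )
        n_samples = len(set(sample[m]))
        keep.append(n_samples / n_cohort <= max_fraction)
    return svs.loc[np.array(keep)].copy()


def filter_tcga(svs: pd.DataFrame, min_fraction: float = 0.2, min_pairs: int = 4) -> pd.DataFrame:
    """Evidence filter: junction fraction >= ``min_fraction`` OR >= ``min_pairs`` read pairs.

    Records missing both evidence fields cannot be evaluated; they are
    dropped with a warning reporting how many were rejected.
    """
    if svs.empty:
        return svs.copy()
    jf = pd.to_numeric(svs["junction_fraction"], errors="coerce")
    vp = pd.to_numeric(svs["variant_read_pairs"], errors="coerce")
    missing_both = jf.isna() & vp.isna()
    if missing_both.any():
        warnings.warn(
            f"{int(missing_both.sum())} SV record(s) lacked both junction_fraction and "
            "variant_read_pairs and were rejected",
            stacklevel=2,
        )
    keep = jf.ge(min_fraction).fillna(False) | vp.ge(min_pairs).fillna(False)
    return svs.loc[keep].copy()


def classify_breakpoints(chrom1, pos1, strand1, chrom2, pos2, strand2) -> str:
    """BEDPE orientation-pair event class for an ordered same-chromosome pair."""
    if chrom1 != chrom2:
        return "other"
    if pos1 > pos2:
        pos1, strand1, pos2, strand2 = pos2, strand2, pos1, strand1
    pair = (strand1, strand2)
    if pair == ("+", "-"):
        return "deletion"
    if pair == ("-", "+"):
        return "duplication"
    if strand1 == strand2:
        return "inversion"
    return "other"


def annotate_intragenic(svs: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Report (SV, gene, event class) for SVs with both breakpoints inside one gene.

    Returns a table carrying the original SV index plus ``gene_id`` and
    ``event_class``.  SVs intragenic to no gene are omitted.
    """
    rows = []
    for idx, row in svs.iterrows():
        for g in genes:
            if (
                row["chrom1"] == g.chrom
                and row["chrom2"] == g.chrom
                and g.start <= row["pos1"] < g.end
                and g.start <= row["pos2"] < g.end
            ):
                rows.append(
                    {
                        "sv_index": idx,
                        "sample_id": row.get("sample_id", ""),
                        "gene_id": g.gene_id,
                        "chrom": g.chrom,
                        "start": int(min(row["pos1"], row["pos2"])),
                        "end": int(max(row["pos1"], row["pos2"])),
                        "event_class": classify_breakpoints(
                            row["chrom1"], row["pos1"], row["strand1"],
                            row["chrom2"], row["pos2"], row["strand2"],
                        ),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sv_index", "sample_id", "gene_id", "chrom", "start", "end", "event_class"]
    )


def affected_exons(
    interval: tuple[int, int], gene: GeneModel, event_class: str = "deletion"
) -> tuple[list[int], bool | None]:
    """Exons hit by an intragenic event, and whether a deletion is in-frame.

    For a deletion, exons *fully contained* in the deleted interval are
    listed (1-based indices in transcript order) and ``in_frame`` is true
    iff the summed coding length removed is divisible by 3.  For other
    event classes the overlapping exons are listed and ``in_frame`` is
    not applicable (None).
    """
    start, end = interval
    hit: list[int] = []
    removed_coding = 0
    for gi, (es, ee) in enumerate(gene.exons):
        if event_class == "deletion":
            contained = es >= start and ee <= end
            if contained:
                hit.append(gene.transcript_exon_index(gi))
                removed_coding += gene.coding_lengths[gi]
        else:
            if es < end and start < ee:
                hit.append(gene.transcript_exon_index(gi))
    hit.sort()
    if event_class != "deletion":
        return hit, None
    return hit, removed_coding % 3 == 0


def annotate_enhancer_overlap(svs: pd.DataFrame, enhancers: pd.DataFrame) -> pd.Series:
    """Optional: does either breakpoint-spanned interval touch a regulatory BED interval.

    ``enhancers`` needs columns chrom, start, end.  Returns a boolean
    Series aligned to ``svs``; interchromosomal records are False.
    """
    flags = []
    for row in svs.itertuples(index=False):
        if row.chrom1 != row.chrom2:
            flags.append(False)
            continue
        lo, hi = sorted([row.pos1, row.pos2])
        sub = enhancers[enhancers["chrom"] == row.chrom1]
        flags.append(bool(((sub["start"] < hi) & (lo < sub["end"])).any()))
    return pd.Series(flags, index=svs.index)


def write_bedpe(svs: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write SVs as 10-column BEDPE plus named evidence columns."""
    cols = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
        "strand1", "strand2", "sample_id", "unique_reads", "junction_fraction", "variant_read_pairs",
    ]
    out = pd.DataFrame(
        {
            "chrom1": svs["chrom1"],
            "start1": svs["pos1"],
            "end1": svs["pos1"] + 1,
            "chrom2": svs["chrom2"],
            "start2": svs["pos2"],
            "end2": svs["pos2"] + 1,
            "name": svs.get("name", pd.Series(["."] * len(svs), index=svs.index)),
            "score": ".",
            "strand1": svs["strand1"],
            "strand2": svs["strand2"],
            "sample_id": svs["sample_id"],
            "unique_reads": svs["unique_reads"],
            "junction_fraction": svs["junction_fraction"],
            "variant_read_pairs": svs["variant_read_pairs"],
        }
    )
    with open(path, "w") as fh:
        if header:
            fh.write(f"## {header}\n")
        fh.write("#" + "\t".join(cols) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Read the BEDPE dialect written by :func:`write_bedpe`."""
    names = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
        "strand1", "strand2", "sample_id", "unique_reads", "junction_fraction", "variant_read_pairs",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "chrom1": df["chrom1"],
            "pos1": df["start1"].astype(int),
            "strand1": df["strand1"],
            "chrom2": df["chrom2"],
            "pos2": df["start2"].astype(int),
            "strand2": df["strand2"],
            "unique_reads": df["unique_reads"].astype(int),
            "junction_fraction": df["junction_fraction"],
            "variant_read_pairs": df["variant_read_pairs"],
        }
    )
    return out
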