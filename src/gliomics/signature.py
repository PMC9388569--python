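"""Trinucleotide substitution spectra and POLE-hypermutator scoring.

Single-nucleotide substitutions are binned into the standard 96 channels:
six pyrimidine-reference substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
by the 16 combinations of 5' and 3' flanking bases.  Purine-reference
calls are reverse-complemented onto the pyrimidine strand, so counting is
strand-invariant.  Channel labels follow the COSMIC convention, e.g.
``T[C>A]T`` for a TCT>TAT substitution.

POLE exonuclease-domain mutant tumors show a characteristic hypermutator
spectrum concentrated in TCT>TAT, TCG>TTG and TTT>TGT; the POLE score is
the fraction of a sample's substitutions in those three channels, and a
sample is flagged as a hypermutator when both its mutation load and POLE
score clear configurable thresholds.
"""

from __future__ import annotations

import pandas as pd

SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
BASES = "ACGT"
#: the 96 channels in COSMIC order (substitution-major, then 5' base, then 3' base)
CHANNELS = [f"{f}[{r}>{a}]{t}" for (r, a) in SUBSTITUTIONS for f in BASES for t in BASES]
#: TCT>TAT, TCG>TTG, TTT>TGT — the POLE-mutant hypermutator channels
POLE_CHANNELS = ("T[C>A]T", "T[C>T]G", "T[T>G]T")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Slice [start0, end0) from a mapping of chrom -> sequence (str or FASTA record)."""
    seq = reference[chrom]
    return str(seq[start0:end0]).upper()


def trinucleotide_context(chrom: str, pos: int, ref: str, alt: str, reference) -> str:
    """Channel label for a single-base substitution at 1-based ``pos``.

    The reference base must match ``ref``; both flanking bases must exist.
    Purine-reference substitutions are reverse-complemented, so the result
    is always pyrimidine-centered, formatted ``5'[ref>alt]3'``.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        raise ValueError(f"only single-nucleotide substitutions are accepted, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    chrom_len = len(reference[chrom])
    if pos < 2 or pos > chrom_len - 1:
        raise ValueError(f"{chrom}:{pos} lacks a flanking base (contig length {chrom_len})")
    tri = _fetch(reference, chrom, pos - 2, pos + 1)
    if tri[1] != ref:
        raise ValueError(f"ref mismatch at {chrom}:{pos}: call says {ref!r}, reference has {tri[1]!r}")
    if ref in "AG":
        tri = tri.translate(_COMPLEMENT)[::-1]
        alt = alt.translate(_COMPLEMENT)
    return f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"


def count_channels(calls: pd.DataFrame, reference) -> pd.Series:
    """96-channel substitution counts for a set of SNV calls.

    No implicit deduplication: a call listed twice is counted twice.  Any
    context error is re-raised naming the offending call.
    """
    counts = pd.Series(0, index=CHANNELS, dtype=int)
    for row in calls.itertuples(index=False):
        try:
            ch = trinucleotide_context(row.chrom, int(row.pos), row.ref, row.alt, reference)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"call {row.chrom}:{row.pos} {row.ref}>{row.alt}: {exc}") from exc
        counts[ch] += 1
    return counts


def pole_signature_score(counts: pd.Series) -> float:
    """Fraction of substitutions in the three POLE hypermutator channels."""
    total = int(counts.sum())
    if total == 0:
        raise ValueError("POLE score undefined for an empty spectrum (total = 0)")
    return float(sum(counts[ch] for ch in POLE_CHANNELS)) / total


def flag_hypermutator(counts: pd.Series, min_mutations: int = 500, min_score: float = 0.2) -> bool:
    """True iff mutation load and POLE score both clear their thresholds."""
    total = int(counts.sum())
    if total == 0 or total < min_mutations:
        return False
    return pole_signature_score(counts) >= min_score


def signature_matrix(per_sample: dict[str, pd.Series]) -> pd.DataFrame:
    """Assemble per-sample spectra into a 96 x samples table."""
    return pd.DataFrame({sid: counts.reindex(CHANNELS) for sid, counts in per_sample.items()})
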