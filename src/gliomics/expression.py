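"""Count normalization and paired primary/relapse expression contrasts.

Normalization is the median-of-ratios scheme: a sample's size factor is
the median, over genes with positive counts in every sample, of the ratio
of its count to the gene's geometric mean across samples.  This removes
library-size differences while being robust to a minority of
differentially expressed genes.  Paired fold changes (relapse vs primary)
are then ratios of normalized counts, with a pseudo-count of 1 added to
both sides when either is zero.

Full differential-expression inference (dispersion estimation, shrinkage,
Wald tests) is deliberately out of scope; matrices of already-normalized
counts can be used directly by passing unit size factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Requires at least one gene with a positive count in every sample.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples; size factors undefined")
    sub = counts.loc[positive].astype(float)
    geomean = np.exp(np.log(sub).mean(axis=1))
    return sub.div(geomean, axis=0).median(axis=0)


@dataclass
class FoldChange:
    gene: str
    primary: float  # normalized count
    relapse: float
    fold_change: float


def paired_fold_change(
    counts: pd.DataFrame,
    gene: str,
    sample_primary: str,
    sample_relapse: str,
    factors: pd.Series | None = None,
) -> FoldChange:
    """Normalized primary/relapse counts and their relapse/primary ratio.

    When either normalized count is zero, a pseudo-count of 1 is added to
    both before forming the ratio, keeping the fold change finite.
    """
    if gene not in counts.index:
        raise KeyError(f"gene {gene!r} not in the count matrix")
    for s in (sample_primary, sample_relapse):
        if s not in counts.columns:
            raise KeyError(f"sample {s!r} not in the count matrix")
    if factors is None:
        factors = size_factors(counts)
    p = float(counts.loc[gene, sample_primary]) / float(factors[sample_primary])
    r = float(counts.loc[gene, sample_relapse]) / float(factors[sample_relapse])
    if p == 0.0 or r == 0.0:
        fc = (r + 1.0) / (p + 1.0)
    else:
        fc = r / p
    return FoldChange(gene=gene, primary=p, relapse=r, fold_change=fc)
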