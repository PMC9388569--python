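"""Somatic-variant filtering for paired primary/relapse tumor cohorts.

Candidate somatic calls are kept in a pandas DataFrame with one row per
call per sample (columns in :data:`VARIANT_COLUMNS`).  Three filters are
applied in the pipeline:

1. read-support / VAF thresholds (``alt_reads >= 3`` and ``VAF >= 0.10``
   by default),
2. a cross-patient chi-squared artifact test: under the null that every
   patient shares one underlying allele fraction at a site (the behavior
   of a recurrent technical artifact), pooled per-patient alt/ref counts
   form a 2 x P contingency table; only sites where the null is *rejected*
   (heterogeneous fractions, i.e. genuine patient-specific somatic events)
   are retained,
3. exclusion of known germline sites from a blacklist (gnomAD-style
   sites-only VCF).

Variant coordinates are 1-based (VCF convention).  The support and
germline filters are pure row predicates, so their composition is
order-independent.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]
VARIANT_COLUMNS = VARIANT_KEY + ["sample_id", "patient_id", "timepoint", "alt_reads", "ref_reads", "vaf"]


def with_vaf(calls: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the ``vaf`` column (re)computed from read counts."""
    out = calls.copy()
    depth = out["alt_reads"] + out["ref_reads"]
    if (depth <= 0).any():
        raise ValueError("every call must have alt_reads + ref_reads > 0")
    out["vaf"] = out["alt_reads"] / depth
    return out


def filter_by_support(calls: pd.DataFrame, min_alt: int = 3, min_vaf: float = 0.10) -> pd.DataFrame:
    """Keep calls with ``alt_reads >= min_alt`` and ``VAF >= min_vaf``.

    Both boundaries are inclusive ("at least 3 unique supporting reads",
    "10% or higher").  Row order is preserved.
    """
    if calls.empty:
        return calls.copy()
    if (calls["alt_reads"] < 0).any() or (calls["ref_reads"] < 0).any():
        raise ValueError("read counts must be non-negative")
    vaf = calls["alt_reads"] / (calls["alt_reads"] + calls["ref_reads"])
    return calls.loc[(calls["alt_reads"] >= min_alt) & (vaf >= min_vaf)].copy()


def cohort_variant_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Pool each patient's primary+relapse reads per variant.

    Returns one row per (variant key, patient) with ``alt_sum`` and
    ``total_sum``.  Rows with ``alt_reads = 0`` may be included in ``calls``
    to represent reference-only coverage of a site in a patient; they
    contribute to ``total_sum`` only.
    """
    g = calls.groupby(VARIANT_KEY + ["patient_id"], sort=False)
    out = g.agg(alt_sum=("alt_reads", "sum"), ref_sum=("ref_reads", "sum")).reset_index()
    out["total_sum"] = out["alt_sum"] + out["ref_sum"]
    return out.drop(columns="ref_sum")


def artifact_chisq(alt_sums, total_sums) -> tuple[float, float, int]:
    """Pearson chi-squared test of one shared allele fraction across patients.

    ``alt_sums``/``total_sums`` are per-patient pooled counts.  Patients with
    ``total_sum = 0`` are excluded; at least two usable patients are
    required.  With pooled fraction ``f = sum(alt)/sum(total)``, the
    statistic sums ``(obs - exp)^2 / exp`` over the alt and ref cells of
    every patient and is referred to a chi-squared distribution with
    ``P - 1`` degrees of freedom.  Degenerate margins (``f`` of 0 or 1)
    yield statistic 0, p-value 1.
    """
    alt = np.asarray(alt_sums, dtype=float)
    total = np.asarray(total_sums, dtype=float)
    if alt.shape != total.shape:
        raise ValueError("alt_sums and total_sums must have equal length")
    if (alt < 0).any() or (total < alt).any():
        raise ValueError("require 0 <= alt_sum <= total_sum per patient")
    usable = total > 0
    alt, total = alt[usable], total[usable]
    n_patients = len(alt)
    if n_patients < 2:
        raise ValueError("artifact test undefined: fewer than 2 patients with reads at this site")
    dof = n_patients - 1
    f = alt.sum() / total.sum()
    if f == 0.0 or f == 1.0:
        return 0.0, 1.0, dof
    exp_alt = f * total
    exp_ref = (1.0 - f) * total
    ref = total - alt
    stat = float((((alt - exp_alt) ** 2) / exp_alt).sum() + (((ref - exp_ref) ** 2) / exp_ref).sum())
    return stat, float(stats.chi2.sf(stat, dof)), dof


def filter_artifacts(
    calls: pd.DataFrame, cohort_counts: pd.DataFrame, alpha: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove shared-artifact variants by the cross-patient chi-squared test.

    A call is retained iff the test rejects the shared-fraction null at
    ``alpha`` (p < alpha): heterogeneous per-patient fractions indicate a
    genuine patient-specific somatic event, whereas an artifact reproduces
    the same fraction in every patient.  Returns ``(retained_calls, audit)``
    where the audit table lists statistic, df, p and decision per variant.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if calls.empty:
        audit = pd.DataFrame(columns=["variant", "statistic", "df", "p", "decision"])
        return calls.copy(), audit
    grouped = {
        key: (sub["alt_sum"].to_numpy(), sub["total_sum"].to_numpy())
        for key, sub in cohort_counts.groupby(VARIANT_KEY, sort=False)
    }
    audit_rows = []
    pvals = {}
    keys = calls[VARIANT_KEY].drop_duplicates().itertuples(index=False, name=None)
    for key in keys:
        if key not in grouped:
            chrom, pos, ref, alt = key
            raise KeyError(f"variant {chrom}:{pos} {ref}>{alt} missing from cohort counts")
        stat, p, dof = artifact_chisq(*grouped[key])
        pvals[key] = p
        chrom, pos, ref, alt = key
        audit_rows.append(
            {
                "variant": f"{chrom}:{pos}:{ref}>{alt}",
                "statistic": stat,
                "df": dof,
                "p": p,
                "decision": "retained" if p < alpha else "removed_artifact",
            }
        )
    audit = pd.DataFrame(audit_rows)
    key_iter = calls[VARIANT_KEY].itertuples(index=False, name=None)
    keep = np.array([pvals[k] < alpha for k in key_iter])
    return calls.loc[keep].copy(), audit


def filter_germline(calls: pd.DataFrame, blacklist: set[tuple]) -> pd.DataFrame:
    """Drop calls whose (chrom, pos, ref, alt) is recorded in a germline blacklist."""
    if calls.empty or not blacklist:
        return calls.copy()
    keys = list(calls[VARIANT_KEY].itertuples(index=False, name=None))
    keep = np.array([k not in blacklist for k in keys])
    return calls.loc[keep].copy()


def load_blacklist(path: str | Path) -> set[tuple]:
    """Load a sites-only VCF-like blacklist into a set of variant keys.

    Accepts header lines (``#...``); each data line needs at least the
    CHROM POS ID REF ALT columns.  Malformed lines raise with the 1-based
    line number.
    """
    sites: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"malformed blacklist line {lineno}: expected >=5 columns, got {len(fields)}")
            chrom, pos, _id, ref, alt = fields[:5]
            try:
                pos_i = int(pos)
            except ValueError:
                raise ValueError(f"malformed blacklist line {lineno}: non-integer POS {pos!r}") from None
            for a in alt.split(","):
                sites.add((chrom, pos_i, ref, a))
    return sites


def write_vcf(calls: pd.DataFrame, path: str | Path, sample_id: str | None = None) -> None:
    """Write one sample's calls as a minimal VCF with ``AD`` = alt,ref.

    Note this dialect stores AD as (alt, ref) — the order used throughout
    this package — not the (ref, alt) order of the full VCF spec.
    """
    if sample_id is None:
        ids = calls["sample_id"].unique()
        if len(ids) != 1:
            raise ValueError("write_vcf takes single-sample tables; pass sample_id to subset")
        sample_id = ids[0]
    sub = calls.loc[calls["sample_id"] == sample_id]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=2,Type=Integer,Description="Alt,Ref read counts">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for row in sub.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tAD\t"
                f"{int(row.alt_reads)},{int(row.ref_reads)}\n"
            )


def read_vcf(path: str | Path, patient_id: str = "", timepoint: str = "") -> pd.DataFrame:
    """Read the minimal VCF dialect written by :func:`write_vcf`."""
    rows = []
    sample_id = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_id = line.split("\t")[-1]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"malformed VCF line {lineno}: expected 10 columns")
            chrom, pos, _id, ref, alt = fields[:5]
            ad = fields[9].split(",")
            if len(ad) != 2:
                raise ValueError(f"malformed VCF line {lineno}: AD must be alt,ref")
            alt_reads, ref_reads = int(ad[0]), int(ad[1])
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": ref,
                    "alt": alt,
                    "sample_id": sample_id,
                    "patient_id": patient_id,
                    "timepoint": timepoint,
                    "alt_reads": alt_reads,
                    "ref_reads": ref_reads,
                }
            )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS[:-1])
    return with_vaf(df) if not df.empty else df.assign(vaf=pd.Series(dtype=float))
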