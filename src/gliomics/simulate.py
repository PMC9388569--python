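"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators cover the two halves of the analysis:

:func:`simulate_paired_cohort` emulates a small cohort of patients each
with a primary and a relapsed tumor sequenced against the toy genome:

* patient-specific true somatic SNVs (one shared allele fraction per
  patient, binomial read counts at Poisson depth),
* a shared-artifact stratum: sites carrying the *same* underlying allele
  fraction in every patient — exactly the null the cross-patient
  chi-squared filter removes,
* rare-germline leak-through sites, private to a patient but recorded in
  the gnomAD-style blacklist,
* one hypermutator patient whose relapse carries a mutation load far
  above its primary, with a configurable fraction of mutations drawn from
  the three POLE channels (TCT>TAT, TCG>TTG, TTT>TGT),
* coverage tracks realizing configured arm-level copy ratios (1p/19q
  loss, chromosome 7 gain) plus focal TSS deletions in relapse samples,
* intragenic SVs (deletion/inversion) in relapse samples, along with
  sub-threshold decoys and a recurrent cross-sample artifact junction.

:func:`simulate_tcga_like_tables` emulates a WHO-classifiable reference
cohort: expression decreasing with tumor grade, exponential
proportional-hazards survival with an elevated hazard for the
low-expression group and independent uniform censoring, per-gene
methylation probe clusters with one cluster anticorrelated with
expression by construction, and a clinical marker table sufficient for
WHO-2021 subtyping.

Identical seed + config gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .copynumber import CoverageTrack
from .genome import ToyGenome, build_toy_genome
from .signature import POLE_CHANNELS, trinucleotide_context
from .variants import VARIANT_COLUMNS, cohort_variant_counts

#: pyrimidine-strand trinucleotide and alt base realizing each POLE channel
_POLE_PLANT = {
    "T[C>A]T": ("TCT", "A"),
    "T[C>T]G": ("TCG", "T"),
    "T[T>G]T": ("TTT", "G"),
}


@dataclass
class SimulationConfig:
    """All knobs of both generators; defaults emulate the study conditions."""

    seed: int = 0
    # paired cohort
    n_patients: int = 5
    n_true_somatic: int = 92  # protein-altering load of the hypermutator's primary tumor
    n_artifacts: int = 30
    n_germline: int = 5
    artifact_vaf: float = 0.5
    depth_mean: float = 60.0  # reads per variant site and per 1 kb window
    hypermutator_patient: str | None = "case2"
    hypermutator_relapse_mutations: int = 1145  # >12x the primary load
    pole_fraction: float = 0.8
    window_size: int = 1000
    arm_events: list = field(
        default_factory=lambda: [("1p", 0.5), ("19q", 0.5), ("7p", 1.5), ("7q", 1.5)]
    )
    focal_deletions: list = field(default_factory=lambda: [("PTPRD", 50_000)])
    focal_del_ratio: float = 0.25
    sv_events: list = field(default_factory=lambda: [("CNTNAP2", "deletion"), ("CNTNAP2", "inversion")])
    # reference (TCGA-like) cohort
    n_cohort: int = 581
    grade_effect: float = 0.8  # per-grade drop in mean log2 expression of the marker genes
    hazard_ratio_low_expression: float = 3.0
    baseline_hazard: float = 1.0 / 60.0  # per month; mean 60-month survival in the high group
    censoring_rate: float = 0.2
    survival_gene: str = "CNTNAP2"
    probes_per_gene: int = 10
    anticorrelated_cluster_size: int = 5
    beta_noise_sd: float = 0.05

    def validate(self, genome: ToyGenome) -> None:
        for name in ("artifact_vaf", "pole_fraction", "censoring_rate", "focal_del_ratio"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.window_size <= 0:
            raise ValueError(f"window_size must be positive, got {self.window_size}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.hazard_ratio_low_expression <= 0:
            raise ValueError("hazard_ratio_low_expression must be positive")
        if self.censoring_rate >= 1:
            raise ValueError("censoring_rate must be below 1")
        if not 1 <= self.anticorrelated_cluster_size < self.probes_per_gene:
            raise ValueError("anticorrelated_cluster_size must be >= 1 and below probes_per_gene")
        arms = set(genome.arms["arm"])
        for arm, ratio in self.arm_events:
            if arm not in arms:
                raise ValueError(f"arm_events references unknown arm {arm!r}")
            if ratio <= 0:
                raise ValueError(f"arm copy ratio must be positive, got {ratio}")
        gene_ids = set(genome.gene_ids)
        for gene, span in self.focal_deletions:
            if gene not in gene_ids:
                raise ValueError(f"focal_deletions references unknown gene {gene!r}")
            if span <= 0:
                raise ValueError(f"focal deletion span must be positive, got {span}")
        for gene, kind in self.sv_events:
            if gene not in gene_ids:
                raise ValueError(f"sv_events references unknown gene {gene!r}")
            if kind not in ("deletion", "inversion", "duplication"):
                raise ValueError(f"sv_events type must be deletion/inversion/duplication, got {kind!r}")
        if self.hypermutator_patient is not None:
            if self.hypermutator_patient not in self.patient_ids:
                raise ValueError(
                    f"hypermutator_patient {self.hypermutator_patient!r} not among {self.patient_ids}"
                )
            if self.hypermutator_relapse_mutations < self.n_true_somatic:
                raise ValueError("hypermutator relapse load must be >= the primary load")

    @property
    def patient_ids(self) -> list[str]:
        return [f"case{i}" for i in range(1, self.n_patients + 1)]


@dataclass
class PairedBundle:
    """Everything :func:`simulate_paired_cohort` produces."""

    config: SimulationConfig
    genome: ToyGenome
    variants: pd.DataFrame  # VARIANT_COLUMNS + truth
    cohort_counts: pd.DataFrame  # per-variant, per-patient pooled alt/total
    coverage: dict[str, CoverageTrack]  # tumor samples
    normal: CoverageTrack
    svs: pd.DataFrame  # SV_COLUMNS + truth
    cohort_svs: pd.DataFrame
    blacklist: set
    expression_counts: pd.DataFrame  # genes x samples raw counts
    truth: dict

    def write(self, outdir: str | Path) -> list[Path]:
        """Write every table in the formats the pipeline reads; returns the paths."""
        from .copynumber import write_bedgraph
        from .rearrangements import write_bedpe

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        seed_note = f"seed={self.config.seed}"
        paths = []

        def _tsv(df, name):
            p = out / name
            with open(p, "w") as fh:
                fh.write(f"# {seed_note}\n")
                df.to_csv(fh, sep="\t", index=False)
            paths.append(p)

        _tsv(self.variants, "variants.tsv")
        _tsv(self.cohort_counts, "cohort_counts.tsv")
        _tsv(self.cohort_svs, "cohort_svs.tsv")
        cov_dir = out / "coverage"
        cov_dir.mkdir(exist_ok=True)
        for sid, track in sorted(self.coverage.items()):
            p = cov_dir / f"{sid}.bedGraph"
            write_bedgraph(track, p, header=seed_note)
            paths.append(p)
        p = cov_dir / "normal.bedGraph"
        write_bedgraph(self.normal, p, header=seed_note)
        paths.append(p)
        p = out / "svs.bedpe"
        write_bedpe(self.svs, p, header=seed_note)
        paths.append(p)
        p = out / "blacklist.vcf"
        with open(p, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=gliomics-simulate {seed_note}\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for chrom, pos, ref, alt in sorted(self.blacklist):
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
        paths.append(p)
        p = out / "expression_counts.tsv"
        with open(p, "w") as fh:
            fh.write(f"# {seed_note}\n")
            self.expression_counts.to_csv(fh, sep="\t", index_label="gene")
        paths.append(p)
        p = out / "arms.bed"
        self.genome.write_arms_bed(p)
        paths.append(p)
        p = out / "genes.bed12"
        self.genome.write_genes_bed12(p)
        paths.append(p)
        return paths


@dataclass
class CohortTables:
    """Everything :func:`simulate_tcga_like_tables` produces."""

    config: SimulationConfig
    expression: pd.DataFrame  # genes x samples, log2 scale
    methylation: pd.DataFrame  # probes x samples beta values
    probe_map: pd.DataFrame  # columns probe, gene
    clinical: pd.DataFrame  # markers, grade, time_months, event
    truth: dict

    def write(self, outdir: str | Path) -> list[Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        seed_note = f"# seed={self.config.seed}\n"
        paths = []
        for name, df, label in [
            ("expression.tsv", self.expression, "gene"),
            ("methylation.tsv", self.methylation, "probe"),
        ]:
            p = out / name
            with open(p, "w") as fh:
                fh.write(seed_note)
                df.to_csv(fh, sep="\t", index_label=label)
            paths.append(p)
        for name, df in [("probe_map.tsv", self.probe_map), ("clinical.tsv", self.clinical)]:
            p = out / name
            with open(p, "w") as fh:
                fh.write(seed_note)
                df.to_csv(fh, sep="\t", index=False)
            paths.append(p)
        return paths


# ---------------------------------------------------------------------------
# paired primary/relapse cohort
# ---------------------------------------------------------------------------

_TRIPLET_CACHE: dict[str, dict[str, np.ndarray]] = {}


def _triplet_positions(genome: ToyGenome, triplet: str) -> dict[str, np.ndarray]:
    """1-based center positions of every occurrence of ``triplet`` per chromosome."""
    if triplet not in _TRIPLET_CACHE:
        t0, t1, t2 = (c.encode() for c in triplet)
        per_chrom = {}
        for chrom, seq in genome.chroms.items():
            b = np.frombuffer(seq.encode(), dtype="S1")
            m = (b[:-2] == t0) & (b[1:-1] == t1) & (b[2:] == t2)
            per_chrom[chrom] = np.flatnonzero(m) + 2
        _TRIPLET_CACHE[triplet] = per_chrom
    return _TRIPLET_CACHE[triplet]


def _sample_pole_sites(rng: np.random.Generator, genome: ToyGenome, n: int) -> list[tuple]:
    """n SNVs drawn uniformly from the three POLE channels."""
    sites = []
    channels = list(POLE_CHANNELS)
    picks = rng.integers(0, len(channels), size=n)
    for k in picks:
        triplet, alt = _POLE_PLANT[channels[k]]
        per_chrom = _triplet_positions(genome, triplet)
        chroms = list(per_chrom)
        weights = np.array([len(per_chrom[c]) for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        pos = int(per_chrom[chrom][rng.integers(len(per_chrom[chrom]))])
        sites.append((chrom, pos, triplet[1], alt))
    return sites


def _sample_random_sites(
    rng: np.random.Generator, genome: ToyGenome, n: int, avoid_pole: bool = False
) -> list[tuple]:
    """n random SNVs; optionally resampled until outside the POLE channels."""
    chroms = list(genome.chroms)
    lengths = np.array([genome.chrom_length(c) for c in chroms], dtype=float)
    p = lengths / lengths.sum()
    sites = []
    while len(sites) < n:
        chrom = chroms[rng.choice(len(chroms), p=p)]
        seq = genome.chroms[chrom]
        pos = int(rng.integers(2, len(seq)))  # 1-based, both flanks inside
        ref = seq[pos - 1]
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[rng.integers(3)]
        if avoid_pole:
            if trinucleotide_context(chrom, pos, ref, alt, genome) in POLE_CHANNELS:
                continue
        sites.append((chrom, pos, ref, alt))
    return sites


def _site_rows(rng, sites, sample_id, patient_id, timepoint, vaf, depth_mean, truth):
    rows = []
    for chrom, pos, ref, alt in sites:
        depth = max(1, int(rng.poisson(depth_mean)))
        alt_reads = int(rng.binomial(depth, vaf))
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "sample_id": sample_id, "patient_id": patient_id, "timepoint": timepoint,
                "alt_reads": alt_reads, "ref_reads": depth - alt_reads, "truth": truth,
            }
        )
    return rows


def _plant_sv(rng, gene, kind, sample_id, support_range=(8, 30)) -> dict:
    """One intragenic SV of the requested class inside ``gene``.

    Deletions span whole internal exons (transcript exons 2..k) so the
    affected-exon report has non-trivial content; inversions sit in an
    internal intron, mirroring an intronic enhancer-region inversion.
    """
    n = gene.n_exons
    if kind == "deletion" and n >= 9:
        lo = gene.intron(1)  # between transcript exons 1 and 2
        hi = gene.intron(8)  # between transcript exons 8 and 9
        pos1 = int(rng.integers(lo[0], lo[1]))
        pos2 = int(rng.integers(hi[0], hi[1]))
        strands = ("+", "-")
    elif kind == "deletion":
        lo, hi = gene.intron(1), gene.intron(n - 1)
        pos1 = int(rng.integers(lo[0], lo[1]))
        pos2 = int(rng.integers(hi[0], hi[1]))
        strands = ("+", "-")
    elif kind == "duplication":
        lo, hi = gene.intron(1), gene.intron(n - 1)
        pos1 = int(rng.integers(lo[0], lo[1]))
        pos2 = int(rng.integers(hi[0], hi[1]))
        strands = ("-", "+")
    else:  # inversion within one large intron
        intron = max((gene.intron(i) for i in range(1, n)), key=lambda iv: iv[1] - iv[0])
        a = int(rng.integers(intron[0], intron[0] + (intron[1] - intron[0]) // 3))
        b = int(rng.integers(intron[1] - (intron[1] - intron[0]) // 3, intron[1]))
        pos1, pos2 = a, b
        strands = ("+", "+") if rng.random() < 0.5 else ("-", "-")
    if pos1 > pos2:
        pos1, pos2 = pos2, pos1
    lo_pos, hi_pos = (pos1, pos2)
    return {
        "sample_id": sample_id,
        "chrom1": gene.chrom, "pos1": lo_pos, "strand1": strands[0],
        "chrom2": gene.chrom, "pos2": hi_pos, "strand2": strands[1],
        "unique_reads": int(rng.integers(*support_range)),
        "junction_fraction": round(float(rng.uniform(0.25, 0.6)), 3),
        "variant_read_pairs": int(rng.integers(5, 20)),
        "truth": f"planted_{kind}_{gene.gene_id}",
    }


def simulate_paired_cohort(config: SimulationConfig) -> PairedBundle:
    """Generate variant tables, coverage tracks and SV tables for the paired cohort."""
    genome = build_toy_genome()
    config.validate(genome)

    # --- somatic / artifact / germline variants -----------------------------
    rng = np.random.default_rng([config.seed, 1])
    rows: list[dict] = []
    germline_sites_all: list[tuple] = []
    for pid in config.patient_ids:
        vaf = float(rng.uniform(0.25, 0.55))
        hyper = pid == config.hypermutator_patient
        if hyper:
            n_primary = config.n_true_somatic
            pole_primary = int(rng.binomial(n_primary, config.pole_fraction))
            primary_sites = _sample_pole_sites(rng, genome, pole_primary) + _sample_random_sites(
                rng, genome, n_primary - pole_primary, avoid_pole=True
            )
            n_extra = config.hypermutator_relapse_mutations - n_primary
            pole_extra = int(rng.binomial(n_extra, config.pole_fraction))
            extra_sites = _sample_pole_sites(rng, genome, pole_extra) + _sample_random_sites(
                rng, genome, n_extra - pole_extra, avoid_pole=True
            )
            relapse_sites = primary_sites + extra_sites
        else:
            primary_sites = _sample_random_sites(rng, genome, config.n_true_somatic)
            relapse_sites = primary_sites
        rows += _site_rows(rng, primary_sites, f"{pid}-primary", pid, "primary", vaf,
                           config.depth_mean, "somatic")
        rows += _site_rows(rng, relapse_sites, f"{pid}-relapse", pid, "relapse", vaf,
                           config.depth_mean, "somatic")
        # rare germline leak-through: private to the patient, het fraction, blacklisted
        n_g = config.n_germline
        g_sites = _sample_random_sites(rng, genome, n_g)
        germline_sites_all += g_sites
        for tp in ("primary", "relapse"):
            rows += _site_rows(rng, g_sites, f"{pid}-{tp}", pid, tp, 0.5, config.depth_mean, "germline")

    artifact_sites = _sample_random_sites(rng, genome, config.n_artifacts)
    for pid in config.patient_ids:
        for tp in ("primary", "relapse"):
            rows += _site_rows(rng, artifact_sites, f"{pid}-{tp}", pid, tp,
                               config.artifact_vaf, config.depth_mean, "artifact")

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS[:-1] + ["truth"])
    depth = variants["alt_reads"] + variants["ref_reads"]
    variants.insert(len(VARIANT_COLUMNS) - 1, "vaf", variants["alt_reads"] / depth)

    # --- per-patient pooled counts incl. reference-only coverage ------------
    carriers = cohort_variant_counts(variants)
    keys = variants[["chrom", "pos", "ref", "alt"]].drop_duplicates()
    full = keys.merge(pd.DataFrame({"patient_id": config.patient_ids}), how="cross")
    cohort_counts = full.merge(carriers, on=["chrom", "pos", "ref", "alt", "patient_id"], how="left")
    missing = cohort_counts["alt_sum"].isna()
    n_missing = int(missing.sum())
    ref_depth = rng.poisson(config.depth_mean, size=n_missing) + rng.poisson(config.depth_mean, size=n_missing)
    cohort_counts.loc[missing, "alt_sum"] = 0
    cohort_counts.loc[missing, "total_sum"] = np.maximum(ref_depth, 1)
    cohort_counts["alt_sum"] = cohort_counts["alt_sum"].astype(int)
    cohort_counts["total_sum"] = cohort_counts["total_sum"].astype(int)

    blacklist = {s for s in germline_sites_all}
    # blacklist decoys: sites never called, as in any real germline database
    blacklist |= set(_sample_random_sites(rng, genome, 20))

    # --- coverage tracks -----------------------------------------------------
    rng_cov = np.random.default_rng([config.seed, 2])
    w = config.window_size
    n_windows = {c: math.ceil(genome.chrom_length(c) / w) for c in genome.chroms}

    def _ratio_vectors(relapse: bool) -> dict[str, np.ndarray]:
        ratios = {c: np.ones(n_windows[c]) for c in genome.chroms}
        for arm, ratio in config.arm_events:
            chrom, start, end = genome.arm_interval(arm)
            ratios[chrom][start // w : math.ceil(end / w)] = ratio
        if relapse:
            for gene_id, span in config.focal_deletions:
                g = genome.gene(gene_id)
                lo = max(0, g.tss - span // 2)
                hi = min(genome.chrom_length(g.chrom), g.tss + span // 2)
                ratios[g.chrom][lo // w : math.ceil(hi / w)] = config.focal_del_ratio
        return ratios

    coverage: dict[str, CoverageTrack] = {}
    for pid in config.patient_ids:
        for tp in ("primary", "relapse"):
            ratios = _ratio_vectors(relapse=(tp == "relapse"))
            counts = {c: rng_cov.poisson(config.depth_mean * r) for c, r in ratios.items()}
            coverage[f"{pid}-{tp}"] = CoverageTrack(f"{pid}-{tp}", w, counts)
    normal = CoverageTrack(
        "normal", w, {c: rng_cov.poisson(config.depth_mean, size=n_windows[c]) for c in genome.chroms}
    )

    # --- structural variants -------------------------------------------------
    rng_sv = np.random.default_rng([config.seed, 3])
    sv_rows: list[dict] = []

    def _recurrent_artifact(sample_id) -> dict:
        return {
            "sample_id": sample_id,
            "chrom1": "chr1", "pos1": 50_000 + int(rng_sv.integers(-20, 21)), "strand1": "+",
            "chrom2": "chr1", "pos2": 55_000 + int(rng_sv.integers(-20, 21)), "strand2": "-",
            "unique_reads": int(rng_sv.integers(10, 40)),
            "junction_fraction": round(float(rng_sv.uniform(0.2, 0.5)), 3),
            "variant_read_pairs": int(rng_sv.integers(5, 20)),
            "truth": "recurrent_artifact",
        }

    def _background(sample_id) -> dict:
        # gene-free stretch of chr10
        p1 = int(rng_sv.integers(10_000, 350_000))
        p2 = p1 + int(rng_sv.integers(5_000, 80_000))
        return {
            "sample_id": sample_id,
            "chrom1": "chr10", "pos1": p1, "strand1": "+",
            "chrom2": "chr10", "pos2": p2, "strand2": "-",
            "unique_reads": int(rng_sv.integers(6, 15)),
            "junction_fraction": round(float(rng_sv.uniform(0.2, 0.5)), 3),
            "variant_read_pairs": int(rng_sv.integers(4, 12)),
            "truth": "background",
        }

    event_genes = sorted({g for g, _ in config.sv_events} | {g for g, _ in config.focal_deletions})
    for pid in config.patient_ids:
        sv_rows.append(_recurrent_artifact(f"{pid}-primary"))
        sv_rows.append(_background(f"{pid}-primary"))
        sid = f"{pid}-relapse"
        for gene_id, kind in config.sv_events:
            sv_rows.append(_plant_sv(rng_sv, genome.gene(gene_id), kind, sid))
        # sub-threshold decoys: intragenic but below the unique-read cutoff
        for gene_id in (event_genes or genome.gene_ids)[:2]:
            decoy = _plant_sv(rng_sv, genome.gene(gene_id), "deletion", sid, support_range=(1, 5))
            decoy["truth"] = f"decoy_lowsupport_{gene_id}"
            decoy["junction_fraction"] = round(float(rng_sv.uniform(0.01, 0.15)), 3)
            decoy["variant_read_pairs"] = int(rng_sv.integers(0, 4))
            sv_rows.append(decoy)
        sv_rows.append(_recurrent_artifact(sid))
        sv_rows.append(_background(sid))
    svs = pd.DataFrame(sv_rows)

    cohort_sv_rows = []
    for i in range(1, 11):
        cohort_sv_rows.append(_recurrent_artifact(f"cohort{i}"))
        cohort_sv_rows.append(_background(f"cohort{i}"))
    cohort_svs = pd.DataFrame(cohort_sv_rows)

    # --- paired expression counts -------------------------------------------
    rng_expr = np.random.default_rng([config.seed, 4])
    bg_genes = [f"GENE{i:02d}" for i in range(1, 7)]
    genes = genome.gene_ids + bg_genes
    base = {g: int(rng_expr.integers(300, 2000)) for g in genes}
    samples = [f"{pid}-{tp}" for pid in config.patient_ids for tp in ("primary", "relapse")]
    lib = {s: float(rng_expr.uniform(0.7, 1.4)) for s in samples}
    silenced = set(event_genes)
    counts = {}
    for s in samples:
        relapse = s.endswith("relapse")
        col = []
        for g in genes:
            mu = base[g] * lib[s]
            if relapse and g in silenced:
                mu *= 0.25  # expression collapse of the rearranged genes upon relapse
            col.append(rng_expr.poisson(mu))
        counts[s] = col
    expression_counts = pd.DataFrame(counts, index=genes)

    truth = {
        "artifact_keys": {tuple(s) for s in artifact_sites},
        "germline_keys": {tuple(s) for s in germline_sites_all},
        "silenced_genes": sorted(silenced),
        "sv_planted": [f"planted_{kind}_{gene}" for gene, kind in config.sv_events],
    }
    return PairedBundle(
        config=config, genome=genome, variants=variants, cohort_counts=cohort_counts,
        coverage=coverage, normal=normal, svs=svs, cohort_svs=cohort_svs,
        blacklist=blacklist, expression_counts=expression_counts, truth=truth,
    )


# ---------------------------------------------------------------------------
# TCGA-like reference cohort
# ---------------------------------------------------------------------------


def _censoring_horizon(hazards: np.ndarray, target: float) -> float:
    """Horizon tau of Uniform(0, tau) censoring achieving an expected censored fraction."""

    def mean_censor_prob(tau: float) -> float:
        lt = hazards * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt))

    return brentq(lambda tau: mean_censor_prob(tau) - target, 1e-9, 1e9)


def simulate_tcga_like_tables(config: SimulationConfig) -> CohortTables:
    """Generate expression, methylation, probe-map and clinical tables."""
    genome = build_toy_genome()
    config.validate(genome)
    n = config.n_cohort
    if n < 10:
        raise ValueError(f"n_cohort must be >= 10 for rank statistics, got {n}")
    rng = np.random.default_rng([config.seed, 5])
    cases = [f"TCGA-{i:04d}" for i in range(1, n + 1)]

    subtype = rng.choice(["oligo", "astro", "gbm"], size=n, p=[0.26, 0.39, 0.35])
    grade = np.empty(n, dtype=int)
    grade[subtype == "oligo"] = rng.choice([2, 3], size=(subtype == "oligo").sum(), p=[0.55, 0.45])
    grade[subtype == "astro"] = rng.choice([2, 3, 4], size=(subtype == "astro").sum(), p=[0.4, 0.4, 0.2])
    grade[subtype == "gbm"] = rng.choice([2, 3, 4], size=(subtype == "gbm").sum(), p=[0.15, 0.15, 0.7])

    idh = subtype != "gbm"
    codel = subtype == "oligo"
    is_gbm = subtype == "gbm"
    chr7 = is_gbm & (rng.random(n) < 0.8)
    chr10 = is_gbm & (rng.random(n) < 0.8)
    tert = np.where(is_gbm, rng.random(n) < 0.7, np.where(codel, rng.random(n) < 0.9, rng.random(n) < 0.1))
    egfr = is_gbm & (rng.random(n) < 0.4)

    marker_genes = {"CNTNAP2": 9.5, "PTPRD": 11.2}
    bg_genes = {f"GENE{i:02d}": 8.0 for i in range(1, 9)}
    expr_rows = {}
    for g, base in marker_genes.items():
        expr_rows[g] = base - config.grade_effect * (grade - 2) + rng.normal(0.0, 0.7, size=n)
    for g, base in bg_genes.items():
        expr_rows[g] = base + rng.normal(0.0, 1.0, size=n)
    expression = pd.DataFrame(expr_rows, index=cases).T

    sg = config.survival_gene
    if sg not in expression.index:
        raise ValueError(f"survival_gene {sg!r} not among simulated genes")
    sg_expr = expression.loc[sg]
    low = (sg_expr < sg_expr.mean()).to_numpy()
    hazards = config.baseline_hazard * np.where(low, config.hazard_ratio_low_expression, 1.0)
    event_times = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        tau = _censoring_horizon(hazards, config.censoring_rate)
        censor_times = rng.uniform(0.0, tau, size=n)
        time = np.minimum(event_times, censor_times)
        event = event_times <= censor_times
    else:
        time, event = event_times, np.ones(n, dtype=bool)
    time = np.maximum(time, 1e-6)

    clinical = pd.DataFrame(
        {
            "case_id": cases,
            "idh_mutant": idh,
            "codel_1p19q": codel,
            "grade": grade,
            "chr7_gain": chr7,
            "chr10_loss": chr10,
            "tert_promoter": tert,
            "egfr_amplified": egfr,
            "time_months": np.maximum(np.round(time, 3), 0.001),
            "event": event.astype(int),
        }
    )

    # methylation: per gene one cluster anticorrelated with expression, one
    # cluster tracking an independent latent signal
    beta_rows = {}
    probe_map_rows = []
    planted = {}
    k = config.anticorrelated_cluster_size
    for g in expression.index:
        e = expression.loc[g].to_numpy()
        z = (e - e.mean()) / (e.std() + 1e-12)
        latent = rng.normal(0.0, 1.0, size=n)
        planted[g] = []
        for j in range(config.probes_per_gene):
            probe = f"cg_{g}_{j:02d}"
            offset = float(rng.uniform(-0.08, 0.08))
            if j < k:
                signal = 0.5 - 0.3 * np.tanh(z)
                planted[g].append(probe)
            else:
                signal = 0.5 + 0.3 * np.tanh(latent)
            noise = rng.normal(0.0, config.beta_noise_sd, size=n) if config.beta_noise_sd > 0 else 0.0
            beta_rows[probe] = np.clip(signal + offset + noise, 0.0, 1.0)
            probe_map_rows.append({"probe": probe, "gene": g})
    methylation = pd.DataFrame(beta_rows, index=cases).T
    probe_map = pd.DataFrame(probe_map_rows)

    truth = {
        "subtype": pd.Series(subtype, index=cases),
        "low_group": pd.Series(low, index=cases),
        "planted_probes": planted,
        "survival_gene": sg,
    }
    return CohortTables(
        config=config, expression=expression, methylation=methylation,
        probe_map=probe_map, clinical=clinical, truth=truth,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("arm_events", "focal_deletions", "sv_events"):
        if key in d:
            d[key] = [tuple(x) for x in d[key]]
    return SimulationConfig(**d)
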