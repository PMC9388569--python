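"""End-to-end orchestration: simulate (or load) inputs, run every analysis
stage, and write summary artifacts with a checksummed manifest.

A single YAML/dict config drives the run.  Every threshold of the
analysis is surfaced here with its default: 3 supporting reads and 10%
VAF for somatic calls, chi-squared alpha 0.01, 5 unique reads and the 30%
cohort-recurrence cap for SVs, the 0.2 junction fraction / 4 read-pair
evidence rule, 1000 bp windows with 200-fold median decimation, arm
thresholds of +/-0.3, focal-deletion threshold -1.0 within 3 Mb, probe
variance 0.01, beta cutoff 0.3, and the expression cutoffs 7.8 (CNTNAP2)
and 10.5 (PTPRD).

Outputs are deterministic given config + seed; the manifest lists every
file with its sha256.  A stage failure leaves completed outputs in place
and writes a machine-readable ``error_report.json``.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import classify as classify_mod
from . import copynumber as cn
from . import expression as expr_mod
from . import methylation as meth_mod
from . import rearrangements as sv_mod
from . import signature as sig_mod
from . import survival as surv_mod
from . import variants as var_mod
from .simulate import SimulationConfig, config_from_dict, simulate_paired_cohort, simulate_tcga_like_tables

STAGES = ["simulate", "variants", "signature", "cna", "sv", "methylation", "classify", "survival", "oncoprint"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "gliomics_out",
    "simulate": {},  # SimulationConfig overrides
    "variants": {"min_alt": 3, "min_vaf": 0.10, "alpha": 0.01},
    "signature": {"min_mutations": 500, "min_score": 0.2},
    "cna": {
        "decimation": 200, "loss_thr": -0.3, "gain_thr": 0.3,
        "focal_decimation": 10, "del_thr": -1.5, "max_span": 3_000_000, "min_windows": 2,
    },
    "sv": {"min_reads": 5, "max_fraction": 0.30, "match_window": 100, "min_fraction": 0.2, "min_pairs": 4},
    "methylation": {"min_variance": 0.01, "n_clusters": 2, "beta_cutoff": 0.3},
    "survival": {"cutoffs": {"CNTNAP2": 7.8, "PTPRD": 10.5}, "cutoff_mode": "fixed"},
    "expression": {"low_fold_change": 0.5},
}


class ConfigError(ValueError):
    """Raised before any stage runs when the config is invalid."""


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in overrides.items():
        if key not in out:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(out[key], dict) and key not in ("simulate", "cutoffs"):
            if not isinstance(val, dict):
                raise ConfigError(f"config section {path + key!r} must be a mapping")
            out[key] = _merge(out[key], val, path=f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(source: dict | str | Path | None = None) -> dict:
    """Merge user config (dict or YAML path) over defaults, then validate."""
    if source is None:
        overrides = {}
    elif isinstance(source, dict):
        overrides = source
    else:
        with open(source) as fh:
            overrides = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    v = cfg["variants"]
    if not 0 < v["alpha"] <= 1:
        raise ConfigError(f"variants.alpha must be in (0, 1], got {v['alpha']}")
    if not 0 <= v["min_vaf"] <= 1:
        raise ConfigError(f"variants.min_vaf must be in [0, 1], got {v['min_vaf']}")
    if v["min_alt"] < 0:
        raise ConfigError("variants.min_alt must be non-negative")
    s = cfg["sv"]
    if not 0 <= s["max_fraction"] <= 1:
        raise ConfigError(f"sv.max_fraction must be in [0, 1], got {s['max_fraction']}")
    if not 0 <= s["min_fraction"] <= 1:
        raise ConfigError(f"sv.min_fraction must be in [0, 1], got {s['min_fraction']}")
    c = cfg["cna"]
    if c["decimation"] < 1:
        raise ConfigError("cna.decimation must be >= 1")
    if c["loss_thr"] >= c["gain_thr"]:
        raise ConfigError("cna.loss_thr must be below cna.gain_thr")
    m = cfg["methylation"]
    if m["min_variance"] < 0:
        raise ConfigError("methylation.min_variance must be non-negative")
    if cfg["survival"]["cutoff_mode"] not in ("fixed", "mean"):
        raise ConfigError("survival.cutoff_mode must be 'fixed' or 'mean'")
    # the simulation config validates itself against the genome
    sim = dict(cfg["simulate"])
    sim.setdefault("seed", cfg["seed"])
    config_from_dict(sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def oncoprint_table(alterations: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample alteration summary.

    ``alterations`` has columns gene, sample_id, alteration; each cell of
    the result joins that pair's distinct alteration classes with ';' in
    sorted order.  Rows and columns are sorted, so identical input gives
    a byte-identical table.
    """
    if alterations.empty:
        return pd.DataFrame()
    cells = (
        alterations.groupby(["gene", "sample_id"])["alteration"]
        .apply(lambda v: ";".join(sorted(set(v))))
        .reset_index()
    )
    table = cells.pivot(index="gene", columns="sample_id", values="alteration").fillna("")
    return table.sort_index(axis=0).sort_index(axis=1)


def run_pipeline(config: dict | str | Path | None = None, stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all) and return the output manifest."""
    cfg = load_config(config)
    stages = list(STAGES) if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg["seed"], "stages": {}}
    alterations: list[dict] = []
    current = "simulate"
    try:
        # ---- inputs (always needed) ----------------------------------------
        sim_overrides = dict(cfg["simulate"])
        sim_overrides.setdefault("seed", cfg["seed"])
        sim_config: SimulationConfig = config_from_dict(sim_overrides)
        bundle = simulate_paired_cohort(sim_config)
        cohort = simulate_tcga_like_tables(sim_config)
        if "simulate" in stages:
            paths = bundle.write(outdir / "inputs") + cohort.write(outdir / "inputs")
            manifest["stages"]["simulate"] = _checksums(paths)

        genome = bundle.genome
        counts_in = len(bundle.variants)

        # ---- variants -------------------------------------------------------
        if "variants" in stages:
            current = "variants"
            vcfg = cfg["variants"]
            supported = var_mod.filter_by_support(bundle.variants, vcfg["min_alt"], vcfg["min_vaf"])
            retained, audit = var_mod.filter_artifacts(supported, bundle.cohort_counts, vcfg["alpha"])
            final = var_mod.filter_germline(retained, bundle.blacklist)
            paths = []
            paths.append(_write_tsv(final, outdir / "variants_filtered.tsv"))
            paths.append(_write_tsv(audit, outdir / "variants_artifact_audit.tsv"))
            manifest["stages"]["variants"] = _checksums(paths)
            manifest["stages"]["variants"]["counts"] = {
                "input": counts_in, "after_support": len(supported),
                "after_artifact": len(retained), "after_germline": len(final),
            }
            for row in final.itertuples(index=False):
                for g in genome.genes:
                    pos0 = row.pos - 1
                    if row.chrom == g.chrom and g.start <= pos0 < g.end:
                        alterations.append({"gene": g.gene_id, "sample_id": row.sample_id, "alteration": "mutation"})
        else:
            final = bundle.variants

        # ---- signature ------------------------------------------------------
        if "signature" in stages:
            current = "signature"
            scfg = cfg["signature"]
            per_sample = {}
            flags = []
            for sid, sub in final.groupby("sample_id", sort=True):
                counts = sig_mod.count_channels(sub, genome)
                per_sample[sid] = counts
                total = int(counts.sum())
                score = sig_mod.pole_signature_score(counts) if total else float("nan")
                flags.append(
                    {
                        "sample_id": sid, "total_mutations": total, "pole_score": score,
                        "hypermutator": sig_mod.flag_hypermutator(counts, scfg["min_mutations"], scfg["min_score"]),
                    }
                )
            matrix = sig_mod.signature_matrix(per_sample)
            p1 = outdir / "signature_96.tsv"
            matrix.to_csv(p1, sep="\t", index_label="channel")
            p2 = _write_tsv(pd.DataFrame(flags), outdir / "hypermutator_flags.tsv")
            manifest["stages"]["signature"] = _checksums([p1, p2])

        # ---- copy number ----------------------------------------------------
        if "cna" in stages:
            current = "cna"
            ccfg = cfg["cna"]
            arm_calls = {}
            paths = []
            codel_rows = []
            focal_rows = []
            tracks_dir = outdir / "tracks"
            tracks_dir.mkdir(exist_ok=True)
            for sid, track in sorted(bundle.coverage.items()):
                lr = cn.log_ratio(track, bundle.normal)
                dec = cn.median_decimate(lr, ccfg["decimation"])
                p_raw = tracks_dir / f"{sid}.logratio.bedGraph"
                p_dec = tracks_dir / f"{sid}.logratio.decimated.bedGraph"
                cn.write_bedgraph(lr, p_raw)
                cn.write_bedgraph(dec, p_dec)
                paths += [p_raw, p_dec]
                calls = cn.arm_summary(dec, genome.arms, ccfg["loss_thr"], ccfg["gain_thr"])
                arm_calls[sid] = calls
                codel_rows.append({"sample_id": sid, "codeletion_1p19q": cn.detect_codeletion(calls)})
                focal_track = cn.median_decimate(lr, ccfg["focal_decimation"])
                for ev in cn.focal_deletions(
                    focal_track, genome.genes, ccfg["del_thr"], ccfg["max_span"], ccfg["min_windows"]
                ):
                    focal_rows.append(
                        {
                            "sample_id": sid, "gene": ev.gene_id, "chrom": ev.chrom,
                            "start": ev.start, "end": ev.end, "tss_overlap": ev.tss_overlap,
                        }
                    )
                    alterations.append(
                        {
                            "gene": ev.gene_id, "sample_id": sid,
                            "alteration": "focal_deletion_tss" if ev.tss_overlap else "focal_deletion",
                        }
                    )
            paths.append(_write_tsv(cn.arm_calls_frame(arm_calls), outdir / "arm_calls.tsv"))
            paths.append(_write_tsv(pd.DataFrame(codel_rows), outdir / "codeletion.tsv"))
            paths.append(
                _write_tsv(
                    pd.DataFrame(focal_rows, columns=["sample_id", "gene", "chrom", "start", "end", "tss_overlap"]),
                    outdir / "focal_deletions.tsv",
                )
            )
            manifest["stages"]["cna"] = _checksums(paths)

        # ---- structural variants -------------------------------------------
        if "sv" in stages:
            current = "sv"
            svcfg = cfg["sv"]
            step1 = sv_mod.filter_support(bundle.svs, svcfg["min_reads"])
            step2 = sv_mod.filter_recurrent(step1, bundle.cohort_svs, svcfg["max_fraction"], svcfg["match_window"])
            step3 = sv_mod.filter_tcga(step2, svcfg["min_fraction"], svcfg["min_pairs"])
            annos = sv_mod.annotate_intragenic(step3, genome.genes)
            anno_rows = []
            for row in annos.itertuples(index=False):
                gene = genome.gene(row.gene_id)
                exons, in_frame = sv_mod.affected_exons((row.start, row.end), gene, row.event_class)
                anno_rows.append(
                    {
                        "sample_id": row.sample_id, "gene": row.gene_id, "event_class": row.event_class,
                        "start": row.start, "end": row.end,
                        "exons": ",".join(map(str, exons)),
                        "in_frame": "NA" if in_frame is None else str(bool(in_frame)),
                    }
                )
                alterations.append(
                    {"gene": row.gene_id, "sample_id": row.sample_id, "alteration": f"sv_{row.event_class}"}
                )
            paths = [
                _write_tsv(step3.drop(columns=["truth"], errors="ignore"), outdir / "svs_filtered.tsv"),
                _write_tsv(
                    pd.DataFrame(
                        anno_rows,
                        columns=["sample_id", "gene", "event_class", "start", "end", "exons", "in_frame"],
                    ),
                    outdir / "svs_intragenic.tsv",
                ),
            ]
            manifest["stages"]["sv"] = _checksums(paths)
            manifest["stages"]["sv"]["counts"] = {
                "input": len(bundle.svs), "after_support": len(step1),
                "after_recurrent": len(step2), "after_evidence": len(step3),
            }

        # ---- paired expression ---------------------------------------------
        current = "expression"
        factors = expr_mod.size_factors(bundle.expression_counts)
        fc_rows = []
        for pid in sim_config.patient_ids:
            for g in genome.gene_ids:
                fc = expr_mod.paired_fold_change(
                    bundle.expression_counts, g, f"{pid}-primary", f"{pid}-relapse", factors
                )
                fc_rows.append(
                    {
                        "patient_id": pid, "gene": g, "normalized_primary": round(fc.primary, 2),
                        "normalized_relapse": round(fc.relapse, 2), "fold_change": round(fc.fold_change, 4),
                    }
                )
                if fc.fold_change <= cfg["expression"]["low_fold_change"]:
                    alterations.append(
                        {"gene": g, "sample_id": f"{pid}-relapse", "alteration": "low_expression"}
                    )
        if "variants" in stages or "sv" in stages or "cna" in stages:
            p = _write_tsv(pd.DataFrame(fc_rows), outdir / "paired_fold_changes.tsv")
            manifest["stages"].setdefault("variants", {})  # ensure ordering stability in manifest
            manifest["stages"]["expression"] = _checksums([p])

        # ---- methylation collapse ------------------------------------------
        if "methylation" in stages:
            current = "methylation"
            mcfg = cfg["methylation"]
            gene_beta, provenance = meth_mod.collapse_matrix(
                cohort.methylation, cohort.probe_map, cohort.expression,
                min_variance=mcfg["min_variance"], n_clusters=mcfg["n_clusters"],
            )
            status = (gene_beta >= mcfg["beta_cutoff"]).astype(int) if not gene_beta.empty else gene_beta
            p1 = outdir / "gene_methylation.tsv"
            gene_beta.to_csv(p1, sep="\t", index_label="gene")
            p2 = _write_tsv(provenance, outdir / "methylation_provenance.tsv")
            p3 = outdir / "methylation_status.tsv"
            status.to_csv(p3, sep="\t", index_label="gene")
            manifest["stages"]["methylation"] = _checksums([p1, p2, p3])

        # ---- WHO-2021 classification ---------------------------------------
        if "classify" in stages:
            current = "classify"
            labels = classify_mod.classify_cohort(cohort.clinical)
            labelled = cohort.clinical.assign(who2021=labels.values)
            p = _write_tsv(labelled, outdir / "who2021_labels.tsv")
            manifest["stages"]["classify"] = _checksums([p])
            manifest["stages"]["classify"]["counts"] = labels.value_counts().to_dict()

        # ---- survival associations -----------------------------------------
        if "survival" in stages:
            current = "survival"
            scfg = cfg["survival"]
            times = cohort.clinical.set_index("case_id")["time_months"]
            events = cohort.clinical.set_index("case_id")["event"].astype(bool)
            results = []
            groups = {}
            for gene, cut in scfg["cutoffs"].items():
                if gene not in cohort.expression.index:
                    continue
                expr = cohort.expression.loc[gene]
                eg = surv_mod.dichotomize_expression(
                    expr, cutoff_mode=scfg["cutoff_mode"],
                    fixed_cutoff=cut, gene=gene,
                )
                groups[gene] = eg
                res = surv_mod.survival_by_group(times, events, eg.labels, "low", "high")
                res.update({"comparison": f"{gene}_low_vs_high", "cutoff": eg.cutoff})
                results.append(res)
            if len(groups) >= 2:
                g1, g2 = list(groups)[:2]
                combo = surv_mod.combined_low_group(groups[g1], groups[g2])
                res = surv_mod.survival_by_group(times, events, combo, "low/low", "other")
                res.update({"comparison": f"{g1}+{g2}_lowlow_vs_other", "cutoff": float("nan")})
                results.append(res)
            p = _write_tsv(pd.DataFrame(results), outdir / "survival_comparisons.tsv")
            manifest["stages"]["survival"] = _checksums([p])

        # ---- oncoprint ------------------------------------------------------
        if "oncoprint" in stages:
            current = "oncoprint"
            table = oncoprint_table(pd.DataFrame(alterations, columns=["gene", "sample_id", "alteration"]))
            if table.empty:
                samples = sorted(bundle.coverage)
                table = pd.DataFrame("", index=sorted(genome.gene_ids), columns=samples)
            p = outdir / "oncoprint.tsv"
            table.to_csv(p, sep="\t", index_label="gene")
            manifest["stages"]["oncoprint"] = _checksums([p])
    except (ConfigError,):
        raise
    except Exception as exc:  # partial failure: keep finished outputs, report machine-readably
        report = {"stage": current, "error": f"{type(exc).__name__}: {exc}"}
        with open(outdir / "error_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise StageError(current, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def _checksums(paths: list[Path]) -> dict:
    return {"files": {p.name: _sha256(p) for p in sorted(paths, key=lambda q: q.name)}}
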