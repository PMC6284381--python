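"""Cohort-level orchestration: manifest validation, stage execution and the
report bundle.

A cohort manifest (YAML) lists per-sample variant tables plus optional
cohort-level methylation, ATAC and coverage inputs. ``run_pipeline`` executes
every stage whose inputs are present, writes the stage outputs to the bundle
directory, and records per-stage status together with the configuration hash
and seed so that identical reruns produce identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atac as atac_mod
from . import cna as cna_mod
from . import io
from . import methylation as meth_mod
from . import variants as var_mod
from .config import ConcordanceConfig, SimulationConfig
from .simulate import simulate_cna_coverage, simulate_cohort, simulate_methylation, simulate_atac

logger = logging.getLogger("pdxfid")

__all__ = ["validate_manifest", "run_pipeline", "write_synthetic_cohort"]


def validate_manifest(manifest: dict, base_dir: Path | None = None) -> list[str]:
    """Report-only validation: missing primary partners, unreadable paths,
    blast contents outside (0, 1]."""
    issues = []
    base = Path(base_dir) if base_dir else Path(".")
    samples = manifest.get("samples", [])
    by_key = {(s["patient"], s["timepoint"], s["origin"]): s for s in samples}
    for s in samples:
        if s["origin"] == "PDX":
            if (s["patient"], s["timepoint"], "PRI") not in by_key:
                issues.append(
                    f"PDX sample {s['sample_id']} has no primary partner"
                )
        blast = s.get("blast_content")
        if blast is not None and not 0 < blast <= 1:
            issues.append(
                f"sample {s['sample_id']}: blast_content {blast} outside (0, 1]"
            )
        path = s.get("variants")
        if path and not (base / path).exists():
            issues.append(f"sample {s['sample_id']}: missing file {path}")
    for key in ("beta", "atac_counts", "atac_meta", "coverage_tumor",
                "coverage_remission", "peaks_primary", "peaks_pdx", "mlpa"):
        path = manifest.get(key)
        if path and not (base / path).exists():
            issues.append(f"missing file for '{key}': {path}")
    return issues


def _config_hash(config) -> str:
    payload = {
        k: repr(v) for k, v in dataclasses.asdict(config).items()
    } if dataclasses.is_dataclass(config) else {"config": repr(config)}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_variants(manifest, base, outdir, config: ConcordanceConfig):
    samples = manifest["samples"]
    tables = {}
    for s in samples:
        df = io.read_variants_tsv(base / s["variants"])
        tables[(s["patient"], s["timepoint"], s["origin"])] = (s, df)
    all_records = pd.concat([df for _, df in tables.values()], ignore_index=True)
    filtered = var_mod.apply_detection_filters(all_records, config)

    pairings, classifications, summaries = [], {}, []
    patients = sorted({s["patient"] for s in samples})
    for patient in patients:
        entry = {}
        for tp in ("INI", "REL"):
            pri = filtered.loc[
                (filtered["patient"] == patient)
                & (filtered["timepoint"] == tp)
                & (filtered["origin"] == "PRI")
            ]
            pdx = filtered.loc[
                (filtered["patient"] == patient)
                & (filtered["timepoint"] == tp)
                & (filtered["origin"] == "PDX")
            ]
            if pri.empty or pdx.empty:
                continue
            pairing = var_mod.pair_variants(pri, pdx, config)
            pairing.insert(0, "patient", patient)
            pairing.insert(1, "timepoint", tp)
            pairings.append(pairing)
            meta = tables.get((patient, tp, "PRI"), ({}, None))[0]
            blast = meta.get("blast_content", 1.0) or 1.0
            try:
                mode = var_mod.classify_engraftment_mode(
                    pairing, config, blast_primary=blast
                )
                entry[f"engraftment_mode_{tp}"] = mode["mode"]
                entry[f"engraftment_reasons_{tp}"] = mode["reasons"]
            except ValueError as exc:
                entry[f"engraftment_mode_{tp}"] = f"error: {exc}"
        ini = filtered.loc[
            (filtered["patient"] == patient)
            & (filtered["timepoint"] == "INI")
            & (filtered["origin"] == "PRI")
        ]
        rel = filtered.loc[
            (filtered["patient"] == patient)
            & (filtered["timepoint"] == "REL")
            & (filtered["origin"] == "PRI")
        ]
        if not ini.empty and not rel.empty:
            initial_clonal = var_mod.clonal_keys(ini, config)
            if initial_clonal:
                entry["relapse_type"] = var_mod.classify_relapse_type(
                    initial_clonal, var_mod.detected_keys(rel)
                )
        classifications[patient] = entry

    combined = pd.concat(pairings, ignore_index=True)
    summary = var_mod.preservation_summary(
        combined, config, timepoints=combined["timepoint"]
    )
    conc = var_mod.af_concordance(combined)
    combined.to_csv(outdir / "variant_pairings.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "preservation_summary.tsv", sep="\t", index=False)
    io.write_json(
        {"classifications": classifications, "af_concordance": conc},
        outdir / "variant_classification.json",
    )
    return {"n_pairings": int(len(combined)), "af_concordance": conc}


def _stage_cna(manifest, base, outdir):
    tumor = io.read_coverage_tsv(base / manifest["coverage_tumor"])
    remission = io.read_coverage_tsv(base / manifest["coverage_remission"])
    ratios = cna_mod.coverage_log2ratio(
        cna_mod.gc_correct(tumor), cna_mod.gc_correct(remission)
    )
    segments = cna_mod.segment_ratios(ratios)
    calls = cna_mod.call_large_cna(segments)
    calls.to_csv(outdir / "cna_calls.tsv", sep="\t", index=False)
    result = {"n_segments": int(len(segments)), "n_large_cna": int(len(calls))}
    if manifest.get("mlpa"):
        mlpa = pd.read_csv(base / manifest["mlpa"])
        pri = mlpa.loc[mlpa["origin"] == "PRI"]
        pdx = mlpa.loc[mlpa["origin"] == "PDX"]
        result["mlpa"] = cna_mod.mlpa_concordance(pri, pdx)
    io.write_json(result, outdir / "cna_concordance.json")
    return result


def _stage_methylation(manifest, base, outdir):
    beta = io.read_beta_csv(base / manifest["beta"])
    pairs = sorted({c.rsplit("_", 1)[0] for c in beta.columns})
    events = meth_mod.event_matrix(beta, pairs)
    p_hypo, p_hyper = meth_mod.estimate_baseline(events)
    recurrence = meth_mod.recurrent_promoters(events, p_hypo=p_hypo, p_hyper=p_hyper)
    conc = meth_mod.global_concordance(beta, pairs)
    events.to_csv(outdir / "methylation_events.tsv", sep="\t")
    recurrence.to_csv(outdir / "methylation_recurrence.tsv", sep="\t", index=False)
    blasts = manifest.get("blast_per_pair", {})
    result = {
        "baseline_p_hypo": p_hypo,
        "baseline_p_hyper": p_hyper,
        "spearman_rho": conc["spearman_rho"],
        "pearson_r": conc["pearson_r"],
        "events_per_pair": conc["events_per_pair"],
        "n_recurrent": int(
            recurrence.loc[recurrence["significant"], "promoter_id"].nunique()
        ),
    }
    if blasts:
        shared = [p for p in pairs if p in blasts]
        if len(shared) >= 3:
            result["blast_event_correlation"] = meth_mod.blast_event_correlation(
                [conc["events_per_pair"][p] for p in shared],
                [blasts[p] for p in shared],
            )
    io.write_json(result, outdir / "methylation_concordance.json")
    return result


def _stage_atac(manifest, base, outdir):
    peaks_pri = io.read_peaks_bed(base / manifest["peaks_primary"])
    peaks_pdx = io.read_peaks_bed(base / manifest["peaks_pdx"])
    counts = pd.read_csv(base / manifest["atac_counts"], index_col=0)
    meta = pd.read_csv(base / manifest["atac_meta"], index_col=0)
    sharing = atac_mod.peak_sharing_curve(
        peaks_pri, peaks_pdx, height_thresholds=[0, 10, 25, 50, 100]
    )
    diff = atac_mod.differential_accessibility(counts, meta)
    pca = atac_mod.pca_embedding(counts)
    sharing.to_csv(outdir / "atac_sharing_curve.tsv", sep="\t", index=False)
    diff.to_csv(outdir / "atac_differential.tsv", sep="\t")
    pca.to_csv(outdir / "atac_pca.tsv", sep="\t")
    share50 = sharing.loc[
        sharing["height_threshold"] == 50, "fraction_shared"
    ]
    result = {
        "n_peaks": int(len(counts)),
        "fraction_shared_height50": float(share50.iloc[0]) if len(share50) else None,
        "n_hyper": int((diff["direction"] == "hyper").sum()),
        "n_hypo": int((diff["direction"] == "hypo").sum()),
    }
    io.write_json(result, outdir / "atac_concordance.json")
    return result


_STAGES = {
    "variants": (_stage_variants, ("samples",)),
    "cna": (_stage_cna, ("coverage_tumor", "coverage_remission")),
    "methylation": (_stage_methylation, ("beta",)),
    "atac": (_stage_atac, ("peaks_primary", "peaks_pdx", "atac_counts", "atac_meta")),
}


def run_pipeline(
    manifest: dict,
    outdir,
    config: ConcordanceConfig | None = None,
    base_dir=None,
    seed: int = 0,
    stages: list[str] | None = None,
) -> dict:
    """Run every stage whose manifest inputs are present; emit a bundle.

    A stage with missing inputs is marked skipped; a failing stage is logged
    and marked failed while the remaining stages still run. The bundle
    directory receives the per-stage tables plus ``run_metadata.json``.
    """
    config = config or ConcordanceConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir else Path(".")
    status, results = {}, {}
    for name, (fn, required) in _STAGES.items():
        if stages and name not in stages:
            status[name] = "skipped"
            continue
        if any(not manifest.get(k) for k in required):
            status[name] = "skipped"
            logger.info("stage %s skipped (inputs missing)", name)
            continue
        t0 = time.monotonic()
        try:
            if name == "variants":
                results[name] = fn(manifest, base, outdir, config)
            else:
                results[name] = fn(manifest, base, outdir)
            status[name] = "ok"
        except Exception as exc:  # stage isolation is deliberate
            logger.exception("stage %s failed", name)
            status[name] = f"failed: {exc}"
        logger.info("stage %s: %s (%.1fs)", name, status[name],
                    time.monotonic() - t0)
    metadata = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": status,
        "results": results,
    }
    io.write_json(metadata, outdir / "run_metadata.json")
    return metadata


def write_synthetic_cohort(
    outdir, config: SimulationConfig | None = None, seed: int = 0
) -> Path:
    """Simulate a full cohort and write it to disk with a manifest.

    Returns the manifest path. The manifest plus files are exactly what
    ``run_pipeline`` consumes, so the synthetic route exercises the same I/O
    as user-provided data.
    """
    config = config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(config, seed)

    samples, truth_labels = [], {}
    for pt in cohort:
        truth_labels[pt["patient"]] = {
            "relapse_type": pt["relapse_type"],
            "mode_ini": pt["mode_ini"],
            "mode_rel": pt["mode_rel"],
        }
        for (tp, origin), table in pt["tables"].items():
            sid = f"{pt['patient']}_{tp}_{origin}"
            path = f"variants_{sid}.tsv"
            io.write_variants_tsv(table.drop(columns="mutation_id"), outdir / path)
            samples.append(
                {
                    "patient": pt["patient"],
                    "sample_id": sid,
                    "timepoint": tp,
                    "origin": origin,
                    "blast_content": pt["blast"][f"{tp}_{origin}"],
                    "variants": path,
                }
            )

    pairs = {
        f"{pt['patient']}INI": pt["blast"]["INI_PRI"] for pt in cohort
    }
    beta, meth_truth = simulate_methylation(config, pairs, int(rng.integers(2**31)))
    io.write_beta_csv(beta, outdir / "beta.csv")

    peaks, counts, meta, atac_truth = simulate_atac(config, int(rng.integers(2**31)))
    io.write_peaks_bed(peaks["PRI"], outdir / "peaks_primary.bed")
    io.write_peaks_bed(peaks["PDX"], outdir / "peaks_pdx.bed")
    counts.to_csv(outdir / "atac_counts.csv")
    meta.to_csv(outdir / "atac_meta.csv")

    tumor, remission, cna_truth = simulate_cna_coverage(
        config, int(rng.integers(2**31))
    )
    io.write_coverage_tsv(tumor, outdir / "coverage_tumor.tsv")
    io.write_coverage_tsv(remission, outdir / "coverage_remission.tsv")

    io.write_json(
        {
            "patients": truth_labels,
            "methylation": {
                k: v for k, v in meth_truth.items() if k != "blast_per_sample"
            },
            "cna": cna_truth,
            "atac_hypo_peaks": atac_truth["hypo_peaks"],
        },
        outdir / "truth.json",
    )
    manifest = {
        "seed": seed,
        "samples": samples,
        "beta": "beta.csv",
        "blast_per_pair": pairs,
        "peaks_primary": "peaks_primary.bed",
        "peaks_pdx": "peaks_pdx.bed",
        "atac_counts": "atac_counts.csv",
        "atac_meta": "atac_meta.csv",
        "coverage_tumor": "coverage_tumor.tsv",
        "coverage_remission": "coverage_remission.tsv",
    }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
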