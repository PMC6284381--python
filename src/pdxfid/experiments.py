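"""Self-contained simulation studies over the synthetic cohort generator.

Each function generates data with known ground truth, runs the corresponding
analysis stage, and measures recovery. They are the package's calibration
experiments: classifier label recovery, per-class preservation-rate
recovery, methylation recurrence sensitivity/FDR, differential-accessibility
error rates, and copy-number recall.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from . import atac as atac_mod
from . import cna as cna_mod
from . import methylation as meth_mod
from . import variants as var_mod
from .config import ConcordanceConfig, SimulationConfig
from .simulate import (
    simulate_atac,
    simulate_cna_coverage,
    simulate_cohort,
    simulate_methylation,
    simulate_patient,
    simulate_preservation_cohort,
)

__all__ = [
    "classifier_recovery",
    "preservation_recovery",
    "cohort_variant_statistics",
    "methylation_recovery",
    "methylation_blast_correlation",
    "atac_null_type1_error",
    "atac_planted_recall",
    "cna_planted_recovery",
]


def _truncnorm(rng, mean, sd, lo):
    b = rng.normal(mean, sd)
    while not lo <= b <= 1.0:
        b = rng.normal(mean, sd)
    return float(b)


def classifier_recovery(
    n_patients: int = 100,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    conc_config: ConcordanceConfig | None = None,
) -> dict:
    """Recovery of planted relapse-type and engraftment-mode labels.

    Simulates full patients (initial + relapse phylogenies, engrafted PDXs,
    50x variant tables), runs the detection filters and both classifiers,
    and reports label accuracy. Engraftment mode is assessed on the
    initial-diagnosis pair.
    """
    sim_config = sim_config or SimulationConfig()
    conc_config = conc_config or ConcordanceConfig()
    rng = np.random.default_rng(seed)
    type_ok = mode_ok = 0
    for i in range(n_patients):
        pt = simulate_patient(f"P{i + 1}", sim_config, int(rng.integers(2**31)))
        allrec = pd.concat(pt["tables"].values(), ignore_index=True)
        filt = var_mod.apply_detection_filters(allrec, conc_config)

        def sub(tp, orig):
            return filt.loc[(filt["timepoint"] == tp) & (filt["origin"] == orig)]

        initial_clonal = var_mod.clonal_keys(sub("INI", "PRI"), conc_config)
        predicted_type = var_mod.classify_relapse_type(
            initial_clonal, var_mod.detected_keys(sub("REL", "PRI"))
        )
        if predicted_type == f"type{pt['relapse_type']}":
            type_ok += 1

        pairing = var_mod.pair_variants(
            sub("INI", "PRI"), sub("INI", "PDX"), conc_config
        )
        predicted_mode = var_mod.classify_engraftment_mode(
            pairing,
            conc_config,
            blast_primary=pt["blast"]["INI_PRI"],
            blast_pdx=pt["blast"]["INI_PDX"],
        )["mode"]
        if predicted_mode == f"mode{pt['mode_ini']}":
            mode_ok += 1
    return {
        "n_patients": n_patients,
        "relapse_type_accuracy": type_ok / n_patients,
        "engraftment_mode_accuracy": mode_ok / n_patients,
    }


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1 - level) / 2
    lo = float(beta_dist.ppf(a, k, n - k + 1)) if k > 0 else 0.0
    hi = float(beta_dist.ppf(1 - a, k + 1, n - k)) if k < n else 1.0
    return lo, hi


def preservation_recovery(
    n_patients: int = 100,
    seed: int = 0,
    p_clonal: float = 0.93,
    p_subclonal: float = 0.48,
    depth: float = 50.0,
) -> dict:
    """Recovery of per-class preservation probabilities.

    Mutations are preserved with class-specific Bernoulli rates; the
    estimate runs through the package's detection filters and per-patient
    detection sets, stratified by the simulator's true clonality class.
    Reports estimates with exact (Clopper-Pearson) 95% intervals.
    """
    conc_config = ConcordanceConfig()
    pri, pdx, truth = simulate_preservation_cohort(
        n_patients, seed=seed, p_clonal=p_clonal, p_subclonal=p_subclonal,
        depth=depth,
    )
    filt = var_mod.apply_detection_filters(
        pd.concat([pri, pdx], ignore_index=True), conc_config
    )
    detected: dict[tuple[str, str], set] = {}
    for (patient, origin), g in filt.groupby(["patient", "origin"]):
        detected[(patient, origin)] = set(var_mod.variant_key(g))
    in_pri = np.array(
        [r.key in detected.get((r.patient, "PRI"), set())
         for r in truth.itertuples()]
    )
    in_pdx = np.array(
        [r.key in detected.get((r.patient, "PDX"), set())
         for r in truth.itertuples()]
    )
    out = {}
    for label, true_p in (("clonal", p_clonal), ("subclonal", p_subclonal)):
        sel = (truth["clonal"] == (label == "clonal")).to_numpy() & in_pri
        n = int(sel.sum())
        k = int((sel & in_pdx).sum())
        lo, hi = _clopper_pearson(k, n)
        out[label] = {
            "true_p": true_p,
            "estimate": k / n,
            "k": k,
            "n": n,
            "ci95": (lo, hi),
            "covered": lo <= true_p <= hi,
        }
    return out


def cohort_variant_statistics(
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    conc_config: ConcordanceConfig | None = None,
) -> dict:
    """Cohort-level SNV/InDel preservation and AF concordance statistics for
    a tree-based synthetic cohort (both timepoints)."""
    sim_config = sim_config or SimulationConfig()
    conc_config = conc_config or ConcordanceConfig()
    cohort = simulate_cohort(sim_config, seed)
    pairings = []
    for pt in cohort:
        allrec = pd.concat(pt["tables"].values(), ignore_index=True)
        filt = var_mod.apply_detection_filters(allrec, conc_config)
        for tp in ("INI", "REL"):
            pri = filt.loc[(filt["timepoint"] == tp) & (filt["origin"] == "PRI")]
            pdx = filt.loc[(filt["timepoint"] == tp) & (filt["origin"] == "PDX")]
            if len(pri) and len(pdx):
                pairing = var_mod.pair_variants(pri, pdx, conc_config)
                pairing["timepoint"] = tp
                pairings.append(pairing)
    combined = pd.concat(pairings, ignore_index=True)
    summary = var_mod.preservation_summary(
        combined, conc_config, timepoints=combined["timepoint"]
    ).set_index(["scope", "group"])
    conc = var_mod.af_concordance(combined)
    return {
        "overall_preservation": float(summary.loc[("overall", "all"), "fraction"]),
        "clonal_preservation": float(
            summary.loc[("clonality", "clonal"), "fraction"]
        ),
        "subclonal_preservation": float(
            summary.loc[("clonality", "subclonal"), "fraction"]
        ),
        "af_pearson_r": conc["pearson_r"],
        "mean_af_primary": conc["mean_af_primary"],
        "mean_af_pdx": conc["mean_af_pdx"],
        "wilcoxon_p": conc["wilcoxon_p"],
        "n_variants": int(summary.loc[("overall", "all"), "n_total"]),
    }


def methylation_recovery(
    n_pairs: int = 11,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
) -> dict:
    """Sensitivity and FDR of the recurrence test on a planted
    hypermethylated promoter set (initial-diagnosis blast contents)."""
    sim_config = sim_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    blasts = {
        f"P{i + 1}": _truncnorm(rng, *sim_config.blast_ini)
        for i in range(n_pairs)
    }
    beta, truth = simulate_methylation(sim_config, blasts, int(rng.integers(2**31)))
    pairs = sorted(blasts)
    events = meth_mod.event_matrix(beta, pairs)
    p_hypo, p_hyper = meth_mod.estimate_baseline(events)
    recurrence = meth_mod.recurrent_promoters(events, p_hypo=p_hypo, p_hyper=p_hyper)
    called = set(
        recurrence.loc[
            (recurrence["direction"] == "hyper") & recurrence["significant"],
            "promoter_id",
        ]
    )
    planted = set(truth["planted_hyper_promoters"])
    tp = len(called & planted)
    return {
        "sensitivity": tp / len(planted),
        "fdr": (len(called) - tp) / max(len(called), 1),
        "n_called": len(called),
        "n_planted": len(planted),
        "baseline_p_hypo": p_hypo,
        "baseline_p_hyper": p_hyper,
    }


def methylation_blast_correlation(
    n_patients: int = 11,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
) -> float:
    """Correlation between blast content and per-pair event counts over a
    cohort spanning initial-diagnosis and relapse blast contents."""
    sim_config = sim_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    blasts = {}
    for i in range(n_patients):
        blasts[f"P{i + 1}INI"] = _truncnorm(rng, *sim_config.blast_ini)
        blasts[f"P{i + 1}REL"] = _truncnorm(rng, *sim_config.blast_rel)
    beta, _ = simulate_methylation(sim_config, blasts, int(rng.integers(2**31)))
    pairs = sorted(blasts)
    events = meth_mod.event_matrix(beta, pairs)
    counts = [(events[p] != "none").sum() for p in pairs]
    return meth_mod.blast_event_correlation(counts, [blasts[p] for p in pairs])


def atac_null_type1_error(
    n_seeds: int = 50,
    seed: int = 0,
    nb_dispersion: float | None = None,
) -> dict:
    """Empirical type-I error of the paired NB Wald test under the null
    (no planted accessibility changes)."""
    rates = []
    base = SimulationConfig(hypo_peak_fraction=0.0)
    if nb_dispersion is not None:
        base.nb_dispersion = nb_dispersion
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        _, counts, meta, _ = simulate_atac(base, int(rng.integers(2**31)))
        diff = atac_mod.differential_accessibility(counts, meta)
        rates.append(float((diff["pvalue"] < 0.05).mean()))
    return {
        "mean_rate": float(np.mean(rates)),
        "max_rate": float(np.max(rates)),
        "n_seeds": n_seeds,
    }


def atac_planted_recall(
    seed: int = 0, sim_config: SimulationConfig | None = None
) -> dict:
    """Recall of planted hypo-accessible peaks (2-fold reduction in 5% of
    peaks at the default design of 6 pairs)."""
    sim_config = sim_config or SimulationConfig()
    _, counts, meta, truth = simulate_atac(sim_config, seed)
    diff = atac_mod.differential_accessibility(counts, meta)
    called_hypo = set(diff.index[diff["direction"] == "hypo"])
    planted = set(truth["hypo_peaks"])
    planted_called = diff.loc[
        diff.index.isin(planted) & diff["significant"]
    ]
    return {
        "recall": len(called_hypo & planted) / len(planted),
        "all_planted_called_hypo": bool(
            (planted_called["direction"] == "hypo").all()
        ),
        "n_planted": len(planted),
    }


def cna_planted_recovery(n_seeds: int = 100, seed: int = 0) -> dict:
    """Recall and direction accuracy for planted >1 Mb copy-number events at
    ~3x coverage, across independent simulations."""
    rng = np.random.default_rng(seed)
    recovered = total = 0
    direction_correct = True
    for _ in range(n_seeds):
        tumor, remission, truth = simulate_cna_coverage(
            SimulationConfig(), int(rng.integers(2**31))
        )
        ratios = cna_mod.coverage_log2ratio(
            cna_mod.gc_correct(tumor), cna_mod.gc_correct(remission)
        )
        calls = cna_mod.call_large_cna(cna_mod.segment_ratios(ratios))
        for t in truth:
            total += 1
            hits = calls.loc[
                (calls["chrom"] == t["chrom"])
                & (calls["start"] < t["end"])
                & (calls["end"] > t["start"])
            ]
            match = hits.loc[
                [
                    (min(h.end, t["end"]) - max(h.start, t["start"]))
                    / (t["end"] - t["start"]) > 0.5
                    for h in hits.itertuples()
                ]
            ]
            if len(match):
                recovered += 1
                if not (match["direction"] == t["direction"]).all():
                    direction_correct = False
    return {
        "recall": recovered / total,
        "direction_always_correct": direction_correct,
        "n_events": total,
        "n_seeds": n_seeds,
    }
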