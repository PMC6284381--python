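"""SNV/InDel concordance between matched samples.

Operations to filter somatic variant tables the way a paired-cohort exome
study does (functional class, population frequency, read support with a
multi-sample rescue), pair variants across matched samples, summarize
preservation by allele-frequency class, and classify each patient's relapse
type (1: clonal set maintained, 2: clonal subset lost) and engraftment mode
(A: clonal composition and architecture captured, B: remodeled by clonal
selection).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ConcordanceConfig
from .stats import pearson_r, poisson_binomial_tail, wilcoxon_paired_p

__all__ = [
    "variant_key",
    "apply_detection_filters",
    "pair_variants",
    "classify_clonality",
    "preservation_summary",
    "af_concordance",
    "pdx_specific_consistency",
    "classify_relapse_type",
    "classify_engraftment_mode",
    "detected_keys",
    "clonal_keys",
]

_FUNCTIONAL_KEEP = {"nonsynonymous", "stopgain", "stoploss"}


def variant_key(df: pd.DataFrame) -> pd.Series:
    """Canonical string key chrom:pos:ref:alt for each record."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str)
    )


def apply_detection_filters(
    records: pd.DataFrame, config: ConcordanceConfig | None = None
) -> pd.DataFrame:
    """Filter raw variant records to confidently called somatic variants.

    Keeps records that are (i) non-synonymous, stopgain or stoploss,
    (ii) at or below the population-frequency ceiling, and (iii) supported by
    at least ``min_supporting_reads`` alt reads -- unless the same variant was
    called in another sample of the same patient, which rescues low-support
    records.
    """
    config = config or ConcordanceConfig()
    for field in ("functional_class", "population_frequency", "alt_reads", "patient"):
        if field not in records.columns:
            raise ValueError(f"missing required annotation field: {field}")
    df = records.copy()
    df["_key"] = variant_key(df)
    keep_class = df["functional_class"].isin(_FUNCTIONAL_KEEP)
    keep_popfreq = df["population_frequency"] <= config.population_frequency_ceiling
    n_samples = df.groupby(["patient", "_key"])["sample_id"].transform("nunique")
    keep_reads = (df["alt_reads"] >= config.min_supporting_reads) | (n_samples >= 2)
    out = df.loc[keep_class & keep_popfreq & keep_reads].drop(columns="_key")
    return out.reset_index(drop=True)


def classify_clonality(af: float, config: ConcordanceConfig | None = None) -> str:
    """'clonal' iff AF >= the clonality threshold (inclusive), else 'subclonal'."""
    config = config or ConcordanceConfig()
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"AF must be in [0, 1], got {af}")
    return "clonal" if af >= config.clonal_af_threshold else "subclonal"


def pair_variants(
    primary: pd.DataFrame,
    pdx: pd.DataFrame,
    config: ConcordanceConfig | None = None,
) -> pd.DataFrame:
    """Outer-join primary and PDX variant tables on (chrom, pos, ref, alt).

    A side without the variant contributes AF 0 and detected=False. Status
    partitions every pairing into preserved / lost / pdx_specific.
    """
    config = config or ConcordanceConfig()
    pats = set(primary.get("patient", pd.Series(dtype=str)).unique()) | set(
        pdx.get("patient", pd.Series(dtype=str)).unique()
    )
    if len(pats) > 1:
        raise ValueError(f"mismatched patient ids in pairing: {sorted(pats)}")

    cols = ["chrom", "pos", "ref", "alt", "gene", "AF", "alt_reads", "total_reads"]

    def _side(df):
        if df.empty:
            return pd.DataFrame(columns=cols)
        return df[[c for c in cols if c in df.columns]].copy()

    left, right = _side(primary), _side(pdx)
    merged = left.merge(
        right, on=["chrom", "pos", "ref", "alt"], how="outer",
        suffixes=("_primary", "_pdx"),
    )
    if "gene_primary" in merged.columns:
        merged["gene"] = merged["gene_primary"].fillna(merged["gene_pdx"])
        merged = merged.drop(columns=["gene_primary", "gene_pdx"])
    merged["detected_primary"] = merged["AF_primary"].notna()
    merged["detected_pdx"] = merged["AF_pdx"].notna()
    for c in ("AF_primary", "AF_pdx", "alt_reads_primary", "alt_reads_pdx",
              "total_reads_primary", "total_reads_pdx"):
        if c in merged.columns:
            merged[c] = pd.to_numeric(merged[c], errors="coerce").fillna(0.0)
    merged["clonality_primary"] = np.where(
        merged["detected_primary"],
        np.where(merged["AF_primary"] >= config.clonal_af_threshold, "clonal",
                 "subclonal"),
        "",
    )
    merged["status"] = np.select(
        [
            merged["detected_primary"] & merged["detected_pdx"],
            merged["detected_primary"] & ~merged["detected_pdx"],
        ],
        ["preserved", "lost"],
        default="pdx_specific",
    )
    merged["key"] = variant_key(merged)
    if merged["key"].duplicated().any():
        raise ValueError("duplicate variant keys within a sample pair")
    return merged


def preservation_summary(
    pairings: pd.DataFrame,
    config: ConcordanceConfig | None = None,
    timepoints: pd.Series | None = None,
) -> pd.DataFrame:
    """Preservation counts and fractions overall, per AF bin, per clonality
    class and (when a per-row timepoint is supplied) per timepoint.

    Only variants detected in the primary enter the denominator; preserved
    means also detected in the PDX.
    """
    config = config or ConcordanceConfig()
    if pairings.empty:
        warnings.warn("empty pairing set; returning empty summary")
        return pd.DataFrame(columns=["scope", "group", "n_total", "n_preserved",
                                     "fraction"])
    df = pairings.loc[pairings["detected_primary"]].copy()
    df["preserved"] = df["status"] == "preserved"
    rows = [
        {
            "scope": "overall",
            "group": "all",
            "n_total": len(df),
            "n_preserved": int(df["preserved"].sum()),
        }
    ]
    edges = list(config.af_bin_edges)
    bins = pd.cut(df["AF_primary"], edges, include_lowest=True)
    for interval, g in df.groupby(bins, observed=False):
        rows.append(
            {
                "scope": "af_bin",
                "group": str(interval),
                "n_total": len(g),
                "n_preserved": int(g["preserved"].sum()),
            }
        )
    for label, g in df.groupby("clonality_primary"):
        rows.append(
            {
                "scope": "clonality",
                "group": label,
                "n_total": len(g),
                "n_preserved": int(g["preserved"].sum()),
            }
        )
    if timepoints is not None:
        df["_tp"] = timepoints.reindex(df.index)
        for label, g in df.groupby("_tp"):
            rows.append(
                {
                    "scope": "timepoint",
                    "group": label,
                    "n_total": len(g),
                    "n_preserved": int(g["preserved"].sum()),
                }
            )
    out = pd.DataFrame(rows)
    out["fraction"] = np.where(
        out["n_total"] > 0, out["n_preserved"] / out["n_total"], np.nan
    )
    return out


def af_concordance(pairings: pd.DataFrame) -> dict:
    """AF agreement of preserved variants: Pearson r, per-side means and a
    two-sided Wilcoxon signed-rank test of the paired AFs."""
    pres = pairings.loc[pairings["status"] == "preserved"]
    out = {
        "n_preserved": int(len(pres)),
        "mean_af_primary": float(pres["AF_primary"].mean()) if len(pres) else float("nan"),
        "mean_af_pdx": float(pres["AF_pdx"].mean()) if len(pres) else float("nan"),
    }
    if len(pres) < 3:
        out["pearson_r"] = float("nan")
        out["wilcoxon_p"] = float("nan")
        return out
    out["pearson_r"] = pearson_r(pres["AF_primary"], pres["AF_pdx"])
    out["wilcoxon_p"] = wilcoxon_paired_p(
        pres["AF_primary"].to_numpy(), pres["AF_pdx"].to_numpy()
    )
    return out


def pdx_specific_consistency(
    afs, config: ConcordanceConfig | None = None
) -> dict:
    """AF dispersion of PDX-specific variants co-occurring in one model.

    A small standard deviation indicates the variants ride on a single
    selected clone; the flag is undefined for fewer than two variants.
    """
    config = config or ConcordanceConfig()
    afs = np.asarray(afs, dtype=float)
    if len(afs) < 2:
        return {"n": int(len(afs)), "af_sd": float("nan"), "single_clone": None}
    sd = float(np.std(afs, ddof=1))
    return {
        "n": int(len(afs)),
        "af_sd": sd,
        "single_clone": bool(sd <= config.single_clone_af_sd_tolerance),
    }


def detected_keys(filtered: pd.DataFrame) -> set[str]:
    """Variant keys present in a filtered table (i.e. called variants)."""
    return set(variant_key(filtered))


def clonal_keys(
    filtered: pd.DataFrame, config: ConcordanceConfig | None = None
) -> set[str]:
    """Keys of variants at or above the clonality AF threshold."""
    config = config or ConcordanceConfig()
    sel = filtered["AF"] >= config.clonal_af_threshold
    return set(variant_key(filtered.loc[sel]))


def classify_relapse_type(
    initial_clonal: set[str], relapse_detected: set[str]
) -> str:
    """Type 1 iff every initial clonal mutation is detected at relapse
    (at any AF); type 2 otherwise."""
    if not initial_clonal:
        raise ValueError("initial clonal mutation set is empty")
    return "type1" if initial_clonal <= set(relapse_detected) else "type2"


def classify_engraftment_mode(
    pairing: pd.DataFrame,
    config: ConcordanceConfig | None = None,
    blast_primary: float = 1.0,
    blast_pdx: float = 1.0,
) -> dict:
    """Mode A (clonal composition and architecture captured) vs mode B
    (remodeled by clonal selection), with reason codes.

    Allele frequencies are blast-corrected before comparison. Mode B is
    called when any of three read-count-backed criteria fires:

    * ``clonal_loss`` -- a clonal primary mutation is absent from the PDX;
    * ``af_shift`` -- a preserved mutation's AF shifts beyond the
      architecture tolerance AND a Fisher exact test on the supporting read
      counts rejects equal underlying frequencies (Bonferroni across the
      preserved mutations at the configured alpha);
    * ``subclone_selection`` -- either a cluster of two or more PDX-specific
      variants at clonal-level AF (a formerly undetected clone selected to
      dominance), or the joint loss of detected subclonal mutations is more
      extreme than sampling dropout explains (Poisson-binomial tail over the
      per-variant dropout probabilities below the configured alpha).

    The per-mutation shift tolerance alone cannot separate 50x sampling noise
    from selection, so each reason is additionally anchored in read-level
    evidence; thresholds stay as configured.
    """
    config = config or ConcordanceConfig()
    if pairing.empty or not pairing["detected_pdx"].any():
        raise ValueError("pairing has no PDX detections; missing PDX sample?")
    df = pairing.copy()
    df["af_c_primary"] = np.clip(df["AF_primary"] / max(blast_primary, 1e-6), 0, 1)
    df["af_c_pdx"] = np.clip(df["AF_pdx"] / max(blast_pdx, 1e-6), 0, 1)

    reasons: list[str] = []
    details: dict = {}

    clonal_pri = df["detected_primary"] & (
        df["af_c_primary"] >= config.clonal_af_threshold
    )
    lost_clonal = df.loc[clonal_pri & ~df["detected_pdx"]]
    if len(lost_clonal):
        reasons.append("clonal_loss")
        details["lost_clonal_keys"] = lost_clonal["key"].tolist()

    # af_shift: Fisher exact on read counts, Bonferroni across preserved
    pres = df.loc[df["status"] == "preserved"]
    n_pres = max(len(pres), 1)
    shift_keys = []
    for _, row in pres.iterrows():
        delta = abs(row["af_c_pdx"] - row["af_c_primary"])
        if delta <= config.architecture_af_tolerance:
            continue
        table = [
            [int(row["alt_reads_primary"]),
             int(row["total_reads_primary"] - row["alt_reads_primary"])],
            [int(row["alt_reads_pdx"]),
             int(row["total_reads_pdx"] - row["alt_reads_pdx"])],
        ]
        if min(row["total_reads_primary"], row["total_reads_pdx"]) < 1:
            continue
        p = sps.fisher_exact(table, alternative="two-sided")[1]
        if p < config.architecture_alpha / n_pres:
            shift_keys.append(row["key"])
    if shift_keys:
        reasons.append("af_shift")
        details["shifted_keys"] = shift_keys

    # subclone_selection (i): PDX-specific clonal-level cluster
    spec = df.loc[
        (df["status"] == "pdx_specific")
        & (df["af_c_pdx"] >= config.clonal_af_threshold)
    ]
    if len(spec) >= 2:
        reasons.append("subclone_selection")
        details["pdx_specific_cluster"] = spec["key"].tolist()

    # subclone_selection (ii): excess dropout of detected subclones
    cand = df.loc[
        df["detected_primary"]
        & (df["af_c_primary"] < config.clonal_af_threshold)
        & (df["af_c_primary"] >= config.dropout_min_af)
    ]
    if len(cand):
        depths = df.loc[df["detected_pdx"], "total_reads_pdx"]
        depth_est = float(depths.mean()) if len(depths) else 50.0
        q = np.array(
            [
                float(
                    sps.binom.cdf(
                        config.min_supporting_reads - 1,
                        max(int(round(depth_est)), 1),
                        min(af * blast_pdx, 1.0),
                    )
                )
                for af in cand["af_c_primary"]
            ]
        )
        k_obs = int((~cand["detected_pdx"]).sum())
        p_drop = poisson_binomial_tail(q, k_obs)
        details["dropout_p"] = p_drop
        details["dropout_k"] = k_obs
        if k_obs >= 1 and p_drop < config.architecture_alpha:
            if "subclone_selection" not in reasons:
                reasons.append("subclone_selection")
            details["dropped_keys"] = cand.loc[~cand["detected_pdx"], "key"].tolist()

    mode = "modeA" if not reasons else "modeB"
    return {"mode": mode, "reasons": reasons, "details": details}
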