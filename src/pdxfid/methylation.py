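"""Promoter methylation concordance between matched samples.

Probe-level beta values are averaged over strand-aware promoter windows
(-1500/+500 bp around the TSS); a matched pair shows an "event" at a
promoter when the beta difference reaches 0.2 in absolute value; recurrence
of events across patients is tested against a binomial baseline, and global
concordance is summarized by rank and linear correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .stats import binomial_tail, pearson_r

__all__ = [
    "aggregate_promoters",
    "call_events",
    "event_matrix",
    "estimate_baseline",
    "binomial_tail",
    "recurrent_promoters",
    "blast_event_correlation",
    "expression_context",
    "global_concordance",
    "variable_promoter_clustering",
]

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


def aggregate_promoters(
    probes: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Average probe betas over promoter windows.

    ``probes`` carries probe_id, chrom, pos and one beta column per sample;
    ``annotation`` carries promoter_id, gene, chrom, tss, strand. The window
    spans 1500 bp upstream to 500 bp downstream of the TSS relative to
    transcription direction; probes falling in overlapping promoters count in
    each. Promoters with fewer than three probes or without a gene symbol are
    flagged ``analyzable=False`` (kept for global correlation, excluded from
    differential analysis).
    """
    sample_cols = [
        c for c in probes.columns if c not in ("probe_id", "chrom", "pos")
    ]
    vals = probes[sample_cols].to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("probe beta values outside [0, 1]")
    rows = []
    by_chrom = {
        chrom: g.sort_values("pos") for chrom, g in probes.groupby("chrom")
    }
    for _, prom in annotation.iterrows():
        g = by_chrom.get(prom["chrom"])
        if g is None:
            n, means = 0, {}
        else:
            if prom.get("strand", "+") == "+":
                lo = prom["tss"] - PROMOTER_UPSTREAM
                hi = prom["tss"] + PROMOTER_DOWNSTREAM
            else:
                lo = prom["tss"] - PROMOTER_DOWNSTREAM
                hi = prom["tss"] + PROMOTER_UPSTREAM
            pos = g["pos"].to_numpy()
            i, j = np.searchsorted(pos, [lo, hi + 1])
            sel = g.iloc[i:j]
            n = len(sel)
            means = {c: float(sel[c].mean()) for c in sample_cols} if n else {}
        gene = prom.get("gene")
        rows.append(
            {
                "promoter_id": prom["promoter_id"],
                "gene": gene,
                "n_probes": n,
                "analyzable": bool(
                    n >= 3 and isinstance(gene, str) and gene != ""
                ),
                **means,
            }
        )
    return pd.DataFrame(rows)


def call_events(
    beta_primary: pd.Series, beta_pdx: pd.Series, delta: float = 0.2
) -> pd.Series:
    """Per-promoter event labels for one matched pair.

    'hyper' when beta_pdx - beta_primary >= delta, 'hypo' when
    beta_primary - beta_pdx >= delta, else 'none'; the threshold is
    inclusive.
    """
    if not beta_primary.index.equals(beta_pdx.index):
        raise ValueError("primary and PDX promoter universes differ")
    d = beta_pdx - beta_primary
    return pd.Series(
        np.select([d >= delta, d <= -delta], ["hyper", "hypo"], default="none"),
        index=beta_primary.index,
        name="event",
    )


def event_matrix(
    beta: pd.DataFrame, pairs: list[str], delta: float = 0.2
) -> pd.DataFrame:
    """Events for each pair, from a beta matrix with ``<pair>_PRI`` /
    ``<pair>_PDX`` columns."""
    return pd.DataFrame(
        {
            pair: call_events(beta[f"{pair}_PRI"], beta[f"{pair}_PDX"], delta)
            for pair in pairs
        }
    )


def estimate_baseline(events: pd.DataFrame) -> tuple[float, float]:
    """Baseline per-direction event probabilities: direction total over
    (promoters x pairs). Returns (p_hypo, p_hyper)."""
    if events.size == 0:
        raise ValueError("empty event matrix")
    total = events.size
    vals = events.to_numpy()
    return (
        float((vals == "hypo").sum() / total),
        float((vals == "hyper").sum() / total),
    )


def recurrent_promoters(
    events: pd.DataFrame,
    p_hypo: float = 0.003,
    p_hyper: float = 0.018,
    rule: str = "count",
    k_hyper: int = 4,
    k_hypo: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Recurrence of methylation events across sample pairs.

    For every promoter and direction, reports the event count k, the number
    of pairs n, and the exact binomial upper-tail probability P(X >= k) at
    the direction's baseline. Significance follows either the count rule
    (hyper in >= ``k_hyper`` pairs / hypo in >= ``k_hypo`` pairs, the
    default) or a tail-probability cutoff (``rule='tail'``).
    """
    if rule not in ("count", "tail"):
        raise ValueError("rule must be 'count' or 'tail'")
    n = events.shape[1]
    vals = events.to_numpy()
    rows = []
    for direction, p_base, k_min in (
        ("hyper", p_hyper, k_hyper),
        ("hypo", p_hypo, k_hypo),
    ):
        k = (vals == direction).sum(axis=1)
        for prom, ki in zip(events.index, k):
            tail = binomial_tail(int(ki), n, p_base)
            sig = (ki >= k_min) if rule == "count" else (tail <= alpha)
            rows.append(
                {
                    "promoter_id": prom,
                    "direction": direction,
                    "k": int(ki),
                    "n": n,
                    "baseline_p": p_base,
                    "tail_p": tail,
                    "significant": bool(sig and ki > 0),
                }
            )
    return pd.DataFrame(rows)


def blast_event_correlation(event_counts, blast) -> float:
    """Pearson correlation between per-pair primary blast content and the
    per-pair total number of methylation events."""
    event_counts = np.asarray(event_counts, dtype=float)
    blast = np.asarray(blast, dtype=float)
    if len(blast) < 3:
        raise ValueError("need at least 3 pairs")
    return pearson_r(blast, event_counts)


def expression_context(
    expression: pd.DataFrame, genes: list[str] | None = None
) -> pd.DataFrame:
    """Classify genes by their expression across patients.

    'expressed' when mean FPKM >= 5; else 'variable' when the SD is >= 3 and
    at least three patients reach 5 FPKM; else 'silent' when mean FPKM <= 2;
    else 'unclassified' (the 2 < mean < 5 gap).
    """
    df = expression if genes is None else expression.loc[
        expression.index.intersection(genes)
    ]
    vals = df.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("negative expression values")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    n_ge5 = (vals >= 5).sum(axis=1)
    cls = np.select(
        [mean >= 5, (sd >= 3) & (n_ge5 >= 3), mean <= 2],
        ["expressed", "variable", "silent"],
        default="unclassified",
    )
    return pd.DataFrame(
        {
            "gene": df.index,
            "mean_fpkm": mean,
            "sd_fpkm": sd,
            "n_patients_ge5": n_ge5,
            "class": cls,
        }
    ).set_index("gene")


def global_concordance(
    beta: pd.DataFrame, pairs: list[str], delta: float = 0.2
) -> dict:
    """Pooled primary-vs-PDX promoter beta concordance.

    Spearman rho and Pearson r over all (promoter, pair) beta values, plus
    the per-pair count of promoters with an absolute difference of at least
    ``delta``.
    """
    pri = np.concatenate([beta[f"{p}_PRI"].to_numpy() for p in pairs])
    pdx = np.concatenate([beta[f"{p}_PDX"].to_numpy() for p in pairs])
    rho = float(sps.spearmanr(pri, pdx)[0])
    r = pearson_r(pri, pdx)
    per_pair = {
        p: int(
            (np.abs(beta[f"{p}_PDX"] - beta[f"{p}_PRI"]) >= delta).sum()
        )
        for p in pairs
    }
    return {"spearman_rho": rho, "pearson_r": r, "events_per_pair": per_pair}


def variable_promoter_clustering(
    beta: pd.DataFrame, top_n: int, n_clusters: int = 2
) -> dict:
    """Hierarchical clustering of samples on the most variable promoters.

    Promoters are ranked by variance across samples (ties broken by
    promoter id); samples are clustered with Euclidean distance and complete
    linkage. Returns the linkage matrix, the sample order (cophenetic leaf
    order) and flat cluster labels.
    """
    if top_n > len(beta):
        raise ValueError("top_n exceeds the number of promoters")
    var = beta.var(axis=1)
    order = sorted(beta.index, key=lambda p: (-var[p], p))
    top = beta.loc[order[:top_n]]
    data = top.to_numpy().T  # samples x promoters
    link = hierarchy.linkage(data, method="complete", metric="euclidean")
    leaves = hierarchy.leaves_list(link)
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return {
        "linkage": link,
        "samples": list(beta.columns),
        "leaf_order": [beta.columns[i] for i in leaves],
        "cluster_labels": dict(zip(beta.columns, labels.tolist())),
        "top_promoters": order[:top_n],
    }
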