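"""Large copy-number alterations from low-coverage WGS, and CNA/MLPA
concordance between matched samples.

Coverage is summarized in uniform 10-kb bins, GC-corrected by decile-median
normalization, expressed as tumor/remission log2 ratios, segmented by
recursive binary splitting on mean shifts, and thresholded into large
(> 1 Mb) amplification/deletion calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "gc_correct",
    "coverage_log2ratio",
    "segment_ratios",
    "call_large_cna",
    "cna_set_concordance",
    "mlpa_concordance",
]


def gc_correct(bins: pd.DataFrame) -> pd.DataFrame:
    """Divide each bin's count by the median count of its GC decile, then
    rescale so the genome-wide median ratio is 1.

    Expects columns chrom, start, gc_fraction, read_count; returns a copy
    with a ``ratio`` column.
    """
    if len(bins) < 100:
        raise ValueError("need at least 100 bins for GC correction")
    counts = bins["read_count"].to_numpy(dtype=float)
    if not np.any(counts > 0):
        raise ValueError("all-zero coverage")
    gc = bins["gc_fraction"].to_numpy(dtype=float)
    deciles = np.clip(
        np.searchsorted(np.quantile(gc, np.linspace(0.1, 0.9, 9)), gc, side="right"),
        0, 9,
    )
    ratio = np.empty_like(counts)
    for d in range(10):
        sel = deciles == d
        if not sel.any():
            continue
        med = np.median(counts[sel])
        ratio[sel] = counts[sel] / med if med > 0 else 0.0
    med_all = np.median(ratio[ratio > 0])
    if med_all > 0:
        ratio = ratio / med_all
    out = bins.copy()
    out["ratio"] = ratio
    return out


def coverage_log2ratio(
    tumor: pd.DataFrame,
    remission: pd.DataFrame,
    pseudocount: float = 0.5,
    min_remission_count: int = 10,
) -> pd.DataFrame:
    """Per-bin log2((tumor + eps) / (remission + eps)); bins with remission
    read count below the floor are masked (NaN).

    Operates on the ``ratio`` column when present (GC-corrected input, with
    the 0.5-count pseudocount rescaled to the ratio scale), else on raw
    ``read_count``. Both inputs must share the same bin grid.
    """
    if len(tumor) != len(remission) or not (
        tumor["chrom"].to_numpy() == remission["chrom"].to_numpy()
    ).all() or not (
        tumor["start"].to_numpy() == remission["start"].to_numpy()
    ).all():
        raise ValueError("tumor and remission bin grids differ")
    if "ratio" in tumor.columns and "ratio" in remission.columns:
        eps_t = pseudocount / max(np.median(tumor["read_count"]), 1.0)
        eps_r = pseudocount / max(np.median(remission["read_count"]), 1.0)
        vt = tumor["ratio"].to_numpy(dtype=float)
        vr = remission["ratio"].to_numpy(dtype=float)
    else:
        eps_t = eps_r = pseudocount
        vt = tumor["read_count"].to_numpy(dtype=float)
        vr = remission["read_count"].to_numpy(dtype=float)
    log2r = np.log2((vt + eps_t) / (vr + eps_r))
    log2r = np.where(remission["read_count"].to_numpy() < min_remission_count,
                     np.nan, log2r)
    out = tumor[["chrom", "start"]].copy()
    out["log2_ratio"] = log2r
    return out


def _binary_segment(x: np.ndarray, min_seg_bins: int, z_threshold: float,
                    offset: int, out: list) -> None:
    n = len(x)
    if n < 2 * min_seg_bins:
        out.append((offset, offset + n))
        return
    s = float(np.std(x, ddof=1))
    if s == 0:
        out.append((offset, offset + n))
        return
    cs = np.cumsum(x)
    idx = np.arange(min_seg_bins, n - min_seg_bins + 1)
    m1 = cs[idx - 1] / idx
    m2 = (cs[-1] - cs[idx - 1]) / (n - idx)
    z = np.abs(m1 - m2) / (s * np.sqrt(1.0 / idx + 1.0 / (n - idx)))
    j = int(np.argmax(z))
    if z[j] > z_threshold:
        split = int(idx[j])
        _binary_segment(x[:split], min_seg_bins, z_threshold, offset, out)
        _binary_segment(x[split:], min_seg_bins, z_threshold, offset + split, out)
    else:
        out.append((offset, offset + n))


def segment_ratios(
    ratios: pd.DataFrame,
    min_seg_bins: int = 10,
    z_threshold: float = 5.0,
    bin_width: int = 10_000,
) -> pd.DataFrame:
    """Piecewise-constant segmentation of per-bin log2 ratios.

    Recursive binary splitting per chromosome: a split is accepted when the
    two-sample z statistic of the segment means exceeds ``z_threshold`` and
    both sides span at least ``min_seg_bins`` bins. Deterministic for fixed
    input. Masked (NaN) bins are excluded from the statistics but retain
    their genomic positions in the emitted segments.
    """
    segs = []
    for chrom, g in ratios.groupby("chrom", sort=False):
        g = g.sort_values("start")
        valid = g.loc[g["log2_ratio"].notna()]
        if valid.empty:
            continue
        x = valid["log2_ratio"].to_numpy()
        starts = valid["start"].to_numpy()
        pieces: list[tuple[int, int]] = []
        _binary_segment(x, min_seg_bins, z_threshold, 0, pieces)
        for a, b in sorted(pieces):
            segs.append(
                {
                    "chrom": chrom,
                    "start": int(starts[a]),
                    "end": int(starts[b - 1]) + bin_width,
                    "n_bins": b - a,
                    "mean_log2_ratio": float(np.mean(x[a:b])),
                }
            )
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "n_bins",
                                       "mean_log2_ratio"])


def call_large_cna(
    segments: pd.DataFrame,
    gain_cut: float = 0.3,
    loss_cut: float = -0.3,
    min_size: int = 1_000_000,
) -> pd.DataFrame:
    """Emit large CNA calls from segments beyond the amplitude cutoffs and
    the minimum size (strictly greater than ``min_size``)."""
    if segments.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction",
                                     "mean_log2_ratio", "size"])
    df = segments.copy()
    df["size"] = df["end"] - df["start"]
    gains = df.loc[(df["mean_log2_ratio"] >= gain_cut) & (df["size"] > min_size)].copy()
    gains["direction"] = "amplification"
    losses = df.loc[(df["mean_log2_ratio"] <= loss_cut) & (df["size"] > min_size)].copy()
    losses["direction"] = "deletion"
    out = pd.concat([gains, losses], ignore_index=True)
    return out[["chrom", "start", "end", "direction", "mean_log2_ratio", "size"]]


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def cna_set_concordance(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    min_reciprocal_overlap: float = 0.5,
) -> dict:
    """Fraction of calls in ``calls_a`` matched by a same-direction call in
    ``calls_b`` with at least the given reciprocal overlap."""
    n_total = len(calls_a)
    n_preserved = 0
    for _, a in calls_a.iterrows():
        for _, b in calls_b.iterrows():
            if a["chrom"] != b["chrom"] or a["direction"] != b["direction"]:
                continue
            if _reciprocal_overlap(a["start"], a["end"], b["start"], b["end"]) >= \
                    min_reciprocal_overlap:
                n_preserved += 1
                break
    return {
        "n_preserved": n_preserved,
        "n_total": n_total,
        "fraction": n_preserved / n_total if n_total else float("nan"),
    }


def mlpa_concordance(primary: pd.DataFrame, pdx: pd.DataFrame) -> dict:
    """Retention of targeted copy-number aberrations between matched samples.

    Both tables carry (sample_id, region, state) with state in
    {deleted, normal, amplified}; the numerator counts non-normal primary
    states matched by the identical state in the PDX record of the same
    region.
    """
    valid = {"deleted", "normal", "amplified"}
    for df, name in ((primary, "primary"), (pdx, "pdx")):
        bad = set(df["state"]) - valid
        if bad:
            raise ValueError(f"invalid MLPA states in {name}: {bad}")
    if set(primary["region"]) != set(pdx["region"]):
        raise ValueError("MLPA region panels differ between primary and PDX")
    pdx_state = pdx.set_index("region")["state"]
    aberrant = primary.loc[primary["state"] != "normal"]
    n_total = len(aberrant)
    n_preserved = int(
        (aberrant["state"].to_numpy()
         == pdx_state.reindex(aberrant["region"]).to_numpy()).sum()
    )
    return {
        "n_preserved": n_preserved,
        "n_total": n_total,
        "fraction": n_preserved / n_total if n_total else float("nan"),
    }
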