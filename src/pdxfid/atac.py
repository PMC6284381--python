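"""ATAC-seq QC metrics and primary-vs-PDX accessibility concordance.

Quality control (TSS enrichment, FRiP, insert-size structure), height-
stratified peak sharing between matched peak sets, per-peak count agreement,
median-of-ratios normalization, a paired negative-binomial Wald test for
differential accessibility (a self-contained approximation of the standard
multi-factor count-model engines), shuffle-based annotation overlap
enrichment, and PCA of the count matrix.

All intervals are 0-based half-open; adjacent intervals do not overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "tss_enrichment",
    "frip",
    "peak_sharing_curve",
    "per_peak_concordance",
    "size_factors",
    "differential_accessibility",
    "shuffled_overlap_enrichment",
    "pca_embedding",
    "insert_size_summary",
]


def tss_enrichment(
    profile: np.ndarray, center_halfwidth: int = 50, flank_width: int = 100
) -> float:
    """ENCODE-style TSS enrichment score of an aggregate coverage profile.

    ``profile`` is per-base coverage of a window centered on the TSS
    (aggregated over the TSS set); the score is the mean coverage of the
    central +/- ``center_halfwidth`` bp divided by the mean coverage of the
    outermost ``flank_width`` bp on each side. NaN when the flanks carry no
    signal.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim == 2:  # per-TSS matrix: aggregate first
        profile = profile.mean(axis=0)
    n = len(profile)
    mid = n // 2
    center = profile[mid - center_halfwidth : mid + center_halfwidth + 1]
    flanks = np.concatenate([profile[:flank_width], profile[-flank_width:]])
    if flanks.mean() == 0:
        return float("nan")
    return float(center.mean() / flanks.mean())


def frip(in_peak_counts, total_reads) -> np.ndarray:
    """Fraction of reads in peaks per sample."""
    in_peak = np.atleast_1d(np.asarray(in_peak_counts, dtype=float))
    total = np.atleast_1d(np.asarray(total_reads, dtype=float))
    if np.any(total <= 0):
        raise ValueError("total mapped reads must be positive")
    return in_peak / total


def _trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, g in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(g["start"].astype(int), g["end"].astype(int))
        )
    return trees


def peak_sharing_curve(
    peaks_primary: pd.DataFrame,
    peaks_pdx: pd.DataFrame,
    height_thresholds,
) -> pd.DataFrame:
    """Fraction of primary peaks shared with the PDX, by height threshold.

    For each threshold t, among primary peaks with height >= t, the fraction
    overlapped (>= 1 bp, half-open semantics) by any PDX peak. The curve is
    reported as computed, without forced monotonicity.
    """
    trees = _trees(peaks_pdx)
    overlapped = np.array(
        [
            bool(trees.get(row.chrom) and trees[row.chrom].overlap(row.start, row.end))
            for row in peaks_primary.itertuples()
        ]
    )
    heights = peaks_primary["height"].to_numpy(dtype=float)
    rows = []
    for t in height_thresholds:
        sel = heights >= t
        n = int(sel.sum())
        rows.append(
            {
                "height_threshold": t,
                "n_peaks": n,
                "n_shared": int(overlapped[sel].sum()),
                "fraction_shared": overlapped[sel].mean() if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors, anchored to geometric mean 1.

    Falls back to total-count ratios (with a warning) when no peak is
    nonzero in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        logs = np.log(mat[all_nonzero])
        log_gm = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - log_gm, axis=0))
    else:
        warnings.warn("no all-nonzero peak; using total-count size factors")
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(np.maximum(totals, 1))))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def per_peak_concordance(counts: pd.DataFrame, sample_a: str, sample_b: str) -> dict:
    """Pearson correlation (and r^2) of log1p size-factor-normalized per-peak
    counts between two samples."""
    if len(counts) < 10:
        raise ValueError("need at least 10 peaks")
    sub = counts[[sample_a, sample_b]]
    sf = size_factors(sub)
    norm = np.log1p(sub / sf)
    x, y = norm[sample_a].to_numpy(), norm[sample_b].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return {"pearson_r": float("nan"), "r_squared": float("nan")}
    r = float(sps.pearsonr(x, y)[0])
    return {"pearson_r": r, "r_squared": r * r}


def differential_accessibility(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    lfc_threshold: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired negative-binomial Wald test for PDX-vs-primary accessibility.

    Counts are normalized by median-of-ratios size factors. Per peak, the
    condition effect is estimated from the per-patient log2 ratios
    (patient acts as a blocking factor), weighted inversely to a delta-method
    variance built from a method-of-moments NB dispersion shrunk halfway to a
    mean-dependent trend. The Wald statistic is referred to a t distribution
    with (pairs - 1) degrees of freedom. A peak is significant when p < alpha
    and |log2FC| > lfc_threshold; positive log2FC means hyper-accessible in
    the PDX.
    """
    patients = sorted(meta["patient"].unique())
    if len(patients) < 3:
        raise ValueError("need at least 3 patient pairs")
    pri_cols, pdx_cols = [], []
    for p in patients:
        sel = meta.loc[meta["patient"] == p]
        pri = sel.index[sel["condition"] == "PRI"]
        pdx = sel.index[sel["condition"] == "PDX"]
        if len(pri) != 1 or len(pdx) != 1:
            raise ValueError(f"patient {p} is not a complete primary/PDX pair")
        pri_cols.append(pri[0])
        pdx_cols.append(pdx[0])

    sf = size_factors(counts)
    norm = counts / sf
    a = norm[pri_cols].to_numpy(dtype=float)  # peaks x pairs, primary
    b = norm[pdx_cols].to_numpy(dtype=float)
    n_pairs = len(patients)
    ln2sq = np.log(2.0) ** 2

    d = np.log2(b + 0.5) - np.log2(a + 0.5)  # per-pair log2 ratios
    mu_a = np.maximum(a, 0.5)
    mu_b = np.maximum(b, 0.5)
    count_var = (1.0 / mu_a + 1.0 / mu_b) / ln2sq  # Poisson part of Var(d)

    # method-of-moments dispersion from the residual variance of d
    s2 = d.var(axis=1, ddof=1)
    alpha_hat = np.maximum(0.0, (s2 - count_var.mean(axis=1)) * ln2sq / 2.0)
    base_mean = (a.mean(axis=1) + b.mean(axis=1)) / 2.0
    # mean-dependent trend: median dispersion in log-mean bins
    order = np.argsort(base_mean)
    trend = np.empty_like(alpha_hat)
    n_bins = max(10, len(alpha_hat) // 500)
    splits = np.array_split(order, n_bins)
    for idx in splits:
        trend[idx] = np.median(alpha_hat[idx])
    disp = 0.5 * alpha_hat + 0.5 * trend

    var_d = count_var + 2.0 * disp[:, None] / ln2sq
    w = 1.0 / np.maximum(var_d, 1e-12)
    lfc = (w * d).sum(axis=1) / w.sum(axis=1)
    se = 1.0 / np.sqrt(w.sum(axis=1))
    stat = lfc / se
    pval = 2.0 * sps.t.sf(np.abs(stat), df=n_pairs - 1)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "dispersion": disp,
            "stat": stat,
            "pvalue": pval,
        },
        index=counts.index,
    )
    out["significant"] = (out["pvalue"] < alpha) & (
        np.abs(out["log2_fold_change"]) > lfc_threshold
    )
    out["direction"] = np.select(
        [out["significant"] & (out["log2_fold_change"] > 0),
         out["significant"] & (out["log2_fold_change"] < 0)],
        ["hyper", "hypo"],
        default="none",
    )
    return out


def _merge_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = {}
    for chrom, g in df.groupby("chrom"):
        ivs = g.sort_values("start")[["start", "end"]].to_numpy()
        starts, ends = [], []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
        starts.append(cur_s)
        ends.append(cur_e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def _count_overlaps(
    starts: np.ndarray, ends: np.ndarray, ann: tuple[np.ndarray, np.ndarray]
) -> int:
    a_start, a_end = ann
    idx = np.searchsorted(a_start, ends, side="left")
    hit = (idx > 0) & (a_end[np.maximum(idx - 1, 0)] > starts)
    return int(hit.sum())


def shuffled_overlap_enrichment(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom_sizes: dict[str, int],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Observed vs expected peak-annotation overlap under random placement.

    The null preserves each peak's width and chromosome, placing it uniformly
    within the chromosome. Returns the observed overlapping-peak count, the
    mean and SD of the shuffled counts, and their ratio.
    """
    missing = set(peaks["chrom"]) - set(chrom_sizes)
    if missing:
        raise ValueError(f"chrom_sizes missing chromosomes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    ann = _merge_intervals(annotation)
    observed = 0
    expected_counts = np.zeros(n_shuffles)
    for chrom, g in peaks.groupby("chrom"):
        widths = (g["end"] - g["start"]).to_numpy()
        if np.any(widths > chrom_sizes[chrom]):
            raise ValueError(f"peak wider than chromosome {chrom}")
        if chrom in ann:
            observed += _count_overlaps(
                g["start"].to_numpy(), g["end"].to_numpy(), ann[chrom]
            )
            limit = chrom_sizes[chrom] - widths
            for i in range(n_shuffles):
                s = (rng.uniform(size=len(widths)) * (limit + 1)).astype(np.int64)
                expected_counts[i] += _count_overlaps(s, s + widths, ann[chrom])
    exp_mean = float(expected_counts.mean())
    exp_sd = float(expected_counts.std(ddof=1)) if n_shuffles > 1 else float("nan")
    return {
        "observed": observed,
        "expected_mean": exp_mean,
        "expected_sd": exp_sd,
        "ratio": observed / exp_mean if exp_mean > 0 else float("inf"),
    }


def pca_embedding(
    counts: pd.DataFrame, top_n_variable_peaks: int = 1000, n_components: int = 2
) -> pd.DataFrame:
    """Sample coordinates on the first principal components of the log1p
    size-factor-normalized counts, restricted to the most variable peaks.

    The sign of each component is fixed by making its largest-magnitude
    loading positive.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sf = size_factors(counts)
    norm = np.log1p(counts / sf)
    var = norm.var(axis=1)
    top = norm.loc[var.nlargest(min(top_n_variable_peaks, len(norm))).index]
    data = top.to_numpy().T  # samples x peaks
    data = data - data.mean(axis=0)
    n_comp = min(n_components, data.shape[0] - 1, data.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(data)
    for k in range(n_comp):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] = -coords[:, k]
    return pd.DataFrame(
        coords,
        index=counts.columns,
        columns=[f"PC{k + 1}" for k in range(n_comp)],
    )


def insert_size_summary(fragment_lengths, nucleosome_band=(180, 247)) -> dict:
    """Sub-nucleosomal and mono-nucleosomal fragment fractions, and whether
    the length histogram shows the characteristic mono-nucleosome peak
    (a local maximum inside the 180-247 bp band)."""
    lengths = np.asarray(fragment_lengths, dtype=float)
    if len(lengths) == 0:
        raise ValueError("empty fragment-length input")
    if len(lengths) < 1000:
        warnings.warn("fewer than 1000 fragments; summaries will be noisy")
    lo, hi = nucleosome_band
    frac_sub100 = float((lengths < 100).mean())
    frac_mono = float(((lengths >= lo) & (lengths <= hi)).mean())
    edges = np.arange(0, max(lengths.max(), hi + 60) + 10, 10)
    hist, _ = np.histogram(lengths, bins=edges)
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(hist, kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2
    band = (centers >= lo) & (centers <= hi)
    flag = False
    if band.any():
        i0 = np.flatnonzero(band)[0]
        for i in np.flatnonzero(band):
            left = smooth[i - 1] if i > 0 else 0.0
            right = smooth[i + 1] if i < len(smooth) - 1 else 0.0
            if smooth[i] > 0 and smooth[i] >= left and smooth[i] >= right and (
                smooth[i] > left or smooth[i] > right
            ):
                flag = True
                break
        del i0
    return {
        "fraction_sub100": frac_sub100,
        "fraction_mononucleosome": frac_mono,
        "nucleosome_periodicity": bool(flag),
    }
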