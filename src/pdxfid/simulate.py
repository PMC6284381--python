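"""Synthetic matched primary/PDX cohorts with known ground truth.

Every downstream stage of the fidelity analysis is exercised against data
from this module: variant tables sampled read-by-read from clone phylogenies,
promoter methylation matrices built from a blast-content mixture model,
negative-binomially distributed ATAC peak counts with height-dependent peak
reproducibility, and GC-biased binned coverage with planted copy-number
segments. Fixed seeds give byte-identical outputs.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .phylogeny import (
    ClonePhylogeny,
    simulate_clone_tree,
    simulate_engraftment,
    simulate_relapse,
)

__all__ = [
    "mutation_locus",
    "render_variant_table",
    "simulate_methylation",
    "simulate_atac",
    "simulate_cna_coverage",
    "simulate_preservation_cohort",
    "simulate_patient",
    "simulate_cohort",
]

_BASES = ("A", "C", "G", "T")

VARIANT_COLUMNS = [
    "patient",
    "sample_id",
    "timepoint",
    "origin",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "functional_class",
    "population_frequency",
    "alt_reads",
    "total_reads",
    "AF",
    "detected",
]


def mutation_locus(mutation_id: str) -> tuple[str, int, str, str, str]:
    """Deterministic (chrom, pos, ref, alt, gene) for a mutation id.

    The same id maps to the same locus in every sample of a patient, so
    variant keys are comparable across tables.
    """
    h = zlib.crc32(mutation_id.encode())
    chrom = f"chr{1 + h % 22}"
    pos = 1_000_000 + (h // 22) % 100_000_000
    ref = _BASES[h % 4]
    alt = _BASES[(h % 4 + 1 + (h >> 8) % 3) % 4]
    gene = f"GENE{h % 5000:04d}"
    return chrom, pos, ref, alt, gene


def render_variant_table(
    phylo: ClonePhylogeny,
    depth: float,
    blast: float,
    seed: int,
    patient: str = "P1",
    sample_id: str = "P1_INI_PRI",
    timepoint: str = "INI",
    origin: str = "PRI",
    min_supporting_reads: int = 5,
) -> pd.DataFrame:
    """Sample an observed somatic-variant table from a clone phylogeny.

    Under the heterozygous-diploid model the expected AF of a mutation is
    ``0.5 * blast * cell_fraction``. Total reads per site are Poisson(depth),
    alt reads binomial; only sites with at least one alt read yield a row
    (a caller emits nothing otherwise), and rows with fewer than
    ``min_supporting_reads`` alt reads are flagged as not detected.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 < blast <= 1.0:
        raise ValueError("blast must be in (0, 1]")
    phylo.validate()
    rng = np.random.default_rng(seed)
    fractions = phylo.mutation_fractions()
    muts = sorted(fractions)
    n = len(muts)
    exp_af = 0.5 * blast * np.array([fractions[m] for m in muts])
    total = rng.poisson(depth, size=n)
    alt = rng.binomial(total, np.clip(exp_af, 0.0, 1.0))
    rows = []
    for i, m in enumerate(muts):
        if alt[i] < 1:
            continue
        chrom, pos, ref, altb, gene = mutation_locus(m)
        rows.append(
            {
                "patient": patient,
                "sample_id": sample_id,
                "timepoint": timepoint,
                "origin": origin,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": altb,
                "gene": gene,
                "functional_class": "nonsynonymous",
                "population_frequency": 0.0,
                "alt_reads": int(alt[i]),
                "total_reads": int(total[i]),
                "AF": float(alt[i] / total[i]) if total[i] > 0 else 0.0,
                "detected": bool(alt[i] >= min_supporting_reads),
                "mutation_id": m,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["mutation_id"])


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation(
    config: SimulationConfig,
    blast_per_sample: dict[str, float],
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Promoter beta matrix for matched primary/PDX pairs, plus truth labels.

    Observed primary beta is a blast-content mixture of a leukemic and a
    normal methylome plus Gaussian noise; the PDX side is pure leukemia
    (blast ~1). A designated immune-like promoter set gains
    ``hypermethylation_delta`` in the PDX compartment of the first
    ``n_hyper_patients`` patients -- the planted recurrent set.

    Returns a beta DataFrame (promoters x samples, columns ``<pair>_PRI`` /
    ``<pair>_PDX``) and a truth dict with the planted promoter ids.
    """
    for b in blast_per_sample.values():
        if not 0.0 < b <= 1.0:
            raise ValueError("blast values must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = config.n_promoters
    promoters = [f"PROM{i:05d}" for i in range(n)]
    beta_leuk = rng.beta(0.4, 0.4, size=n)
    # normal hematopoietic background: identical except for a differential
    # subset shifted by a moderate (Laplace) amount, as between related
    # blood cell types
    beta_norm = beta_leuk.copy()
    diff_idx = rng.choice(
        n, size=int(round(config.celltype_differential_fraction * n)), replace=False
    )
    beta_norm[diff_idx] = np.clip(
        beta_norm[diff_idx]
        + rng.laplace(0, config.celltype_shift_scale, size=len(diff_idx)),
        0, 1,
    )
    # hypermethylation targets are promoters with headroom to gain
    # methylation (lowly methylated in the leukemia)
    low = np.flatnonzero(beta_leuk <= 0.5)
    planted_idx = rng.choice(
        low, size=min(config.immune_gene_set_size, len(low)), replace=False
    )
    pairs = sorted(blast_per_sample)
    hyper_pairs = pairs[: config.n_hyper_patients]

    cols = {}
    for pair in pairs:
        b = blast_per_sample[pair]
        pri = b * beta_leuk + (1 - b) * beta_norm
        pri = pri + rng.normal(0, config.beta_noise_sd, size=n)
        leuk_pdx = beta_leuk.copy()
        if pair in hyper_pairs:
            leuk_pdx[planted_idx] = leuk_pdx[planted_idx] + config.hypermethylation_delta
        pdx = leuk_pdx + rng.normal(0, config.beta_noise_sd, size=n)
        cols[f"{pair}_PRI"] = np.clip(pri, 0, 1)
        cols[f"{pair}_PDX"] = np.clip(pdx, 0, 1)
    beta = pd.DataFrame(cols, index=pd.Index(promoters, name="promoter"))
    truth = {
        "planted_hyper_promoters": [promoters[i] for i in sorted(planted_idx)],
        "hyper_pairs": hyper_pairs,
        "celltype_differential_promoters": [promoters[i] for i in sorted(diff_idx)],
        "blast_per_sample": dict(blast_per_sample),
    }
    return beta, truth


# ---------------------------------------------------------------------------
# ATAC


def _nb_draw(rng, mean, dispersion):
    """Negative binomial with mean/dispersion parameterization
    (Var = mean + dispersion * mean^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_atac(
    config: SimulationConfig, seed: int
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, dict]:
    """Synthetic ATAC peak sets and a paired count matrix with truth labels.

    Peaks live on a three-chromosome toy genome. Per-peak counts are negative
    binomial around ``height * patient_effect * size_factor``. A primary peak
    is re-called in the PDX with probability ``1 - exp(-height / scale)``
    (increasing, saturating near 1), and a designated hypo-accessible subset
    has its PDX-side means multiplied by ``hypo_peak_factor``.

    Returns (peak sets per condition, count matrix, sample metadata, truth).
    """
    rng = np.random.default_rng(seed)
    chroms = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    n = config.n_peaks
    chrom_names = list(chroms)
    chrom_idx = rng.integers(len(chrom_names), size=n)
    widths = rng.integers(200, 1000, size=n)
    starts = np.array(
        [
            rng.integers(0, chroms[chrom_names[c]] - w)
            for c, w in zip(chrom_idx, widths)
        ]
    )
    heights = np.exp(
        rng.normal(config.peak_height_log_mean, config.peak_height_log_sd, size=n)
    )
    peaks_primary = pd.DataFrame(
        {
            "peak_id": [f"peak{i:05d}" for i in range(n)],
            "chrom": [chrom_names[c] for c in chrom_idx],
            "start": starts,
            "end": starts + widths,
            "height": heights,
        }
    )
    p_recall = 1.0 - np.exp(-heights / config.reproducibility_height_scale)
    recalled = rng.uniform(size=n) < p_recall
    jitter = rng.integers(-100, 101, size=n)
    pdx = peaks_primary.loc[recalled].copy()
    pdx["start"] = np.clip(pdx["start"] + jitter[recalled], 0, None)
    pdx["end"] = pdx["start"] + widths[recalled]

    n_pairs = config.n_atac_pairs
    hypo_idx = rng.choice(
        n, size=int(round(config.hypo_peak_fraction * n)), replace=False
    )
    hypo_mask = np.zeros(n, dtype=bool)
    hypo_mask[hypo_idx] = True

    samples, cols = [], {}
    for p in range(n_pairs):
        patient = f"P{p + 1}"
        patient_effect = np.exp(
            rng.normal(0, config.atac_patient_effect_sd, size=n)
        )
        for cond in ("PRI", "PDX"):
            sf = float(np.exp(rng.normal(0, config.atac_size_factor_sd)))
            mu = heights * patient_effect * sf
            if cond == "PDX":
                mu = np.where(hypo_mask, mu * config.hypo_peak_factor, mu)
            sid = f"{patient}_{cond}"
            cols[sid] = _nb_draw(rng, mu, config.nb_dispersion)
            samples.append({"sample_id": sid, "patient": patient, "condition": cond})
    counts = pd.DataFrame(cols, index=pd.Index(peaks_primary["peak_id"], name="peak_id"))
    meta = pd.DataFrame(samples).set_index("sample_id")
    truth = {
        "hypo_peaks": peaks_primary.loc[hypo_mask, "peak_id"].tolist(),
        "recall_probability": p_recall,
        "recalled": recalled,
        "chrom_sizes": chroms,
    }
    return {"PRI": peaks_primary, "PDX": pdx}, counts, meta, truth


# ---------------------------------------------------------------------------
# low-coverage WGS


def simulate_cna_coverage(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """10-kb binned tumor and remission coverage with planted large CNAs.

    Both samples share a multiplicative GC bias; the tumor carries
    ``n_planted_cna`` segments of copy number 1 or 3 spanning more than 1 Mb.
    Counts are Poisson around ~3x coverage.
    """
    rng = np.random.default_rng(seed)
    frames, truth = [], []
    width = config.cna_bin_width
    for ci in range(config.cna_n_chroms):
        chrom = f"chr{ci + 1}"
        nb = config.cna_bins_per_chrom
        gc = np.clip(rng.normal(0.41, 0.06, size=nb), 0.2, 0.8)
        bias = np.exp(config.cna_gc_bias_strength * (gc - 0.41))
        cn = np.full(nb, 2.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(nb) * width,
                    "gc_fraction": gc,
                    "_bias": bias,
                    "_cn": cn,
                }
            )
        )
    bins = pd.concat(frames, ignore_index=True)

    occupied: dict[str, list[tuple[int, int]]] = {}
    for k in range(config.n_planted_cna):
        chrom = f"chr{1 + k % config.cna_n_chroms}"
        sel = bins["chrom"] == chrom
        nb = int(sel.sum())
        seg_bins = int(rng.integers(120, 400))  # 1.2 - 4 Mb
        margin = 50  # keep planted segments well separated
        for _ in range(100):
            start_bin = int(rng.integers(0, nb - seg_bins))
            if all(
                start_bin + seg_bins + margin <= s or start_bin >= e + margin
                for s, e in occupied.get(chrom, [])
            ):
                break
        else:
            continue
        occupied.setdefault(chrom, []).append((start_bin, start_bin + seg_bins))
        cn = float(rng.choice([1.0, 3.0]))
        idx = bins.index[sel][start_bin : start_bin + seg_bins]
        bins.loc[idx, "_cn"] = cn
        truth.append(
            {
                "chrom": chrom,
                "start": start_bin * config.cna_bin_width,
                "end": (start_bin + seg_bins) * config.cna_bin_width,
                "copy_number": cn,
                "direction": "deletion" if cn < 2 else "amplification",
            }
        )

    lam_rem = config.cna_base_count * bins["_bias"].to_numpy()
    lam_tum = lam_rem * bins["_cn"].to_numpy() / 2.0
    remission = bins[["chrom", "start", "gc_fraction"]].copy()
    remission["read_count"] = rng.poisson(lam_rem)
    tumor = bins[["chrom", "start", "gc_fraction"]].copy()
    tumor["read_count"] = rng.poisson(lam_tum)
    return tumor, remission, truth


# ---------------------------------------------------------------------------
# cohorts


def simulate_preservation_cohort(
    n_patients: int,
    seed: int,
    p_clonal: float = 0.93,
    p_subclonal: float = 0.48,
    depth: float = 50.0,
    muts_range: tuple[int, int] = (15, 40),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Idealized per-mutation preservation cohort for parameter recovery.

    Each patient carries a mix of clonal (AF ~ U(0.30, 0.55)) and subclonal
    (AF ~ U(0.20, 0.30)) mutations; each is independently preserved in the
    PDX with the per-class Bernoulli probability. Read support is sampled at
    ``depth`` on both sides. Returns (primary table, pdx table, truth).
    """
    rng = np.random.default_rng(seed)
    pri_rows, pdx_rows, truth_rows = [], [], []
    mut_counter = 0
    for p in range(n_patients):
        patient = f"P{p + 1}"
        n_mut = int(rng.integers(muts_range[0], muts_range[1] + 1))
        for _ in range(n_mut):
            mid = f"S{mut_counter:05d}"
            mut_counter += 1
            clonal = bool(rng.uniform() < 0.5)
            af = float(rng.uniform(0.30, 0.55) if clonal else rng.uniform(0.20, 0.30))
            preserved = bool(
                rng.uniform() < (p_clonal if clonal else p_subclonal)
            )
            chrom, pos, ref, alt, gene = mutation_locus(patient + mid)
            base = {
                "patient": patient,
                "timepoint": "INI",
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "functional_class": "nonsynonymous",
                "population_frequency": 0.0,
                "mutation_id": mid,
            }
            for side, present in (("PRI", True), ("PDX", preserved)):
                if not present:
                    continue
                total = int(rng.poisson(depth))
                a = int(rng.binomial(total, af)) if total > 0 else 0
                if a < 1:
                    continue
                row = dict(base)
                row.update(
                    {
                        "sample_id": f"{patient}_INI_{side}",
                        "origin": side,
                        "alt_reads": a,
                        "total_reads": total,
                        "AF": a / total,
                        "detected": a >= 5,
                    }
                )
                (pri_rows if side == "PRI" else pdx_rows).append(row)
            truth_rows.append(
                {
                    "patient": patient,
                    "mutation_id": mid,
                    "key": f"{chrom}:{pos}:{ref}:{alt}",
                    "clonal": clonal,
                    "true_af": af,
                    "preserved": preserved,
                }
            )
    cols = VARIANT_COLUMNS + ["mutation_id"]
    return (
        pd.DataFrame(pri_rows, columns=cols),
        pd.DataFrame(pdx_rows, columns=cols),
        pd.DataFrame(truth_rows),
    )


def simulate_patient(
    patient: str,
    config: SimulationConfig,
    seed: int,
    relapse_type: int | None = None,
    mode_ini: str | None = None,
    mode_rel: str | None = None,
) -> dict:
    """Simulate one patient: initial and relapse phylogenies, engrafted PDX
    phylogenies, and the four observed variant tables (INI/REL x PRI/PDX).

    Returns a dict carrying the tables, phylogenies and truth labels.
    """
    rng = np.random.default_rng(seed)
    relapse_type = relapse_type if relapse_type is not None else int(rng.integers(1, 3))
    mode_ini = mode_ini if mode_ini is not None else ("A" if rng.uniform() < 0.5 else "B")
    mode_rel = mode_rel if mode_rel is not None else ("A" if rng.uniform() < 0.5 else "B")
    n_clones = int(rng.integers(*config.n_clones_range, endpoint=True))
    n_mut = int(rng.integers(*config.n_mutations_range, endpoint=True))
    sub = rng.integers(0, 2**31 - 1, size=8)

    ini = simulate_clone_tree(n_clones, n_mut, int(sub[0]))
    rel = simulate_relapse(
        ini, relapse_type, config.n_relapse_gained, int(sub[1]),
        clonal_cell_fraction=config.clonal_cell_fraction,
    )
    pdx_ini = simulate_engraftment(ini, mode_ini, config, int(sub[2]))
    pdx_rel = simulate_engraftment(rel, mode_rel, config, int(sub[3]))

    def trunc_normal(mean, sd, lo):
        b = rng.normal(mean, sd)
        while not lo <= b <= 1.0:
            b = rng.normal(mean, sd)
        return float(b)

    blast_ini = trunc_normal(*config.blast_ini)
    blast_rel = trunc_normal(*config.blast_rel)
    blast_pdx_ini = float(rng.uniform(*config.pdx_blast_range))
    blast_pdx_rel = float(rng.uniform(*config.pdx_blast_range))

    depth = config.read_depth
    mr = config.min_supporting_reads
    tables = {
        ("INI", "PRI"): render_variant_table(
            ini, depth, blast_ini, int(sub[4]), patient,
            f"{patient}_INI_PRI", "INI", "PRI", mr),
        ("REL", "PRI"): render_variant_table(
            rel, depth, blast_rel, int(sub[5]), patient,
            f"{patient}_REL_PRI", "REL", "PRI", mr),
        ("INI", "PDX"): render_variant_table(
            pdx_ini, depth, blast_pdx_ini, int(sub[6]), patient,
            f"{patient}_INI_PDX", "INI", "PDX", mr),
        ("REL", "PDX"): render_variant_table(
            pdx_rel, depth, blast_pdx_rel, int(sub[7]), patient,
            f"{patient}_REL_PDX", "REL", "PDX", mr),
    }
    return {
        "patient": patient,
        "relapse_type": relapse_type,
        "mode_ini": mode_ini,
        "mode_rel": mode_rel,
        "phylogenies": {"INI": ini, "REL": rel, "INI_PDX": pdx_ini, "REL_PDX": pdx_rel},
        "blast": {
            "INI_PRI": blast_ini,
            "REL_PRI": blast_rel,
            "INI_PDX": blast_pdx_ini,
            "REL_PDX": blast_pdx_rel,
        },
        "tables": tables,
    }


def simulate_cohort(config: SimulationConfig, seed: int) -> list[dict]:
    """Simulate ``config.n_patients`` patients with independent sub-seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=config.n_patients)
    return [
        simulate_patient(f"P{i + 1}", config, int(s)) for i, s in enumerate(seeds)
    ]
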