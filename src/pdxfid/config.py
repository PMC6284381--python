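"""Configuration objects for simulation and concordance analysis.

Defaults mirror the study conditions of a paired primary/PDX T-ALL cohort:
~50x exome depth, blast contents around 87% (initial diagnosis) and 69%
(relapse), a 30% allele-frequency clonality cut-off, the 0.2 promoter
methylation event threshold, and 3x low-coverage WGS in 10-kb bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence


def _default_loss_probability(cell_fraction: float) -> float:
    """Probability that a subclone fails to engraft, as a function of its size.

    Decays quickly with cell fraction: clones below ~10% of cells are at
    appreciable risk, clones above ~25% essentially never drop out.
    """
    return math.exp(-20.0 * cell_fraction)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic matched primary/PDX cohort generator."""

    n_patients: int = 12
    n_clones_range: tuple[int, int] = (2, 5)
    n_mutations_range: tuple[int, int] = (20, 40)
    read_depth: float = 50.0
    #: truncated-normal blast content (mean, sd, lower bound) per timepoint
    blast_ini: tuple[float, float, float] = (0.87, 0.07, 0.50)
    blast_rel: tuple[float, float, float] = (0.69, 0.27, 0.20)
    pdx_blast_range: tuple[float, float] = (0.95, 1.0)
    min_supporting_reads: int = 5
    #: cell-fraction threshold above which a clone's mutations read as clonal
    #: (AF >= 0.30 at full blast under the heterozygous-diploid model)
    clonal_cell_fraction: float = 0.60
    n_relapse_gained: int = 5
    subclone_loss_probability: Callable[[float], float] = field(
        default=_default_loss_probability, repr=False
    )
    mode_a_fraction_tolerance: float = 0.05

    # methylation
    n_promoters: int = 2000
    beta_noise_sd: float = 0.05
    celltype_differential_fraction: float = 0.30
    #: Laplace scale of leukemia-vs-normal beta shifts at differential promoters
    celltype_shift_scale: float = 0.15
    immune_gene_set_size: int = 50
    hypermethylation_delta: float = 0.30
    n_hyper_patients: int = 5

    # ATAC
    n_peaks: int = 5000
    n_atac_pairs: int = 6
    peak_height_log_mean: float = math.log(80.0)
    peak_height_log_sd: float = 0.8
    #: residual (within-patient) NB dispersion of paired counts; the
    #: between-patient component is carried by atac_patient_effect_sd
    nb_dispersion: float = 0.05
    #: P(primary peak re-called in PDX) = 1 - exp(-height / scale)
    reproducibility_height_scale: float = 19.0
    hypo_peak_fraction: float = 0.05
    hypo_peak_factor: float = 0.5
    atac_patient_effect_sd: float = 0.3
    atac_size_factor_sd: float = 0.2

    # low-coverage WGS
    cna_bin_width: int = 10_000
    cna_bins_per_chrom: int = 3000
    cna_n_chroms: int = 2
    cna_base_count: float = 200.0  # ~3x coverage of a 10-kb bin with 150-bp reads
    cna_gc_bias_strength: float = 1.5
    n_planted_cna: int = 3

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        for lo, hi in (self.n_clones_range, self.n_mutations_range):
            if lo > hi or lo < 1:
                raise ValueError("invalid range parameter")


@dataclass
class ConcordanceConfig:
    """Thresholds of the SNV/InDel concordance and classification stage.

    All comparisons against thresholds are inclusive (``>=``), following the
    field convention of calling mutations with AF >= 30% clonal.
    """

    clonal_af_threshold: float = 0.30
    counting_af_floor: float = 0.20
    pdx_specific_af_threshold: float = 0.10
    min_supporting_reads: int = 5
    population_frequency_ceiling: float = 0.01
    architecture_af_tolerance: float = 0.15
    af_bin_edges: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)
    #: per-patient significance level of the architecture evidence tests
    architecture_alpha: float = 1e-3
    #: minimum blast-corrected primary AF for a lost variant to count as
    #: dropout evidence (guards against winner's-curse at the detection limit)
    dropout_min_af: float = 0.15
    single_clone_af_sd_tolerance: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "clonal_af_threshold",
            "counting_af_floor",
            "pdx_specific_af_threshold",
            "population_frequency_ceiling",
            "architecture_af_tolerance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
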