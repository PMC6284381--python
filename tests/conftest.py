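import pandas as pd
import pytest

from pdxfid.config import ConcordanceConfig, SimulationConfig


@pytest.fixture
def sim_config():
    return SimulationConfig()


@pytest.fixture
def conc_config():
    return ConcordanceConfig()


def make_variant_row(
    patient="P1",
    sample_id="P1_INI_PRI",
    timepoint="INI",
    origin="PRI",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="GENE1",
    functional_class="nonsynonymous",
    population_frequency=0.0,
    alt_reads=20,
    total_reads=50,
):
    return {
        "patient": patient,
        "sample_id": sample_id,
        "timepoint": timepoint,
        "origin": origin,
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": gene,
        "functional_class": functional_class,
        "population_frequency": population_frequency,
        "alt_reads": alt_reads,
        "total_reads": total_reads,
        "AF": alt_reads / total_reads,
        "detected": alt_reads >= 5,
    }


@pytest.fixture
def variant_row_factory():
    return make_variant_row


def variant_table(rows):
    return pd.DataFrame(rows)
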