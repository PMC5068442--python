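import io

import pytest

import divescaling as dv
from divescaling.data_prep import REQUIRED_COLUMNS


@pytest.fixture
def toy_tree():
    """Three tips, one cherry: depths A=B=2, C=2; shared(A,B)=1."""
    return dv.read_newick("((A:1,B:1):1,C:2);")


def records_csv(*rows: dict) -> io.StringIO:
    """Build an in-memory dive-record CSV from partial row dicts."""
    defaults = {
        "species": "Testus exampli",
        "genus": "Testus",
        "taxon_class": "mammal",
        "mass_g": "1000",
        "temp_C": "",
        "temp_source": "",
        "median_dive_min": "5",
        "max_dive_min": "10",
        "life_stage_sex": "",
    }
    lines = [",".join(REQUIRED_COLUMNS)]
    for row in rows:
        merged = {**defaults, **{k: str(v) for k, v in row.items()}}
        lines.append(",".join(merged[c] for c in REQUIRED_COLUMNS))
    return io.StringIO("\n".join(lines) + "\n")


@pytest.fixture
def small_sim():
    """A small simulated dataset with all variance components active."""
    truth = dv.SimTruth(
        n_species=25, records_per_species=3, seed=42,
        sigma2_phylo=0.09, sigma2_species=0.04, sigma2_resid=0.09,
    )
    return dv.simulate_dataset(truth)
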