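import warnings

import numpy as np
import pandas as pd
import pytest

from detritrace.synthetic import EdnaScenario, generate_edna_dataset

# the sampler warns when ESS dips below 100 on tiny test chains; that is
# expected diagnostics, not a failure
warnings.filterwarnings("ignore", category=RuntimeWarning, message=".*effective sample size.*")


@pytest.fixture(scope="session")
def lossless_edna():
    """No dropout, no sample contamination: recovery should be exact."""
    scenario = EdnaScenario(dropout=0.0, contamination_rate=0.0)
    return scenario, generate_edna_dataset(scenario, seed=11)


@pytest.fixture(scope="session")
def noisy_edna():
    scenario = EdnaScenario(dropout=0.15, contamination_rate=0.2)
    return scenario, generate_edna_dataset(scenario, seed=5)


@pytest.fixture()
def toy_isotopes():
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(5)],
            "d13c": [-19.0, -15.0, -9.0, -8.0, -12.0],
            "d15n": [1.0, 2.0, 3.0, 4.0, 5.0],
        }
    )


def make_hits(rows):
    """Build a hit table from (esv, marker, lineage-tuple, identity, coverage, evalue)."""
    ranks = ("phylum", "class", "order", "family", "genus", "species")
    out = []
    for esv, marker, lineage, ident, cov, ev in rows:
        rec = {"esv_id": esv, "marker": marker}
        rec.update({r: lineage[i] if i < len(lineage) else None for i, r in enumerate(ranks)})
        rec.update({"pct_identity": ident, "pct_coverage": cov, "evalue": ev})
        out.append(rec)
    return pd.DataFrame(out)
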