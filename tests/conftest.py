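import numpy as np
import pandas as pd
import pytest

from sclc_tme import CohortSpec, PanelSpec, generate_cohort, generate_expression


@pytest.fixture(scope="session")
def small_panel():
    return PanelSpec(
        n_genes=300,
        module_sizes={"immune": 20, "proliferation": 20, "neuroendocrine": 10},
        effect_size=2.0,
        noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(n_patients=16, seed=101)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_expression(small_cohort, small_panel):
    samples, _ = small_cohort
    return generate_expression(samples, small_panel, seed=202)


@pytest.fixture()
def toy_counts():
    """Hand-written count table: one sample, two cores, two sections."""
    rows = []
    # core A sections at densities 100 and 120, core B at 60 and 80
    for core, counts in (("A", (100, 120)), ("B", (60, 80))):
        for section, n in zip(("1", "2"), counts):
            rows.append(
                {
                    "sample_id": "S1",
                    "core_id": core,
                    "section_id": section,
                    "marker": "CD68",
                    "compartment": "stroma",
                    "cell_count": n,
                    "area_um2": 1_000_000.0,
                }
            )
    return pd.DataFrame(rows)
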