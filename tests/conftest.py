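import numpy as np
import pytest

from gexpquant.fragments import FragmentRecord, GenePanel, PanelEntry, SeparationRun
from gexpquant.synthetic import NoiseSpec, SyntheticAssay


@pytest.fixture(scope="session")
def assay():
    """Default 35-gene first-order assay."""
    return SyntheticAssay.from_spec(seed=1)


@pytest.fixture(scope="session")
def assay_sublinear():
    """35-gene assay with reaction order 0.85 (partial-conversion regime)."""
    return SyntheticAssay.from_spec(reaction_order=0.85, seed=1)


@pytest.fixture
def no_noise():
    return NoiseSpec.none()


@pytest.fixture
def small_panel():
    return GenePanel(
        [
            PanelEntry("geneA", 150, rt_primer_conc_um=0.1),
            PanelEntry("geneB", 200, rt_primer_conc_um=0.01),
            PanelEntry("geneC", 357, rt_primer_conc_um=0.001),
            PanelEntry("KANr", 250, is_spike_in=True),
        ]
    )


@pytest.fixture
def small_run():
    return SeparationRun(
        run_id="run1",
        sample_id="s1",
        fragments=[
            FragmentRecord(1, 149.8, 50.0, 500.0),
            FragmentRecord(2, 200.3, 30.0, 300.0),
            FragmentRecord(3, 250.1, 100.0, 1000.0),
        ],
    )
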