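import pytest

from gliopanel.panel_model import CopyNumberProfile, default_panel_map
from gliopanel.synthetic_cohort import CohortConfig


@pytest.fixture(scope="session")
def panel():
    return default_panel_map()


def make_profile(case_id="case1", **genes) -> CopyNumberProfile:
    return CopyNumberProfile(case_id=case_id, entries=dict(genes))


def flat_profile(panel, value=2.0, case_id="case1", **overrides) -> CopyNumberProfile:
    entries = {gene: value for gene in panel.genes()}
    entries.update(overrides)
    return CopyNumberProfile(case_id=case_id, entries=entries)


def small_config(n_oligo=2, n_mut=2, n_wt=3, n_pilo=1, n_other=2) -> CohortConfig:
    """Down-scaled cohort config for fast I/O and pipeline tests."""
    cfg = CohortConfig()
    for name, n in [
        ("oligodendroglioma", n_oligo),
        ("astrocytoma_idh_mutant", n_mut),
        ("astrocytoma_idh_wildtype", n_wt),
        ("pilocytic_astrocytoma", n_pilo),
        ("other", n_other),
    ]:
        cfg.classes[name].n = n
    return cfg
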