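import warnings

import pytest

from amlclass import GeneratorConfig, generate_cohort, load_panel

warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def strict_cohort():
    """Medium strict-mode synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=11))


@pytest.fixture()
def cohort_dir(tmp_path, strict_cohort):
    """The shared cohort written out as the three TSV tables."""
    from amlclass import write_cohort

    write_cohort(
        strict_cohort.records,
        tmp_path / "mutations.tsv",
        tmp_path / "cytogenetics.tsv",
        tmp_path / "clinical.tsv",
    )
    return tmp_path
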