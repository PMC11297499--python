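import warnings

import numpy as np
import pytest

from tcrbind.data_io import Dataset, TCRRecord
from tcrbind.synthetic import GeneratorConfig, generate_repertoire


def make_record(peptide="GILGFVFTL", cdr3b="CASSIRSSYEQYF", label=1, **kw):
    defaults = dict(
        cdr1a="TSGFYG", cdr2a="NALDGL", cdr3a="CAVRDSNYQLIW",
        cdr1b="SGHAT", cdr2b="FQNNGV",
    )
    defaults.update(kw)
    return TCRRecord(peptide=peptide, cdr3b=cdr3b, label=label, **defaults)


@pytest.fixture
def toy_dataset():
    """Six positives over three peptides with distinct TCRs."""
    recs = [
        make_record("GILGFVFTL", "CASSIRSSYEQYF"),
        make_record("GILGFVFTL", "CASSLAPGATNEKLF"),
        make_record("NLVPMVATV", "CASSPVTGGIYGYTF"),
        make_record("NLVPMVATV", "CASSEARGLANEQFF"),
        make_record("ELAGIGILTV", "CASSQDRDTQYF"),
        make_record("ELAGIGILTV", "CASSYSTGDEQYF"),
    ]
    return Dataset(recs)


@pytest.fixture(scope="session")
def small_repertoire():
    """10 peptides x 50 TCRs, fully penetrant motif — the fast-suite fixture."""
    cfg = GeneratorConfig(n_peptides=10, tcrs_per_peptide=50, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_repertoire(cfg)


@pytest.fixture(autouse=True)
def _quiet_sampling_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
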