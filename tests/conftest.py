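import numpy as np
import pytest

from covpower import substitutions, tree_from_alignment
from covpower.fixtures import structural_template


@pytest.fixture(scope="session")
def template_aln():
    """Mid-diversity structural alignment used across test modules."""
    return structural_template(seed=7, mean_branch=0.1)


@pytest.fixture(scope="session")
def template_tree(template_aln):
    return tree_from_alignment(template_aln)


@pytest.fixture(scope="session")
def template_subs(template_aln, template_tree):
    return substitutions(template_aln, template_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
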