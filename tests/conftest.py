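from fractions import Fraction

import pytest

import epiprior as ep
from epiprior.ahp import JudgmentMatrix


@pytest.fixture(scope="session")
def criteria():
    return ep.default_criteria()


@pytest.fixture
def consistent_3x3():
    """Fully consistent 3x3 matrix with weights (4/7, 2/7, 1/7)."""
    rows = [[1, 2, 4], [Fraction(1, 2), 1, 2], [Fraction(1, 4), Fraction(1, 2), 1]]
    return JudgmentMatrix(["scope", "freq", "mitig"],
                          [[Fraction(x) for x in r] for r in rows])


@pytest.fixture
def cyclic_3x3():
    """Maximally inconsistent circulant matrix (a>b>c>a)."""
    rows = [[1, 3, Fraction(1, 3)], [Fraction(1, 3), 1, 3],
            [3, Fraction(1, 3), 1]]
    return JudgmentMatrix(["a", "b", "c"],
                          [[Fraction(x) for x in r] for r in rows])


@pytest.fixture(scope="session")
def workshop_dir(tmp_path_factory):
    """A complete synthetic workshop input directory (seeded)."""
    out = tmp_path_factory.mktemp("workshop")
    bundle = ep.generate_bundle(ep.SimulationSpec(seed=42))
    ep.write_bundle_inputs(bundle, out)
    return out
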