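import itertools

import pytest

from coatmorph import GenotypeCall, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def unordered_pairs(alleles):
    return list(itertools.combinations_with_replacement(alleles, 2))


@pytest.fixture(scope="session")
def core_genotype_space():
    """All 10 x 10 x 3 unordered genotype combinations over ASIP (without
    the derived ayt), MC1R, and CBD103."""
    asip = unordered_pairs(["ay", "aw", "at", "a"])
    mc1r = unordered_pairs(["EM", "EG", "E", "e"])
    cbd = unordered_pairs(["KB_kbr", "ky"])
    return [
        {
            "ASIP": GenotypeCall("ASIP", a),
            "MC1R": GenotypeCall("MC1R", m),
            "CBD103": GenotypeCall("CBD103", k),
        }
        for a in asip
        for m in mc1r
        for k in cbd
    ]
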