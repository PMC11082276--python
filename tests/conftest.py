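import pytest

from tagms import (
    FattyAcid,
    LipidSpecies,
    MS2Spectrum,
    default_standards,
    parse_species,
)
from tagms.simulate import _TAG_SPECIES


@pytest.fixture
def tag_62_4_spectrum():
    """Four-peak product-ion spectrum of the sodiated 62:4 precursor:
    intense acid losses of the outer 22:1 chains, weaker 18:2 loss, and two
    faint sodium-salt losses."""
    return MS2Spectrum(
        1017.9, ((679.6, 100.0), (737.6, 40.0), (657.6, 8.0), (715.7, 5.0))
    )


@pytest.fixture
def tag_60_4_spectrum():
    """Six-peak product-ion spectrum of the sodiated 60:4 precursor: two
    similar outer acid losses (20:1, 22:1), a weaker 18:2 loss, and three
    faint salt losses."""
    return MS2Spectrum(
        989.9,
        (
            (679.6, 100.0),
            (651.5, 85.0),
            (709.6, 35.0),
            (657.6, 8.0),
            (629.6, 7.0),
            (687.7, 5.0),
        ),
    )


def resolve_sn2(species_str: str) -> LipidSpecies:
    """sn-resolved version of a TAG species: sn-2 is an acyl occurring
    exactly once in the triad (preferring linoleic when unique), the only
    configuration the loss-intensity rule can resolve."""
    sp = parse_species(species_str)
    unique = [a for a in set(sp.acyls) if sp.acyls.count(a) == 1]
    linoleic = FattyAcid(18, 2)
    sn2 = linoleic if linoleic in unique else sorted(unique)[0]
    return LipidSpecies.from_acyls("TAG", sp.acyls, sn2=sn2)


@pytest.fixture
def study_tags():
    """The eight major TAG species of the simulated system, sn-resolved."""
    return [resolve_sn2(s) for s in _TAG_SPECIES.values()]


@pytest.fixture
def standards():
    return default_standards()
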