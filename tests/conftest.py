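import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from krillipid.annotation import AcylPairCandidate, AnnotatedIPL, Evidence
from krillipid.chem_core import FattyAcyl, HeadGroupClass, SumComposition
from krillipid.config import Config

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


#: Independent monoisotopic masses for test-side oracles (hand-entered, not
#: imported from the package).
ORACLE_MASS = {
    "C": 12.0,
    "H": 1.007825032,
    "D": 2.014101778,
    "N": 14.003074005,
    "O": 15.994914620,
    "P": 30.973761630,
    "e": 0.000548580,
}


def oracle_mass(formula_counts: dict, charge: int = 0) -> float:
    """Plain atomic-mass sum oracle, independent of the package's mass math."""
    mass = sum(n * ORACLE_MASS[el] for el, n in formula_counts.items())
    return mass - charge * ORACLE_MASS["e"]


@pytest.fixture
def config() -> Config:
    return Config()


def make_annotated(species: str, pairs: list[tuple[str, str, float, float]]
                   ) -> AnnotatedIPL:
    """Hand-build an annotation: pairs as (fa_a, fa_b, intensity_a,
    intensity_b) with fa tokens like '16:0'."""
    sc = SumComposition.parse(species)
    pair_objs = []
    for a, b, ia, ib in pairs:
        fa_a, fa_b = FattyAcyl.parse(a), FattyAcyl.parse(b)
        sn2 = "a" if ia > ib else "b"
        pair_objs.append(AcylPairCandidate(fa_a, fa_b, ia, ib, sn2))
    evidence = Evidence(sc.cls, [f"{sc.cls.value}+"], 0.0, 0.0, {})
    return AnnotatedIPL(sc, pair_objs, evidence, rt=5.0, area_pos=1e5)
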