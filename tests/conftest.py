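import numpy as np
import pytest

from metbridge.structure_io import AromaticSite, MetSite, ResidueRef
from metbridge.synthetic import (canonical_met_site, make_aromatic_site,
                                 random_rotation)


def rigid_move_met(met: MetSite, rot: np.ndarray, trans: np.ndarray) -> MetSite:
    return MetSite(ref=met.ref, cg=rot @ met.cg + trans,
                   sd=rot @ met.sd + trans, ce=rot @ met.ce + trans)


def rigid_move_aromatic(aro: AromaticSite, rot: np.ndarray,
                        trans: np.ndarray) -> AromaticSite:
    return AromaticSite(
        ref=aro.ref,
        ring_atoms={n: rot @ p + trans for n, p in aro.ring_atoms.items()},
        centroid=rot @ aro.centroid + trans,
        midpoints=aro.midpoints @ rot.T + trans)


def random_met(rng: np.random.Generator, number: int = 1,
               chain: str = "A") -> MetSite:
    """A canonical Met under a random rigid pose."""
    met = canonical_met_site(ResidueRef(chain, number, "", "MET"))
    return rigid_move_met(met, random_rotation(rng), rng.uniform(-15, 15, 3))


def random_sites(rng: np.random.Generator, n_mets: int = 2,
                 n_aromatics: int = 6, box: float = 12.0
                 ) -> tuple[list[MetSite], list[AromaticSite]]:
    """Random in-memory structure: posed Mets plus aromatics scattered in a box."""
    mets = [random_met(rng, number=i + 1) for i in range(n_mets)]
    aromatics = []
    for j in range(n_aromatics):
        rtype = ["PHE", "TYR", "TRP"][int(rng.integers(3))]
        centroid = rng.uniform(-box, box, 3)
        aromatics.append(make_aromatic_site(
            rtype, centroid, ref=ResidueRef("A", 100 + j, "", rtype),
            normal=rng.normal(size=3), spin_deg=float(rng.uniform(0, 360))))
    return mets, aromatics


@pytest.fixture
def rng():
    return np.random.default_rng(20211221)
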