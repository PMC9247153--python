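"""Shared fixtures: tiny deterministic motifs, random PWM factories, and a
small planted-motif fixture directory for pipeline tests."""

import numpy as np
import pytest

from promotif import Background, PFM, pfm_to_pwm
from promotif.simulate import (decoy_pfms, default_planted_pfm, plant_motifs,
                               random_promoters, write_fixture)

TOY_JASPAR = """\
>MA0001.1 TOY
A [ 8 0 1 ]
C [ 0 8 1 ]
G [ 0 0 5 ]
T [ 0 0 1 ]
>MA0002.1 TOY2
A 1 2
C 3 4
G 5 6
T 7 8
"""


@pytest.fixture
def toy_jaspar_text():
    return TOY_JASPAR


@pytest.fixture
def toy_pwm():
    """3-position PWM with a strict per-column argmax (consensus ACG)."""
    pfm = PFM("MA0001.1", "TOY", np.array([[8, 0, 1], [0, 8, 1], [0, 0, 5], [0, 0, 1]], float))
    return pfm_to_pwm(pfm, Background.uniform(), pseudocount=0.8)


def random_pfm(rng: np.random.Generator, m: int, depth: int = 50) -> PFM:
    """A random PFM with Dirichlet column profiles (no zero counts)."""
    counts = rng.dirichlet([1.0, 1.0, 1.0, 1.0], size=m).T * depth + 0.5
    return PFM(f"RND{m}", f"rnd{m}", counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def planted_fixture(tmp_path):
    """Fixture directory: 10 x 800 bp promoters, consensus plant in 8 of 10,
    20 decoys; returns (paths dict, gene list file, planted matrix id)."""
    pfm = default_planted_pfm()
    proms = random_promoters(10, 800, seed=7)
    proms, truths = plant_motifs(proms, pfm, 0.8, "consensus", seed=8)
    pfms = [pfm] + decoy_pfms(pfm, 20, seed=9)
    paths = write_fixture(proms, truths, pfms, str(tmp_path / "fix"), seed=7)
    genes = tmp_path / "genes.txt"
    genes.write_text(",".join(p.gene_id for p in proms) + "\n")
    return paths, str(genes), pfm.matrix_id
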