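"""Shared fixtures: simulated cohorts and small planted genomes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from plastsurvey.model import CircularGenome, Feature, revcomp
from plastsurvey.simulate import simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort16():
    """A 16-taxon simulated cohort under the default toy architecture."""
    return simulate_cohort(n_taxa=16, seed=11)


@pytest.fixture(scope="session")
def cohort6():
    """A small, fast 6-taxon cohort for unit-level checks."""
    return simulate_cohort(n_taxa=6, seed=7)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


def planted_ir_genome(seed: int = 0, n: int = 1000, ir_len: int = 200) -> tuple[CircularGenome, dict]:
    """Random circle with one exact planted inverted repeat.

    Layout: LSC [0, lsc) | IRa | SSC | IRb(=revcomp IRa), with flanks fixed
    so the repeat cannot extend by chance.
    """
    rng = np.random.default_rng(seed)
    ssc = (n - 2 * ir_len) // 3
    lsc = n - 2 * ir_len - ssc
    assert lsc > ssc > 0
    lsc_seq = random_dna(rng, lsc)
    ira = random_dna(rng, ir_len)
    ssc_seq = random_dna(rng, ssc)
    seq = list(lsc_seq + ira + ssc_seq + revcomp(ira))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # block chance extension of the repeat at both junction pairs
    if seq[lsc - 1] == comp[seq[0]]:
        seq[lsc - 1] = next(c for c in "ACGT" if c != comp[seq[0]])
    if seq[lsc + ir_len] == comp[seq[lsc + ir_len + ssc - 1]]:
        seq[lsc + ir_len + ssc - 1] = next(
            c for c in "ACGT" if comp[c] != seq[lsc + ir_len]
        )
    genome = CircularGenome(id=f"planted{seed}", seq="".join(seq))
    truth = {"lsc": lsc, "ssc": ssc, "ir": ir_len, "ira_start": lsc,
             "irb_start": lsc + ir_len + ssc}
    return genome, truth


def make_genome(seq: str, feats: list[tuple[str, str, list[tuple[int, int, int]]]]) -> CircularGenome:
    """Terse genome builder for planted-annotation tests."""
    return CircularGenome(
        id="toy",
        seq=seq,
        features=[Feature(name=n, ftype=t, parts=tuple(p)) for n, t, p in feats],
    )
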