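"""Shared fixtures: a compact synthetic plastome exercising every detector.

The compact genome keeps the full quadripartite anatomy (planted IRs,
junction genes, IR-duplicated and intron-split genes, SSRs of all six
classes, dispersed repeats of all four types) at ~1/6 scale so unit tests
stay fast; full-scale runs live in the acceptance tests.
"""

import pytest

from plastchar.structure import detect_inverted_repeats
from plastchar.synth import (CubProfile, GeneSpec, PlastomeSpec,
                             generate_plastome)


def compact_spec(seed: int = 11) -> PlastomeSpec:
    genes = [
        GeneSpec("psbA", "CDS", "+", "lsc", n_codons=120),
        GeneSpec("matK", "CDS", "-", "lsc", n_codons=150),
        GeneSpec("atpF", "CDS", "+", "lsc", n_codons=110, intron_len=220),
        GeneSpec("trnG-UCC", "tRNA", "+", "lsc", length_nt=72),
        GeneSpec("rpl23", "CDS", "+", "lsc", n_codons=101,
                 offset=-(3 * 103 + 400)),
        GeneSpec("trnM", "tRNA", "+", "lsc", length_nt=73, offset=-(73 + 62)),
        GeneSpec("ndhB", "CDS", "+", "irb", n_codons=120, intron_len=200),
        GeneSpec("trnN", "tRNA", "-", "irb", length_nt=72),
        GeneSpec("ndhF", "CDS", "+", "irb", n_codons=200, offset=-76),
        GeneSpec("chlL", "CDS", "+", "ssc", n_codons=120,
                 offset=-(3 * 122 + 60)),
    ]
    ssrs = [
        ("T", 12, "lsc"), ("A", 10, "lsc"), ("AT", 7, "lsc"),
        ("TA", 6, "ssc"), ("AAT", 4, "lsc"), ("ATAG", 3, "ssc"),
        ("AATAT", 3, "lsc"), ("ATATGC", 3, "irb"),
    ]
    repeats = [
        ("F", 42, 3, ("lsc", "lsc")),
        ("P", 38, 3, ("lsc", "ssc")),
        ("R", 35, 3, ("lsc", "lsc")),
        ("C", 40, 3, ("ssc", "ssc")),
    ]
    return PlastomeSpec(
        region_lengths={"lsc": 12_000, "ssc": 5_000, "ir": 2_500},
        region_gc={"lsc": 0.26, "ssc": 0.25, "ir": 0.43},
        planted_ssrs=tuple(ssrs),
        planted_repeats=tuple(repeats),
        genes=tuple(genes),
        cub_profile=CubProfile.from_at_bias(0.6),
        seed=seed,
    )


@pytest.fixture(scope="session")
def compact_plastome():
    return generate_plastome(compact_spec())


@pytest.fixture(scope="session")
def compact_layout(compact_plastome):
    return detect_inverted_repeats(compact_plastome.genome, min_ir_len=500)
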