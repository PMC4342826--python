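import numpy as np
import pytest

from bactx import genome_model as gm
from bactx.synthetic_data import (
    SimulationParams,
    generate_genome,
    simulate_primary_library,
    simulate_whole_library,
)


@pytest.fixture(scope="session")
def sim():
    """One full synthetic data set at the default study conditions (seed 1)."""
    params = SimulationParams(seed=1)
    annotation, sequence, truth = generate_genome(params)
    primary = simulate_primary_library(truth, params, annotation.length)
    fragments, whole = simulate_whole_library(truth, params, annotation)
    coverage = gm.coverage_from_fragments(fragments, annotation.length)
    return {
        "params": params,
        "annotation": annotation,
        "sequence": sequence,
        "truth": truth,
        "primary": primary,
        "fragments": fragments,
        "whole": whole,
        "coverage": coverage,
    }


@pytest.fixture()
def toy_annotation():
    """A hand-built two-strand annotation on a 5 kb replicon."""
    feats = [
        gm.GeneFeature("geneA", "chr", 200, 400, "+", "CDS"),
        gm.GeneFeature("geneB", "chr", 500, 900, "+", "CDS"),
        gm.GeneFeature("geneC", "chr", 1200, 1600, "-", "CDS"),
        gm.GeneFeature("trnaD", "chr", 2000, 2075, "+", "tRNA"),
        gm.GeneFeature("geneE", "chr", 3000, 3600, "+", "CDS"),
    ]
    return gm.GenomeAnnotation("chr", 5000, feats)


def make_profile(rows, replicon="chr", library=gm.PRIMARY_LIBRARY):
    """Profile from (position, strand, count) triples."""
    counts = {"+": {}, "-": {}}
    for pos, strand, c in rows:
        counts[strand][pos] = c
    return gm.ReadStartProfile(replicon_id=replicon, library=library, counts=counts)


@pytest.fixture()
def profile_factory():
    return make_profile
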