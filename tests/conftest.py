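import numpy as np
import pytest

from epiredist.genome import BinnedTrack, GenomeLayout, IntervalSet
from epiredist.simulate import (
    make_genome_annotation,
    simulate_contact_maps,
    simulate_expression_response,
    simulate_mark_tracks,
)


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (1_000_000, 500_000))


@pytest.fixture
def uniform_track(small_layout) -> BinnedTrack:
    n = small_layout.total_bins(100_000)
    return BinnedTrack(small_layout, 100_000, np.full(n, 7.0), "cpm")


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study (seed 11): annotation, tracks, expression."""
    layout, genes, enhancers, truth = make_genome_annotation(seed=11)
    parental, treated, input_track, cal = simulate_mark_tracks(truth)
    deltas = simulate_expression_response(truth)
    return {
        "layout": layout,
        "genes": genes,
        "enhancers": enhancers,
        "truth": truth,
        "parental": parental,
        "treated": treated,
        "input": input_track,
        "cal": cal,
        "deltas": deltas,
    }


@pytest.fixture(scope="session")
def default_contacts(default_bundle):
    matrices, loop_sets = simulate_contact_maps(default_bundle["truth"])
    return {"matrices": matrices, "loops": loop_sets}
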