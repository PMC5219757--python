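import numpy as np
import pytest

from cobind.regions import BindingCall, build_cobinding_regions, build_region_tf_matrix
from cobind.synthetic import SyntheticConfig, generate
from cobind.topic_model import corpus_from_matrix, extract_outputs, fit_hdp_multistart


def brute_force_merge(intervals):
    """O(n^2) transitive merge of half-open intervals (oracle)."""
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out = []
        for s, e in items:
            for grp in out:
                if s < grp[1] and grp[0] < e:  # strict overlap
                    grp[0] = min(grp[0], s)
                    grp[1] = max(grp[1], e)
                    changed = True
                    break
            else:
                out.append([s, e])
        items = out
    return sorted((s, e) for s, e in items)


@pytest.fixture(scope="session")
def small_dataset():
    """300 planted regions, 6 modules, 20% two-module (fast, deterministic)."""
    return generate(SyntheticConfig(n_regions=300, seed=5))


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Fitted HDP on the small dataset, shared across tests."""
    ds = small_dataset
    regions = build_cobinding_regions(ds.calls)
    matrix = build_region_tf_matrix(regions, ds.truth.vocabulary)
    corpus = corpus_from_matrix(matrix)
    state = fit_hdp_multistart(corpus, seeds=(1, 2, 3), max_iter=800)
    mtm, assignments = extract_outputs(state, corpus)
    return {
        "dataset": ds,
        "regions": regions,
        "matrix": matrix,
        "corpus": corpus,
        "state": state,
        "mtm": mtm,
        "assignments": assignments,
    }


@pytest.fixture
def random_calls():
    def make(n, seed=0, chroms=("chr1", "chr2"), factors=("A", "B", "C"), span=100_000):
        rng = np.random.default_rng(seed)
        return [
            BindingCall(
                factor=factors[rng.integers(len(factors))],
                chrom=chroms[rng.integers(len(chroms))],
                summit=int(rng.integers(0, span)),
            )
            for _ in range(n)
        ]

    return make
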