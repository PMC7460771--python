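import numpy as np
import pytest

from hemescreen.io_formats import CountMatrix, SampleMeta
from hemescreen.simulate import SimConfig, generate_experiment


def make_count_matrix(counts, treatments, dataset="ds1"):
    """Build a CountMatrix from a raw array and per-column treatment labels."""
    counts = np.asarray(counts)
    reps = {}
    samples = []
    for j, t in enumerate(treatments):
        reps[t] = reps.get(t, 0) + 1
        samples.append(
            SampleMeta(
                sample_id=f"{dataset}_{t}_r{reps[t]}",
                dataset_id=dataset,
                treatment=t,
                replicate=reps[t],
            )
        )
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        counts=counts,
        samples=samples,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """One 3-treatment dataset with planted responders, shared across tests."""
    cfg = SimConfig(
        n_genes=1200,
        n_import=60,
        n_export=60,
        n_serum=60,
        dispersion=0.1,
        seed=42,
    )
    matrices, annotation, truth = generate_experiment(cfg)
    return cfg, matrices[0], annotation, truth
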