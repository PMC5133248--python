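import numpy as np
import pytest

from tagsip import simulate as sim


@pytest.fixture(scope="session")
def small_experiment():
    """A small but fully realistic paired experiment (fast to analyze).

    30 OTUs, half labeled at excess 0.3-0.8, plus an LNT-like null pair.
    """
    cfg = sim.SimConfig(seed=7, reads_per_gradient=1_200_000)
    rng = np.random.default_rng(7)
    community = sim.example_community(30, rng=rng)
    ids = [o.otu_id for o in community]
    treatments = [
        sim.TreatmentSpec("Nitrate", excess=sim.labeled_excess(ids, rng)),
        sim.TreatmentSpec("LNT", excess=sim.null_excess(ids, rng)),
    ]
    return sim.generate_paired_experiment(community, treatments, cfg)


@pytest.fixture()
def experiment_dir(tmp_path, small_experiment):
    """The same experiment written out in the pipeline's file formats."""
    cfg = sim.SimConfig(seed=7, reads_per_gradient=1_200_000)
    rng = np.random.default_rng(7)
    community = sim.example_community(30, rng=rng)
    ids = [o.otu_id for o in community]
    treatments = [
        sim.TreatmentSpec("Nitrate", excess=sim.labeled_excess(ids, rng)),
        sim.TreatmentSpec("LNT", excess=sim.null_excess(ids, rng)),
    ]
    out = sim.generate_paired_experiment(community, treatments, cfg, outdir=tmp_path / "sim")
    return out
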