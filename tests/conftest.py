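import numpy as np
import pandas as pd
import pytest

from stressomics import simulate as sim
from stressomics.config import PipelineConfig
from stressomics.containers import LongitudinalMatrix


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic scenario (seed 1)."""
    from stressomics import pipeline

    outdir = tmp_path_factory.mktemp("pipeline_default")
    cfg = PipelineConfig(seed=1)
    results = pipeline.run_all(cfg, outdir)
    return outdir, cfg, results


def make_matrix(values, n_times=None, animals=None, times=None, batch=None, sex=None):
    """Small LongitudinalMatrix helper: rows ordered animal-major."""
    values = pd.DataFrame(np.asarray(values, dtype=float))
    values.columns = [f"v{j}" for j in values.columns]
    n = len(values)
    if animals is None:
        n_times = n_times or 2
        animals = np.repeat(np.arange(n // n_times), n_times)
        times = np.tile(np.arange(n_times), n // n_times)
    return LongitudinalMatrix(
        values=values,
        animal=np.asarray(animals),
        time=np.asarray(times),
        batch=np.zeros(n, dtype=int) if batch is None else np.asarray(batch),
        sex=sex,
    )


def noiseless_bio_spec(effects=None, between_sd=0.0, baseline=100.0):
    """Single-variable spec with all noise terms off unless requested."""
    return sim.BioKineticsSpec(
        variables={
            "cortisol": sim.VariableKinetics(
                baseline=baseline,
                noise_sd=0.0,
                between_sd=between_sd,
                batch_sd=0.0,
                effects=effects or {},
            )
        }
    )
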