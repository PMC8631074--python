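import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gumfoot.enrichment import FIBER, GLUE_FIBER, LFQMatrix
from gumfoot.simulate import DropletSimConfig, generate_droplet_experiment

#: Pooled peptide counts (unmodified, glyc-only, phos-only, both) per
#: sample type, as published for the two study species.
PUBLISHED_PTM_COUNTS = {
    ("L_hesperus", GLUE_FIBER): (6590, 885, 319, 63),
    ("L_hesperus", FIBER): (4704, 70, 36, 8),
    ("P_tepidariorum", GLUE_FIBER): (11141, 1087, 1099, 136),
    ("P_tepidariorum", FIBER): (3753, 94, 112, 14),
}


@pytest.fixture
def noisefree_experiment():
    cfg = DropletSimConfig(seed=11, angle_noise_sd=0.0)
    line, geom, series, truth = generate_droplet_experiment(cfg)
    return cfg, line, geom, series, truth


def toy_lfq_matrix(
    values: dict[str, list[float]],
    scores: dict[str, list[float]] | None = None,
    ptm_modified: dict[str, list[bool]] | None = None,
    ptm_scores: dict[str, float] | None = None,
) -> LFQMatrix:
    """Hand-built 4 GlueFiber + 4 Fiber, two-run matrix for rule tests."""
    sample_ids = [
        "GF_r1_1", "GF_r1_2", "F_r1_1", "F_r1_2",
        "GF_r2_1", "GF_r2_2", "F_r2_1", "F_r2_2",
    ]
    samples = pd.DataFrame(
        {
            "sample_type": [GLUE_FIBER, GLUE_FIBER, FIBER, FIBER] * 2,
            "run": [1, 1, 1, 1, 2, 2, 2, 2],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    proteins = list(values)
    vdf = pd.DataFrame.from_dict(values, orient="index", columns=sample_ids)
    if scores is None:
        scores = {p: [100.0, 100.0] for p in proteins}
    sdf = pd.DataFrame.from_dict(scores, orient="index", columns=[1, 2])
    kwargs = {}
    if ptm_modified is not None:
        kwargs["ptm_modified"] = pd.DataFrame.from_dict(
            ptm_modified, orient="index", columns=sample_ids
        )
        kwargs["ptm_scores"] = pd.Series(ptm_scores or {p: 0.0 for p in proteins})
    return LFQMatrix(values=vdf, samples=samples, scores=sdf, **kwargs)
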