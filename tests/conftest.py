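import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rarecell as rc

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schema():
    return rc.build_feature_schema()


@pytest.fixture(scope="session")
def mini_slide():
    """A small but fully populated slide: commons, all 8 rare phenotypes,
    artifacts; shared across read-only tests."""
    spec = rc.SyntheticSlideSpec(
        grid_rows=2, grid_cols=2, frame_height_px=256, frame_width_px=256,
        n_common_events=150,
        rare_prevalence={t: 2.0 for t in rc.CELL_TYPES},
        artifact_rates={"bubble": 1.0, "flare": 1.0},
        seed=11,
    )
    stack, truth = rc.generate_slide(spec, slide_id="mini")
    return spec, stack, truth


@pytest.fixture(scope="session")
def mini_events(mini_slide, schema):
    _, stack, _ = mini_slide
    return rc.segment_slide(stack, schema)


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-scale pipeline run (simulate -> compare), shared by the
    end-to-end tests; returns (config, manifest, out_dir)."""
    out = tmp_path_factory.mktemp("desk_run")
    cfg = rc.make_config("desk", seed=1, out_root=str(out))
    manifest = rc.run_pipeline(cfg)
    return cfg, manifest, out


def random_feature_table(schema, n, rng, shift_groups=None, shift=0.0):
    """Synthetic schema-shaped feature table: standard-normal columns, with an
    optional mean shift on the named feature groups (for planted separability)."""
    import pandas as pd

    x = rng.normal(size=(n, len(schema)))
    if shift_groups:
        cols = [i for i, g in enumerate(schema.groups)
                if any(g.startswith(p) for p in shift_groups)]
        x[:, cols] += shift
    return pd.DataFrame(x, columns=list(schema.names))
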