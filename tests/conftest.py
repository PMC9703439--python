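"""Shared fixtures: scaled-down synthetic cohorts run through the full pipeline.

Test cohorts use shorter trials (and correspondingly shorter FIR filters)
and fewer subjects than the study design so the suite stays fast; the
generator's effect structure is unchanged.
"""

import numpy as np
import pytest

from newstrf.io_core import PipelineConfig
from newstrf.synthetic import CohortConfig, EffectPlan, generate_cohort
from newstrf.preprocess import preprocess_cohort
from newstrf.trf import estimate_cohort_trfs
from newstrf.components import build_feature_table, compute_component_measures


def make_mini_cfg(**overrides) -> PipelineConfig:
    """Pipeline config with filter orders scaled to short (~20 s) trials."""
    defaults = dict(bp1_order=600, bp2_order=400)
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def run_pipeline(cohort_cfg: CohortConfig, cfg: PipelineConfig,
                 plan: EffectPlan | None = None) -> dict:
    """Generate -> preprocess -> TRF -> components -> features."""
    ds, gt = generate_cohort(cohort_cfg, plan)
    pre, reports = preprocess_cohort(ds, cfg)
    trf_df, diagnostics, lam_star = estimate_cohort_trfs(pre, cfg)
    measures = compute_component_measures(trf_df, cfg)
    features = build_feature_table(measures, pre.ratings, pre.subjects)
    return {"ds": ds, "gt": gt, "pre": pre, "trf": trf_df,
            "lambda": lam_star, "measures": measures, "features": features,
            "cfg": cfg, "cohort_cfg": cohort_cfg}


@pytest.fixture(scope="session")
def small_pipeline():
    """10-subject cohort (3 depressed / 7 non-depressed) at default effects."""
    cc = CohortConfig(n_depressed=3, n_nondepressed=7, trial_duration_s=(18, 22),
                      fs_hz=200, snr_db=0.0, effect_scale=1.0, seed=11)
    return run_pipeline(cc, make_mini_cfg(seed=11))


@pytest.fixture(scope="session")
def separated_features(separated_pipeline):
    return separated_pipeline["features"]


@pytest.fixture(scope="session")
def separated_pipeline():
    """Strongly separated cohort (effect_scale 3, low noise): 6 + 14 subjects."""
    cc = CohortConfig(n_depressed=6, n_nondepressed=14, trial_duration_s=(18, 22),
                      fs_hz=200, snr_db=0.0, effect_scale=3.0, seed=7)
    return run_pipeline(cc, make_mini_cfg(seed=7))


@pytest.fixture(scope="session")
def shift_recovery():
    """Cohort whose only injected effect is a coherent 25 ms latency shift of
    the early (N1/P2) response (depressed group, positive news) at the
    default -10 dB SNR."""
    plan = EffectPlan(
        n1_latency_shift_positive_ms=25.0, p2_latency_shift_positive_ms=25.0,
        n400_latency_negative_vs_positive_ms=0.0,
        n400_amp_gain_negative_depressed=1.0, n1_amp_gain_nondepressed=1.0,
        arousal_shift_depressed=0.0, comprehensibility_shift_depressed=0.0)
    cc = CohortConfig(n_depressed=8, n_nondepressed=8, trial_duration_s=(30, 40),
                      fs_hz=200, snr_db=-10.0, effect_scale=1.0, seed=3)
    return run_pipeline(cc, PipelineConfig(seed=3), plan)
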