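"""Shared fixtures: ground-truth parameter sets and cohort factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dualerror as de

#: best-fit values for the distracted SPE+TE model used as generative truth
EXP4_TRUTH = {"c_j": 0.84, "sigma_d": 11.8, "beta_te": 0.02}
#: observed no-jump updates (deg) at the 3 and 7 deg clamps
EXP4_TOTALS = {3.0: 0.5, 7.0: 0.9}
#: participant split across the four jump-range sets (sums to 210)
EXP4_SPLIT = {"exp4a": 53, "exp4b": 53, "exp4c": 52, "exp4d": 52}


@pytest.fixture(scope="session")
def distracted_te_spec() -> de.ModelSpec:
    return de.ModelSpec.from_id("distracted_spe_te")


@pytest.fixture(scope="session")
def exp4_truth_params(distracted_te_spec) -> de.ModelParams:
    return de.params_for_no_jump_totals(distracted_te_spec, EXP4_TOTALS, **EXP4_TRUTH)


@pytest.fixture(scope="session")
def exp4_cohort_factory(distracted_te_spec, exp4_truth_params):
    """Factory for full four-set synthetic cohorts at the study's size."""

    def make(seed: int, noise_sd: float = 0.15, between_subject_sd: float = 0.1,
             split: dict | None = None) -> pd.DataFrame:
        split = split or EXP4_SPLIT
        seeds = np.random.SeedSequence(seed).generate_state(len(split)) % (2**31)
        frames = []
        for (exp, n_p), s in zip(split.items(), seeds):
            cfg = de.SimConfig(
                spec=distracted_te_spec, params=exp4_truth_params,
                noise_sd=noise_sd, n_participants=n_p,
                between_subject_sd=between_subject_sd, seed=int(s),
            )
            cohort = de.simulate_cohort(exp, cfg)
            cohort["participant_id"] = exp + "_" + cohort["participant_id"]
            frames.append(cohort)
        return pd.concat(frames, ignore_index=True)

    return make


@pytest.fixture(scope="session")
def noiseless_exp4a_cohort(distracted_te_spec, exp4_truth_params) -> pd.DataFrame:
    cfg = de.SimConfig(
        spec=distracted_te_spec, params=exp4_truth_params,
        noise_sd=0.0, n_participants=3, seed=11,
    )
    return de.simulate_cohort("exp4a", cfg)
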