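"""Shared fixtures.

The expensive strong-shift benchmark runs (source pretraining plus paired
least-confidence / random active-learning loops over several seeds) are
computed once per session and shared between the experiment tests and the
acceptance tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from alshift.active_learning import ALConfig, run_active_learning
from alshift.classifier import ArchConfig, TrainConfig, build_classifier, train
from alshift.evaluation import build_combined_test, evaluate_classifier
from alshift.experiment import prepare_data, run_phase1, strong_shift_experiment_config
from alshift.synthetic import DomainShiftSpec, generate_domain


@pytest.fixture()
def tiny_spec() -> DomainShiftSpec:
    return DomainShiftSpec(
        domain_id="tiny",
        image_size=(16, 16, 3),
        n_train_per_class=6,
        n_test_per_class=3,
        class_signal_amplitude=0.6,
        texture_noise_sd=0.02,
        seed=7,
    )


@pytest.fixture()
def tiny_dataset(tiny_spec):
    return generate_domain(tiny_spec)


@pytest.fixture()
def easy_spec() -> DomainShiftSpec:
    """Linearly separable toy domain: strong clean signal, tiny images."""
    return DomainShiftSpec(
        domain_id="easy",
        image_size=(16, 16, 3),
        n_train_per_class=50,
        n_test_per_class=15,
        class_signal_amplitude=1.0,
        texture_noise_sd=0.0,
        background_level=0.2,
        seed=11,
    )


@pytest.fixture()
def small_arch() -> ArchConfig:
    return ArchConfig(input_size=(16, 16, 3), conv_filters=(8, 16), kernel_size=3)


@pytest.fixture()
def fast_train() -> TrainConfig:
    return TrainConfig(max_epochs=10, learning_rate=0.05, seed=0)


N_STRONG_SEEDS = 5


@pytest.fixture(scope="session")
def strong_shift_runs():
    """Per-seed results on the strong-shift benchmark.

    For each root seed: phase-1 metrics (M1, Mav1) and two full AL runs
    (least_confidence and random) sharing the same w1, pool and test sets.
    """
    results = []
    for root_seed in range(N_STRONG_SEEDS):
        cfg = strong_shift_experiment_config(seed=root_seed)
        data = prepare_data(cfg, root_seed)
        w1, recs1 = run_phase1(cfg, data, root_seed)
        entry = {
            "seed": root_seed,
            "M1": recs1["M1"],
            "Mav1": recs1["Mav1"],
            "data": data,
        }
        al_tc = replace(cfg.al_train_config, seed=root_seed)
        for strategy in ("least_confidence", "random"):
            al_cfg = ALConfig(
                N=len(data.target.train), l=cfg.al_l, m=cfg.al_m,
                strategy=strategy, seed=root_seed,
            )
            w12, al_state = run_active_learning(
                w1.clone(), data.target, data.target.test, data.combined_test,
                al_cfg, al_tc,
            )
            entry[strategy] = {
                "state": al_state,
                "M12": evaluate_classifier(w12, data.target.test, "T2"),
                "Mav12": evaluate_classifier(w12, data.combined_test, "T1+T2"),
                "curve_T2": np.array(
                    [e.metrics["T2"].accuracy for e in al_state.history]
                ),
                "fractions": np.array(
                    [e.fraction_labeled for e in al_state.history]
                ),
            }
        results.append(entry)
    return results
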