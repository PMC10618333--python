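"""End-to-end drivers at desk scale.

These functions pin the problem sizes used throughout the package's
demonstrations and checks: a 2,000-molecule scaffold corpus for
generator pretraining, the 1,453-row synthetic affinity table for the
predictor, and a 30-epoch REINFORCE run at softmax temperature 0.80
with initial objective weights (0.6, 0.4) and weight-update step 0.05.
Model widths are kept small (embedding 48-64, 48-128 recurrent units)
so a full pipeline runs in minutes on one CPU core; training uses
float32 arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import nn
from .fixtures import FixtureSpec, make_affinity_table, make_corpus
from .generator import GeneratorConfig, SmilesGenerator
from .predictor import Pic50Predictor, PredictorConfig
from .rewards import ScalarizationState
from .rl import ReinforceOptimizer, RLConfig
from .tokenizer import TokenVocabulary

#: staged learning-rate schedule for generator pretraining: (epochs, lr)
PRETRAIN_SCHEDULE: tuple[tuple[int, float], ...] = (
    (30, 2.5e-3), (15, 1e-3), (10, 5e-4),
)


def toy_generator_config(**overrides) -> GeneratorConfig:
    defaults = dict(embedding_dim=64, units_per_layer=128, max_len=60,
                    learning_rate=2.5e-3, batch_size=128, temperature=0.8)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def toy_predictor_config(configuration: str = "I", **overrides) -> PredictorConfig:
    defaults = dict(configuration=configuration, embedding_dim=48,
                    recurrent_units=48, max_len=60, batch_size=64,
                    epochs=40, patience=10)
    defaults.update(overrides)
    return PredictorConfig(**defaults)


def pretrain_generator(corpus: list[str], seed: int = 0,
                       schedule=PRETRAIN_SCHEDULE,
                       config: GeneratorConfig | None = None,
                       verbose: bool = False) -> tuple[SmilesGenerator, list[float]]:
    """Pretrain the SMILES language model with the staged LR schedule."""
    with nn.default_dtype(np.float32):
        gen = SmilesGenerator(TokenVocabulary(), config or toy_generator_config(),
                              seed=seed)
        trace: list[float] = []
        for stage, (epochs, lr) in enumerate(schedule):
            gen.config.learning_rate = lr
            trace += gen.pretrain(corpus, epochs=epochs, seed=seed + stage,
                                  verbose=verbose)
    return gen, trace


def train_toy_predictor(table: pd.DataFrame | None = None, seed: int = 0,
                        configuration: str = "I", epochs: int | None = None,
                        run_cv: bool = False) -> tuple[Pic50Predictor, dict]:
    """Train the default predictor on the synthetic affinity table."""
    from .predictor import train_predictor

    if table is None:
        table = make_affinity_table(FixtureSpec(n=1453, seed=seed + 3))
    with nn.default_dtype(np.float32):
        model, report = train_predictor(table, toy_predictor_config(configuration),
                                        seed=seed, epochs=epochs, run_cv=run_cv)
    return model, report


def run_toy_rl(generator: SmilesGenerator, predictor: Pic50Predictor,
               epochs: int = 30, seed: int = 0, batch_size: int = 64,
               verbose: bool = False):
    """REINFORCE biasing run at the framework's standard settings."""
    config = RLConfig(epochs=epochs, batch_size=batch_size,
                      learning_rate=5e-4, gamma=1.0, temperature=0.80,
                      use_baseline=True)
    state = ScalarizationState(w1=0.6, w2=0.4, step=0.05)
    with nn.default_dtype(np.float32):
        biased = generator.clone()
        opt = ReinforceOptimizer(biased, predictor, state=state, config=config)
        log = opt.run(seed=seed, verbose=verbose)
    return biased, log


def toy_pipeline(seed: int = 0, corpus_n: int = 2000, rl_epochs: int = 30,
                 verbose: bool = False) -> dict:
    """Full pretrain -> predictor -> RL -> evaluation pipeline at desk scale."""
    from .evaluation import generation_report, property_shift_report

    corpus = make_corpus(FixtureSpec(n=corpus_n, seed=seed + 1))
    gen, trace = pretrain_generator(corpus, seed=seed, verbose=verbose)
    predictor, pred_report = train_toy_predictor(seed=seed)
    biased, log = run_toy_rl(gen, predictor, epochs=rl_epochs, seed=seed,
                             verbose=verbose)
    with nn.no_grad():
        sample_unbiased = gen.sample(200, temperature=0.8, seed=seed + 11)
        sample_biased = biased.sample(200, temperature=0.8, seed=seed + 12)
    shift = property_shift_report(sample_unbiased, sample_biased, predictor)
    report = generation_report(sample_unbiased, corpus, predictor=predictor)
    return {
        "corpus": corpus,
        "generator": gen,
        "biased_generator": biased,
        "predictor": predictor,
        "predictor_report": pred_report,
        "pretrain_trace": trace,
        "rl_log": log,
        "shift": shift,
        "generation_report": report,
    }
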