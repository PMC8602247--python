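"""Shared fixtures: random peptide makers and small trained models.

The trained-model fixtures are session-scoped so the (CPU-cheap but not
free) training runs happen once and are reused by the library-engineering
and error-control tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from phosphodia import neural_model as nm
from phosphodia import synthetic_data as sd
from phosphodia.peptide_codec import ModifiedPeptide, PHOSPHO, OXIDATION, Precursor


def random_peptide(rng: np.random.Generator, min_len=7, max_len=20) -> ModifiedPeptide:
    """One random valid phosphopeptide (possibly with oxidation/acetyl)."""
    from phosphodia.peptide_codec import AMINO_ACIDS

    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    mods = {}
    sty = [i + 1 for i, a in enumerate(seq) if a in "STY"]
    if sty and rng.random() < 0.85:
        for pos in rng.choice(sty, size=min(len(sty), int(rng.integers(1, 3))), replace=False):
            mods[int(pos)] = PHOSPHO
    ms = [i + 1 for i, a in enumerate(seq) if a == "M" and (i + 1) not in mods]
    if ms and rng.random() < 0.3:
        mods[int(rng.choice(ms))] = OXIDATION
    return ModifiedPeptide(seq, mods, bool(rng.random() < 0.15))


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small synthetic corpus of precursors + ground-truth spectra/RTs."""
    cfg = sd.GeneratorConfig(seed=11, n_peptides=48, min_len=7, max_len=16)
    precursors = sd.gen_peptides(cfg)
    L = max(len(p.peptide) for p in precursors)
    spectra = sd.gen_ground_truth_spectra(precursors, cfg, L=L)
    rts = sd.gen_ground_truth_rt([p.peptide for p in precursors], cfg)
    return cfg, precursors, spectra, rts, L


@pytest.fixture(scope="session")
def trained_models(tiny_corpus):
    """A small ion model + RT ensemble trained on the tiny corpus."""
    cfg, precursors, spectra, rts, L = tiny_corpus
    ion_cfg = nm.IonModelConfig.reduced(max_len=L)
    ion_model = nm.build_ion_model(ion_cfg, seed=5)
    tcfg = nm.TrainConfig(
        learning_rate=1e-3, max_epochs=60, batch_size=48, seed=5, stop_at_metric=0.9
    )
    ion_ckpt, _ = nm.train(ion_model, (precursors, spectra), (precursors, spectra), tcfg)

    rt_cfg = nm.RTModelConfig.reduced(max_len=L, depths=(2,))
    rt_ens = nm.build_rt_ensemble(rt_cfg, seed=5)
    peptides = [p.peptide for p in precursors]
    rcfg = nm.TrainConfig(learning_rate=1e-3, max_epochs=25, batch_size=48, seed=5)
    rt_ckpt, _ = nm.train(rt_ens, (peptides, rts), (peptides, rts), rcfg)
    return ion_model, rt_ens, ion_ckpt, rt_ckpt
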