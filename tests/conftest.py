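"""Shared fixtures: small libraries plus one full-scale simulated screen.

The full-scale screen (200 pairs, depth 1000, default noise) is built once
per session and shared by the recovery, background and bookkeeping tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import paircut as pc
from paircut.calling import (CallingConfig, LibraryIndex, call_reads,
                             subtract_background)


@pytest.fixture(scope="session")
def small_library():
    genes = pc.synthesize_gene_sequences(10, 1500, seed=2)
    return pc.design_library(genes, ["TTTV"], seed=2, max_pairs=50)


@pytest.fixture(scope="session")
def screen_library():
    genes = pc.synthesize_gene_sequences(40, 1500, seed=2)
    lib = pc.design_library(genes, ["TTTV"], seed=2, max_pairs=200)
    assert len(lib) == 200
    return lib


@pytest.fixture(scope="session")
def screen_truth_rates(screen_library):
    rng = np.random.default_rng(3)
    return {p.pair_id: float(rng.uniform(0.0, 0.6)) for p in screen_library}


@pytest.fixture(scope="session")
def screen_run(screen_library, screen_truth_rates):
    """Edited screen at depth 1000 with default noise, fully called."""
    effector = pc.EffectorModel("synthetic", {})
    ds = pc.generate_dataset(screen_library, effector, pc.NoiseModel(),
                             depth_per_pair=1000, seed=5,
                             per_pair_rates=screen_truth_rates)
    cfg = CallingConfig()
    index = LibraryIndex(screen_library)
    exp, stats = call_reads((r.sequence for r in ds.experimental), index, cfg)
    ctrl, _ = call_reads((r.sequence for r in ds.control), index, cfg)
    final = subtract_background(exp, ctrl)
    return {"dataset": ds, "config": cfg, "index": index, "exp": exp,
            "ctrl": ctrl, "final": final, "stats": stats,
            "rates": screen_truth_rates}


@pytest.fixture(scope="session")
def null_run(screen_library):
    """Same screen with editing disabled: noise only, then full calling."""
    effector = pc.EffectorModel("synthetic", {})
    rates = {p.pair_id: 0.0 for p in screen_library}
    ds = pc.generate_dataset(screen_library, effector, pc.NoiseModel(),
                             depth_per_pair=1000, seed=7, per_pair_rates=rates)
    cfg = CallingConfig()
    index = LibraryIndex(screen_library)
    exp, _ = call_reads((r.sequence for r in ds.experimental), index, cfg)
    ctrl, _ = call_reads((r.sequence for r in ds.control), index, cfg)
    final = subtract_background(exp, ctrl)
    return {"dataset": ds, "config": cfg, "final": final}
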