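"""Shared helpers: seeded RNG streams and logging."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("scsubpop")

# Fixed offsets so each simulated artifact component has its own stream and
# adding one component (e.g. more SNPs) never perturbs another.
STREAM_OFFSETS = {
    "genes": 1,
    "cells": 2,
    "counts": 3,
    "dropout": 4,
    "qc_plant": 5,
    "genotypes": 6,
    "alleles": 7,
    "cycle": 8,
    "generic": 9,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named RNG stream derived from a master seed."""
    return np.random.default_rng([int(seed), STREAM_OFFSETS[name]])


def child_seed(seed: int, k: int) -> int:
    """Derive a reproducible 31-bit child seed for libraries needing an int."""
    ss = np.random.SeedSequence([int(seed), int(k)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
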