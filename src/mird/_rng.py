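"""Seeded random-stream plumbing.

A single master seed fans out into named substreams so that enabling or
disabling one consumer (model sampling, subject-level uniforms, bootstrap
resampling, the trial simulator) never perturbs the draws of another.
Subject-level uniforms are additionally keyed per subject id, so adding or
removing a subject leaves every other subject's variates untouched.
"""

from __future__ import annotations

import zlib

import numpy as np

# Fixed numeric tags for the named substreams.
STREAM_MODEL = 1
STREAM_UNIFORMS = 2
STREAM_BOOTSTRAP = 3
STREAM_SIMULATOR = 4


def _id_key(subject_id) -> int:
    """Stable non-negative integer key for an opaque subject id."""
    if isinstance(subject_id, (int, np.integer)) and not isinstance(subject_id, bool):
        return int(subject_id) & 0xFFFFFFFF
    return zlib.crc32(str(subject_id).encode("utf-8"))


def stream(seed: int, *key: int) -> np.random.Generator:
    """Generator for the substream identified by ``key`` under ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.Generator(np.random.PCG64(ss))


def subject_uniforms(seed: int, subject_id, n: int) -> np.ndarray:
    """``n`` open-interval Uniform(0,1) variates private to one subject.

    Draw ``b``-th imputation's variate as element ``b-1``; the stream depends
    only on (seed, subject id), never on the rest of the dataset.
    """
    rng = stream(seed, STREAM_UNIFORMS, _id_key(subject_id))
    u = rng.random(n)
    # rng.random() lives in [0, 1); push exact zeros off the boundary.
    return np.nextafter(u, 1.0)
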