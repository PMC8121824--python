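"""Outlier-particle detection from mutual Bhattacharyya similarity.

After alignment, every pair of particles is scored with the anisotropic
Bhattacharyya overlap; summing rows of the N x N similarity matrix gives one
quality score per particle, and particles whose scores fall in the low tail
(more than k scaled MADs below the median) are flagged.  This only works
when most particles are of good quality and the fusion has not failed.
"""

from __future__ import annotations

import numpy as np

from smlmfuse.gmm_registration import bhattacharyya_cost
from smlmfuse.lie_averaging import AbsolutePoseSet
from smlmfuse.particle_store import ParticleSet, RigidTransform, apply_transform

MAD_SCALE = 1.4826  # normal-consistency constant


def similarity_matrix(ps: ParticleSet, poses: AbsolutePoseSet) -> np.ndarray:
    """Symmetric N x N matrix of Bhattacharyya overlaps between aligned
    particles; the diagonal (self-overlap) is set to 0."""
    n = len(ps)
    if n < 3:
        raise ValueError("need at least 3 particles for outlier scoring")
    aligned = [apply_transform(ps[i], poses[i].inverse()) for i in range(n)]
    eye = RigidTransform.identity()
    mat = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            s = bhattacharyya_cost(aligned[i], aligned[j], eye)
            mat[i, j] = mat[j, i] = s
    return mat


def particle_scores(matrix: np.ndarray) -> np.ndarray:
    """One quality score per particle: the row sum of the similarity matrix."""
    matrix = np.asarray(matrix, float)
    return matrix.sum(axis=1)


def flag_outliers(scores: np.ndarray, k: float = 3.0,
                  two_sided: bool = False) -> np.ndarray:
    """Boolean mask of outlier particles by the scaled-MAD rule.

    A particle is an outlier when its score is more than ``k`` scaled median
    absolute deviations below the median (low tail only by default: bad
    particles produce the extended low tail of the score histogram, while
    unusually high overlap is not penalized).  A small floor on the MAD
    prevents the all-equal degeneracy from flagging everything.
    """
    scores = np.asarray(scores, float)
    med = np.median(scores)
    mad = MAD_SCALE * np.median(np.abs(scores - med))
    mad = max(mad, 1e-12 * max(abs(med), 1.0))
    low = scores < med - k * mad
    if two_sided:
        return low | (scores > med + k * mad)
    return low


def rank_particles(scores: np.ndarray) -> np.ndarray:
    """Particle indices sorted from best (highest score) to worst."""
    return np.argsort(np.asarray(scores))[::-1]
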