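"""Gray-level co-occurrence texture features over the nuclear mask.

The co-occurrence matrix is built at distance 1 over the four standard
offsets (E, S, SE, SW) pooled into one symmetric matrix; both endpoints of
a pixel pair must lie inside the mask, so the background never contaminates
the texture.  The full 256-level range is used without re-quantization.

Features: entropy (bits by default), contrast, local homogeneity (inverse
difference moment) and cluster prominence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import NucleusImage
from .errors import ValidationError

#: Default offsets as (drow, dcol): east, south, southeast, southwest.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

LEVELS = 256


@dataclass(frozen=True)
class GrayCooccurrence:
    """Normalized symmetric co-occurrence matrix with marginal means."""

    p: np.ndarray
    mu_x: float
    mu_y: float


@dataclass(frozen=True)
class GlcmFeatures:
    entropy: float
    contrast: float
    local_homogeneity: float
    cluster_prominence: float


def compute_glcm(
    nucleus: NucleusImage | np.ndarray,
    mask: np.ndarray | None = None,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int = LEVELS,
) -> GrayCooccurrence:
    """Accumulate pixel-pair counts over ``offsets`` and normalize.

    Each ordered pair is counted in both directions, which makes the matrix
    symmetric by construction.  Accepts a :class:`NucleusImage` or a raw
    gray array with an explicit ``mask`` (``None`` means all pixels).
    """
    if isinstance(nucleus, NucleusImage):
        gray = nucleus.gray
        mask = nucleus.mask
    else:
        gray = np.asarray(nucleus)
        if mask is None:
            mask = np.ones(gray.shape, dtype=bool)
        mask = np.asarray(mask).astype(bool)
    gray = gray.astype(np.int64)
    h, w = gray.shape
    counts = np.zeros(levels * levels, dtype=np.float64)
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), min(h, h - dr))
        c0 = slice(max(0, -dc), min(w, w - dc))
        r1 = slice(max(0, dr), min(h, h + dr))
        c1 = slice(max(0, dc), min(w, w + dc))
        valid = mask[r0, c0] & mask[r1, c1]
        i = gray[r0, c0][valid]
        j = gray[r1, c1][valid]
        counts += np.bincount(i * levels + j, minlength=levels * levels)
        counts += np.bincount(j * levels + i, minlength=levels * levels)
    total = counts.sum()
    if total == 0:
        raise ValidationError("mask admits no valid pixel pairs")
    p = (counts / total).reshape(levels, levels)
    idx = np.arange(levels, dtype=np.float64)
    mu_x = float((p.sum(axis=1) * idx).sum())
    mu_y = float((p.sum(axis=0) * idx).sum())
    return GrayCooccurrence(p=p, mu_x=mu_x, mu_y=mu_y)


def glcm_features(cooc: GrayCooccurrence, log_base: float = 2.0) -> GlcmFeatures:
    """Entropy, contrast, local homogeneity and cluster prominence of ``p``."""
    p = cooc.p
    levels = p.shape[0]
    nz = p[p > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(log_base))).sum())
    idx = np.arange(levels, dtype=np.float64)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    contrast = float((diff2 * p).sum())
    local_homogeneity = float((p / (1.0 + diff2)).sum())
    dev = idx[:, None] + idx[None, :] - cooc.mu_x - cooc.mu_y
    cluster_prominence = float(((dev**4) * p).sum())
    return GlcmFeatures(
        entropy=entropy,
        contrast=contrast,
        local_homogeneity=local_homogeneity,
        cluster_prominence=cluster_prominence,
    )
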