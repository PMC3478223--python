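"""Geometric morphometry: nuclear area, form factor, gray mean and SD.

The form factor is the circularity index 4*pi*A/P^2 with the perimeter
measured along the 8-connected boundary chain code (axial step 1, diagonal
step sqrt(2)).  Digitization effects can push values slightly above 1 for
round nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import NucleusImage
from .errors import ValidationError

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# Moore neighborhood in clockwise order starting east, as (dr, dc)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class MorphometryResult:
    area_um2: float
    form_factor: float
    mean_gray: float
    sd_gray: float


def nuclear_area(nucleus: NucleusImage) -> float:
    """Foreground pixel count times calibration squared (um^2)."""
    return float(nucleus.mask.sum()) * nucleus.calibration**2


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace (clockwise), Jacob's stopping rule.

    Returns the closed sequence of boundary pixel coordinates; the last
    element equals the first.  Single-pixel masks return a length-1 path.
    """
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # uppermost-leftmost foreground pixel
    if mask.sum() == 1:
        return [start]
    # backtrack starts at the pixel west of start (background by construction)
    path = [start]
    current = start
    prev_dir = 4  # direction pointing back west
    first_move = None
    while True:
        found = False
        # scan clockwise beginning one step past the backtrack direction
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            dr, dc = _MOORE[d]
            nxt = (current[0] + dr, current[1] + dc)
            if padded[nxt]:
                if first_move is None:
                    first_move = d
                elif current == start and d == first_move and len(path) > 1:
                    return path  # re-entered start with the initial move
                path.append(nxt)
                current = nxt
                prev_dir = (d + 4) % 8  # new backtrack direction
                found = True
                break
        if not found:  # isolated pixel (already handled) – defensive
            return path
        if len(path) > 8 * padded.size:  # pragma: no cover - safety valve
            raise RuntimeError("boundary trace failed to terminate")


def chain_code_perimeter(mask: np.ndarray) -> float:
    """Perimeter of the 8-connected boundary: axial steps 1, diagonal sqrt 2."""
    path = _trace_boundary(np.asarray(mask, dtype=bool))
    if len(path) < 2:
        return 0.0
    length = 0.0
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        length += _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return length


def form_factor(nucleus: NucleusImage, largest_component: bool = False) -> float:
    """Circularity 4*pi*A/P^2 of the mask.

    Requires a single 4-connected component; with ``largest_component=True``
    the largest component is used instead of raising.
    """
    mask = nucleus.mask
    labels, n_comp = ndimage.label(mask, structure=_FOUR_CONN)
    if n_comp == 0:
        raise ValidationError("empty mask")
    if n_comp > 1:
        if not largest_component:
            raise ValidationError(
                f"mask has {n_comp} connected components; expected 1"
            )
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    area_px = float(mask.sum())
    perimeter = chain_code_perimeter(mask)
    if perimeter == 0.0:
        raise ValidationError("mask too small for a boundary perimeter")
    return float(4.0 * np.pi * area_px / perimeter**2)


def gray_stats(nucleus: NucleusImage) -> tuple[float, float]:
    """Mean and population SD (divisor N) of gray values inside the mask."""
    values = nucleus.gray[nucleus.mask]
    if values.size < 2:
        raise ValidationError("need at least 2 foreground pixels")
    return float(values.mean()), float(values.std())


def morphometry(nucleus: NucleusImage, largest_component: bool = False) -> MorphometryResult:
    mean, sd = gray_stats(nucleus)
    return MorphometryResult(
        area_um2=nuclear_area(nucleus),
        form_factor=form_factor(nucleus, largest_component=largest_component),
        mean_gray=mean,
        sd_gray=sd,
    )
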