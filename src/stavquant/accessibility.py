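"""Antibody-accessibility scoring from co-stained two-channel images.

A TurboID-HA tagged protein is imaged with both fluorescent
streptavidin (which reaches biotinylated targets even inside
phase-separated, protein-dense regions) and anti-HA (which often does
not).  The streptavidin channel defines where the protein actually is;
the accessibility score asks how much anti-HA signal shows up there:

    score = (median HA in mask - median HA in background)
            / (median strep in mask - median strep in background)

computed per cell within the streptavidin-defined reference mask and
aggregated by the median over cells.  A score near 1 means the epitope
is as accessible as the biotin; a score near 0 means the antibody
fails where the protein resides — the signature of a phase-separated
environment.  Scores are binned into increment classes to build an
N-/C-terminus accessibility table across tagged proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters

from .profiles import Projection

__all__ = [
    "AccessibilityScore",
    "reference_mask",
    "accessibility_score_cell",
    "accessibility_score",
    "bin_accessibility",
]

EPS = 1e-6  # detector units; guards the streptavidin denominator


@dataclass
class AccessibilityScore:
    protein: str
    terminus: str  # "N" or "C"
    score: float | None
    n_cells: int
    increment_class: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.terminus not in ("N", "C"):
            raise ValueError("terminus must be 'N' or 'C'")
        if self.score is not None and self.score < 0:
            raise ValueError("score must be >= 0")


def reference_mask(
    proj: Projection,
    reference_channel: str = "strep",
    threshold: float | None = None,
    annulus: np.ndarray | None = None,
    background_erosion_px: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference mask from the streptavidin channel, plus background region.

    The mask is the set of pixels above an automatic Otsu threshold in
    the reference channel (or an explicit ``threshold`` override),
    optionally intersected with a user-supplied nuclear-rim ``annulus``.
    The background region is the below-threshold area eroded by
    ``background_erosion_px`` so it does not touch the signal.
    """
    img = proj.channel(reference_channel)
    if threshold is None:
        if np.ptp(img) == 0:
            raise ValueError(
                f"reference channel {reference_channel!r} is blank; cannot build a mask"
            )
        threshold = float(filters.threshold_otsu(img))
    mask = img > threshold
    if annulus is not None:
        mask &= np.asarray(annulus, dtype=bool)
    if not mask.any():
        raise ValueError(
            f"empty reference mask (channel {reference_channel!r}, threshold {threshold:g})"
        )
    background = ~(img > threshold)
    if background_erosion_px > 0:
        background = ndimage.binary_erosion(background, iterations=background_erosion_px)
    if not background.any():
        raise ValueError("empty background region after erosion")
    return mask, background


def accessibility_score_cell(
    proj: Projection,
    mask: np.ndarray,
    background: np.ndarray,
    ha_channel: str = "HA",
    strep_channel: str = "strep",
    eps: float = EPS,
) -> tuple[float | None, str | None]:
    """Per-cell accessibility score; (None, flag) when the reference is dark.

    Medians (not means) are used throughout for robustness to hot
    pixels and pore-to-pore variability.
    """
    ha = proj.channel(ha_channel)
    st = proj.channel(strep_channel)
    ha_sig = float(np.median(ha[mask])) - float(np.median(ha[background]))
    st_sig = float(np.median(st[mask])) - float(np.median(st[background]))
    if st_sig <= eps:
        return None, "no reference signal"
    return max(0.0, ha_sig) / st_sig, None


def accessibility_score(
    projections: list[Projection],
    protein: str,
    terminus: str,
    *,
    ha_channel: str = "HA",
    strep_channel: str = "strep",
    reference_channel: str | None = None,
    threshold: float | None = None,
    n_min: int = 10,
    eps: float = EPS,
) -> AccessibilityScore:
    """Median accessibility score across cells for one (protein, terminus).

    Each projection is one cell; its reference mask is rebuilt from its
    own streptavidin channel.  Cells whose reference signal does not
    exceed background are flagged and excluded.  Fewer than ``n_min``
    scored cells flags the aggregate as under-sampled.
    """
    reference_channel = reference_channel or strep_channel
    per_cell: list[float] = []
    flags: list[str] = []
    for i, proj in enumerate(projections):
        try:
            mask, background = reference_mask(
                proj, reference_channel=reference_channel, threshold=threshold
            )
        except ValueError as exc:
            flags.append(f"cell {i}: {exc}")
            continue
        s, flag = accessibility_score_cell(
            proj, mask, background, ha_channel=ha_channel, strep_channel=strep_channel, eps=eps
        )
        if flag:
            flags.append(f"cell {i}: {flag}")
            continue
        per_cell.append(s)
    if not per_cell:
        return AccessibilityScore(
            protein=protein, terminus=terminus, score=None, n_cells=0,
            flags=flags + ["no scorable cells"],
        )
    if len(per_cell) < n_min:
        flags.append(f"only {len(per_cell)} cells (< {n_min})")
    return AccessibilityScore(
        protein=protein,
        terminus=terminus,
        score=float(np.median(per_cell)),
        n_cells=len(per_cell),
        flags=flags,
    )


def bin_accessibility(
    scores: list[AccessibilityScore], class_edges: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0)
) -> pd.DataFrame:
    """Assign increment classes and assemble the accessibility table.

    ``class_edges`` must be strictly increasing and start at 0; class i
    is the half-open interval [edge_i, edge_{i+1}) (the last extends to
    infinity), so a score exactly on an edge falls in the upper
    interval.  Flagged scores get class "undetermined".  The result has
    at most one row per (protein, terminus).
    """
    edges = np.asarray(class_edges, dtype=float)
    if edges.size < 1 or edges[0] != 0.0:
        raise ValueError("class_edges must start at 0")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("class_edges must be strictly increasing")
    seen = set()
    rows = []
    for s in scores:
        key = (s.protein, s.terminus)
        if key in seen:
            raise ValueError(f"duplicate (protein, terminus) entry {key}")
        seen.add(key)
        if s.score is None:
            cls: int | str = "undetermined"
        else:
            cls = int(np.searchsorted(edges, s.score, side="right") - 1)
            s.increment_class = cls
        rows.append(
            {
                "protein": s.protein,
                "terminus": s.terminus,
                "score": s.score,
                "increment_class": cls,
                "n_cells": s.n_cells,
                "flags": ";".join(s.flags),
            }
        )
    return pd.DataFrame(rows, columns=["protein", "terminus", "score", "increment_class", "n_cells", "flags"])
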