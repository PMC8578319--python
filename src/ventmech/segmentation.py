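"""White matter hyperintensity segmentation by global thresholding.

Bright voxels are segmented from a brain mask Omega by the rule
``s(v) > mu + k sigma`` (population sigma over Omega, strict inequality,
k = 2.5 by default), and connected components whose exterior boundary is
majority-adjacent to CSF (> 50%, face adjacency) are removed as
septum/choroid-plexus structures.  Connectivity (4 or 8) and the sigma
convention are exposed as dialect flags; defaults are 4-connectivity and
the population (1/N) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import LABELS

__all__ = ["SegmentationResult", "threshold_mask", "prune_csf_adjacent", "segment"]

_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


@dataclass
class ComponentRecord:
    label: int
    size: int
    boundary_pixels: int
    csf_boundary_pixels: int
    removed: bool

    @property
    def csf_fraction(self) -> float:
        return self.csf_boundary_pixels / max(self.boundary_pixels, 1)


@dataclass
class SegmentationResult:
    omega: np.ndarray          # brain mask
    raw_mask: np.ndarray       # thresholded mask (before pruning)
    mask: np.ndarray           # final mask
    threshold: float
    mu: float
    sigma: float
    components: list[ComponentRecord]

    def audit_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "component": c.label,
                    "size_px": c.size,
                    "boundary_px": c.boundary_pixels,
                    "csf_boundary_px": c.csf_boundary_pixels,
                    "csf_fraction": c.csf_fraction,
                    "removed": c.removed,
                }
                for c in self.components
            ]
        )


def threshold_mask(image: np.ndarray, omega: np.ndarray, k: float = 2.5, population_sigma: bool = True):
    """Strict global threshold ``s(v) > mu + k sigma`` inside omega.

    A constant image has sigma = 0 and yields an empty mask (the strict
    inequality never holds), not an error.
    """
    omega = np.asarray(omega, bool)
    if not np.any(omega):
        raise ValueError("brain mask omega is empty")
    vals = np.asarray(image, float)[omega]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0 if population_sigma else 1))
    thr = mu + k * sigma
    mask = (np.asarray(image, float) > thr) & omega
    return mask, mu, sigma, thr


def prune_csf_adjacent(mask: np.ndarray, csf_mask: np.ndarray, connectivity: int = 4):
    """Remove connected components with > 50% of their exterior boundary
    adjacent to CSF.

    Components are found with the given pixel connectivity; a component's
    boundary is its set of face-adjacent exterior pixels inside the image
    (border-clipped neighbours are not counted).
    """
    if mask.shape != csf_mask.shape:
        raise ValueError("mask and CSF mask must share shape")
    struct = _STRUCTS[connectivity]
    labeled, n = ndimage.label(mask, structure=struct)
    out = np.asarray(mask, bool).copy()
    records = []
    face = _STRUCTS[4]  # boundary adjacency is always by face
    for lab in range(1, n + 1):
        comp = labeled == lab
        ring = ndimage.binary_dilation(comp, structure=face) & ~comp
        n_b = int(ring.sum())
        n_csf = int((ring & np.asarray(csf_mask, bool)).sum())
        removed = n_b > 0 and n_csf / n_b > 0.5
        if removed:
            out[comp] = False
        records.append(
            ComponentRecord(
                label=lab,
                size=int(comp.sum()),
                boundary_pixels=n_b,
                csf_boundary_pixels=n_csf,
                removed=removed,
            )
        )
    return out, records


def segment(
    image: np.ndarray,
    label_image: np.ndarray,
    k: float = 2.5,
    connectivity: int = 4,
    population_sigma: bool = True,
    omega_labels=("white_matter", "gray_matter", "cavity"),
    csf_labels=("csf", "cavity"),
) -> SegmentationResult:
    """Threshold + CSF-adjacency pruning with a per-component audit trail.

    Omega defaults to the brain tissue plus the ventricular cavity (the
    whole-brain mask convention of uniformity-corrected FLAIR pipelines:
    intraventricular CSF is part of the mask, which is what allows bright
    intraventricular structures to be caught and pruned); the CSF mask used
    for adjacency is subarachnoid plus intraventricular CSF.
    """
    label_image = np.asarray(label_image)
    omega = np.isin(label_image, [LABELS[l] for l in omega_labels])
    csf = np.isin(label_image, [LABELS[l] for l in csf_labels])
    raw, mu, sigma, thr = threshold_mask(image, omega, k=k, population_sigma=population_sigma)
    mask, records = prune_csf_adjacent(raw, csf, connectivity=connectivity)
    return SegmentationResult(
        omega=omega, raw_mask=raw, mask=mask, threshold=thr, mu=mu, sigma=sigma,
        components=records,
    )
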