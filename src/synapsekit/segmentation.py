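"""Contact segmentation and SMAC partitioning.

The cell-substrate contact footprint is defined by the IRM channel (close
membrane apposition appears dark), and partitioned into the central, peripheral
and distal supramolecular activation clusters (c/p/dSMAC) using the UCHT1
(TCR ligand) and ICAM1 (adhesion) channels.

All automatic thresholds are Otsu's method, so segmentation is invariant to
affine intensity rescaling of each channel; absolute overrides are accepted
everywhere an automatic threshold is used.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as _closing, disk

from .types import (
    CSMAC,
    DSMAC,
    OUTSIDE,
    PSMAC,
    ContactMask,
    NoContactError,
    RegionPartition,
)

MIN_CONTACT_AREA_UM2 = 5.0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = cc_label(mask, return_num=True)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labeled.ravel())[1:]
    return labeled == (int(np.argmax(sizes)) + 1)


def _otsu_or_none(values: np.ndarray) -> float | None:
    """Otsu threshold, or None when the values carry no contrast."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.ptp(values) == 0:
        return None
    try:
        return float(threshold_otsu(values))
    except ValueError:
        return None


def contact_mask_from_irm(
    irm: np.ndarray,
    pixel_size: float,
    *,
    threshold: float | None = None,
    min_area_um2: float = MIN_CONTACT_AREA_UM2,
    closing_radius_px: int = 3,
) -> ContactMask:
    """Segment the IRM-defined contact footprint.

    Pixels below the (automatic or supplied) threshold are taken as contact,
    morphologically closed with a 3-pixel-radius disc, hole-filled, and the
    largest connected component retained.

    Raises
    ------
    NoContactError
        If no below-threshold component reaches ``min_area_um2``.
    """
    irm = np.asarray(irm, dtype=float)
    if irm.size == 0:
        raise ValueError("IRM image is empty")
    if threshold is None:
        threshold = _otsu_or_none(irm.ravel())
        if threshold is None:
            raise NoContactError("IRM image has no intensity contrast")
    dark = irm < threshold
    dark = _closing(dark, disk(closing_radius_px))
    dark = ndimage.binary_fill_holes(dark)
    component = _largest_component(dark)
    if component.sum() * pixel_size**2 < min_area_um2:
        raise NoContactError(
            f"largest dark component is below the minimum contact area of {min_area_um2} um^2"
        )
    return ContactMask(mask=component, pixel_size=pixel_size)


def contact_center(contact: ContactMask | RegionPartition) -> tuple[float, float]:
    """Area centroid of the contact mask, in um (x, y)."""
    mask = contact.mask if isinstance(contact, ContactMask) else contact.contact_mask
    if not mask.any():
        raise ValueError("contact mask is empty")
    ii, jj = np.nonzero(mask)
    ps = contact.pixel_size
    return (float((jj + 0.5).mean() * ps), float((ii + 0.5).mean() * ps))


def _enriched_within(values_img: np.ndarray, contact: np.ndarray, threshold: float | None) -> np.ndarray:
    """In-contact pixels above the channel's automatic (or given) threshold.

    The threshold is computed over in-contact pixels only; a contrast-free
    channel yields no enrichment.
    """
    if threshold is None:
        threshold = _otsu_or_none(values_img[contact])
        if threshold is None:
            return np.zeros_like(contact, dtype=bool)
    return contact & (values_img > threshold)


def partition_regions(
    contact: ContactMask,
    ucht1: np.ndarray,
    icam1: np.ndarray,
    *,
    ucht1_threshold: float | None = None,
    icam1_threshold: float | None = None,
    intensity_weighted_center: bool = False,
    weight_image: np.ndarray | None = None,
) -> RegionPartition:
    """Partition the contact into cSMAC, pSMAC and dSMAC.

    cSMAC is the largest connected UCHT1-enriched component inside the
    contact (suppressing peripheral TCR microclusters); pSMAC is the
    ICAM1-enriched remainder; dSMAC is everything else in the contact. The
    three labels partition the contact exactly. The reported center is the
    contact-mask area centroid by default, or the centroid weighted by
    ``weight_image`` when ``intensity_weighted_center`` is set.
    """
    ucht1 = np.asarray(ucht1, dtype=float)
    icam1 = np.asarray(icam1, dtype=float)
    mask = contact.mask
    if ucht1.shape != mask.shape or icam1.shape != mask.shape:
        raise ValueError("channel shapes must match the contact mask")

    csmac = _largest_component(_enriched_within(ucht1, mask, ucht1_threshold))
    psmac = _enriched_within(icam1, mask, icam1_threshold) & ~csmac
    dsmac = mask & ~csmac & ~psmac

    labels = np.full(mask.shape, OUTSIDE, dtype=np.int8)
    labels[dsmac] = DSMAC
    labels[psmac] = PSMAC
    labels[csmac] = CSMAC

    if intensity_weighted_center:
        if weight_image is None:
            raise ValueError("intensity_weighted_center requires a weight_image")
        w = np.asarray(weight_image, dtype=float) * mask
        if w.sum() <= 0:
            raise ValueError("weight image has no in-contact intensity")
        ii, jj = np.nonzero(mask)
        ps = contact.pixel_size
        wv = w[ii, jj]
        center = (
            float(np.average((jj + 0.5) * ps, weights=wv)),
            float(np.average((ii + 0.5) * ps, weights=wv)),
        )
    else:
        center = contact_center(contact)

    flags = {
        "empty_csmac": not csmac.any(),
        "empty_psmac": not psmac.any(),
    }
    return RegionPartition(labels=labels, pixel_size=contact.pixel_size, center=center, flags=flags)


def segment_synapse(image, **kwargs) -> RegionPartition:
    """Convenience: contact mask from IRM then SMAC partition, in one call."""
    contact = contact_mask_from_irm(image["irm"], image.pixel_size)
    return partition_regions(contact, image["ucht1"], image["icam1"], **kwargs)
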