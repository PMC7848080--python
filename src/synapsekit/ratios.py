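"""Membrane intensity ratios from z-stacks and vesicle-contact profiles.

Two ratio statistics: distal-versus-basal membrane intensity from a confocal
z-stack (mean intensity in a 3 x 3 um box at the synapse center, profiled
across z; peaks over the lower and upper halves of the z-range are the basal
and distal intensities), and the outside-versus-inside intensity ratio of a
membrane profile sampled across a cell-vesicle contact.
"""
from __future__ import annotations

import math

import numpy as np

from .types import MembraneProfile, ZStack

BOX_UM = 3.0


def box_z_profile(stack: ZStack, center: tuple[float, float], box_um: float = BOX_UM) -> np.ndarray:
    """Mean intensity per z-plane inside the centered box."""
    half = box_um / 2.0
    ps = stack.pixel_size
    rows, cols = stack.planes.shape[1:]
    x, y = center
    j0, j1 = int(np.floor((x - half) / ps)), int(np.ceil((x + half) / ps))
    i0, i1 = int(np.floor((y - half) / ps)), int(np.ceil((y + half) / ps))
    if i0 < 0 or j0 < 0 or i1 > rows or j1 > cols:
        raise ValueError("the box extends beyond the image")
    return stack.planes[:, i0:i1, j0:j1].mean(axis=(1, 2))


def distal_basal_ratio(
    stack: ZStack,
    center: tuple[float, float],
    box_um: float = BOX_UM,
) -> float:
    """Distal over basal membrane intensity at the synapse center.

    The stack must be ordered basal (coverslip-proximal) first. Basal
    intensity is the peak of the box profile over the lower half of the
    z-range, distal the peak over the upper half; for an odd number of
    planes the middle plane belongs to both halves, which makes the ratio of
    a z-mirrored stack exactly the reciprocal of the original.
    """
    profile = box_z_profile(stack, center, box_um)
    n = len(profile)
    half = math.ceil(n / 2)
    basal = float(profile[:half].max())
    distal = float(profile[n - half:].max())
    if basal <= 0:
        raise ValueError("basal intensity is zero")
    return distal / basal


def guv_contact_ratio(profile: MembraneProfile) -> float:
    """Mean intensity outside the contact over mean intensity inside.

    Outside samples are expected on both sides of the contact out to one
    contact-width; shorter flanks are accepted but flagged on the profile
    (``truncated``). Values above one indicate exclusion from the contact.
    """
    inside = profile.intensity[profile.is_contact]
    idx = np.flatnonzero(profile.is_contact)
    spacing = float(np.median(np.diff(profile.arclength_um)))
    width = profile.arclength_um[idx[-1]] - profile.arclength_um[idx[0]] + spacing
    left = profile.intensity[: idx[0]]
    right = profile.intensity[idx[-1] + 1:]
    flank = width / spacing
    if len(left) + 0.5 < flank or len(right) + 0.5 < flank:
        profile.truncated = True
    outside = np.concatenate([left, right])
    inside_mean = float(inside.mean())
    if inside_mean <= 0:
        raise ValueError("inside mean intensity is zero")
    return float(outside.mean()) / inside_mean
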