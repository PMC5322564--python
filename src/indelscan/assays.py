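"""Closed-form assay quantifications: SURVEYOR densitometry and tumour volume.

The SURVEYOR mismatch-cleavage assay estimates the edited fraction of a cell
population from agarose-gel band intensities.  After cross-annealing, a
heteroduplex forms whenever the two strands come from differently edited
alleles; the cleaved fraction ``(b + c) / (a + b + c)`` therefore estimates
``1 - p_wt**2`` for wild-type allele fraction ``p_wt``, giving the square-root
formula below.
"""

from __future__ import annotations

import math


def surveyor_indel_percent(a: float, b: float, c: float) -> float:
    """Indel percentage from SURVEYOR gel band intensities.

    ``100 * (1 - sqrt(1 - (b + c) / (a + b + c)))``, where ``a`` is the
    integrated intensity of the undigested product and ``b``, ``c`` those of
    the two cleaved products.  Scale-invariant in ``(a, b, c)`` and strictly
    increasing in the cleaved fraction; ranges over [0, 100].
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("band intensities must be non-negative")
    total = a + b + c
    if total == 0:
        raise ValueError("all band intensities are zero")
    cleaved_fraction = (b + c) / total
    return 100.0 * (1.0 - math.sqrt(1.0 - cleaved_fraction))


def cleaved_fraction_for(indel_percent: float) -> float:
    """Inverse of :func:`surveyor_indel_percent`: the cleaved fraction giving
    a target indel percentage."""
    if not 0 <= indel_percent <= 100:
        raise ValueError("indel percentage must be in [0, 100]")
    return 1.0 - (1.0 - indel_percent / 100.0) ** 2


def tumour_volume(d_short: float, d_long: float) -> float:
    """Xenograft tumour volume from two caliper diameters (mm).

    ``(d_short ** 2 * d_long) / 2``, the standard ellipsoid approximation;
    result in mm^3.
    """
    if d_short <= 0 or d_long <= 0:
        raise ValueError("diameters must be positive")
    if d_short > d_long:
        raise ValueError("d_short must not exceed d_long")
    return (d_short ** 2 * d_long) / 2.0
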