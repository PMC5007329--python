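"""Unit conversions between optical density, cell density and habitat counts.

The calibration OD600 0.1 ≈ 3×10⁶ cells/ml gives the single conversion
constant used throughout; it is approximate (strain- and
instrument-dependent) but adequate for order-of-magnitude ecology, e.g.
translating culture densities into expected yeast numbers in a ~100 nL
insect gut.
"""

from __future__ import annotations

__all__ = ["OD_TO_CELLS_PER_ML", "od_to_density", "ecological_cell_count"]

#: cells·ml⁻¹ per OD600 unit, from the calibration point OD 0.1 ≈ 3e6 cells/ml.
OD_TO_CELLS_PER_ML = 3e7


def od_to_density(od: float) -> float:
    """Convert OD600 to cells per ml (approximate linear calibration)."""
    if od < 0:
        raise ValueError("optical density must be non-negative")
    return od * OD_TO_CELLS_PER_ML


def ecological_cell_count(density_per_ml: float, volume_nl: float) -> float:
    """Expected cell count in a habitat of ``volume_nl`` nanolitres.

    At 10⁵–10⁷ cells/ml and a ~100 nL fly-gut volume this spans roughly
    10–1,000 cells — few enough that local sex ratio and density fluctuate,
    which is what makes sensing them worthwhile.
    """
    if density_per_ml < 0 or volume_nl < 0:
        raise ValueError("density and volume must be non-negative")
    return density_per_ml * volume_nl * 1e-6  # nL -> ml
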