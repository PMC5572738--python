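"""Vesicle geometry: how many phospholipids a unilamellar vesicle holds.

A large unilamellar vesicle of outer radius ``r`` (nm) with bilayer
thickness ``d`` (nm) exposes an outer leaflet of area 4*pi*r^2 and an inner
leaflet of area 4*pi*(r-d)^2. Dividing the total leaflet area by the area
occupied by one phospholipid headgroup gives the lipid count per vesicle.
For a 100-nm-radius POPC/POPG vesicle this is ~3.5e5 lipids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

#: Area per phospholipid in a fluid POPC/POPG bilayer (nm^2).
DEFAULT_AREA_PER_LIPID = 0.70

#: Bilayer thickness used to offset the inner-leaflet radius (nm).
DEFAULT_BILAYER_THICKNESS = 4.0


@dataclass(frozen=True)
class VesicleGeometry:
    """Geometry of a single unilamellar vesicle.

    Parameters
    ----------
    r_outer:
        Outer-leaflet radius in nm.
    area_per_lipid:
        Area per phospholipid headgroup in nm^2.
    bilayer_thickness:
        Bilayer thickness in nm; the inner leaflet has radius
        ``r_outer - bilayer_thickness``. May be 0 (flat-bilayer convention,
        equal leaflet areas).
    """

    r_outer: float
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID
    bilayer_thickness: float = DEFAULT_BILAYER_THICKNESS

    def __post_init__(self) -> None:
        if not self.area_per_lipid > 0:
            raise InvalidParameterError(
                f"area_per_lipid must be positive, got {self.area_per_lipid}"
            )
        if self.bilayer_thickness < 0:
            raise InvalidParameterError(
                f"bilayer_thickness must be >= 0, got {self.bilayer_thickness}"
            )
        if not self.r_outer > self.bilayer_thickness:
            raise InvalidParameterError(
                "r_outer must exceed bilayer_thickness "
                f"(got r_outer={self.r_outer}, thickness={self.bilayer_thickness})"
            )


def lipids_per_vesicle(geom: VesicleGeometry) -> float:
    """Number of phospholipids in both leaflets of a vesicle.

    Returns ``4*pi*(r^2 + (r-d)^2) / A``. With ``d=0`` this reduces to the
    equal-leaflet form ``8*pi*r^2/A`` used in the occupancy model.
    """
    r = geom.r_outer
    ri = geom.r_outer - geom.bilayer_thickness
    return 4.0 * math.pi * (r * r + ri * ri) / geom.area_per_lipid
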