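"""Scalar virology assay formulas.

Three pure functions used to quantify antiviral protection: efficiency
of plating (EOP), the ΔCT estimate of relative viral genome load, and
the unadsorbed-virus percentage of adsorption assays. All are
scale-free where dimensionally required: rescaling both titres by a
common factor changes neither the EOP nor the percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class TitreMeasurement:
    """A plaque-assay titre in PFU/mL."""

    strain_id: str
    titre: float

    def __post_init__(self) -> None:
        if not self.titre > 0:
            raise ValueError("titre must be positive (PFU/mL)")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Threshold cycles for the chromosomal (radA) and viral (repA) amplicons."""

    ct_radA: float
    ct_repA: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_radA) and math.isfinite(self.ct_repA)):
            raise ValueError("CT values must be finite")


def eop(titre_test: float, titre_ref: float) -> float:
    """Efficiency of plating: test-host titre over reference-host titre.

    A protective system reduces the EOP below 1 (e.g. ~1e-4 for a
    10^4-fold drop in plaquing).
    """
    if not titre_ref > 0:
        raise ValueError("reference titre must be positive")
    return titre_test / titre_ref


def relative_viral_load(m: QpcrMeasurement) -> float:
    """Viral genome copies per host chromosome, 2^(CT(radA) − CT(repA)).

    The sign convention follows the assay definition exactly: the
    chromosomal reference CT minus the viral target CT, so a lower viral
    CT (more viral DNA) gives a larger fold value.
    """
    return 2.0 ** (m.ct_radA - m.ct_repA)


def unadsorbed_pct(titre_t: float, titre_0: float) -> float:
    """Extracellular (unadsorbed) virus as a percentage of the initial
    titre, the cell-free t = 0 sample defining 100%."""
    if not titre_0 > 0:
        raise ValueError("initial titre must be positive")
    return 100.0 * titre_t / titre_0
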