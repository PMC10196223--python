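"""genoscape: eco-genetic conservation prioritization.

A reusable implementation of a landscape-genetics / niche-modelling /
prioritization workflow for range-wide population conservation planning:
diversity and differentiation metrics, dbRDA variance partitioning
(IBD/IBE/IBR/IBC), LD-based effective population size and M-ratio
bottleneck tests, maxent-style suitability modelling with future-scenario
area and altitude accounting, ancestry-under-climate forecasting, and two
population-prioritization procedures (allele-complementarity reserve
selection and the conservation index C_i = A_r * F_c / C_l).
"""

from importlib.resources import files as _files

import pandas as _pd

__version__ = "0.1.0"

from .containers import (AncestryMatrix, ClimateStack, DistMatrix,
                         GenotypeTable, RasterGrid, SuitabilityMap)


def load_reference_sites() -> _pd.DataFrame:
    """Published per-population reference inputs for the South Caucasus
    sweet-chestnut system: coordinates, altitude, sample size, conservation
    index and mutation-scaled theta, as printed in the source tables."""
    with _files("genoscape.data").joinpath("south_caucasus_sites.csv").open() as fh:
        return _pd.read_csv(fh)


__all__ = ["AncestryMatrix", "ClimateStack", "DistMatrix", "GenotypeTable",
           "RasterGrid", "SuitabilityMap", "load_reference_sites",
           "__version__"]
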