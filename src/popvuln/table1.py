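"""Published per-population census and vulnerability table (fixture).

The thirteen censused populations of the study species with their
published parameters: elevation, plant counts by stage and reproductive
status, stem-length statistics, occupied area, densities, inter-plant
distances, and mean CCVI per scenario set.  Populations are listed in
latitudinal order.  This table is the deterministic input for the
population-level association models and the arithmetic consistency
checks; the underlying plant coordinates are withheld by the authors, so
the skewness and CCVI columns here are published values, not recomputable
ones.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

_CSV = """\
population,elevation_m,n_plants,mean_stem_cm,sd_stem_cm,n_fruiting,n_young,n_adult,skewness,mean_distance_m,sd_distance_m,area_ha,density_per_ha,young_density_per_ha,adult_density_per_ha,ccvi_mean,ccvi_mean_sd,ccvi_ssp126,ccvi_ssp126_sd,ccvi_ssp585,ccvi_ssp585_sd
Picazo Norte,951,11,46.2,42.7,1,5,6,1.88,27.3,26.1,0.044,251.1,114.2,137.0,0.977,0.081,1.003,0.068,0.951,0.086
Picazo Centro,919,209,77.7,42.0,103,35,174,0.56,22.2,13.5,0.159,1318.3,220.8,1097.5,0.963,0.086,0.999,0.065,0.927,0.090
Picazo Sur,889,109,55.9,35.5,33,33,76,1.32,9.5,5.3,0.046,2383.1,721.5,1661.6,0.994,0.083,1.041,0.050,0.948,0.083
El Morrillo Norte,979,4,35.0,15.8,0,2,2,0.37,4.1,1.7,0.002,1726.3,863.1,863.1,1.043,0.066,1.056,0.056,1.030,0.075
El Morrillo Sur,895,77,52.2,35.9,10,27,50,0.97,36.4,23.6,0.480,160.6,56.3,104.3,1.041,0.067,1.054,0.056,1.028,0.074
Los Patos,1086,298,59.7,28.7,71,59,239,0.36,21.8,13.2,0.295,1010.2,200.0,810.2,1.012,0.105,1.056,0.070,0.968,0.116
Rabones Oeste,795,22,45.5,30.9,7,12,10,1.14,16.7,9.6,0.055,402.0,219.3,182.7,1.089,0.053,1.069,0.056,1.110,0.040
Rabones Este,907,283,43.0,28.8,78,137,146,2.39,92.0,86.8,0.977,289.8,140.3,149.5,1.054,0.036,1.039,0.028,1.070,0.036
Loma Larga Este,1143,181,66.0,30.8,49,29,152,0.38,53.1,44.9,0.618,293.0,46.9,246.1,0.947,0.087,0.954,0.076,0.940,0.097
Loma Larga Oeste,1057,89,59.4,26.3,26,12,77,0.79,11.7,7.1,0.046,1947.0,262.5,1684.4,0.976,0.061,0.968,0.057,0.983,0.065
Montecillo,637,251,46.4,28.4,35,98,153,2.41,50.6,36.0,0.716,350.7,136.9,213.8,1.049,0.052,1.024,0.024,1.075,0.060
Los Hualles,750,33,39.2,24.5,2,16,17,1.67,45.9,39.6,0.366,90.2,43.7,46.5,0.962,0.082,0.952,0.050,0.972,0.104
Vado Azul,772,48,70.8,41.7,7,10,38,1.02,126.7,104.3,0.609,78.8,16.4,62.4,0.969,0.133,0.956,0.096,0.983,0.161
"""


def load_table1() -> pd.DataFrame:
    """The published per-population table as a validated DataFrame."""
    df = pd.read_csv(io.StringIO(_CSV))
    if len(df) != 13:
        raise AssertionError("census table must have 13 populations")
    if not (df["n_young"] + df["n_adult"] == df["n_plants"]).all():
        raise AssertionError("young + adult counts must equal the plant count")
    return df


def young_proportion(df: pd.DataFrame | None = None) -> np.ndarray:
    df = df if df is not None else load_table1()
    return (df["n_young"] / df["n_plants"]).to_numpy()
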