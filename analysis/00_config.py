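"""Shared configuration for the analysis scripts.

One desk-scale synthetic herd stands in for a breed's herdbook: about
2,000 animals over three generations on six farms, with seasonal
rainfall, drought years and hot-season heat load.  All scripts write
their tables under results/ and are deterministic for a fixed seed.
"""

from pathlib import Path

from cattlernm.simulate import SimScenario

SEED = 20260901 % (2**31)
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

EC_NAMES = ("sumPrec365", "sumPrec280", "sumPrec90", "meanTHI90")


def herd_scenario(seed: int = SEED) -> SimScenario:
    return SimScenario(n_founders=250, n_generations=3, n_farms=6,
                       n_veg_zones=3, years=(2000, 2015), seed=seed)
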