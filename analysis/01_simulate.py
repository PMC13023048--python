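"""Generate the synthetic herdbook: pedigree, weather and phenotypes.

Writes pedigree.csv, phenotypes.csv, weather CSVs and the truth ledger
under results/data/ and prints the data-structure summary.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

cfg = import_module("00_config")

from cattlernm.simulate import simulate_dataset, write_outputs  # noqa: E402


def main():
    scenario = cfg.herd_scenario()
    pedigree, weather, records, truth = simulate_dataset(scenario)
    cfg.DATA.mkdir(parents=True, exist_ok=True)
    write_outputs(cfg.DATA, pedigree, weather, records, truth)
    print(f"pedigree: {len(pedigree)} animals "
          f"({pedigree['dam'].notna().sum()} with known dam)")
    print(f"records:  {len(records)} (BW {records['bw_kg'].notna().sum()}, "
          f"WW {records['ww_kg'].notna().sum()})")
    print(f"farms: {records['farm'].nunique()}, "
          f"potential contemporary groups: {records['cg_id'].nunique()}")
    print(f"BW mean {records['bw_kg'].mean():.1f} kg "
          f"(sd {records['bw_kg'].std():.1f}); "
          f"WW mean {records['ww_kg'].mean():.1f} kg "
          f"(sd {records['ww_kg'].std():.1f})")
    print(f"written to {cfg.DATA}")


if __name__ == "__main__":
    main()
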