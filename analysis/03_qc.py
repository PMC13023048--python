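"""Apply the record filters and form contemporary groups.

Exclusions (no birth date / no trait), the +/-3.5 SD outlier screen,
parity recoding, and the farm x year x season contemporary groups with
the more-than-five-records rule.  Writes the cleaned records and the QC
log.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = import_module("00_config")

from cattlernm import qc  # noqa: E402


def main():
    records = pd.read_csv(cfg.DATA / "phenotypes.csv", parse_dates=["birth_date"])
    cleaned, report = qc.run_qc(records)
    cleaned.to_csv(cfg.RESULTS / "records_qc.csv", index=False)
    report.exclusions.to_csv(cfg.RESULTS / "qc_exclusions.csv", index=False)
    counts = report.counts()
    print(f"input records:    {counts['input']}")
    for reason, n in counts["excluded"].items():
        print(f"  excluded {reason}: {n}")
    for trait, n in counts["outliers"].items():
        print(f"  outliers set missing ({trait}): {n}")
    print(f"dropped groups:   {len(report.dropped_groups)} "
          f"(all with <= 5 records)")
    print(f"retained records: {counts['retained']} in "
          f"{cleaned['cg_id'].nunique()} contemporary groups")


if __name__ == "__main__":
    main()
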