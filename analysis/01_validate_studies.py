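"""Screen the 14-study rs966221 table: totals, internal consistency, control HWE.

Writes results/validation.csv and prints the exclusion-relevant findings:
which rows' genotype sums disagree with the reported sample sizes (the
genotype counts are the analysis's source of truth) and whether any retained
study's controls fail the HWE screen at p < 0.001 (none should — studies
failing it were excluded upstream of this table).
"""

import csv
from pathlib import Path

from allelemeta import load_rs966221_table, total_counts, validate_studies

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = load_rs966221_table()
    cases, controls = total_counts(table)
    print(f"{len(table)} studies; {cases} cases, {controls} controls")

    reports = validate_studies(table, hwe_threshold=0.001)
    OUT.mkdir(exist_ok=True)
    with (OUT / "validation.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["study_id", "case_sum_mismatch", "control_sum_mismatch", "hwe_flag"])
        for r in reports:
            w.writerow([r.study_id, r.case_sum_mismatch, r.control_sum_mismatch, r.hwe_flag])

    mismatched = [r for r in reports if r.case_sum_mismatch or r.control_sum_mismatch]
    print(f"\n{len(mismatched)} studies with genotype-sum/sample-size mismatches:")
    for r in mismatched:
        for m in r.messages:
            print(f"  {r.study_id}: {m}")
    flagged = [r.study_id for r in reports if r.hwe_flag]
    print(f"\ncontrol HWE failures at p < 0.001: {flagged or 'none'}")
    print(f"\nwrote {OUT / 'validation.csv'}")


if __name__ == "__main__":
    main()
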