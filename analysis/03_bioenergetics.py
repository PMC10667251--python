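"""Mitochondrial stress-test reduction and ATP production rates.

Reduces every well's OCR/ECAR trace to basal, proton-leak, maximal and
non-mitochondrial respiration, computes the mitochondrial ATP rate from the
oxygen deficit (P/O 2.75), aggregates clones to patients, and compares
conditions.
"""

import argparse
from pathlib import Path

import pandas as pd

from fluxcohort.bioenergetics import (
    InjectionSchedule,
    SeahorseTrace,
    ecar_ocr_ratio,
    mito_atp_rate,
    reduce_seahorse_trace,
)
from fluxcohort.io import read_trace_table
from fluxcohort.stats import aggregate_clones_to_patients, two_group_test

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()
    traces = read_trace_table(args.cohort / "traces.csv")
    schedule = InjectionSchedule()

    rows = []
    for well, g in traces.groupby("well"):
        g = g.sort_values("meas_index")
        p = reduce_seahorse_trace(
            SeahorseTrace(g["ocr"].to_numpy(), g["ecar"].to_numpy(), schedule,
                          celltype=str(g["celltype"].iloc[0]))
        )
        rows.append(
            {"well": well, "patient": g["patient"].iloc[0],
             "clone": g["clone"].iloc[0], "replicate": g["replicate"].iloc[0],
             "condition": g["condition"].iloc[0],
             "ocr_basal": p.ocr_basal, "ocr_proton_leak": p.ocr_proton_leak,
             "ocr_maximal": p.ocr_maximal, "ocr_atp_linked": p.ocr_atp_linked,
             "ocr_nonmito": p.ocr_nonmito, "mito_atp": mito_atp_rate(p),
             "ecar_basal": p.ecar_basal, "ecar_ocr": ecar_ocr_ratio(p),
             "qc_flag": p.qc_flag or ""}
        )
    bio = pd.DataFrame(rows)
    bio.to_csv(ROOT / "results" / "bioenergetics.csv", index=False)

    print("per-patient bioenergetics, Ctrl vs sPD:")
    for var in ("ocr_basal", "ocr_atp_linked", "ocr_maximal", "mito_atp",
                "ecar_basal", "ecar_ocr"):
        agg = aggregate_clones_to_patients(bio.rename(columns={var: "value"}))
        a = agg.loc[agg.condition == "Ctrl", "value"]
        b = agg.loc[agg.condition == "sPD", "value"]
        res = two_group_test(a, b)
        print(f"  {var:15s} Ctrl {a.mean():8.2f}  sPD {b.mean():8.2f}  "
              f"fold {b.mean()/a.mean():.3f}  ({res['test']}, "
              f"p = {res['p_value']:.3g})")
    flagged = (bio["qc_flag"] != "").sum()
    print(f"wells flagged by QC: {flagged}/{len(bio)}")


if __name__ == "__main__":
    main()
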