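#!/usr/bin/env python
"""One-way sensitivity analyses over the full scenario catalogue.

Each named scenario overrides the base case (treatment start age,
discontinuation, waning, effect size, start state, treated states,
horizon, drug price, administration route, discount rate, misdiagnosis
disutility, drug-specific trial inputs, alternative BBM accuracy
sources) and reports incremental cost, QALYs, ICER and incremental net
health benefit for its comparator pair(s).
"""

from pathlib import Path

from adcea import load_base_case
from adcea.scenarios import run_sensitivity

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    params = load_base_case()
    table = run_sensitivity(params)
    table.to_csv(OUT / "sensitivity.csv", index=False)

    csf = table[(table.strategy == "CSF")
                & (table.error == "")].set_index("scenario")
    print(csf[["d_cost", "d_qaly", "icer", "icer_label", "inhb"]]
          .round(3).to_string(), "\n")

    base = csf.loc["base_case"]
    print(f"Base case ICER vs SoC: €{base.icer:,.0f}/QALY.")
    moved = (csf.icer - base.icer).abs().sort_values(ascending=False)
    print("Largest one-way movers:", ", ".join(moved.index[:4]))
    failures = table[table.error != ""]
    if len(failures):
        print(f"{len(failures)} scenario(s) failed:",
              ", ".join(failures.scenario))
    else:
        print("All scenarios ran successfully.")


if __name__ == "__main__":
    main()
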