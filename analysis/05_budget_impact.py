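#!/usr/bin/env python
"""Five-year budget-impact projection from the payer perspective.

Open cohort: prevalent pool of 8000 patients split 50/50 between FC II
and FC III plus 605 incident patients per year with the same split, all
traced quarterly through each arm's Markov model; annual budget = direct
medical + drug cost, undiscounted.

Writes results/budget_usd.csv, results/budget_millions.csv and
results/budget_incremental.json.
"""

import json
from pathlib import Path

from pahcea import build_budget_table, default_parameters, incremental_budget

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = default_parameters()
    table = build_budget_table(params)
    OUT.mkdir(exist_ok=True)
    table.to_frame().to_csv(OUT / "budget_usd.csv")
    display = table.to_frame(millions=True).round(1)
    display.to_csv(OUT / "budget_millions.csv")
    inc = incremental_budget(table)
    (OUT / "budget_incremental.json").write_text(json.dumps(inc, indent=2) + "\n")
    print("annual budget (million USD):")
    print(display.to_string())
    print(f"\n5-year incremental budget of adopting sildenafil: "
          f"FC II {inc['FC2']:,.0f} USD, FC III {inc['FC3']:,.0f} USD, "
          f"combined {inc['combined']:,.0f} USD")


if __name__ == "__main__":
    main()
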