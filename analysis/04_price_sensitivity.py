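#!/usr/bin/env python
"""One-way sensitivity analysis and the originator-price threshold.

Produces the tornado tables (ICER at each input's mean +/- 1.96 SE,
clipped to domain), the generic-vs-originator drug price comparison,
and the bisection search for the originator price reduction at which
sildenafil reaches the WTP threshold.

Writes results/tornado_fc{2,3}.csv, results/price_scenarios.csv and
results/threshold_price.json.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from pahcea import default_parameters, one_way_analysis, threshold_price_search
from pahcea.sensitivity import price_scenario_icers
from pahcea.states import FunctionalClass as FC

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = default_parameters()
    OUT.mkdir(exist_ok=True)
    price_rows = []
    for fc in (FC.FC2, FC.FC3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tornado = one_way_analysis(params, fc)
        tornado.to_csv(OUT / f"tornado_{fc.name.lower()}.csv", index=False)
        top = tornado.iloc[0]
        print(f"{fc.name}: widest one-way swing is {top['parameter']} "
              f"(ICER {top['icer_low']:.0f} .. {top['icer_high']:.0f})")
        prices = price_scenario_icers(params, fc)
        prices["start"] = fc.name
        price_rows.append(prices)
        print(f"{fc.name}: originator-price ICER is {prices['ratio']:.1f}x "
              f"the generic-price ICER ({prices['originator']:.0f} vs "
              f"{prices['generic']:.0f} USD/QALY)")
    pd.DataFrame(price_rows).to_csv(OUT / "price_scenarios.csv", index=False)

    thr = threshold_price_search(params)
    (OUT / "threshold_price.json").write_text(json.dumps({
        "multiplier": thr.multiplier,
        "percent_reduction": thr.percent_reduction,
        "icer_at_multiplier": thr.icer_at_multiplier,
        "wtp": thr.wtp,
        "implied_tablet_price_usd":
            thr.multiplier * params.costs.tablet_price["sildenafil_originator"],
    }, indent=2) + "\n")
    print(f"threshold: originator sildenafil becomes cost-effective after a "
          f"{thr.percent_reduction:.1f}% price reduction "
          f"(implied tablet price "
          f"{thr.multiplier * params.costs.tablet_price['sildenafil_originator']:.3f} USD, "
          f"close to the generic {params.costs.tablet_price['sildenafil_generic']:.2f})")


if __name__ == "__main__":
    main()
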