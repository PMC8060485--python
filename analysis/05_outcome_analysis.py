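"""3-month outcome associations in the symptomatic group.

Writes the outcome table; reports the Woolf OR for the two-vein ipsilateral
CVF- category (favorable outcome as the case) and the NIHSS-adjusted
logistic fit when it is estimable.
"""

import json
from pathlib import Path

import pandas as pd

from cvflow.tables import outcome_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores = pd.read_csv(ROOT / "scores.csv")
    table = outcome_table(scores)
    table.to_csv(ROOT / "table_outcome.csv", index=False)
    orr = table.attrs["cvf2_or"]
    print(f"two-vein ipsilateral CVF- vs favorable outcome: "
          f"OR {orr['or']:.3f} (95% CI {orr['ci_low']:.3f}-{orr['ci_high']:.3f}, {orr['method']})")
    for key in ("cvf2_logistic", "cvf2_logistic_adjusted"):
        fit = table.attrs[key]
        label = "adjusted" if "adjusted" in key else "univariate"
        if "error" in fit:
            print(f"{label} logistic fit: {fit['error']}")
        else:
            print(f"{label} logistic OR {fit['or']:.3f} "
                  f"(95% CI {fit['ci_low']:.3f}-{fit['ci_high']:.3f}, p = {fit['p']:.3f})")
    (ROOT / "outcome_models.json").write_text(
        json.dumps({k: v for k, v in table.attrs.items()}, indent=2, default=float)
    )


if __name__ == "__main__":
    main()
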