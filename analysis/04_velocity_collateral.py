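"""CVF velocity (median-split rCVF indices) vs collateral status.

Writes the velocity table with one Woolf OR per rCVF index and reports the
early-to-peak (rCVF21) association.
"""

from pathlib import Path

import pandas as pd

from cvflow.tables import velocity_collateral_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores = pd.read_csv(ROOT / "scores.csv")
    table = velocity_collateral_table(scores)
    table.to_csv(ROOT / "table_velocity.csv", index=False)
    row = table.set_index("index").loc["rcvf21"]
    print(f"fast rCVF21 threshold: {row['threshold_s']:.2f} s")
    print(f"fast among good collateral {row['fast_good']}, among poor {row['fast_poor']}")
    print(f"OR {row['or']:.2f} (95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), p = {row['p']}")


if __name__ == "__main__":
    main()
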