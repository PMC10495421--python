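#!/usr/bin/env python
"""Pre-estimation diagnostics: stationarity, lag order, Granger causality.

Checks every emotion series for a unit root (ADF), compares information
criteria across VAR lag orders, and runs pairwise Granger-causality
tests, writing the tables to results/diagnostics/.
"""

import argparse
import json
from pathlib import Path

from emovar import EmotionPanel, adf_test, granger_tests, select_lag_order


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/synthetic/panel.csv"))
    ap.add_argument("--p-max", type=int, default=4)
    ap.add_argument("--out-dir", type=Path, default=Path("results/diagnostics"))
    args = ap.parse_args()

    panel = EmotionPanel.from_csv(args.panel)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    # partial out the known step dummies first: a permanent level shift
    # left in the series would mimic a unit root
    xex = panel.exog.to_numpy() if panel.n_exog else None
    adf = {name: adf_test(col, exog=xex) for name, col in panel.freq.items()}
    stationary = sum(r for _, r in adf.values())
    (args.out_dir / "adf.json").write_text(
        json.dumps({k: {"statistic": s, "reject_unit_root": r}
                    for k, (s, r) in adf.items()}, indent=1)
    )
    print(f"ADF rejects a unit root for {stationary}/{panel.n_emotions} series")

    p_star, table = select_lag_order(panel, p_max=args.p_max)
    table.to_csv(args.out_dir / "lag_order_criteria.csv")
    print(f"BIC selects lag order p = {p_star} "
          f"(AIC argmin: {int(table['aic'].idxmin())})")

    pmat = granger_tests(panel)
    pmat.to_csv(args.out_dir / "granger_pvalues.csv")
    n_pairs = panel.n_emotions * (panel.n_emotions - 1)
    rej = int((pmat.to_numpy() < 0.05).sum())
    print(f"Granger causality rejected at 5% for {rej}/{n_pairs} ordered pairs "
          f"(pairwise cross-effects are individually weak; the structured "
          f"model pools them)")


if __name__ == "__main__":
    main()
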