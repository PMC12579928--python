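#!/usr/bin/env python
"""Filter the data, tune and fit the richness model, evaluate it.

Applies the standard plot filters, splits the one-time plots 80/20
stratified by richness, runs a reduced-scale grid tuning (the full
node-size x mtry grid on a subsample with a smaller forest), fits the final
200-tree forest, and reports hold-out and repeated cross-validation
accuracy. The fitted model is stored under scratch/ for the later steps.
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from divtrend import plot_data, richness_model as rm  # noqa: E402

N_TREES = 200


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20)
    ap.add_argument("--skip-tuning", action="store_true")
    args = ap.parse_args()

    world = ROOT / "scratch" / "world"
    static = plot_data.read_plots(world / "static_plots.csv")
    retained, log = plot_data.apply_filters(static)
    print(f"filters: kept {len(retained)}/{len(static)} "
          f"(rejections {dict(log)})")

    train, test = plot_data.stratified_split(retained, seed=args.seed)

    best = rm.Hyperparams(n_trees=N_TREES, min_node_size=5, mtry=3, seed=args.seed)
    if not args.skip_tuning:
        sub = train.sample(n=3000, random_state=args.seed)
        tuned, table = rm.tune(sub, k=5, n_trees=50, seed=args.seed)
        table.to_csv(ROOT / "results" / "tuning_table.csv", index=False)
        print(f"tuning (25 combinations, reduced scale): best node size "
              f"{tuned.min_node_size}, mtry {tuned.mtry}")
        best = rm.Hyperparams(n_trees=N_TREES, min_node_size=tuned.min_node_size,
                              mtry=tuned.mtry, seed=args.seed)

    model = rm.fit(train, best)
    em = rm.evaluate(model, test)
    cv = rm.repeated_cv(train.sample(n=4000, random_state=args.seed),
                        rm.Hyperparams(n_trees=50, min_node_size=best.min_node_size,
                                       mtry=best.mtry, seed=args.seed),
                        k=5, repeats=3, seed=args.seed)
    print(f"hold-out: RMSE {em.rmse:.2f}, R2 {em.r2:.3f}")
    print(f"repeated CV (reduced scale): RMSE {cv['rmse'].mean():.2f} "
          f"± {cv['rmse'].std():.2f}")

    pd.DataFrame([
        {"metric": "rmse_test", "value": em.rmse, "n": len(test)},
        {"metric": "r2_test", "value": em.r2, "n": len(test)},
        {"metric": "pearson_r_test", "value": em.pearson_r, "n": len(test)},
        {"metric": "rmse_cv_mean", "value": cv["rmse"].mean(), "n": len(cv)},
        {"metric": "r2_cv_mean", "value": cv["r2"].mean(), "n": len(cv)},
    ]).to_csv(ROOT / "results" / "model_metrics.csv", index=False)

    model.save(ROOT / "scratch" / "model.joblib")
    train.to_csv(ROOT / "scratch" / "train.csv", index=False)
    test.to_csv(ROOT / "scratch" / "test.csv", index=False)
    print("wrote results/model_metrics.csv and scratch/model.joblib")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
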