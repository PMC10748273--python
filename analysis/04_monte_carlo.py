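"""Probabilistic risk assessment: fit normal/lognormal distributions to
the fraction-corrected concentrations, propagate 50,000 draws to Er/RI,
and summarize class probabilities, percentile bands, and the
contribution-to-variance sensitivities.  Writes the mc_* tables under
results/.
"""

from pathlib import Path

from fracrisk.io import RunConfig, read_sites, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
SEED = 2024


def main() -> None:
    sites = read_sites(ROOT / "results" / "sites.csv")
    cfg = RunConfig(sites=sites, mode="modified", mc_enabled=True,
                    n_draws=50_000, seed=SEED)
    tables = run_pipeline(cfg)
    for name in ("mc_specs", "mc_class_probabilities", "mc_percentiles",
                 "mc_sensitivity"):
        tables[name].to_csv(ROOT / "results" / f"{name}.csv", index=False)

    specs = tables["mc_specs"]
    print("fitted corrected-concentration distributions:")
    print(specs[["metal", "family", "loc", "scale", "outliers_removed"]]
          .round(3).to_string(index=False))

    probs = tables["mc_class_probabilities"]
    ri = probs[probs["index"] == "RI"].set_index("class")["probability_pct"]
    print(f"\nRI class probabilities (%): "
          + ", ".join(f"{c}={v:.2f}" for c, v in ri.items()))

    sens = tables["mc_sensitivity"]
    print("\ncontribution to RI variance (%):")
    print(sens.round(2).to_string(index=False))
    top = sens.iloc[0]
    print(f"\n{top['metal']} drives {top['contribution_pct']:.1f}% of the RI "
          f"variance — the priority pollutant for management")


if __name__ == "__main__":
    main()
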