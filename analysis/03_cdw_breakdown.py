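#!/usr/bin/env python
"""Show why raw CDW calibration fails: precipitate breaks the correlation.

Simulates a campaign whose decline-phase samples carry insoluble precipitate
(30-50 % of the biological dry weight) that inflates CDW without adding any
permittivity, then tabulates the Pearson correlation of fresh-sample ΔC
against total CDW per fermentation phase. The early-phase correlation stays
near 1 while the pooled correlation degrades — the failure mode that
motivates calibrating against viability-corrected biomass instead of CDW.
Writes results/cdw_correlations.csv.
"""

from pathlib import Path

from viacal import SimulationConfig, UniformLaw, cdw_correlation_diagnostics, simulate_campaign

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 42) -> None:
    cfg = SimulationConfig(
        n_samples=26,
        seed=seed,
        precipitate_law=UniformLaw(0.3, 0.5),
        alpha_law=UniformLaw(0.95, 1.0),
    )
    dataset, truth = simulate_campaign(cfg)
    table = cdw_correlation_diagnostics(dataset, truth)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "cdw_correlations.csv", index=False)

    print(table.to_string(index=False))
    by = table.set_index("group")
    print(
        f"\noverall CDW correlation r = {by.loc['overall', 'r_cdw']:.3f} vs "
        f"early-phase r = {by.loc['early', 'r_cdw']:.3f}: late-phase precipitate "
        "degrades the naive CDW calibration, while the correlation against the "
        f"true viable biomass stays at r = {by.loc['overall', 'r_viable_true']:.3f}"
    )


if __name__ == "__main__":
    main()
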