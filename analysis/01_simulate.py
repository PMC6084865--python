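#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces 30 years (1987–2016) of: a seasonally phase-locked ENSO index,
soil-moisture/temperature fields over the Philippines domain with a negative
4-month-lead ENSO teleconnection, tropical-Pacific SST, quarterly crop panels
per region × system, an 18-member pseudo-model warming ensemble, and tropical
rice occurrence points. Everything is written under results/simulated/.
"""

from pathlib import Path

from paddyclim import crops, pipeline
from paddyclim.config import SimConfig

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    inputs = pipeline.simulate_inputs(cfg)

    crops.write_crop_table(inputs["panel"], OUT / "crop_panel.csv")
    inputs["enso"].to_frame("enso_index").to_csv(OUT / "enso_index.csv")
    inputs["accessions"].to_csv(OUT / "accessions.csv", index=False)
    for name in ("soil_moisture", "temperature", "sst"):
        inputs[name].to_dataset(name=name).to_netcdf(OUT / f"{name}.nc", engine="scipy")
    ens = inputs["ensemble"]
    ens.global_anomaly.to_csv(OUT / "global_anomaly.csv")

    panel = inputs["panel"]
    n_missing = int(panel[["area_ha", "production_t"]].isna().sum().sum())
    print(f"seed {SEED}: {cfg.n_years} years, grid {inputs['soil_moisture'].shape}")
    print(f"ENSO index: sd={inputs['enso'].std():.3f}, "
          f"winter/summer variance ratio="
          f"{inputs['enso'].groupby(inputs['enso'].index.month).var()[12] / inputs['enso'].groupby(inputs['enso'].index.month).var()[6]:.2f}")
    print(f"crop panel: {len(panel)} records, {n_missing} missing cells "
          f"({n_missing / (2 * len(panel)):.2%}, rainfed only)")
    print(f"pseudo-models: {len(ens.models)}, global-mean warming "
          f"{ens.delta_t_global.min():.2f}–{ens.delta_t_global.max():.2f} °C")
    print(f"accessions: {len(inputs['accessions'])} tropical occurrence points")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
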