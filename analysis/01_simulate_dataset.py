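#!/usr/bin/env python
"""Generate the synthetic study datasets used by the downstream analyses.

Writes two datasets under results/data/:

* ``root_9v9`` — the discovery design: 9 +Pi vs 9 -Pi root replicates over
  three late timepoints, with eight CHH hypermethylation implants (delta
  0.5, 12 sites each) placed in TEs near genes, plus the unmethylated
  spike-in chromosome and a matched DE table.
* ``persistence_3x3`` — triplicate +Pi / -Pi / resupply groups at a late
  timepoint with half the implants persistent and half transient.
"""

from pathlib import Path

from psimeth.synthetic_data import Implant, SimConfig, persistence_design, write_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    root_cfg = SimConfig(seed=101)
    paths = write_dataset(root_cfg, OUT / "root_9v9")
    print(f"root_9v9: {len(root_cfg.samples)} samples, "
          f"{len(root_cfg.implants)} implants -> {paths['sample_sheet'].parent}")

    pers_cfg = SimConfig(
        seed=102,
        samples=persistence_design(),
        implants=[Implant(persistence_class="persistent") for _ in range(4)]
        + [Implant(persistence_class="transient") for _ in range(4)],
    )
    paths = write_dataset(pers_cfg, OUT / "persistence_3x3")
    print(f"persistence_3x3: {len(pers_cfg.samples)} samples, "
          f"4 persistent + 4 transient implants -> {paths['sample_sheet'].parent}")


if __name__ == "__main__":
    main()
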