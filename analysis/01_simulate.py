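"""Generate the frozen default synthetic dataset (seed 1) and write it to disk.

Produces the wide-CSV spectra + metadata files that the later drivers (and
anyone wanting to poke at the data) read back: 80 calibration and 24
validation samples, balanced mutant/wild-type, 3 replicate spectra each,
paraffin-embedded preparation.
"""

from pathlib import Path

from nirdx.spectra_io import write_spectra
from nirdx.synthetic_data import SyntheticConfig, generate

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(seed=1)
    cal, val = generate(config)
    provenance = f"synthetic seed={config.seed} effect_size={config.effect_size}"
    write_spectra(cal, OUT / "calibration_spectra.csv", OUT / "calibration_meta.csv",
                  header_comment=provenance)
    write_spectra(val, OUT / "validation_spectra.csv", OUT / "validation_meta.csv",
                  header_comment=provenance)
    print(f"calibration: {cal.n_spectra} spectra / {len(set(cal.sample_ids))} samples")
    print(f"validation:  {val.n_spectra} spectra / {len(set(val.sample_ids))} samples")
    print(f"grid: {len(cal.grid)} points, "
          f"{cal.grid.values[0]:.0f} -> {cal.grid.values[-1]:.0f} cm^-1")
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
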