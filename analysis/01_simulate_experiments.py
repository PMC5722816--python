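"""Generate the synthetic pump-probe experiments used by the later steps.

Writes, for each excitation (508 nm = carotenoid, 690 nm = Chl red edge),
the two detection windows (480-610 and 590-720 nm, 76 channels each) as
delimited TA matrices with ground-truth sidecars.  The matrices are bulky
raw data, so they go under scratch/simulated/ rather than results/.
"""

import json
from pathlib import Path

from astakin import generate_paper_like
from astakin.io import write_ta_matrix

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for excitation in (508, 690):
        for kind in ("target", "sequential"):
            blue, red = generate_paper_like(excitation, seed=SEED, kind=kind)
            for name, ds in (("blue", blue), ("red", red)):
                stem = f"ta_{excitation}nm_{kind}_{name}"
                write_ta_matrix(OUT / f"{stem}.tsv", ds)
                with open(OUT / f"{stem}.truth.json", "w") as fh:
                    json.dump(ds.truth, fh, indent=2)
                print(
                    f"{stem}: {ds.dA.shape[0]} delays x {ds.dA.shape[1]} channels, "
                    f"noise sigma {ds.noise_sigma:.3f} mOD"
                )
    print(f"\nwrote synthetic experiments to {OUT}")


if __name__ == "__main__":
    main()
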