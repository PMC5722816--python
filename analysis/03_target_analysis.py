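"""Simultaneous target analysis of both excitations (the core inference).

Generates the paired 508/690-nm experiments (two windows each), then fits
the two shipped compartmental models at once: the quencher S_q shares one
spectrum and one decay rate across all four datasets, triplet spectra obey
their zero regions, and five rates are re-estimated from perturbed starts
(the S1 -> Chl transfer, the S1/S*/S_q ground losses and the fastest
Chl -> S_q quenching rate).  Writes the recovered-rate table and the SADS
of every dataset under results/target/.
"""

from pathlib import Path

from astakin import TARGET_TRUTH_NS, recover_target_rates
from astakin.io import write_spectra

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "target"
DATASET_NAMES = ["508nm_blue", "508nm_red", "690nm_blue", "690nm_red"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fit = recover_target_rates(SEED)
    print("simultaneous fit of 4 datasets; cost"
          f" {fit.cost:.4g} (chi2 {fit.extra['chi2']:.4g}), converged={fit.converged}")
    print(f"\n{'rate':>15} {'true (ns^-1)':>13} {'fitted':>9} {'stderr':>8} {'err %':>6}")
    with open(OUT / "rates.tsv", "w") as fh:
        fh.write("parameter\ttrue_ns\tfitted_ns\tstderr_ns\n")
        for name, truth in TARGET_TRUTH_NS.items():
            val = fit.rates[name]
            se = fit.stderr.get(name, float("nan"))
            print(f"{name:>15} {truth:>13g} {val:>9.4g} {se:>8.2g} "
                  f"{100 * (val / truth - 1):>6.1f}")
            fh.write(f"{name}\t{truth:g}\t{val:.6g}\t{se:.3g}\n")
    for name, ss in zip(DATASET_NAMES, fit.spectra):
        write_spectra(OUT / f"sads_{name}.tsv", ss)
    print(f"\nwrote target-analysis results to {OUT}")
    print("note: the three dark-state ground losses are weakly identified at "
          "the generator's 2% noise (see docs/methods.md); expect ~10-20% "
          "scatter on them and tight recovery of the transfer rates.")


if __name__ == "__main__":
    main()
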