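"""Calibration sweep for the log-normal abundance spread.

The generator draws per-gene baseline abundances from a log-normal with
spread sigma. This sweep shows how sigma shapes the copy-number
distribution of distinct clean tags — the real libraries had >80% of
distinct tags below 10 copies — and how it trades off against the expected
count of a median gene (and hence DE detectability at fixed depth).
Writes results/07_sigma_sweep.tsv.
"""

from _common import RESULTS

from dgetag.pipeline import run_pipeline
from dgetag.synthetic_data import SimulationConfig
from dgetag.tag_filtering import copy_number_distribution, low_copy_fraction


def main() -> None:
    sigmas = [0.8, 1.0, 1.2, 1.5, 1.8]
    with open(RESULTS / "07_sigma_sweep.tsv", "w") as fh:
        fh.write("sigma\tdistinct_clean_ste\tlow_copy_frac_ste\tsensitivity\tempirical_fdr\n")
        for sigma in sigmas:
            config = SimulationConfig(lognormal_sigma=sigma)
            result = run_pipeline(config)
            dist = copy_number_distribution(result.clean["Ste"])
            frac = low_copy_fraction(dist)
            rec = result.recovery
            fh.write(f"{sigma}\t{result.clean['Ste'].n_distinct}\t{frac:.4f}"
                     f"\t{rec['sensitivity']:.3f}\t{rec['empirical_fdr']:.4f}\n")
            print(f"sigma={sigma}: {result.clean['Ste'].n_distinct} distinct tags, "
                  f"{100 * frac:.1f}% low-copy, sensitivity {rec['sensitivity']:.2f}")
    print("default sigma=1.2 balances tail heaviness against planted-signal depth")


if __name__ == "__main__":
    main()
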