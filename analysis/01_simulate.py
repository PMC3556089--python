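"""Generate the default synthetic experiment and write its artifacts.

Emits the reference transcriptome, the decoy-bearing genome, both raw tag
libraries and the planted-truth table under scratch/sim/ (they are bulky),
plus a compact summary under results/.
"""

from _common import RESULTS, SCRATCH

from dgetag.io_formats import write_fasta, write_results_tsv, write_tag_table
from dgetag.synthetic_data import (
    SimulationConfig,
    TruthRow,
    generate_transcriptome,
    simulate_libraries,
)


def main() -> None:
    config = SimulationConfig()
    reference = generate_transcriptome(config)
    libraries = simulate_libraries(reference, config)

    outdir = SCRATCH / "sim"
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(reference.transcripts, outdir / "ref.fa")
    write_fasta(reference.genome, outdir / "genome.fa")
    write_tag_table(libraries.ste_raw, outdir / "ste_raw.tsv")
    write_tag_table(libraries.fer_raw, outdir / "fer_raw.tsv")
    write_results_tsv(list(reference.truth.values()), outdir / "truth.tsv", TruthRow)

    classes = {}
    for row in reference.truth.values():
        classes[row.true_class] = classes.get(row.true_class, 0) + 1
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "01_simulation_summary.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"config_hash\t{config.config_hash()}\n")
        fh.write(f"n_reference_genes\t{len(reference.transcripts)}\n")
        fh.write(f"n_alien_genes\t{len(reference.alien_transcripts)}\n")
        for name, table in (("Ste", libraries.ste_raw), ("Fer", libraries.fer_raw)):
            fh.write(f"{name}_raw_copies\t{table.total_copies}\n")
            fh.write(f"{name}_raw_distinct\t{table.n_distinct}\n")
            for k, v in libraries.noise[name].items():
                fh.write(f"{name}_injected_{k}\t{v}\n")
        for cls, n in sorted(classes.items()):
            fh.write(f"truth_{cls}\t{n}\n")
    print(f"simulation (hash {config.config_hash()}) written to {outdir}")


if __name__ == "__main__":
    main()
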