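"""End-to-end composition of the pipeline stages on simulated libraries.

Glue used by the analysis drivers, the test suite and the acceptance
script: simulate -> index -> filter -> map -> quantify -> test -> recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .diff_expression import DEGRecord, DEThresholds, classify_degs
from .quantification import GeneExpression, quantify
from .reference_index import ANTISENSE, SENSE, extract_reference_tags
from .synthetic_data import (
    SimulatedLibraries,
    SimulatedReference,
    SimulationConfig,
    generate_transcriptome,
    simulate_libraries,
)
from .tag_filtering import FilterReport, filter_tags
from .tag_mapping import MappingRecord, map_library


@dataclass
class PipelineResult:
    config: SimulationConfig
    reference: SimulatedReference
    libraries: SimulatedLibraries
    filter_reports: dict[str, FilterReport]
    clean: dict[str, object]  # library -> TagCountTable
    mapping: dict[str, list[MappingRecord]]
    expression: dict[str, list[GeneExpression]]
    degs: list[DEGRecord]
    recovery: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig,
    thresholds: DEThresholds | None = None,
    use_genome: bool = True,
) -> PipelineResult:
    reference = generate_transcriptome(config)
    libraries = simulate_libraries(reference, config)

    index = extract_reference_tags(reference.transcripts, (SENSE, ANTISENSE))
    genome_index = (
        extract_reference_tags(reference.genome, (SENSE, ANTISENSE), source="genome")
        if use_genome
        else None
    )

    clean, reports, mapping, expression = {}, {}, {}, {}
    gene_ids = [t.gene_id for t in reference.transcripts]
    for name, raw in (("Ste", libraries.ste_raw), ("Fer", libraries.fer_raw)):
        clean[name], reports[name] = filter_tags(raw, [config.adaptor_seq])
        mapping[name] = map_library(clean[name], index, genome_index)
        expression[name] = quantify(mapping[name], clean[name], gene_ids)

    n1 = clean["Ste"].total_copies
    n2 = clean["Fer"].total_copies
    degs = classify_degs(expression["Ste"], expression["Fer"], n1, n2, thresholds)

    result = PipelineResult(
        config=config,
        reference=reference,
        libraries=libraries,
        filter_reports=reports,
        clean=clean,
        mapping=mapping,
        expression=expression,
        degs=degs,
    )
    result.recovery = recovery_metrics(result)
    return result


_DETECTED = {
    "up": {"up_in_fer", "fer_specific"},
    "down": {"down_in_fer", "ste_specific"},
    "fer_specific": {"fer_specific"},
    "ste_specific": {"ste_specific"},
}


def recovery_metrics(result: PipelineResult) -> dict[str, float]:
    """Sensitivity / empirical FDR of DEG calling against the planted truth."""
    truth = result.reference.truth
    by_gene = {r.gene_id: r for r in result.degs}

    planted_de = [g for g, t in truth.items()
                  if t.true_class in ("up", "down") and t.in_reference]
    detected_de = sum(
        1 for g in planted_de
        if by_gene[g].deg_class in _DETECTED[truth[g].true_class]
    )

    significant = [r for r in result.degs if r.deg_class != "unchanged"]
    false_pos = sum(1 for r in significant if truth[r.gene_id].true_class == "null")

    fer_spec = [g for g, t in truth.items()
                if t.true_class == "fer_specific" and t.in_reference]
    fer_spec_ok = sum(1 for g in fer_spec if by_gene[g].deg_class == "fer_specific")

    return {
        "n_planted_de": len(planted_de),
        "sensitivity": detected_de / len(planted_de) if planted_de else float("nan"),
        "n_significant": len(significant),
        "empirical_fdr": false_pos / len(significant) if significant else 0.0,
        "n_fer_specific_planted": len(fer_spec),
        "n_fer_specific_recovered": fer_spec_ok,
    }


def fer_only_unknown_tags(result: PipelineResult) -> list[str]:
    """Distinct clean tags that map nowhere and occur only in the Fer
    library — the signature of transcripts from an off-reference (alien)
    chromosome."""
    unknown_fer = {r.tag for r in result.mapping["Fer"] if r.category == "unknown"}
    return sorted(unknown_fer - set(result.clean["Ste"].counts))
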