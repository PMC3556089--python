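"""Synthetic transcriptome, genome and tag libraries with planted truth.

The generator emulates the statistical structure of a two-library DGE
tag-sequencing experiment comparing sterile ("Ste") and fertile ("Fer")
floral buds:

* a toy transcriptome in which every gene carries at least one CATG site
  with 17 nt downstream, plus a genome assembling the genes with random
  intergenic spacers (whose chance CATG sites act as decoys for the
  genome-mapping stage);
* per-gene baseline abundances drawn log-normally (heavy tail: most
  distinct tags at low copy number, a few very abundant);
* planted truth — up-/down-regulated genes at a fixed |log2| effect,
  Fer-only and Ste-only genes, and "alien" genes kept out of the reference
  entirely (their tags surface only in Fer and map nowhere, emulating
  transcripts from an introgressed alien chromosome);
* protocol noise — tags sampled with a 3'-most-site bias (NlaIII/MmeI
  digestion releases mainly the 3'-most CATG tag), per-copy base-call
  errors confined to the 17-nt variable region, N-containing reads, and
  adaptor reads.

All randomness flows from ``config.seed`` through spawned generators, so
every artifact is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import TagCountTable, TranscriptRecord
from .reference_index import ANCHOR, TAG_LENGTH, _scan_sense

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    length_range: tuple[int, int] = (300, 1500)
    n_de_genes: int = 100
    de_log2: float = 2.0
    n_fer_specific_genes: int = 30
    n_ste_specific_genes: int = 10
    n_alien_genes: int = 10
    library_depths: tuple[int, int] = (500_000, 500_000)
    base_error_rate: float = 0.001
    frac_N_reads: float = 0.004
    adaptor_read_rate: float = 0.04
    three_prime_bias: float = 0.85
    lognormal_sigma: float = 1.2
    min_expected_count: float = 50.0
    genes_per_contig: int = 50
    spacer_length_range: tuple[int, int] = (300, 800)
    adaptor_seq: str = "TCGTATGCCGTCTTCTGCTTG"
    seed: int = 42

    def __post_init__(self) -> None:
        for p in (self.base_error_rate, self.frac_N_reads,
                  self.adaptor_read_rate, self.three_prime_bias):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.library_depths) <= 0:
            raise ValueError("library depths must be positive")
        if self.length_range[0] < TAG_LENGTH + len(ANCHOR):
            raise ValueError(
                f"minimum transcript length {self.length_range[0]} cannot "
                f"guarantee a CATG site with 17 nt downstream"
            )
        if len(self.adaptor_seq) != TAG_LENGTH:
            raise ValueError("adaptor_seq must be tag-length (21 nt)")
        planted = (self.n_de_genes + self.n_fer_specific_genes
                   + self.n_ste_specific_genes)
        if planted > self.n_genes:
            raise ValueError("more planted genes than genes")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass
class TruthRow:
    gene_id: str
    true_class: str  # up | down | fer_specific | ste_specific | null
    true_log2: float  # log2(Fer/Ste); +/-inf for specific genes
    expected_tag_sites: int
    in_reference: bool

    def to_row(self):
        return (self.gene_id, self.true_class, self.true_log2,
                self.expected_tag_sites, self.in_reference)

    @classmethod
    def from_row(cls, cells):
        return cls(cells[0], cells[1], float(cells[2]), int(cells[3]),
                   cells[4] == "True")


@dataclass
class SimulatedReference:
    transcripts: list[TranscriptRecord]  # the reference the index is built from
    alien_transcripts: list[TranscriptRecord]  # off-reference (alien chromosome)
    genome: list[TranscriptRecord]  # contigs: genes + intergenic decoy spacers
    truth: dict[str, TruthRow]
    baseline_weights: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedLibraries:
    ste_raw: TagCountTable
    fer_raw: TagCountTable
    noise: dict[str, dict[str, int]]  # per-library injected N/adaptor copies


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _ensure_catg_site(seq: str, rng: np.random.Generator) -> str:
    """Guarantee at least one CATG with >= 17 nt downstream."""
    if any(True for _ in _scan_sense(seq)):
        return seq
    pos = int(rng.integers(0, len(seq) - TAG_LENGTH + 1))
    return seq[:pos] + ANCHOR + seq[pos + len(ANCHOR):]


def _make_transcripts(rng, prefix: str, n: int, length_range) -> list[TranscriptRecord]:
    out = []
    lo, hi = length_range
    width = len(str(max(n, 1)))
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = _ensure_catg_site(_random_sequence(rng, length), rng)
        out.append(TranscriptRecord(f"{prefix}{i + 1:0{width}d}", seq))
    return out


def generate_transcriptome(config: SimulationConfig) -> SimulatedReference:
    """Build reference and alien transcripts, a decoy-bearing genome, and
    the planted-truth table.

    Planted DE and library-specific genes are drawn only from genes whose
    baseline expected count reaches ``min_expected_count`` at the shallower
    library depth: a fold change planted on an effectively silent gene is
    not a recoverable signal and would only blur recovery statistics.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_seq, rng_truth = (np.random.default_rng(s) for s in ss.spawn(2))

    transcripts = _make_transcripts(rng_seq, "gene", config.n_genes, config.length_range)
    aliens = _make_transcripts(rng_seq, "alien", config.n_alien_genes, config.length_range)

    # genome: contigs of genes joined by random intergenic spacers (decoys)
    genome: list[TranscriptRecord] = []
    lo_sp, hi_sp = config.spacer_length_range
    for c, start in enumerate(range(0, len(transcripts), config.genes_per_contig)):
        parts = []
        for rec in transcripts[start:start + config.genes_per_contig]:
            parts.append(_random_sequence(rng_seq, int(rng_seq.integers(lo_sp, hi_sp + 1))))
            parts.append(rec.sequence)
        parts.append(_random_sequence(rng_seq, int(rng_seq.integers(lo_sp, hi_sp + 1))))
        genome.append(TranscriptRecord(f"contig{c + 1:03d}", "".join(parts)))

    # baseline abundances and planted truth
    all_records = transcripts + aliens
    weights = rng_truth.lognormal(mean=0.0, sigma=config.lognormal_sigma,
                                  size=len(all_records))
    props = weights / weights.sum()
    min_depth = min(config.library_depths)
    eligible = [
        i for i in range(config.n_genes)
        if props[i] * min_depth >= config.min_expected_count
    ]
    n_planted = (config.n_de_genes + config.n_fer_specific_genes
                 + config.n_ste_specific_genes)
    if len(eligible) < n_planted:
        raise ValueError(
            f"only {len(eligible)} genes reach the expected-count floor; "
            f"{n_planted} planted genes requested"
        )
    chosen = rng_truth.choice(eligible, size=n_planted, replace=False)
    n_up = config.n_de_genes // 2
    classes: dict[int, tuple[str, float]] = {}
    for k, idx in enumerate(chosen):
        if k < n_up:
            classes[idx] = ("up", config.de_log2)
        elif k < config.n_de_genes:
            classes[idx] = ("down", -config.de_log2)
        elif k < config.n_de_genes + config.n_fer_specific_genes:
            classes[idx] = ("fer_specific", float("inf"))
        else:
            classes[idx] = ("ste_specific", float("-inf"))

    truth: dict[str, TruthRow] = {}
    baseline: dict[str, float] = {}
    for i, rec in enumerate(all_records):
        is_alien = i >= config.n_genes
        cls, lg2 = ("fer_specific", float("inf")) if is_alien else classes.get(i, ("null", 0.0))
        n_sites = sum(1 for _ in _scan_sense(rec.sequence))
        truth[rec.gene_id] = TruthRow(rec.gene_id, cls, lg2, n_sites, not is_alien)
        baseline[rec.gene_id] = float(weights[i])

    return SimulatedReference(transcripts, aliens, genome, truth, baseline)


def _site_weights(n_sites: int, bias: float) -> np.ndarray:
    """3'-most site takes `bias` extra mass; the rest is uniform."""
    w = np.full(n_sites, (1.0 - bias) / n_sites)
    w[-1] += bias
    return w


def _expression_multiplier(row: TruthRow, library: str) -> float:
    half = 2.0 ** (abs(row.true_log2) / 2.0) if np.isfinite(row.true_log2) else 0.0
    if row.true_class == "null":
        return 1.0
    if row.true_class == "up":
        return half if library == "Fer" else 1.0 / half
    if row.true_class == "down":
        return 1.0 / half if library == "Fer" else half
    if row.true_class == "fer_specific":
        return 1.0 if library == "Fer" else 0.0
    if row.true_class == "ste_specific":
        return 0.0 if library == "Fer" else 1.0
    raise ValueError(row.true_class)


def simulate_libraries(
    reference: SimulatedReference, config: SimulationConfig
) -> SimulatedLibraries:
    """Sample two raw tag libraries from the planted expression state."""
    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_ste = np.random.default_rng(ss[1])
    rng_fer = np.random.default_rng(ss[2])

    records = reference.transcripts + reference.alien_transcripts
    site_tags: list[str] = []
    site_gene_idx: list[int] = []
    site_base_w: list[float] = []
    for gi, rec in enumerate(records):
        sites = [tag for _, tag in _scan_sense(rec.sequence)]
        # sites are scanned 5'->3'; the last one is the 3'-most
        w = _site_weights(len(sites), config.three_prime_bias)
        base = reference.baseline_weights[rec.gene_id]
        for tag, sw in zip(sites, w):
            site_tags.append(tag)
            site_gene_idx.append(gi)
            site_base_w.append(base * sw)
    site_base_w = np.asarray(site_base_w)
    site_gene_idx = np.asarray(site_gene_idx)

    out = {}
    noise = {}
    p_err_tag = 1.0 - (1.0 - config.base_error_rate) ** (TAG_LENGTH - len(ANCHOR))
    for library, depth, rng in (
        ("Ste", config.library_depths[0], rng_ste),
        ("Fer", config.library_depths[1], rng_fer),
    ):
        mult = np.array([
            _expression_multiplier(reference.truth[rec.gene_id], library)
            for rec in records
        ])
        probs = site_base_w * mult[site_gene_idx]
        total = probs.sum()
        if total <= 0:
            raise ValueError("no expressed gene in library " + library)
        counts = rng.multinomial(depth, probs / total)

        counter: Counter[str] = Counter()
        n_err = rng.binomial(counts, p_err_tag)
        kept = counts - n_err
        for tag, c in zip(site_tags, kept):
            if c > 0:
                counter[tag] += int(c)
        # single uniform substitution in the 17-nt region per corrupted copy
        err_sites = np.repeat(np.arange(len(site_tags)), n_err)
        if err_sites.size:
            pos = rng.integers(len(ANCHOR), TAG_LENGTH, size=err_sites.size)
            shift = rng.integers(1, 4, size=err_sites.size)
            for si, p, sh in zip(err_sites, pos, shift):
                tag = site_tags[si]
                orig = "ACGT".index(tag[p])
                sub = "ACGT"[(orig + sh) % 4]
                counter[tag[:p] + sub + tag[p + 1:]] += 1

        # injected low-quality (N-containing) reads
        n_N = int(rng.binomial(depth, config.frac_N_reads))
        if n_N:
            src = rng.choice(len(site_tags), size=n_N, p=probs / total)
            pos = rng.integers(0, TAG_LENGTH, size=n_N)
            for si, p in zip(src, pos):
                tag = site_tags[si]
                counter[tag[:p] + "N" + tag[p + 1:]] += 1

        # injected adaptor reads
        n_ad = int(rng.binomial(depth, config.adaptor_read_rate))
        if n_ad:
            counter[config.adaptor_seq] += n_ad

        out[library] = TagCountTable(library, dict(counter))
        noise[library] = {"n_containing_N": n_N, "n_adaptor": n_ad}

    return SimulatedLibraries(out["Ste"], out["Fer"], noise)
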