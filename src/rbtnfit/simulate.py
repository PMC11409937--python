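"""Synthetic community generator for the RB-TnSeq fitness pipeline.

Emulates, at desk scale, the data a barcoded-transposon community fitness
experiment produces: a bacterium-like genome (~85% coding), a Tn5 insertion
library with 20-bp random barcodes, condition-dependent selection over a
3-day growth experiment (alone, with phage, with fungi, with both),
multinomial sequencing of the barcodes, and dilution-plating counts whose
default scenario reproduces the qualitative extinction of the host when
phage and fungi act together.

The generative fitness model is the exact inverse of the estimator: a
strain's relative abundance at day 3 is proportional to its initial
abundance times 2**f, where f is the planted per-gene, per-condition
fitness (log2 units over the 3-day experiment); intergenic strains inherit
f = 0. Strain-level drift within a gene is not simulated — all strains of
a gene share its fitness, matching the per-gene inference target.

Planted effect classes (defaults; the majority of genes is neutral with
fitness exactly 0, the assumption behind mode normalization):

- ``antagonistic-pleiotropic`` ("LPS-like", e.g. O-antigen synthesis):
  +2 in every phage-containing condition, -1.5 with fungi only;
- ``phage-benefit``: +2 in phage-containing conditions;
- ``fungus-cost``: -1.5 in fungi-containing conditions;
- ``generally-deleterious``: -2 everywhere;
- ``neutral``: 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .layout import (
    BARSEQ_LEFT,
    BARSEQ_RIGHT,
    JUNCTION_TAG,
    BarseqReadLayout,
    revcomp,
)
from .mapping import assign_genes

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BYTE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_IDX[_b] = _i

DEFAULT_CONDITIONS = ("alone", "phage", "fungi", "phage_fungi")
DEFAULT_COMPOSITION = {
    "alone": frozenset(),
    "phage": frozenset({"phage"}),
    "fungi": frozenset({"fungi"}),
    "phage_fungi": frozenset({"phage", "fungi"}),
}


class SimConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic community.

    Defaults are desk scale: a 200-kb genome with 150 genes, 10,000
    insertions, and 5e5 reads per sample; four growth conditions over three
    days with three biological replicates and one pooled T0 reference.
    """

    genome_length: int = 200_000
    n_genes: int = 150
    coding_fraction: float = 0.85
    n_insertions: int = 10_000
    barcode_length: int = 20
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    days: int = 3
    read_depth_per_sample: int = 500_000
    seed: int = 0
    composition: dict[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    # library construction / read layout
    mapping_reads_per_insertion: int = 3
    flank_length: int = 30
    chimera_fraction: float = 0.0
    junction_free_fraction: float = 0.0
    barseq_error_rate: float = 0.0
    abundance_sigma: float = 0.5
    min_gene_length: int = 90

    def validate(self) -> "SimConfig":
        if not 0 < self.coding_fraction <= 1:
            raise SimConfigError("coding_fraction must be in (0, 1]")
        if self.barcode_length < 8:
            raise SimConfigError("barcode_length must be >= 8")
        for name in (
            "genome_length", "n_genes", "n_insertions", "n_replicates",
            "days", "read_depth_per_sample", "mapping_reads_per_insertion",
        ):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        target = round(self.coding_fraction * self.genome_length)
        if self.n_genes * self.min_gene_length > target:
            raise SimConfigError(
                f"{self.n_genes} genes of >= {self.min_gene_length} bp cannot "
                f"fit in {target} coding bp"
            )
        unknown = set(self.conditions) - set(self.composition)
        if unknown:
            raise SimConfigError(f"conditions without composition: {sorted(unknown)}")
        return self


@dataclass
class EffectSpec:
    """Planted fitness-effect structure (log2 units per 3-day experiment)."""

    n_antagonistic: int = 8
    n_phage_benefit: int = 5
    n_fungus_cost: int = 5
    n_deleterious: int = 7
    antagonistic_phage: float = 2.0
    antagonistic_fungi: float = -1.5
    phage_benefit: float = 2.0
    fungus_cost: float = -1.5
    deleterious: float = -2.0

    @property
    def n_nonneutral(self) -> int:
        return (
            self.n_antagonistic + self.n_phage_benefit
            + self.n_fungus_cost + self.n_deleterious
        )


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return _BASE_BYTES[rng.integers(0, 4, n)].tobytes().decode()


def _partition_lengths(
    total: int, n: int, minimum: int, rng: np.random.Generator
) -> np.ndarray:
    """n integer lengths >= minimum summing exactly to total, with spread."""
    w = rng.dirichlet(np.full(n, 30.0))
    lengths = np.maximum(minimum, np.round(w * total).astype(int))
    diff = total - int(lengths.sum())
    step = 1 if diff > 0 else -1
    i = 0
    while diff != 0:
        j = i % n
        if step > 0 or lengths[j] > minimum:
            lengths[j] += step
            diff -= step
        i += 1
    return lengths


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[str, pd.DataFrame]:
    """Random genome plus non-overlapping genes on both strands.

    The total gene span equals ``round(coding_fraction * genome_length)``
    exactly; intergenic space is spread randomly between genes.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    target = round(config.coding_fraction * config.genome_length)
    lengths = _partition_lengths(target, config.n_genes, config.min_gene_length, rng)
    gaps = rng.multinomial(
        config.genome_length - target,
        np.full(config.n_genes + 1, 1.0 / (config.n_genes + 1)),
    )
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    genes = pd.DataFrame(
        {
            "locus_tag": [f"HAF_{i + 1:04d}" for i in range(config.n_genes)],
            "seqid": "chr1",
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
        }
    )
    genome = _random_dna(config.genome_length, rng)
    return genome, genes


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200:
            raise SimConfigError(
                "barcode collision rate too high; increase barcode_length"
            )
        draw = rng.integers(0, 4, (n - len(out), length))
        for row in draw:
            bc = _BASE_BYTES[row].tobytes().decode()
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_library(
    genome: str,
    genes: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """True insertion pool: uniform positions, unique barcodes, chimeras.

    A ``chimera_fraction`` of barcodes is additionally emitted at a second
    genomic location (flagged ``chimeric``) so the pool-design filter has
    something to reject.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_insertions
    positions = rng.integers(0, len(genome), n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    barcodes = _random_barcodes(n, config.barcode_length, rng)
    pool = pd.DataFrame(
        {
            "barcode": barcodes,
            "position": positions,
            "strand": strands,
            "chimeric": False,
        }
    )
    n_chimeric = int(round(config.chimera_fraction * n))
    if n_chimeric:
        picks = rng.choice(n, size=n_chimeric, replace=False)
        second = pd.DataFrame(
            {
                "barcode": [barcodes[i] for i in picks],
                "position": rng.integers(0, len(genome), n_chimeric),
                "strand": np.where(rng.random(n_chimeric) < 0.5, "+", "-"),
                "chimeric": True,
            }
        )
        pool = pd.concat([pool, second], ignore_index=True)
    ann = assign_genes(pool["position"].to_numpy(), genes, len(genome))
    return pd.concat([pool, ann], axis=1)


def mapping_reads(
    pool: pd.DataFrame,
    genome: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Yield (name, sequence) transposon-junction reads for the pool.

    Each pool row gets ``mapping_reads_per_insertion`` reads of the form
    junction tag + barcode + genomic flank (circular extraction). A
    ``junction_free_fraction`` of reads carries a scrambled tag instead,
    for negative testing of junction detection.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = len(genome)
    doubled = genome + genome
    flank_len = config.flank_length
    for row in pool.itertuples(index=False):
        pos = int(row.position)
        if row.strand == "+":
            flank = doubled[pos : pos + flank_len]
        else:
            start = (pos - flank_len) % L
            flank = revcomp(doubled[start : start + flank_len])
        for i in range(config.mapping_reads_per_insertion):
            tag = JUNCTION_TAG
            if (
                config.junction_free_fraction > 0
                and rng.random() < config.junction_free_fraction
            ):
                tag = _random_dna(len(JUNCTION_TAG), rng)
                if tag == JUNCTION_TAG:  # vanishing chance; force a difference
                    tag = "A" + tag[1:] if tag[0] != "A" else "C" + tag[1:]
            yield f"{row.barcode}_{i}", tag + row.barcode + flank


def make_true_effects(
    genes: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    spec: EffectSpec | None = None,
) -> pd.DataFrame:
    """Planted per-gene, per-condition fitness with class labels (long form)."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spec = spec or EffectSpec()
    if spec.n_nonneutral > len(genes):
        raise SimConfigError("more non-neutral genes requested than genes exist")
    tags = genes["locus_tag"].to_numpy()
    picks = rng.choice(len(tags), size=spec.n_nonneutral, replace=False)
    classes = pd.Series("neutral", index=tags, name="gene_class")
    cursor = 0
    for label, count in [
        ("antagonistic-pleiotropic", spec.n_antagonistic),
        ("phage-benefit", spec.n_phage_benefit),
        ("fungus-cost", spec.n_fungus_cost),
        ("generally-deleterious", spec.n_deleterious),
    ]:
        classes.iloc[picks[cursor : cursor + count]] = label
        cursor += count

    rows = []
    for tag in tags:
        cls = classes[tag]
        for cond in config.conditions:
            comp = config.composition[cond]
            phage = "phage" in comp
            fungi = "fungi" in comp
            if cls == "antagonistic-pleiotropic":
                f = (
                    spec.antagonistic_phage
                    if phage
                    else (spec.antagonistic_fungi if fungi else 0.0)
                )
            elif cls == "phage-benefit":
                f = spec.phage_benefit if phage else 0.0
            elif cls == "fungus-cost":
                f = spec.fungus_cost if fungi else 0.0
            elif cls == "generally-deleterious":
                f = spec.deleterious
            else:
                f = 0.0
            rows.append(
                {"locus_tag": tag, "gene_class": cls, "condition": cond, "fitness": f}
            )
    return pd.DataFrame(rows)


def simulate_selection(
    pool: pd.DataFrame,
    effects: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcode x sample count matrix under the planted selection.

    Initial strain abundances are lognormal; the T0 sample is a multinomial
    draw from the unselected library, and each condition x replicate day-3
    sample is a multinomial draw from abundances reweighted by
    ``2**f_gene,condition``. Returns (counts, sample sheet).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    strains = pool.drop_duplicates("barcode").reset_index(drop=True)
    a0 = rng.lognormal(0.0, config.abundance_sigma, len(strains))
    p0 = a0 / a0.sum()

    fmat = effects.pivot(index="locus_tag", columns="condition", values="fitness")
    depth = config.read_depth_per_sample
    counts = {"T0": rng.multinomial(depth, p0)}
    sheet_rows = [
        {"sample": "T0", "condition": "T0", "replicate": 0, "timepoint": "T0"}
    ]
    for cond in config.conditions:
        f = (
            strains["locus_tag"]
            .map(fmat[cond])
            .fillna(0.0)  # intergenic strains inherit neutral fitness
            .to_numpy()
        )
        weight = p0 * np.exp2(f)
        total = weight.sum()
        if not np.isfinite(total) or total <= 0:
            raise SimConfigError("planted effects drive the whole library extinct")
        p3 = weight / total
        for rep in range(1, config.n_replicates + 1):
            name = f"{cond}_r{rep}"
            counts[name] = rng.multinomial(depth, p3)
            sheet_rows.append(
                {
                    "sample": name,
                    "condition": cond,
                    "replicate": rep,
                    "timepoint": "T3",
                }
            )
    matrix = pd.DataFrame(
        counts, index=pd.Index(strains["barcode"], name="barcode"), dtype=int
    )
    sheet = pd.DataFrame(sheet_rows)
    sheet["has_phage"] = [
        "phage" in config.composition.get(c, frozenset()) for c in sheet["condition"]
    ]
    sheet["has_fungi"] = [
        "fungi" in config.composition.get(c, frozenset()) for c in sheet["condition"]
    ]
    return matrix, sheet


def barseq_reads(
    count_vector: pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    layout: BarseqReadLayout | None = None,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """BarSeq amplicon reads realizing one sample's count vector.

    Each read is left flank + barcode + right flank with per-base
    substitution errors at ``config.barseq_error_rate``; at rate 0 the read
    multiset reproduces the counts exactly. Returns the (shuffled) reads
    and stats including the committed number of barcode-corrupted reads.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    layout = layout or BarseqReadLayout()
    barcodes = count_vector.index.to_numpy()
    counts = count_vector.to_numpy(dtype=int)
    if (counts < 0).any():
        raise ValueError("negative barcode counts")
    templates = np.frombuffer(
        "".join(layout.left + bc + layout.right for bc in barcodes).encode(),
        dtype=np.uint8,
    ).reshape(len(barcodes), layout.read_length)
    order = np.repeat(np.arange(len(barcodes)), counts)
    rng.shuffle(order)
    reads = templates[order].copy()

    bc_lo = len(layout.left)
    bc_hi = bc_lo + layout.barcode_length
    n_corrupted = 0
    if config.barseq_error_rate > 0 and reads.size:
        mask = rng.random(reads.shape) < config.barseq_error_rate
        if mask.any():
            idx = _BYTE_TO_IDX[reads[mask]]
            shift = rng.integers(1, 4, idx.shape)
            reads[mask] = _BASE_BYTES[(idx + shift) % 4]
            n_corrupted = int(mask[:, bc_lo:bc_hi].any(axis=1).sum())
    out = [
        (f"r{i}", reads[i].tobytes().decode()) for i in range(reads.shape[0])
    ]
    stats = {"n_reads": len(out), "n_barcode_corrupted": n_corrupted}
    return out, stats


def write_barseq_fastq(
    counts: pd.DataFrame,
    out_dir,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write one FASTQ per sample; return per-sample read/corruption stats."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in counts.columns:
        path = out_dir / f"{sample}.fastq"
        reads, stats = barseq_reads(counts[sample], config, rng)
        rio.write_fastq(path, reads)
        rows.append({"sample": sample, "fastq": str(path), **stats})
    return pd.DataFrame(rows)


def default_growth_scenario() -> pd.DataFrame:
    """True titers (per ml) per condition and day for the plating assay.

    Encodes the qualitative pattern of the community density experiment:
    the host grows steadily alone or with fungi, dips and partially
    recovers under phage alone, and is extinct by day 3 when phage and
    fungi act together; phage persists except with both fungi present.
    """
    rows = [
        ("alone", "cfu", [5e8, 1.5e9, 2e9]),
        ("fungi", "cfu", [4e8, 1.0e9, 1.8e9]),
        ("phage", "cfu", [1e6, 1e8, 2e5]),
        ("phage_fungi", "cfu", [1e6, 1e7, 0.0]),
        ("phage", "pfu", [1e8, 1e9, 1e9]),
        ("phage_fungi", "pfu", [1e8, 1e8, 1e6]),
    ]
    out = []
    for label, unit, titers in rows:
        for day, titer in enumerate(titers, start=1):
            out.append({"label": label, "day": day, "unit": unit, "titer": titer})
    return pd.DataFrame(out)


def simulate_growth_assay(
    scenario: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    volume_ml: float = 0.1,
    target_count: float = 100.0,
) -> pd.DataFrame:
    """Dilution-plating counts around the true titers.

    The dilution is chosen per observation to put the Poisson mean near
    ``target_count`` (clipped to <= 1); counts are then Poisson with mean
    ``titer * volume * dilution``. A true titer of 0 yields all-zero counts.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if (scenario["titer"] < 0).any():
        raise ValueError("negative true titers")
    rows = []
    for sc in scenario.itertuples(index=False):
        if sc.titer > 0:
            exponent = max(0, round(np.log10(sc.titer * volume_ml / target_count)))
            dilution = 10.0 ** (-exponent)
        else:
            dilution = 1.0
        lam = sc.titer * volume_ml * dilution
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                rows.append(
                    {
                        "label": sc.label,
                        "day": sc.day,
                        "unit": sc.unit,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "dilution": dilution,
                        "volume_ml": volume_ml,
                        "count": int(rng.poisson(lam)),
                    }
                )
    return pd.DataFrame(rows)


DEFAULT_CATEGORIES = (
    "Glycan biosynthesis and metabolism",
    "Lipopolysaccharide biosynthesis proteins",
    "Protein families: metabolism",
    "Carbohydrate metabolism",
    "Amino acid metabolism",
    "Membrane transport",
    "Genetic information processing",
)


def make_annotations(
    effects: pd.DataFrame,
    rng: np.random.Generator | None = None,
    unannotated_fraction: float = 0.1,
) -> pd.DataFrame:
    """Gene -> category table standing in for an external BRITE-style export.

    Antagonistic ("LPS-like") genes receive glycan/LPS categories; other
    genes draw 1-2 categories at random, with a fraction left unannotated.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    by_gene = effects.drop_duplicates("locus_tag").set_index("locus_tag")["gene_class"]
    rows = []
    for tag, cls in by_gene.items():
        if cls == "antagonistic-pleiotropic":
            rows.append({"locus_tag": tag, "category": DEFAULT_CATEGORIES[0]})
            rows.append({"locus_tag": tag, "category": DEFAULT_CATEGORIES[1]})
            rows.append({"locus_tag": tag, "category": DEFAULT_CATEGORIES[2]})
            continue
        if rng.random() < unannotated_fraction:
            continue
        k = 1 + int(rng.random() < 0.4)
        for cat in rng.choice(DEFAULT_CATEGORIES[2:], size=k, replace=False):
            rows.append({"locus_tag": tag, "category": str(cat)})
    return pd.DataFrame(rows, columns=["locus_tag", "category"])


@dataclass
class SimOutput:
    """Everything one simulated experiment produced."""

    config: SimConfig
    genome: str
    genes: pd.DataFrame
    pool: pd.DataFrame
    effects: pd.DataFrame
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    plate_counts: pd.DataFrame
    annotations: pd.DataFrame

    def write(self, out_dir, with_reads: bool = True) -> dict[str, str]:
        """Serialize to plain-text files; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": str(out / "genome.fasta"),
            "gff": str(out / "genes.gff"),
            "pool": str(out / "pool_truth.tsv"),
            "effects": str(out / "true_effects.tsv"),
            "counts": str(out / "counts_truth.tsv"),
            "sample_sheet": str(out / "sample_sheet.tsv"),
            "plate_counts": str(out / "plate_counts.tsv"),
            "annotations": str(out / "annotations.tsv"),
        }
        rio.write_fasta(paths["genome"], {"chr1": self.genome})
        rio.write_gff(paths["gff"], self.genes)
        rio.write_tsv(self.pool, paths["pool"])
        rio.write_tsv(self.effects, paths["effects"])
        rio.write_tsv(self.counts.reset_index(), paths["counts"])
        sheet = self.sample_sheet
        rio.write_tsv(self.plate_counts, paths["plate_counts"])
        rio.write_tsv(self.annotations, paths["annotations"])
        if with_reads:
            seeds = np.random.SeedSequence(self.config.seed).spawn(6)
            paths["mapping_reads"] = str(out / "mapping_reads.fastq")
            rio.write_fastq(
                paths["mapping_reads"],
                mapping_reads(
                    self.pool, self.genome, self.config,
                    np.random.default_rng(seeds[4]),
                ),
            )
            stats = write_barseq_fastq(
                self.counts, out / "barseq", self.config,
                np.random.default_rng(seeds[5]),
            )
            sheet = sheet.merge(stats[["sample", "fastq"]], on="sample")
        rio.write_tsv(sheet, paths["sample_sheet"])
        return paths


def simulate_community(
    config: SimConfig | None = None,
    effect_spec: EffectSpec | None = None,
    scenario: pd.DataFrame | None = None,
) -> SimOutput:
    """Run the whole generator deterministically from ``config.seed``.

    Stage RNGs are spawned from one seed sequence, so identical configs
    give identical outputs. Read FASTQs are produced lazily by
    :meth:`SimOutput.write` (same spawned seeds, hence also deterministic).
    """
    config = (config or SimConfig()).validate()
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    genome, genes = simulate_genome(config, np.random.default_rng(seeds[0]))
    pool = simulate_library(genome, genes, config, np.random.default_rng(seeds[1]))
    effects = make_true_effects(
        genes, config, np.random.default_rng(seeds[2]), effect_spec
    )
    counts, sheet = simulate_selection(
        pool, effects, config, np.random.default_rng(seeds[3])
    )
    growth_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 17)).generate_state(1)
    )
    plate = simulate_growth_assay(
        scenario if scenario is not None else default_growth_scenario(),
        config, growth_rng,
    )
    ann_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 23)).generate_state(1))
    annotations = make_annotations(effects, ann_rng)
    return SimOutput(
        config=config,
        genome=genome,
        genes=genes,
        pool=pool,
        effects=effects,
        counts=counts,
        sample_sheet=sheet,
        plate_counts=plate,
        annotations=annotations,
    )
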