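"""Synthetic strain panels and metagenome reads with planted ground truth.

The generator emulates the statistical structure the profiler relies on:

* each species carries an ancestral set of toxin/antitoxin gene groups;
  different species' homologs are diverged far enough (default 0.25
  substitutions/site per species branch) that they fall into distinct
  groups at the default 88% grouping identity, reproducing the
  species-specific presence/absence pattern;
* strains of one species subsample the species gene set (presence
  probability 0.8 by default) and accumulate point variants (0.02
  substitutions/site) plus rare short indels (0.002/site), so gene
  repertoires and variants are strain specific but cluster within the
  species group;
* reads are drawn uniformly along each planted strain's genes at a chosen
  mean depth, on a uniformly random strand, with i.i.d. base errors —
  fragmented coverage with dropouts arises naturally at low depth.

Everything is deterministic given the seed: re-running a generator with
the same spec yields byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import ValidationError
from .markerdb import GENE_NAMES, TAGene

__all__ = [
    "StrainPanelSpec",
    "CommunitySpec",
    "TruthSet",
    "StrainPanel",
    "SimRead",
    "mutate_sequence",
    "simulate_strain_panel",
    "simulate_reads",
    "evaluate_recovery",
    "write_panel",
    "write_fastq",
    "write_truth",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
#: constant Phred+33 quality token for Q30
Q30 = "?"


@dataclass(frozen=True)
class StrainPanelSpec:
    n_species: int = 2
    strains_per_species: int = 5
    groups_per_species: tuple[int, int] = (4, 6)
    p_gene_presence: float = 0.8
    inter_species_divergence: float = 0.25
    intra_species_variant_rate: float = 0.02
    indel_rate: float = 0.002
    gene_length: tuple[int, int] = (200, 400)
    shared_groups: tuple[tuple[int, int, int], ...] = ()  # (species_a, species_b, n shared)
    genera: tuple[str, ...] = ("genus_A", "genus_B")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.strains_per_species < 1:
            raise ValidationError("panel needs at least one species and one strain")
        for name in ("p_gene_presence",):
            if not 0 < getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")
        for name in ("inter_species_divergence", "intra_species_variant_rate", "indel_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValidationError(f"{name} must be in [0, 1)")
        if self.gene_length[0] < 60:
            raise ValidationError("gene_length must be >= 60")
        if self.groups_per_species[0] < 1:
            raise ValidationError("groups_per_species must be >= 1")


@dataclass(frozen=True)
class CommunitySpec:
    planted: tuple[tuple[str, float], ...]  # (strain_id, relative abundance)
    read_length: int = 250
    mean_depth: float = 20.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1 or self.mean_depth <= 0:
            raise ValidationError("read_length and mean_depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValidationError("error_rate must be in [0, 1)")
        for _, ab in self.planted:
            if ab < 0:
                raise ValidationError("abundances must be >= 0")


@dataclass
class TruthSet:
    """Planted ground truth: strain taxonomy, gene repertoires and, after
    read simulation, per-read source annotations."""

    strains: dict[str, dict] = field(default_factory=dict)
    # strain -> {"species":..., "genus":..., "genes": {gene_id: sequence}}
    reads: dict[str, dict] = field(default_factory=dict)
    # read_id -> {"strain":..., "gene":..., "start":..., "strand":...}

    def planted_strains(self) -> list[str]:
        return sorted({info["strain"] for info in self.reads.values()})

    def repertoire_signature(self, strain: str) -> tuple[str, ...]:
        return tuple(sorted(self.strains[strain]["genes"].values()))

    def to_dict(self) -> dict:
        return {"strains": self.strains, "reads": self.reads}


@dataclass
class StrainPanel:
    spec: StrainPanelSpec
    genes: list[TAGene]
    truth: TruthSet

    def gene_sequences(self) -> dict[str, str]:
        return {g.gene_id: g.sequence for g in self.genes}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def mutate_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> str:
    """Per-site Bernoulli substitution to a uniformly chosen different
    base; indels (insertion or deletion, equal odds) of length 1–3 at the
    indel rate."""
    if not 0 <= sub_rate <= 1 or not 0 <= indel_rate < 1:
        raise ValidationError("mutation rates must be in [0, 1)")
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        base = seq[i]
        if sub_rate and rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != base]
            base = choices[rng.integers(0, 3)]
        if indel_rate and rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion of this and following bases
                i += length
                continue
            out.append(base)
            out.append(_random_seq(rng, length))
            i += 1
            continue
        out.append(base)
        i += 1
    return "".join(out)


def _slot_name(slot: int) -> str:
    family = "mazEF" if (slot // 2) % 2 == 0 else "relBE"
    role = "toxin" if slot % 2 == 0 else "antitoxin"
    return GENE_NAMES[(family, role)], family, role


def simulate_strain_panel(spec: StrainPanelSpec) -> StrainPanel:
    """Generate a strain panel with planted repertoires.

    Deterministic given ``spec.seed``; every strain keeps at least one
    gene.  Species share no groups unless ``shared_groups`` plants common
    ancestral genes for designated species pairs.
    """
    rng = np.random.default_rng(spec.seed)
    max_slots = spec.groups_per_species[1]
    # genus-level ancestral gene per slot; species diverge from it
    slot_lengths = [
        int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
        for _ in range(max_slots)
    ]
    genus_ancestors = [_random_seq(rng, L) for L in slot_lengths]
    n_slots = [
        int(rng.integers(spec.groups_per_species[0], spec.groups_per_species[1] + 1))
        for _ in range(spec.n_species)
    ]
    species_ancestors: list[list[str]] = []
    for _ in range(spec.n_species):
        species_ancestors.append(
            [
                mutate_sequence(anc, spec.inter_species_divergence, 0.0, rng)
                for anc in genus_ancestors
            ]
        )
    for a, b, n_shared in spec.shared_groups:
        for slot in range(min(n_shared, max_slots)):
            species_ancestors[b][slot] = species_ancestors[a][slot]

    genes: list[TAGene] = []
    truth = TruthSet()
    for sp in range(spec.n_species):
        species = f"species_{sp + 1:02d}"
        genus = spec.genera[sp % len(spec.genera)]
        slots = list(range(n_slots[sp]))
        for st in range(spec.strains_per_species):
            strain = f"{species}_st{st + 1}"
            present = [s for s in slots if rng.random() < spec.p_gene_presence]
            if not present:
                present = [slots[0]]
            strain_genes: dict[str, str] = {}
            for slot in present:
                name, family, role = _slot_name(slot)
                seq = mutate_sequence(
                    species_ancestors[sp][slot],
                    spec.intra_species_variant_rate,
                    spec.indel_rate,
                    rng,
                )
                gene_id = f"{strain}.g{slot:02d}.{name}"
                genes.append(
                    TAGene(
                        gene_id=gene_id,
                        strain_id=strain,
                        species=species,
                        genus=genus,
                        family=family,
                        role=role,
                        sequence=seq,
                        name=name,
                    )
                )
                strain_genes[gene_id] = seq
            truth.strains[strain] = {
                "species": species,
                "genus": genus,
                "genes": strain_genes,
            }
    return StrainPanel(spec=spec, genes=genes, truth=truth)


@dataclass
class SimRead:
    read_id: str
    sequence: str
    qualities: str
    strain: str
    gene: str
    start: int
    strand: str


def simulate_reads(panel: StrainPanel, community: CommunitySpec) -> list[SimRead]:
    """Draw reads from the planted strains' genes.

    Read count per gene is Poisson with mean depth × gene length / read
    length; strands are uniform; base errors i.i.d.  Fragment starts are
    uniform and may overhang the gene boundaries (the overhang is clipped,
    keeping at least half a read inside), emulating reads drawn from a
    genome in which the gene is embedded — without this, gene ends would
    be systematically undercovered.  Also records each read's source in
    ``panel.truth``.
    """
    from .align import reverse_complement

    rng = np.random.default_rng(community.seed)
    unknown = [s for s, _ in community.planted if s not in panel.truth.strains]
    if unknown:
        raise ValidationError(f"planted strains absent from panel: {unknown}")
    reads: list[SimRead] = []
    counter = 0
    for strain, abundance in community.planted:
        if abundance == 0:
            continue
        depth = community.mean_depth * abundance
        for gene_id in sorted(panel.truth.strains[strain]["genes"]):
            seq = panel.truth.strains[strain]["genes"][gene_id]
            rl = community.read_length
            if rl > len(seq):
                warnings.warn(
                    f"read length {rl} exceeds gene {gene_id} length {len(seq)}; truncating"
                )
                rl = len(seq)
            n_reads = int(rng.poisson(depth * len(seq) / rl))
            min_overlap = rl // 2
            for _ in range(n_reads):
                start = int(rng.integers(min_overlap - rl, len(seq) - min_overlap + 1))
                fragment = seq[max(0, start) : start + rl]
                start = max(0, start)
                if community.error_rate:
                    frag = list(fragment)
                    errs = np.flatnonzero(rng.random(len(frag)) < community.error_rate)
                    for p in errs:
                        choices = [b for b in "ACGT" if b != frag[p]]
                        frag[p] = choices[rng.integers(0, 3)]
                    fragment = "".join(frag)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    fragment = reverse_complement(fragment)
                read_id = f"r{counter:07d}"
                counter += 1
                reads.append(
                    SimRead(
                        read_id=read_id,
                        sequence=fragment,
                        qualities=Q30 * len(fragment),
                        strain=strain,
                        gene=gene_id,
                        start=start,
                        strand=strand,
                    )
                )
                panel.truth.reads[read_id] = {
                    "strain": strain,
                    "gene": gene_id,
                    "start": start,
                    "strand": strand,
                }
    return reads


def evaluate_recovery(report, truth: TruthSet) -> dict:
    """Score a profile report against the planted truth.

    recovered: planted strain appears in some reported set.
    false_precision: reported singleton whose strain is unplanted while an
    indistinguishable planted twin (identical gene repertoire) exists.
    """
    planted = truth.planted_strains()
    reported_sets = [set(row.strain_set) for row in report.rows]
    reported = set().union(*reported_sets) if reported_sets else set()
    recovered = [s for s in planted if s in reported]
    signatures = {s: truth.repertoire_signature(s) for s in truth.strains}
    false_precision = 0
    for row in report.rows:
        if row.n_strains_in_set != 1:
            continue
        (strain,) = row.strain_set
        if strain in planted:
            continue
        twin_exists = any(
            signatures.get(strain) == signatures[p] for p in planted
        )
        if twin_exists:
            false_precision += 1
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "recovery_rate": len(recovered) / len(planted) if planted else 0.0,
        "false_precision": false_precision,
        "set_sizes": {
            s: next(
                (row.n_strains_in_set for row in report.rows if s in row.strain_set),
                None,
            )
            for s in planted
        },
    }


# ---------------------------------------------------------------------------
# file emission (same dialects the rest of the pipeline consumes)


def write_panel(panel: StrainPanel, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genes.fasta"
    meta = outdir / "metadata.tsv"
    with open(fasta, "w") as fh:
        for g in panel.genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")
    with open(meta, "w") as fh:
        fh.write("gene_id\tstrain_id\tspecies\tgenus\tfamily\trole\tname\n")
        for g in panel.genes:
            fh.write(
                f"{g.gene_id}\t{g.strain_id}\t{g.species}\t{g.genus}\t"
                f"{g.family}\t{g.role}\t{g.name}\n"
            )
    return {"fasta": fasta, "metadata": meta}


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")


def write_truth(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
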