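"""Marker database: grouping of toxin–antitoxin genes and marker discovery.

The reference side of the pipeline.  Annotated type-II toxin–antitoxin (TA)
genes — toxins and antitoxins of the MazEF and RelBE superfamilies, each
tied to a strain — are

1. screened against plasmid sequences so that only chromosomally encoded
   genes remain (genes with a plasmid homolog can move horizontally and
   would not track strain ancestry),
2. clustered into homologous *gene groups* by single linkage over pairwise
   global-alignment identity,
3. partitioned within each group into sequence-identical *variants*, and
4. scanned for *discriminative markers*: positions, in the coordinates of
   the group representative, where at least two variants disagree
   (substitutions, deletions, or insertions keyed to the preceding
   representative position).

The resulting :class:`MarkerDatabase` also records each strain's
*repertoire* — the set of (group, variant) pairs its chromosome carries —
which is what the profiler matches read evidence against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import (
    ScoringScheme,
    ValidationError,
    check_dna,
    global_align,
    local_align,
    sequence_identity,
)

__all__ = [
    "TAGene",
    "BuildParams",
    "GeneGroup",
    "MarkerPosition",
    "MarkerDatabase",
    "cluster_genes",
    "find_discriminative_markers",
    "screen_plasmid_homologs",
    "build_database",
    "save_database",
    "load_database",
    "build_presence_matrix",
    "read_gene_table",
    "read_fasta",
    "DatabaseFormatError",
]

FORMAT_VERSION = 1
MIN_GENE_LENGTH = 60

#: canonical gene names by (family, role)
GENE_NAMES = {
    ("mazEF", "toxin"): "mazF",
    ("mazEF", "antitoxin"): "mazE",
    ("relBE", "toxin"): "relE",
    ("relBE", "antitoxin"): "relB",
}


class DatabaseFormatError(ValueError):
    """Malformed or version-incompatible database file."""


@dataclass
class TAGene:
    """One annotated TA gene sequence tied to a strain."""

    gene_id: str
    strain_id: str
    species: str
    genus: str
    family: str
    role: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        check_dna(self.sequence, f"gene {self.gene_id}")
        if len(self.sequence) < MIN_GENE_LENGTH:
            raise ValidationError(
                f"gene {self.gene_id}: sequence shorter than {MIN_GENE_LENGTH} nt"
            )
        if not self.name:
            self.name = GENE_NAMES.get((self.family, self.role), self.family)


@dataclass(frozen=True)
class BuildParams:
    grouping_identity: float = 0.88
    plasmid_identity: float = 0.80
    plasmid_min_coverage: float = 0.50
    linkage: str = "single"

    def __post_init__(self) -> None:
        for name in ("grouping_identity", "plasmid_identity", "plasmid_min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.linkage != "single":
            raise ValidationError(f"unsupported linkage: {self.linkage!r}")


@dataclass
class VariantProfile:
    """A variant's sequence expressed in representative coordinates.

    ``columns[r]`` is the variant's base at representative position *r*
    ("-" where the variant deletes that position).  ``insertions`` maps a
    representative position to the string inserted immediately after it
    (-1 keys an insertion before position 0).
    """

    columns: str
    insertions: dict[int, str] = field(default_factory=dict)

    def sequence(self) -> str:
        parts = [self.insertions.get(-1, "")]
        for r, c in enumerate(self.columns):
            if c != "-":
                parts.append(c)
            parts.append(self.insertions.get(r, ""))
        return "".join(parts)

    def column_map(self) -> tuple[list[int | None], dict[int, tuple[int, int]]]:
        """Variant-sequence coordinates of each representative column and
        of each insertion (as half-open ranges)."""
        col_map: list[int | None] = []
        ins_map: dict[int, tuple[int, int]] = {}
        cursor = len(self.insertions.get(-1, ""))
        if -1 in self.insertions:
            ins_map[-1] = (0, cursor)
        for r, c in enumerate(self.columns):
            if c == "-":
                col_map.append(None)
            else:
                col_map.append(cursor)
                cursor += 1
            ins = self.insertions.get(r, "")
            if ins:
                ins_map[r] = (cursor, cursor + len(ins))
                cursor += len(ins)
        return col_map, ins_map

    def state_at(self, position: int, insertion: bool) -> str:
        if insertion:
            return self.insertions.get(position, "")
        return self.columns[position]


@dataclass
class GeneGroup:
    group_id: str
    member_gene_ids: list[str]
    representative_id: str
    variants: dict[str, list[str]]  # variant_id -> member gene ids
    profiles: dict[str, VariantProfile] = field(default_factory=dict)

    def variant_of(self, gene_id: str) -> str:
        for vid, members in self.variants.items():
            if gene_id in members:
                return vid
        raise KeyError(gene_id)


@dataclass
class MarkerPosition:
    """A discriminative position of one gene group.

    ``position`` is a 0-based column on the representative; when
    ``insertion`` is true the marker is the inserted string following that
    position ("" for variants without an insertion there).
    """

    group_id: str
    position: int
    insertion: bool
    states: dict[str, str]  # variant_id -> state

    @property
    def key(self) -> tuple[int, bool]:
        return (self.position, self.insertion)


@dataclass
class MarkerDatabase:
    genes: list[TAGene]
    groups: list[GeneGroup]
    markers: list[MarkerPosition]
    repertoires: dict[str, set[tuple[str, str]]]  # strain -> {(group, variant)}
    params: BuildParams
    removed_plasmid_homologs: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._gene_by_id = {g.gene_id: g for g in self.genes}
        self._group_by_id = {g.group_id: g for g in self.groups}
        self._markers_by_group: dict[str, list[MarkerPosition]] = {}
        for m in self.markers:
            self._markers_by_group.setdefault(m.group_id, []).append(m)
        self._variant_by_gene: dict[str, tuple[str, str]] = {}
        for grp in self.groups:
            for vid, members in grp.variants.items():
                for gid in members:
                    self._variant_by_gene[gid] = (grp.group_id, vid)

    def gene(self, gene_id: str) -> TAGene:
        return self._gene_by_id[gene_id]

    def group(self, group_id: str) -> GeneGroup:
        return self._group_by_id[group_id]

    def group_and_variant_of(self, gene_id: str) -> tuple[str, str]:
        return self._variant_by_gene[gene_id]

    def markers_of(self, group_id: str) -> list[MarkerPosition]:
        return self._markers_by_group.get(group_id, [])

    def representative_length(self, group_id: str) -> int:
        grp = self._group_by_id[group_id]
        return len(self._gene_by_id[grp.representative_id].sequence)

    def variant_sequence(self, group_id: str, variant_id: str) -> str:
        grp = self._group_by_id[group_id]
        return self._gene_by_id[grp.variants[variant_id][0]].sequence

    def strains(self) -> list[str]:
        return sorted(self.repertoires)

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id}")
            seen[g.gene_id] = g.gene_id
        grouped = [gid for grp in self.groups for gid in grp.member_gene_ids]
        if sorted(grouped) != sorted(seen):
            raise ValidationError("genes and group membership disagree")
        for grp in self.groups:
            if grp.representative_id not in grp.member_gene_ids:
                raise ValidationError(f"group {grp.group_id}: representative not a member")
            flat = sorted(gid for members in grp.variants.values() for gid in members)
            if flat != sorted(grp.member_gene_ids):
                raise ValidationError(f"group {grp.group_id}: variants do not partition members")
        for strain, rep in self.repertoires.items():
            for group_id, variant_id in rep:
                if variant_id not in self._group_by_id[group_id].variants:
                    raise ValidationError(
                        f"repertoire of {strain} references unknown variant "
                        f"{group_id}/{variant_id}"
                    )
        removed = {gid for gid, _ in self.removed_plasmid_homologs}
        if removed & set(seen):
            raise ValidationError("removed plasmid homologs still present in database")


# ---------------------------------------------------------------------------
# clustering


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _pairwise_identity(a: str, b: str, scoring: ScoringScheme) -> float:
    return sequence_identity(a, b, scoring)


def cluster_genes(
    genes: Sequence[TAGene],
    params: BuildParams | None = None,
    scoring: ScoringScheme | None = None,
) -> list[GeneGroup]:
    """Single-linkage grouping of genes by global-alignment identity.

    Two genes are joined when their identity strictly exceeds
    ``params.grouping_identity``; groups are the connected components of
    that graph.  Output is deterministic: groups are ordered by their
    smallest member gene_id and labelled ``<gene name>-<number>`` with
    numbering per gene name in that order.
    """
    if not genes:
        raise ValidationError("cluster_genes: empty gene list")
    params = params or BuildParams()
    scoring = scoring or ScoringScheme()
    genes = sorted(genes, key=lambda g: g.gene_id)
    uf = _UnionFind(g.gene_id for g in genes)
    by_id = {g.gene_id: g for g in genes}
    # identical sequences are trivially linked; align only distinct pairs
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            if uf.find(gi.gene_id) == uf.find(gj.gene_id):
                continue
            if gi.sequence == gj.sequence:
                uf.union(gi.gene_id, gj.gene_id)
                continue
            if _pairwise_identity(gi.sequence, gj.sequence, scoring) > params.grouping_identity:
                uf.union(gi.gene_id, gj.gene_id)
    components: dict[str, list[str]] = {}
    for g in genes:
        components.setdefault(uf.find(g.gene_id), []).append(g.gene_id)
    ordered = sorted(components.values(), key=lambda ms: min(ms))
    counts: dict[str, int] = {}
    groups: list[GeneGroup] = []
    for members in ordered:
        members = sorted(members)
        # longest member; ties broken by taking the lexicographically
        # smallest gene_id among the longest
        longest = max(len(by_id[gid].sequence) for gid in members)
        rep = min(gid for gid in members if len(by_id[gid].sequence) == longest)
        name = by_id[rep].name
        counts[name] = counts.get(name, 0) + 1
        group_id = f"{name}-{counts[name]}"
        variant_classes: dict[str, list[str]] = {}
        for gid in members:
            variant_classes.setdefault(by_id[gid].sequence, []).append(gid)
        ordered_variants = sorted(variant_classes.values(), key=lambda ms: min(ms))
        variants = {
            f"{group_id}.v{i + 1}": sorted(ms) for i, ms in enumerate(ordered_variants)
        }
        groups.append(
            GeneGroup(
                group_id=group_id,
                member_gene_ids=members,
                representative_id=rep,
                variants=variants,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# marker discovery


def _profile_from_alignment(variant_seq: str, rep_seq: str, scoring: ScoringScheme) -> VariantProfile:
    """Express a variant in representative coordinates via global alignment."""
    aln = global_align(variant_seq, rep_seq, scoring)
    columns: list[str] = []
    insertions: dict[int, str] = {}
    qpos = 0  # variant cursor
    for op, n in aln.operations:
        if op in "=X":
            columns.extend(variant_seq[qpos + i] for i in range(n))
            qpos += n
        elif op == "D":  # representative base absent from variant
            columns.extend("-" * n)
        elif op == "I":  # variant bases inserted relative to representative
            key = len(columns) - 1
            insertions[key] = insertions.get(key, "") + variant_seq[qpos : qpos + n]
            qpos += n
    return VariantProfile(columns="".join(columns), insertions=insertions)


def compute_profiles(
    group: GeneGroup,
    sequences: Mapping[str, str],
    scoring: ScoringScheme | None = None,
) -> dict[str, VariantProfile]:
    """Align each variant's sequence to the group representative."""
    scoring = scoring or ScoringScheme()
    rep_seq = sequences[group.representative_id]
    profiles: dict[str, VariantProfile] = {}
    for vid, members in group.variants.items():
        vseq = sequences[members[0]]
        if vseq == rep_seq:
            profiles[vid] = VariantProfile(columns=rep_seq)
        else:
            profiles[vid] = _profile_from_alignment(vseq, rep_seq, scoring)
    return profiles


def find_discriminative_markers(
    group: GeneGroup,
    profiles: Mapping[str, VariantProfile] | None = None,
) -> list[MarkerPosition]:
    """Positions (substitutions, deletions, insertions) at which at least
    two variant classes of the group disagree.

    Requires each variant's representative-anchored profile; if the group
    already carries profiles they are used.
    """
    profiles = profiles or group.profiles
    missing = set(group.variants) - set(profiles)
    if missing:
        raise ValidationError(
            f"group {group.group_id}: missing alignments for variants {sorted(missing)}"
        )
    vids = sorted(group.variants)
    markers: list[MarkerPosition] = []
    if len(vids) < 2:
        return markers
    rep_len = len(next(iter(profiles.values())).columns)
    for r in range(rep_len):
        states = {vid: profiles[vid].columns[r] for vid in vids}
        if len(set(states.values())) > 1:
            markers.append(MarkerPosition(group.group_id, r, False, states))
    ins_keys = sorted({k for p in profiles.values() for k in p.insertions})
    for r in ins_keys:
        states = {vid: profiles[vid].insertions.get(r, "") for vid in vids}
        if len(set(states.values())) > 1:
            markers.append(MarkerPosition(group.group_id, r, True, states))
    # variant classes are distinct sequences anchored to one frame, so every
    # pair must be separated by some marker; assert the construction holds
    for i, u in enumerate(vids):
        for v in vids[i + 1 :]:
            if not any(m.states[u] != m.states[v] for m in markers):
                raise AssertionError(
                    f"group {group.group_id}: variants {u}/{v} share all marker states"
                )
    return markers


# ---------------------------------------------------------------------------
# plasmid screen


def screen_plasmid_homologs(
    genes: Sequence[TAGene],
    plasmids: Mapping[str, str] | Sequence[str],
    params: BuildParams | None = None,
    scoring: ScoringScheme | None = None,
) -> tuple[list[TAGene], list[tuple[str, float]]]:
    """Chromosomal-only filter.

    A gene is removed iff some local alignment against a plasmid reaches
    ``plasmid_identity`` over at least ``plasmid_min_coverage`` of the gene
    length.  Returns (retained, removed-with-best-identity).
    """
    params = params or BuildParams()
    scoring = scoring or ScoringScheme()
    if isinstance(plasmids, Mapping):
        plasmid_seqs = [plasmids[k] for k in sorted(plasmids)]
    else:
        plasmid_seqs = list(plasmids)
    retained: list[TAGene] = []
    removed: list[tuple[str, float]] = []
    for gene in genes:
        best = 0.0
        for pseq in plasmid_seqs:
            aln = local_align(gene.sequence, pseq, scoring)
            qlen = aln.query_interval[1] - aln.query_interval[0]
            if qlen / len(gene.sequence) >= params.plasmid_min_coverage:
                best = max(best, aln.identity)
        if best >= params.plasmid_identity:
            removed.append((gene.gene_id, best))
        else:
            retained.append(gene)
    return retained, removed


# ---------------------------------------------------------------------------
# database assembly and serialization


def build_database(
    genes: Sequence[TAGene],
    plasmids: Mapping[str, str] | Sequence[str] = (),
    params: BuildParams | None = None,
    scoring: ScoringScheme | None = None,
) -> MarkerDatabase:
    """Full reference build: plasmid screen, grouping, marker discovery,
    strain repertoires."""
    params = params or BuildParams()
    scoring = scoring or ScoringScheme()
    if not genes:
        raise ValidationError("build_database: no genes")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate gene ids: {dupes}")
    retained, removed = screen_plasmid_homologs(genes, plasmids, params, scoring)
    if not retained:
        raise ValidationError("all genes removed by the plasmid screen")
    groups = cluster_genes(retained, params, scoring)
    sequences = {g.gene_id: g.sequence for g in retained}
    markers: list[MarkerPosition] = []
    for grp in groups:
        grp.profiles = compute_profiles(grp, sequences, scoring)
        markers.extend(find_discriminative_markers(grp))
    repertoires: dict[str, set[tuple[str, str]]] = {}
    by_id = {g.gene_id: g for g in retained}
    for grp in groups:
        for vid, members in grp.variants.items():
            for gid in members:
                repertoires.setdefault(by_id[gid].strain_id, set()).add((grp.group_id, vid))
    db = MarkerDatabase(
        genes=list(retained),
        groups=groups,
        markers=markers,
        repertoires=repertoires,
        params=params,
        removed_plasmid_homologs=removed,
    )
    db.validate()
    return db


def _db_to_dict(db: MarkerDatabase) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "params": asdict(db.params),
        "genes": [asdict(g) for g in db.genes],
        "groups": [
            {
                "group_id": grp.group_id,
                "member_gene_ids": grp.member_gene_ids,
                "representative_id": grp.representative_id,
                "variants": grp.variants,
                "profiles": {
                    vid: {
                        "columns": p.columns,
                        "insertions": {str(k): v for k, v in p.insertions.items()},
                    }
                    for vid, p in grp.profiles.items()
                },
            }
            for grp in db.groups
        ],
        "markers": [
            {
                "group_id": m.group_id,
                "position": m.position,
                "insertion": m.insertion,
                "states": m.states,
            }
            for m in db.markers
        ],
        "repertoires": {
            strain: sorted(list(pair) for pair in rep)
            for strain, rep in db.repertoires.items()
        },
        "removed_plasmid_homologs": [
            {"gene_id": gid, "identity": ident} for gid, ident in db.removed_plasmid_homologs
        ],
    }


def save_database(db: MarkerDatabase, path) -> None:
    with open(path, "w") as fh:
        json.dump(_db_to_dict(db), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_database(path) -> MarkerDatabase:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DatabaseFormatError(f"not a valid database JSON file: {exc}") from exc
    version = data.get("format_version")
    if version != FORMAT_VERSION:
        raise DatabaseFormatError(
            f"unsupported database format version {version!r} (expected {FORMAT_VERSION})"
        )
    try:
        genes = [TAGene(**g) for g in data["genes"]]
        groups = []
        for g in data["groups"]:
            groups.append(
                GeneGroup(
                    group_id=g["group_id"],
                    member_gene_ids=list(g["member_gene_ids"]),
                    representative_id=g["representative_id"],
                    variants={k: list(v) for k, v in g["variants"].items()},
                    profiles={
                        vid: VariantProfile(
                            columns=p["columns"],
                            insertions={int(k): v for k, v in p["insertions"].items()},
                        )
                        for vid, p in g["profiles"].items()
                    },
                )
            )
        markers = [
            MarkerPosition(m["group_id"], m["position"], m["insertion"], dict(m["states"]))
            for m in data["markers"]
        ]
        repertoires = {
            strain: {tuple(pair) for pair in rep}
            for strain, rep in data["repertoires"].items()
        }
        removed = [
            (r["gene_id"], float(r["identity"]))
            for r in data["removed_plasmid_homologs"]
        ]
        params = BuildParams(**data["params"])
    except (KeyError, TypeError) as exc:
        raise DatabaseFormatError(f"malformed database file: missing/invalid field {exc}") from exc
    db = MarkerDatabase(
        genes=genes,
        groups=groups,
        markers=markers,
        repertoires=repertoires,
        params=params,
        removed_plasmid_homologs=removed,
    )
    db.validate()
    return db


# ---------------------------------------------------------------------------
# presence/absence matrix


def build_presence_matrix(db: MarkerDatabase, level: str = "species") -> pd.DataFrame:
    """Binary taxon × gene-group matrix (1 = some gene of the taxon belongs
    to the group), the tabular form of the presence/absence heatmaps."""
    if level == "species":
        taxon_of = {g.gene_id: g.species for g in db.genes}
    elif level == "strain":
        taxon_of = {g.gene_id: g.strain_id for g in db.genes}
    else:
        raise ValidationError(f"unknown level {level!r}: expected 'species' or 'strain'")
    taxa = sorted(set(taxon_of.values()))
    cols = sorted(grp.group_id for grp in db.groups)
    mat = pd.DataFrame(0, index=taxa, columns=cols, dtype=int)
    for grp in db.groups:
        for gid in grp.member_gene_ids:
            mat.loc[taxon_of[gid], grp.group_id] = 1
    mat.index.name = level
    return mat


# ---------------------------------------------------------------------------
# file input


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_table(fasta_path, metadata_path) -> list[TAGene]:
    """Load genes from a FASTA plus a metadata TSV (columns: gene_id,
    strain_id, species, genus, family, role[, name])."""
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = ["gene_id", "strain_id", "species", "genus", "family", "role"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata table lacks columns: {missing}")
    genes = []
    for _, row in meta.iterrows():
        if row["gene_id"] not in seqs:
            raise ValidationError(
                f"metadata references gene_id {row['gene_id']} absent from FASTA"
            )
        genes.append(
            TAGene(
                gene_id=row["gene_id"],
                strain_id=row["strain_id"],
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                role=row["role"],
                sequence=seqs[row["gene_id"]],
                name=row.get("name", "") or "",
            )
        )
    return genes
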