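"""Strain inference from read evidence over toxin–antitoxin markers.

Given reads mapped onto marker genes, the profiler

1. collects *marker observations* — for every discriminative position
   covered by at least one accepted read, the observed states with their
   read support; a read showing a state declared by no variant contributes
   a conflict only (its evidence at that marker is discarded),
2. detects gene variants per group: the candidate set is the smallest set
   of variants consistent with every sufficiently supported observed state
   (marker dropouts in uncovered regions enlarge it),
3. builds the boolean gene discernibility matrix G — G(u, v) = 1 when the
   observed, supported markers cannot separate variants u and v,
4. builds the asymmetric strain discernibility matrix St — St(i, j) = 1
   when strain i cannot be distinguished from strain j: every detected
   gene of i is either shared with j or its variants cannot be resolved
   from j's; St is not symmetric because j may carry additional detected
   genes that i lacks,
5. derives indiscernible strain sets as connected components of the mutual
   relation St(i, j) AND St(j, i); a set's size is the performance measure
   (1 = the strain is fully resolved),
6. applies the reporting thresholds: a strain set is reported when its
   aggregate breadth of coverage exceeds 60% and more than two (or at
   least half) of its markers are observed with support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import ReadAlignment, ValidationError
from .markerdb import MarkerDatabase, MarkerPosition

__all__ = [
    "MarkerObservation",
    "Evidence",
    "GeneDetection",
    "GeneDiscernibilityMatrix",
    "StrainDiscernibilityMatrix",
    "IndiscernibleSet",
    "ReportThresholds",
    "ReportRow",
    "ProfileReport",
    "collect_evidence",
    "detect_gene_variants",
    "build_gene_discernibility",
    "build_strain_discernibility",
    "derive_indiscernible_sets",
    "apply_report_thresholds",
    "profile",
    "write_report",
    "write_evidence",
]

MarkerKey = tuple[int, bool]  # (representative position, is_insertion)


@dataclass
class MarkerObservation:
    """Read support per observed state at one discriminative position."""

    group_id: str
    position: int
    insertion: bool
    support: dict[str, int] = field(default_factory=dict)
    conflicts: int = 0

    @property
    def key(self) -> MarkerKey:
        return (self.position, self.insertion)

    def supported_states(self, min_support: int) -> set[str]:
        return {s for s, n in self.support.items() if n >= min_support}


@dataclass
class Evidence:
    """Per-group marker observations and breadth-of-coverage masks."""

    observations: dict[str, dict[MarkerKey, MarkerObservation]]
    coverage: dict[str, set[int]]
    n_reads_used: int = 0
    n_reads_ambiguous: int = 0


@dataclass
class GeneDetection:
    group_id: str
    candidate_variants: list[str]
    breadth: float
    observed_markers: list[MarkerKey]
    discarded_markers: list[MarkerKey]
    supported_states: dict[MarkerKey, set[str]]
    mixed: bool = False
    inconsistent: bool = False


@dataclass
class GeneDiscernibilityMatrix:
    index: list[str]  # variant ids
    group_of: dict[str, str]
    matrix: np.ndarray  # boolean, 1 = cannot be distinguished

    def lookup(self, u: str, v: str) -> bool:
        return bool(self.matrix[self.index.index(u), self.index.index(v)])


@dataclass
class StrainDiscernibilityMatrix:
    index: list[str]  # strain ids with >=1 detected marker variant
    matrix: np.ndarray  # St(i, j) = 1: i cannot be distinguished from j

    def lookup(self, i: str, j: str) -> bool:
        return bool(self.matrix[self.index.index(i), self.index.index(j)])


@dataclass
class IndiscernibleSet:
    members: list[str]
    chained: bool = False  # component held together transitively only

    @property
    def performance(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ReportThresholds:
    """Reporting cut-offs: breadth of coverage strictly above
    ``min_coverage`` and observed supporting markers strictly above
    ``min_markers_abs`` or at least ``min_markers_frac`` of the strain's
    markers."""

    min_coverage: float = 0.60
    min_markers_abs: int = 2
    min_markers_frac: float = 0.50
    coverage_mode: str = "breadth"  # or "gene_fraction"

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_markers_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_mode not in ("breadth", "gene_fraction"):
            raise ValidationError(f"unknown coverage_mode {self.coverage_mode!r}")


@dataclass
class ReportRow:
    genus: str
    species: str
    strain_set: tuple[str, ...]
    n_strains_in_set: int
    coverage: float
    markers_observed: int
    markers_total: int
    performance: int
    chained: bool = False


@dataclass
class ProfileReport:
    rows: list[ReportRow]
    strain_stats: dict[str, dict] = field(default_factory=dict)

    def reported_strains(self) -> set[str]:
        return {s for row in self.rows for s in row.strain_set}

    def species_rows(self) -> list[dict]:
        out: dict[tuple[str, str], dict] = {}
        for row in self.rows:
            key = (row.genus, row.species)
            agg = out.setdefault(
                key,
                {"genus": row.genus, "species": row.species, "n_strain_sets": 0,
                 "best_coverage": 0.0, "best_performance": None},
            )
            agg["n_strain_sets"] += 1
            agg["best_coverage"] = max(agg["best_coverage"], row.coverage)
            if agg["best_performance"] is None or row.performance < agg["best_performance"]:
                agg["best_performance"] = row.performance
        return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# step 3: evidence collection


def _observe_marker(
    marker: MarkerPosition,
    variant_id: str,
    col_map: list[int | None],
    ins_map: dict[int, tuple[int, int]],
    observed: Mapping[int, str],
) -> str | None:
    """State a read (already projected onto its best-matching variant's
    coordinates) shows at one marker, or None if the read does not span
    the marker."""
    if not marker.insertion:
        r = marker.position
        vpos = col_map[r]
        if vpos is not None:
            return observed.get(vpos)
        # the variant deletes this representative position: the deletion is
        # observed when the read spans both anchored flanks
        left = next((col_map[x] for x in range(r - 1, -1, -1) if col_map[x] is not None), None)
        right = next((col_map[x] for x in range(r + 1, len(col_map)) if col_map[x] is not None), None)
        if left is None or right is None:
            return None
        if left in observed and right in observed:
            return "-"
        return None
    # insertion marker keyed to the representative position before it
    r = marker.position
    left = next((col_map[x] for x in range(r, -1, -1) if col_map[x] is not None), None) if r >= 0 else None
    right = next((col_map[x] for x in range(r + 1, len(col_map)) if col_map[x] is not None), None)
    if left is None and right is None:
        return None
    for anchor in (left, right):
        if anchor is not None and anchor not in observed:
            return None
    start, end = ins_map.get(r, (0, 0))
    bases = []
    for p in range(start, end):
        if p not in observed:
            return None
        if observed[p] != "-":
            bases.append(observed[p])
    return "".join(bases)


def collect_evidence(
    alignments: Sequence[ReadAlignment],
    db: MarkerDatabase,
) -> Evidence:
    """Tally marker observations and coverage from accepted read placements.

    Placements of one read are grouped; a read whose best placements span
    more than one gene group is ambiguous and contributes no evidence.
    A read whose observed state at a discriminative position matches no
    declared variant state increments that marker's conflict count only.
    """
    known_genes = {g.gene_id for g in db.genes}
    by_read: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        if not aln.accepted:
            continue
        if aln.gene_id not in known_genes:
            raise ValidationError(f"alignment references unknown gene {aln.gene_id}")
        by_read.setdefault(aln.read_id, []).append(aln)

    # cache per-variant coordinate maps
    maps: dict[tuple[str, str], tuple[list[int | None], dict[int, tuple[int, int]]]] = {}

    def variant_maps(group_id: str, variant_id: str):
        key = (group_id, variant_id)
        if key not in maps:
            maps[key] = db.group(group_id).profiles[variant_id].column_map()
        return maps[key]

    observations: dict[str, dict[MarkerKey, MarkerObservation]] = {}
    coverage: dict[str, set[int]] = {}
    n_used = 0
    n_ambiguous = 0
    for read_id in sorted(by_read):
        placements = by_read[read_id]
        best = max(p.score for p in placements)
        placements = [p for p in placements if p.score == best]
        groups = {db.group_and_variant_of(p.gene_id)[0] for p in placements}
        if len(groups) > 1:
            n_ambiguous += 1
            continue
        n_used += 1
        placement = min(placements, key=lambda p: p.gene_id)
        group_id, variant_id = db.group_and_variant_of(placement.gene_id)
        col_map, ins_map = variant_maps(group_id, variant_id)
        cov = coverage.setdefault(group_id, set())
        obs_keys = placement.observed
        for r, vpos in enumerate(col_map):
            if vpos is not None and vpos in obs_keys:
                cov.add(r)
        group_obs = observations.setdefault(group_id, {})
        for marker in db.markers_of(group_id):
            state = _observe_marker(marker, variant_id, col_map, ins_map, placement.observed)
            if state is None:
                continue
            rec = group_obs.get(marker.key)
            if rec is None:
                rec = MarkerObservation(group_id, marker.position, marker.insertion)
                group_obs[marker.key] = rec
            if state in set(marker.states.values()):
                rec.support[state] = rec.support.get(state, 0) + 1
            else:
                rec.conflicts += 1
    return Evidence(
        observations=observations,
        coverage=coverage,
        n_reads_used=n_used,
        n_reads_ambiguous=n_ambiguous,
    )


# ---------------------------------------------------------------------------
# step 4a: gene variant detection


def detect_gene_variants(
    evidence: Evidence,
    db: MarkerDatabase,
    min_support: int = 1,
    discard_conflicted_markers: bool = False,
) -> list[GeneDetection]:
    """Smallest variant set per detected group consistent with the
    sufficiently supported observed marker states.

    With ``discard_conflicted_markers`` (strict mode) any marker that saw a
    conflicting read is dropped entirely instead of per read.
    """
    detections: list[GeneDetection] = []
    for group_id in sorted(evidence.coverage):
        cov = evidence.coverage[group_id]
        if not cov:
            continue
        group = db.group(group_id)
        group_obs = evidence.observations.get(group_id, {})
        supported: dict[MarkerKey, set[str]] = {}
        discarded: list[MarkerKey] = []
        for key, rec in sorted(group_obs.items()):
            if rec.conflicts:
                discarded.append(key)
                if discard_conflicted_markers:
                    continue
            states = rec.supported_states(min_support)
            if states:
                supported[key] = states
        marker_by_key = {m.key: m for m in db.markers_of(group_id)}
        candidates = [
            vid
            for vid in sorted(group.variants)
            if all(
                marker_by_key[key].states[vid] in states
                for key, states in supported.items()
            )
        ]
        inconsistent = False
        if not candidates:
            # evidence excluded every catalogued variant (novel variant or
            # error pile-up): fall back to the full group, flagged
            candidates = sorted(group.variants)
            inconsistent = True
        detections.append(
            GeneDetection(
                group_id=group_id,
                candidate_variants=candidates,
                breadth=len(cov) / db.representative_length(group_id),
                observed_markers=sorted(supported),
                discarded_markers=discarded,
                supported_states=supported,
                mixed=any(len(states) > 1 for states in supported.values()),
                inconsistent=inconsistent,
            )
        )
    return detections


# ---------------------------------------------------------------------------
# step 4b: gene discernibility matrix G


def build_gene_discernibility(
    detections: Sequence[GeneDetection],
    db: MarkerDatabase,
) -> GeneDiscernibilityMatrix:
    """G(u, v) = 1 iff u and v are candidate variants of the same group and
    no observed marker with a supported state separates them; variants of
    different groups are always distinguishable (0)."""
    index: list[str] = []
    group_of: dict[str, str] = {}
    for det in detections:
        for vid in det.candidate_variants:
            index.append(vid)
            group_of[vid] = det.group_id
    index = sorted(index)
    n = len(index)
    matrix = np.zeros((n, n), dtype=bool)
    pos = {vid: i for i, vid in enumerate(index)}
    for det in detections:
        cands = det.candidate_variants
        marker_by_key = {m.key: m for m in db.markers_of(det.group_id)}
        informative = list(det.supported_states)
        # state fingerprint per candidate over informative markers
        states = {
            vid: tuple(marker_by_key[key].states[vid] for key in informative)
            for vid in cands
        }
        for u in cands:
            for v in cands:
                matrix[pos[u], pos[v]] = states[u] == states[v]
    return GeneDiscernibilityMatrix(index=index, group_of=group_of, matrix=matrix)


# ---------------------------------------------------------------------------
# step 5: strain discernibility matrix St


def build_strain_discernibility(
    G: GeneDiscernibilityMatrix,
    detections: Sequence[GeneDetection],
    db: MarkerDatabase,
) -> StrainDiscernibilityMatrix:
    """St(i, j) = 0 (i distinguishable from j) iff some detected group
    supports a variant of i's repertoire that j cannot account for: j
    either lacks the group or every variant j carries there is
    distinguishable from every supported candidate of i.  St is asymmetric:
    extra detected genes in j distinguish j from i but not i from j."""
    cands: dict[str, set[str]] = {d.group_id: set(d.candidate_variants) for d in detections}
    rep_by_group: dict[str, dict[str, set[str]]] = {}
    for strain, rep in db.repertoires.items():
        groups: dict[str, set[str]] = {}
        for group_id, variant_id in rep:
            groups.setdefault(group_id, set()).add(variant_id)
        rep_by_group[strain] = groups
    strains = sorted(
        strain
        for strain, groups in rep_by_group.items()
        if any(v in cands.get(g, ()) for g, vs in groups.items() for v in vs)
    )
    gpos = {vid: i for i, vid in enumerate(G.index)}

    def indistinguishable(v: str, u: str) -> bool:
        if u not in gpos:  # u excluded by evidence -> distinguishable
            return False
        return bool(G.matrix[gpos[v], gpos[u]])

    n = len(strains)
    St = np.ones((n, n), dtype=bool)
    for a, i in enumerate(strains):
        for b, j in enumerate(strains):
            for group_id, vi_all in rep_by_group[i].items():
                if group_id not in cands:
                    continue
                vi = vi_all & cands[group_id]
                if not vi:
                    continue
                uj = rep_by_group[j].get(group_id)
                if uj is None or all(
                    not indistinguishable(v, u) for v in vi for u in uj
                ):
                    St[a, b] = False
                    break
    return StrainDiscernibilityMatrix(index=strains, matrix=St)


# ---------------------------------------------------------------------------
# step 6: indiscernible sets


def derive_indiscernible_sets(St: StrainDiscernibilityMatrix) -> list[IndiscernibleSet]:
    """Connected components of the mutual relation M = St AND St^T.

    Components glued together only through intermediate strains (a chain
    with some non-mutual pair inside) are flagged ``chained``."""
    n = len(St.index)
    M = St.matrix & St.matrix.T
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if M[i, j]:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    sets = []
    for members in sorted(comps.values(), key=lambda ms: St.index[min(ms)]):
        chained = any(
            not M[i, j] for i in members for j in members if i < j
        )
        sets.append(
            IndiscernibleSet(members=[St.index[i] for i in sorted(members)], chained=chained)
        )
    return sets


# ---------------------------------------------------------------------------
# reporting


def _strain_stats(
    strain: str,
    detections_by_group: Mapping[str, GeneDetection],
    db: MarkerDatabase,
    thresholds: ReportThresholds,
) -> dict:
    rep = db.repertoires[strain]
    rep_groups = sorted({g for g, _ in rep})
    variant_of = {g: v for g, v in rep}
    detected = [g for g in rep_groups if g in detections_by_group]
    if thresholds.coverage_mode == "gene_fraction":
        coverage = len(detected) / len(rep_groups) if rep_groups else 0.0
    else:
        covered = sum(
            detections_by_group[g].breadth * db.representative_length(g) for g in detected
        )
        total = sum(db.representative_length(g) for g in detected)
        coverage = covered / total if total else 0.0
    markers_total = sum(len(db.markers_of(g)) for g in rep_groups)
    observed = 0
    for g in detected:
        det = detections_by_group[g]
        vid = variant_of[g]
        for m in db.markers_of(g):
            states = det.supported_states.get(m.key)
            if states and m.states[vid] in states:
                observed += 1
    passes = coverage > thresholds.min_coverage and (
        markers_total == 0
        or observed > thresholds.min_markers_abs
        or observed / markers_total >= thresholds.min_markers_frac
    )
    return {
        "strain": strain,
        "coverage": coverage,
        "markers_observed": observed,
        "markers_total": markers_total,
        "passes": passes,
    }


def apply_report_thresholds(
    sets: Sequence[IndiscernibleSet],
    detections: Sequence[GeneDetection],
    db: MarkerDatabase,
    thresholds: ReportThresholds | None = None,
) -> ProfileReport:
    """Keep the indiscernible sets whose evidence clears the coverage and
    marker-count thresholds; one report row per reported set."""
    thresholds = thresholds or ReportThresholds()
    by_group = {d.group_id: d for d in detections}
    taxon: dict[str, tuple[str, str]] = {}
    for gene in db.genes:
        taxon[gene.strain_id] = (gene.genus, gene.species)
    rows: list[ReportRow] = []
    all_stats: dict[str, dict] = {}
    for iset in sets:
        stats = [_strain_stats(s, by_group, db, thresholds) for s in iset.members]
        for st in stats:
            all_stats[st["strain"]] = st
        if not any(st["passes"] for st in stats):
            continue
        best = max(stats, key=lambda st: (st["markers_observed"], st["coverage"]))
        genera = sorted({taxon[s][0] for s in iset.members})
        species = sorted({taxon[s][1] for s in iset.members})
        rows.append(
            ReportRow(
                genus=",".join(genera),
                species=",".join(species),
                strain_set=tuple(iset.members),
                n_strains_in_set=len(iset.members),
                coverage=best["coverage"],
                markers_observed=best["markers_observed"],
                markers_total=best["markers_total"],
                performance=iset.performance,
                chained=iset.chained,
            )
        )
    rows.sort(key=lambda r: (r.genus, r.species, r.strain_set))
    return ProfileReport(rows=rows, strain_stats=all_stats)


def profile(
    alignments: Sequence[ReadAlignment],
    db: MarkerDatabase,
    min_support: int = 1,
    thresholds: ReportThresholds | None = None,
    discard_conflicted_markers: bool = False,
) -> tuple[ProfileReport, Evidence, Sequence[GeneDetection], GeneDiscernibilityMatrix, StrainDiscernibilityMatrix, list[IndiscernibleSet]]:
    """Run inference end to end from read placements; returns the report
    plus every intermediate object for inspection."""
    evidence = collect_evidence(alignments, db)
    detections = detect_gene_variants(
        evidence, db, min_support=min_support,
        discard_conflicted_markers=discard_conflicted_markers,
    )
    G = build_gene_discernibility(detections, db)
    St = build_strain_discernibility(G, detections, db)
    sets = derive_indiscernible_sets(St)
    report = apply_report_thresholds(sets, detections, db, thresholds)
    return report, evidence, detections, G, St, sets


REPORT_COLUMNS = [
    "genus",
    "species",
    "strain_set",
    "n_strains_in_set",
    "coverage",
    "markers_observed",
    "markers_total",
    "performance",
]


def write_report(report: ProfileReport, path, format: str = "tsv") -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for row in report.rows:
                fh.write(
                    "\t".join(
                        [
                            row.genus,
                            row.species,
                            ",".join(row.strain_set),
                            str(row.n_strains_in_set),
                            f"{row.coverage:.4f}",
                            str(row.markers_observed),
                            str(row.markers_total),
                            str(row.performance),
                        ]
                    )
                    + "\n"
                )
    elif format == "json":
        payload = {
            "rows": [
                {
                    "genus": r.genus,
                    "species": r.species,
                    "strain_set": list(r.strain_set),
                    "n_strains_in_set": r.n_strains_in_set,
                    "coverage": r.coverage,
                    "markers_observed": r.markers_observed,
                    "markers_total": r.markers_total,
                    "performance": r.performance,
                    "chained": r.chained,
                }
                for r in report.rows
            ],
            "species": report.species_rows(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")


def write_evidence(
    path,
    evidence: Evidence,
    detections: Sequence[GeneDetection],
    G: GeneDiscernibilityMatrix,
    St: StrainDiscernibilityMatrix,
    sets: Sequence[IndiscernibleSet],
) -> None:
    """Full evidence dump (observations, matrices as index + bit rows) for
    debugging and downstream analysis."""

    def marker_key_str(key: MarkerKey) -> str:
        pos, ins = key
        return f"ins@{pos}" if ins else str(pos)

    payload = {
        "n_reads_used": evidence.n_reads_used,
        "n_reads_ambiguous": evidence.n_reads_ambiguous,
        "observations": {
            group: {
                marker_key_str(key): {
                    "support": rec.support,
                    "conflicts": rec.conflicts,
                }
                for key, rec in sorted(obs.items())
            }
            for group, obs in sorted(evidence.observations.items())
        },
        "coverage": {g: sorted(cov) for g, cov in sorted(evidence.coverage.items())},
        "detections": [
            {
                "group_id": d.group_id,
                "candidate_variants": d.candidate_variants,
                "breadth": d.breadth,
                "observed_markers": [marker_key_str(k) for k in d.observed_markers],
                "discarded_markers": [marker_key_str(k) for k in d.discarded_markers],
                "mixed": d.mixed,
                "inconsistent": d.inconsistent,
            }
            for d in detections
        ],
        "gene_discernibility": {
            "index": G.index,
            "rows": ["".join("1" if x else "0" for x in row) for row in G.matrix],
        },
        "strain_discernibility": {
            "index": St.index,
            "rows": ["".join("1" if x else "0" for x in row) for row in St.matrix],
        },
        "indiscernible_sets": [
            {"members": s.members, "performance": s.performance, "chained": s.chained}
            for s in sets
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
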