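"""Synthetic marker databases and random partial evidence, built by direct
construction (no alignment) so matrix logic can be exercised over many
random panels cheaply.

Variants within a group differ by substitutions only, so every variant's
profile in representative coordinates is simply its own sequence.
"""

from __future__ import annotations

import numpy as np

from tastrain.markerdb import (
    BuildParams,
    GeneGroup,
    MarkerDatabase,
    TAGene,
    VariantProfile,
    find_discriminative_markers,
)
from tastrain.profiler import Evidence, MarkerObservation

NAMES = [("mazEF", "toxin"), ("mazEF", "antitoxin"), ("relBE", "toxin"), ("relBE", "antitoxin")]


def random_direct_db(
    rng: np.random.Generator,
    n_strains: int = 6,
    n_groups: int = 8,
    max_variants: int = 3,
    gene_length: int = 80,
    n_subs: tuple[int, int] = (1, 3),
) -> MarkerDatabase:
    strains = [f"st{i + 1}" for i in range(n_strains)]
    genes: list[TAGene] = []
    groups: list[GeneGroup] = []
    markers = []
    repertoires: dict[str, set[tuple[str, str]]] = {s: set() for s in strains}
    name_counts: dict[str, int] = {}
    for g in range(n_groups):
        base = "".join(rng.choice(list("ACGT"), size=gene_length))
        n_var = int(rng.integers(1, max_variants + 1))
        variant_seqs = [base]
        while len(variant_seqs) < n_var:
            seq = list(base)
            for pos in rng.choice(gene_length, size=int(rng.integers(n_subs[0], n_subs[1] + 1)), replace=False):
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            seq = "".join(seq)
            if seq not in variant_seqs:
                variant_seqs.append(seq)
        # every group is carried by a random non-empty strain subset
        n_present = int(rng.integers(1, n_strains + 1))
        present = sorted(rng.choice(n_strains, size=n_present, replace=False))
        assignment = {strains[i]: int(rng.integers(0, len(variant_seqs))) for i in present}
        family, role = NAMES[g % len(NAMES)]
        from tastrain.markerdb import GENE_NAMES

        name = GENE_NAMES[(family, role)]
        name_counts[name] = name_counts.get(name, 0) + 1
        group_id = f"{name}-{name_counts[name]}"
        member_ids: dict[int, list[str]] = {}
        for strain, v_idx in sorted(assignment.items()):
            gene_id = f"{strain}.g{g:02d}.{name}"
            genes.append(
                TAGene(
                    gene_id=gene_id,
                    strain_id=strain,
                    species=f"sp{(int(strain[2:]) - 1) // 3 + 1}",
                    genus="genus_T",
                    family=family,
                    role=role,
                    sequence=variant_seqs[v_idx],
                    name=name,
                )
            )
            member_ids.setdefault(v_idx, []).append(gene_id)
        used = sorted(member_ids)  # variant indices that have members
        variants = {
            f"{group_id}.v{k + 1}": sorted(member_ids[v_idx])
            for k, v_idx in enumerate(used)
        }
        profiles = {
            f"{group_id}.v{k + 1}": VariantProfile(columns=variant_seqs[v_idx])
            for k, v_idx in enumerate(used)
        }
        members = sorted(gid for ms in variants.values() for gid in ms)
        group = GeneGroup(
            group_id=group_id,
            member_gene_ids=members,
            representative_id=min(members),
            variants=variants,
            profiles=profiles,
        )
        groups.append(group)
        markers.extend(find_discriminative_markers(group))
        for k, v_idx in enumerate(used):
            for gid in member_ids[v_idx]:
                strain = gid.split(".")[0]
                repertoires[strain].add((group_id, f"{group_id}.v{k + 1}"))
    repertoires = {s: r for s, r in repertoires.items() if r}
    db = MarkerDatabase(
        genes=genes,
        groups=groups,
        markers=markers,
        repertoires=repertoires,
        params=BuildParams(),
    )
    db.validate()
    return db


def random_partial_evidence(
    rng: np.random.Generator,
    db: MarkerDatabase,
    planted: list[str],
    p_group_detected: float = 0.9,
    p_marker_observed: float = 0.7,
):
    """Random well-formed evidence from a planted strain subset: per group,
    a random coverage mask; per covered marker, a non-empty random subset
    of the planted variants' states, with small support counts and
    occasional conflicting reads."""
    observations: dict[str, dict] = {}
    coverage: dict[str, set[int]] = {}
    supported_by_group: dict[str, dict] = {}
    for group in db.groups:
        planted_variants = sorted(
            {
                v
                for s in planted
                for g, v in db.repertoires.get(s, ())
                if g == group.group_id
            }
        )
        if not planted_variants or rng.random() > p_group_detected:
            continue
        rep_len = db.representative_length(group.group_id)
        frac = 0.3 + 0.7 * rng.random()
        mask = {int(p) for p in np.flatnonzero(rng.random(rep_len) < frac)}
        if not mask:
            mask = {int(rng.integers(0, rep_len))}
        coverage[group.group_id] = mask
        group_obs: dict = {}
        supported: dict = {}
        for m in db.markers_of(group.group_id):
            if m.position not in mask or rng.random() > p_marker_observed:
                continue
            states = sorted({m.states[v] for v in planted_variants})
            keep = [s for s in states if rng.random() < 0.8]
            if not keep:
                keep = [states[int(rng.integers(0, len(states)))]]
            rec = MarkerObservation(group.group_id, m.position, m.insertion)
            for s in keep:
                rec.support[s] = int(rng.integers(1, 4))
            if rng.random() < 0.15:
                rec.conflicts = int(rng.integers(1, 3))
            group_obs[m.key] = rec
            supported[m.key] = set(keep)
        observations[group.group_id] = group_obs
        supported_by_group[group.group_id] = supported
    evidence = Evidence(observations=observations, coverage=coverage)
    return evidence, supported_by_group
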