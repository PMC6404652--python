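import numpy as np
import pytest

from oracles import oracle_candidates, oracle_gene_matrix, oracle_strain_matrix
from synthdb import random_direct_db, random_partial_evidence
from tastrain.align import ReadAlignment, ValidationError
from tastrain.profiler import (
    Evidence,
    GeneDetection,
    IndiscernibleSet,
    MarkerObservation,
    StrainDiscernibilityMatrix,
    apply_report_thresholds,
    build_gene_discernibility,
    build_strain_discernibility,
    collect_evidence,
    derive_indiscernible_sets,
    detect_gene_variants,
    write_report,
)


def make_alignment(read_id, gene_id, gene_seq, start, end, subs=None, score=None):
    """Error-free (or selectively mutated) read placement on a gene."""
    observed = {p: gene_seq[p] for p in range(start, end)}
    for p, base in (subs or {}).items():
        observed[p] = base
    return ReadAlignment(
        read_id=read_id,
        gene_id=gene_id,
        strand="+",
        gene_interval=(start, end),
        observed=observed,
        n_mismatch=len(subs or {}),
        score=float(end - start) if score is None else score,
    )


def simple_two_variant_db():
    """Deterministic single-group db: v1/v2 differ only at position 17."""
    import numpy as np
    from synthdb import random_direct_db

    rng = np.random.default_rng(170)
    while True:
        db = random_direct_db(rng, n_strains=2, n_groups=1, max_variants=2)
        group = db.groups[0]
        if len(group.variants) == 2 and len(db.markers) >= 1:
            return db


class TestCollectEvidence:
    def setup_method(self):
        self.db = simple_two_variant_db()
        self.group = self.db.groups[0]
        self.v1, self.v2 = sorted(self.group.variants)
        self.marker = self.db.markers_of(self.group.group_id)[0]
        self.gene_v1 = self.group.variants[self.v1][0]
        self.seq_v1 = self.db.gene(self.gene_v1).sequence

    def test_error_free_reads_support_their_variant(self):
        pos = self.marker.position
        alns = [
            make_alignment(f"r{i}", self.gene_v1, self.seq_v1, 0, len(self.seq_v1))
            for i in range(5)
        ]
        ev = collect_evidence(alns, self.db)
        rec = ev.observations[self.group.group_id][(pos, False)]
        assert rec.support == {self.marker.states[self.v1]: 5}
        assert rec.conflicts == 0
        assert ev.coverage[self.group.group_id] == set(range(len(self.seq_v1)))

    def test_undeclared_state_counts_as_conflict_only(self):
        pos = self.marker.position
        declared = set(self.marker.states.values())
        novel = next(b for b in "ACGT" if b not in declared)
        aln = make_alignment(
            "r1", self.gene_v1, self.seq_v1, 0, len(self.seq_v1), subs={pos: novel}
        )
        ev = collect_evidence([aln], self.db)
        rec = ev.observations[self.group.group_id][(pos, False)]
        assert rec.support == {}
        assert rec.conflicts == 1

    def test_no_reads_no_evidence(self):
        ev = collect_evidence([], self.db)
        assert ev.observations == {} and ev.coverage == {}

    def test_unknown_gene_is_consistency_error(self):
        aln = make_alignment("r1", "nope", self.seq_v1, 0, 10)
        with pytest.raises(ValidationError):
            collect_evidence([aln], self.db)

    def test_cross_group_ambiguous_read_discarded(self):
        db = random_direct_db(np.random.default_rng(3), n_strains=3, n_groups=2)
        g1, g2 = db.groups[0], db.groups[1]
        gene1, gene2 = g1.member_gene_ids[0], g2.member_gene_ids[0]
        seq1, seq2 = db.gene(gene1).sequence, db.gene(gene2).sequence
        alns = [
            make_alignment("r1", gene1, seq1, 0, 40, score=40.0),
            make_alignment("r1", gene2, seq2, 0, 40, score=40.0),
        ]
        ev = collect_evidence(alns, db)
        assert ev.n_reads_ambiguous == 1 and ev.n_reads_used == 0
        assert ev.observations == {}


class TestDetectGeneVariants:
    def setup_method(self):
        self.db = simple_two_variant_db()
        self.group = self.db.groups[0]
        self.v1, self.v2 = sorted(self.group.variants)
        self.markers = self.db.markers_of(self.group.group_id)

    def evidence(self, covered, support_states=None, counts=1):
        obs = {}
        for m in self.markers:
            if m.position not in covered:
                continue
            rec = MarkerObservation(m.group_id, m.position, m.insertion)
            for state in (support_states or {}).get(m.key, []):
                rec.support[state] = counts
            obs[m.key] = rec
        return Evidence(
            observations={self.group.group_id: obs},
            coverage={self.group.group_id: covered},
        )

    def test_observed_state_selects_single_variant(self):
        L = self.db.representative_length(self.group.group_id)
        states = {m.key: [m.states[self.v1]] for m in self.markers}
        ev = self.evidence(set(range(L)), states)
        (det,) = detect_gene_variants(ev, self.db)
        assert det.candidate_variants == [self.v1]
        assert det.breadth == 1.0
        assert not det.mixed

    def test_uncovered_marker_leaves_both_candidates(self):
        covered = {0} - {m.position for m in self.markers}
        covered = covered or {max(m.position for m in self.markers) + 1}
        ev = self.evidence(covered)
        dets = detect_gene_variants(ev, self.db)
        assert dets[0].candidate_variants == sorted([self.v1, self.v2])

    def test_mixed_support_keeps_both_and_flags(self):
        states = {m.key: [m.states[self.v1], m.states[self.v2]] for m in self.markers}
        L = self.db.representative_length(self.group.group_id)
        ev = self.evidence(set(range(L)), states)
        (det,) = detect_gene_variants(ev, self.db)
        assert det.mixed
        assert det.candidate_variants == sorted([self.v1, self.v2])

    def test_min_support_filters_weak_states(self):
        states = {m.key: [m.states[self.v2]] for m in self.markers}
        L = self.db.representative_length(self.group.group_id)
        ev = self.evidence(set(range(L)), states, counts=1)
        (det,) = detect_gene_variants(ev, self.db, min_support=2)
        # single-read support is below min_support: no constraint remains
        assert det.candidate_variants == sorted([self.v1, self.v2])

    def test_three_variant_exclusion_matches_bruteforce(self, rng):
        for _ in range(20):
            db = random_direct_db(rng, n_strains=6, n_groups=3, max_variants=3)
            planted = sorted(db.repertoires)[:2]
            ev, supported = random_partial_evidence(rng, db, planted)
            dets = detect_gene_variants(ev, db)
            for det in dets:
                expect = oracle_candidates(db, det.group_id, supported[det.group_id])
                assert det.candidate_variants == expect


class TestDiscernibilityMatrices:
    def test_fully_covered_two_variant_group_is_identity(self):
        db = simple_two_variant_db()
        group = db.groups[0]
        v1, v2 = sorted(group.variants)
        markers = db.markers_of(group.group_id)
        supported = {m.key: {m.states[v1], m.states[v2]} for m in markers}
        det = GeneDetection(
            group_id=group.group_id,
            candidate_variants=[v1, v2],
            breadth=1.0,
            observed_markers=sorted(supported),
            discarded_markers=[],
            supported_states=supported,
            mixed=True,
        )
        G = build_gene_discernibility([det], db)
        assert np.array_equal(G.matrix, np.eye(2, dtype=bool))

    def test_zero_covered_markers_give_all_ones_block(self):
        db = simple_two_variant_db()
        group = db.groups[0]
        det = GeneDetection(
            group_id=group.group_id,
            candidate_variants=sorted(group.variants),
            breadth=0.1,
            observed_markers=[],
            discarded_markers=[],
            supported_states={},
        )
        G = build_gene_discernibility([det], db)
        assert G.matrix.all()

    def test_cross_group_blocks_are_zero(self, rng):
        db = random_direct_db(rng, n_strains=4, n_groups=2, max_variants=2)
        dets = [
            GeneDetection(
                group_id=grp.group_id,
                candidate_variants=sorted(grp.variants),
                breadth=1.0,
                observed_markers=[],
                discarded_markers=[],
                supported_states={},
            )
            for grp in db.groups
        ]
        G = build_gene_discernibility(dets, db)
        for a, u in enumerate(G.index):
            for b, v in enumerate(G.index):
                if G.group_of[u] != G.group_of[v]:
                    assert not G.matrix[a, b]

    def test_identical_repertoires_are_mutually_indistinguishable(self):
        # two strains carrying the same variant of the same group, fully
        # covered: St = all ones
        rng = np.random.default_rng(8)
        while True:
            db = random_direct_db(rng, n_strains=2, n_groups=2, max_variants=1)
            reps = [frozenset(r) for r in db.repertoires.values()]
            if len(reps) == 2 and reps[0] == reps[1]:
                break
        ev, supported = random_partial_evidence(rng, db, sorted(db.repertoires))
        dets = detect_gene_variants(ev, db)
        G = build_gene_discernibility(dets, db)
        St = build_strain_discernibility(G, dets, db)
        assert St.matrix.all()

    def test_extra_detected_group_is_asymmetric(self, rng):
        # strain B carries everything strain A does plus one more detected
        # group: B is distinguishable from A, A is not from B
        while True:
            db = random_direct_db(rng, n_strains=2, n_groups=3, max_variants=1)
            reps = {s: {g for g, _ in r} for s, r in db.repertoires.items()}
            if len(reps) == 2:
                a, b = sorted(reps)
                if reps[a] < reps[b]:
                    break
        ev, supported = random_partial_evidence(
            rng, db, [a, b], p_group_detected=1.0, p_marker_observed=1.0
        )
        dets = detect_gene_variants(ev, db)
        G = build_gene_discernibility(dets, db)
        St = build_strain_discernibility(G, dets, db)
        ia, ib = St.index.index(a), St.index.index(b)
        assert St.matrix[ia, ib]      # A cannot be told from B
        assert not St.matrix[ib, ia]  # B's extra gene distinguishes it

    def test_matrices_match_bruteforce_oracle(self, rng):
        for _ in range(25):
            db = random_direct_db(
                rng,
                n_strains=int(rng.integers(2, 9)),
                n_groups=int(rng.integers(1, 13)),
                max_variants=3,
            )
            n_planted = int(rng.integers(1, min(4, len(db.repertoires)) + 1))
            planted = sorted(db.repertoires)[:n_planted]
            ev, supported = random_partial_evidence(rng, db, planted)
            dets = detect_gene_variants(ev, db)
            G = build_gene_discernibility(dets, db)
            index, oG, candidates = oracle_gene_matrix(db, supported)
            assert G.index == index
            for a, u in enumerate(index):
                for b, v in enumerate(index):
                    assert G.matrix[a, b] == oG[(u, v)], (u, v)
            St = build_strain_discernibility(G, dets, db)
            strains, oSt = oracle_strain_matrix(db, candidates, oG)
            assert St.index == strains
            for a, i in enumerate(strains):
                for b, j in enumerate(strains):
                    assert St.matrix[a, b] == oSt[(i, j)], (i, j)

    def test_diagonals_are_one(self, rng):
        for _ in range(10):
            db = random_direct_db(rng, n_strains=5, n_groups=4)
            planted = sorted(db.repertoires)[:2]
            ev, _ = random_partial_evidence(rng, db, planted)
            dets = detect_gene_variants(ev, db)
            G = build_gene_discernibility(dets, db)
            assert G.matrix.diagonal().all()
            St = build_strain_discernibility(G, dets, db)
            assert St.matrix.diagonal().all()


class TestIndiscernibleSets:
    def mk(self, index, rows):
        return StrainDiscernibilityMatrix(
            index=index, matrix=np.array(rows, dtype=bool)
        )

    def test_all_distinguishable_gives_singletons(self):
        St = self.mk(["a", "b", "c"], np.eye(3))
        sets = derive_indiscernible_sets(St)
        assert [s.members for s in sets] == [["a"], ["b"], ["c"]]
        assert all(s.performance == 1 and not s.chained for s in sets)

    def test_mutual_triple_is_one_set(self):
        St = self.mk(["a", "b", "c"], np.ones((3, 3)))
        (s,) = derive_indiscernible_sets(St)
        assert s.members == ["a", "b", "c"] and s.performance == 3
        assert not s.chained

    def test_chain_component_is_flagged(self):
        # mutual a-b and b-c but not a-c: one chained component
        M = [[1, 1, 0], [1, 1, 1], [0, 1, 1]]
        St = self.mk(["a", "b", "c"], M)
        (s,) = derive_indiscernible_sets(St)
        assert s.members == ["a", "b", "c"]
        assert s.chained

    def test_asymmetric_pairs_are_separated(self):
        # St(a,b)=1 but St(b,a)=0: not mutual, so separate sets
        St = self.mk(["a", "b"], [[1, 1], [0, 1]])
        sets = derive_indiscernible_sets(St)
        assert [s.members for s in sets] == [["a"], ["b"]]


class TestReportThresholds:
    def make_fixture(self, breadth, n_supported, n_markers=10):
        """Single strain with one group carrying n_markers; n_supported of
        them observed with the strain's state."""
        rng = np.random.default_rng(60)
        while True:
            db = random_direct_db(
                rng, n_strains=2, n_groups=1, max_variants=2,
                gene_length=120, n_subs=(n_markers, n_markers),
            )
            if len(db.groups[0].variants) == 2:
                markers = db.markers_of(db.groups[0].group_id)
                if len(markers) >= n_markers:
                    break
        group = db.groups[0]
        strain = sorted(db.repertoires)[0]
        (gid, vid), *_ = sorted(db.repertoires[strain])
        markers = db.markers_of(gid)[:n_markers]
        # restrict the db's marker list to exactly n_markers for the test
        db.markers = markers
        db._markers_by_group = {gid: markers}
        supported = {
            m.key: {m.states[vid]} for m in markers[:n_supported]
        }
        det = GeneDetection(
            group_id=gid,
            candidate_variants=[vid],
            breadth=breadth,
            observed_markers=sorted(supported),
            discarded_markers=[],
            supported_states=supported,
        )
        iset = IndiscernibleSet(members=[strain])
        return db, det, iset, strain

    @pytest.mark.parametrize(
        "breadth,n_supported,included",
        [
            (0.59, 5, False),   # coverage below the strict 60% bar
            (0.61, 5, True),    # 5 of 10 markers: frac rule (>= 50%)
            (0.61, 3, True),    # 3 > 2 absolute rule
            (0.61, 2, False),   # 2 not > 2 and 2/10 < 50%
            (0.60, 5, False),   # boundary: strictly greater required
        ],
    )
    def test_inclusion_rules(self, breadth, n_supported, included):
        db, det, iset, strain = self.make_fixture(breadth, n_supported)
        report = apply_report_thresholds([iset], [det], db)
        assert (strain in report.reported_strains()) == included

    def test_markerless_strain_reported_on_coverage_alone(self):
        # monovariant groups have no markers: presence/absence mode
        rng = np.random.default_rng(61)
        while True:
            db = random_direct_db(rng, n_strains=1, n_groups=2, max_variants=1)
            if not db.markers:
                break
        strain = sorted(db.repertoires)[0]
        dets = [
            GeneDetection(g.group_id, sorted(g.variants), 0.9, [], [], {})
            for g in db.groups
        ]
        report = apply_report_thresholds([IndiscernibleSet([strain])], dets, db)
        assert strain in report.reported_strains()


class TestWriteReport:
    def test_empty_report_is_header_only(self, tmp_path):
        from tastrain.profiler import ProfileReport

        path = tmp_path / "report.tsv"
        write_report(ProfileReport(rows=[]), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("genus\tspecies\tstrain_set")

    def test_json_roundtrip_and_determinism(self, tmp_path, rng):
        import json

        db = random_direct_db(rng, n_strains=3, n_groups=3)
        planted = sorted(db.repertoires)[:2]
        ev, _ = random_partial_evidence(rng, db, planted)
        dets = detect_gene_variants(ev, db)
        G = build_gene_discernibility(dets, db)
        St = build_strain_discernibility(G, dets, db)
        sets = derive_indiscernible_sets(St)
        report = apply_report_thresholds(sets, dets, db)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_report(report, p1, "json")
        write_report(report, p2, "json")
        assert p1.read_bytes() == p2.read_bytes()
        payload = json.loads(p1.read_text())
        assert {r["strain_set"][0] for r in payload["rows"]} <= set(db.repertoires)
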