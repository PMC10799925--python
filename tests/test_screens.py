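"""The four screening cascades and funnel bookkeeping."""

import numpy as np
import pytest

from phagescan import screens, seqcluster
from phagescan import synthetic_data as sd
from phagescan.io_formats import DomainAnnotation, ProteinRecord
from phagescan.screens import (CandidateReport, FunnelLog, ReferenceHit,
                               ScreenConfig, acr_screen,
                               counterdefense_screen,
                               defense_candidate_screen, fusion_scan)


def assert_funnel_conserved(funnel: FunnelLog):
    for name, n_in, n_ret, n_exc in funnel.stages:
        assert n_in == n_ret + n_exc
    for (_, _, prev_ret, _), (_, n_in, _, _) in zip(funnel.stages,
                                                    funnel.stages[1:]):
        assert n_in == prev_ret


class TestAcrScreen:
    def test_planted_homologs_recovered_no_decoys(self, screen_fixture):
        fx = screen_fixture
        reports, funnel = acr_screen(fx.catalog, fx.structures, fx.references,
                                     fx.reference_structures, fx.domains)
        assert_funnel_conserved(funnel)
        retained = {r.candidate_id for r in reports if r.retained}
        plants = {t.protein_id for t in fx.truth if t.expected_hit}
        assert retained == plants
        by_id = {r.candidate_id: r for r in reports}
        for t in fx.truth:
            if t.expected_hit:
                hit = by_id[t.protein_id].reference_hits[0]
                assert hit.reference_id in t.reference_ids
                assert hit.tm_shorter >= 0.6

    def test_domain_annotation_toggles_plant_off(self, screen_fixture):
        fx = screen_fixture
        plant = next(t.protein_id for t in fx.truth if t.expected_hit)
        domains = list(fx.domains) + [DomainAnnotation(plant, "planted_dom",
                                                       1e-5)]
        reports, _ = acr_screen(fx.catalog, fx.structures, fx.references,
                                fx.reference_structures, domains)
        assert plant not in {r.candidate_id for r in reports if r.retained}

    def test_oversize_plant_excluded_at_length(self, screen_fixture):
        fx = screen_fixture
        big = ProteinRecord("big_plant", "A" * 250)
        catalog = list(fx.catalog) + [big]
        structures = dict(fx.structures)
        structures["big_plant"] = fx.reference_structures["acr_ref_1"]
        reports, _ = acr_screen(catalog, structures, fx.references,
                                fx.reference_structures, fx.domains)
        rep = next(r for r in reports if r.candidate_id == "big_plant")
        assert rep.stage_verdicts[0] == ("length", False,
                                         "250 aa vs max 200")
        assert not rep.retained

    def test_best_hit_per_reference_flagged(self, screen_fixture):
        fx = screen_fixture
        reports, _ = acr_screen(fx.catalog, fx.structures, fx.references,
                                fx.reference_structures, fx.domains)
        best = [h.reference_id for r in reports for h in r.reference_hits
                if h.best_for_reference]
        assert len(best) == len(set(best))  # at most one best per reference

    def test_empty_reference_set_error(self, screen_fixture):
        fx = screen_fixture
        with pytest.raises(ValueError):
            acr_screen(fx.catalog, fx.structures, [], {}, fx.domains)

    def test_pure_filters_commute(self):
        """Length, divergence, pI and domain stages are per-candidate
        predicates, so the surviving SET is order-independent."""
        rng = np.random.default_rng(50)
        refs = [ProteinRecord("ref", sd._random_residues(80, rng))]
        recs = []
        for i in range(12):
            L = int(rng.integers(150, 260))
            acid = 0.3 if i % 2 else 0.02
            base = 0.03 if i % 2 else 0.3
            recs.append(ProteinRecord(f"c{i}",
                                      sd._random_residues(L, rng, acid, base)))
        domains = [DomainAnnotation("c3", "d", 1e-4)]
        dom_ids = {"c3"}

        def f_len(rs):
            return [r for r in rs if r.length <= 200]

        def f_div(rs):
            return seqcluster.divergence_filter(rs, refs)[0]

        def f_pi(rs):
            from phagescan.physchem import pi_filter
            return pi_filter(rs)[0]

        def f_dom(rs):
            return [r for r in rs if r.protein_id not in dom_ids]

        import itertools
        results = set()
        for perm in itertools.permutations([f_len, f_div, f_pi, f_dom]):
            out = recs
            for f in perm:
                out = f(out)
            results.add(frozenset(r.protein_id for r in out))
        assert len(results) == 1

    def test_threshold_monotonicity(self, screen_fixture):
        fx = screen_fixture
        lo, _ = acr_screen(fx.catalog, fx.structures, fx.references,
                           fx.reference_structures, fx.domains,
                           ScreenConfig(acr_tm_cut=0.6))
        hi, _ = acr_screen(fx.catalog, fx.structures, fx.references,
                           fx.reference_structures, fx.domains,
                           ScreenConfig(acr_tm_cut=0.95))
        assert {r.candidate_id for r in hi if r.retained} <= \
            {r.candidate_id for r in lo if r.retained}


@pytest.fixture(scope="module")
def mini():
    """30 intervening decoys + 1 planted 220-aa structural homolog."""
    rng = np.random.default_rng(60)
    ref_fold = sd.gen_fold("helix_hairpin", 220, seed=61)
    ref_seq = sd._random_residues(220, rng)
    ref = ProteinRecord("def_ref", ref_seq)
    ref_structs = {"def_ref": sd.StructureModel("def_ref",
                                                ref_fold.coords, ref_seq)}
    plant_seq = sd._plant_sequence(ref_seq, 220, rng, [ref])
    plant_fold = sd.perturb_structure(ref_structs["def_ref"], 0.8, True,
                                      seed=62)
    recs = [ProteinRecord("plant", plant_seq)]
    structures = {"plant": sd.StructureModel("plant", plant_fold.coords,
                                             plant_seq)}
    domains = []
    for i in range(30):
        if i < 10:
            L = int(rng.integers(80, 180))   # too short
        else:
            L = int(rng.integers(210, 250))
        seq = sd._random_residues(L, rng)
        pid = f"dec{i:02d}"
        recs.append(ProteinRecord(pid, seq))
        if i % 3 == 0:
            domains.append(DomainAnnotation(pid, "dom", 1e-6))
        else:
            structures[pid] = sd.gen_fold("coil", L,
                                          seed=int(rng.integers(2**31)))
    return recs, structures, [ref], ref_structs, domains


@pytest.fixture(scope="module")
def pair():
    """A remote counter-defense homolog pair (180 aa vs 200 aa)."""
    rng = np.random.default_rng(70)
    ref_fold = sd.gen_fold("helix_hairpin", 200, seed=71)
    ref_seq = sd._random_residues(200, rng)
    ref = ProteinRecord("anti_ref", ref_seq)
    ref_structs = {"anti_ref": sd.StructureModel("anti_ref",
                                                 ref_fold.coords,
                                                 ref_seq)}
    cand_seq = sd._plant_sequence(ref_seq, 180, rng, [ref])
    cand_fold = sd.perturb_structure(ref_structs["anti_ref"], 0.6, True,
                                     seed=72)
    cand = ProteinRecord("cand", cand_seq)
    structures = {"cand": sd.StructureModel(
        "cand", cand_fold.coords[:180].copy(), cand_seq)}
    return cand, structures, ref, ref_structs


class TestDefenseScreen:
    def test_planted_homolog_sole_hit(self, mini):
        recs, structures, refs, ref_structs, domains = mini
        reports, funnel = defense_candidate_screen(recs, structures, refs,
                                                   ref_structs, domains)
        assert_funnel_conserved(funnel)
        assert {r.candidate_id for r in reports if r.retained} == {"plant"}

    def test_short_plant_excluded_at_length(self, mini):
        recs, structures, refs, ref_structs, domains = mini
        short_seq = recs[0].sequence[:150]
        recs2 = [ProteinRecord("short_plant", short_seq)] + recs[1:]
        structures2 = dict(structures)
        structures2["short_plant"] = sd.StructureModel(
            "short_plant", structures["plant"].coords[:150].copy(),
            short_seq)
        reports, _ = defense_candidate_screen(recs2, structures2, refs,
                                              ref_structs, domains)
        rep = next(r for r in reports if r.candidate_id == "short_plant")
        assert not rep.retained
        assert ("length", False, "150 aa vs min 200") in rep.stage_verdicts

    def test_raising_tm_cut_gives_zero_hits(self, mini):
        recs, structures, refs, ref_structs, domains = mini
        reports, _ = defense_candidate_screen(
            recs, structures, refs, ref_structs, domains,
            ScreenConfig(defense_tm_cut=0.999))
        assert not [r for r in reports if r.retained]


class TestCounterDefenseScreen:
    def test_remote_homolog_retained(self, pair):
        cand, structures, ref, ref_structs = pair
        out = counterdefense_screen([cand], structures, [ref], ref_structs)
        assert len(out) == 1
        p = out[0]
        assert p.tm_ok and p.len_ok and p.divergent and p.retained
        assert p.len_ratio == pytest.approx(0.9)

    def test_truncated_candidate_fails_length_ratio(self, pair):
        cand, structures, ref, ref_structs = pair
        short = ProteinRecord("short", cand.sequence[:120])
        structs = {"short": sd.StructureModel(
            "short", structures["cand"].coords[:120].copy(),
            short.sequence)}
        out = counterdefense_screen([short], structs, [ref], ref_structs)
        assert not out[0].len_ok and not out[0].retained
        assert out[0].len_ratio == pytest.approx(0.6)

    def test_sequence_similar_pair_rejected(self, pair):
        cand, structures, ref, ref_structs = pair
        twin = ProteinRecord("twin", ref.sequence)
        structs = {"twin": ref_structs["anti_ref"]}
        out = counterdefense_screen([twin], structs, [ref], ref_structs)
        assert out[0].tm_ok and out[0].len_ok
        assert not out[0].divergent and not out[0].retained


class TestFusionScan:
    def _report(self, cid, hits):
        rep = CandidateReport(cid)
        rep.reference_hits = hits
        return rep

    def _hit(self, ref, tm, indices):
        return ReferenceHit(ref, tm, tm, tm, 1.0, 0.1, 5.0,
                            query_indices=frozenset(indices))

    def test_concatenated_fusion_detected(self):
        """A candidate built from two reference folds laid end to end."""
        f1 = sd.gen_fold("helix_hairpin", 60, seed=80)
        f2 = sd.gen_fold("strand", 50, seed=81)
        ref1 = sd.StructureModel("acrA", f1.coords, f1.residues)
        ref2 = sd.StructureModel("acrB", f2.coords, f2.residues)
        shift = f1.coords[-1] + np.array([10.0, 0, 0])
        fused_coords = np.vstack([f1.coords,
                                  f2.coords - f2.coords[0] + shift])
        fused = sd.StructureModel("fused", fused_coords,
                                  f1.residues + f2.residues)
        fused = sd.perturb_structure(fused, 0.5, True, seed=82)
        from phagescan.structalign import structure_align
        hits = []
        for ref in (ref1, ref2):
            aln = structure_align(fused, ref)
            assert aln.tm_shorter >= 0.6
            hits.append(self._hit(ref.protein_id, aln.tm_shorter,
                                  [i for i, _ in aln.pairs]))
        rep = self._report("fused", hits)
        out = fusion_scan([rep])
        assert len(out) == 1
        assert out[0].putative_fusion and out[0].jaccard < 0.25

    def test_single_hit_not_reported(self):
        rep = self._report("c", [self._hit("r1", 0.8, range(50))])
        assert fusion_scan([rep]) == []

    def test_same_reference_twice_not_reported(self):
        rep = self._report("c", [self._hit("r1", 0.8, range(50)),
                                 self._hit("r1", 0.7, range(40, 90))])
        assert fusion_scan([rep]) == []

    def test_overlapping_segments_not_flagged_fusion(self):
        rep = self._report("c", [self._hit("r1", 0.8, range(50)),
                                 self._hit("r2", 0.7, range(5, 55))])
        out = fusion_scan([rep])
        assert len(out) == 1
        assert not out[0].putative_fusion and out[0].jaccard > 0.25


class TestFunnelLog:
    def test_conservation_enforced(self):
        f = FunnelLog()
        f.add("a", 10, 7)
        with pytest.raises(ValueError):
            f.add("b", 9, 5)  # breaks chaining
        with pytest.raises(ValueError):
            f.add("b", 7, 8)  # retained > in

    def test_write_tsv(self, tmp_path):
        f = FunnelLog()
        f.add("a", 10, 7)
        f.add("b", 7, 2)
        p = tmp_path / "funnel.tsv"
        f.write_tsv(p)
        lines = p.read_text().strip().split("\n")
        assert lines[1] == "a\t10\t7\t3"
        assert lines[2] == "b\t7\t2\t5"
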