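"""The four screening decision procedures, composed from the primitives.

Each screen is an ordered cascade of filters (a "funnel") with full
per-stage accounting:

* :func:`acr_screen` — anti-CRISPR discovery: small (≤ 200 aa), redundancy-
  reduced (95% identity clusters), sequence-divergent from known Acrs,
  acidic (pI ≤ 7), domain-less candidates whose predicted fold matches a
  reference Acr at TM ≥ 0.6 (shorter-chain normalization).
* :func:`defense_candidate_screen` — single-gene defense discovery on
  proteins mined from defense islands: 50% identity clusters, no conserved-
  domain hit, ≥ 200 aa, fold match to a reference single-gene system at
  TM > 0.65, and no detectable sequence similarity to the references.
* :func:`counterdefense_screen` — remote homologs of known counter-defense
  proteins: TM (shorter) > 0.6, shorter chain ≥ 70% of the longer, and no
  detectable sequence similarity.
* :func:`fusion_scan` — candidates hitting two distinct references; when
  the two reference hits cover disjoint candidate segments (Jaccard of the
  aligned residue sets < 0.25) the candidate is flagged a putative fusion.

Structures are aligned for cluster centroids only; members inherit their
centroid's verdict through the report's ``member_ids``. The funnel
conserves counts at every stage: n_in = n_retained + n_excluded, and each
stage's input is the previous stage's retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import physchem, seqcluster, structalign
from .io_formats import DomainAnnotation, ProteinRecord, StructureModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """All screening thresholds in one visible, versionable place."""

    acr_max_len: int = 200
    acr_cluster_id: float = 0.95
    defense_cluster_id: float = 0.50
    max_ref_identity: float = 0.30
    evalue_cut: float = 0.1
    max_pi: float = 7.0
    domain_evalue_cut: float = 0.01
    acr_tm_cut: float = 0.6
    defense_tm_cut: float = 0.65
    counter_tm_cut: float = 0.6
    counter_len_ratio: float = 0.70
    defense_min_len: int = 200
    island_min_gap: int = 1000
    island_max_gap: int = 15000
    fusion_jaccard_cut: float = 0.25
    tm_normalization: str = "shorter"   # which TM the similarity calls use

    def __post_init__(self) -> None:
        for name in ("acr_cluster_id", "defense_cluster_id",
                     "max_ref_identity", "acr_tm_cut", "defense_tm_cut",
                     "counter_tm_cut", "counter_len_ratio"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.acr_max_len <= 0 or self.defense_min_len <= 0:
            raise ValueError("length thresholds must be positive")


DEFAULT_SCREEN = ScreenConfig()


@dataclass
class ReferenceHit:
    reference_id: str
    tm_query: float
    tm_target: float
    tm_shorter: float
    rmsd: float
    identity: float
    evalue: float
    query_indices: frozenset[int] = frozenset()
    best_for_reference: bool = False


@dataclass
class CandidateReport:
    """A screened candidate with per-filter provenance and reference hits."""

    candidate_id: str
    stage_verdicts: list[tuple[str, bool, str]] = field(default_factory=list)
    reference_hits: list[ReferenceHit] = field(default_factory=list)
    member_ids: list[str] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return all(ok for _, ok, _ in self.stage_verdicts) and bool(
            self.reference_hits)

    @property
    def best_reference(self) -> str | None:
        if not self.reference_hits:
            return None
        return max(self.reference_hits, key=lambda h: h.tm_shorter).reference_id


@dataclass
class FunnelLog:
    """Ordered per-stage (name, n_in, n_retained, n_excluded) counts."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_retained: int) -> None:
        if self.stages and n_in != self.stages[-1][2]:
            raise ValueError(
                f"funnel break at {name!r}: n_in {n_in} != previous retained "
                f"{self.stages[-1][2]}")
        if not (0 <= n_retained <= n_in):
            raise ValueError(f"stage {name!r}: retained {n_retained} of {n_in}")
        self.stages.append((name, n_in, n_retained, n_in - n_retained))
        logger.info("funnel %-14s in=%d retained=%d excluded=%d",
                    name, n_in, n_retained, n_in - n_retained)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tn_retained\tn_excluded\n")
            for name, n_in, n_ret, n_exc in self.stages:
                fh.write(f"{name}\t{n_in}\t{n_ret}\t{n_exc}\n")


def _tm_call(aln: structalign.StructuralAlignment, config: ScreenConfig) -> float:
    return {"shorter": aln.tm_shorter, "query": aln.tm_query,
            "target": aln.tm_target}[config.tm_normalization]


def _domain_hits(domains: Sequence[DomainAnnotation],
                 cut: float) -> set[str]:
    return {d.protein_id for d in domains if d.evalue <= cut}


def _align_and_report(candidates: Sequence[ProteinRecord],
                      structures: Mapping[str, StructureModel],
                      refs: Sequence[ProteinRecord],
                      ref_structures: Mapping[str, StructureModel],
                      tm_cut: float, strict: bool,
                      reports: dict[str, CandidateReport],
                      config: ScreenConfig,
                      align_config: structalign.AlignConfig,
                      ) -> list[ProteinRecord]:
    """Structure-align candidates against every reference; a hit needs
    TM ≥ tm_cut (or > when ``strict``). Returns candidates with ≥ 1 hit."""
    survivors: list[ProteinRecord] = []
    for cand in candidates:
        model = structures[cand.protein_id]
        hits: list[ReferenceHit] = []
        for ref in refs:
            aln = structalign.structure_align(model,
                                              ref_structures[ref.protein_id],
                                              align_config)
            tm = _tm_call(aln, config)
            passed = tm > tm_cut if strict else tm >= tm_cut
            if passed:
                seq_aln = seqcluster.local_align(
                    cand.sequence, ref.sequence,
                    a_id=cand.protein_id, b_id=ref.protein_id)
                hits.append(ReferenceHit(
                    reference_id=ref.protein_id,
                    tm_query=aln.tm_query, tm_target=aln.tm_target,
                    tm_shorter=aln.tm_shorter, rmsd=aln.rmsd,
                    identity=seq_aln.identity, evalue=seq_aln.evalue,
                    query_indices=frozenset(i for i, _ in aln.pairs),
                ))
        hits.sort(key=lambda h: -h.tm_shorter)
        rep = reports[cand.protein_id]
        rep.reference_hits = hits
        rep.stage_verdicts.append(
            ("structure_tm", bool(hits),
             f"{len(hits)} reference hit(s) at TM "
             f"{'>' if strict else '≥'} {tm_cut}"))
        if hits:
            survivors.append(cand)
    return survivors


def _flag_best_per_reference(reports: Mapping[str, CandidateReport]) -> None:
    best: dict[str, tuple[float, ReferenceHit]] = {}
    for rep in reports.values():
        for hit in rep.reference_hits:
            cur = best.get(hit.reference_id)
            if cur is None or hit.tm_shorter > cur[0]:
                best[hit.reference_id] = (hit.tm_shorter, hit)
    for _, hit in best.values():
        hit.best_for_reference = True


def acr_screen(catalog: Sequence[ProteinRecord],
               structures: Mapping[str, StructureModel],
               acr_refs: Sequence[ProteinRecord],
               acr_ref_structures: Mapping[str, StructureModel],
               domains: Sequence[DomainAnnotation],
               config: ScreenConfig = DEFAULT_SCREEN,
               align_config: structalign.AlignConfig = structalign.DEFAULT_CONFIG,
               ) -> tuple[list[CandidateReport], FunnelLog]:
    """The anti-CRISPR discovery cascade.

    Stages: (1) length ≤ 200 aa; (2) 95%-identity clustering, centroids
    proceed; (3) sequence-divergence gate against the reference Acrs;
    (4) pI ≤ 7; (5) no conserved-domain hit at E ≤ 0.01; (6) candidates
    lacking a structure are excluded (logged, not an error); (7) structural
    alignment against every reference, hit at TM ≥ 0.6; finally the best
    hit per reference is flagged. Returns per-candidate reports and the
    funnel log.
    """
    if not acr_refs:
        raise ValueError("empty Acr reference set")
    funnel = FunnelLog()
    reports = {r.protein_id: CandidateReport(r.protein_id) for r in catalog}

    def verdict(recs, stage, passed_ids, detail_fn) -> None:
        for r in recs:
            ok = r.protein_id in passed_ids
            reports[r.protein_id].stage_verdicts.append(
                (stage, ok, detail_fn(r)))

    # 1. length
    short = [r for r in catalog if r.length <= config.acr_max_len]
    verdict(catalog, "length", {r.protein_id for r in short},
            lambda r: f"{r.length} aa vs max {config.acr_max_len}")
    funnel.add("length", len(catalog), len(short))

    # 2. redundancy clustering; centroids proceed
    clusters = seqcluster.greedy_cluster(short, config.acr_cluster_id) \
        if short else []
    by_id = {r.protein_id: r for r in short}
    centroids = [by_id[c.centroid_id] for c in clusters]
    for c in clusters:
        reports[c.centroid_id].member_ids = list(c.member_ids)
        for mid in c.member_ids:
            ok = mid == c.centroid_id
            reports[mid].stage_verdicts.append(
                ("cluster", ok,
                 f"cluster {c.cluster_id}, centroid {c.centroid_id}"))
    funnel.add("cluster", len(short), len(centroids))

    # 3. sequence divergence from known Acrs
    retained, excluded = seqcluster.divergence_filter(
        centroids, acr_refs, config.max_ref_identity, config.evalue_cut)
    exc_map = {r.protein_id: e for r, e in excluded}
    verdict(centroids, "divergence", {r.protein_id for r in retained},
            lambda r: (f"excluded by {exc_map[r.protein_id].criterion} vs "
                       f"{exc_map[r.protein_id].reference_id}"
                       if r.protein_id in exc_map else "divergent"))
    funnel.add("divergence", len(centroids), len(retained))

    # 4. acidity
    acidic, basic = physchem.pi_filter(retained, config.max_pi)
    verdict(retained, "pi", {r.protein_id for r in acidic},
            lambda r: f"pI {physchem.isoelectric_point(r.sequence):.2f}")
    funnel.add("pi", len(retained), len(acidic))

    # 5. no conserved-domain hit
    dom = _domain_hits(domains, config.domain_evalue_cut)
    undomained = [r for r in acidic if r.protein_id not in dom]
    verdict(acidic, "domain", {r.protein_id for r in undomained},
            lambda r: "CDD hit" if r.protein_id in dom else "no CDD hit")
    funnel.add("domain", len(acidic), len(undomained))

    # 6. structure availability
    with_struct = [r for r in undomained if r.protein_id in structures]
    verdict(undomained, "no_structure", {r.protein_id for r in with_struct},
            lambda r: "structure available" if r.protein_id in structures
            else "no structure predicted")
    funnel.add("no_structure", len(undomained), len(with_struct))

    # 7. structural similarity to reference Acrs
    survivors = _align_and_report(with_struct, structures, acr_refs,
                                  acr_ref_structures, config.acr_tm_cut,
                                  strict=False, reports=reports,
                                  config=config, align_config=align_config)
    funnel.add("structure_tm", len(with_struct), len(survivors))
    _flag_best_per_reference(reports)
    return list(reports.values()), funnel


def defense_candidate_screen(intervening: Sequence[ProteinRecord],
                             structures: Mapping[str, StructureModel],
                             defense_refs: Sequence[ProteinRecord],
                             defense_ref_structures: Mapping[str, StructureModel],
                             domains: Sequence[DomainAnnotation],
                             config: ScreenConfig = DEFAULT_SCREEN,
                             align_config: structalign.AlignConfig = structalign.DEFAULT_CONFIG,
                             ) -> tuple[list[CandidateReport], FunnelLog]:
    """The single-gene defense-candidate cascade on island-mined proteins.

    Stages: (1) 50%-identity clustering; (2) no conserved-domain hit;
    (3) length ≥ 200 aa (single-gene defense proteins tend to be large);
    (4) structure availability; (5) structural alignment against reference
    single-gene systems, hit at TM > 0.65; (6) sequence-divergence check
    against the same references (remote homologs only).
    """
    if not defense_refs:
        raise ValueError("empty defense reference set")
    funnel = FunnelLog()
    reports = {r.protein_id: CandidateReport(r.protein_id) for r in intervening}

    clusters = seqcluster.greedy_cluster(intervening, config.defense_cluster_id) \
        if intervening else []
    by_id = {r.protein_id: r for r in intervening}
    centroids = [by_id[c.centroid_id] for c in clusters]
    for c in clusters:
        reports[c.centroid_id].member_ids = list(c.member_ids)
        for mid in c.member_ids:
            reports[mid].stage_verdicts.append(
                ("cluster", mid == c.centroid_id,
                 f"cluster {c.cluster_id}, centroid {c.centroid_id}"))
    funnel.add("cluster", len(intervening), len(centroids))

    dom = _domain_hits(domains, config.domain_evalue_cut)
    undomained = [r for r in centroids if r.protein_id not in dom]
    for r in centroids:
        reports[r.protein_id].stage_verdicts.append(
            ("domain", r.protein_id not in dom,
             "CDD hit" if r.protein_id in dom else "no CDD hit"))
    funnel.add("domain", len(centroids), len(undomained))

    long_enough = [r for r in undomained if r.length >= config.defense_min_len]
    for r in undomained:
        reports[r.protein_id].stage_verdicts.append(
            ("length", r.length >= config.defense_min_len,
             f"{r.length} aa vs min {config.defense_min_len}"))
    funnel.add("length", len(undomained), len(long_enough))

    with_struct = [r for r in long_enough if r.protein_id in structures]
    for r in long_enough:
        reports[r.protein_id].stage_verdicts.append(
            ("no_structure", r.protein_id in structures,
             "structure available" if r.protein_id in structures
             else "no structure predicted"))
    funnel.add("no_structure", len(long_enough), len(with_struct))

    survivors = _align_and_report(with_struct, structures, defense_refs,
                                  defense_ref_structures,
                                  config.defense_tm_cut, strict=True,
                                  reports=reports, config=config,
                                  align_config=align_config)
    funnel.add("structure_tm", len(with_struct), len(survivors))

    retained, excluded = seqcluster.divergence_filter(
        survivors, defense_refs, config.max_ref_identity, config.evalue_cut)
    exc_map = {r.protein_id: e for r, e in excluded}
    for r in survivors:
        ok = r.protein_id not in exc_map
        reports[r.protein_id].stage_verdicts.append(
            ("divergence", ok,
             f"excluded by {exc_map[r.protein_id].criterion}"
             if not ok else "divergent"))
        if not ok:
            reports[r.protein_id].reference_hits = []
    funnel.add("divergence", len(survivors), len(retained))
    _flag_best_per_reference(reports)
    return list(reports.values()), funnel


@dataclass
class CounterDefensePair:
    """One candidate/reference pair with the three retention criteria."""

    candidate_id: str
    reference_id: str
    tm_shorter: float
    len_ratio: float
    identity: float
    evalue: float
    tm_ok: bool
    len_ok: bool
    divergent: bool

    @property
    def retained(self) -> bool:
        return self.tm_ok and self.len_ok and self.divergent


def counterdefense_screen(candidates: Sequence[ProteinRecord],
                          structures: Mapping[str, StructureModel],
                          refs: Sequence[ProteinRecord],
                          ref_structures: Mapping[str, StructureModel],
                          config: ScreenConfig = DEFAULT_SCREEN,
                          align_config: structalign.AlignConfig = structalign.DEFAULT_CONFIG,
                          ) -> list[CounterDefensePair]:
    """Remote-homolog calling against known counter-defense proteins.

    A pair is retained iff TM (shorter) > 0.6, the shorter chain is at
    least 70% the length of the longer, and the sequences show no
    detectable similarity (identity ≤ 30% and E-value ≥ 0.1). All pairs
    are reported with their per-criterion outcomes.
    """
    db_n = sum(r.length for r in refs) or 1
    out: list[CounterDefensePair] = []
    for cand in candidates:
        for ref in refs:
            aln = structalign.structure_align(
                structures[cand.protein_id], ref_structures[ref.protein_id],
                align_config)
            tm = _tm_call(aln, config)
            shorter = min(cand.length, ref.length)
            longer = max(cand.length, ref.length)
            seq_aln = seqcluster.local_align(cand.sequence, ref.sequence,
                                             db_residues=db_n)
            similar = ((seq_aln.n_columns >= 0.5 * shorter
                        and seq_aln.evalue <= 10.0
                        and seq_aln.identity > config.max_ref_identity)
                       or seq_aln.evalue < config.evalue_cut)
            out.append(CounterDefensePair(
                candidate_id=cand.protein_id, reference_id=ref.protein_id,
                tm_shorter=tm, len_ratio=shorter / longer,
                identity=seq_aln.identity, evalue=seq_aln.evalue,
                tm_ok=tm > config.counter_tm_cut,
                len_ok=shorter >= config.counter_len_ratio * longer,
                divergent=not similar,
            ))
    return out


@dataclass
class FusionCandidate:
    candidate_id: str
    reference_ids: tuple[str, str]
    intervals: tuple[tuple[int, int], tuple[int, int]]  # candidate-side spans
    jaccard: float
    putative_fusion: bool


def fusion_scan(reports: Sequence[CandidateReport],
                config: ScreenConfig = DEFAULT_SCREEN) -> list[FusionCandidate]:
    """Find candidates structurally similar to two distinct references.

    For every pair of distinct-reference hits at TM ≥ the Acr cut, the
    candidate-side aligned residue sets are compared; a Jaccard overlap
    below the configured cut (default 0.25) marks the candidate a putative
    fusion of the two reference folds.
    """
    out: list[FusionCandidate] = []
    for rep in reports:
        hits = [h for h in rep.reference_hits
                if h.tm_shorter >= config.acr_tm_cut and h.query_indices]
        best_by_ref: dict[str, ReferenceHit] = {}
        for h in hits:
            cur = best_by_ref.get(h.reference_id)
            if cur is None or h.tm_shorter > cur.tm_shorter:
                best_by_ref[h.reference_id] = h
        refs = sorted(best_by_ref)
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                a, b = best_by_ref[refs[i]], best_by_ref[refs[j]]
                inter = len(a.query_indices & b.query_indices)
                union = len(a.query_indices | b.query_indices)
                jac = inter / union if union else 0.0
                out.append(FusionCandidate(
                    candidate_id=rep.candidate_id,
                    reference_ids=(refs[i], refs[j]),
                    intervals=((min(a.query_indices), max(a.query_indices)),
                               (min(b.query_indices), max(b.query_indices))),
                    jaccard=jac,
                    putative_fusion=jac < config.fusion_jaccard_cut,
                ))
    return out
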