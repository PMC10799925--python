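"""Defense-island mining: inter-system regions, intervening proteins,
marker prevalence, and gene neighborhoods.

Anti-phage defense systems cluster in genomic "defense islands", so a gene
sandwiched between two annotated systems is a strong candidate for a new
defense gene. The miner takes located systems on each contig, forms a
region for every ADJACENT pair whose edge-to-edge gap lies within a window
(1-15 kb by default, inclusive at both bounds), and collects the genes
fully contained in the open interval between the two system footprints.
Only adjacent pairs form regions — a third system inside the gap would
split it — so no intervening gene is double-counted. Coordinates are
1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import DefenseSystemAnnotation, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class InterSystemRegion:
    """The gap between two adjacent defense systems on one contig.

    ``gap_bp`` is the edge-to-edge distance ``right.start - left.end - 1``,
    i.e. the number of basepairs strictly between the two footprints.
    """

    genome_id: str
    contig_id: str
    left_system: DefenseSystemAnnotation
    right_system: DefenseSystemAnnotation
    intervening_protein_ids: list[str]

    @property
    def gap_bp(self) -> int:
        return self.right_system.start - self.left_system.end - 1


@dataclass(frozen=True)
class PrevalenceResult:
    """How often a marker gene co-occurs with a defense system across
    genomes."""

    system_name: str
    marker_id: str
    carriers: int
    total: int

    @property
    def percent(self) -> float:
        return round(100.0 * self.carriers / self.total, 2)


def find_intersystem_regions(systems: Sequence[DefenseSystemAnnotation],
                             genes: Sequence[ProteinRecord],
                             min_gap: int = 1000,
                             max_gap: int = 15000) -> list[InterSystemRegion]:
    """Mine adjacent system pairs with an in-window gap and collect the
    genes fully inside the open interval between them.

    Systems are sorted by start within each contig; a gene counts as
    intervening only when both its ends lie strictly between the left
    system's end and the right system's start (boundary genes likely belong
    to the systems themselves). Strand is ignored. Genes on contigs with no
    annotated systems are skipped with a warning.
    """
    by_contig: dict[tuple[str, str], list[DefenseSystemAnnotation]] = {}
    for s in systems:
        by_contig.setdefault((s.genome_id, s.contig_id), []).append(s)
    genes_by_contig: dict[str, list[ProteinRecord]] = {}
    known_contigs = {c for _, c in by_contig}
    for g in genes:
        if g.contig_id is None or g.start is None:
            continue
        if g.contig_id not in known_contigs:
            logger.warning("gene %s on unannotated contig %s; skipped",
                           g.protein_id, g.contig_id)
            continue
        genes_by_contig.setdefault(g.contig_id, []).append(g)

    regions: list[InterSystemRegion] = []
    for (genome_id, contig_id), anns in sorted(by_contig.items()):
        anns = sorted(anns, key=lambda a: (a.start, a.end))
        contig_genes = genes_by_contig.get(contig_id, [])
        for left, right in zip(anns, anns[1:]):
            gap = right.start - left.end - 1
            if gap < min_gap or gap > max_gap:
                continue
            inside = [g.protein_id for g in contig_genes
                      if g.start > left.end and g.end < right.start]
            regions.append(InterSystemRegion(
                genome_id=genome_id, contig_id=contig_id,
                left_system=left, right_system=right,
                intervening_protein_ids=sorted(
                    inside, key=lambda pid: next(
                        g.start for g in contig_genes if g.protein_id == pid)),
            ))
    return regions


def extract_intervening_proteins(regions: Iterable[InterSystemRegion],
                                 catalog: Mapping[str, ProteinRecord]
                                 ) -> list[ProteinRecord]:
    """Deduplicated intervening records in first-seen order, ready for
    50%-identity clustering. Unresolvable ids are warned and counted."""
    seen: set[str] = set()
    out: list[ProteinRecord] = []
    n_missing = 0
    for region in regions:
        for pid in region.intervening_protein_ids:
            if pid in seen:
                continue
            seen.add(pid)
            rec = catalog.get(pid)
            if rec is None:
                n_missing += 1
                logger.warning("intervening protein %s not in catalog; skipped", pid)
                continue
            out.append(rec)
    if n_missing:
        logger.warning("%d intervening protein id(s) unresolvable", n_missing)
    return out


def prevalence(systems: Sequence[DefenseSystemAnnotation],
               marker_hits: Iterable[str], system_name: str,
               marker_id: str = "marker") -> PrevalenceResult:
    """Fraction of system-bearing genomes that also carry the marker.

    ``total`` counts distinct genomes with at least one annotation of
    ``system_name``; ``carriers`` counts those also present in
    ``marker_hits``. Genomes carrying the marker without the system are
    excluded from both counts. Raises when no genome carries the system
    (the rate is undefined).
    """
    with_system = {s.genome_id for s in systems if s.system_name == system_name}
    if not with_system:
        raise ValueError(f"no genome carries system {system_name!r}")
    carriers = len(with_system & set(marker_hits))
    return PrevalenceResult(system_name=system_name, marker_id=marker_id,
                            carriers=carriers, total=len(with_system))


def gene_neighborhood(marker_id: str, genes: Sequence[ProteinRecord],
                      window_bp: int = 10000
                      ) -> list[tuple[ProteinRecord, int]]:
    """Genes overlapping a window around the marker, as (record, offset)
    sorted by start; offsets are signed, relative to the marker's start.

    Supports locus diagrams of the marker's genomic context. A window of 0
    returns only genes overlapping the marker itself.
    """
    marker = next((g for g in genes if g.protein_id == marker_id), None)
    if marker is None:
        raise ValueError(f"marker {marker_id!r} not found")
    if marker.start is None or marker.contig_id is None:
        raise ValueError(f"marker {marker_id!r} has no coordinates")
    lo, hi = marker.start - window_bp, marker.end + window_bp
    hits = [g for g in genes
            if g.contig_id == marker.contig_id and g.start is not None
            and g.end >= lo and g.start <= hi]
    hits.sort(key=lambda g: (g.start, g.protein_id))
    return [(g, g.start - marker.start) for g in hits]
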