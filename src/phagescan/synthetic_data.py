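"""Seeded generators for every input class the pipeline consumes.

Desk-scale stand-ins for the real inputs (viral protein catalogs, predicted
monomer structures, defense-system annotations on metagenome-assembled
genomes), built so that every planted signal has a known ground truth:

* ideal-geometry CA folds (helix / strand / helix hairpin / random coil)
  whose cross-archetype TM-scores are low by construction;
* structural homologs made by Gaussian coordinate noise plus a random
  rigid transform, which degrades TM monotonically with sigma;
* sequences with controlled acid/base composition and controlled pairwise
  identity (for clustering and the sequence-divergence gate);
* annotated genomes with planted defense systems, inter-system gaps in and
  out of the mining window, and a rare marker gene planted at an exact
  prevalence (carrier count by rounding, not Bernoulli, so recovery is
  exact).

All generators are deterministic: one seed, byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import physchem, seqcluster
from .io_formats import (DefenseSystemAnnotation, DomainAnnotation,
                         ProteinRecord, StructureModel, write_ca_trace,
                         write_defense_table, write_domain_table, write_fasta)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_ACIDIC = "DE"
_BASIC = "KR"


# ---------------------------------------------------------------------------
# Folds

def _random_residues(length: int, rng: np.random.Generator,
                     acid_fraction: float = 0.0,
                     base_fraction: float = 0.0) -> str:
    """Sequence with a controlled share of acidic (D/E) and basic (K/R)
    residues; the remainder is uniform over the other 16 amino acids."""
    others = [a for a in _AA20 if a not in _ACIDIC + _BASIC]
    out = []
    for _ in range(length):
        u = rng.random()
        if u < acid_fraction:
            out.append(_ACIDIC[rng.integers(2)])
        elif u < acid_fraction + base_fraction:
            out.append(_BASIC[rng.integers(2)])
        else:
            out.append(others[rng.integers(len(others))])
    return "".join(out)


def _helix(length: int, z0: float = 0.0, direction: float = 1.0,
           x0: float = 0.0) -> np.ndarray:
    # idealised CA helix: radius 2.3 Å, rise 1.5 Å/residue, 100°/residue
    i = np.arange(length)
    theta = np.deg2rad(100.0) * i
    return np.stack([
        x0 + 2.3 * np.cos(theta),
        2.3 * np.sin(theta),
        z0 + direction * 1.5 * i,
    ], axis=1)


def _strand(length: int) -> np.ndarray:
    # near-linear extended trace: 3.5 Å/residue with a 0.5 Å zig-zag
    i = np.arange(length)
    return np.stack([
        3.5 * i,
        0.5 * (-1.0) ** i,
        np.zeros(length),
    ], axis=1)


def _helix_hairpin(length: int) -> np.ndarray:
    n1 = (length - 4) // 2
    n2 = length - 4 - n1
    up = _helix(n1)
    down = _helix(n2, z0=up[-1, 2], direction=-1.0, x0=7.0)
    # 4-residue turn by linear interpolation between the two helix ends
    a, b = up[-1], down[0]
    turn = np.stack([a + (b - a) * k / 5.0 for k in range(1, 5)])
    return np.vstack([up, turn, down])


def _coil(length: int, rng: np.random.Generator) -> np.ndarray:
    # seeded self-avoiding random walk, 3.8 Å steps, 3.4 Å exclusion
    pts = [np.zeros(3)]
    while len(pts) < length:
        placed = False
        for _ in range(200):
            v = rng.normal(size=3)
            v *= 3.8 / np.linalg.norm(v)
            cand = pts[-1] + v
            d = np.linalg.norm(np.array(pts) - cand, axis=1)
            if np.all(d[:-1] > 3.4) if len(pts) > 1 else True:
                pts.append(cand)
                placed = True
                break
        if not placed:  # walk trapped itself; restart from a fresh direction
            pts = pts[: max(1, len(pts) - 5)]
    return np.stack(pts[:length])


ARCHETYPES = ("helix", "strand", "helix_hairpin", "coil")


def gen_fold(archetype: str, length: int, seed: int) -> StructureModel:
    """Ideal-geometry CA trace of the requested archetype.

    Consecutive CA-CA distances fall in [3.6, 4.0] Å except in hairpin-turn
    regions. Same archetype/length/seed -> identical coordinates.
    """
    if length < 10:
        raise ValueError("fold length must be ≥ 10")
    rng = np.random.default_rng(seed)
    if archetype == "helix":
        coords = _helix(length)
    elif archetype == "strand":
        coords = _strand(length)
    elif archetype == "helix_hairpin":
        coords = _helix_hairpin(length)
    elif archetype == "coil":
        coords = _coil(length, rng)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    residues = _random_residues(length, rng)
    return StructureModel(protein_id=f"{archetype}_{length}_{seed}",
                          coords=coords, residues=residues)


def perturb_structure(model: StructureModel, sigma: float, rigid: bool,
                      seed: int) -> StructureModel:
    """Gaussian coordinate noise (sigma per axis) plus an optional random
    proper rigid transform; residue codes preserved."""
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    rng = np.random.default_rng(seed)
    coords = model.coords + rng.normal(scale=sigma, size=model.coords.shape) \
        if sigma > 0 else model.coords.copy()
    if rigid:
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20.0, 20.0, size=3)
        coords = coords @ R.T + t
    return StructureModel(protein_id=f"{model.protein_id}_perturbed",
                          coords=coords, residues=model.residues,
                          plddt=model.plddt)


def mutate_to_identity(sequence: str, target_identity: float, seed: int,
                       scoring: seqcluster.ScoringScheme = seqcluster.DEFAULT_SCORING
                       ) -> str:
    """Substitute random positions until the global-alignment identity to
    the original drops to ``target_identity`` or below; length preserved.

    Random protein sequences bottom out near ~5% identity, so targets below
    0.05 are rejected.
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity < 0.05:
        raise ValueError("identity targets below the ~5% random floor are unreachable")
    if target_identity == 1.0:
        return sequence
    rng = np.random.default_rng(seed)
    seq = list(sequence)
    for _ in range(200 * len(sequence)):
        aln = seqcluster.global_align("".join(seq), sequence, scoring)
        if aln.identity <= target_identity:
            return "".join(seq)
        for _ in range(max(1, len(seq) // 20)):
            pos = int(rng.integers(len(seq)))
            choices = [a for a in _AA20 if a != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
    raise RuntimeError("mutation did not reach the identity target")


# ---------------------------------------------------------------------------
# Screen fixture (Acr-style catalog with planted structural homologs)

@dataclass(frozen=True)
class PlantSpec:
    """One planted structural homolog of a reference."""

    reference_id: str
    target_identity: float = 0.15
    sigma: float = 0.8
    rigid: bool = True


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic catalog and genome generators."""

    seed: int = 0
    n_decoys: int = 50
    length_range: tuple[int, int] = (60, 180)
    planted: list[PlantSpec] = field(default_factory=list)
    acid_fraction: float = 0.25
    base_fraction: float = 0.05
    genomes: int = 400
    systems_per_genome: tuple[int, int] = (2, 4)
    gap_inside_prob: float = 0.6
    marker_prevalence: float = 0.05

    def __post_init__(self) -> None:
        for f in (self.acid_fraction, self.base_fraction,
                  self.gap_inside_prob, self.marker_prevalence):
            if not (0 <= f <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        for spec in self.planted:
            if spec.sigma < 0:
                raise ValueError("sigma must be ≥ 0")


@dataclass
class TruthRow:
    protein_id: str
    kind: str          # plant / decoy / fusion_plant
    expected_hit: bool
    fails_at: str | None = None   # stage name a decoy is built to fail
    reference_ids: tuple[str, ...] = ()


@dataclass
class ScreenFixture:
    """Synthetic Acr-screen input with its ground truth."""

    catalog: list[ProteinRecord]
    structures: dict[str, StructureModel]
    domains: list[DomainAnnotation]
    references: list[ProteinRecord]
    reference_structures: dict[str, StructureModel]
    truth: list[TruthRow]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "pdb").mkdir(parents=True, exist_ok=True)
        (outdir / "refs_pdb").mkdir(parents=True, exist_ok=True)
        write_fasta(self.catalog, outdir / "catalog.fasta")
        write_fasta(self.references, outdir / "references.fasta")
        write_domain_table(self.domains, outdir / "domains.tsv")
        for pid, model in sorted(self.structures.items()):
            write_ca_trace(model, outdir / "pdb" / f"{pid}.pdb")
        for pid, model in sorted(self.reference_structures.items()):
            write_ca_trace(model, outdir / "refs_pdb" / f"{pid}.pdb")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("protein_id\tkind\texpected_hit\tfails_at\treference_ids\n")
            for row in self.truth:
                fh.write(f"{row.protein_id}\t{row.kind}\t{int(row.expected_hit)}\t"
                         f"{row.fails_at or '.'}\t{','.join(row.reference_ids) or '.'}\n")


_REF_ARCHETYPES = ("helix_hairpin", "helix", "strand")


def _plant_sequence(ref_seq: str, length: int, rng: np.random.Generator,
                    references: list[ProteinRecord]) -> str:
    """A sequence with no detectable similarity to any reference but an
    acidic composition, emulating the remote-homolog regime where only the
    fold is conserved."""
    for attempt in range(50):
        seq = _random_residues(length, rng, acid_fraction=0.30,
                               base_fraction=0.03)
        retained, _ = seqcluster.divergence_filter(
            [ProteinRecord("tmp", seq)], references)
        if retained and physchem.isoelectric_point(seq) <= 6.5:
            return seq
    raise RuntimeError("could not draw a divergent acidic plant sequence")


def gen_screen_fixture(config: GeneratorConfig) -> ScreenFixture:
    """Synthetic protein catalog + structures + domain table + references,
    with a truth table recording what each screen stage should do.

    Decoys cover every exclusion stage: oversize (> 200 aa), basic
    (pI > 7), reference-similar sequences, CDD-annotated, structure-less,
    and well-behaved decoys with a non-reference fold. Plants are structural
    homologs of the references (perturbed reference fold, divergent acidic
    sequence).
    """
    rng = np.random.default_rng(config.seed)
    # references: distinct archetypes so cross-reference TM stays low
    references: list[ProteinRecord] = []
    reference_structures: dict[str, StructureModel] = {}
    ref_len = {"helix_hairpin": 90, "helix": 70, "strand": 64}
    for k, arch in enumerate(_REF_ARCHETYPES):
        rid = f"acr_ref_{k + 1}"
        fold = gen_fold(arch, ref_len[arch], seed=int(rng.integers(2**31)))
        seq = _random_residues(len(fold), rng, acid_fraction=0.28,
                               base_fraction=0.04)
        references.append(ProteinRecord(rid, seq))
        reference_structures[rid] = StructureModel(rid, fold.coords, seq)

    catalog: list[ProteinRecord] = []
    structures: dict[str, StructureModel] = {}
    domains: list[DomainAnnotation] = []
    truth: list[TruthRow] = []

    def add(rec: ProteinRecord, row: TruthRow,
            model: StructureModel | None = None) -> None:
        catalog.append(rec)
        truth.append(row)
        if model is not None:
            structures[rec.protein_id] = StructureModel(
                rec.protein_id, model.coords, rec.sequence)

    # planted structural homologs
    ref_by_id = {r.protein_id: r for r in references}
    for k, spec in enumerate(config.planted):
        ref = ref_by_id[spec.reference_id]
        pid = f"plant_{k + 1}"
        seq = _plant_sequence(ref.sequence, ref.length, rng, references)
        fold = perturb_structure(reference_structures[ref.protein_id],
                                 spec.sigma, spec.rigid,
                                 seed=int(rng.integers(2**31)))
        add(ProteinRecord(pid, seq),
            TruthRow(pid, "plant", True, None, (ref.protein_id,)), fold)

    # decoys, cycling through the failure modes
    lo, hi = config.length_range
    n = config.n_decoys
    kinds = (["oversize"] * max(1, n // 8) + ["basic"] * max(1, n // 8)
             + ["refsim"] * max(1, n // 10) + ["domained"] * max(1, n // 8)
             + ["nostructure"] * max(1, n // 10))
    kinds += ["clean"] * (n - len(kinds))
    for k, kind in enumerate(kinds[:n]):
        pid = f"decoy_{k + 1:03d}"
        length = int(rng.integers(lo, hi + 1))
        if kind == "oversize":
            length = int(rng.integers(205, 260))
            seq = _random_residues(length, rng, config.acid_fraction,
                                   config.base_fraction)
            row = TruthRow(pid, "decoy", False, "length")
        elif kind == "basic":
            seq = _random_residues(length, rng, acid_fraction=0.02,
                                   base_fraction=0.30)
            row = TruthRow(pid, "decoy", False, "pi")
        elif kind == "refsim":
            ref = references[k % len(references)]
            seq = mutate_to_identity(ref.sequence, 0.5,
                                     seed=int(rng.integers(2**31)))
            row = TruthRow(pid, "decoy", False, "divergence")
        else:
            seq = _random_residues(length, rng, config.acid_fraction,
                                   config.base_fraction)
            row = TruthRow(pid, "decoy", False,
                           "domain" if kind == "domained"
                           else "no_structure" if kind == "nostructure"
                           else "tm")
        if kind == "domained":
            domains.append(DomainAnnotation(pid, f"pfam{k:04d}",
                                            float(10.0 ** -rng.integers(3, 12))))
        model = None
        if kind in ("clean", "domained", "refsim", "basic"):
            model = gen_fold("coil", len(seq), seed=int(rng.integers(2**31)))
        add(ProteinRecord(pid, seq), row, model)

    return ScreenFixture(catalog, structures, domains, references,
                         reference_structures, truth)


# ---------------------------------------------------------------------------
# Defense genomes (annotated contigs with planted islands and marker)

@dataclass
class RegionTruth:
    genome_id: str
    contig_id: str
    left_name: str
    right_name: str
    gap_bp: int
    intervening_ids: tuple[str, ...]


@dataclass
class DefenseGenomesFixture:
    systems: list[DefenseSystemAnnotation]
    genes: list[ProteinRecord]               # all with coordinates
    intervening_structures: dict[str, StructureModel]
    domains: list[DomainAnnotation]
    defense_refs: list[ProteinRecord]
    defense_ref_structures: dict[str, StructureModel]
    marker_carriers: set[str]                # genome ids carrying the marker
    truth_regions: list[RegionTruth]
    truth_total_brex: int
    planted_candidate_ids: tuple[str, ...]   # defense-screen plants

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "pdb").mkdir(parents=True, exist_ok=True)
        (outdir / "refs_pdb").mkdir(parents=True, exist_ok=True)
        write_defense_table(self.systems, outdir / "systems.tsv")
        write_fasta(self.genes, outdir / "genes.fasta")
        with open(outdir / "genes.tsv", "w") as fh:
            fh.write("protein_id\tgenome_id\tcontig_id\tstart\tend\tstrand\n")
            for g in self.genes:
                fh.write(f"{g.protein_id}\t{g.genome_id}\t{g.contig_id}\t"
                         f"{g.start}\t{g.end}\t{g.strand}\n")
        write_domain_table(self.domains, outdir / "domains.tsv")
        write_fasta(self.defense_refs, outdir / "refs.fasta")
        for pid, model in sorted(self.intervening_structures.items()):
            write_ca_trace(model, outdir / "pdb" / f"{pid}.pdb")
        for pid, model in sorted(self.defense_ref_structures.items()):
            write_ca_trace(model, outdir / "refs_pdb" / f"{pid}.pdb")
        with open(outdir / "marker_hits.tsv", "w") as fh:
            fh.write("genome_id\n")
            for gid in sorted(self.marker_carriers):
                fh.write(gid + "\n")


_SYSTEM_POOL = ("BREX_type_3", "RM_type_I", "CBASS_type_II", "Thoeris_type_I",
                "Gabija", "Wadjet")


def gen_defense_genomes(config: GeneratorConfig) -> DefenseGenomesFixture:
    """Annotated toy genomes with planted defense islands and a rare marker.

    Each genome is one contig carrying a BREX system plus further systems
    from a small pool; consecutive inter-system gaps are drawn inside
    [1000, 15000] bp with probability ``gap_inside_prob`` and outside it
    otherwise. Genes fully inside the in-window gaps are the plantable
    intervening proteins; boundary-straddling genes are also placed (and
    must NOT be counted by the miner). The marker gene is planted in a
    BREX-adjacent in-window gap of exactly ``round(marker_prevalence *
    n_genomes)`` genomes, so prevalence recovery is exact. One planted
    defense candidate (a ≥200 aa structural homolog of a reference
    single-gene system) appears among the intervening proteins of the first
    carrier genomes; decoy intervening proteins come from a small redundant
    sequence pool, many with domain annotations or sub-200-aa lengths, so
    every defense-screen stage is exercised.
    """
    rng = np.random.default_rng(config.seed + 1)

    # reference single-gene defense systems (distinct archetypes)
    refs: list[ProteinRecord] = []
    ref_structs: dict[str, StructureModel] = {}
    for k, (arch, ln) in enumerate((("helix_hairpin", 220), ("helix", 230))):
        rid = f"defense_ref_{k + 1}"
        fold = gen_fold(arch, ln, seed=int(rng.integers(2**31)))
        seq = _random_residues(ln, rng)
        refs.append(ProteinRecord(rid, seq))
        ref_structs[rid] = StructureModel(rid, fold.coords, seq)

    # redundant decoy sequence pool (keeps 50%-identity clustering cheap
    # and emulates catalog redundancy)
    pool_big = [_random_residues(int(rng.integers(200, 260)), rng)
                for _ in range(6)]
    pool_small = [_random_residues(int(rng.integers(80, 180)), rng)
                  for _ in range(6)]

    n_carriers = round(config.marker_prevalence * config.genomes)
    marker_seq = _random_residues(150, rng)
    plant_seq = _plant_sequence(refs[0].sequence, 220, rng, refs)
    plant_fold_base = ref_structs["defense_ref_1"]

    systems: list[DefenseSystemAnnotation] = []
    genes: list[ProteinRecord] = []
    structures: dict[str, StructureModel] = {}
    domains: list[DomainAnnotation] = []
    truth_regions: list[RegionTruth] = []
    carriers: set[str] = set()
    planted_ids: list[str] = []

    gene_serial = 0

    def new_gene(genome: str, contig: str, start: int, end: int,
                 seq: str) -> ProteinRecord:
        nonlocal gene_serial
        gene_serial += 1
        rec = ProteinRecord(f"g{gene_serial:06d}", seq, genome_id=genome,
                            contig_id=contig, start=start, end=end,
                            strand="+" if rng.random() < 0.5 else "-")
        genes.append(rec)
        return rec

    for gnum in range(config.genomes):
        genome = f"MAG{gnum + 1:05d}"
        contig = f"{genome}_c1"
        n_sys = int(rng.integers(config.systems_per_genome[0],
                                 config.systems_per_genome[1] + 1))
        names = ["BREX_type_3"] + [
            _SYSTEM_POOL[int(rng.integers(1, len(_SYSTEM_POOL)))]
            for _ in range(n_sys - 1)
        ]
        is_carrier = gnum < n_carriers
        if is_carrier:
            carriers.add(genome)
        pos = 1000
        placed: list[DefenseSystemAnnotation] = []
        for s, name in enumerate(names):
            width = int(rng.integers(4000, 9000))
            sys_genes = []
            gpos = pos
            while gpos < pos + width - 600:
                glen = int(rng.integers(300, 900))
                rec = new_gene(genome, contig, gpos,
                               min(gpos + glen, pos + width), "M" + pool_small[
                                   int(rng.integers(len(pool_small)))][:40])
                sys_genes.append(rec.protein_id)
                gpos += glen + 50
            ann = DefenseSystemAnnotation(genome, contig, name, pos,
                                          pos + width, "+", sys_genes)
            systems.append(ann)
            placed.append(ann)
            if s == len(names) - 1:
                break
            # draw the gap to the next system
            force_inside = is_carrier and s == 0
            inside = force_inside or rng.random() < config.gap_inside_prob
            if inside:
                gap = int(rng.integers(2500, 14000))
            else:
                gap = int(rng.integers(100, 900)) if rng.random() < 0.5 \
                    else int(rng.integers(15500, 25000))
            gap_start, gap_end = ann.end, ann.end + gap + 1  # open interval
            intervening: list[str] = []
            if inside and gap >= 2000:
                cursor = gap_start + 120
                budget = 2 if not force_inside else 3
                slot = 0
                while slot < budget and cursor + 700 < gap_end - 120:
                    if force_inside and slot == 0:
                        rec = new_gene(genome, contig, cursor,
                                       cursor + 3 * 150, marker_seq)
                    elif force_inside and slot == 1 and gnum < 3:
                        rec = new_gene(genome, contig, cursor,
                                       cursor + 3 * 220, plant_seq)
                        structures[rec.protein_id] = StructureModel(
                            rec.protein_id,
                            perturb_structure(
                                plant_fold_base, 0.8, True,
                                seed=int(rng.integers(2**31))).coords,
                            plant_seq)
                        planted_ids.append(rec.protein_id)
                    else:
                        big = rng.random() < 0.5
                        seq = (pool_big if big else pool_small)[
                            int(rng.integers(6))]
                        seq = _light_mutate(seq, rng)
                        rec = new_gene(genome, contig, cursor,
                                       cursor + 3 * len(seq), seq)
                        if rng.random() < 0.6:
                            domains.append(DomainAnnotation(
                                rec.protein_id, "cdd_hit",
                                float(10.0 ** -rng.integers(3, 10))))
                        else:
                            structures[rec.protein_id] = gen_fold(
                                "coil", len(seq),
                                seed=int(rng.integers(2**31)))
                    intervening.append(rec.protein_id)
                    cursor = rec.end + int(rng.integers(150, 400))
                    slot += 1
                # one boundary-straddling gene that must not be counted
                if rng.random() < 0.3:
                    new_gene(genome, contig, gap_end - 200, gap_end + 400,
                             pool_small[int(rng.integers(6))])
            if 1000 <= gap <= 15000:
                truth_regions.append(RegionTruth(
                    genome, contig, name, names[s + 1], gap,
                    tuple(intervening)))
            pos = gap_end

    # the marker has no structure and no domain hit; give it a domain-free
    # record in the domain table implicitly (absence)
    return DefenseGenomesFixture(
        systems=systems, genes=genes, intervening_structures=structures,
        domains=domains, defense_refs=refs,
        defense_ref_structures=ref_structs,
        marker_carriers=carriers, truth_regions=truth_regions,
        truth_total_brex=config.genomes,
        planted_candidate_ids=tuple(planted_ids),
    )


def _light_mutate(seq: str, rng: np.random.Generator) -> str:
    """A handful of substitutions (~2%), keeping ≥95% identity to the pool
    ancestor so 50%-identity clustering collapses each family."""
    s = list(seq)
    for _ in range(max(1, len(s) // 50)):
        pos = int(rng.integers(len(s)))
        s[pos] = _AA20[int(rng.integers(20))]
    return "".join(s)
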